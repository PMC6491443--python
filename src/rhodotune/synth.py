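"""Synthetic inputs with the statistical structure the analyses assume.

Every pipeline stage can be exercised without downloads: a toy all-*trans*
retinal PDB with configurable bond-length alternation and dihedral twists, a
point-charge cavity with Thr-like / Ser-like dipoles or anions, the printed
excitation-energy table, Gaussian-band bleach spectrum pairs, saturating pH
traces and sequential-photocycle transient-absorption matrices.

Printed study numbers (absorption maxima, the 4.8 ms wild-type turnover, the
0.1160 wild-type BLA, the 0-150 s illumination window) enter these
generators only as *parameters*; nothing here asserts them as results. All
stochastic output is reproducible under a fixed seed (documented default
20190430).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .assays import AbsorptionSpectrum, PhTrace
from .electrostatics import PointChargeEnvironment, Site
from .errors import GenerationError
from .geometry import (
    CHAIN_ATOMS,
    ChromophoreGeometry,
    _dihedral,
)
from .kinetics import PhotocycleScheme, TransientAbsorptionData, simulate_ta
from .constants import NM_CM_FACTOR

__all__ = [
    "DEFAULT_SEED",
    "FixtureSpec",
    "make_retinal_pdb",
    "make_chain_geometry",
    "make_charge_env",
    "make_excitation_table",
    "make_spectrum_pair",
    "make_ph_trace",
    "make_ta",
]

DEFAULT_SEED = 20190430

_DOUBLE_LENGTH = 1.35  # Angstrom, reference double-bond length
_CE_LENGTH = 1.47
_BOND_ANGLE = 120.0  # degrees, sp2 zig-zag


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request; equal specs yield identical output."""

    seed: int
    kind: str  # retinal_pdb | charge_env | ta_matrix | spectrum_pair | ph_trace | excitation_table
    parameters: dict = field(default_factory=dict)


def _zigzag_chain(bond_lengths: Sequence[float]) -> np.ndarray:
    """Planar all-trans chain in the xy-plane with 120-degree bond angles."""
    half = math.radians(180.0 - _BOND_ANGLE) / 2.0
    directions = [
        np.array([math.cos(half), math.sin(half) * (+1 if i % 2 == 0 else -1), 0.0])
        for i in range(len(bond_lengths))
    ]
    coords = [np.zeros(3)]
    for d, u in zip(bond_lengths, directions):
        coords.append(coords[-1] + d * u)
    return np.array(coords)


def _set_dihedral(
    coords: np.ndarray, names: Sequence[str], central: tuple[int, int], target: float
) -> np.ndarray:
    """Rotate tail atoms about a central bond so the dihedral equals target."""
    i, j = central
    quad = coords[[i - 1, i, j, j + 1]]
    current = _dihedral(*quad)
    axis = coords[j] - coords[i]
    axis = axis / np.linalg.norm(axis)
    out = coords.copy()
    for delta in (target - current, -(target - current)):
        rot = Rotation.from_rotvec(np.radians(delta) * axis)
        cand = coords.copy()
        cand[j + 1 :] = rot.apply(coords[j + 1 :] - coords[j]) + coords[j]
        achieved = _dihedral(cand[i - 1], cand[i], cand[j], cand[j + 1])
        if abs((achieved - target + 180.0) % 360.0 - 180.0) < 1e-8:
            out = cand
            break
    return out


def make_chain_geometry(
    bla_target: float = 0.1160,
    twists: Optional[Mapping[str, float]] = None,
    source_label: str = "synthetic retinal",
) -> ChromophoreGeometry:
    """Toy retinal chain (C5..C15, N, CE) with requested BLA and twists.

    ``twists`` maps a dihedral name (by central bond, e.g. ``"C15-N"``) to a
    deviation from planarity in degrees, limited to +-90. The built geometry
    recovers ``bla_target`` exactly under the package BLA convention.
    """
    if not (0.0 <= bla_target <= 0.2):
        raise GenerationError(f"bla_target {bla_target} outside [0, 0.2] A")
    single = _DOUBLE_LENGTH + bla_target
    # bonds C5-C6 .. C15-N alternate double/single starting with C5=C6
    lengths = [(_DOUBLE_LENGTH if i % 2 == 0 else single) for i in range(11)]
    lengths.append(_CE_LENGTH)  # N-CE
    names = CHAIN_ATOMS + ("CE",)
    coords = _zigzag_chain(lengths)
    if twists:
        path = list(names)
        valid = {f"{path[i]}-{path[i + 1]}": (i, i + 1) for i in range(1, len(path) - 2)}
        for dname, twist in twists.items():
            if dname not in valid:
                raise GenerationError(f"no twistable dihedral named {dname!r}")
            if not (-90.0 < float(twist) < 90.0):
                raise GenerationError(f"twist {dname}={twist} outside (-90, 90) deg")
            target = 180.0 - float(twist)
            coords = _set_dihedral(coords, names, valid[dname], target)
    return ChromophoreGeometry(names=names, coords=coords, source_label=source_label)


def _pdb_atom_line(
    serial: int, name: str, altloc: str, res_name: str, res_id: int,
    xyz: np.ndarray, occupancy: float, element: str,
) -> str:
    return (
        f"HETATM{serial:5d}  {name:<3s}{altloc:1s}{res_name:<3s} A{res_id:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occupancy:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def make_retinal_pdb(
    bla_target: float = 0.1160,
    twists: Optional[Mapping[str, float]] = None,
    seed: int = DEFAULT_SEED,
    residue_name: str = "RET",
    altloc_atom: Optional[str] = None,
    altloc_occupancies: tuple[float, float] = (0.7, 0.3),
    altloc_displacement: float = 0.8,
) -> str:
    """PDB text for a toy retinal chromophore.

    With ``altloc_atom`` set, that atom is written twice as altloc A/B with
    the given occupancies; the B conformer is displaced by
    ``altloc_displacement`` Angstrom along +z, so occupancy-based altloc
    resolution is observable downstream. ``seed`` is accepted for interface
    uniformity; the geometry itself is deterministic.
    """
    geom = make_chain_geometry(bla_target, twists)
    lines = [
        "HEADER    SYNTHETIC RETINAL CHROMOPHORE FIXTURE",
        f"REMARK 999 toy all-trans chain, target BLA {bla_target:.4f} A",
    ]
    serial = 1
    for name in geom.names:
        xyz = geom.position(name)
        element = "N" if name == "N" else "C"
        if name == altloc_atom:
            lines.append(
                _pdb_atom_line(serial, name, "A", residue_name, 301, xyz,
                               altloc_occupancies[0], element)
            )
            serial += 1
            displaced = xyz + np.array([0.0, 0.0, altloc_displacement])
            lines.append(
                _pdb_atom_line(serial, name, "B", residue_name, 301, displaced,
                               altloc_occupancies[1], element)
            )
        else:
            lines.append(
                _pdb_atom_line(serial, name, " ", residue_name, 301, xyz, 1.0, element)
            )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


_MIN_PLACEMENT = 2.5  # Angstrom
_DIPOLE_SEPARATION = 0.96  # O-H like


def _placement_direction(geometry: ChromophoreGeometry, anchor: str) -> np.ndarray:
    """Out-of-plane normal at the anchor atom (clears the chain on both sides)."""
    path = geometry.chain_path()
    i = path.index(anchor)
    tri = path[max(0, i - 1) : i + 2]
    if len(tri) < 3:  # chain terminus: use the first three atoms from it
        tri = path[:3] if i == 0 else path[-3:]
    p0, p1, p2 = (geometry.position(a) for a in tri)
    v = np.cross(p1 - p0, p2 - p1)
    n = np.linalg.norm(v)
    if n < 1e-9:
        v, n = np.array([0.0, 0.0, 1.0]), 1.0
    return v / n


def _check_clash(positions: Sequence[np.ndarray], geometry: ChromophoreGeometry) -> None:
    for p in positions:
        d = np.linalg.norm(geometry.coords - p, axis=1).min()
        if d < _MIN_PLACEMENT:
            raise GenerationError(
                f"placement {d:.2f} A from the chromophore (< {_MIN_PLACEMENT} A)"
            )


def make_charge_env(
    style: str,
    geometry: ChromophoreGeometry,
    distance: float = 3.5,
    dipole_charge: float = 0.4,
    seed: int = DEFAULT_SEED,
    residue_id: Optional[int] = None,
    position: Optional[np.ndarray] = None,
    sites: Optional[Sequence[Site]] = None,
    formal_charges: Optional[Mapping[int, float]] = None,
) -> PointChargeEnvironment:
    """Point-charge cavity fragments oriented like the study's key residues.

    Styles:

    * ``thr_near_ionone`` — net-neutral O-H-like dipole with its negative
      pole facing the beta-ionone carbon C5 (Thr219-like, red-shifting);
    * ``ser_near_schiff`` — the same dipole with its negative pole facing
      the Schiff-base nitrogen (Ser254-like, blue-shifting; its removal is
      the S254A analogue);
    * ``anion_at`` — one full -1 e charge at ``position``;
    * ``custom`` — caller-supplied ``sites`` and ``formal_charges``.
    """
    if style == "custom":
        return PointChargeEnvironment(
            sites=tuple(sites or ()), formal_charges=dict(formal_charges or {})
        )
    if style == "anion_at":
        if position is None:
            raise GenerationError("anion_at requires a position")
        pos = np.asarray(position, dtype=float)
        _check_clash([pos], geometry)
        rid = 999 if residue_id is None else residue_id
        return PointChargeEnvironment(
            sites=(Site(rid, "CLA", "CL", pos, -1.0),),
            formal_charges={rid: -1.0},
        )
    if style not in ("thr_near_ionone", "ser_near_schiff"):
        raise GenerationError(f"unknown charge-environment style {style!r}")
    anchor, default_rid, res_name, o_name, h_name = (
        ("C5", 219, "THR", "OG1", "HG1")
        if style == "thr_near_ionone"
        else ("N", 254, "SER", "OG", "HG")
    )
    rid = default_rid if residue_id is None else residue_id
    direction = _placement_direction(geometry, anchor)
    p_neg = geometry.position(anchor) + distance * direction
    p_pos = p_neg + _DIPOLE_SEPARATION * direction
    _check_clash([p_neg, p_pos], geometry)
    return PointChargeEnvironment(
        sites=(
            Site(rid, res_name, o_name, p_neg, -dipole_charge),
            Site(rid, res_name, h_name, p_pos, +dipole_charge),
        ),
        formal_charges={rid: 0.0},
    )


def make_excitation_table() -> pd.DataFrame:
    """The published excitation-energy decomposition rows, exactly as printed.

    Columns: protein/vacuum gaps (kcal/mol), the printed electrostatic
    column, and the printed parenthetical deltas versus the wild type
    (NaN for the wild-type row). Bookkeeping input only.
    """
    rows = [
        ("KR2 WT", 55.2, 43.1, 12.1, np.nan, np.nan, np.nan),
        ("P219G", 54.3, 43.8, 10.5, -0.9, 0.7, -1.6),
        ("P219T", 53.5, 44.5, 9.0, -1.7, 1.3, -3.1),
        ("S254A", 53.1, 43.6, 9.5, -2.1, 0.5, -2.6),
        ("P219T/S254A", 51.5, 45.9, 5.6, -3.7, 2.7, -6.5),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "label", "dE_protein", "dE_vacuum", "printed_electrostatic",
            "printed_delta_protein", "printed_delta_vacuum",
            "printed_delta_electrostatic",
        ],
    )


def make_spectrum_pair(
    lambda_max: float = 542.0,
    noise_sigma: float = 0.002,
    seed: int = DEFAULT_SEED,
    amplitude: float = 0.5,
    band_sigma_wavenumber: float = 1700.0,
    baseline: float = 0.1,
    oxime_center_nm: float = 360.0,
    grid_nm: tuple[float, float, float] = (330.0, 750.0, 1.0),
) -> tuple[AbsorptionSpectrum, AbsorptionSpectrum]:
    """Before/after hydroxylamine-bleach spectrum pair.

    The "before" spectrum carries the chromophore band at ``lambda_max``;
    "after" replaces it with a retinal-oxime band in the near UV. Both get
    independent Gaussian noise of sd ``noise_sigma`` AU.
    """
    rng = np.random.default_rng(seed)
    w = np.arange(*grid_nm, dtype=float)
    nu = NM_CM_FACTOR / w

    def band(center_nm: float, amp: float, sigma: float) -> np.ndarray:
        nu0 = NM_CM_FACTOR / center_nm
        return amp * np.exp(-0.5 * ((nu - nu0) / sigma) ** 2)

    before = baseline + band(lambda_max, amplitude, band_sigma_wavenumber)
    after = baseline + band(oxime_center_nm, amplitude * 1.1, 2000.0)
    if noise_sigma:
        before = before + rng.normal(0.0, noise_sigma, w.shape)
        after = after + rng.normal(0.0, noise_sigma, w.shape)
    return (
        AbsorptionSpectrum(w, before, label=f"before bleach ({lambda_max:g} nm)"),
        AbsorptionSpectrum(w, after, label="after bleach"),
    )


def make_ph_trace(
    slope: float = 1e-3,
    tau_s: float = 60.0,
    illumination: tuple[float, float] = (0.0, 150.0),
    t_start: float = -30.0,
    t_end: float = 300.0,
    rate_hz: float = 1.0,
    noise_sigma: float = 5e-5,
    seed: int = DEFAULT_SEED,
    ph0: float = 7.0,
) -> PhTrace:
    """Saturating light-on pH trace with initial slope ``slope`` (pH/s).

    During illumination pH follows ph0 + A(1 - exp(-t/tau)) with A = slope *
    tau, so the true initial rate equals ``slope``; after light-off it
    relaxes back exponentially.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(t_start, t_end + 0.5 / rate_hz, 1.0 / rate_hz)
    t_on, t_off = illumination
    amp = slope * tau_s
    ph = np.full_like(t, ph0)
    on = (t >= t_on) & (t <= t_off)
    ph[on] = ph0 + amp * (1.0 - np.exp(-(t[on] - t_on) / tau_s))
    after = t > t_off
    peak = amp * (1.0 - np.exp(-(t_off - t_on) / tau_s))
    ph[after] = ph0 + peak * np.exp(-(t[after] - t_off) / (2.0 * tau_s))
    if noise_sigma:
        ph = ph + rng.normal(0.0, noise_sigma, t.shape)
    return PhTrace(times=t, ph=ph, illumination_window=illumination)


def make_ta(
    turnover_s: float = 4.8e-3,
    n_wavelengths: int = 50,
    n_times: int = 200,
    t_range_s: tuple[float, float] = (1e-6, 0.2),
    wavelength_range_nm: tuple[float, float] = (380.0, 700.0),
    noise_sigma: float = 0.002,
    n_averages: int = 90,
    seed: int = DEFAULT_SEED,
    scheme: Optional[PhotocycleScheme] = None,
) -> TransientAbsorptionData:
    """Transient-absorption matrix from a KR2-like 4-intermediate chain.

    Defaults mirror the flash-photolysis conditions the analyses assume:
    log-spaced times, 0.002 AU shot noise reduced by 90-trace averaging, and
    a final decay equal to the wild-type 4.8 ms turnover.
    """
    if scheme is None:
        scheme = PhotocycleScheme.kr2_like(turnover_s)
    wavelengths = np.linspace(*wavelength_range_nm, n_wavelengths)
    times = np.geomspace(*t_range_s, n_times)
    return simulate_ta(
        scheme, wavelengths, times,
        noise_sigma=noise_sigma, seed=seed, n_averages=n_averages,
    )


_FIXTURE_MAKERS = {
    "retinal_pdb": lambda p, seed: make_retinal_pdb(seed=seed, **p),
    "charge_env": lambda p, seed: make_charge_env(seed=seed, **p),
    "excitation_table": lambda p, seed: make_excitation_table(**p),
    "spectrum_pair": lambda p, seed: make_spectrum_pair(seed=seed, **p),
    "ph_trace": lambda p, seed: make_ph_trace(seed=seed, **p),
    "ta_matrix": lambda p, seed: make_ta(seed=seed, **p),
}


def make_fixture(spec: FixtureSpec):
    """Dispatch a :class:`FixtureSpec` to its generator."""
    try:
        maker = _FIXTURE_MAKERS[spec.kind]
    except KeyError:
        raise GenerationError(f"unknown fixture kind {spec.kind!r}") from None
    return maker(dict(spec.parameters), spec.seed)
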