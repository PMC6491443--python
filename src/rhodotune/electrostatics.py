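"""Two-state point-charge surrogate for vertical excitation energies.

The visible absorption of a retinal protein is set by the S1-S0 energy gap
of its protonated Schiff-base chromophore. The protein environment tunes
that gap electrostatically: the S0 state carries its +1e charge mostly on
the Schiff-base end, while in S1 the charge delocalizes toward the
beta-ionone ring. An environment charge therefore interacts *differently*
with the two states, and the difference of Coulomb energies

    dE_electrostatic = V(S1 charges, env) - V(S0 charges, env)

is the electrostatic contribution to the gap. The total gap decomposes as

    dE_protein = dE_vacuum + dE_electrostatic,

where ``dE_vacuum`` is the gas-phase gap of the chromophore at its in-protein
geometry (supplied by the caller: a published value, an external engine, or
:func:`surrogate_vacuum_energy`). A red-shifting perturbation lowers
``dE_protein``.

Per-residue attribution follows the charge-off recipe: zero one residue's
point charges, recompute the gap (``dE_off``); the residue's contribution is
``dE_protein - dE_off``. Because Coulomb energies are linear in the
environment charges, these contributions sum exactly to the total
electrostatic term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import constants
from .errors import (
    ConfigurationError,
    ConsistencyError,
    DomainError,
    LookupError_,
    SingularityError,
)
from .geometry import CHAIN_ATOMS, ChromophoreGeometry, ConjugationMetrics

__all__ = [
    "ChromophoreChargeModel",
    "Site",
    "PointChargeEnvironment",
    "ExcitationDecomposition",
    "ChargeOffResult",
    "state_potential_energy",
    "vertical_excitation",
    "decompose_printed",
    "charge_off",
    "charge_off_all",
    "compare_charge_off",
    "surrogate_vacuum_energy",
    "flag_printed_deltas",
]

_CHARGE_TOL = 1e-6
_MIN_SEPARATION = 0.5  # Angstrom


@dataclass(frozen=True)
class ChromophoreChargeModel:
    """Per-atom partial charges (units of e) of the chromophore in S0 and S1.

    Both states carry a net charge of +1e (protonated Schiff base). The
    default set is illustrative rather than ab initio: it is constructed to
    be sign- and trend-correct, with S0 charge concentrated on the
    Schiff-base end (N, C15, C13) and S1 charge shifted toward the
    beta-ionone ring.
    """

    atoms: tuple[str, ...]
    q_s0: np.ndarray
    q_s1: np.ndarray

    def __post_init__(self) -> None:
        q0 = np.asarray(self.q_s0, dtype=float)
        q1 = np.asarray(self.q_s1, dtype=float)
        object.__setattr__(self, "q_s0", q0)
        object.__setattr__(self, "q_s1", q1)
        if q0.shape != (len(self.atoms),) or q1.shape != (len(self.atoms),):
            raise ConsistencyError("charge arrays must match the atom list")
        for name, q in (("S0", q0), ("S1", q1)):
            if abs(float(q.sum()) - 1.0) > _CHARGE_TOL:
                raise DomainError(
                    f"{name} charges must sum to +1 e, got {float(q.sum()):.8f}"
                )

    @classmethod
    def default(cls) -> "ChromophoreChargeModel":
        atoms = CHAIN_ATOMS
        q0 = np.zeros(len(atoms))
        majors0 = {"N": 0.45, "C15": 0.25, "C13": 0.15}
        rest = [a for a in atoms if a not in majors0]
        for a, q in majors0.items():
            q0[atoms.index(a)] = q
        remainder = 1.0 - sum(majors0.values())
        for a in rest:
            q0[atoms.index(a)] = remainder / len(rest)
        q1 = np.zeros(len(atoms))
        for a, q in {
            "N": 0.15, "C13": 0.15, "C11": 0.15, "C9": 0.15, "C7": 0.15, "C5": 0.25,
        }.items():
            q1[atoms.index(a)] = q
        return cls(atoms=atoms, q_s0=q0, q_s1=q1)

    def charges(self, state: str) -> np.ndarray:
        if state == "S0":
            return self.q_s0
        if state == "S1":
            return self.q_s1
        raise LookupError_(state)


def charge_centroid(
    model: ChromophoreChargeModel, geom: ChromophoreGeometry, state: str
) -> np.ndarray:
    """Charge-weighted centroid of one electronic state (net charge +1e)."""
    pos = np.array([geom.position(a) for a in model.atoms])
    q = model.charges(state)
    return pos.T @ q / float(q.sum())


@dataclass(frozen=True)
class Site:
    """One environment point charge."""

    residue_id: int
    residue_name: str
    atom_name: str
    position: np.ndarray  # (3,) Angstrom
    charge: float  # e

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


@dataclass(frozen=True)
class PointChargeEnvironment:
    """Residue-grouped point charges around the chromophore.

    ``formal_charges`` declares each residue's net formal charge (0 for
    neutral residues); the summed site charges must match it to 1e-6 e.
    """

    sites: tuple[Site, ...]
    formal_charges: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        totals: dict[int, float] = {}
        for s in self.sites:
            totals[s.residue_id] = totals.get(s.residue_id, 0.0) + s.charge
        for rid, total in totals.items():
            formal = float(self.formal_charges.get(rid, 0.0))
            if abs(total - formal) > _CHARGE_TOL:
                raise DomainError(
                    f"residue {rid} net charge {total:.6f} e differs from "
                    f"declared formal charge {formal:.6f} e"
                )

    def residue_ids(self) -> tuple[int, ...]:
        seen: dict[int, None] = {}
        for s in self.sites:
            seen.setdefault(s.residue_id)
        return tuple(seen)

    def without_residue(self, residue_id: int) -> "PointChargeEnvironment":
        """Environment with one residue's charges zeroed (charge-off)."""
        if residue_id not in self.residue_ids():
            raise LookupError_(residue_id)
        kept = tuple(s for s in self.sites if s.residue_id != residue_id)
        formal = {k: v for k, v in dict(self.formal_charges).items() if k != residue_id}
        return PointChargeEnvironment(sites=kept, formal_charges=formal)

    def scaled(self, factor: float) -> "PointChargeEnvironment":
        sites = tuple(replace(s, charge=s.charge * factor) for s in self.sites)
        formal = {k: v * factor for k, v in dict(self.formal_charges).items()}
        return PointChargeEnvironment(sites=sites, formal_charges=formal)

    def positions(self) -> np.ndarray:
        if not self.sites:
            return np.zeros((0, 3))
        return np.array([s.position for s in self.sites])

    def charges(self) -> np.ndarray:
        return np.array([s.charge for s in self.sites])


def state_potential_energy(
    geom: ChromophoreGeometry,
    atom_charges: Mapping[str, float] | np.ndarray,
    env: PointChargeEnvironment,
    atoms: Sequence[str] = CHAIN_ATOMS,
    dielectric: float = 1.0,
) -> float:
    """Coulomb energy (kcal/mol) between chromophore charges and environment.

    No cutoff; the dielectric divides the whole sum (1 = vacuum Coulomb).
    """
    if not env.sites:
        return 0.0
    if isinstance(atom_charges, Mapping):
        q_chr = np.array([atom_charges[a] for a in atoms], dtype=float)
    else:
        q_chr = np.asarray(atom_charges, dtype=float)
        if q_chr.shape != (len(atoms),):
            raise ConsistencyError("atom_charges must align with the atom list")
    pos_chr = np.array([geom.position(a) for a in atoms])
    pos_env = env.positions()
    r = np.linalg.norm(pos_chr[:, None, :] - pos_env[None, :, :], axis=-1)
    if float(r.min()) < _MIN_SEPARATION:
        raise SingularityError(
            f"environment site within {_MIN_SEPARATION} A of a chromophore atom"
        )
    q_env = env.charges()
    return float(constants.COULOMB_KCAL_A / dielectric * (q_chr @ (1.0 / r) @ q_env))


@dataclass(frozen=True)
class ExcitationDecomposition:
    """Vertical excitation energy split into geometric and electrostatic parts.

    All values in kcal/mol. ``dE_electrostatic = dE_protein - dE_vacuum``
    holds exactly. ``deltas_vs_reference`` (protein, vacuum, electrostatic)
    is present only when a reference decomposition was supplied.
    """

    label: str
    dE_protein: float
    dE_vacuum: float
    dE_electrostatic: float
    deltas_vs_reference: Optional[tuple[float, float, float]] = None


def vertical_excitation(
    geom: ChromophoreGeometry,
    charge_model: ChromophoreChargeModel,
    env: PointChargeEnvironment,
    dE_vacuum: float,
    label: str = "",
    dielectric: float = 1.0,
    reference: Optional[ExcitationDecomposition] = None,
) -> ExcitationDecomposition:
    """Excitation decomposition from the two-state point-charge model."""
    v0 = state_potential_energy(
        geom, charge_model.q_s0, env, charge_model.atoms, dielectric
    )
    v1 = state_potential_energy(
        geom, charge_model.q_s1, env, charge_model.atoms, dielectric
    )
    d_elec = v1 - v0
    return decompose_printed(label, dE_vacuum + d_elec, float(dE_vacuum), reference)


def decompose_printed(
    label: str,
    dE_protein: float,
    dE_vacuum: float,
    reference: Optional[ExcitationDecomposition] = None,
) -> ExcitationDecomposition:
    """Bookkeeping decomposition from protein and vacuum gap values."""
    dE_protein = float(dE_protein)
    dE_vacuum = float(dE_vacuum)
    if not (math.isfinite(dE_protein) and math.isfinite(dE_vacuum)):
        raise DomainError("excitation energies must be finite")
    d_elec = dE_protein - dE_vacuum
    deltas = None
    if reference is not None:
        deltas = (
            dE_protein - reference.dE_protein,
            dE_vacuum - reference.dE_vacuum,
            d_elec - reference.dE_electrostatic,
        )
    return ExcitationDecomposition(
        label=label,
        dE_protein=dE_protein,
        dE_vacuum=dE_vacuum,
        dE_electrostatic=d_elec,
        deltas_vs_reference=deltas,
    )


@dataclass(frozen=True)
class ChargeOffResult:
    """Per-residue spectral contribution from the charge-off recipe.

    ``contribution = dE_protein - dE_off`` (kcal/mol): positive means the
    residue blue-shifts the model, negative means it red-shifts it.
    """

    residue_id: int
    dE_off: float
    contribution: float
    classification: Optional[str] = None


def charge_off(
    geom: ChromophoreGeometry,
    charge_model: ChromophoreChargeModel,
    env: PointChargeEnvironment,
    dE_vacuum: float,
    residue_id: int,
    dielectric: float = 1.0,
) -> ChargeOffResult:
    """Contribution of one residue: gap with its charges zeroed vs the full gap."""
    full = vertical_excitation(geom, charge_model, env, dE_vacuum, dielectric=dielectric)
    off_env = env.without_residue(residue_id)
    off = vertical_excitation(geom, charge_model, off_env, dE_vacuum, dielectric=dielectric)
    return ChargeOffResult(
        residue_id=residue_id,
        dE_off=off.dE_protein,
        contribution=full.dE_protein - off.dE_protein,
    )


def charge_off_all(
    geom: ChromophoreGeometry,
    charge_model: ChromophoreChargeModel,
    env: PointChargeEnvironment,
    dE_vacuum: float,
    dielectric: float = 1.0,
) -> dict[int, ChargeOffResult]:
    """Charge-off contributions for every residue in the environment."""
    return {
        rid: charge_off(geom, charge_model, env, dE_vacuum, rid, dielectric)
        for rid in env.residue_ids()
    }


def compare_charge_off(
    variant: Mapping[int, ChargeOffResult],
    reference: Mapping[int, ChargeOffResult],
    mutated_sites: Sequence[int],
    tolerance: float = 0.01,
) -> list[ChargeOffResult]:
    """Classify per-residue contribution changes between two models.

    Residues at declared ``mutated_sites`` are classified ``direct`` (the
    point charges themselves changed). Conserved residues whose contribution
    changed by more than ``tolerance`` kcal/mol are ``indirect`` (environment
    reorganization). Returns one row per residue present in either model,
    with ``contribution`` holding the variant-minus-reference difference.
    """
    if not mutated_sites:
        raise ConfigurationError("at least one mutated site must be declared")
    mutated = set(int(m) for m in mutated_sites)
    rows: list[ChargeOffResult] = []
    for rid in sorted(set(variant) | set(reference)):
        c_var = variant[rid].contribution if rid in variant else 0.0
        c_ref = reference[rid].contribution if rid in reference else 0.0
        diff = c_var - c_ref
        if rid in mutated:
            cls = "direct"
        elif abs(diff) > tolerance:
            cls = "indirect"
        else:
            cls = "unchanged"
        off_var = variant[rid].dE_off if rid in variant else math.nan
        rows.append(
            ChargeOffResult(
                residue_id=rid, dE_off=off_var, contribution=diff, classification=cls
            )
        )
    return rows


def surrogate_vacuum_energy(
    metrics: ConjugationMetrics | tuple[float, float],
    params: Optional[tuple[float, float, float]] = None,
) -> float:
    """Affine surrogate for the gas-phase S1-S0 gap (kcal/mol).

    ``dE_vac = a + b*BLA + c*sum(distortions)``. Default parameters are the
    calibrated values in :mod:`rhodotune.constants`; pass ``params=(a, b, c)``
    to recalibrate. Accepts a :class:`ConjugationMetrics` or a raw
    ``(bla, total_distortion)`` pair.
    """
    if params is None:
        params = (
            constants.VACUUM_SURROGATE_A,
            constants.VACUUM_SURROGATE_B,
            constants.VACUUM_SURROGATE_C,
        )
    if len(params) != 3 or not all(math.isfinite(p) for p in params):
        raise ConfigurationError("surrogate params must be a finite (a, b, c) triple")
    a, b, c = params
    if isinstance(metrics, ConjugationMetrics):
        bla_value = metrics.bla
        distortion = metrics.total_distortion
    else:
        bla_value, distortion = metrics
    return a + b * float(bla_value) + c * float(distortion)


def flag_printed_deltas(
    table,
    reference_label: str = "KR2 WT",
    tolerance: float = 0.05,
) -> list[dict]:
    """Cross-check printed per-mutant deltas against recomputed ones.

    ``table`` is a DataFrame with columns ``label, dE_protein, dE_vacuum``
    and (for non-reference rows) printed parenthetical deltas
    ``printed_delta_protein, printed_delta_vacuum, printed_delta_electrostatic``.
    Returns one record per printed delta whose recomputed value differs by
    ``tolerance`` kcal/mol or more — these are flagged, never "corrected".
    """
    ref_rows = table[table["label"] == reference_label]
    if len(ref_rows) != 1:
        raise ConsistencyError(f"reference row {reference_label!r} not found uniquely")
    ref = ref_rows.iloc[0]
    ref_elec = float(ref["dE_protein"]) - float(ref["dE_vacuum"])
    flags: list[dict] = []
    for _, row in table.iterrows():
        if row["label"] == reference_label:
            continue
        elec = float(row["dE_protein"]) - float(row["dE_vacuum"])
        recomputed = {
            "protein": float(row["dE_protein"]) - float(ref["dE_protein"]),
            "vacuum": float(row["dE_vacuum"]) - float(ref["dE_vacuum"]),
            "electrostatic": elec - ref_elec,
        }
        for kind, value in recomputed.items():
            printed = row.get(f"printed_delta_{kind}")
            if printed is None or (isinstance(printed, float) and math.isnan(printed)):
                continue
            if abs(value - float(printed)) >= tolerance:
                flags.append(
                    {
                        "label": str(row["label"]),
                        "column": kind,
                        "printed": float(printed),
                        "recomputed": value,
                    }
                )
    return flags
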