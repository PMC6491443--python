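"""Retinal chromophore geometry: bond lengths, BLA and dihedral distortions.

The conjugated polyene chain of the all-*trans* retinal protonated Schiff
base is represented by the heavy atoms C5..C15 plus the Schiff-base nitrogen
N (and, when available, the lysine CE that continues the chain past N).
Two quantities summarize conjugation and planarity:

* **BLA** (bond-length alternation) — mean formal single-bond length minus
  mean formal double-bond length along the chain. More conjugation means
  lower BLA and a red-shifted absorption.
* **Dihedral distortion** — for each consecutive atom quadruple, the absolute
  deviation of the signed dihedral from the nearest planar value (0 or 180
  degrees). A planar all-trans chromophore has all distortions at zero.

Bond classification is a fixed convention here: singles are C6-C7, C8-C9,
C10-C11, C12-C13, C14-C15; doubles are C5-C6, C7-C8, C9-C10, C11-C12,
C13-C14 and the Schiff-base C15-N. Hydrogens are ignored throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io

from .errors import (
    ConsistencyError,
    DegenerateGeometryError,
    FormatError,
    MissingAtomError,
)

__all__ = [
    "CHAIN_ATOMS",
    "FORMAL_SINGLE_BONDS",
    "FORMAL_DOUBLE_BONDS",
    "ChromophoreGeometry",
    "ConjugationMetrics",
    "load_chromophore",
    "bond_lengths",
    "bla",
    "signed_dihedrals",
    "dihedral_distortions",
    "compute_metrics",
    "compare_to_reference",
]

#: Polyene chain atoms in canonical order (beta-ionone end -> Schiff base).
CHAIN_ATOMS: tuple[str, ...] = (
    "C5", "C6", "C7", "C8", "C9", "C10", "C11", "C12", "C13", "C14", "C15", "N",
)

#: Optional atoms extending the chain (lysine CE continues past N).
EXTENSION_ATOMS: tuple[str, ...] = ("CE",)

_BONDS: tuple[tuple[str, str], ...] = tuple(
    (CHAIN_ATOMS[i], CHAIN_ATOMS[i + 1]) for i in range(len(CHAIN_ATOMS) - 1)
)

FORMAL_SINGLE_BONDS: tuple[str, ...] = (
    "C6-C7", "C8-C9", "C10-C11", "C12-C13", "C14-C15",
)
FORMAL_DOUBLE_BONDS: tuple[str, ...] = (
    "C5-C6", "C7-C8", "C9-C10", "C11-C12", "C13-C14", "C15-N",
)

_BOND_RANGE = (1.2, 1.7)  # plausible heavy-atom bond length window, Angstrom


def _bond_name(a: str, b: str) -> str:
    return f"{a}-{b}"


@dataclass(frozen=True)
class ChromophoreGeometry:
    """Ordered chromophore atoms with Cartesian coordinates in Angstrom."""

    names: tuple[str, ...]
    coords: np.ndarray  # shape (n_atoms, 3)
    source_label: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.shape != (len(self.names), 3) or not np.all(np.isfinite(coords)):
            raise FormatError("coords must be a finite (n_atoms, 3) array")
        counts = {n: self.names.count(n) for n in self.names}
        dup = [n for n, c in counts.items() if c > 1]
        if dup:
            raise FormatError(f"duplicate atoms: {dup}")
        for atom in CHAIN_ATOMS:
            if atom not in self.names:
                raise MissingAtomError(atom)
        # consecutive chain atoms must be bonded-distance apart
        for a, b in _BONDS:
            d = float(np.linalg.norm(self.position(a) - self.position(b)))
            if not (_BOND_RANGE[0] <= d <= _BOND_RANGE[1]):
                raise FormatError(
                    f"bond {_bond_name(a, b)} length {d:.3f} A outside "
                    f"{_BOND_RANGE[0]}-{_BOND_RANGE[1]} A"
                )

    def position(self, name: str) -> np.ndarray:
        try:
            return self.coords[self.names.index(name)]
        except ValueError:
            raise MissingAtomError(name) from None

    @property
    def has_extension(self) -> bool:
        return "CE" in self.names

    def chain_path(self) -> tuple[str, ...]:
        """Chain atoms in order, extended by CE when present."""
        return CHAIN_ATOMS + (("CE",) if self.has_extension else ())


@dataclass(frozen=True)
class ConjugationMetrics:
    """Derived conjugation/planarity metrics for one chromophore."""

    bond_lengths: dict[str, float]
    bla: float
    dihedrals: dict[str, float]
    distortions: dict[str, float]
    source_label: str = ""

    @property
    def total_distortion(self) -> float:
        return float(sum(self.distortions.values()))


def load_chromophore(
    pdb_text: str,
    retinal_residue_name: str = "RET",
    source_label: str = "",
) -> ChromophoreGeometry:
    """Extract the retinal chain from PDB-format text.

    Both ATOM and HETATM records are accepted; alternate locations are
    resolved by highest occupancy. Raises :class:`MissingAtomError` naming
    the first absent chain atom, and :class:`FormatError` on duplicate atoms
    that are not altloc variants.
    """
    pdb_file = pdb_io.PDBFile.read(io.StringIO(pdb_text))
    atoms = pdb_file.get_structure(model=1, altloc="occupancy")
    sel = atoms[atoms.res_name == retinal_residue_name]
    if sel.array_length() == 0:
        raise FormatError(f"no residue named {retinal_residue_name!r} in PDB input")
    wanted = CHAIN_ATOMS + EXTENSION_ATOMS
    names: list[str] = []
    coords: list[np.ndarray] = []
    stripped = np.char.strip(sel.atom_name.astype(str))
    for atom in wanted:
        idx = np.where(stripped == atom)[0]
        if len(idx) > 1:
            raise FormatError(f"duplicate atom {atom!r} without altloc identifiers")
        if len(idx) == 1:
            names.append(atom)
            coords.append(sel.coord[idx[0]])
    geom = ChromophoreGeometry(
        names=tuple(names),
        coords=np.asarray(coords, dtype=float),
        source_label=source_label or retinal_residue_name,
    )
    return geom


def bond_lengths(geom: ChromophoreGeometry) -> dict[str, float]:
    """Euclidean lengths (Angstrom) of the 11 chain bonds C5-C6 .. C15-N."""
    out: dict[str, float] = {}
    for a, b in _BONDS:
        out[_bond_name(a, b)] = float(
            np.linalg.norm(geom.position(a) - geom.position(b))
        )
    return out


def bla(
    lengths: Mapping[str, float],
    single_bonds: Sequence[str] = FORMAL_SINGLE_BONDS,
    double_bonds: Sequence[str] = FORMAL_DOUBLE_BONDS,
) -> float:
    """Bond-length alternation: mean(singles) - mean(doubles), Angstrom."""
    for bond in tuple(single_bonds) + tuple(double_bonds):
        if bond not in lengths:
            raise ConsistencyError(f"bond {bond!r} missing from lengths")
    s = float(np.mean([lengths[b] for b in single_bonds]))
    d = float(np.mean([lengths[b] for b in double_bonds]))
    return s - d


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees for four points (IUPAC convention)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    nb1 = np.linalg.norm(b1)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or nb1 < 1e-10:
        raise DegenerateGeometryError("collinear atoms: dihedral undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1 / nb1))
    return float(np.degrees(np.arctan2(y, x)))


def signed_dihedrals(geom: ChromophoreGeometry) -> dict[str, float]:
    """Signed dihedrals (deg) for every consecutive quadruple along the chain.

    Each dihedral is named after its central bond; the C15-N dihedral exists
    only when the lysine CE atom is present to complete the quadruple.
    """
    path = geom.chain_path()
    out: dict[str, float] = {}
    for i in range(len(path) - 3):
        quad = path[i : i + 4]
        name = _bond_name(quad[1], quad[2])
        out[name] = _dihedral(*(geom.position(a) for a in quad))
    return out


def dihedral_distortions(geom: ChromophoreGeometry) -> dict[str, float]:
    """Absolute deviation (deg) of each dihedral from the nearest of 0/180."""
    out = {}
    for name, angle in signed_dihedrals(geom).items():
        a = abs(angle)
        out[name] = float(min(a, 180.0 - a))
    return out


def compute_metrics(geom: ChromophoreGeometry) -> ConjugationMetrics:
    """Bundle bond lengths, BLA, dihedrals and distortions for one geometry."""
    lengths = bond_lengths(geom)
    return ConjugationMetrics(
        bond_lengths=lengths,
        bla=bla(lengths),
        dihedrals=signed_dihedrals(geom),
        distortions=dihedral_distortions(geom),
        source_label=geom.source_label,
    )


def compare_to_reference(
    metrics: Mapping[str, float], reference_metrics: Mapping[str, float]
) -> dict[str, float]:
    """Elementwise variant-minus-reference differences over matching keys."""
    if set(metrics) != set(reference_metrics):
        missing = set(metrics) ^ set(reference_metrics)
        raise ConsistencyError(f"key mismatch between metrics: {sorted(missing)}")
    return {k: float(metrics[k] - reference_metrics[k]) for k in metrics}
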