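"""Solvent-accessible surface area and hydrophobic-surface statistics.

Shrake-Rupley SASA with a deterministic golden-spiral point distribution on
each probe-expanded atomic sphere: a surface point is accessible iff it lies
inside no other expanded sphere, and an atom's area is the accessible
fraction of 4*pi*(r+probe)^2.  On top of that, a single scalar statistic
summarizes what surface hydrophobicity rendering shows qualitatively: the
fraction of the total surface contributed by hydrophobic residue types.
Applying the QTY code shrinks that fraction because every substituted
residue leaves the hydrophobic set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .structure import StructureModel

#: Kyte-Doolittle-positive residues plus A, P, W (one-letter codes).
DEFAULT_HYDROPHOBIC_SET = frozenset("AVLIPFMW")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLU": "E",
    "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class RadiusTable:
    """Van der Waals radii per element (Å) with a fallback for others."""

    radii: Mapping[str, float] = field(
        default_factory=lambda: {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
    )
    default: float = 1.7

    def __post_init__(self) -> None:
        if self.default <= 0 or any(r <= 0 for r in self.radii.values()):
            raise ValueError("all radii must be positive")

    def radius(self, element: str) -> float:
        return self.radii.get(element.upper(), self.default)


DEFAULT_RADII = RadiusTable()


@dataclass
class SASAResult:
    atom_area: np.ndarray  # Å², aligned with the heavy atoms used
    residue_area: dict[tuple[str, int, str], float]  # (chain, res_seq, icode) -> Å²
    total_area: float
    probe: float
    n_points: int


def sphere_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors from the golden-spiral (Fibonacci) lattice."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    radii: RadiusTable = DEFAULT_RADII,
) -> SASAResult:
    """Per-atom, per-residue and total SASA of a structure.

    Hydrogens are ignored.  Neighbor candidates are found with a KD-tree
    cutoff search, which only limits which spheres are *tested* — the
    accessibility of each surface point, and hence the result, is
    independent of the search strategy.  The golden-spiral point set makes
    the estimate fully deterministic.
    """
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    heavy = [a for a in model.atoms if a.element.upper() != "H"]
    if not heavy:
        raise ValueError("model has no heavy atoms")

    centers = np.array([[a.x, a.y, a.z] for a in heavy])
    expanded = np.array([radii.radius(a.element) + probe for a in heavy])
    unit = sphere_points(n_points)

    tree = cKDTree(centers)
    max_r = expanded.max()
    areas = np.empty(len(heavy))
    for i in range(len(heavy)):
        ri = expanded[i]
        pts = centers[i] + ri * unit
        neighbors = [j for j in tree.query_ball_point(centers[i], ri + max_r) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - centers[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * math.pi * ri * ri * accessible.mean()

    residue_area: dict[tuple[str, int, str], float] = {}
    for a, area in zip(heavy, areas):
        key = (a.chain, a.res_seq, a.icode)
        residue_area[key] = residue_area.get(key, 0.0) + float(area)
    return SASAResult(
        atom_area=areas,
        residue_area=residue_area,
        total_area=float(areas.sum()),
        probe=probe,
        n_points=n_points,
    )


def hydrophobic_surface_fraction(
    sasa: SASAResult,
    model: StructureModel,
    hydrophobic_set: frozenset[str] = DEFAULT_HYDROPHOBIC_SET,
) -> float:
    """Fraction of total SASA contributed by hydrophobic residue types.

    Residue types are taken from the model's 3-letter names; the default
    hydrophobic set is {A, V, L, I, P, F, M, W}, so every QTY substitution
    (L/I/V/F -> Q/T/Y) moves a residue out of the set.
    """
    if sasa.total_area <= 0:
        raise ValueError("total SASA is zero")
    names = model.residue_names()
    hydro = 0.0
    for key, area in sasa.residue_area.items():
        one = THREE_TO_ONE.get(names.get(key, ""), "")
        if one in hydrophobic_set:
            hydro += area
    return hydro / sasa.total_area
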