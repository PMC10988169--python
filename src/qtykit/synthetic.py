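"""Synthetic multi-pass membrane proteins for end-to-end testing.

Real inputs to this kind of analysis are a downloaded sequence, a TM
annotation, and experimental plus predicted 3D models.  This module
generates consistent stand-ins: a sequence whose helical segments are
enriched in hydrophobic residues and whose loops are polar, a TM topology
covering exactly the helices, and a CA-only alpha-helical bundle whose
residue numbering matches the sequence.  Loops are deliberately left out of
the coordinates, mimicking the unresolved unstructured loops of cryo-EM
models, so correspondence building exercises the same trimming as real data.
Gaussian noise and rigid displacement produce controlled superposition test
pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .sequence import ProteinSequence, TMTopology, QTYRecord
from .structure import Atom, StructureModel

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "E": "GLU",
    "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

#: Helix composition enriched in the residues of hydrophobic TM helices
#: (~58% L/I/V/F, the QTY-substitutable set).
DEFAULT_TM_COMPOSITION: Mapping[str, float] = {
    "L": 0.22, "I": 0.13, "V": 0.13, "F": 0.10, "A": 0.12, "G": 0.08,
    "S": 0.05, "T": 0.04, "M": 0.04, "W": 0.02, "Y": 0.03, "P": 0.02, "C": 0.02,
}

#: Loop composition enriched in polar and charged residues.
DEFAULT_LOOP_COMPOSITION: Mapping[str, float] = {
    "S": 0.12, "T": 0.10, "N": 0.10, "Q": 0.08, "D": 0.09, "E": 0.09,
    "K": 0.09, "R": 0.08, "G": 0.09, "P": 0.08, "H": 0.04, "A": 0.04,
}


def _validate_composition(comp: Mapping[str, float], label: str) -> None:
    if abs(sum(comp.values()) - 1.0) > 1e-9:
        raise ValueError(f"{label} probabilities must sum to 1")
    bad = set(comp) - set(ONE_TO_THREE)
    if bad or any(p < 0 for p in comp.values()):
        raise ValueError(f"{label}: invalid residues {bad} or negative probabilities")


@dataclass(frozen=True)
class BundleSpec:
    """Parameters of a synthetic TM-helix bundle.

    Defaults emulate a mid-size transporter TM domain: 6 helices of 22
    residues (a typical bilayer-spanning length) joined by 6-residue loops.
    """

    n_helices: int = 6
    helix_len: int = 22
    loop_len: int = 6
    tm_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TM_COMPOSITION)
    )
    loop_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOOP_COMPOSITION)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_helices <= 12:
            raise ValueError("n_helices must be in [2, 12]")
        if self.helix_len < 1 or self.loop_len < 1:
            raise ValueError("helix_len and loop_len must be >= 1")
        _validate_composition(self.tm_composition, "tm_composition")
        _validate_composition(self.loop_composition, "loop_composition")

    @property
    def total_length(self) -> int:
        return self.n_helices * self.helix_len + (self.n_helices + 1) * self.loop_len

    @property
    def spans(self) -> tuple[tuple[int, int], ...]:
        out = []
        pos = self.loop_len + 1
        for _ in range(self.n_helices):
            out.append((pos, pos + self.helix_len - 1))
            pos += self.helix_len + self.loop_len
        return tuple(out)


@dataclass(frozen=True)
class HelixGeometry:
    """Ideal alpha-helix constants: rise/residue, twist/residue, CA radius."""

    rise: float = 1.5  # Å
    twist_deg: float = 100.0
    ca_radius: float = 2.3  # Å
    axis_spacing: float = 10.0  # Å between adjacent helix axes

    def __post_init__(self) -> None:
        if min(self.rise, self.twist_deg, self.ca_radius, self.axis_spacing) <= 0:
            raise ValueError("all helix-geometry constants must be positive")


def _draw(rng: np.random.Generator, comp: Mapping[str, float], n: int) -> str:
    letters = sorted(comp)
    probs = np.array([comp[a] for a in letters])
    return "".join(rng.choice(letters, size=n, p=probs / probs.sum()))


def generate_membrane_protein(spec: BundleSpec) -> tuple[ProteinSequence, TMTopology]:
    """A random sequence with hydrophobic helices and polar loops, plus its topology.

    Layout: loop, (helix, loop) * n_helices; the TM spans cover exactly the
    helix segments.  Deterministic for a given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    parts = [_draw(rng, spec.loop_composition, spec.loop_len)]
    for _ in range(spec.n_helices):
        parts.append(_draw(rng, spec.tm_composition, spec.helix_len))
        parts.append(_draw(rng, spec.loop_composition, spec.loop_len))
    seq = ProteinSequence(
        id=f"synthetic_{spec.n_helices}tm_seed{spec.seed}",
        residues="".join(parts),
        description=f"synthetic {spec.n_helices}-helix membrane protein",
    )
    return seq, TMTopology(sequence_id=seq.id, spans=spec.spans)


def generate_bundle_structure(
    spec: BundleSpec, geom: HelixGeometry = HelixGeometry()
) -> StructureModel:
    """CA-only alpha-helical bundle consistent with :func:`generate_membrane_protein`.

    Helix axes sit on a circle with adjacent axes ``geom.axis_spacing``
    apart, alternating up/down like an antiparallel bundle.  Residue numbers
    are the sequence positions of the TM spans; loop residues have no atoms.
    """
    seq, topo = generate_membrane_protein(spec)
    n = spec.n_helices
    circle_r = geom.axis_spacing / (2.0 * math.sin(math.pi / n))
    twist = math.radians(geom.twist_deg)
    atoms: list[Atom] = []
    for h, (start, end) in enumerate(topo.spans):
        angle = 2.0 * math.pi * h / n
        cx, cy = circle_r * math.cos(angle), circle_r * math.sin(angle)
        up = h % 2 == 0
        for j in range(spec.helix_len):
            theta = twist * j
            z = geom.rise * (j if up else spec.helix_len - 1 - j)
            res_seq = start + j
            atoms.append(
                Atom(
                    chain="A", res_seq=res_seq, icode="",
                    res_name=ONE_TO_THREE[seq.residues[res_seq - 1]],
                    atom_name="CA", element="C",
                    x=cx + geom.ca_radius * math.cos(theta),
                    y=cy + geom.ca_radius * math.sin(theta),
                    z=z,
                )
            )
    return StructureModel(atoms, model_id="synthetic")


def perturb_structure(
    model: StructureModel,
    sigma: float,
    rigid: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None,
    seed: int = 0,
) -> StructureModel:
    """Add i.i.d. Gaussian coordinate noise (σ per coordinate, Å), then a rigid motion.

    ``rigid`` is (Euler xyz angles in degrees, translation in Å).
    Deterministic for a given ``seed``; atom identities are preserved.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    xyz = model.coords() + rng.normal(0.0, sigma, size=(len(model.atoms), 3))
    if rigid is not None:
        angles, translation = rigid
        R = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
        xyz = xyz @ R.T + np.asarray(translation, dtype=float)
    atoms = [
        Atom(a.chain, a.res_seq, a.icode, a.res_name, a.atom_name, a.element,
             float(p[0]), float(p[1]), float(p[2]), a.occupancy, a.altloc, a.b)
        for a, p in zip(model.atoms, xyz)
    ]
    return StructureModel(atoms, model_id=model.model_id)


def apply_qty_relabel(model: StructureModel, record: QTYRecord) -> StructureModel:
    """Rename residues to the QTY variant without moving any atom.

    Stands in for a predicted variant structure under the premise that the
    backbone is essentially unchanged by the substitutions, which lets
    surface-hydrophobicity comparisons run on identical coordinates.
    """
    variant = record.variant.residues
    atoms = []
    for a in model.atoms:
        if not 1 <= a.res_seq <= len(variant):
            raise ValueError(
                f"residue {a.res_seq} outside the variant sequence (length {len(variant)})"
            )
        atoms.append(
            Atom(a.chain, a.res_seq, a.icode, ONE_TO_THREE[variant[a.res_seq - 1]],
                 a.atom_name, a.element, a.x, a.y, a.z, a.occupancy, a.altloc, a.b)
        )
    return StructureModel(atoms, model_id=model.model_id)
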