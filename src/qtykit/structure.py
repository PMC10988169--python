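"""Structure ingestion and superposition.

Reads PDB/mmCIF coordinate files (via gemmi) into a flat atom model, builds
residue correspondences between two structures of the same protein (trimming
residues unresolved in either one, as happens with unstructured loops in
cryo-EM models), and computes optimal rigid superpositions: closed-form
Kabsch fit plus PyMOL-style iterative outlier-rejection refinement.  RMSDs
are computed over CA atoms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .sequence import TMTopology

logger = logging.getLogger(__name__)

#: residue identity within a chain: (res_seq, insertion code)
ResidueId = tuple[int, str]

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class Atom:
    chain: str
    res_seq: int
    icode: str
    res_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    altloc: str = ""
    b: float = 0.0

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class StructureModel:
    """Atoms grouped implicitly into residues and chains by their ids."""

    atoms: list[Atom]
    model_id: str = "1"

    def __post_init__(self) -> None:
        keys = set()
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError(f"non-finite coordinates on atom {a}")
            k = (a.chain, a.res_seq, a.icode, a.atom_name, a.altloc)
            if k in keys:
                raise ValueError(f"duplicate atom {k}")
            keys.add(k)

    def __len__(self) -> int:
        return len(self.atoms)

    def chains(self) -> list[str]:
        """Chain names in file order."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def chain_atoms(self, chain: str) -> list[Atom]:
        out = [a for a in self.atoms if a.chain == chain]
        if not out:
            raise ValueError(f"chain {chain!r} not present (have {self.chains()})")
        return out

    def residues(self, chain: str) -> dict[ResidueId, dict[str, Atom]]:
        """Ordered mapping (res_seq, icode) -> {atom_name: Atom} for one chain."""
        out: dict[ResidueId, dict[str, Atom]] = {}
        for a in self.chain_atoms(chain):
            out.setdefault((a.res_seq, a.icode), {})[a.atom_name] = a
        return out

    def residue_names(self, chain: str | None = None) -> dict[tuple[str, int, str], str]:
        out: dict[tuple[str, int, str], str] = {}
        for a in self.atoms:
            if chain is None or a.chain == chain:
                out.setdefault((a.chain, a.res_seq, a.icode), a.res_name)
        return out

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def ca_coords(self, chain: str) -> tuple[list[ResidueId], np.ndarray]:
        ids, xyz = [], []
        for rid, atoms in self.residues(chain).items():
            if "CA" in atoms:
                ids.append(rid)
                xyz.append(atoms["CA"].xyz)
        return ids, np.array(xyz, dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """A copy with every coordinate mapped to R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_atoms = []
        for a in self.atoms:
            x, y, z = R @ np.array([a.x, a.y, a.z]) + t
            new_atoms.append(
                Atom(a.chain, a.res_seq, a.icode, a.res_name, a.atom_name,
                     a.element, float(x), float(y), float(z), a.occupancy, a.altloc, a.b)
            )
        return StructureModel(new_atoms, model_id=self.model_id)


# --------------------------------------------------------------------------
# File I/O
# --------------------------------------------------------------------------

def _blank(ch: str) -> str:
    return "" if ch in ("\x00", " ", "") else ch


def read_structure(source: str | Path, format: str = "pdb") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Defaults follow single-conformer analysis practice: first model only,
    HETATM and waters excluded, and for altloc duplicates the
    highest-occupancy conformer (ties broken by alphabetically first altloc).
    mmCIF files are read with author (auth_) chain and residue numbering so
    they agree with PDB-format numbering and sequence-based annotations.
    """
    fmts = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}
    if format not in fmts:
        raise ValueError(f"format must be 'pdb' or 'mmcif', got {format!r}")
    try:
        st = gemmi.read_structure(str(source), format=fmts[format])
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse {source} as {format}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{source}: no coordinate models")
    model = st[0]

    # group altloc conformers of the same atom, then pick one
    grouped: dict[tuple[str, int, str, str], list[gemmi.Atom]] = {}
    meta: dict[tuple[str, int, str, str], str] = {}
    order: list[tuple[str, int, str, str]] = []
    for chain in model:
        for residue in chain:
            if residue.het_flag != "A" or residue.name in _WATER_NAMES:
                continue
            for atom in residue:
                key = (chain.name, residue.seqid.num, _blank(residue.seqid.icode), atom.name)
                if key not in grouped:
                    grouped[key] = []
                    meta[key] = residue.name
                    order.append(key)
                grouped[key].append(atom)

    atoms: list[Atom] = []
    for key in order:
        candidates = grouped[key]
        best = min(candidates, key=lambda a: (-a.occ, _blank(a.altloc) or "~"))
        chain_name, res_seq, icode, atom_name = key
        atoms.append(
            Atom(
                chain=chain_name, res_seq=res_seq, icode=icode,
                res_name=meta[key], atom_name=atom_name,
                element=best.element.name,
                x=best.pos.x, y=best.pos.y, z=best.pos.z,
                occupancy=best.occ, altloc=_blank(best.altloc), b=best.b_iso,
            )
        )
    if not atoms:
        raise ValueError(f"{source}: no ATOM records after filtering (HETATM/waters are excluded)")
    return StructureModel(atoms, model_id=str(model.num))


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as fixed-column PDB v3.3 ATOM records."""
    lines = []
    for i, a in enumerate(model.atoms, start=1):
        name = a.atom_name
        if len(name) < 4 and len(a.element) == 1:
            name = " " + name
        lines.append(
            f"ATOM  {i % 100000:5d} {name:<4s}{a.altloc or ' ':1s}{a.res_name:>3s} "
            f"{a.chain[:1]:1s}{a.res_seq % 10000:4d}{a.icode or ' ':1s}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{a.b:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Correspondence
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueCorrespondence:
    """One-to-one residue pairing restricted to residues with a CA in both."""

    chain_a: str
    chain_b: str
    pairs: tuple[tuple[ResidueId, ResidueId], ...]


def build_correspondence(
    a: StructureModel,
    b: StructureModel,
    mode: str = "by_resnum",
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> ResidueCorrespondence:
    """Pair CA-bearing residues of one chain of ``a`` with one chain of ``b``.

    ``by_resnum`` pairs residues sharing (res_seq, icode); ``by_position``
    pairs the i-th CA with the i-th CA up to the shorter chain.  Residues
    missing a CA in either model (e.g. unresolved loops) are dropped, which
    is exactly the loop-trimming needed before comparing a cryo-EM model
    with a full-length prediction.
    """
    chain_a = chain_a or a.chains()[0]
    chain_b = chain_b or b.chains()[0]
    ids_a, _ = a.ca_coords(chain_a)
    ids_b, _ = b.ca_coords(chain_b)
    if mode == "by_resnum":
        set_b = set(ids_b)
        pairs = tuple((rid, rid) for rid in ids_a if rid in set_b)
    elif mode == "by_position":
        pairs = tuple(zip(ids_a, ids_b))
    else:
        raise ValueError(f"mode must be 'by_resnum' or 'by_position', got {mode!r}")
    if not pairs:
        raise ValueError(
            f"empty correspondence between chain {chain_a!r} and chain {chain_b!r}"
        )
    return ResidueCorrespondence(chain_a=chain_a, chain_b=chain_b, pairs=pairs)


def correspondence_coords(
    a: StructureModel, b: StructureModel, corr: ResidueCorrespondence
) -> tuple[np.ndarray, np.ndarray]:
    """Paired CA coordinate arrays (P from ``a``, Q from ``b``)."""
    res_a = a.residues(corr.chain_a)
    res_b = b.residues(corr.chain_b)
    P = np.array([res_a[ra]["CA"].xyz for ra, _ in corr.pairs], dtype=float)
    Q = np.array([res_b[rb]["CA"].xyz for _, rb in corr.pairs], dtype=float)
    return P, Q


# --------------------------------------------------------------------------
# Kabsch superposition and refinement
# --------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper orthogonal, applied to Q
    translation: np.ndarray  # 3-vector
    n_input_pairs: int
    n_used_pairs: int
    rmsd_all: float
    rmsd_refined: float
    cycle_log: list[tuple[int, float]] = field(default_factory=list)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _check_cloud(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"coordinate sets must both be (n, 3); got {P.shape} and {Q.shape}")
    if len(P) < 3:
        raise ValueError(f"need at least 3 paired atoms, got {len(P)}")
    for X, label in ((P, "P"), (Q, "Q")):
        s = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise ValueError(f"degenerate (collinear) coordinate set {label}")
    return P, Q


def kabsch_superpose(P: Sequence | np.ndarray, Q: Sequence | np.ndarray) -> SuperpositionResult:
    """Least-squares proper rigid superposition of Q onto P (Kabsch, via SVD).

    The reflection case is corrected by flipping the sign of the singular
    vector with the smallest singular value, so the returned rotation always
    has determinant +1.
    """
    P, Q = _check_cloud(P, Q)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - qc).T @ (P - pc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    rmsd = float(np.sqrt(np.mean(np.sum((P - (Q @ R.T + t)) ** 2, axis=1))))
    return SuperpositionResult(
        rotation=R, translation=t,
        n_input_pairs=len(P), n_used_pairs=len(P),
        rmsd_all=rmsd, rmsd_refined=rmsd, cycle_log=[(len(P), rmsd)],
    )


def refine_superpose(
    P: Sequence | np.ndarray,
    Q: Sequence | np.ndarray,
    cycles: int = 5,
    reject_factor: float = 2.0,
) -> SuperpositionResult:
    """Kabsch fit with iterative outlier rejection.

    Each cycle refits on the retained pairs, then discards pairs whose
    post-fit distance exceeds ``reject_factor`` times the current RMSD.
    Stops after ``cycles`` cycles, when no pair is discarded, or when fewer
    than 3 pairs would remain.  ``rmsd_all`` is the cycle-0 (all-pair) RMSD;
    ``rmsd_refined`` is the final RMSD over retained pairs.
    """
    P, Q = _check_cloud(P, Q)
    n = len(P)
    mask = np.ones(n, dtype=bool)
    fit = kabsch_superpose(P, Q)
    log = [(n, fit.rmsd_all)]
    rmsd_all = fit.rmsd_all
    current = fit
    for _ in range(cycles):
        d = np.linalg.norm(P[mask] - current.apply(Q[mask]), axis=1)
        keep = d <= reject_factor * current.rmsd_refined
        if keep.all():
            break
        if keep.sum() < 3:
            break
        new_mask = mask.copy()
        new_mask[np.flatnonzero(mask)[~keep]] = False
        mask = new_mask
        current = kabsch_superpose(P[mask], Q[mask])
        log.append((int(mask.sum()), current.rmsd_all))
    return SuperpositionResult(
        rotation=current.rotation, translation=current.translation,
        n_input_pairs=n, n_used_pairs=int(mask.sum()),
        rmsd_all=rmsd_all, rmsd_refined=current.rmsd_all, cycle_log=log,
    )


# --------------------------------------------------------------------------
# TM-domain extraction and the end-to-end comparison
# --------------------------------------------------------------------------

def extract_tm_domain(
    model: StructureModel, topo: TMTopology, chain: str | None = None
) -> StructureModel:
    """Keep only atoms of residues inside the TM spans of one chain."""
    chain = chain or model.chains()[0]
    chain_atoms = model.chain_atoms(chain)
    kept = [a for a in chain_atoms if topo.covers(a.res_seq)]
    if not kept:
        raise ValueError(
            f"no atoms of chain {chain!r} fall inside the TM spans "
            f"({len(topo.spans)} span(s))"
        )
    present = {a.res_seq for a in chain_atoms}
    for s, e in topo.spans:
        missing = [p for p in range(s, e + 1) if p not in present]
        if missing:
            logger.warning(
                "TM span (%d, %d): %d residue(s) unresolved in chain %s",
                s, e, len(missing), chain,
            )
    return StructureModel(kept, model_id=model.model_id)


def superpose_structures(
    a: StructureModel,
    b: StructureModel,
    chain_a: str | None = None,
    chain_b: str | None = None,
    mode: str = "by_resnum",
    tm_only: bool = False,
    topo: TMTopology | None = None,
    cycles: int = 5,
    reject_factor: float = 2.0,
) -> tuple[SuperpositionResult, StructureModel]:
    """Full comparison of two structures of the same protein.

    Selects one chain per model (first chain by default, e.g. one monomer of
    a homodimer), optionally cuts both down to the TM domain, builds the
    CA correspondence, and runs outlier-rejection refinement.  Returns the
    result together with the transformed copy of ``b`` for inspection.
    """
    chain_a = chain_a or a.chains()[0]
    chain_b = chain_b or b.chains()[0]
    sel_a, sel_b = a, b
    if tm_only:
        if topo is None:
            raise ValueError("tm_only=True requires a TM topology")
        sel_a = extract_tm_domain(a, topo, chain_a)
        sel_b = extract_tm_domain(b, topo, chain_b)
    corr = build_correspondence(sel_a, sel_b, mode=mode, chain_a=chain_a, chain_b=chain_b)
    P, Q = correspondence_coords(sel_a, sel_b, corr)
    result = refine_superpose(P, Q, cycles=cycles, reject_factor=reject_factor)
    return result, b.transformed(result.rotation, result.translation)
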