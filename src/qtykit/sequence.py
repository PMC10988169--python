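"""Sequence-level QTY analysis.

The QTY code renders multi-pass membrane proteins water-soluble by replacing
the four hydrophobic residues found in transmembrane (TM) alpha helices with
structurally analogous hydrophilic ones:

    L -> Q    I -> T    V -> T    F -> Y

Substitutions are confined to annotated TM spans; everything outside the
membrane is untouched.  This module implements the transform and the sequence
characteristics used to compare a native membrane protein with its QTY
variant: total and TM-restricted variation percentages, isoelectric point
(Bjellqvist/Expasy pKa set, bisection on the net-charge curve), average
molecular weight, and Kyte-Doolittle mean hydropathy (GRAVY).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)

#: The fixed QTY substitution mapping (T replaces both I and V).
QTY_MAPPING: Mapping[str, str] = {"L": "Q", "I": "T", "V": "T", "F": "Y"}


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20 canonical one-letter codes."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence '{self.id}' is empty")
        bad = set(self.residues) - _CANONICAL_SET
        if bad:
            raise ValueError(
                f"sequence '{self.id}' contains non-canonical residue(s) "
                f"{''.join(sorted(bad))!r}; only {CANONICAL_RESIDUES} are accepted"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TMTopology:
    """Ordered, non-overlapping 1-based inclusive transmembrane spans."""

    sequence_id: str
    spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        spans = tuple((int(s), int(e)) for s, e in self.spans)
        object.__setattr__(self, "spans", spans)
        prev_end = 0
        for s, e in spans:
            if s < 1:
                raise ValueError(f"span ({s},{e}): start must be >= 1")
            if s > e:
                raise ValueError(f"span ({s},{e}): start > end")
            if s <= prev_end:
                raise ValueError(
                    f"span ({s},{e}) overlaps or is out of order "
                    f"(previous span ends at {prev_end})"
                )
            prev_end = e

    @property
    def n_tm_residues(self) -> int:
        return sum(e - s + 1 for s, e in self.spans)

    def covers(self, position: int) -> bool:
        """True if the 1-based ``position`` lies inside some TM span."""
        return any(s <= position <= e for s, e in self.spans)

    def validate_for(self, seq: ProteinSequence) -> None:
        if self.sequence_id != seq.id:
            raise ValueError(
                f"topology is for '{self.sequence_id}', sequence is '{seq.id}'"
            )
        if self.spans and self.spans[-1][1] > len(seq):
            raise ValueError(
                f"span {self.spans[-1]} exceeds sequence length {len(seq)}"
            )


@dataclass(frozen=True)
class SubstitutionRule:
    """The QTY substitution code.  Fixed in v1: exactly L->Q, I->T, V->T, F->Y."""

    mapping: Mapping[str, str] = field(default_factory=lambda: dict(QTY_MAPPING))

    def __post_init__(self) -> None:
        if dict(self.mapping) != dict(QTY_MAPPING):
            raise ValueError("the substitution rule is fixed to L->Q, I->T, V->T, F->Y")

    @property
    def substitutable(self) -> frozenset[str]:
        return frozenset(self.mapping)

    @property
    def replacements(self) -> frozenset[str]:
        return frozenset(self.mapping.values())


@dataclass(frozen=True)
class Substitution:
    position: int  # 1-based
    from_res: str
    to_res: str


@dataclass(frozen=True)
class SequenceMetrics:
    total_variation_pct: float
    tm_variation_pct: float
    pI_native: float
    pI_variant: float
    mw_native: float
    mw_variant: float
    gravy_native: float
    gravy_variant: float


@dataclass(frozen=True)
class QTYRecord:
    """A native sequence, its QTY variant, and the derived characteristics."""

    native: ProteinSequence
    variant: ProteinSequence
    substitutions: tuple[Substitution, ...]
    metrics: SequenceMetrics


# --------------------------------------------------------------------------
# pKa model (Expasy / Bjellqvist set)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PKaTable:
    """Ionizable-group pKa values with charge signs.

    Termini pKa values are residue-specific where the table provides them,
    with a generic fallback.  Basic groups (N-terminus, H, K, R) contribute
    positive charge; acidic groups (C-terminus, D, E, C, Y) negative.
    """

    n_term: Mapping[str, float]
    n_term_default: float
    c_term: Mapping[str, float]
    c_term_default: float
    basic: Mapping[str, float]
    acidic: Mapping[str, float]


#: Bjellqvist pKa set as used by the Expasy Compute pI/Mw tool.
BJELLQVIST = PKaTable(
    n_term={"A": 7.59, "M": 7.00, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.70},
    n_term_default=7.50,
    c_term={"D": 4.55, "E": 4.75},
    c_term_default=3.55,
    basic={"K": 10.00, "R": 12.00, "H": 5.98},
    acidic={"D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00},
)


def net_charge(seq: ProteinSequence, pH: float, table: PKaTable = BJELLQVIST) -> float:
    """Model net charge at ``pH``: sum of Henderson-Hasselbalch group charges.

    Z(pH) = sum_basic 1/(1+10^(pH-pKa)) - sum_acidic 1/(1+10^(pKa-pH));
    strictly decreasing in pH.
    """
    counts = Counter(seq.residues)
    z = 1.0 / (1.0 + 10.0 ** (pH - table.n_term.get(seq.residues[0], table.n_term_default)))
    z -= 1.0 / (1.0 + 10.0 ** (table.c_term.get(seq.residues[-1], table.c_term_default) - pH))
    for aa, pka in table.basic.items():
        z += counts[aa] / (1.0 + 10.0 ** (pH - pka))
    for aa, pka in table.acidic.items():
        z -= counts[aa] / (1.0 + 10.0 ** (pka - pH))
    return z


def isoelectric_point(seq: ProteinSequence, table: PKaTable = BJELLQVIST) -> float:
    """pH at which the modeled net charge crosses zero.

    Bisection on [0, 14]; Z is strictly decreasing so the root is unique.
    The bracket is narrowed below 1e-4 pH units, which bounds the root error
    regardless of how shallow the charge curve is near the crossing.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-4:
        mid = 0.5 * (lo + hi)
        z = net_charge(seq, mid, table)
        if z > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# Mass and hydropathy
# --------------------------------------------------------------------------

#: Expasy average residue masses (Da); a free protein adds one water.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_MASS = 18.02

#: Kyte-Doolittle hydropathy values.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "E": -3.5, "Q": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def molecular_weight(seq: ProteinSequence) -> float:
    """Average molecular weight in Da (residue-mass sum plus one water)."""
    return sum(AVERAGE_RESIDUE_MASS[aa] for aa in seq.residues) + WATER_MASS


def gravy(seq: ProteinSequence) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    return sum(KYTE_DOOLITTLE[aa] for aa in seq.residues) / len(seq)


# --------------------------------------------------------------------------
# The QTY transform
# --------------------------------------------------------------------------

def variation_percentages(
    native: ProteinSequence, variant: ProteinSequence, topo: TMTopology
) -> tuple[float, float]:
    """(total %, TM %) of positions that differ, each rounded to 2 decimals.

    The TM denominator is the residue count inside the native TM annotation;
    by convention the TM percentage is 0 when there are no spans.
    """
    if len(native) != len(variant):
        raise ValueError(
            f"sequence lengths differ: {len(native)} vs {len(variant)}"
        )
    diff = [i + 1 for i, (a, b) in enumerate(zip(native.residues, variant.residues)) if a != b]
    total_pct = 100.0 * len(diff) / len(native)
    n_tm = topo.n_tm_residues
    tm_diff = sum(1 for p in diff if topo.covers(p))
    tm_pct = 100.0 * tm_diff / n_tm if n_tm else 0.0
    return round(total_pct, 2), round(tm_pct, 2)


def qty_transform(
    seq: ProteinSequence,
    topo: TMTopology,
    rule: SubstitutionRule | None = None,
    table: PKaTable = BJELLQVIST,
) -> QTYRecord:
    """Apply the QTY code inside the TM spans of ``seq``.

    Every L/I/V/F inside a span is replaced (L->Q, I->T, V->T, F->Y); all
    other positions, including L/I/V/F outside the membrane, are untouched.
    """
    rule = rule or SubstitutionRule()
    topo.validate_for(seq)
    chars = list(seq.residues)
    subs: list[Substitution] = []
    for s, e in topo.spans:
        for pos in range(s, e + 1):
            aa = chars[pos - 1]
            new = rule.mapping.get(aa)
            if new is not None:
                chars[pos - 1] = new
                subs.append(Substitution(pos, aa, new))
    variant = ProteinSequence(
        id=f"{seq.id}_QTY",
        residues="".join(chars),
        description=(seq.description + " QTY variant").strip(),
    )
    total_pct, tm_pct = variation_percentages(seq, variant, topo)
    metrics = SequenceMetrics(
        total_variation_pct=total_pct,
        tm_variation_pct=tm_pct,
        pI_native=isoelectric_point(seq, table),
        pI_variant=isoelectric_point(variant, table),
        mw_native=molecular_weight(seq),
        mw_variant=molecular_weight(variant),
        gravy_native=gravy(seq),
        gravy_variant=gravy(variant),
    )
    return QTYRecord(native=seq, variant=variant, substitutions=tuple(subs), metrics=metrics)


# --------------------------------------------------------------------------
# Alignment rendering
# --------------------------------------------------------------------------

def render_alignment(rec: QTYRecord, topo: TMTopology, width: int = 60) -> str:
    """Pairwise native/variant alignment in wrapped text blocks.

    Per block: a TM-annotation line ('H' over span columns), the native line,
    a marker line ('|' identical, '*' different), and the variant line.
    Sequences and markers are recoverable from the text (see
    :func:`parse_alignment`).
    """
    if width < 10:
        raise ValueError("alignment width must be >= 10")
    nat, var = rec.native.residues, rec.variant.residues
    marker = "".join("|" if a == b else "*" for a, b in zip(nat, var))
    helix = "".join("H" if topo.covers(i + 1) else "." for i in range(len(nat)))
    gutter = max(len(rec.native.id), len(rec.variant.id), 2)
    blocks = []
    for start in range(0, len(nat), width):
        end = min(start + width, len(nat))
        blocks.append(
            "\n".join(
                [
                    f"{'TM'.ljust(gutter)}  {helix[start:end]}",
                    f"{rec.native.id.ljust(gutter)}  {nat[start:end]}",
                    f"{''.ljust(gutter)}  {marker[start:end]}",
                    f"{rec.variant.id.ljust(gutter)}  {var[start:end]}",
                ]
            )
        )
    return "\n\n".join(blocks) + "\n"


def parse_alignment(text: str) -> tuple[str, str, str]:
    """Recover (native residues, marker line, variant residues) from a block text."""
    nat, marker, var = [], [], []
    for block in text.strip().split("\n\n"):
        lines = block.splitlines()
        if len(lines) != 4:
            raise ValueError("malformed alignment block")
        # the marker line is blank-gutter + markers, so it locates the sequence column
        start = len(lines[2]) - len(lines[2].lstrip())
        nat.append(lines[1][start:])
        marker.append(lines[2][start:])
        var.append(lines[3][start:])
    return "".join(nat), "".join(marker), "".join(var)


# --------------------------------------------------------------------------
# Topology and FASTA I/O
# --------------------------------------------------------------------------

_TRANSMEM_RE = re.compile(r"TRANSMEM\s+(\d+)\.\.(\d+)")


def read_topology(text: str, dialect: str = "uniprot", sequence_id: str = "") -> TMTopology:
    """Parse TM spans from UniProt-style ``TRANSMEM a..b`` lines or 2-column TSV.

    Spans are 1-based inclusive, sorted, and validated (overlaps rejected).
    """
    spans: list[tuple[int, int]] = []
    if dialect == "uniprot":
        for m in _TRANSMEM_RE.finditer(text):
            spans.append((int(m.group(1)), int(m.group(2))))
    elif dialect == "tsv":
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"expected 2 columns, got {len(fields)}: {line!r}")
            try:
                spans.append((int(fields[0]), int(fields[1])))
            except ValueError as exc:
                raise ValueError(f"non-numeric span fields in line {line!r}") from exc
    else:
        raise ValueError(f"unknown topology dialect {dialect!r}")
    spans.sort()
    return TMTopology(sequence_id=sequence_id, spans=tuple(spans))


def read_topology_table(text: str) -> dict[str, TMTopology]:
    """Parse a 3-column TSV (sequence id, start, end) into per-id topologies."""
    by_id: dict[str, list[tuple[int, int]]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 3:
            raise ValueError(f"expected 3 columns (id, start, end): {line!r}")
        try:
            by_id.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
        except ValueError as exc:
            raise ValueError(f"non-numeric span fields in line {line!r}") from exc
    return {
        sid: TMTopology(sequence_id=sid, spans=tuple(sorted(spans)))
        for sid, spans in by_id.items()
    }


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out = []
    for r in records:
        desc = r.description[len(r.id):].strip() if r.description.startswith(r.id) else r.description
        out.append(ProteinSequence(id=r.id, residues=str(r.seq).upper(), description=desc))
    return out


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description) for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")  # wraps at 60 columns
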