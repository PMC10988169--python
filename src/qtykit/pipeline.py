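"""End-to-end study orchestration.

A study manifest lists proteins, each with a sequence, a TM annotation, and
optionally a native and a variant structure.  ``run_report`` produces one
row per protein with the sequence characteristics of the QTY comparison
(pI, MW, GRAVY, variation percentages) and, when structures are given, the
whole-protein and TM-domain-only superposition RMSDs.  Failures are
isolated per entry: one bad structure must not abort a six-protein batch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import sequence as seqmod
from .sequence import ProteinSequence, TMTopology, QTYRecord, qty_transform
from .structure import StructureModel, read_structure, superpose_structures

logger = logging.getLogger(__name__)

#: Fixed report schema (stable column order).
REPORT_COLUMNS = [
    "id", "length", "n_tm_spans",
    "pI_native", "pI_qty", "MW_native", "MW_qty",
    "GRAVY_native", "GRAVY_qty",
    "total_variation_pct", "tm_variation_pct",
    "rmsd_all", "rmsd_refined", "n_pairs_used",
    "tm_rmsd_all", "tm_rmsd_refined", "tm_n_pairs_used",
    "error",
]


@dataclass(frozen=True)
class ManifestEntry:
    id: str
    fasta: str
    topology: str
    native_structure: str | None = None
    native_chain: str | None = None
    variant_structure: str | None = None
    variant_chain: str | None = None


@dataclass(frozen=True)
class StudyOptions:
    cycles: int = 5
    reject_factor: float = 2.0
    tm_only: bool = True  # additionally report TM-domain-only RMSDs
    mode: str = "by_resnum"
    output_dir: str = "."


@dataclass(frozen=True)
class StudyManifest:
    entries: tuple[ManifestEntry, ...]
    options: StudyOptions = StudyOptions()

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("manifest entry ids must be unique")
        for e in self.entries:
            paths = [p for p in (e.fasta, e.topology, e.native_structure, e.variant_structure) if p]
            if len(set(paths)) != len(paths):
                raise ValueError(f"entry {e.id!r}: paths must be distinct")


def load_manifest(path: str | Path) -> StudyManifest:
    """Load a YAML or JSON manifest (``entries`` list + optional ``options``)."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict) or "entries" not in data:
        raise ValueError(f"manifest {path} must be a mapping with an 'entries' list")
    base = Path(path).parent
    entries = []
    for raw in data["entries"]:
        raw = dict(raw)
        for key in ("fasta", "topology", "native_structure", "variant_structure"):
            if raw.get(key):
                raw[key] = str((base / raw[key]))
        entries.append(ManifestEntry(**raw))
    options = StudyOptions(**data.get("options", {}))
    return StudyManifest(entries=tuple(entries), options=options)


def _load_entry_inputs(entry: ManifestEntry) -> tuple[ProteinSequence, TMTopology]:
    seqs = seqmod.read_fasta(entry.fasta)
    match = [s for s in seqs if s.id == entry.id] or seqs
    seq = match[0]
    text = Path(entry.topology).read_text()
    dialect = "uniprot" if "TRANSMEM" in text else "tsv"
    topo = seqmod.read_topology(text, dialect=dialect, sequence_id=seq.id)
    return seq, topo


def _structure_cells(entry: ManifestEntry, topo: TMTopology, opts: StudyOptions) -> dict:
    cells: dict = {}
    if not (entry.native_structure and entry.variant_structure):
        return cells
    fmt_of = lambda p: "mmcif" if str(p).endswith((".cif", ".mmcif")) else "pdb"
    native = read_structure(entry.native_structure, format=fmt_of(entry.native_structure))
    variant = read_structure(entry.variant_structure, format=fmt_of(entry.variant_structure))
    res, _ = superpose_structures(
        native, variant, chain_a=entry.native_chain, chain_b=entry.variant_chain,
        mode=opts.mode, cycles=opts.cycles, reject_factor=opts.reject_factor,
    )
    cells.update(
        rmsd_all=round(res.rmsd_all, 3), rmsd_refined=round(res.rmsd_refined, 3),
        n_pairs_used=res.n_used_pairs,
    )
    if opts.tm_only and topo.spans:
        res_tm, _ = superpose_structures(
            native, variant, chain_a=entry.native_chain, chain_b=entry.variant_chain,
            mode=opts.mode, tm_only=True, topo=topo,
            cycles=opts.cycles, reject_factor=opts.reject_factor,
        )
        cells.update(
            tm_rmsd_all=round(res_tm.rmsd_all, 3),
            tm_rmsd_refined=round(res_tm.rmsd_refined, 3),
            tm_n_pairs_used=res_tm.n_used_pairs,
        )
    return cells


def run_report(manifest: StudyManifest) -> pd.DataFrame:
    """One row per manifest entry with the full QTY comparison.

    Sequence characteristics are rounded to 2 decimals and RMSDs to 3, so a
    rerun on identical inputs is byte-identical.  A failing entry yields a
    row with its error message; the run aborts only if every entry fails.
    """
    rows = []
    n_failed = 0
    for entry in manifest.entries:
        row: dict = {c: None for c in REPORT_COLUMNS}
        row["id"] = entry.id
        try:
            seq, topo = _load_entry_inputs(entry)
            rec = qty_transform(seq, topo)
            m = rec.metrics
            row.update(
                length=len(seq), n_tm_spans=len(topo.spans),
                pI_native=round(m.pI_native, 2), pI_qty=round(m.pI_variant, 2),
                MW_native=round(m.mw_native, 2), MW_qty=round(m.mw_variant, 2),
                GRAVY_native=round(m.gravy_native, 3), GRAVY_qty=round(m.gravy_variant, 3),
                total_variation_pct=m.total_variation_pct,
                tm_variation_pct=m.tm_variation_pct,
            )
            row.update(_structure_cells(entry, topo, manifest.options))
        except Exception as exc:  # noqa: BLE001 - per-entry isolation is the contract
            n_failed += 1
            row["error"] = str(exc)
            logger.error("entry %s failed: %s", entry.id, exc)
        rows.append(row)
    if n_failed == len(manifest.entries):
        raise RuntimeError("all manifest entries failed")
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(df: pd.DataFrame, path: str | Path, fmt: str = "tsv") -> None:
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        df.to_json(path, orient="records", indent=2)
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def run_transform(
    fasta_path: str | Path, topology_path: str | Path, out_dir: str | Path
) -> tuple[list[QTYRecord], list[str]]:
    """Apply the QTY code to every record of a FASTA file.

    Writes ``qty_variants.fasta`` (ids suffixed ``_QTY``) and
    ``qty_substitutions.tsv`` (id, position, from, to) to ``out_dir``.
    The topology file is either a 2-column TSV / UniProt-style annotation
    (single-record FASTA) or a 3-column TSV keyed by sequence id.
    Records without a topology fail individually; the error list reports
    them while other records still succeed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seqs = seqmod.read_fasta(fasta_path)
    text = Path(topology_path).read_text()

    topologies: dict[str, TMTopology] = {}
    if "TRANSMEM" in text:
        if len(seqs) > 1:
            raise ValueError("UniProt-style topology files apply to a single-record FASTA")
        topologies[seqs[0].id] = seqmod.read_topology(text, "uniprot", sequence_id=seqs[0].id)
    else:
        ncols = len(text.split("\n", 1)[0].split())
        if ncols == 3:
            topologies = seqmod.read_topology_table(text)
        else:
            if len(seqs) > 1:
                raise ValueError("2-column topology TSV applies to a single-record FASTA; "
                                 "use 3 columns (id, start, end) for multi-record input")
            topologies[seqs[0].id] = seqmod.read_topology(text, "tsv", sequence_id=seqs[0].id)

    records, errors, sub_rows = [], [], []
    for seq in seqs:
        topo = topologies.get(seq.id)
        if topo is None:
            errors.append(f"{seq.id}: no topology found")
            logger.error("no topology for %s", seq.id)
            continue
        try:
            rec = qty_transform(seq, topo)
        except Exception as exc:  # noqa: BLE001
            errors.append(f"{seq.id}: {exc}")
            logger.error("transform failed for %s: %s", seq.id, exc)
            continue
        records.append(rec)
        sub_rows.extend(
            {"id": seq.id, "position": s.position, "from": s.from_res, "to": s.to_res}
            for s in rec.substitutions
        )
    if records:
        seqmod.write_fasta([r.variant for r in records], out_dir / "qty_variants.fasta")
        pd.DataFrame(sub_rows, columns=["id", "position", "from", "to"]).to_csv(
            out_dir / "qty_substitutions.tsv", sep="\t", index=False
        )
    if not records:
        raise RuntimeError("every record failed: " + "; ".join(errors))
    return records, errors
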