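"""Readers and writers for the screen's tabular and genomic formats.

Text formats only: annotation TSVs, wide 0/1 matrix TSVs, BED6 fragment
intervals with a companion label TSV, GFF3 gene models (via gffutils),
expression-evidence TSVs, tissue tables, and JSON reports.  GFF3 is
1-based inclusive on disk and converted to the package's internal 0-based
half-open coordinates on ingest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

from .genomic_binning import (
    ExpressionEvidence,
    FragmentRecord,
    GeneModel,
)
from .ontology import DomainOntology, StageAxis
from .pattern_matrix import AnnotationRecord, OverlayMatrix, PatternMatrix
from .temporal import TissueTable

__all__ = [
    "read_annotation_tsv",
    "write_annotation_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_overlay_tsv",
    "read_gene_models_gff3",
    "write_gene_models_gff3",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_fragments_bed",
    "write_fragments_bed",
    "read_labels_tsv",
    "write_labels_tsv",
    "write_bins_tsv",
    "read_counts_tsv",
    "read_tissue_tsv",
    "write_tissue_tsv",
    "write_json",
]

_ANNOT_COLS = ["subject_id", "subject_kind", "gene_id", "stage", "domains"]


def read_annotation_tsv(path: str | Path) -> list[AnnotationRecord]:
    """Read annotation records: one row per (subject, stage), domains ';'-joined."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records = []
    for row in df.itertuples(index=False):
        domains = frozenset(d for d in str(row.domains).split(";") if d)
        records.append(
            AnnotationRecord(
                subject_id=row.subject_id,
                stage=row.stage,
                domains=domains,
                subject_kind=row.subject_kind or "line",
                gene_id=row.gene_id or None,
            )
        )
    return records


def write_annotation_tsv(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "subject_kind": r.subject_kind,
            "gene_id": r.gene_id or "",
            "stage": r.stage,
            "domains": ";".join(sorted(r.domains)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_ANNOT_COLS).to_csv(path, sep="\t", index=False)


def write_matrix_tsv(
    matrices: Mapping[str, PatternMatrix] | Sequence[PatternMatrix],
    path: str | Path,
) -> None:
    """Wide binary matrix: one row per (subject, stage), one column per domain."""
    if isinstance(matrices, Mapping):
        matrices = list(matrices.values())
    frames = []
    for m in matrices:
        df = m.data.copy()
        df.insert(0, "subject_id", m.subject_id)
        df.insert(1, "stage", df.index)
        frames.append(df.reset_index(drop=True))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_matrix_tsv(
    path: str | Path,
    ontology: DomainOntology | None = None,
    axis: StageAxis | None = None,
) -> dict[str, PatternMatrix]:
    ontology = ontology or DomainOntology()
    axis = axis or StageAxis()
    df = pd.read_csv(path, sep="\t")
    out: dict[str, PatternMatrix] = {}
    for subject_id, grp in df.groupby("subject_id", sort=False):
        pm = PatternMatrix.zeros(str(subject_id), ontology, axis)
        for row in grp.itertuples(index=False):
            for d in ontology.codes:
                if getattr(row, d, 0):
                    pm.set_bit(row.stage, d)
        out[str(subject_id)] = pm
    return out


def write_overlay_tsv(
    overlays: Mapping[str, OverlayMatrix] | Sequence[OverlayMatrix],
    path: str | Path,
) -> None:
    """Overlay codes 0/1/2/3 = NONE/ENDO_ONLY/GFP_ONLY/BOTH, wide layout."""
    if isinstance(overlays, Mapping):
        overlays = list(overlays.values())
    frames = []
    for ov in overlays:
        df = ov.codes.copy()
        df.insert(0, "gene_id", ov.gene_id)
        df.insert(1, "stage", df.index)
        frames.append(df.reset_index(drop=True))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models


def read_gene_models_gff3(path: str | Path) -> dict[str, GeneModel]:
    """Read gene/mRNA/exon features into isoform-resolved gene models."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        isoforms: dict[str, tuple[tuple[int, int], ...]] = {}
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = tuple(
                (e.start - 1, e.end)  # GFF3 1-based inclusive -> half-open
                for e in db.children(mrna, featuretype="exon", order_by="start")
            )
            if exons:
                isoforms[mrna.id] = exons
        if isoforms:
            models[gene.id] = GeneModel(gene.id, gene.seqid, gene.strand, isoforms)
    return models


def write_gene_models_gff3(
    models: Mapping[str, GeneModel], path: str | Path
) -> None:
    lines = ["##gff-version 3"]
    for gene_id in sorted(models):
        m = models[gene_id]
        g_lo = min(a for ex in m.isoforms.values() for a, _ in ex)
        g_hi = max(b for ex in m.isoforms.values() for _, b in ex)
        lines.append(
            f"{m.chrom}\tcrmscreen\tgene\t{g_lo + 1}\t{g_hi}\t.\t{m.strand}\t.\t"
            f"ID={gene_id}"
        )
        for iso in sorted(m.isoforms):
            exons = sorted(m.isoforms[iso])
            t_lo, t_hi = exons[0][0], exons[-1][1]
            lines.append(
                f"{m.chrom}\tcrmscreen\tmRNA\t{t_lo + 1}\t{t_hi}\t.\t{m.strand}\t.\t"
                f"ID={iso};Parent={gene_id}"
            )
            for k, (a, b) in enumerate(exons):
                lines.append(
                    f"{m.chrom}\tcrmscreen\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t"
                    f"ID={iso}.e{k + 1};Parent={iso}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression_tsv(path: str | Path) -> ExpressionEvidence:
    """Expression-evidence table: isoform_id, early, mid, late (0/1)."""
    df = pd.read_csv(path, sep="\t")
    flags = {
        str(r.isoform_id): {
            "early": bool(int(r.early)),
            "mid": bool(int(r.mid)),
            "late": bool(int(r.late)),
        }
        for r in df.itertuples(index=False)
    }
    return ExpressionEvidence(flags)


def write_expression_tsv(evidence: ExpressionEvidence, path: str | Path) -> None:
    rows = [
        {
            "isoform_id": iso,
            "early": int(f.get("early", False)),
            "mid": int(f.get("mid", False)),
            "late": int(f.get("late", False)),
        }
        for iso, f in sorted(evidence.flags.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# fragments


def write_fragments_bed(frags: Sequence[FragmentRecord], path: str | Path) -> None:
    """BED6: chrom, start, end, name=fragment_id, score=0, strand='.'."""
    with open(path, "w") as fh:
        for f in frags:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.fragment_id}\t0\t.\n")


def read_fragments_bed(
    path: str | Path, labels: pd.DataFrame | None = None
) -> list[FragmentRecord]:
    """Read BED6 fragments; join line/gene/GFP metadata from a label table."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "start": int, "end": int, "name": str},
    )
    meta = {}
    if labels is not None:
        meta = labels.set_index("fragment_id").to_dict("index")
    frags = []
    for row in df.itertuples(index=False):
        info = meta.get(row.name, {})
        frags.append(
            FragmentRecord(
                fragment_id=row.name,
                line_id=str(info.get("line_id", row.name)),
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                gene_id=str(info.get("gene_id", "")),
                gfp_positive=(
                    bool(int(info["gfp"])) if "gfp" in info else None
                ),
            )
        )
    return frags


def read_labels_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"fragment_id": str})
    for col in ("fragment_id", "line_id", "gene_id", "gfp"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def write_labels_tsv(frags: Sequence[FragmentRecord], path: str | Path) -> None:
    rows = [
        {
            "fragment_id": f.fragment_id,
            "line_id": f.line_id,
            "gene_id": f.gene_id,
            "gfp": int(bool(f.gfp_positive)),
        }
        for f in frags
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bins_tsv(frags: Sequence[FragmentRecord], path: str | Path) -> None:
    rows = [
        {
            "fragment_id": f.fragment_id,
            "gene_id": f.gene_id,
            "bin": f.bin,
            "length_bp": f.length_bp,
            "gfp": int(bool(f.gfp_positive)),
        }
        for f in frags
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> "pd.DataFrame":
    """Standalone counts table: bin, n_total, n_positive."""
    df = pd.read_csv(path, sep="\t")
    for col in ("bin", "n_total", "n_positive"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# tissues / JSON


def read_tissue_tsv(path: str | Path) -> TissueTable:
    df = pd.read_csv(path, sep="\t").set_index("line_id")
    return TissueTable(df)


def write_tissue_tsv(table: TissueTable, path: str | Path) -> None:
    df = table.data.copy()
    df.insert(0, "line_id", df.index)
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
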