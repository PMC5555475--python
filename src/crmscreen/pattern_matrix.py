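"""Binary spatiotemporal expression matrices and recapitulation scoring.

Each annotated subject (a GAL4 reporter line or an endogenous gene) is
encoded as a stage x domain matrix of bits: 1 where expression was observed
in that domain at that stage, 0 otherwise.  Matrices for the individual
reporter lines of a gene are collapsed (bitwise OR) into a single
gene-level reporter pattern, restricted to the stages where the endogenous
gene itself is expressed.  Overlaying the collapsed reporter matrix on the
endogenous in-situ matrix classifies every cell as NONE / ENDO_ONLY /
GFP_ONLY / BOTH, from which per-domain percent recapitulation and per-gene
full/partial/none calls are derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import DomainOntology, StageAxis

__all__ = [
    "PatternMatrix",
    "OverlayCode",
    "OverlayMatrix",
    "RecapCall",
    "RecapReport",
    "AnnotationRecord",
    "encode_pattern_table",
    "collapse_lines",
    "overlay",
    "percent_recapitulation",
    "recapitulation_call",
]

#: Spatial domains that should not normally co-occur with ``U`` (uniform
#: expression in all follicle cells) at the same stage.
_SPATIAL_DOMAINS = frozenset(
    {"AD", "AV", "M", "R", "F", "D", "P", "SC"}
)


class OverlayCode(IntEnum):
    """Cell-wise comparison of endogenous vs reporter bits."""

    NONE = 0       # (endo=0, gfp=0)
    ENDO_ONLY = 1  # (endo=1, gfp=0)
    GFP_ONLY = 2   # (endo=0, gfp=1)
    BOTH = 3       # (endo=1, gfp=1)


class RecapCall(str):
    pass


FULL = "FULL"
PARTIAL = "PARTIAL"
NONE = "NONE"


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotation row: a subject expresses a set of domains at a stage."""

    subject_id: str
    stage: str
    domains: frozenset[str]
    subject_kind: str = "line"  # "line" or "gene"
    gene_id: str | None = None


@dataclass
class PatternMatrix:
    """Binary stage x domain expression matrix for one subject.

    ``data`` is a pandas DataFrame indexed by the full stage axis with one
    column per ontology domain, dtype int8, entries in {0, 1}.  An optional
    ``observed`` mask of the same shape distinguishes stages that were
    assayed (True) from stages with no observation; by default every cell
    is treated as observed-absent.
    """

    subject_id: str
    data: pd.DataFrame
    ontology: DomainOntology = field(default_factory=DomainOntology)
    axis: StageAxis = field(default_factory=StageAxis)
    observed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        expected_index = list(self.axis.stages)
        expected_cols = list(self.ontology.codes)
        if list(self.data.index) != expected_index or list(self.data.columns) != expected_cols:
            self.data = self.data.reindex(
                index=expected_index, columns=expected_cols, fill_value=0
            )
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{self.subject_id}: matrix entries must be 0 or 1")
        self.data = self.data.astype(np.int8)

    @classmethod
    def zeros(
        cls,
        subject_id: str,
        ontology: DomainOntology | None = None,
        axis: StageAxis | None = None,
    ) -> "PatternMatrix":
        ontology = ontology or DomainOntology()
        axis = axis or StageAxis()
        data = pd.DataFrame(
            np.zeros((len(axis), len(ontology)), dtype=np.int8),
            index=list(axis.stages),
            columns=list(ontology.codes),
        )
        return cls(subject_id, data, ontology, axis)

    def set_bit(self, stage: str, domain: str, value: int = 1) -> None:
        if stage not in self.axis:
            raise ValueError(f"unknown stage {stage!r}")
        if domain not in self.ontology:
            raise ValueError(f"unknown domain {domain!r}")
        self.data.loc[stage, domain] = int(bool(value))

    def nonzero_cells(self) -> set[tuple[str, str]]:
        rows, cols = np.nonzero(self.data.to_numpy())
        return {
            (self.data.index[r], self.data.columns[c]) for r, c in zip(rows, cols)
        }

    def stage_domains(self, stage: str) -> frozenset[str]:
        """Set of domains expressed at a stage (the stage's 'pattern')."""
        row = self.data.loc[stage]
        return frozenset(row.index[row.to_numpy() == 1])

    def count_bits(self) -> int:
        return int(self.data.to_numpy().sum())

    def same_axes(self, other: "PatternMatrix") -> bool:
        return (
            self.axis.stages == other.axis.stages
            and self.ontology.codes == other.ontology.codes
        )

    def copy(self) -> "PatternMatrix":
        return PatternMatrix(
            self.subject_id,
            self.data.copy(),
            self.ontology,
            self.axis,
            None if self.observed is None else self.observed.copy(),
        )


@dataclass
class OverlayMatrix:
    """Cell-wise overlay of an endogenous matrix with a reporter matrix."""

    gene_id: str
    codes: pd.DataFrame  # int8 entries holding OverlayCode values
    ontology: DomainOntology
    axis: StageAxis

    def count(self, code: OverlayCode) -> int:
        return int((self.codes.to_numpy() == int(code)).sum())

    def count_in_domain(self, domain: str, code: OverlayCode) -> int:
        return int((self.codes[domain].to_numpy() == int(code)).sum())

    @property
    def n_endogenous(self) -> int:
        return self.count(OverlayCode.ENDO_ONLY) + self.count(OverlayCode.BOTH)


@dataclass
class RecapReport:
    """Per-domain percent recapitulation and per-gene overlap calls.

    ``per_domain_pct`` maps each domain with at least one endogenous-positive
    cell to 100 x (#BOTH) / (#endogenous-positive cells); domains with no
    endogenous signal are absent (undefined), never reported as 0.
    """

    per_domain_pct: dict[str, float]
    per_gene_call: dict[str, str]
    per_domain_counts: dict[str, tuple[int, int]]  # domain -> (both, endo_total)

    def n_calls(self, call: str) -> int:
        return sum(1 for c in self.per_gene_call.values() if c == call)


def encode_pattern_table(
    rows: Iterable[AnnotationRecord],
    ontology: DomainOntology | None = None,
    axis: StageAxis | None = None,
    warn_uniform_conflict: bool = True,
) -> dict[str, PatternMatrix]:
    """Encode annotation records into one binary matrix per subject.

    Every (stage, domain) cell not mentioned by any record is 0.  Unknown
    stage or domain labels raise ``ValueError`` naming the offending record.
    A warning (not an error) is emitted when ``U`` (uniform) co-occurs with
    spatial domains at the same stage, which is usually an annotation slip.
    """
    ontology = ontology or DomainOntology()
    axis = axis or StageAxis()
    rows = list(rows)
    axis.validate_labels([r.stage for r in rows])
    matrices: dict[str, PatternMatrix] = {}
    for rec in rows:
        if rec.stage not in axis:
            raise ValueError(f"record {rec}: unknown stage {rec.stage!r}")
        bad = [d for d in rec.domains if d not in ontology]
        if bad:
            raise ValueError(f"record {rec}: unknown domain label(s) {bad}")
        pm = matrices.get(rec.subject_id)
        if pm is None:
            pm = PatternMatrix.zeros(rec.subject_id, ontology, axis)
            matrices[rec.subject_id] = pm
        for d in rec.domains:
            pm.set_bit(rec.stage, d)
        if warn_uniform_conflict and "U" in rec.domains:
            conflict = rec.domains & _SPATIAL_DOMAINS
            if conflict:
                warnings.warn(
                    f"{rec.subject_id}@{rec.stage}: uniform (U) co-occurs with "
                    f"spatial domain(s) {sorted(conflict)}",
                    stacklevel=2,
                )
    return matrices


def collapse_lines(
    line_matrices: Sequence[PatternMatrix] | Mapping[str, PatternMatrix],
    endo: PatternMatrix,
    gene_id: str | None = None,
) -> PatternMatrix:
    """Collapse reporter-line matrices to a single gene-level matrix.

    Bitwise OR across lines, then zero every stage at which the endogenous
    pattern has no expression: a reporter is only comparable to the gene at
    stages where the gene itself is detected.
    """
    if isinstance(line_matrices, Mapping):
        line_matrices = list(line_matrices.values())
    if not line_matrices:
        raise ValueError("no line matrices to collapse")
    for m in line_matrices:
        if not m.same_axes(endo):
            raise ValueError(
                f"line {m.subject_id} and endogenous matrix use different axes"
            )
    stacked = np.stack([m.data.to_numpy() for m in line_matrices])
    merged = stacked.max(axis=0)
    endo_active = endo.data.to_numpy().any(axis=1)
    merged[~endo_active, :] = 0
    data = pd.DataFrame(
        merged.astype(np.int8),
        index=list(endo.axis.stages),
        columns=list(endo.ontology.codes),
    )
    return PatternMatrix(
        gene_id or endo.subject_id, data, endo.ontology, endo.axis
    )


def overlay(gfp: PatternMatrix, endo: PatternMatrix) -> OverlayMatrix:
    """Cell-wise overlay: code = endo_bit + 2 * gfp_bit (NONE..BOTH)."""
    if not gfp.same_axes(endo):
        raise ValueError("reporter and endogenous matrices use different axes")
    codes = endo.data.to_numpy().astype(np.int8) + 2 * gfp.data.to_numpy().astype(np.int8)
    return OverlayMatrix(
        endo.subject_id,
        pd.DataFrame(
            codes, index=list(endo.axis.stages), columns=list(endo.ontology.codes)
        ),
        endo.ontology,
        endo.axis,
    )


def percent_recapitulation(
    overlays: Sequence[OverlayMatrix] | Mapping[str, OverlayMatrix],
    per_gene_average: bool = False,
) -> RecapReport:
    """Per-domain percent of endogenous-positive cells hit by the reporter.

    Default pools endogenous-positive cells per domain across genes and
    stages; ``per_gene_average=True`` instead computes the percentage per
    gene and averages over genes with endogenous signal in the domain.
    """
    if isinstance(overlays, Mapping):
        overlays = list(overlays.values())
    if not overlays:
        raise ValueError("need at least one overlay")
    domains = overlays[0].ontology.codes
    per_domain_pct: dict[str, float] = {}
    per_domain_counts: dict[str, tuple[int, int]] = {}
    for d in domains:
        both = [ov.count_in_domain(d, OverlayCode.BOTH) for ov in overlays]
        endo = [
            ov.count_in_domain(d, OverlayCode.BOTH)
            + ov.count_in_domain(d, OverlayCode.ENDO_ONLY)
            for ov in overlays
        ]
        total_endo = sum(endo)
        per_domain_counts[d] = (sum(both), total_endo)
        if total_endo == 0:
            continue  # undefined, deliberately absent from the report
        if per_gene_average:
            fracs = [b / e for b, e in zip(both, endo) if e > 0]
            per_domain_pct[d] = 100.0 * float(np.mean(fracs))
        else:
            per_domain_pct[d] = 100.0 * sum(both) / total_endo
    per_gene_call = {ov.gene_id: recapitulation_call(ov) for ov in overlays}
    return RecapReport(per_domain_pct, per_gene_call, per_domain_counts)


def recapitulation_call(ov: OverlayMatrix) -> str:
    """FULL / PARTIAL / NONE call for one gene's overlay.

    FULL: every endogenous-positive cell is also reporter-positive.
    NONE: no cell is positive in both.  PARTIAL: anything in between.
    An overlay with zero endogenous cells has no defined call.
    """
    n_both = ov.count(OverlayCode.BOTH)
    n_endo_only = ov.count(OverlayCode.ENDO_ONLY)
    if n_both + n_endo_only == 0:
        raise ValueError(
            f"{ov.gene_id}: overlay has no endogenous-positive cells; "
            "recapitulation is undefined"
        )
    if n_endo_only == 0:
        return FULL
    if n_both == 0:
        return NONE
    return PARTIAL
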