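"""Pattern persistence and change accounting across developmental stages.

A line's *pattern* at a stage is the set of domains it expresses there; a
(line, stage) pair with a nonempty set is one *line-pattern instance*.
Walking each line along the stage axis, every instance is classified on
arrival as

* ``persist_same``    — expressed at the previous stage with the same set,
* ``persist_changed`` — expressed at the previous stage with a different set,
* ``new``             — the line's first expressed stage,
* ``reappear_same``   — re-expression after >= 1 empty stage, same set as
  at the last expressed stage,
* ``reappear_changed``— re-expression after a gap with a different set,

and on departure as persisting (same or changed) into the next stage or
``dropped`` (next stage empty, or end of axis).  Change events are
attributed to the earlier instance of the pair.  The inflow and outflow
tallies are conserved stage by stage, which the test-suite checks on
random data.

The module also reports per-domain expression durations, the distribution
of distinct domains per line (a proxy for the number of separable
cis-regulatory modules in a fragment), and cross-tissue expression breadth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import StageAxis
from .pattern_matrix import PatternMatrix

__all__ = [
    "StageFlow",
    "TransitionSummary",
    "TissueTable",
    "TissueBreadth",
    "transition_summary",
    "domain_duration",
    "domains_per_line_histogram",
    "tissue_breadth",
    "DEFAULT_TISSUES",
]

DEFAULT_TISSUES: tuple[str, ...] = (
    "brain", "vnc", "larval_cns", "embryo", "discs", "ovary",
)


@dataclass
class StageFlow:
    """Arrival/departure tallies for one stage."""

    expressed: int = 0
    # arrivals
    persist_same_in: int = 0
    persist_changed_in: int = 0
    new: int = 0
    reappear_same: int = 0
    reappear_changed: int = 0
    # departures
    persist_same_out: int = 0
    persist_changed_out: int = 0
    dropped: int = 0

    def check(self) -> None:
        inflow = (
            self.persist_same_in
            + self.persist_changed_in
            + self.new
            + self.reappear_same
            + self.reappear_changed
        )
        outflow = self.persist_same_out + self.persist_changed_out + self.dropped
        if inflow != self.expressed or outflow != self.expressed:
            raise AssertionError(
                f"stage flow not conserved: expressed={self.expressed} "
                f"inflow={inflow} outflow={outflow}"
            )


@dataclass
class TransitionSummary:
    """Per-stage flows plus screen-level totals."""

    per_stage: dict[str, StageFlow]
    instances: int
    changed_next: int
    changed_gap: int

    @property
    def changed_total(self) -> int:
        return self.changed_next + self.changed_gap

    @property
    def changed_fraction(self) -> float:
        return self.changed_total / self.instances if self.instances else 0.0

    def check_conservation(self) -> None:
        for flow in self.per_stage.values():
            flow.check()
        if self.instances != sum(f.expressed for f in self.per_stage.values()):
            raise AssertionError("instances != sum of per-stage expressed counts")

    def to_dict(self) -> dict:
        return {
            "instances": self.instances,
            "changed_next": self.changed_next,
            "changed_gap": self.changed_gap,
            "changed_total": self.changed_total,
            "changed_percent": round(100 * self.changed_fraction, 1),
            "stages": {
                s: {
                    "expressed": f.expressed,
                    "persist_same_in": f.persist_same_in,
                    "persist_changed_in": f.persist_changed_in,
                    "new": f.new,
                    "reappear_same": f.reappear_same,
                    "reappear_changed": f.reappear_changed,
                    "persist_same_out": f.persist_same_out,
                    "persist_changed_out": f.persist_changed_out,
                    "dropped": f.dropped,
                }
                for s, f in self.per_stage.items()
            },
        }


def transition_summary(
    matrices: Sequence[PatternMatrix] | Mapping[str, PatternMatrix],
    axis: StageAxis | None = None,
) -> TransitionSummary:
    """Tally pattern persistence, change, drop, gain, and reappearance."""
    if isinstance(matrices, Mapping):
        matrices = list(matrices.values())
    if matrices:
        axis = axis or matrices[0].axis
        for m in matrices:
            if m.axis.stages != axis.stages:
                raise ValueError(f"{m.subject_id}: stage axis differs")
    elif axis is None:
        axis = StageAxis()
    stages = list(axis.stages)
    flows = {s: StageFlow() for s in stages}
    changed_next = 0
    changed_gap = 0
    instances = 0
    for m in matrices:
        patterns = [m.stage_domains(s) for s in stages]
        last_expressed_idx: int | None = None
        for i, (s, pat) in enumerate(zip(stages, patterns)):
            if not pat:
                continue
            flow = flows[s]
            flow.expressed += 1
            instances += 1
            # arrival classification
            if last_expressed_idx is None:
                flow.new += 1
            elif last_expressed_idx == i - 1:
                if patterns[last_expressed_idx] == pat:
                    flow.persist_same_in += 1
                else:
                    flow.persist_changed_in += 1
            else:
                if patterns[last_expressed_idx] == pat:
                    flow.reappear_same += 1
                else:
                    flow.reappear_changed += 1
            # departure classification, attributed to this (earlier) instance
            nxt = patterns[i + 1] if i + 1 < len(stages) else frozenset()
            if not nxt:
                flow.dropped += 1
                # a later different pattern after a gap counts as a change
                # charged to this instance only if this is the last stage
                # before the gap
                j = next(
                    (k for k in range(i + 1, len(stages)) if patterns[k]), None
                )
                if j is not None and patterns[j] != pat:
                    changed_gap += 1
            elif nxt == pat:
                flow.persist_same_out += 1
            else:
                flow.persist_changed_out += 1
                changed_next += 1
            last_expressed_idx = i
    return TransitionSummary(flows, instances, changed_next, changed_gap)


def domain_duration(
    matrices: Sequence[PatternMatrix] | Mapping[str, PatternMatrix],
    mode: str = "total",
) -> pd.DataFrame:
    """Mean +/- SD of per-line stage counts for each expressed domain.

    ``mode="total"`` counts all stages with a 1-bit in the domain;
    ``mode="runs"`` instead measures the longest consecutive run.  Domains
    never expressed by any line are omitted.  SD is the population SD.
    """
    if isinstance(matrices, Mapping):
        matrices = list(matrices.values())
    if not matrices:
        raise ValueError("need at least one matrix")
    if mode not in ("total", "runs"):
        raise ValueError("mode must be 'total' or 'runs'")
    domains = matrices[0].ontology.codes
    rows = []
    for d in domains:
        counts = []
        for m in matrices:
            col = m.data[d].to_numpy()
            if not col.any():
                continue
            if mode == "total":
                counts.append(int(col.sum()))
            else:
                best = run = 0
                for v in col:
                    run = run + 1 if v else 0
                    best = max(best, run)
                counts.append(best)
        if counts:
            arr = np.asarray(counts, dtype=float)
            rows.append(
                {
                    "domain": d,
                    "n_lines": arr.size,
                    "mean_stages": float(arr.mean()),
                    "sd_stages": float(arr.std(ddof=0)),
                }
            )
    return pd.DataFrame(
        rows, columns=["domain", "n_lines", "mean_stages", "sd_stages"]
    ).set_index("domain")


def domains_per_line_histogram(
    matrices: Sequence[PatternMatrix] | Mapping[str, PatternMatrix],
) -> pd.DataFrame:
    """Distribution of distinct expressed domains per line.

    Counts domains with any 1-bit across all stages; returns counts and
    percent of lines per distinct-domain number.
    """
    if isinstance(matrices, Mapping):
        matrices = list(matrices.values())
    if not matrices:
        raise ValueError("need at least one matrix")
    per_line = [int((m.data.to_numpy().any(axis=0)).sum()) for m in matrices]
    counts = pd.Series(per_line).value_counts().sort_index()
    out = pd.DataFrame(
        {"n_lines": counts, "percent": 100.0 * counts / counts.sum()}
    )
    out.index.name = "n_domains"
    return out


@dataclass
class TissueTable:
    """Binary line x tissue expression table."""

    data: pd.DataFrame  # index line_id, columns tissues, entries {0,1}

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("tissue table entries must be 0 or 1")
        self.data = self.data.astype(np.int8)

    @property
    def tissues(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_lines(self) -> int:
        return len(self.data)


@dataclass
class TissueBreadth:
    """Cross-tissue expression summary for a screen."""

    per_tissue_percent: dict[str, float]
    n_tissues_histogram: dict[int, int]
    n_all_negative: int
    n_lines: int

    def to_dict(self) -> dict:
        return {
            "n_lines": self.n_lines,
            "per_tissue_percent": self.per_tissue_percent,
            "n_tissues_histogram": {
                str(k): v for k, v in self.n_tissues_histogram.items()
            },
            "n_all_negative": self.n_all_negative,
        }


def tissue_breadth(table: TissueTable) -> TissueBreadth:
    """Per-tissue positive percentages and per-line tissue-count histogram."""
    if table.n_lines == 0:
        raise ValueError("tissue table is empty")
    df = table.data
    per_tissue = {t: 100.0 * float(df[t].mean()) for t in df.columns}
    row_sums = df.sum(axis=1)
    hist = row_sums.value_counts().sort_index()
    return TissueBreadth(
        per_tissue_percent=per_tissue,
        n_tissues_histogram={int(k): int(v) for k, v in hist.items()},
        n_all_negative=int((row_sums == 0).sum()),
        n_lines=table.n_lines,
    )
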