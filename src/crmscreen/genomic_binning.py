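"""Positional binning of reporter fragments against gene models.

Each reporter fragment is associated with a gene and classified into one of
three positional bins relative to that gene's oogenesis-relevant isoform:

* ``PROXIMAL`` — upstream of the transcription start site (more precisely,
  5' of the first-intron donor site in gene orientation; midpoints inside
  exon 1 fall here),
* ``INTRON1``  — within the first intron,
* ``DISTAL``   — at or downstream of the start of exon 2.

The relevant isoform is the longest genomic-span isoform with expression
evidence during oogenesis (any of the early / mid / late egg-chamber stage
groups); its 5'-most position in gene orientation is the TSS.  First
introns shorter than ``min_intron_bp`` (default 300 bp, the design floor of
the fragment collection) do not define an INTRON1 zone.

Fragments are classified by their midpoint — a single deterministic rule
for the rare fragments straddling a zone boundary; the per-zone overlap
fractions are retained on each record for audit.

All internal coordinates are 0-based half-open; GFF3 input (1-based
inclusive) is converted on ingest.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PROXIMAL",
    "INTRON1",
    "DISTAL",
    "BINS",
    "GeneModel",
    "ExpressionEvidence",
    "LocusZones",
    "FragmentRecord",
    "BinCounts",
    "FragmentSizeStats",
    "select_tss_isoform",
    "locus_zones",
    "classify_fragment",
    "classify_fragments",
    "tally_bins",
    "fragment_size_stats",
]

PROXIMAL = "PROXIMAL"
INTRON1 = "INTRON1"
DISTAL = "DISTAL"
BINS: tuple[str, str, str] = (PROXIMAL, INTRON1, DISTAL)

STAGE_GROUPS: tuple[str, str, str] = ("early", "mid", "late")


@dataclass(frozen=True)
class GeneModel:
    """Isoform-resolved exon structure of one gene.

    ``isoforms`` maps isoform id to exon intervals (0-based half-open
    genomic coordinates), stored sorted 5'->3' in gene orientation: by
    ascending start on the + strand, descending on the - strand.
    """

    gene_id: str
    chrom: str
    strand: str
    isoforms: dict[str, tuple[tuple[int, int], ...]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.isoforms:
            raise ValueError(f"{self.gene_id}: needs at least one isoform")
        oriented: dict[str, tuple[tuple[int, int], ...]] = {}
        for iso, exons in self.isoforms.items():
            ex = sorted(
                (tuple(e) for e in exons),
                key=lambda e: e[0],
                reverse=(self.strand == "-"),
            )
            for a, b in ex:
                if b <= a:
                    raise ValueError(f"{self.gene_id}/{iso}: empty exon [{a},{b})")
            genomic = sorted(ex)
            for (a1, b1), (a2, b2) in zip(genomic, genomic[1:]):
                if a2 < b1:
                    raise ValueError(f"{self.gene_id}/{iso}: overlapping exons")
            oriented[iso] = tuple(ex)
        object.__setattr__(self, "isoforms", oriented)

    def span(self, isoform_id: str) -> int:
        exons = self.isoforms[isoform_id]
        lo = min(a for a, _ in exons)
        hi = max(b for _, b in exons)
        return hi - lo

    def tss(self, isoform_id: str) -> int:
        """5'-most genomic position of the isoform in gene orientation."""
        exons = self.isoforms[isoform_id]
        if self.strand == "+":
            return min(a for a, _ in exons)
        return max(b for _, b in exons)


@dataclass(frozen=True)
class ExpressionEvidence:
    """Per-isoform boolean expression flags for the three stage groups.

    Stage groups follow the egg-chamber RNA sampling design: ``early``
    (stage <= 9), ``mid`` (stages 10A-10B), ``late`` (stage >= 11).
    """

    flags: dict[str, dict[str, bool]]

    def is_expressed(self, isoform_id: str) -> bool:
        f = self.flags.get(isoform_id)
        return bool(f) and any(f.get(g, False) for g in STAGE_GROUPS)


@dataclass(frozen=True)
class LocusZones:
    """Zone boundaries of one locus, genomic coordinates plus orientation.

    In gene-oriented coordinates tss <= b1 <= b2: ``b1`` is the first-intron
    donor boundary (gene-oriented end of exon 1), ``b2`` the acceptor
    boundary (gene-oriented start of exon 2).  When ``has_intron1`` is
    false (single exon, or first intron below the minimum length) the
    INTRON1 bin is unreachable and ``b1`` alone splits PROXIMAL from DISTAL.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    b1: int
    b2: int
    has_intron1: bool

    def oriented(self, pos: float) -> float:
        """Map a genomic position onto the 5'->3' gene axis."""
        return pos if self.strand == "+" else -pos


@dataclass
class FragmentRecord:
    """One reporter fragment: interval, line id, GFP label, assigned bin."""

    fragment_id: str
    line_id: str
    chrom: str
    start: int
    end: int
    gene_id: str
    gfp_positive: bool | None = None
    bin: str | None = None
    zone_overlap: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"{self.fragment_id}: zero/negative length [{self.start},{self.end})"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class BinCounts:
    """Per-bin totals and GFP-positive counts for a screen."""

    n_total: dict[str, int]
    n_positive: dict[str, int]

    def __post_init__(self) -> None:
        for b in self.n_total:
            if not 0 <= self.n_positive.get(b, 0) <= self.n_total[b]:
                raise ValueError(f"bin {b}: positives exceed totals")

    @property
    def N(self) -> int:
        return sum(self.n_total.values())

    @property
    def K(self) -> int:
        return sum(self.n_positive.values())

    def as_vectors(self, order: Sequence[str] = BINS) -> tuple[np.ndarray, np.ndarray]:
        tot = np.array([self.n_total.get(b, 0) for b in order])
        pos = np.array([self.n_positive.get(b, 0) for b in order])
        return tot, pos


@dataclass(frozen=True)
class FragmentSizeStats:
    """Mean +/- SE fragment size per bin (kb) and pairwise Welch t-tests."""

    mean_kb: dict[str, float]
    se_kb: dict[str, float]
    n: dict[str, int]
    pairwise_p: dict[tuple[str, str], float]


def select_tss_isoform(
    model: GeneModel,
    evidence: ExpressionEvidence,
    override: str | None = None,
) -> tuple[str, int]:
    """Pick the isoform defining the gene's TSS for binning.

    Among isoforms with expression evidence in any stage group, the one
    with the greatest genomic span wins; span ties go to the 5'-most TSS,
    then the lexicographically smallest isoform id.  ``override`` names an
    isoform directly (for literature-curated TSS assignments) and skips the
    evidence requirement.
    """
    if override is not None:
        if override not in model.isoforms:
            raise KeyError(f"{model.gene_id}: override isoform {override!r} unknown")
        return override, model.tss(override)
    expressed = [iso for iso in model.isoforms if evidence.is_expressed(iso)]
    if not expressed:
        raise ValueError(
            f"{model.gene_id}: no isoform has expression evidence; pass "
            "override= with a literature-curated isoform id"
        )

    def sort_key(iso: str):
        tss = model.tss(iso)
        oriented_tss = tss if model.strand == "+" else -tss
        return (-model.span(iso), oriented_tss, iso)

    winner = min(expressed, key=sort_key)
    return winner, model.tss(winner)


def locus_zones(
    model: GeneModel, isoform_id: str, min_intron_bp: int = 300
) -> LocusZones:
    """Compute the PROXIMAL / INTRON1 / DISTAL boundaries for an isoform."""
    exons = model.isoforms[isoform_id]
    tss = model.tss(isoform_id)
    e1 = exons[0]
    if model.strand == "+":
        b1 = e1[1]
        b2 = exons[1][0] if len(exons) > 1 else e1[1]
    else:
        b1 = e1[0]
        b2 = exons[1][1] if len(exons) > 1 else e1[0]
    # intron 1 spans [b1, b2) on the + strand and [b2, b1) on the - strand
    has_intron1 = len(exons) >= 2 and abs(b2 - b1) >= min_intron_bp
    return LocusZones(
        model.gene_id, model.chrom, model.strand, tss, b1, b2, has_intron1
    )


def classify_fragment(frag: FragmentRecord, zones: LocusZones) -> str:
    """Assign a fragment to PROXIMAL / INTRON1 / DISTAL by its midpoint.

    The midpoint is mapped onto the gene-oriented axis: strictly 5' of the
    intron-1 donor -> PROXIMAL; in [donor, acceptor) -> INTRON1; at or 3'
    of the acceptor -> DISTAL.  Without a qualifying first intron the donor
    boundary alone separates PROXIMAL from DISTAL.
    """
    if frag.chrom != zones.chrom:
        raise ValueError(
            f"{frag.fragment_id}: chrom {frag.chrom} != gene chrom {zones.chrom}"
        )
    gm = zones.oriented(frag.midpoint)
    gb1 = zones.oriented(zones.b1)
    gb2 = zones.oriented(zones.b2)
    if gm < gb1:
        assigned = PROXIMAL
    elif zones.has_intron1 and gm < gb2:
        assigned = INTRON1
    else:
        assigned = DISTAL
    frag.bin = assigned
    frag.zone_overlap = _zone_overlap_fractions(frag, zones)
    return assigned


def _zone_overlap_fractions(
    frag: FragmentRecord, zones: LocusZones
) -> dict[str, float]:
    """Fraction of the fragment's bases in each zone (audit trail)."""
    g_lo = zones.oriented(frag.start)
    g_hi = zones.oriented(frag.end)
    lo, hi = min(g_lo, g_hi), max(g_lo, g_hi)
    gb1 = zones.oriented(zones.b1)
    gb2 = zones.oriented(zones.b2)
    length = hi - lo
    prox = max(0.0, min(hi, gb1) - lo)
    if zones.has_intron1:
        intr = max(0.0, min(hi, gb2) - max(lo, gb1))
        dist = max(0.0, hi - max(lo, gb2))
    else:
        intr = 0.0
        dist = max(0.0, hi - max(lo, gb1))
    return {
        PROXIMAL: prox / length,
        INTRON1: intr / length,
        DISTAL: dist / length,
    }


def classify_fragments(
    frags: Iterable[FragmentRecord],
    zones_by_gene: Mapping[str, LocusZones],
) -> list[FragmentRecord]:
    """Classify every fragment against its own associated gene's zones."""
    out = []
    for frag in frags:
        try:
            zones = zones_by_gene[frag.gene_id]
        except KeyError:
            raise KeyError(
                f"{frag.fragment_id}: no zones for gene {frag.gene_id!r}"
            ) from None
        classify_fragment(frag, zones)
        out.append(frag)
    return out


def tally_bins(frags: Iterable[FragmentRecord]) -> BinCounts:
    """Per-bin fragment totals and GFP-positive counts."""
    n_total = {b: 0 for b in BINS}
    n_positive = {b: 0 for b in BINS}
    for frag in frags:
        if frag.bin is None:
            raise ValueError(f"{frag.fragment_id}: fragment not yet classified")
        if frag.bin not in n_total:
            n_total[frag.bin] = 0
            n_positive[frag.bin] = 0
        n_total[frag.bin] += 1
        if frag.gfp_positive:
            n_positive[frag.bin] += 1
    return BinCounts(n_total, n_positive)


def fragment_size_stats(
    frags: Iterable[FragmentRecord],
) -> FragmentSizeStats:
    """Mean and standard error of fragment sizes per bin, in kb.

    Pairwise bins are compared with Welch's unequal-variance two-sample
    t-test; a bin with fewer than two fragments is skipped (its comparisons
    are reported as NaN).
    """
    sizes: dict[str, list[float]] = {}
    for frag in frags:
        if frag.bin is None:
            raise ValueError(f"{frag.fragment_id}: fragment not yet classified")
        sizes.setdefault(frag.bin, []).append(frag.length_bp / 1000.0)
    mean_kb: dict[str, float] = {}
    se_kb: dict[str, float] = {}
    n: dict[str, int] = {}
    for b, vals in sizes.items():
        arr = np.asarray(vals)
        n[b] = arr.size
        mean_kb[b] = float(arr.mean())
        se_kb[b] = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    pairwise_p: dict[tuple[str, str], float] = {}
    present = [b for b in BINS if b in sizes] + sorted(set(sizes) - set(BINS))
    for i, a in enumerate(present):
        for b in present[i + 1 :]:
            if n[a] < 2 or n[b] < 2:
                warnings.warn(f"bin with n<2 in comparison ({a},{b}); skipped")
                pairwise_p[(a, b)] = float("nan")
                continue
            res = stats.ttest_ind(sizes[a], sizes[b], equal_var=False)
            pairwise_p[(a, b)] = float(res.pvalue)
    return FragmentSizeStats(mean_kb, se_kb, n, pairwise_p)
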