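"""Synthetic screen generator.

Produces data with the statistical structure the analysis assumes — gene
models with first introns of at least the collection's 300 bp floor,
~3 kb reporter fragments tiling each locus from the 5' flank to the 3'
flank, per-zone Bernoulli GFP labels, stage-persistent domain patterns
with a tunable change rate, and multi-tissue expression flags — plus a
frozen fixture of the published screen's printed aggregate counts.

Reproducibility: every stage of the generator draws from its own
``numpy`` ``SeedSequence`` sub-stream keyed by (stage id, gene/line
index), so enlarging one part of a simulation (e.g. adding genes) never
perturbs the draws of another (e.g. fragment labels).

The generator records each fragment's *truth bin* using its own strand
arithmetic over the raw exon list, deliberately independent of the
classifier in :mod:`crmscreen.genomic_binning`; agreement between the two
on cleanly contained fragments is therefore a genuine test, not a
tautology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_binning import (
    DISTAL,
    INTRON1,
    PROXIMAL,
    BinCounts,
    ExpressionEvidence,
    FragmentRecord,
    GeneModel,
)
from .ontology import DomainOntology, StageAxis
from .pattern_matrix import AnnotationRecord
from .temporal import DEFAULT_TISSUES, TissueTable

__all__ = [
    "SimConfig",
    "generate_gene_models",
    "generate_fragments",
    "label_fragments",
    "generate_pattern_tables",
    "generate_tissue_table",
    "simulate_screen",
    "paper_fixture",
    "ScreenConstants",
]

# sub-stream ids (never renumber: reproducibility contract)
_S_MODELS = 1
_S_FRAGMENTS = 2
_S_LABELS = 3
_S_PATTERNS = 4
_S_TISSUES = 5

#: domains a simulated line can draw (OTHER, the stage-14 structures and the
#: uniform pseudo-domain U excluded: simulated patterns are spatial sets, and
#: U co-occurring with spatial domains would trip the annotation validator)
_SIM_DOMAINS: tuple[str, ...] = (
    "G", "StC", "PC", "BC", "SC", "AD", "AV", "M", "R", "F", "D", "P",
)


@dataclass
class SimConfig:
    """Parameters of the synthetic screen.

    Defaults state the published screen's conditions: ~3 kb fragments,
    per-zone positive rates 23/140, 22/72 and 9/69, a 10.3% pattern-change
    rate, and tissue marginals of 84/78/85/77/20/19 percent.  The scale
    (60 genes, ~280 fragments) mirrors the screen's shape.
    """

    seed: int = 0
    n_genes: int = 60
    exon_count_range: tuple[int, int] = (2, 6)
    exon_len_range: tuple[int, int] = (150, 600)
    first_intron_len_range: tuple[int, int] = (300, 3000)
    other_intron_len_range: tuple[int, int] = (100, 2000)
    min_intron_bp: int = 300
    decoy_fraction: float = 0.5
    flank_bp: int = 6000
    fragment_length_mean_bp: float = 3000.0
    fragment_length_jitter_bp: float = 300.0
    zone_rates: dict[str, float] = field(
        default_factory=lambda: {
            PROXIMAL: 23 / 140,
            INTRON1: 22 / 72,
            DISTAL: 9 / 69,
        }
    )
    # pattern model
    n_lines: int = 54
    lines_per_gene: int = 3
    domain_count_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.48, 2: 0.33, 3: 0.19}
    )
    persistence_prob: float = 0.8
    change_prob: float = 0.103
    gap_prob: float = 0.05
    extra_domain_prob: float = 0.3
    recap_case_probs: dict[str, float] = field(
        default_factory=lambda: {"FULL": 0.4, "PARTIAL": 0.4, "NONE": 0.2}
    )
    # tissue model
    n_screen_lines: int = 281
    tissue_marginals: dict[str, float] = field(
        default_factory=lambda: dict(
            zip(DEFAULT_TISSUES, (0.84, 0.78, 0.85, 0.77, 0.20, 0.19))
        )
    )
    n_all_negative: int = 8

    def __post_init__(self) -> None:
        probs = (
            list(self.zone_rates.values())
            + [self.persistence_prob, self.change_prob, self.gap_prob,
               self.extra_domain_prob, self.decoy_fraction]
            + list(self.tissue_marginals.values())
            + list(self.domain_count_probs.values())
            + list(self.recap_case_probs.values())
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for lo, hi in (
            self.exon_count_range,
            self.exon_len_range,
            self.first_intron_len_range,
            self.other_intron_len_range,
        ):
            if lo <= 0 or hi < lo:
                raise ValueError("length/count ranges must be positive and ordered")
        if self.first_intron_len_range[0] < self.min_intron_bp:
            raise ValueError(
                "first intron lower bound below min_intron_bp: the collection "
                "excludes such loci"
            )
        if self.fragment_length_mean_bp <= 0:
            raise ValueError("fragment length must be positive")
        if not 0 <= self.n_all_negative <= self.n_screen_lines:
            raise ValueError("n_all_negative must not exceed n_screen_lines")

    def rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=tuple(key))
        )


def generate_gene_models(
    cfg: SimConfig,
) -> tuple[dict[str, GeneModel], ExpressionEvidence]:
    """Simulate isoform-resolved gene models with expression evidence.

    Each gene lives on its own contig with balanced strands.  Every gene
    has one expressed isoform (``.RA``); a configurable fraction also gets
    a longer-span decoy isoform (``.RB``) with a distinct, further-5'
    first exon but no expression evidence, exercising TSS selection.
    """
    models: dict[str, GeneModel] = {}
    flags: dict[str, dict[str, bool]] = {}
    for i in range(cfg.n_genes):
        rng = cfg.rng(_S_MODELS, i)
        gene_id = f"g{i + 1:03d}"
        chrom = f"chr_{gene_id}"
        strand = "+" if i % 2 == 0 else "-"
        n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        exon_lens = rng.integers(
            cfg.exon_len_range[0], cfg.exon_len_range[1] + 1, size=n_exons
        )
        intron_lens = [
            int(rng.integers(*_incl(cfg.first_intron_len_range)))
        ] + [
            int(rng.integers(*_incl(cfg.other_intron_len_range)))
            for _ in range(max(0, n_exons - 2))
        ]
        start = int(rng.integers(50_000, 80_000))
        # lay out gene-oriented, then mirror for the minus strand
        oriented: list[tuple[int, int]] = []
        pos = 0
        for j, elen in enumerate(exon_lens):
            oriented.append((pos, pos + int(elen)))
            pos += int(elen)
            if j < n_exons - 1:
                pos += intron_lens[j]
        if strand == "+":
            exons = [(start + a, start + b) for a, b in oriented]
        else:
            # mirror the oriented layout: oriented offset x -> start + (pos - x)
            exons = [(start + pos - b, start + pos - a) for a, b in oriented]
        isoforms = {f"{gene_id}.RA": tuple(exons)}
        flags[f"{gene_id}.RA"] = _evidence_flags(rng)
        if rng.random() < cfg.decoy_fraction:
            # decoy: distinct first exon 1-2 kb further 5', longer span,
            # sharing the downstream exons — but never expressed
            shift = int(rng.integers(1000, 2001))
            d_len = int(rng.integers(*_incl(cfg.exon_len_range)))
            genomic = sorted(exons)
            if strand == "+":
                first = genomic[0]
                decoy_first = (first[0] - shift - d_len, first[0] - shift)
                decoy = [decoy_first] + genomic[1:]
            else:
                last = genomic[-1]
                decoy_first = (last[1] + shift, last[1] + shift + d_len)
                decoy = genomic[:-1] + [decoy_first]
            isoforms[f"{gene_id}.RB"] = tuple(decoy)
            flags[f"{gene_id}.RB"] = {"early": False, "mid": False, "late": False}
        models[gene_id] = GeneModel(gene_id, chrom, strand, isoforms)
    return models, ExpressionEvidence(flags)


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    return rng_pair[0], rng_pair[1] + 1


def _evidence_flags(rng: np.random.Generator) -> dict[str, bool]:
    """At least one stage group expressed."""
    while True:
        f = {g: bool(rng.random() < 0.7) for g in ("early", "mid", "late")}
        if any(f.values()):
            return f


def _truth_zone(model: GeneModel, midpoint: float, min_intron_bp: int) -> str:
    """Generator-side zone arithmetic over the raw exon list.

    Written against genomic coordinates with explicit per-strand branches —
    an implementation independent of ``LocusZones``/``classify_fragment``.
    """
    exons = sorted(model.isoforms[f"{model.gene_id}.RA"])
    if model.strand == "+":
        exon1, exon2 = exons[0], (exons[1] if len(exons) > 1 else None)
        intron_ok = exon2 is not None and exon2[0] - exon1[1] >= min_intron_bp
        if midpoint < exon1[1]:
            return PROXIMAL
        if intron_ok and midpoint < exon2[0]:
            return INTRON1
        return DISTAL
    exon1, exon2 = exons[-1], (exons[-2] if len(exons) > 1 else None)
    intron_ok = exon2 is not None and exon1[0] - exon2[1] >= min_intron_bp
    if midpoint >= exon1[0]:
        return PROXIMAL
    if intron_ok and midpoint >= exon2[1]:
        return INTRON1
    return DISTAL


def generate_fragments(
    models: Mapping[str, GeneModel], cfg: SimConfig
) -> tuple[list[FragmentRecord], dict[str, str]]:
    """Tile each locus with ~3 kb fragments; return records + truth bins."""
    frags: list[FragmentRecord] = []
    truth: dict[str, str] = {}
    for i, (gene_id, model) in enumerate(sorted(models.items())):
        rng = cfg.rng(_S_FRAGMENTS, i)
        exons = sorted(model.isoforms[f"{gene_id}.RA"])
        lo = max(0, min(a for a, _ in exons) - cfg.flank_bp)
        hi = max(b for _, b in exons) + cfg.flank_bp
        pos = lo
        j = 0
        while True:
            length = int(
                np.clip(
                    rng.normal(cfg.fragment_length_mean_bp, cfg.fragment_length_jitter_bp),
                    500,
                    None,
                )
            )
            if pos + length > hi:
                break
            fid = f"{gene_id}_f{j:02d}"
            frag = FragmentRecord(
                fragment_id=fid,
                line_id=f"L_{fid}",
                chrom=model.chrom,
                start=pos,
                end=pos + length,
                gene_id=gene_id,
            )
            frags.append(frag)
            truth[fid] = _truth_zone(model, frag.midpoint, cfg.min_intron_bp)
            pos += length
            j += 1
    return frags, truth


def label_fragments(
    frags: Sequence[FragmentRecord],
    truth_bins: Mapping[str, str],
    cfg: SimConfig,
) -> dict[str, bool]:
    """Independent Bernoulli GFP label per fragment at its truth-bin rate."""
    labels: dict[str, bool] = {}
    for k, frag in enumerate(frags):
        b = truth_bins[frag.fragment_id]
        if b not in cfg.zone_rates:
            raise KeyError(f"{frag.fragment_id}: no rate for bin {b!r}")
        rng = cfg.rng(_S_LABELS, k)
        positive = bool(rng.random() < cfg.zone_rates[b])
        frag.gfp_positive = positive
        labels[frag.fragment_id] = positive
    return labels


def generate_pattern_tables(
    cfg: SimConfig,
    ontology: DomainOntology | None = None,
    axis: StageAxis | None = None,
) -> tuple[list[AnnotationRecord], list[AnnotationRecord], dict[str, str]]:
    """Simulate line and endogenous annotation tables with planted truth.

    Each line draws a domain set (size from ``domain_count_probs``), an
    onset stage, geometric per-stage survival at ``persistence_prob``, an
    optional single-stage gap (``gap_prob``), and at each surviving
    transition swaps one domain with probability ``change_prob``.

    Lines are grouped into genes (``lines_per_gene``); each gene's
    endogenous pattern derives from the union of its lines' patterns with
    a planted recapitulation outcome: FULL (union as is), PARTIAL (extra
    endogenous-only domains planted), or NONE (endogenous domains disjoint
    from the reporters').  Returns (line records, endogenous records,
    gene -> planted call).
    """
    ontology = ontology or DomainOntology()
    axis = axis or StageAxis()
    stages = list(axis.stages)
    domain_pool = [d for d in _SIM_DOMAINS if d in ontology.codes]
    k_vals = sorted(cfg.domain_count_probs)
    k_probs = np.array([cfg.domain_count_probs[k] for k in k_vals], dtype=float)
    k_probs = k_probs / k_probs.sum()

    line_records: list[AnnotationRecord] = []
    line_patterns: dict[str, dict[str, frozenset[str]]] = {}
    for li in range(cfg.n_lines):
        rng = cfg.rng(_S_PATTERNS, li)
        line_id = f"L{li + 1:03d}"
        gene_id = f"pg{li // cfg.lines_per_gene + 1:03d}"
        k = int(rng.choice(k_vals, p=k_probs))
        current = set(
            map(str, rng.choice(domain_pool, size=min(k, len(domain_pool)), replace=False))
        )
        onset = int(rng.integers(0, len(stages)))
        per_stage: dict[str, frozenset[str]] = {}
        s = onset
        gap_used = False
        while s < len(stages):
            per_stage[stages[s]] = frozenset(current)
            if rng.random() >= cfg.persistence_prob:
                break
            nxt = s + 1
            if not gap_used and nxt < len(stages) - 1 and rng.random() < cfg.gap_prob:
                nxt += 1  # skip one stage: the line goes silent, then returns
                gap_used = True
            if rng.random() < cfg.change_prob:
                unused = [d for d in domain_pool if d not in current]
                if unused:
                    current = set(current)
                    current.remove(str(rng.choice(sorted(current))))
                    current.add(str(rng.choice(unused)))
            s = nxt
        line_patterns[line_id] = per_stage
        for st, doms in per_stage.items():
            line_records.append(
                AnnotationRecord(line_id, st, doms, "line", gene_id)
            )

    # endogenous patterns per gene with planted FULL/PARTIAL/NONE outcome
    endo_records: list[AnnotationRecord] = []
    planted: dict[str, str] = {}
    genes: dict[str, list[str]] = {}
    for li in range(cfg.n_lines):
        line_id = f"L{li + 1:03d}"
        genes.setdefault(f"pg{li // cfg.lines_per_gene + 1:03d}", []).append(line_id)
    cases = sorted(cfg.recap_case_probs)
    case_probs = np.array([cfg.recap_case_probs[c] for c in cases], dtype=float)
    case_probs = case_probs / case_probs.sum()
    for gi, (gene_id, members) in enumerate(sorted(genes.items())):
        rng = cfg.rng(_S_PATTERNS, 10_000 + gi)
        union: dict[str, set[str]] = {}
        for line_id in members:
            for st, doms in line_patterns[line_id].items():
                union.setdefault(st, set()).update(doms)
        if not union:
            continue
        case = str(rng.choice(cases, p=case_probs))
        endo: dict[str, set[str]] = {}
        if case == "NONE":
            for st, doms in union.items():
                free = [d for d in domain_pool if d not in doms]
                if not free:
                    case = "FULL"
                    endo = {st: set(d) for st, d in union.items()}
                    break
                endo[st] = set(
                    map(
                        str,
                        rng.choice(free, size=min(len(doms), len(free)), replace=False),
                    )
                )
        if case == "PARTIAL":
            endo = {st: set(doms) for st, doms in union.items()}
            extras_planted = False
            for st in sorted(endo):
                free = [d for d in domain_pool if d not in endo[st]]
                if free and (not extras_planted or rng.random() < cfg.extra_domain_prob):
                    endo[st].add(str(rng.choice(free)))
                    extras_planted = True
            if not extras_planted:
                case = "FULL"
        if case == "FULL":
            endo = {st: set(doms) for st, doms in union.items()}
        planted[gene_id] = case
        for st in sorted(endo, key=stages.index):
            endo_records.append(
                AnnotationRecord(gene_id, st, frozenset(endo[st]), "gene", gene_id)
            )
    return line_records, endo_records, planted


def generate_tissue_table(cfg: SimConfig) -> TissueTable:
    """Bernoulli line x tissue table with planted all-negative lines.

    The last ``n_all_negative`` lines are forced all-zero; the remaining
    rows are redrawn until nonzero, so the planted count is exact.
    """
    tissues = list(cfg.tissue_marginals)
    p = np.array([cfg.tissue_marginals[t] for t in tissues])
    rows = []
    n_pos = cfg.n_screen_lines - cfg.n_all_negative
    for li in range(cfg.n_screen_lines):
        rng = cfg.rng(_S_TISSUES, li)
        if li >= n_pos:
            rows.append(np.zeros(len(tissues), dtype=np.int8))
            continue
        while True:
            row = (rng.random(len(tissues)) < p).astype(np.int8)
            if row.any():
                rows.append(row)
                break
    data = pd.DataFrame(
        np.vstack(rows),
        index=[f"FL{li + 1:03d}" for li in range(cfg.n_screen_lines)],
        columns=tissues,
    )
    return TissueTable(data)


@dataclass(frozen=True)
class ScreenConstants:
    """The published screen's printed aggregate counts, frozen as a fixture."""

    bin_sizes: dict[str, int]
    bin_positives: dict[str, int]
    n_lines: int
    n_gfp_positive: int
    n_recapitulating: int
    instances: int
    changed_total: int
    changed_next: int
    changed_gap: int
    tissue_percent: dict[str, float]
    n_all_negative: int
    fragment_mean_kb: dict[str, float]
    fragment_se_kb: dict[str, float]

    @property
    def bin_counts(self) -> BinCounts:
        return BinCounts(dict(self.bin_sizes), dict(self.bin_positives))


def paper_fixture() -> ScreenConstants:
    """Printed aggregate counts of the published 281-line screen."""
    return ScreenConstants(
        bin_sizes={PROXIMAL: 140, INTRON1: 72, DISTAL: 69},
        bin_positives={PROXIMAL: 23, INTRON1: 22, DISTAL: 9},
        n_lines=281,
        n_gfp_positive=54,
        n_recapitulating=16,
        instances=339,
        changed_total=35,
        changed_next=30,
        changed_gap=5,
        tissue_percent=dict(
            zip(DEFAULT_TISSUES, (84.0, 78.0, 85.0, 77.0, 20.0, 19.0))
        ),
        n_all_negative=8,
        fragment_mean_kb={PROXIMAL: 3.17, INTRON1: 3.06, DISTAL: 2.56},
        fragment_se_kb={PROXIMAL: 0.06, INTRON1: 0.10, DISTAL: 0.13},
    )


def simulate_screen(cfg: SimConfig):
    """Convenience end-to-end simulation.

    Returns a dict with gene models, expression evidence, fragments (GFP
    labels set), truth bins, line/endogenous annotation records, planted
    recapitulation calls, and the tissue table.
    """
    models, evidence = generate_gene_models(cfg)
    frags, truth = generate_fragments(models, cfg)
    labels = label_fragments(frags, truth, cfg)
    line_recs, endo_recs, planted = generate_pattern_tables(cfg)
    tissues = generate_tissue_table(cfg)
    return {
        "models": models,
        "evidence": evidence,
        "fragments": frags,
        "truth_bins": truth,
        "labels": labels,
        "line_records": line_recs,
        "endo_records": endo_recs,
        "planted_calls": planted,
        "tissue_table": tissues,
    }
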