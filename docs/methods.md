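# Methods

## Scope and model

`crmscreen` analyses enhancer-reporter screens in which genomic DNA
fragments drive GAL4/UAS-GFP during *Drosophila* oogenesis. The analysis
has four stages: encoding expression annotations as binary matrices,
binning fragments by position in the gene model, testing the positional
distribution of active fragments, and accounting for how patterns change
across egg-chamber stages. A seeded generator produces synthetic screens
for validation.

## Binary pattern matrices

An annotation is a statement "subject X expresses domain set D at stage
s". Subjects are reporter lines or endogenous genes; domains come from a
fixed ontology of expression primitives (germarium G, stalk cells StC,
polar cells PC, border cells BC, stretched cells SC, anterior-dorsal AD,
anterior-ventral AV, midline M, roof R, floor F, dorsal D, posterior P,
uniform U, the stage-14 structures DA and Op, and a trailing OTHER
bucket); stages run S2…S14 with S10 split into 10A/10B. Encoding yields a
stage × domain bit matrix per subject; unmentioned cells are 0
(observed-absent by default; an optional mask can mark stages as not
assayed).

Design choices where conventions differ between groups:

* **U alongside spatial domains.** U (uniform) is an ordinary column; no
  mutual exclusion with spatial domains is enforced, but a validator warns
  when U co-occurs with a spatial domain at one stage, since that usually
  indicates an annotation slip.
* **Early-stage granularity.** Stages 2–8 may be annotated individually or
  as one grouped label `S2-8`; mixing the two granularities in one dataset
  is rejected.
* **BC vs PC.** Border and polar cells are often indistinguishable in
  images; they remain separate codes, and callers may alias them upstream.

**Collapsing.** A gene's reporter lines are combined by bitwise OR and then
zeroed at stages where the endogenous pattern has no bit — a reporter is
only interpretable against the gene where the gene is detected. OR makes
the operation idempotent and order-independent.

**Overlay and recapitulation.** Cell-wise comparison of the endogenous
matrix (e) and collapsed reporter matrix (g) yields code e + 2g ∈
{NONE, ENDO_ONLY, GFP_ONLY, BOTH}. Percent recapitulation per domain is
100 · #BOTH / (#BOTH + #ENDO_ONLY), pooling cells across genes and stages
by default (per-gene averaging is available; the pooled convention is the
default because it weights each annotated cell equally). Domains with no
endogenous-positive cell are undefined and omitted, never reported as 0%.
Per gene, the call is FULL when every endogenous bit is covered, NONE when
no bit is covered, PARTIAL otherwise; the underlying counts are exposed so
stricter thresholds can be applied.

## Positional binning

For each gene the relevant isoform is the one with the greatest genomic
span among isoforms with expression evidence in any of the three
egg-chamber stage groups (early ≤ S9, mid S10A–B, late ≥ S11); span ties
go to the 5′-most TSS, then the lexicographically smallest isoform id. A
manual override hook supports literature-curated TSS assignments, and the
selection errors informatively when no isoform has evidence.

With exon 1 and exon 2 of the chosen isoform, the locus splits at the
first-intron donor (b1, gene-oriented end of exon 1) and acceptor (b2,
gene-oriented start of exon 2): midpoints strictly 5′ of b1 are
*Proximal*, in [b1, b2) *Intron 1*, at/3′ of b2 *Distal*. Consequences of
the midpoint rule:

* Fragments straddling a boundary get a single deterministic bin; their
  per-zone overlap fractions are recorded for audit. (Containment-based
  and midpoint classifications coincide for fragments inside one zone,
  which is the common case for ~3 kb fragments.)
* Midpoints inside exon 1 are Proximal; at/after exon 2 start, Distal.
* First introns shorter than `min_intron_bp` (default 300 bp — fragment
  collections exclude shorter introns by design) yield no Intron 1 zone;
  b1 then splits Proximal from Distal, so a midpoint inside such a short
  intron is Distal.

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive)
is converted on ingest. Classification operates on the gene-oriented axis
(positions negated for minus-strand genes), making it invariant under
reflection of a whole locus.

Fragment sizes are summarised per bin as mean ± SE (sample SD/√n, kb) and
compared pairwise with Welch's unequal-variance t-test — chosen because
bin sizes and variances differ; bins with n < 2 are skipped with a
warning.

## Enrichment statistics

Let N fragments contain K GFP-positive ones; the global success rate is
p̂ = K/N (kept as an exact rational; displayed as an integer percent). A
bin of n fragments expects n·p̂ positives.

* **χ² goodness-of-fit**: T = Σ (Oᵢ − Eᵢ)²/Eᵢ with Eᵢ = nᵢ·p̂ unrounded,
  df = #bins − 1, upper-tail p (for df = 2 this equals exp(−T/2)).
* **Exact binomial tails**: P(X ≥ k) or P(X ≤ k) for X ~ Binom(n, p),
  summed over the exact pmf in log-space (gammaln + logsumexp), so deep
  tails retain full relative accuracy. The side is the direction of the
  observed deviation (enrichment above expectation, depletion below).
* **Rate conventions**: the χ² expectation uses exact K/N; the binomial
  tests default to the display-rounded percent rate (0.19 for 54/281),
  matching the reporting convention "the success rate is 19%". Both are
  configurable. Percent deviations use the integer-rounded expected count
  as denominator — the convention under which reports quote "22 observed
  vs 14 expected: 57% more".
* **Multiple testing**: per-bin tails are reported uncorrected by default
  (the conventional presentation for three planned bins); a Bonferroni
  option is available.

A calibration caveat the test-suite makes explicit: a *fixed* one-tailed
exact test has size ≤ α by construction (discreteness makes it
conservative), but choosing the tail from the observed direction unions
two one-sided rejection regions and can double the size (to ≈ 0.10 at
α = 0.05 for the screen's bin sizes). Reported p-values are plain
one-tailed tails; consumers testing a two-sided question should correct
accordingly.

## Temporal dynamics

A line's pattern at a stage is its domain set; each nonempty (line, stage)
pair is an instance. Instances are classified on arrival (persist-same,
persist-changed, new, reappear-same, reappear-changed) and departure
(persist out, dropped), with change events attributed to the earlier
instance of a pair and gap changes requiring ≥ 1 intervening empty stage.
Same-pattern reappearance after a gap is tracked in its own bucket
(neither new nor persisting). Inflow and outflow both sum to the number
expressed at each stage; these identities are asserted at run time
(`check_conservation`) and property-tested on random data.

Domain durations count total expressed stages per line by default (a
run-length mode is available), with population SD. Domains-per-line counts
distinct domains across all stages — under the assumption that each simple
domain is driven by a separate CRM, this histogram estimates CRMs per
fragment. Tissue breadth reports column means, the per-line tissue-count
histogram, and the number of lines expressed nowhere.

## Synthetic generator

Defaults state the published screen's conditions; scale parameters mirror
its shape.

| parameter | default | rationale |
|---|---|---|
| fragment length | 3000 ± 300 bp (normal, clipped ≥ 500) | screens use ~3 kb fragments |
| per-zone positive rates | 23/140, 22/72, 9/69 | the screen's per-bin rates |
| n_genes / fragments | 60 / ~280 | screen shape (22 genes, 281 lines) |
| first intron | uniform 300–3000 bp | collection excludes < 300 bp |
| exons per isoform | uniform 2–6 | typical compact fly loci |
| pattern change probability | 0.103 | the screen's observed 10.3% |
| persistence per stage | 0.8 | patterns persist over multiple stages |
| domains per line | 1: 48%, 2: 33%, 3: 19% | the screen's histogram |
| tissue marginals | 84/78/85/77/20/19% | the screen's six-tissue profile |
| planted all-negative lines | 8 of 281 | the screen's count |

Structure: each gene gets its own contig (sidestepping ambiguity about
fragments nearer a neighbouring gene), balanced strands, one expressed
isoform, and — with probability 0.5 — a longer-span decoy isoform with a
distinct, further-5′ first exon and no expression evidence, exercising
TSS selection. Fragments tile each locus from −6 kb to +6 kb flanks.
Truth bins are computed by generator-side strand arithmetic independent of
the classifier. Endogenous patterns are unions of each gene's line
patterns with a planted outcome (FULL as-is / PARTIAL with extra
endogenous-only domains / NONE disjoint), giving known recapitulation
ground truth. Simulated line patterns draw only spatial domains (U, the
stage-14 structures and OTHER are excluded), so the uniform-conflict
validator stays silent on generated data.

Randomness: every stage and every gene/line index derives its own
`numpy.random.SeedSequence(seed, spawn_key=(stage, index))` stream, so
outputs are bit-stable across platforms and enlarging one component never
perturbs another.

What a green synthetic test does *not* establish: the generator draws
per-fragment labels independently (real lines from one gene share
regulatory context), uses idealised exon structures, emits no sequence,
and its pattern process is a first-order Markov chain — real pattern
changes cluster at the stage-8 axis transition. Published screen-level
aggregates that depend on per-line annotations (339 instances, exact
tissue percentages, per-bin size means) are therefore validated on
synthetic data with planted values, not reproduced.

## Numerical choices

* Integer display rounding is half-away-from-zero (Python's banker's
  rounding would map 13.5 → 13).
* Binomial tails are exact log-space sums; the complement identity
  UPPER(k) + LOWER(k−1) = 1 holds to 1e−12, and tails match brute-force
  outcome enumeration for n ≤ 12 exactly.
* χ² p-values use the regularized incomplete gamma upper tail; the df = 2
  closed form exp(−T/2) agrees to machine precision.
* Welch t-test p-values come from `scipy.stats.ttest_ind(equal_var=False)`.
* TSS tie-breaks are deterministic (span, then 5′-most TSS, then isoform
  id), so isoform dict ordering never matters.

## Known limitations

* Midpoint binning is a stated convention, not a claim about how any
  particular published screen classified straddling fragments.
* Fragments are classified only against their declared associated gene.
* The recapitulation FULL/PARTIAL boundary (complete coverage vs ≥ 1
  overlapping cell) is a fixed convention; the per-domain counts are
  exposed for alternative thresholds.
* Percent recapitulation pools stages by default; a per-stage or per-gene
  reading of the same data will differ and both are available.
* No image processing: matrices begin at the annotation table.
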