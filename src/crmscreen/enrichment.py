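"""Positional enrichment statistics for reporter screens.

The null hypothesis is that GFP-positive fragments (those containing an
active cis-regulatory module) are distributed across the positional bins
in proportion to bin size: with K positives among N screened fragments,
the expected positive count in a bin of n fragments is n * K/N.

Two tests are applied, mirroring common practice in reporter screens:

* a chi-square goodness-of-fit test of the observed per-bin positive
  counts against the proportional expectation (df = #bins - 1), and
* a per-bin one-tailed exact binomial test at the global success rate,
  upper-tailed when the bin is above expectation (enrichment) and
  lower-tailed when below (depletion).

Binomial tails are exact sums of the binomial pmf accumulated in
log-space, so very small tail probabilities remain accurate.

Two rate conventions are supported deliberately.  The chi-square expected
counts use the exact unrounded fraction K/N by default; the binomial tests
use the display-rounded percent rate (e.g. 0.19 for 54/281) by default,
matching how screens commonly report "the success rate is 19%" and then
test at 0.19.  Both are configurable via ``enrichment_analysis``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import special, stats

from .genomic_binning import BINS, BinCounts

__all__ = [
    "UPPER",
    "LOWER",
    "AUTO",
    "BinEnrichment",
    "EnrichmentResult",
    "overall_rate",
    "expected_counts",
    "round_half_away",
    "chi2_gof",
    "binom_tail",
    "log_binom_tail",
    "percent_deviation",
    "enrichment_analysis",
]

UPPER = "UPPER"
LOWER = "LOWER"
AUTO = "AUTO"


def overall_rate(K: int, N: int) -> Fraction:
    """Global success rate K/N, kept as an exact rational."""
    if N <= 0:
        raise ValueError("N must be positive")
    if not 0 <= K <= N:
        raise ValueError("need 0 <= K <= N")
    return Fraction(K, N)


def rate_percent(rate: Fraction | float) -> int:
    """Display rounding of a rate to an integer percent."""
    return round_half_away(100 * float(rate))


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def expected_counts(
    bin_sizes: Sequence[int], rate: Fraction | float
) -> tuple[list[float], list[int]]:
    """Expected positives per bin: unrounded size*rate and its integer round."""
    if any(s <= 0 for s in bin_sizes):
        raise ValueError("bin sizes must be positive")
    raw = [float(s * rate) for s in bin_sizes]
    rounded = [round_half_away(e) for e in raw]
    return raw, rounded


def chi2_gof(
    observed: Sequence[float], expected_raw: Sequence[float]
) -> tuple[float, int, float]:
    """Chi-square goodness-of-fit statistic, df = k-1, upper-tail p.

    stat = sum (O - E)^2 / E.  For df = 2 the upper tail has the closed
    form exp(-stat/2); the general regularized-gamma tail is used here.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected_raw, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("need equal-length vectors of at least two bins")
    if np.any(exp <= 0):
        raise ValueError("all expected counts must be positive")
    stat = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def log_binom_tail(k_obs: int, n: int, p: float, side: str) -> float:
    """log of the exact binomial tail probability.

    UPPER: log P(X >= k_obs); LOWER: log P(X <= k_obs).  The pmf terms
    log C(n,k) + k log p + (n-k) log(1-p) are accumulated with logsumexp.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if not 0 <= k_obs <= n:
        raise ValueError("need 0 <= k_obs <= n")
    if side == UPPER:
        ks = np.arange(k_obs, n + 1)
    elif side == LOWER:
        ks = np.arange(0, k_obs + 1)
    else:
        raise ValueError(f"side must be {UPPER!r} or {LOWER!r}")
    log_pmf = (
        special.gammaln(n + 1)
        - special.gammaln(ks + 1)
        - special.gammaln(n - ks + 1)
        + ks * math.log(p)
        + (n - ks) * math.log1p(-p)
    )
    return float(special.logsumexp(log_pmf))


def binom_tail(k_obs: int, n: int, p: float, side: str = AUTO) -> float:
    """One-tailed exact binomial tail probability.

    ``AUTO`` picks the direction of the observed deviation: UPPER
    (P(X >= k_obs), enrichment) when k_obs > n*p, LOWER (P(X <= k_obs),
    depletion) otherwise.
    """
    if side == AUTO:
        side = UPPER if k_obs > n * p else LOWER
    return min(1.0, math.exp(log_binom_tail(k_obs, n, p, side)))


def percent_deviation(observed: int, expected_rounded: int) -> int:
    """Signed percent deviation of observed from the rounded expectation.

    Uses the integer-rounded expected count as the denominator — the
    convention under which screen reports quote e.g. "22 observed vs 14
    expected: 57% more".
    """
    if expected_rounded <= 0:
        raise ValueError("expected count must be positive")
    return round_half_away(100.0 * (observed - expected_rounded) / expected_rounded)


@dataclass(frozen=True)
class BinEnrichment:
    """Per-bin enrichment summary."""

    bin: str
    n_total: int
    observed: int
    expected_raw: float
    expected_rounded: int
    tail_side: str
    binomial_p: float
    percent_deviation: int


@dataclass(frozen=True)
class EnrichmentResult:
    """Full enrichment analysis of a binned screen."""

    N: int
    K: int
    rate_exact: Fraction
    rate_percent: int
    binom_rate: float
    per_bin: dict[str, BinEnrichment]
    chi2_stat: float
    df: int
    chi2_p: float
    bonferroni: bool = False

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "K": self.K,
            "rate_exact": [self.rate_exact.numerator, self.rate_exact.denominator],
            "rate_percent": self.rate_percent,
            "binom_rate": self.binom_rate,
            "chi2": {"stat": self.chi2_stat, "df": self.df, "p": self.chi2_p},
            "bins": {
                b: {
                    "n_total": e.n_total,
                    "observed": e.observed,
                    "expected_raw": e.expected_raw,
                    "expected_rounded": e.expected_rounded,
                    "tail_side": e.tail_side,
                    "binomial_p": e.binomial_p,
                    "percent_deviation": e.percent_deviation,
                }
                for b, e in self.per_bin.items()
            },
        }

    def summary(self) -> str:
        lines = [
            f"N={self.N} fragments, K={self.K} GFP-positive "
            f"(rate {self.rate_percent}%)",
            f"chi2 = {self.chi2_stat:.3f}, df = {self.df}, "
            f"P = {self.chi2_p:.3g}",
            f"{'bin':<10}{'n':>6}{'obs':>6}{'exp':>6}{'dev%':>7}"
            f"{'side':>7}{'binom P':>10}",
        ]
        for b, e in self.per_bin.items():
            lines.append(
                f"{b:<10}{e.n_total:>6}{e.observed:>6}{e.expected_rounded:>6}"
                f"{e.percent_deviation:>+7}{e.tail_side:>7}{e.binomial_p:>10.3g}"
            )
        return "\n".join(lines)


def enrichment_analysis(
    counts: BinCounts,
    binom_rate: float | None = None,
    chi2_rate: Fraction | float | str = "exact",
    bin_order: Sequence[str] | None = None,
    bonferroni: bool = False,
) -> EnrichmentResult:
    """Run the full enrichment analysis on binned screen counts.

    Parameters
    ----------
    counts
        Per-bin totals and positives.
    binom_rate
        Success rate for the per-bin binomial tests.  Default: the global
        rate rounded to an integer percent (e.g. 54/281 -> 0.19), the
        convention of screen reports.
    chi2_rate
        Rate for chi-square expected counts: ``"exact"`` (K/N unrounded,
        default) or an explicit number.
    bonferroni
        Multiply binomial p-values by the number of bins (off by default;
        screens conventionally report uncorrected one-tailed tails).
    """
    order = list(bin_order) if bin_order is not None else [
        b for b in BINS if b in counts.n_total
    ] + sorted(set(counts.n_total) - set(BINS))
    sizes = [counts.n_total[b] for b in order]
    observed = [counts.n_positive.get(b, 0) for b in order]
    N, K = counts.N, counts.K
    rate = overall_rate(K, N)
    pct = rate_percent(rate)
    if binom_rate is None:
        binom_rate = pct / 100.0
    chi_rate = rate if chi2_rate == "exact" else Fraction(chi2_rate).limit_denominator(10**9)
    expected_raw, expected_rounded = expected_counts(sizes, chi_rate)
    chi2_stat, df, chi2_p = chi2_gof(observed, expected_raw)
    per_bin: dict[str, BinEnrichment] = {}
    n_tests = len(order)
    for b, n, obs, e_raw, e_round in zip(
        order, sizes, observed, expected_raw, expected_rounded
    ):
        side = UPPER if obs > n * binom_rate else LOWER
        p = binom_tail(obs, n, binom_rate, side)
        if bonferroni:
            p = min(1.0, p * n_tests)
        per_bin[b] = BinEnrichment(
            bin=b,
            n_total=n,
            observed=obs,
            expected_raw=e_raw,
            expected_rounded=e_round,
            tail_side=side,
            binomial_p=p,
            percent_deviation=percent_deviation(obs, e_round),
        )
    return EnrichmentResult(
        N=N,
        K=K,
        rate_exact=rate,
        rate_percent=pct,
        binom_rate=float(binom_rate),
        per_bin=per_bin,
        chi2_stat=chi2_stat,
        df=df,
        chi2_p=chi2_p,
        bonferroni=bonferroni,
    )
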