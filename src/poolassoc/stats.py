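"""Follow-up and design statistics for case-control allelic association.

Closed-form statistics used around the pooled-sequencing pipeline: allelic
odds ratios with Woolf confidence intervals, the Cochran-Armitage trend test
for individual-level follow-up genotyping, the exact Hardy-Weinberg
equilibrium test for genotyping QC, exact binomial enrichment of nominal
association signals, and an analytic power calculator for single-variant and
burden designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)


def allelic_or_from_maf(maf_case: float, maf_control: float) -> float:
    """Allelic odds ratio from the case and control minor-allele frequencies.

    ``OR = [maf_case / (1 - maf_case)] / [maf_control / (1 - maf_control)]``.
    """
    for name, f in (("maf_case", maf_case), ("maf_control", maf_control)):
        if not 0.0 < f < 1.0:
            raise ValueError(f"{name} must lie in (0, 1), got {f} (odds undefined)")
    return (maf_case / (1 - maf_case)) / (maf_control / (1 - maf_control))


def allelic_or_ci(
    a: float, b: float, c: float, d: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Woolf confidence interval for the allelic odds ratio.

    ``a``/``b`` are case minor/major allele counts, ``c``/``d`` the control
    counts.  Zero cells get the Haldane-Anscombe 0.5 correction (logged).
    Returns ``(OR, lower, upper)``.
    """
    counts = np.array([a, b, c, d], dtype=float)
    if (counts < 0).any():
        raise ValueError("allele counts must be non-negative")
    if (counts == 0).any():
        logger.info("zero cell in 2x2 table; applying Haldane 0.5 correction")
        counts = counts + 0.5
    if (counts == 0).any():
        raise ValueError("zero margin remains after correction")
    a, b, c, d = counts
    or_ = (a / b) / (c / d)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.isf((1 - level) / 2)
    return float(or_), float(or_ * np.exp(-z * se)), float(or_ * np.exp(z * se))


def armitage_trend(
    case_counts: tuple[int, int, int], control_counts: tuple[int, int, int]
) -> tuple[float, float]:
    """Cochran-Armitage trend test with additive scores (0, 1, 2), 1 df.

    Counts are (homozygous-major, heterozygous, homozygous-minor) per group.
    A zero-variance genotype distribution returns ``(0, 1)``.
    """
    r = np.asarray(case_counts, dtype=float)
    s = np.asarray(control_counts, dtype=float)
    if (r < 0).any() or (s < 0).any():
        raise ValueError("genotype counts must be non-negative")
    if r.sum() == 0 or s.sum() == 0:
        raise ValueError("each group needs at least one genotyped individual")
    x = np.array([0.0, 1.0, 2.0])
    n = r + s
    N = n.sum()
    R = r.sum()
    # T = sum x_i * (r_i * S - s_i * R); Var under H0 via hypergeometric moments
    T = np.sum(x * (r * (N - R) - s * R))
    mean_x = np.sum(x * n) / N
    var = (R * (N - R)) * (N * np.sum(x**2 * n) - np.sum(x * n) ** 2) / N
    if var <= 0:
        return 0.0, 1.0
    chi2 = float(T**2 / var)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium p-value.

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts (Wigginton-style) and sums the probabilities of all
    configurations no more likely than the observed one.  Monomorphic
    samples return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_minor = 2 * n_aa + n_Aa
    n_major = 2 * n_AA + n_Aa
    rare = min(n_minor, n_major)
    if rare == 0:
        return 1.0
    het_values = np.arange(rare % 2, rare + 1, 2)
    # log P(het) ∝ -log het! - log ((rare-het)/2)! - log ((n - (rare+het)/2 ... )
    hom_rare = (rare - het_values) // 2
    hom_common = n - het_values - hom_rare
    logp = (
        het_values * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(het_values + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[het_values == n_Aa]
    if observed.size == 0:  # parity mismatch cannot happen with valid counts
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = float(probs[probs <= observed[0] * (1 + 1e-12)].sum())
    return min(p, 1.0)


def binomial_enrichment(k: int, n: int, p0: float) -> float:
    """Exact one-sided binomial tail: ``P(X >= k)`` for ``X ~ Bin(n, p0)``.

    Used to ask whether ``k`` nominal association signals among ``n`` tests
    exceed the ``p0`` chance rate.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, n], got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    return float(stats.binom.sf(k - 1, n, p0))


@dataclass(frozen=True)
class PowerSpec:
    """Design of a two-group allelic association test.

    ``p0`` is the control minor-allele frequency; under a multiplicative
    model the case frequency is ``p0 * OR / (1 + p0 * (OR - 1))``.  Sample
    sizes are individuals; the test compares allele counts (2n chromosomes
    per group).
    """

    p0: float
    odds_ratio: float
    alpha: float
    n_cases: int
    n_controls: int

    def validate(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ValueError(f"p0 must lie in (0, 1), got {self.p0}")
        if self.odds_ratio <= 0:
            raise ValueError(f"odds_ratio must be > 0, got {self.odds_ratio}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")


def allelic_power(spec: PowerSpec) -> float:
    """Analytic power of the two-sided allelic two-proportion z-test.

    Uses the pooled-variance form: with case frequency ``p1`` implied by the
    odds ratio, the null standard error is computed at the pooled allele
    frequency, and power is the probability that the absolute z statistic
    exceeds ``z_{alpha/2}``:

    ``power = Phi(delta/SE0 - z) + Phi(-delta/SE0 - z)``

    with ``delta = p1 - p0`` and
    ``SE0 = sqrt(pbar (1-pbar) (1/(2 n_case) + 1/(2 n_control)))``.
    At OR = 1 this returns exactly ``alpha``.  Clamped to [0, 1].
    """
    spec.validate()
    p0 = spec.p0
    p1 = p0 * spec.odds_ratio / (1 + p0 * (spec.odds_ratio - 1))
    m1 = 2 * spec.n_cases
    m0 = 2 * spec.n_controls
    pbar = (m1 * p1 + m0 * p0) / (m1 + m0)
    se0 = np.sqrt(pbar * (1 - pbar) * (1 / m1 + 1 / m0))
    z = stats.norm.isf(spec.alpha / 2)
    delta = p1 - p0
    power = stats.norm.sf(z - delta / se0) + stats.norm.cdf(-z - delta / se0)
    return float(np.clip(power, 0.0, 1.0))
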