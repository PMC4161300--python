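"""Early-vs-late branch tests and the early/late effect-size comparison.

Under the null that isolation-causing mutations land in linear proportion
to branch length, the probability that a mutation is "early" (internal
branch b) is t_b / (t_b + t_c + t_d).  Two tests of the observed
early/late split are provided — a Pearson chi-square goodness-of-fit test
and a seeded binomial resampling with the exact binomial tail as internal
oracle — plus a bootstrap comparison of the single early mutation's effect
size against the resampled distribution of late effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .tables import RunConfig
from .trees import ThreeTaxonTree

import logging

logger = logging.getLogger(__name__)


class BranchTestError(ValueError):
    pass


@dataclass(frozen=True)
class BranchProportions:
    p_early: float
    p_late: float

    def __post_init__(self) -> None:
        if not np.isclose(self.p_early + self.p_late, 1.0):
            raise BranchTestError("p_early + p_late must equal 1")
        if not 0.0 <= self.p_early <= 1.0:
            raise BranchTestError("proportions must lie in [0, 1]")


def branch_proportions(tree: ThreeTaxonTree) -> BranchProportions:
    """Null early/late mutation probabilities from branch lengths."""
    denom = tree.total_bcd
    if denom <= 0:
        raise BranchTestError("t_b + t_c + t_d must be > 0")
    p_early = tree.t_b / denom
    return BranchProportions(p_early=p_early, p_late=1.0 - p_early)


@dataclass(frozen=True)
class GofResult:
    chi2: float
    p_value: float
    df: int
    expected_early: float
    expected_late: float


def chisq_gof(n_early: int, n_late: int, props: BranchProportions) -> GofResult:
    """Pearson chi-square test of the early/late split against the null."""
    N = n_early + n_late
    if N < 1:
        raise BranchTestError("need at least one observed mutation")
    expected = np.array([N * props.p_early, N * props.p_late])
    if (expected < 5).any():
        logger.warning(
            "expected counts below 5 (%.2f, %.2f): chi-square approximation is rough",
            *expected,
        )
    chi2, p = stats.chisquare([n_early, n_late], f_exp=expected)
    return GofResult(
        chi2=float(chi2),
        p_value=float(p),
        df=1,
        expected_early=float(expected[0]),
        expected_late=float(expected[1]),
    )


@dataclass(frozen=True)
class BinomialTailResult:
    simulated_fraction: float
    exact_tail: float
    iters: int


def binomial_tail_sim(
    n: int, p_late: float, threshold: int, iters: int = 1000, seed: int = 0
) -> BinomialTailResult:
    """Fraction of Binomial(n, p_late) draws placing >= threshold mutations
    on late branches; the exact tail P(X >= threshold) rides along as the
    closed-form oracle."""
    if not 0 <= threshold <= n:
        raise BranchTestError("threshold must lie in [0, n]")
    if iters < 1:
        raise BranchTestError("iters must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.binomial(n, p_late, size=iters)
    exact = float(stats.binom.sf(threshold - 1, n, p_late))
    return BinomialTailResult(
        simulated_fraction=float(np.mean(draws >= threshold)),
        exact_tail=exact,
        iters=iters,
    )


@dataclass(frozen=True)
class EffectSizeComparison:
    early_value: float
    boot_ci_low: float
    boot_ci_high: float
    n_boot: int
    outside_ci: bool


def bootstrap_effect_ci(
    late_effects: Sequence[float],
    n_boot: int = 500,
    seed: int = 0,
    statistic: str = "mean",
) -> tuple[float, float, np.ndarray]:
    """Percentile 95% CI of the bootstrapped late effect sizes.

    Resamples with replacement at the observed sample size.  The default
    statistic is the resample mean; ``statistic='values'`` keeps the raw
    resampled values, so the early effect is compared against the empirical
    distribution of single-locus effects instead.
    """
    values = np.asarray(late_effects, dtype=float)
    if values.size < 2:
        raise BranchTestError("need at least 2 late effect sizes to bootstrap")
    rng = np.random.default_rng(seed)
    samples = rng.choice(values, size=(n_boot, values.size), replace=True)
    if statistic == "mean":
        dist = samples.mean(axis=1)
    elif statistic == "values":
        dist = samples.ravel()
    else:
        raise BranchTestError(f"unknown statistic {statistic!r}")
    lo, hi = np.percentile(dist, [2.5, 97.5])
    return float(lo), float(hi), dist


def compare_early_late(
    early_value: float,
    late_effects: Sequence[float],
    config: Optional[RunConfig] = None,
    statistic: str = "mean",
    use_magnitude: bool = True,
) -> EffectSizeComparison:
    """Is the early mutation's effect size outside the bootstrap CI of the
    late effects?

    Effects are compared on the magnitude scale |delta %| by default (a
    fertility *reduction* of 47% is "smaller" than one of 60% even though
    -47 > -60); the CI boundary is closed, so a value exactly on it is
    inside.
    """
    config = config or RunConfig()
    if use_magnitude:
        early_value = abs(early_value)
        late_effects = [abs(v) for v in late_effects]
    lo, hi, _ = bootstrap_effect_ci(
        late_effects, n_boot=config.n_boot, seed=config.seed, statistic=statistic
    )
    outside = early_value < lo or early_value > hi
    return EffectSizeComparison(
        early_value=float(early_value),
        boot_ci_low=lo,
        boot_ci_high=hi,
        n_boot=config.n_boot,
        outside_ci=bool(outside),
    )
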