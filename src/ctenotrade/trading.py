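"""Randomization test for gamete trading in paired spawning trials.

The statistic is the *absolute difference total*: for each paired arena,
each side's share of the pair's egg output is computed, and the absolute
difference of the two shares (a number in [0, 1]) is summed over all
replicates.  Under the null hypothesis that the split of a pair's output
is uniform on [0, 1] and independent across arenas, each per-replicate
difference |a - (1 - a)| = |2a - 1| is itself Uniform(0, 1), so the total
over n replicates follows the Irwin-Hall distribution (the sum of n iid
standard uniforms), with mean n/2 and variance n/12.

Two routes to a p-value are provided and cross-checked: a Monte-Carlo
null of simulated totals (the constructed-null procedure), and the exact
Irwin-Hall tail evaluated in arbitrary-precision rational arithmetic.
Coordinated spawning (one partner suppressing its output) pushes the
observed total into the upper tail; more-even-than-random splits push it
into the lower tail.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from math import comb, factorial
from numbers import Rational

import numpy as np
from scipy import stats

from .replicates import (
    AbsoluteDifferenceTotal,
    InsufficientDataError,
    PairedSpawnReplicate,
    ProportionSplit,
    UndefinedSplitError,
)

__all__ = [
    "Tail",
    "NullDistribution",
    "TradingTestResult",
    "TwoSampleTestResult",
    "proportion_split",
    "filter_double_zero",
    "filter_low_total",
    "absolute_difference_total",
    "simulate_null_total",
    "build_null_distribution",
    "irwin_hall_cdf",
    "irwin_hall_critical_value",
    "analytic_p_value",
    "mc_p_value",
    "trading_test",
    "sensitivity_rerun",
    "compare_treatment_differences",
]


class Tail(str, enum.Enum):
    UPPER = "upper"
    LOWER = "lower"


@dataclass(frozen=True)
class NullDistribution:
    """A Monte-Carlo null: simulated absolute-difference totals.

    Each total is a sum of ``n_replicates`` independent |2U - 1| draws
    with U ~ Uniform(0, 1); the sequence is reproducible from ``seed``.
    """

    totals: np.ndarray
    n_replicates: int
    n_sims: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if len(self.totals) != self.n_sims:
            raise ValueError("totals length must equal n_sims")


@dataclass(frozen=True)
class TradingTestResult:
    observed: AbsoluteDifferenceTotal
    tail: Tail
    p_mc: float
    exceed_count: int
    p_analytic: float
    n_sims: int
    seed: int | None = None
    tie_correction: bool = False
    filters_applied: tuple[str, ...] = ()


@dataclass(frozen=True)
class TwoSampleTestResult:
    t_statistic: float
    degrees_freedom: float
    p_value: float
    variant: str  # "pooled" or "welch"
    n_1: int
    n_2: int


def proportion_split(eggs_a: int, eggs_b: int) -> ProportionSplit:
    """Split a pair's egg counts into per-side proportions.

    Raises :class:`UndefinedSplitError` on a zero total: the caller must
    exclude double-zero replicates first rather than receive an imputed
    50/50 split.
    """
    if eggs_a < 0 or eggs_b < 0:
        raise ValueError("egg counts must be non-negative")
    total = eggs_a + eggs_b
    if total == 0:
        raise UndefinedSplitError("proportion split undefined for a zero-egg pair")
    p_a = eggs_a / total
    p_b = 1.0 - p_a
    return ProportionSplit(p_a=p_a, p_b=p_b, abs_diff=abs(p_a - p_b))


def filter_double_zero(
    replicates: list[PairedSpawnReplicate],
) -> list[PairedSpawnReplicate]:
    """Drop replicates in which neither side spawned any eggs.

    Order is preserved and the input list is left untouched.
    """
    return [r for r in replicates if r.total > 0]


def filter_low_total(
    replicates: list[PairedSpawnReplicate], threshold: int
) -> list[PairedSpawnReplicate]:
    """Keep replicates whose combined egg count strictly exceeds ``threshold``.

    A threshold of 25 implements the "25 or fewer total eggs" exclusion:
    a pair totalling exactly 25 is dropped, 26 is kept.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return [r for r in replicates if r.total > threshold]


def absolute_difference_total(
    replicates: list[PairedSpawnReplicate],
) -> AbsoluteDifferenceTotal:
    """Sum of per-replicate |p_a - p_b| over paired replicates.

    Every replicate must be paired with a positive total (apply
    :func:`filter_double_zero` first).
    """
    value = 0.0
    for r in replicates:
        if not r.is_paired:
            raise UndefinedSplitError(
                f"replicate {r.replicate_id!r} is not paired (single combined count)"
            )
        value += proportion_split(r.eggs_a, r.eggs_b).abs_diff
    return AbsoluteDifferenceTotal(value=value, n_replicates=len(replicates))


def simulate_null_total(n_replicates: int, rng: np.random.Generator) -> float:
    """One simulated total under the uniform-split null.

    Draws a ~ U(0,1) per replicate, sets b = 1 - a, and sums |a - b|.
    """
    if n_replicates < 0:
        raise ValueError("n_replicates must be >= 0")
    a = rng.random(n_replicates)
    return float(np.abs(2.0 * a - 1.0).sum())


def build_null_distribution(
    n_replicates: int, n_sims: int = 10_000, seed: int = 0
) -> NullDistribution:
    """Simulate ``n_sims`` null totals; deterministic given ``seed``."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if n_replicates < 0:
        raise ValueError("n_replicates must be >= 0")
    rng = np.random.default_rng(seed)
    a = rng.random((n_sims, n_replicates))
    totals = np.abs(2.0 * a - 1.0).sum(axis=1)
    return NullDistribution(
        totals=totals, n_replicates=n_replicates, n_sims=n_sims, seed=seed
    )


def irwin_hall_cdf(x: float | Rational, n: int) -> float:
    """Exact CDF of the sum of n iid Uniform(0,1) variables.

        F(x) = (1/n!) * sum_{k=0..floor(x)} (-1)^k C(n,k) (x-k)^n

    The alternating sum suffers catastrophic cancellation in double
    precision for moderate n (at n = 26 individual terms reach ~1e22
    while tail values are ~1e-4 of the leading term's scale), so the sum
    is evaluated in exact rational arithmetic: any float argument is a
    dyadic rational and converts losslessly to a Fraction.  The result is
    exact up to the final rounding to float.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    xf = Fraction(x)
    if xf <= 0:
        return 0.0
    if xf >= n:
        return 1.0
    acc = Fraction(0)
    for k in range(int(xf) + 1):
        acc += (-1) ** k * comb(n, k) * (xf - k) ** n
    result = acc / factorial(n)
    return float(min(max(result, Fraction(0)), Fraction(1)))


def irwin_hall_critical_value(alpha: float, n: int, tail: Tail = Tail.UPPER) -> float:
    """Quantile of the Irwin-Hall(n) null: reject when the total falls
    beyond this value in the requested tail at level ``alpha``."""
    from scipy.optimize import brentq

    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    target = 1.0 - alpha if tail is Tail.UPPER else alpha
    return float(brentq(lambda x: irwin_hall_cdf(x, n) - target, 0.0, float(n)))


def analytic_p_value(observed: AbsoluteDifferenceTotal, tail: Tail) -> float:
    """Closed-form tail probability of the observed total under the null.

    Lower tail: F(value); upper tail: 1 - F(value), with F the exact
    Irwin-Hall CDF at n = n_replicates.
    """
    tail = Tail(tail)
    if observed.n_replicates < 1:
        raise ValueError("need at least one replicate")
    cdf = irwin_hall_cdf(observed.value, observed.n_replicates)
    return cdf if tail is Tail.LOWER else 1.0 - cdf


def mc_p_value(
    observed: AbsoluteDifferenceTotal,
    null: NullDistribution,
    tail: Tail,
    tie_correction: bool = False,
    filters_applied: tuple[str, ...] = (),
) -> TradingTestResult:
    """Monte-Carlo p-value of the observed total against a simulated null.

    The upper tail counts simulated totals *strictly larger* than the
    observed value, the lower tail strictly smaller, and divides by the
    number of simulations.  ``tie_correction=True`` instead reports the
    conservative (count + 1) / (n_sims + 1) estimate, which can never be
    exactly zero.
    """
    tail = Tail(tail)
    if observed.n_replicates != null.n_replicates:
        raise ValueError(
            f"replicate-count mismatch: observed n={observed.n_replicates}, "
            f"null n={null.n_replicates}"
        )
    if tail is Tail.UPPER:
        count = int(np.sum(null.totals > observed.value))
    else:
        count = int(np.sum(null.totals < observed.value))
    if tie_correction:
        p = (count + 1) / (null.n_sims + 1)
    else:
        p = count / null.n_sims
    return TradingTestResult(
        observed=observed,
        tail=tail,
        p_mc=p,
        exceed_count=count,
        p_analytic=analytic_p_value(observed, tail),
        n_sims=null.n_sims,
        seed=null.seed,
        tie_correction=tie_correction,
        filters_applied=filters_applied,
    )


def trading_test(
    replicates: list[PairedSpawnReplicate],
    tail: Tail | str = "auto",
    n_sims: int = 10_000,
    seed: int = 0,
    exclude_double_zero: bool = True,
    low_egg_threshold: int | None = None,
    tie_correction: bool = False,
) -> TradingTestResult:
    """Full trading analysis on a set of paired replicates.

    Applies the exclusion filters, computes the absolute difference
    total, builds a fresh Monte-Carlo null with the post-filter replicate
    count, and reports both the Monte-Carlo and analytic tail
    probabilities.  ``tail="auto"`` selects the upper tail when the
    observed total exceeds the null mean n/2 and the lower tail
    otherwise.
    """
    filters: list[str] = []
    working = list(replicates)
    if exclude_double_zero:
        before = len(working)
        working = filter_double_zero(working)
        filters.append(f"double_zero_excluded={before - len(working)}")
    if low_egg_threshold is not None:
        before = len(working)
        working = filter_low_total(working, low_egg_threshold)
        filters.append(
            f"low_total_excluded={before - len(working)} (threshold={low_egg_threshold})"
        )
    if not working:
        raise InsufficientDataError("no replicates remain after filtering")
    observed = absolute_difference_total(working)
    if tail == "auto":
        tail = Tail.UPPER if observed.value > observed.n_replicates / 2 else Tail.LOWER
    null = build_null_distribution(observed.n_replicates, n_sims=n_sims, seed=seed)
    return mc_p_value(
        observed, null, Tail(tail),
        tie_correction=tie_correction, filters_applied=tuple(filters),
    )


def sensitivity_rerun(
    replicates: list[PairedSpawnReplicate],
    threshold: int,
    n_sims: int = 10_000,
    seed: int = 0,
    tail: Tail | str = Tail.UPPER,
    tie_correction: bool = False,
) -> TradingTestResult:
    """Re-run the trading test after dropping low-output pairs.

    Removes pairs with ``threshold`` or fewer total eggs and rebuilds the
    null with the reduced replicate count, so the simulated and
    experimental replicate numbers stay matched.
    """
    return trading_test(
        replicates,
        tail=tail,
        n_sims=n_sims,
        seed=seed,
        exclude_double_zero=True,
        low_egg_threshold=threshold,
        tie_correction=tie_correction,
    )


def compare_treatment_differences(
    diffs_1: list[float] | np.ndarray,
    diffs_2: list[float] | np.ndarray,
    variant: str = "pooled",
) -> TwoSampleTestResult:
    """Two-sample t-test on per-replicate absolute proportion differences.

    Compares the per-replicate |p_a - p_b| values of two treatments
    (e.g. permeable vs sealed).  ``variant`` selects the pooled-variance
    test (default) or Welch's unequal-variance test.
    """
    d1 = np.asarray(diffs_1, dtype=float)
    d2 = np.asarray(diffs_2, dtype=float)
    if d1.size < 2 or d2.size < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    res = stats.ttest_ind(d1, d2, equal_var=(variant == "pooled"))
    return TwoSampleTestResult(
        t_statistic=float(res.statistic),
        degrees_freedom=float(res.df),
        p_value=float(res.pvalue),
        variant=variant,
        n_1=int(d1.size),
        n_2=int(d2.size),
    )
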