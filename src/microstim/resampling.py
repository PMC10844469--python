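"""Resampling inference: exceedance test, permutation ANOVA, rank-sum
comparison, and bootstrap effect sizes.

The exceedance test draws target-sized samples *with replacement* from the
pooled activation calls and counts how many resampled fractions reach the
observed target fraction; the add-one convention (e+1)/(B+1) keeps p-values
strictly positive.  The permutation ANOVA uses the size-weighted
between-group sum of squares of group means, whose ordering under label
permutation is equivalent to the classical F statistic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ResamplingResult",
    "exceedance_test",
    "permutation_anova",
    "rank_sum_test",
    "effect_size_difference",
    "median_ratio_effect",
    "EffectSize",
]


@dataclass(frozen=True)
class ResamplingResult:
    observed: float
    n_resamples: int
    exceedance_count: int
    p_value: float
    seed: int | None = None
    exact: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.exceedance_count <= self.n_resamples):
            raise ValueError("exceedance_count out of range")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must be in (0, 1]")


def _as_calls(group) -> np.ndarray:
    arr = np.asarray(group)
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("calls must be binary")
        arr = arr.astype(bool)
    return arr


def exceedance_test(
    target_group,
    reference_group,
    n_resamples: int = 5000,
    seed: int | None = 0,
) -> ResamplingResult:
    """Pooled with-replacement resampling null for a high target fraction.

    Pools both groups' binary calls, draws ``n_resamples`` samples of the
    target-group size with replacement, and counts resamples whose
    activated fraction is at or above the observed target fraction
    (inclusive).  p = (exceedances + 1) / (n_resamples + 1).
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be at least 100")
    target = _as_calls(target_group)
    reference = _as_calls(reference_group)
    if target.size == 0 or reference.size == 0:
        raise ValueError("both groups must be non-empty")
    pool = np.concatenate([target, reference]).astype(np.int8)
    nt = target.size
    obs_count = int(target.sum())
    rng = np.random.default_rng(seed)
    draws = pool[rng.integers(0, pool.size, size=(n_resamples, nt))]
    exceed = int((draws.sum(axis=1) >= obs_count).sum())
    return ResamplingResult(
        observed=obs_count / nt,
        n_resamples=n_resamples,
        exceedance_count=exceed,
        p_value=(exceed + 1) / (n_resamples + 1),
        seed=seed,
    )


def _between_group_ss(values: np.ndarray, sizes: np.ndarray) -> float:
    grand = values.mean()
    ss = 0.0
    start = 0
    for n in sizes:
        m = values[start : start + n].mean()
        ss += n * (m - grand) ** 2
        start += n
    return ss


def _n_assignments(sizes) -> int:
    total = math.factorial(int(sum(sizes)))
    for n in sizes:
        total //= math.factorial(int(n))
    return total


def _enumerate_assignments(n: int, sizes):
    """Yield index tuples partitioning range(n) into groups of the given sizes."""

    def rec(remaining, sizes_left):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in rec(rest, sizes_left[1:]):
                yield (combo,) + tail

    yield from rec(tuple(range(n)), tuple(sizes))


ENUMERATION_LIMIT = 20000


def permutation_anova(
    groups,
    n_perm: int = 5000,
    seed: int | None = 0,
    exact_limit: int = ENUMERATION_LIMIT,
) -> ResamplingResult:
    """Permutation test of equal group means across two or more groups.

    Statistic: size-weighted between-group sum of squares of group means
    about the grand mean.  When the number of distinct label assignments is
    at most ``exact_limit`` the null is enumerated exactly (p = e/total);
    otherwise ``n_perm`` random label permutations with the add-one p.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    values = np.concatenate(arrays)
    sizes = np.array([a.size for a in arrays])
    n = values.size
    obs = _between_group_ss(values, sizes)
    tol = 1e-12 * max(1.0, abs(obs))

    n_assign = _n_assignments(sizes)
    if n_assign <= exact_limit:
        exceed = 0
        grand = values.mean()
        for assignment in _enumerate_assignments(n, sizes):
            ss = sum(
                len(idx) * (values[list(idx)].mean() - grand) ** 2 for idx in assignment
            )
            if ss >= obs - tol:
                exceed += 1
        return ResamplingResult(
            observed=obs,
            n_resamples=n_assign,
            exceedance_count=exceed,
            p_value=exceed / n_assign,
            seed=seed,
            exact=True,
        )

    rng = np.random.default_rng(seed)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    grand = values.mean()
    exceed = 0
    chunk = max(1, min(n_perm, 5_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        order = np.argsort(rng.random((b, n)), axis=1)
        perm_vals = values[order]
        sums = np.add.reduceat(perm_vals, starts, axis=1)
        ss = (sums**2 / sizes).sum(axis=1) - n * grand**2
        exceed += int((ss >= obs - tol).sum())
        done += b
    return ResamplingResult(
        observed=obs,
        n_resamples=n_perm,
        exceedance_count=exceed,
        p_value=(exceed + 1) / (n_perm + 1),
        seed=seed,
    )


def _exact_rank_sum_with_ties(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating group-A index choices,
    with mid-ranks for ties."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # mid-ranks
    n = pooled.size
    na = a.size
    obs = ranks[:na].sum()
    mean_rank_sum = na * (n + 1) / 2.0
    obs_dev = abs(obs - mean_rank_sum)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(n), na):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mean_rank_sum) >= obs_dev - 1e-9:
            extreme += 1
    return extreme / total


def rank_sum_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison.

    Exact null enumeration when both samples have at most 8 values
    (tie-aware, mid-ranks); otherwise the normal approximation with tie
    and continuity corrections.  Returns (p_value, U statistic).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        # every observation tied: no evidence either way
        return 1.0, float(a.size * b.size / 2.0)
    small = a.size <= 8 and b.size <= 8
    if small and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.pvalue), float(res.statistic)
    if small and has_ties:
        u = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").statistic)
        return _exact_rank_sum_with_ties(a, b), u
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(min(res.pvalue, 1.0)), float(res.statistic)


@dataclass(frozen=True)
class EffectSize:
    """A bootstrap effect size, reported as value +/- one bootstrap SD."""

    value: float
    se: float
    n_boot: int
    seed: int | None = None
    units: str = ""


def effect_size_difference(
    calls_a,
    calls_b,
    n_boot: int = 5000,
    seed: int | None = 0,
) -> EffectSize:
    """Difference in fraction activated (group A minus group B), in
    percentage points, with bootstrap SE (independent resampling within
    each group)."""
    a = _as_calls(calls_a)
    b = _as_calls(calls_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    fa = a[rng.integers(0, a.size, size=(n_boot, a.size))].mean(axis=1)
    fb = b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1)
    diff = 100.0 * (a.mean() - b.mean())
    se = 100.0 * float((fa - fb).std(ddof=0))
    return EffectSize(value=float(diff), se=se, n_boot=n_boot, seed=seed, units="percentage points")


def median_ratio_effect(
    group_a,
    group_b,
    n_boot: int = 5000,
    seed: int | None = 0,
) -> EffectSize:
    """Percent change in median nuclear/cytoplasmic ratio, B relative to A,
    with bootstrap SE."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("both groups need at least 5 values")
    med_a = np.median(a)
    if med_a == 0:
        raise ValueError("group A median is zero; percent change undefined")
    rng = np.random.default_rng(seed)
    ma = np.median(a[rng.integers(0, a.size, size=(n_boot, a.size))], axis=1)
    mb = np.median(b[rng.integers(0, b.size, size=(n_boot, b.size))], axis=1)
    boot = 100.0 * (mb - ma) / ma
    value = 100.0 * (np.median(b) - med_a) / med_a
    return EffectSize(
        value=float(value), se=float(boot.std(ddof=0)), n_boot=n_boot, seed=seed, units="percent"
    )
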