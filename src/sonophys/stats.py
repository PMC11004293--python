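"""Nonparametric test battery with a from-scratch Steel many-one rank test.

The Steel test compares k treatment groups against a single shared control.
For each treatment j, control and treatment observations are jointly
mid-ranked; the treatment rank sum ``R_j`` is standardized with the
tie-corrected two-sample variance

    E[R_j]   = n_j (N_j + 1) / 2,              N_j = n0 + n_j
    Var[R_j] = n0 n_j / (N_j (N_j - 1)) * sum_i (r_i - (N_j+1)/2)^2

giving ``T_j = (R_j - E) / sqrt(Var)``.  Because every comparison shares the
control, the (T_1, ..., T_k) are correlated; under the null they are
asymptotically multivariate normal with the Dunnett-type correlation

    rho_jl = sqrt( n_j n_l / ((n0 + n_j)(n0 + n_l)) )        (1/2 for equal n).

The familywise-adjusted two-sided p-value for treatment j is
``P(max_l |T_l| >= |T_j|)`` under the exchangeable null.  It is evaluated
either by exact enumeration of all partitions of the pooled data (small
groups) or by seeded Monte-Carlo over iid continuous null data (10^5 draws
by default, cached per group-size signature), which reproduces the discrete
joint null of the rank sums — including the shared-control correlation —
rather than its multivariate-normal limit.  The adjusted p is clamped from
below by the per-comparison tail of the same null draws, so it can never
undercut the corresponding unadjusted pairwise test.

Mann–Whitney U, Wilcoxon signed-rank (zero differences dropped, Wilcoxon's
rule), Friedman and Shapiro–Wilk are delegated to scipy.stats, with
degenerate inputs (all-tied data) returned as flagged results instead of
exceptions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .core import InvalidParameterError, UnsupportedSizeError

__all__ = ["StatResult", "rank_test", "steel_test", "normality_gate",
           "steel_statistics"]

DEFAULT_MC_DRAWS = 100_000
EXACT_PARTITION_LIMIT = 50_000


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    n_per_group: Tuple[int, ...]
    adjusted: bool = False
    comparison_label: str = ""
    degenerate: bool = False
    method: str = ""
    seed: Optional[int] = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise InvalidParameterError("p_value must lie in [0, 1]")


def _check_groups(samples: Sequence[np.ndarray], min_n: int = 3) -> List[np.ndarray]:
    arrs = [np.asarray(s, dtype=np.float64).ravel() for s in samples]
    for a in arrs:
        if a.size < min_n:
            raise UnsupportedSizeError(f"group sizes must be >= {min_n} (got {a.size})")
    return arrs


# ---------------------------------------------------------------------------
# Standard battery (scipy-backed)
# ---------------------------------------------------------------------------

def rank_test(kind: str, samples: Sequence, paired: bool = False) -> StatResult:
    """Two-sided Mann–Whitney U, Wilcoxon signed-rank, or Friedman test.

    scipy uses exact enumeration for small untied samples and tie-corrected
    normal/chi-square approximations otherwise.  All-tied paired data
    returns a degenerate flagged result (statistic 0, p 1) — not an error.
    """
    arrs = _check_groups(samples)
    n = tuple(a.size for a in arrs)

    if kind == "mann_whitney_u":
        if len(arrs) != 2:
            raise InvalidParameterError("Mann–Whitney requires exactly two groups")
        res = sps.mannwhitneyu(arrs[0], arrs[1], alternative="two-sided", method="auto")
        return StatResult(kind, float(res.statistic), float(res.pvalue), n)

    if kind == "wilcoxon_signed_rank":
        if len(arrs) != 2 or n[0] != n[1]:
            raise InvalidParameterError("paired test requires two equal-length samples")
        diffs = arrs[0] - arrs[1]
        if np.all(diffs == 0):
            return StatResult(kind, 0.0, 1.0, n, degenerate=True, method="degenerate")
        res = sps.wilcoxon(arrs[0], arrs[1], zero_method="wilcox", alternative="two-sided")
        return StatResult(kind, float(res.statistic), float(res.pvalue), n)

    if kind == "friedman":
        if len(arrs) < 3:
            raise InvalidParameterError("Friedman requires >= 3 related samples")
        if len({a.size for a in arrs}) != 1:
            raise InvalidParameterError("Friedman requires equal-length samples")
        block = np.column_stack(arrs)
        if np.all(block.max(axis=1) == block.min(axis=1)):
            return StatResult(kind, 0.0, 1.0, n, degenerate=True, method="degenerate")
        res = sps.friedmanchisquare(*arrs)
        return StatResult(kind, float(res.statistic), float(res.pvalue), n)

    raise InvalidParameterError(f"unknown test kind {kind!r}")


def normality_gate(sample) -> StatResult:
    """Shapiro–Wilk normality check (3 <= n <= 5000)."""
    x = np.asarray(sample, dtype=np.float64).ravel()
    if not (3 <= x.size <= 5000):
        raise UnsupportedSizeError(f"Shapiro–Wilk supports 3 <= n <= 5000, got {x.size}")
    if np.all(x == x[0]):
        return StatResult("shapiro_wilk", float("nan"), 1.0, (x.size,),
                          degenerate=True, method="degenerate")
    res = sps.shapiro(x)
    return StatResult("shapiro_wilk", float(res.statistic), float(res.pvalue), (x.size,))


# ---------------------------------------------------------------------------
# Steel many-one test
# ---------------------------------------------------------------------------

def _standardized_rank_sum(control: np.ndarray, treatment: np.ndarray) -> Tuple[float, bool]:
    """Tie-corrected standardized Wilcoxon rank sum of treatment vs control."""
    pooled = np.concatenate([control, treatment])
    n0, nj = control.size, treatment.size
    big_n = n0 + nj
    r = sps.rankdata(pooled)
    rank_sum = float(r[n0:].sum())
    expect = nj * (big_n + 1) / 2.0
    spread = float(((r - (big_n + 1) / 2.0) ** 2).sum())
    var = n0 * nj * spread / (big_n * (big_n - 1))
    if var <= 0:
        return 0.0, True
    return (rank_sum - expect) / math.sqrt(var), False


def steel_statistics(control, treatments) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized statistics T_j, degeneracy flags, and the correlation matrix."""
    c = np.asarray(control, dtype=np.float64).ravel()
    ts = [np.asarray(t, dtype=np.float64).ravel() for t in treatments]
    t_stats, degen = zip(*(_standardized_rank_sum(c, t) for t in ts))
    n0 = c.size
    nj = np.array([t.size for t in ts], dtype=float)
    lam = np.sqrt(nj / (n0 + nj))
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)
    return np.asarray(t_stats), np.asarray(degen), corr


_MC_CACHE: dict = {}


def _null_stat_sample(sizes: Tuple[int, ...], n_draws: int, seed: int) -> np.ndarray:
    """Monte-Carlo sample of (T_1, ..., T_k) under the exchangeable null.

    Draws iid continuous data for all groups and recomputes the standardized
    many-one rank statistics, reproducing the *discrete* joint null of the
    rank sums (including the shared-control correlation) rather than its
    multivariate-normal limit.  Cached per (sizes, n_draws, seed); shape
    (n_draws, k).
    """
    key = (sizes, n_draws, seed)
    hit = _MC_CACHE.get(key)
    if hit is not None:
        return hit
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n0, treat_sizes = sizes[0], sizes[1:]
    x = rng.standard_normal((n_draws, sum(sizes)))
    t_null = np.empty((n_draws, len(treat_sizes)))
    offset = n0
    for j, nj in enumerate(treat_sizes):
        pair = np.concatenate([x[:, :n0], x[:, offset:offset + nj]], axis=1)
        offset += nj
        big_n = n0 + nj
        ranks = sps.rankdata(pair, axis=1)  # ties have measure zero here
        rank_sum = ranks[:, n0:].sum(axis=1)
        expect = nj * (big_n + 1) / 2.0
        var = n0 * nj * (big_n + 1) / 12.0
        t_null[:, j] = (rank_sum - expect) / math.sqrt(var)
    # pre-sorted tails make repeated p-value lookups O(log n_draws)
    sample = (np.sort(np.abs(t_null).max(axis=1)),
              np.sort(np.abs(t_null), axis=0))
    if len(_MC_CACHE) > 64:
        _MC_CACHE.clear()
    _MC_CACHE[key] = sample
    return sample


def _iter_partitions(indices: Tuple[int, ...], sizes: Sequence[int]):
    """All ways to split ``indices`` into ordered groups of the given sizes."""
    if len(sizes) == 1:
        yield (indices,)
        return
    for head in itertools.combinations(indices, sizes[0]):
        rest = tuple(i for i in indices if i not in set(head))
        for tail in _iter_partitions(rest, sizes[1:]):
            yield (head,) + tail


def _n_partitions(sizes: Sequence[int]) -> int:
    total = sum(sizes)
    out = 1
    for s in sizes:
        out *= math.comb(total, s)
        total -= s
    return out


def _steel_exact(control: np.ndarray, treatments: List[np.ndarray],
                 observed: np.ndarray) -> np.ndarray:
    """Exact familywise p via enumeration of all group assignments."""
    pooled = np.concatenate([control] + list(treatments))
    sizes = [control.size] + [t.size for t in treatments]
    tol = 1e-9
    exceed = np.zeros(observed.size, dtype=np.int64)
    total = 0
    for part in _iter_partitions(tuple(range(pooled.size)), sizes):
        c = pooled[list(part[0])]
        max_abs = 0.0
        for g in part[1:]:
            t_stat, _ = _standardized_rank_sum(c, pooled[list(g)])
            max_abs = max(max_abs, abs(t_stat))
        total += 1
        exceed += max_abs >= np.abs(observed) - tol
    return exceed / total


def steel_test(
    control,
    treatments: Sequence,
    *,
    method: str = "auto",
    n_draws: int = DEFAULT_MC_DRAWS,
    seed: int = 0,
    exact_limit: int = EXACT_PARTITION_LIMIT,
) -> List[StatResult]:
    """Steel many-one rank test of each treatment against a shared control.

    Returns one familywise-adjusted two-sided :class:`StatResult` per
    treatment.  ``method`` is ``'exact'`` (full partition enumeration,
    guarded by ``exact_limit``), ``'mc'`` (seeded multivariate-normal
    Monte-Carlo), or ``'auto'`` (exact when affordable).
    """
    c = np.asarray(control, dtype=np.float64).ravel()
    ts = _check_groups(treatments)
    if c.size < 3:
        raise UnsupportedSizeError("control group size must be >= 3")
    if len(ts) < 1:
        raise InvalidParameterError("at least one treatment group required")

    t_stats, degen, corr = steel_statistics(c, ts)
    sizes = [c.size] + [t.size for t in ts]
    n_part = _n_partitions(sizes)

    if method == "auto":
        method = "exact" if n_part <= exact_limit else "mc"
    if method == "exact" and n_part > exact_limit:
        raise InvalidParameterError(
            f"{n_part} partitions exceed exact_limit={exact_limit}; use method='mc'")

    tol = 1e-9
    if method == "exact":
        p_adj = _steel_exact(c, ts, t_stats)
        used_seed = None
    elif method == "mc":
        sorted_max, sorted_abs = _null_stat_sample(tuple(sizes), n_draws, seed)
        obs = np.abs(t_stats)
        p_max = (n_draws - np.searchsorted(sorted_max, obs - tol, side="left") + 1) / (n_draws + 1)
        # per-comparison tail from the same null draws; the familywise p can
        # never undercut the corresponding unadjusted pairwise p
        p_single = np.array([
            (n_draws - np.searchsorted(sorted_abs[:, j], obs[j] - tol, side="left") + 1) / (n_draws + 1)
            for j in range(obs.size)])
        p_adj = np.maximum(p_max, p_single)
        used_seed = seed
    else:
        raise InvalidParameterError("method must be 'auto', 'exact' or 'mc'")

    results = []
    for j, (t_stat, p, dg) in enumerate(zip(t_stats, p_adj, degen)):
        results.append(StatResult(
            test="steel",
            statistic=float(t_stat),
            p_value=1.0 if dg else float(min(p, 1.0)),
            n_per_group=(c.size, ts[j].size),
            adjusted=True,
            comparison_label=f"treatment_{j + 1}_vs_control",
            degenerate=bool(dg),
            method=method,
            seed=used_seed,
        ))
    return results
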