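"""Rank-test battery and the Steel many-one test against enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from sonophys import normality_gate, rank_test, steel_test
from sonophys.core import UnsupportedSizeError


# ---------------------------------------------------------------------------
# independent brute-force oracle for the Steel test
# ---------------------------------------------------------------------------

def brute_force_steel(control, treatments):
    """Exact familywise p by explicit enumeration over all group assignments.

    Written independently of the package's exact path: plain nested loops,
    ranks computed by sorting.
    """
    pooled = list(control) + [v for t in treatments for v in t]
    sizes = [len(control)] + [len(t) for t in treatments]
    n = len(pooled)

    def standardized(ctrl, treat):
        pair = list(ctrl) + list(treat)
        order = sorted(range(len(pair)), key=lambda i: pair[i])
        ranks = [0.0] * len(pair)
        i = 0
        while i < len(pair):  # midranks for ties
            j = i
            while j + 1 < len(pair) and pair[order[j + 1]] == pair[order[i]]:
                j += 1
            for k in range(i, j + 1):
                ranks[order[k]] = (i + j) / 2.0 + 1.0
            i = j + 1
        n0, nj = len(ctrl), len(treat)
        big = n0 + nj
        rank_sum = sum(ranks[n0:])
        expect = nj * (big + 1) / 2.0
        spread = sum((r - (big + 1) / 2.0) ** 2 for r in ranks)
        var = n0 * nj * spread / (big * (big - 1))
        return (rank_sum - expect) / math.sqrt(var)

    observed = [abs(standardized(control, t)) for t in treatments]

    def partitions(idx, szs):
        if len(szs) == 1:
            yield [list(idx)]
            return
        for head in itertools.combinations(idx, szs[0]):
            rest = [i for i in idx if i not in head]
            for tail in partitions(rest, szs[1:]):
                yield [list(head)] + tail

    exceed = [0] * len(treatments)
    total = 0
    for part in partitions(tuple(range(n)), sizes):
        ctrl = [pooled[i] for i in part[0]]
        max_abs = max(abs(standardized(ctrl, [pooled[i] for i in g])) for g in part[1:])
        total += 1
        for j, obs in enumerate(observed):
            if max_abs >= obs - 1e-9:
                exceed[j] += 1
    return [e / total for e in exceed]


# ---------------------------------------------------------------------------

class TestRankBattery:
    def test_mann_whitney_fully_separated_small_groups(self):
        res = rank_test("mann_whitney_u", [[1, 2, 3], [4, 5, 6]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 arrangements

    def test_identical_paired_samples_degenerate(self):
        res = rank_test("wilcoxon_signed_rank", [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.degenerate and res.statistic == 0.0 and res.p_value == 1.0

    def test_friedman_identical_columns_degenerate(self):
        res = rank_test("friedman", [[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.degenerate and res.statistic == 0.0 and res.p_value == 1.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 500))
    def test_rank_tests_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=8), rng.normal(1.0, 1.0, size=8)
        a = rank_test("mann_whitney_u", [x, y])
        b = rank_test("mann_whitney_u", [np.exp(x), np.exp(y)])
        assert a.p_value == pytest.approx(b.p_value)
        cols = [rng.normal(size=6) for _ in range(3)]
        fa = rank_test("friedman", cols)
        fb = rank_test("friedman", [np.arctan(c) for c in cols])
        assert fa.p_value == pytest.approx(fb.p_value)

    def test_monotone_invariance_of_steel(self):
        rng = np.random.default_rng(11)
        c = rng.normal(size=6)
        ts = [rng.normal(0.5, 1.0, size=6) for _ in range(2)]
        a = steel_test(c, ts, method="mc", seed=4)
        b = steel_test(np.exp(c), [np.exp(t) for t in ts], method="mc", seed=4)
        for ra, rb in zip(a, b):
            assert ra.statistic == pytest.approx(rb.statistic)
            assert ra.p_value == pytest.approx(rb.p_value)


class TestSteel:
    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_exact_path_matches_brute_force_single_treatment(self, n):
        rng = np.random.default_rng(n)
        control = rng.normal(size=n)
        treat = rng.normal(1.0, 1.0, size=n)
        res = steel_test(control, [treat], method="exact")
        oracle = brute_force_steel(list(control), [list(treat)])
        assert res[0].p_value == pytest.approx(oracle[0], abs=1e-12)

    @pytest.mark.parametrize("n", [3, 4])
    def test_exact_path_matches_brute_force_two_treatments(self, n):
        rng = np.random.default_rng(10 + n)
        control = rng.normal(size=n)
        ts = [rng.normal(0.5, 1.0, size=n), rng.normal(-0.5, 1.0, size=n)]
        res = steel_test(control, ts, method="exact")
        oracle = brute_force_steel(list(control), [list(t) for t in ts])
        for r, p in zip(res, oracle):
            assert r.p_value == pytest.approx(p, abs=1e-12)

    def test_exact_path_handles_ties(self):
        control = [1.0, 2.0, 2.0, 3.0]
        treat = [2.0, 3.0, 3.0, 4.0]
        res = steel_test(control, [treat], method="exact")
        oracle = brute_force_steel(control, [treat])
        assert res[0].p_value == pytest.approx(oracle[0], abs=1e-12)

    def test_single_treatment_matches_mann_whitney(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        y = rng.normal(0.9, 1.0, size=12)
        steel_p = steel_test(x, [y], method="mc", seed=5)[0].p_value
        mw_p = rank_test("mann_whitney_u", [x, y]).p_value
        assert steel_p == pytest.approx(mw_p, abs=0.02)

    def test_large_shift_gives_tiny_adjusted_p(self):
        rng = np.random.default_rng(3)
        control = rng.normal(size=10)
        shifted = rng.normal(5.0, 1.0, size=10)  # +5 SD
        null = rng.normal(size=10)
        res = steel_test(control, [shifted, null], method="mc", seed=6)
        assert res[0].p_value < 1e-3
        assert res[1].p_value > 0.05

    def test_adjusted_p_never_undercuts_pairwise_p(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            c = rng.normal(size=8)
            ts = [rng.normal(rng.uniform(-1, 1), 1.0, size=8) for _ in range(3)]
            res = steel_test(c, ts, method="mc", seed=9)
            for r, t in zip(res, ts):
                assert r.p_value >= rank_test("mann_whitney_u", [c, t]).p_value - 0.02

    def test_familywise_error_calibrated_at_5pct(self):
        rng = np.random.default_rng(77)
        n_rep, rej = 2000, 0
        for _ in range(n_rep):
            groups = rng.standard_normal((4, 10))
            res = steel_test(groups[0], list(groups[1:]), method="mc", seed=321)
            if min(r.p_value for r in res) < 0.05:
                rej += 1
        assert 0.03 <= rej / n_rep <= 0.07  # 3 SE band around 0.05 at 2000 reps

    def test_zero_variance_group_flagged_degenerate(self):
        res = steel_test([1.0, 1.0, 1.0], [[1.0, 1.0, 1.0]], method="mc", seed=0)
        assert res[0].degenerate and res[0].p_value == 1.0


class TestNormalityGate:
    def test_size_limits(self):
        with pytest.raises(UnsupportedSizeError):
            normality_gate([1.0, 2.0])
        with pytest.raises(UnsupportedSizeError):
            normality_gate(np.zeros(5001))

    def test_constant_sample_degenerate(self):
        assert normality_gate([2.0] * 10).degenerate

    def test_gaussian_sample_passes(self):
        x = np.random.default_rng(1).normal(size=200)
        assert normality_gate(x).p_value > 0.01

    def test_bimodal_sample_rejected(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(-4, 0.5, 25), rng.normal(4, 0.5, 25)])
        assert normality_gate(x).p_value < 0.01

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(3)
        ps = [normality_gate(rng.normal(size=25)).p_value for _ in range(200)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01
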