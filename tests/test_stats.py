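"""Group allocation and the gated comparison workflow."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from humeromorph.errors import InsufficientDataError, ParameterError, ValidationError
from humeromorph.stats import (
    ComparisonTable,
    allocate_group,
    bonferroni,
    compare_groups,
    compare_regions_within_group,
    normality_gate,
    signed_rank_test,
)


class TestAllocateGroup:
    @pytest.mark.parametrize(
        "t,group",
        [
            (-6.5, "osteoporotic"),
            (-2.7, "osteoporotic"),
            (-2.5, "osteoporotic"),  # WHO boundary inclusive
            (-2.4999, "osteopenia"),
            (-1.8, "osteopenia"),
            (-1.0, "normal"),
            (-0.9, "normal"),
            (1.6, "normal"),
        ],
    )
    def test_who_bands(self, t, group):
        assert allocate_group(t) == group

    @pytest.mark.parametrize("bad", [float("nan"), float("inf")])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(ValidationError):
            allocate_group(bad)


class TestNormalityGate:
    def test_level_on_gaussian_samples(self):
        rng = np.random.default_rng(1)
        passed = sum(normality_gate(rng.normal(size=30))[0] for _ in range(1000))
        assert passed >= 900  # nominal level 0.05

    def test_power_against_exponential(self):
        rng = np.random.default_rng(2)
        rejected = sum(not normality_gate(rng.exponential(size=50))[0] for _ in range(500))
        assert rejected >= 400  # >= 80% power

    def test_constant_sample_routes_nonparametric(self):
        ok, w = normality_gate([5.0] * 10)
        assert ok is False and math.isnan(w)

    def test_too_small_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            normality_gate([1.0, 2.0])


class TestBonferroni:
    @pytest.mark.parametrize("p,m,want", [(0.02, 3, 0.06), (0.5, 3, 1.0), (0.123, 1, 0.123)])
    def test_examples(self, p, m, want):
        assert bonferroni(p, m) == pytest.approx(want, abs=1e-15)

    @pytest.mark.parametrize("p,m", [(-0.1, 2), (1.1, 2), (0.5, 0)])
    def test_out_of_range_rejected(self, p, m):
        with pytest.raises(ParameterError):
            bonferroni(p, m)


def brute_force_signed_rank_p(d, alternative="two-sided"):
    """Independent oracle: enumerate all 2^n sign assignments of |d|."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    p_le = np.mean(ws <= w_obs + 1e-12)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


class TestSignedRank:
    def test_all_positive_differences_one_sided(self):
        # 6 positive differences: P(W+ = 21) under the null = 1/64
        w, p = signed_rank_test([1, 2, 3, 4, 5, 6], alternative="greater")
        assert w == 21.0
        assert p == pytest.approx(1.0 / 64.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 10))
        # integer-valued differences induce ties and zeros
        d = rng.integers(-5, 6, size=n).astype(float)
        for alt in ("two-sided", "greater", "less"):
            _, p = signed_rank_test(d, alternative=alt)
            assert p == pytest.approx(brute_force_signed_rank_p(d, alt), abs=1e-12), (d, alt)

    def test_large_sample_approximation_is_close(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.3, 1.0, size=60)
        _, p = signed_rank_test(d)
        ref = sps.wilcoxon(d, correction=True, method="approx").pvalue
        assert p == pytest.approx(ref, abs=0.02)

    def test_all_zero_differences_degenerate(self):
        w, p = signed_rank_test([0.0, 0.0, 0.0])
        assert (w, p) == (0.0, 1.0)


class TestCompareRegionsWithinGroup:
    def _frame(self, cols):
        return pd.DataFrame(cols)

    def test_identical_regions_never_significant(self):
        df = self._frame({"h": [20.0] * 6, "m1": [20.0] * 6, "m2": [20.0] * 6})
        tables = compare_regions_within_group(df)
        assert all(t.raw_p == 1.0 for t in tables)
        assert not any(t.significant for t in tables)

    def test_parametric_path_with_gaussian_columns(self):
        rng = np.random.default_rng(0)
        df = self._frame(
            {
                "h": 25 + rng.normal(0, 1, 8),
                "sc1": 18 + rng.normal(0, 1, 8),
                "sc2": 20 + rng.normal(0, 1, 8),
            }
        )
        tables = compare_regions_within_group(df)
        assert {t.test_used for t in tables} == {"repeated_measures_parametric"}
        assert all(t.n_comparisons == 3 for t in tables)

    def test_single_failing_column_routes_family_nonparametric(self):
        rng = np.random.default_rng(0)
        df = self._frame(
            {
                "h": 25 + rng.normal(0, 1, 8),
                "sc1": 18 + rng.normal(0, 1, 8),
                "sc2": np.array([1, 1, 1, 1, 1, 1, 1, 40.0]),  # wildly non-normal
            }
        )
        tables = compare_regions_within_group(df)
        assert {t.test_used for t in tables} == {"wilcoxon_signed_rank"}

    def test_signed_rank_path_matches_enumeration(self):
        df = self._frame(
            {
                "a": [10.0, 11, 12, 13, 14, 15, 16, 40],
                "b": [9.0, 9, 11, 10, 12, 13, 14, 10],
            }
        )
        tables = compare_regions_within_group(df)
        assert tables[0].test_used == "wilcoxon_signed_rank"
        d = df["a"].to_numpy() - df["b"].to_numpy()
        assert tables[0].raw_p == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)

    def test_too_few_donors_rejected(self):
        df = self._frame({"h": [1.0, 2.0], "m1": [2.0, 3.0]})
        with pytest.raises(InsufficientDataError):
            compare_regions_within_group(df)


class TestCompareGroups:
    def test_identical_groups_give_p_one(self):
        t = compare_groups([5.0] * 6, [5.0] * 6)
        assert t.raw_p == 1.0 and not t.significant

    def test_welch_t_matches_closed_form(self):
        a = np.array([24.1, 25.3, 26.0, 24.8, 25.5, 23.9])
        b = np.array([12.2, 13.1, 11.8, 12.9, 12.4, 13.5])
        table = compare_groups(a, b)
        assert table.test_used == "t_test"
        # closed-form Welch t and Satterthwaite df
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        tstat = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p = 2.0 * sps.t.sf(abs(tstat), df)
        assert table.raw_p == pytest.approx(p, abs=1e-10)

    def test_power_at_large_separation(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(500):
            a = rng.normal(25, 2, 6)
            b = rng.normal(12, 2, 6)
            hits += compare_groups(a, b).significant
        assert hits >= 475  # >= 95%

    def test_nonnormal_sample_routes_rank_sum(self):
        a = np.array([1.0, 1, 1, 1, 1, 30])  # gate fails
        b = np.array([5.0, 6, 7, 8, 9, 10])
        assert compare_groups(a, b).test_used == "rank_sum"

    def test_small_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestComparisonTable:
    def test_inconsistent_adjustment_rejected(self):
        with pytest.raises(ValidationError):
            ComparisonTable(
                comparison="x", test_used="t_test", raw_p=0.01,
                adjusted_p=0.5, n_comparisons=3, significant=False,
            )

    def test_build_caps_at_one(self):
        t = ComparisonTable.build("x", "t_test", 0.9, 5)
        assert t.adjusted_p == 1.0 and not t.significant

    def test_donor_order_invariance_of_pipeline(self):
        rng = np.random.default_rng(4)
        a = rng.normal(25, 2, 6)
        b = rng.normal(18, 2, 6)
        t1 = compare_groups(a, b)
        t2 = compare_groups(a[::-1], b[::-1])
        assert t1.raw_p == pytest.approx(t2.raw_p, abs=1e-14)
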