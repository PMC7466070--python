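from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermaquant.errors import ValidationError
from dermaquant.stats import (
    RegionAnnotation,
    abnormal_fraction,
    classify_xenograft,
    cohort_compare,
    make_cohort_table,
    mann_whitney_u,
)


def brute_force_mwu_p(a, b):
    """Two-sided exact p by full enumeration of group labelings (oracle)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    ranks = pooled.argsort().argsort() + 1  # valid for tie-free data

    def ustat(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    obs = min(ustat(range(n1)), n1 * n2 - ustat(range(n1)))
    cnt = tot = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ustat(idx)
        tot += 1
        if min(u, n1 * n2 - u) <= obs:
            cnt += 1
    return cnt / tot


def ann(intervals, length=1000.0):
    return RegionAnnotation(section_id="s", section_length_um=length, intervals=intervals)


class TestAbnormalFraction:
    def test_single_interval(self):
        assert abnormal_fraction(ann([(0.0, 30.0, "abnormal")])) == pytest.approx(3.0)

    def test_overlap_merged(self):
        a = ann([(0.0, 60.0, "abnormal"), (40.0, 100.0, "abnormal")])
        assert abnormal_fraction(a) == pytest.approx(10.0)

    def test_no_abnormal_zero(self):
        assert abnormal_fraction(ann([(0.0, 500.0, "normal")])) == 0.0

    def test_interval_outside_length_rejected(self):
        with pytest.raises(ValidationError, match="intervals"):
            ann([(900.0, 1100.0, "abnormal")])

    @given(st.lists(st.tuples(st.floats(0, 990), st.floats(1, 10)), min_size=1, max_size=8))
    @settings(deadline=None, max_examples=50)
    def test_invariant_under_reordering_and_splitting(self, raw):
        intervals = [(a, min(a + w, 1000.0), "abnormal") for a, w in raw if w > 0 and a < 1000.0]
        if not intervals:
            return
        base = abnormal_fraction(ann(intervals))
        assert abnormal_fraction(ann(intervals[::-1])) == pytest.approx(base)
        split = []
        for a, b, lab in intervals:
            mid = (a + b) / 2
            split += [(a, mid, lab), (mid, b, lab)] if mid > a and b > mid else [(a, b, lab)]
        assert abnormal_fraction(ann(split)) == pytest.approx(base)
        assert 0.0 <= base <= 100.0


class TestClassifyXenograft:
    def test_boundary_counts_as_above(self):
        above, value = classify_xenograft([12.0] * 6)
        assert above and value == 12.0

    def test_all_zero_below(self):
        above, _ = classify_xenograft([0.0] * 6)
        assert not above

    def test_single_extreme_section_pushes_mean_above(self):
        above, value = classify_xenograft([0, 0, 0, 0, 0, 93.0])
        assert above and value == pytest.approx(15.5)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            classify_xenograft([])

    def test_max_summary_option(self):
        above, value = classify_xenograft([0, 0, 20.0], summary="max")
        assert above and value == 20.0


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.p_two_sided == pytest.approx(0.1)
        assert res.method == "exact"

    def test_sample_against_itself_p_one(self):
        res = mann_whitney_u([1.0, 2.0, 5.0, 9.0], [1.0, 2.0, 5.0, 9.0])
        assert res.p_two_sided == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_constant_samples(self):
        res = mann_whitney_u([3.0, 3.0], [3.0, 3.0])
        assert res.degenerate and res.p_two_sided == 1.0

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for n1 in (2, 3, 5):
            for n2 in (2, 4, 6):
                a = rng.normal(size=n1)
                b = rng.normal(size=n2) + rng.normal()
                res = mann_whitney_u(a, b)
                assert res.method == "exact"
                assert res.p_two_sided == pytest.approx(brute_force_mwu_p(a, b), abs=1e-12)

    def test_exact_close_to_normal_approximation_at_n8(self):
        rng = np.random.default_rng(8)
        from scipy.stats import mannwhitneyu

        for _ in range(10):
            a = rng.normal(size=8)
            b = rng.normal(size=8) + 0.5
            exact = mannwhitneyu(a, b, method="exact").pvalue
            approx = mannwhitneyu(a, b, method="asymptotic", use_continuity=True).pvalue
            assert abs(exact - approx) <= 0.02

    @given(
        st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=10),
        st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=10),
    )
    @settings(deadline=None, max_examples=50)
    def test_complement_identity(self, a, b):
        u_ab = mann_whitney_u(a, b).u_statistic
        u_ba = mann_whitney_u(b, a).u_statistic
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))
        assert 0 <= u_ab <= len(a) * len(b)


class TestCohortCompare:
    def _table(self):
        rows = []
        for i in range(6):
            rows.append(dict(cohort="ctl", xenograft_id=f"c{i}", section_id="s1", metric="coh", value=1.0 + 0.1 * i))
            rows.append(dict(cohort="irr", xenograft_id=f"i{i}", section_id="s1", metric="coh", value=5.0 + 0.1 * i))
        return make_cohort_table(rows)

    def test_separated_cohorts_significant(self):
        cmp = cohort_compare(self._table(), "coh", "ctl", "irr")
        assert cmp.test.p_two_sided < 0.01
        assert cmp.median_a < cmp.median_b
        assert cmp.test.stars in ("**", "***", "****")
        assert "Mann-Whitney" in cmp.summary()

    def test_missing_metric_named_in_error(self):
        with pytest.raises(ValidationError, match="nope"):
            cohort_compare(self._table(), "nope", "ctl", "irr")

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            cohort_compare(self._table(), "coh", "ctl", "missing_cohort")

    def test_duplicate_rows_rejected(self):
        rows = [dict(cohort="a", xenograft_id="x", section_id="s", metric="m", value=1.0)] * 2
        with pytest.raises(ValidationError):
            make_cohort_table(rows)

    def test_per_xenograft_aggregation(self):
        rows = []
        for i in range(4):
            for s in range(3):
                rows.append(dict(cohort="ctl", xenograft_id=f"c{i}", section_id=f"s{s}", metric="m", value=float(i)))
                rows.append(dict(cohort="irr", xenograft_id=f"i{i}", section_id=f"s{s}", metric="m", value=10.0 + i))
        cmp = cohort_compare(make_cohort_table(rows), "m", "ctl", "irr", aggregate_per_xenograft=True)
        assert cmp.test.n1 == 4 and cmp.test.n2 == 4
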