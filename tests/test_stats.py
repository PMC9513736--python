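import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats as sps

from ccrings import (
    IccResult,
    PairedCohortTable,
    cohort_summary,
    friedman_compare,
    friedman_statistic,
    icc_two_way,
    shapiro_normality,
)
from ccrings.stats import holm_adjust


class TestShapiro:
    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            shapiro_normality([2.0] * 10)

    def test_size_contract(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="n="):
            shapiro_normality(rng.normal(size=5001))
        with pytest.raises(ValueError, match="n="):
            shapiro_normality([1.0, 2.0])

    def test_skewed_sample_flagged_non_normal(self):
        rng = np.random.default_rng(21)
        sample = rng.lognormal(mean=0.0, sigma=1.0, size=30)
        w, p = shapiro_normality(sample)
        w_ref, p_ref = sps.shapiro(sample)  # reference routine, same sample
        assert (w, p) == (pytest.approx(w_ref), pytest.approx(p_ref))
        assert p < 0.05


class TestFriedman:
    def test_all_tied_rows_give_null_result(self):
        vals = np.tile([3.0, 3.0], (10, 1))
        chi2, df, p = friedman_statistic(vals)
        assert (chi2, df, p) == (0.0, 1, 1.0)

    def test_strict_ordering_3x3_closed_form(self):
        # every eye ranks visit1 < visit2 < visit3 -> chi2 = 12n/(k(k+1)) * sum
        # of squared deviations of mean ranks = 6.0 at n = 3, k = 3
        vals = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [0.1, 0.5, 0.9]])
        chi2, df, p = friedman_statistic(vals)
        assert chi2 == pytest.approx(6.0)
        assert df == 2
        assert p == pytest.approx(float(sps.chi2.sf(6.0, 2)))

    def test_matches_scipy_for_three_visits(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(12, 3))
        chi2, _, p = friedman_statistic(vals)
        ref = sps.friedmanchisquare(*vals.T)
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    @pytest.mark.parametrize("seed", range(6))
    def test_tie_correction_matches_naive_oracle_on_5x2_tables(self, naive_friedman, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 4, size=(5, 2)).astype(float)  # heavy ties
        if np.all(vals[:, 0] == vals[:, 1]):
            vals[0, 0] += 1.0
        chi2, _, _ = friedman_statistic(vals)
        assert chi2 == pytest.approx(naive_friedman(vals), abs=1e-12)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        hnp.arrays(
            np.float64, (8, 3),
            elements=st.integers(min_value=-5, max_value=5).map(float),
        )
    )
    def test_invariant_under_monotone_transforms(self, vals):
        """The statistic is rank-based: applying a strictly increasing
        transform to every value leaves chi-square unchanged."""
        chi2, _, _ = friedman_statistic(vals)
        chi2_t, _, _ = friedman_statistic(np.exp(vals / 5.0) + 3.0)
        assert chi2_t == pytest.approx(chi2, abs=1e-10)

    def test_rank_invariance_to_row_shifts(self):
        rng = np.random.default_rng(17)
        vals = rng.normal(size=(15, 2))
        chi2, _, _ = friedman_statistic(vals)
        shifted = vals.copy()
        shifted[4] += 100.0  # constant added to one eye's values
        chi2_s, _, _ = friedman_statistic(shifted)
        assert chi2_s == pytest.approx(chi2)

    def test_compare_attaches_visit_moments(self):
        vals = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        res = friedman_compare(PairedCohortTable(vals, "FD%", 1))
        assert res.mean_t1 == pytest.approx(2.0)
        assert res.mean_t2 == pytest.approx(4.0)
        assert res.n_used == 3
        assert res.df == 1
        assert res.p_value < 0.1  # all eyes increase

    def test_flagged_rows_dropped_pairwise(self):
        vals = np.array([[1.0, 2.0], [np.nan, 4.0], [3.0, 5.0]])
        table = PairedCohortTable(vals, "FD%", 2)
        assert table.n_eyes == 2


class TestIcc:
    def test_identical_graders_give_exact_one(self):
        x = np.arange(10.0)
        res = icc_two_way(x, x)
        assert res.icc == 1.0

    def test_uncorrelated_permutation_near_zero(self):
        rng = np.random.default_rng(33)
        a = rng.normal(size=50)
        b = rng.permutation(a)
        res = icc_two_way(a, b)
        assert abs(res.icc) < 0.3

    def test_variance_components_recovered(self):
        rng = np.random.default_rng(11)
        n = 200
        subj = rng.normal(0, 3.0, size=n)  # sigma_s^2 = 9
        a = subj + rng.normal(0, 1.0, size=n)
        b = subj + rng.normal(0, 1.0, size=n)
        res = icc_two_way(a, b)
        assert res.icc == pytest.approx(0.9, abs=0.05)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_matches_pingouin_icc3(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(2)
        subj = rng.normal(0, 2.0, size=40)
        a = subj + rng.normal(0, 0.8, size=40)
        b = subj + rng.normal(0, 0.8, size=40)
        res = icc_two_way(a, b)
        df = pd.DataFrame(
            {
                "targets": np.tile(np.arange(40), 2),
                "raters": np.repeat(["A", "B"], 40),
                "ratings": np.concatenate([a, b]),
            }
        )
        ref = pingouin.intraclass_corr(df, "targets", "raters", "ratings")
        row = ref[ref["Type"].isin(["ICC3", "ICC(C,1)"])].iloc[0]
        ci = np.asarray(row[[c for c in ref.columns if c.startswith("CI95")][0]], dtype=float)
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        assert res.ci_low == pytest.approx(ci[0], abs=0.02)  # pingouin rounds its CI
        assert res.ci_high == pytest.approx(ci[1], abs=0.02)

    def test_bounds_and_degenerate_cases(self):
        with pytest.raises(ValueError, match="5 subjects"):
            icc_two_way([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="between-subject"):
            icc_two_way([1.0] * 10, [1.0] * 10)
        rng = np.random.default_rng(4)
        for _ in range(10):
            a, b = rng.normal(size=(2, 20))
            assert icc_two_way(a, b).icc <= 1.0


class TestHolm:
    def test_adjustment_monotone_and_bounded(self):
        p = [0.01, 0.04, 0.03, 0.5]
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)
        assert adj[0] == pytest.approx(0.04)


class _FakeRing:
    def __init__(self, ring, fd, fda, n):
        self.ring, self.fd_percent, self.fd_avg_area_um2 = ring, fd, fda
        self.fd_count, self.denominator_px, self.flagged = n, 1000, False


class _FakeMetrics:
    def __init__(self, fd_by_ring, mnv=0.3, dh=2.0):
        self.rings = tuple(
            _FakeRing(k + 1, fd, fd * 10, int(fd)) for k, fd in enumerate(fd_by_ring)
        )
        self.mnv_area_mm2, self.dh_area_mm2 = mnv, dh

    def metric_array(self, name):
        return np.array([getattr(r, name) for r in self.rings], dtype=float)


class TestCohortSummary:
    def test_identical_eyes_and_visits(self):
        m = _FakeMetrics([50, 49, 48, 47, 46])
        per_eye = {"e1": {"t1": m, "t2": m}, "e2": {"t1": m, "t2": m}}
        tables = cohort_summary(per_eye)
        fd = tables["fd_percent"]
        assert np.all(fd["sd_t1"] == 0)
        assert np.all(fd["p_value"] == 1.0)
        assert set(tables) == {"fd_percent", "fd_avg_area_um2", "fd_count", "lesion_areas"}

    def test_single_eye_rejected(self):
        m = _FakeMetrics([50] * 5)
        with pytest.raises(ValueError, match=">= 2"):
            cohort_summary({"e1": {"t1": m, "t2": m}})

    def test_holm_column_optional(self):
        rng = np.random.default_rng(6)
        per_eye = {
            f"e{i}": {
                "t1": _FakeMetrics(50 + rng.normal(0, 2, 5)),
                "t2": _FakeMetrics(47 + rng.normal(0, 2, 5)),
            }
            for i in range(8)
        }
        assert "p_holm" not in cohort_summary(per_eye)["fd_percent"]
        assert "p_holm" in cohort_summary(per_eye, holm=True)["fd_percent"]
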