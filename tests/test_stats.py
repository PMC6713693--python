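"""Statistics suite: ICC, exact Wilcoxon, baseline comparisons, OLS, HOMA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fatkinetics.stats import (
    P_FLOOR,
    comparisons_vs_baseline,
    compare_decay_constants,
    delta_from_baseline,
    homa_ir,
    icc_oneway,
    ols_simple,
    percent_decline,
    wilcoxon_signed_rank,
)


class TestICC:
    def test_perfect_replicate_agreement(self):
        table = [[1.0, 1.0], [3.0, 3.0], [5.0, 5.0]]
        assert icc_oneway(table).icc == pytest.approx(1.0)

    def test_hand_variance_components(self):
        # MSB = 8, MSW = 0.5 -> ICC = 7.5/8.5 (hand computation)
        res = icc_oneway([[1, 2], [3, 4], [5, 6]])
        assert res.msb == pytest.approx(8.0)
        assert res.msw == pytest.approx(0.5)
        assert res.icc == pytest.approx(7.5 / 8.5)

    def test_zero_between_subject_variance_hits_lower_bound(self):
        res = icc_oneway([[1, 2], [2, 1], [1, 2]])
        assert res.msb == pytest.approx(0.0)
        assert res.icc == pytest.approx(-1.0)  # = -1/(k-1) with k = 2

    @given(
        st.integers(2, 8),
        st.integers(2, 5),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_closed_form_on_random_tables(self, n, k, seed):
        x = np.random.default_rng(seed).normal(size=(n, k))
        res = icc_oneway(x)
        # independent closed form via explicit ANOVA sums of squares
        grand = x.mean()
        ssb = k * sum((row.mean() - grand) ** 2 for row in x)
        ssw = sum((v - row.mean()) ** 2 for row in x for v in row)
        msb, msw = ssb / (n - 1), ssw / (n * (k - 1))
        expected = (msb - msw) / (msb + (k - 1) * msw)
        assert res.icc == pytest.approx(expected, rel=1e-10)
        assert -1.0 / (k - 1) - 1e-12 <= res.icc <= 1.0 + 1e-12

    def test_matches_pingouin_icc1(self):
        rng = np.random.default_rng(9)
        x = rng.normal(scale=1, size=(16, 3)) + rng.normal(
            loc=10, scale=3, size=(16, 1)
        )
        long = pd.DataFrame(
            [
                {"subject": i, "rater": j, "score": x[i, j]}
                for i in range(16)
                for j in range(3)
            ]
        )
        pg = pytest.importorskip("pingouin")
        icc1 = pg.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type").loc["ICC(1,1)", "ICC"]
        assert icc_oneway(x).icc == pytest.approx(icc1, abs=1e-6)

    @pytest.mark.parametrize(
        "table", [[[1.0, 2.0]], [[1.0], [2.0]], [[1.0, np.nan], [2.0, 3.0]]]
    )
    def test_invalid_tables_rejected(self, table):
        with pytest.raises(ValueError):
            icc_oneway(table)


def _enumerated_two_sided_p(d):
    """Oracle: full 2^n enumeration of sign assignments on the midranks."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product([0, 1], repeat=n)]
    )
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(1.0, p)


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == 1.0
        assert res.w == 0.0
        assert res.method == "degenerate"

    def test_five_positive_differences(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.w == 15.0
        assert res.p == pytest.approx(2 / 32)
        assert res.method == "exact"

    def test_sixteen_same_sign_differences(self):
        res = wilcoxon_signed_rank(np.arange(1.0, 17.0))
        assert res.p == pytest.approx(2 / 65536)

    def test_exact_equals_enumeration_on_random_cases(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            n = rng.integers(2, 13)
            d = rng.normal(size=n)
            res = wilcoxon_signed_rank(d)
            assert res.method == "exact"
            assert res.p == pytest.approx(_enumerated_two_sided_p(d), rel=1e-12)

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(5, 19)
            d = rng.normal(size=n)
            res = wilcoxon_signed_rank(d)
            ref = sps.wilcoxon(d, mode="exact")
            assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_ties_fall_back_to_corrected_normal_approximation(self):
        d = np.array([1.0, 1.0, 2.0, 2.0, 3.0, -1.0, 4.0, 5.0])
        res = wilcoxon_signed_rank(d)
        assert res.method == "approximate"
        ref = sps.wilcoxon(d, mode="approx", correction=True)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_antisymmetry_in_pair_order(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=12), rng.normal(size=12)
        assert wilcoxon_signed_rank(x, y).p == pytest.approx(
            wilcoxon_signed_rank(y, x).p
        )

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0, 3.0])
        assert res.n_nonzero == 3


class TestCompareDecayConstants:
    def test_identical_columns_give_p_one(self):
        t = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [1.0, 2.0]})
        res = compare_decay_constants(t)
        assert len(res) == 3
        assert (res["p"] == 1.0).all()

    def test_six_pairs_for_four_compartments(self):
        rng = np.random.default_rng(13)
        t = pd.DataFrame(rng.normal(size=(16, 4)), columns=list("abcd"))
        res = compare_decay_constants(t)
        assert len(res) == 6
        assert not res["low_power"].any()

    def test_low_power_flag_under_six_pairs(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 3, 4, 5, 7]})
        assert compare_decay_constants(t)["low_power"].all()


class TestComparisonsVsBaseline:
    @staticmethod
    def _cohort(deltas):
        rows = []
        rng = np.random.default_rng(14)
        base = 5.3 + 0.2 * rng.standard_normal(10)
        for i, b in enumerate(base):
            rows.append({"subject_id": i, "visit_index": 0, "time": 0.0, "glucose": b})
            for m, d in deltas.items():
                rows.append(
                    {"subject_id": i, "visit_index": m, "time": float(m), "glucose": b + d}
                )
        return pd.DataFrame(rows)

    def test_identical_values_give_adjusted_p_one(self):
        res = comparisons_vs_baseline(self._cohort({3: 0.0}), "glucose")
        assert res["p_adjusted"].iloc[0] == 1.0

    def test_fixed_shift_matches_paired_t_oracle_times_family(self):
        df = self._cohort({3: -0.6, 6: -0.7, 12: -0.6})
        # add per-subject jitter so the t-test is non-degenerate
        rng = np.random.default_rng(15)
        follow = df["time"] > 0
        df.loc[follow, "glucose"] += 0.1 * rng.standard_normal(follow.sum())
        res = comparisons_vs_baseline(df, "glucose")
        assert (res["family"] == 3).all()
        for _, r in res.iterrows():
            m = r["time"]
            b = df[df["time"] == 0].set_index("subject_id")["glucose"]
            f = df[df["time"] == m].set_index("subject_id")["glucose"]
            p_ref = sps.ttest_rel(f[b.index], b).pvalue
            assert r["p_raw"] == pytest.approx(p_ref, rel=1e-10)
            assert r["p_adjusted"] == pytest.approx(min(1.0, 3 * p_ref), rel=1e-10)

    def test_bonferroni_cap_at_one(self):
        df = self._cohort({3: 0.0, 6: 0.0, 12: 0.0, 24: 0.0})
        rng = np.random.default_rng(16)
        follow = df["time"] > 0
        df.loc[follow, "glucose"] += 0.3 * rng.standard_normal(follow.sum())
        res = comparisons_vs_baseline(df, "glucose", family=4)
        assert (res["p_adjusted"] <= 1.0).all()
        assert (res["p_adjusted"] >= res["p_raw"]).all()


class TestOLS:
    def test_perfect_fit_reports_zero_se_and_floor_p(self):
        x = np.arange(5.0)
        res = ols_simple(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.se == pytest.approx(0.0, abs=1e-14)
        assert res.p == P_FLOOR

    def test_hand_computed_example(self):
        res = ols_simple([0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.intercept == pytest.approx(1.0 / 3.0)

    def test_slope_invariant_to_x_translation(self):
        rng = np.random.default_rng(17)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert ols_simple(x, y).slope == pytest.approx(
            ols_simple(x + 100.0, y).slope, rel=1e-9
        )

    def test_matches_normal_equations_and_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(18)
        x = rng.normal(size=30)
        y = 0.3 * x + rng.normal(size=30)
        res = ols_simple(x, y)
        # normal-equation closed form with residual-variance SE
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (len(x) - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.slope == pytest.approx(beta[1], abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)
        fit = sm.OLS(y, X).fit()
        assert res.p == pytest.approx(fit.pvalues[1], rel=1e-8)

    @pytest.mark.parametrize(
        "x,y", [([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]), ([1.0, 2.0], [1.0, 2.0])]
    )
    def test_invalid_inputs_rejected(self, x, y):
        with pytest.raises(ValueError):
            ols_simple(x, y)

    def test_type_i_error_calibration_under_null(self):
        rng = np.random.default_rng(19)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(size=16)
            y = rng.normal(size=16)
            if ols_simple(x, y).p < 0.05:
                rejections += 1
        assert 0.035 <= rejections / reps <= 0.065


class TestDeltaFromBaseline:
    def test_follow_up_equal_to_baseline_gives_zero(self, cohort_df):
        df = cohort_df.copy()
        base = df[df["time"] == 0].groupby("subject_id")["tlv"].mean()
        df.loc[df["time"] == 3, "tlv"] = df.loc[df["time"] == 3, "subject_id"].map(base)
        out = delta_from_baseline(df, "tlv")
        np.testing.assert_allclose(out[out["time"] == 3]["delta"], 0.0, atol=1e-12)

    def test_printed_cohort_means_give_minus_seven(self):
        # 33.6 - 40.6 = -7.0 (difference of printed 3-month and baseline means)
        df = pd.DataFrame(
            {
                "subject_id": ["cohort", "cohort"],
                "visit_index": [0, 1],
                "time": [0.0, 3.0],
                "bmi": [40.6, 33.6],
            }
        )
        out = delta_from_baseline(df, "bmi")
        assert out["delta"].iloc[0] == pytest.approx(-7.0)

    def test_affine_equivariance(self, cohort_df):
        out = delta_from_baseline(cohort_df, "vat")
        scaled = cohort_df.copy()
        scaled["vat"] = 3.0 * scaled["vat"] + 2.0
        out_scaled = delta_from_baseline(scaled, "vat")
        np.testing.assert_allclose(out_scaled["delta"], 3.0 * out["delta"], rtol=1e-10)

    def test_mri_baseline_is_triplicate_mean(self, cohort_df):
        out = delta_from_baseline(cohort_df, "lf_percent")
        sid = out["subject_id"].iloc[0]
        trip = cohort_df[(cohort_df["subject_id"] == sid) & (cohort_df["time"] == 0)]
        assert out[out["subject_id"] == sid]["baseline"].iloc[0] == pytest.approx(
            trip["lf_percent"].mean()
        )

    def test_blood_baseline_is_single_preoperative_value(self, cohort_df):
        out = delta_from_baseline(cohort_df, "insulin")
        sid = out["subject_id"].iloc[0]
        first = cohort_df[
            (cohort_df["subject_id"] == sid) & (cohort_df["visit_index"] == 0)
        ]["insulin"].iloc[0]
        assert out[out["subject_id"] == sid]["baseline"].iloc[0] == pytest.approx(first)


class TestHomaAndDecline:
    def test_printed_homa_values(self):
        assert round(homa_ir(5.3, 7.3), 1) == 1.7
        assert round(homa_ir(4.7, 2.5), 1) == 0.5
        assert homa_ir(0.0, 11.0) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            homa_ir(-1.0, 5.0)

    def test_percent_decline_basics(self):
        assert percent_decline(10.0, 10.0) == 0.0
        assert percent_decline(10.0, 5.0) == 50.0
        with pytest.raises(ValueError):
            percent_decline(0.0, 1.0)

    def test_mean_of_ratios_differs_from_ratio_of_means(self):
        # subjects (10 -> 2) and (20 -> 16): mean of per-subject declines is
        # (80 + 20)/2 = 50, while the decline of the means is 40
        per_subject = percent_decline(np.array([10.0, 20.0]), np.array([2.0, 16.0]))
        assert np.mean(per_subject) == pytest.approx(50.0)
        assert percent_decline(15.0, 9.0) == pytest.approx(40.0)
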