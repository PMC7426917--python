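"""Model-free indices, relevance filter, and the classical test battery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from paytoknow.errors import PayToKnowError, ZeroVarianceError
from paytoknow.stats import (
    cohens_d_dependent,
    knowing_indices,
    mixed_anova_2x2,
    one_sample_t,
    paired_t,
    pearson_r,
    self_relevance_filter,
    yates_chi2,
)


class TestYatesChi2:
    def test_printed_unknown_aversion_counts(self):
        # 35/36 vs 26/36 participants with positive unknown aversion
        res = yates_chi2([[35, 1], [26, 10]])
        assert res.statistic == pytest.approx(6.87, abs=0.005)
        assert res.p_value == pytest.approx(0.009, abs=0.0005)

    def test_balanced_table_is_zero(self):
        assert yates_chi2([[18, 18], [18, 18]]).statistic == 0.0

    def test_symmetric_under_row_and_column_exchange(self):
        t = np.array([[20, 5], [10, 15]])
        base = yates_chi2(t).statistic
        assert yates_chi2(t[::-1]).statistic == pytest.approx(base)
        assert yates_chi2(t[:, ::-1]).statistic == pytest.approx(base)
        assert yates_chi2(t.T).statistic == pytest.approx(base)

    @pytest.mark.parametrize("table", [
        [[20, 5], [10, 15]],
        [[35, 1], [26, 10]],
        [[7, 3], [2, 8]],
        [[50, 50], [60, 40]],
    ])
    def test_matches_scipy_continuity_corrected(self, table):
        ours = yates_chi2(table)
        stat, p, dof, _ = sps.chi2_contingency(np.asarray(table), correction=True)
        assert ours.statistic == pytest.approx(stat)
        assert ours.p_value == pytest.approx(p)
        assert ours.df == dof

    def test_uncorrected_option_matches_scipy(self):
        ours = yates_chi2([[35, 1], [26, 10]], correction=False)
        stat, p, _, _ = sps.chi2_contingency([[35, 1], [26, 10]], correction=False)
        assert ours.statistic == pytest.approx(stat)
        assert not ours.corrected

    def test_small_deviation_clamped_to_zero(self):
        # |O - E| = 0.5 in every cell: the corrected statistic clamps to 0
        assert yates_chi2([[10, 10], [9, 11]]).statistic == 0.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ZeroVarianceError):
            yates_chi2([[0, 0], [5, 5]])


class TestTTests:
    def test_cohens_d_from_difference_scores(self):
        rng = np.random.default_rng(0)
        b = rng.normal(0, 1, 40)
        d = rng.normal(0.1, 0.2, 40)
        a = b + d
        assert cohens_d_dependent(a, b) == pytest.approx(d.mean() / d.std(ddof=1))

    def test_identical_paired_vectors(self):
        x = np.arange(10.0)
        assert cohens_d_dependent(x, x) == 0.0
        with pytest.raises(ZeroVarianceError):
            paired_t(x, x)

    def test_one_sample_against_chance(self):
        x = np.array([0.6, 0.7, 0.55, 0.65, 0.6, 0.72])
        res = one_sample_t(x, popmean=0.5)
        ref = sps.ttest_1samp(x, 0.5)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)
        assert res.df == 5
        assert res.cohens_d == pytest.approx((x.mean() - 0.5) / x.std(ddof=1))

    def test_one_sample_false_positive_rate_calibrated(self):
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 10_000
        data = rng.normal(0, 1, size=(n_rep, 15))
        for row in data:
            hits += one_sample_t(row, 0.0).p_value < 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            one_sample_t(np.ones(5), 0.5)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_generator_coupling_recovered(self):
        from paytoknow.cohort import CohortConfig, _draw_population

        cfg = CohortConfig(n_subjects=500, cohort_seed=31)
        pop = _draw_population(cfg, np.random.default_rng(cfg.cohort_seed))
        r, p = pearson_r([s.bdi for s in pop], [s.beta_pos for s in pop])
        assert r == pytest.approx(-0.35, abs=0.1)
        assert p < 0.001


class TestRelevanceFilter:
    def test_all_equal_ratings_retain_everything(self, homogeneous_frame):
        res = self_relevance_filter(homogeneous_frame)
        assert not res.skipped
        assert len(res.records) == len(homogeneous_frame)
        assert (res.retention["n_retained"] == res.retention["n_total"]).all()

    def test_mean_split_enumeration(self, schedule):
        from paytoknow.cohort import simulate_subject
        from paytoknow.parameters import SubjectParameters
        from paytoknow.task import records_to_frame

        recs = simulate_subject(schedule, SubjectParameters(gamma=6), seed=0)
        df = records_to_frame(recs)
        # 63 positive-trait words rated 10, the rest -10: mean 0, keep the 63
        df["self_relevance"] = np.where(df["valence"] == "positive", 10, -10)
        res = self_relevance_filter(df)
        assert len(res.records) == 63
        assert (res.records["valence"] == "positive").all()

    def test_missing_ratings_skip_filter_with_flag(self, homogeneous_frame):
        df = homogeneous_frame.copy()
        df.loc[df.index[0], "self_relevance"] = np.nan
        res = self_relevance_filter(df)
        assert res.skipped and len(res.records) == len(df)


class TestKnowingIndices:
    def test_ratio_arithmetic(self, schedule):
        from paytoknow.cohort import simulate_subject
        from paytoknow.parameters import SubjectParameters
        from paytoknow.task import records_to_frame

        df = records_to_frame(simulate_subject(schedule, SubjectParameters(gamma=6), seed=2))
        df["choice"] = ["TK"] * 80 + ["NTK"] * 46
        out = knowing_indices(df)
        assert out["knowing_ratio"].item() == pytest.approx(80 / 126)
        assert out["n_trials"].item() == 126
        assert out["n_costly_trials"].item() == 72  # delta_m <= 0 levels: 4 x 18

    def test_all_ntk_gives_zero_ratios(self, homogeneous_frame):
        df = homogeneous_frame.copy()
        df["choice"] = "NTK"
        out = knowing_indices(df)
        assert (out["knowing_ratio"] == 0.0).all()
        assert (out["costly_knowing_ratio"] == 0.0).all()

    def test_costly_subset_is_nonpositive_delta_m(self, homogeneous_frame):
        out = knowing_indices(homogeneous_frame, by=["subject_id"])
        sub = homogeneous_frame[homogeneous_frame.subject_id == "s00"]
        costly = sub[sub.delta_m <= 0]
        expected = (costly["choice"] == "TK").mean()
        got = out.loc[out.subject_id == "s00", "costly_knowing_ratio"].item()
        assert got == pytest.approx(expected)

    def test_overall_ratio_is_weighted_mean_of_levels(self, homogeneous_frame):
        out = knowing_indices(homogeneous_frame, by=["subject_id"])
        per_level = knowing_indices(homogeneous_frame, by=["subject_id", "delta_m"])
        for sid, grp in per_level.groupby("subject_id"):
            weighted = (grp["knowing_ratio"] * grp["n_trials"]).sum() / grp["n_trials"].sum()
            assert out.loc[out.subject_id == sid, "knowing_ratio"].item() == pytest.approx(weighted)

    def test_empty_cell_is_missing_not_zero(self, homogeneous_frame):
        df = homogeneous_frame[homogeneous_frame.delta_m > 0]
        out = knowing_indices(df)
        assert out["costly_knowing_ratio"].isna().all()

    def test_no_records_rejected(self, homogeneous_frame):
        with pytest.raises(PayToKnowError):
            knowing_indices(homogeneous_frame.iloc[0:0])


def _mixed_2x2_oracle(df):
    """Balanced 2x2 mixed ANOVA identities: the within-factor effects reduce
    to t-tests on per-subject difference scores, the between effect to a
    t-test on per-subject means."""
    wide = df.pivot_table(index=["subject_id", "source"], columns="valence",
                          values="knowing_ratio").reset_index()
    d = wide["positive"] - wide["negative"]
    m = (wide["positive"] + wide["negative"]) / 2
    g = wide["source"]
    groups = sorted(g.unique())
    d1, d2 = d[g == groups[0]], d[g == groups[1]]
    m1, m2 = m[g == groups[0]], m[g == groups[1]]
    f_inter = sps.ttest_ind(d1, d2, equal_var=True).statistic ** 2
    f_between = sps.ttest_ind(m1, m2, equal_var=True).statistic ** 2
    # valence main effect: grand mean of d against 0 with the pooled SD
    nd = len(d)
    sp = math.sqrt(((d1 - d1.mean()) ** 2).sum() + ((d2 - d2.mean()) ** 2).sum())
    sp /= math.sqrt(nd - 2)
    f_val = d.mean() ** 2 * nd / sp**2  # t^2 of the grand mean difference score
    return f_between, f_val, f_inter


class TestMixedAnova:
    @staticmethod
    def _make(n_per_group, gap_social, gap_nonsocial, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for gi, (src, gap) in enumerate([("social", gap_social),
                                         ("nonsocial", gap_nonsocial)]):
            for i in range(n_per_group):
                base = rng.normal(0.6, 0.1)
                noise = rng.normal(0, 0.05, 2)
                rows.append({"subject_id": f"{src}{i}", "source": src,
                             "valence": "positive",
                             "knowing_ratio": base + gap / 2 + noise[0]})
                rows.append({"subject_id": f"{src}{i}", "source": src,
                             "valence": "negative",
                             "knowing_ratio": base - gap / 2 + noise[1]})
        return pd.DataFrame(rows)

    def test_matches_hand_computed_sums_of_squares(self):
        df = self._make(12, 0.12, 0.0, seed=5)
        out = mixed_anova_2x2(df).set_index("effect")
        f_between, f_val, f_inter = _mixed_2x2_oracle(df)
        assert out.loc["source", "F"] == pytest.approx(f_between, rel=1e-6)
        assert out.loc["valence", "F"] == pytest.approx(f_val, rel=1e-6)
        assert out.loc["Interaction", "F"] == pytest.approx(f_inter, rel=1e-6)

    def test_null_data_f_near_one_on_average(self):
        fs = []
        for seed in range(60):
            out = mixed_anova_2x2(self._make(10, 0.0, 0.0, seed=seed))
            fs.append(out.set_index("effect").loc["Interaction", "F"])
        assert 0.5 < np.mean(fs) < 1.7

    def test_built_in_interaction_detected_at_study_scale(self):
        hits = 0
        for seed in range(10):
            out = mixed_anova_2x2(self._make(36, 0.11, 0.0, seed=100 + seed))
            hits += out.set_index("effect").loc["Interaction", "p_value"] < 0.05
        assert hits >= 7

    def test_covariate_adjustment_runs(self):
        df = self._make(10, 0.1, 0.0, seed=3)
        df["bdi"] = df["subject_id"].map(
            {sid: i for i, sid in enumerate(df["subject_id"].unique())}).astype(float)
        out = mixed_anova_2x2(df, covariates=["bdi"])
        assert np.isfinite(out["F"]).all()

    def test_missing_cell_names_subject(self):
        df = self._make(5, 0.1, 0.0, seed=1).iloc[:-1]
        with pytest.raises(PayToKnowError, match="nonsocial4"):
            mixed_anova_2x2(df)

    def test_constant_response_rejected(self):
        df = self._make(5, 0.0, 0.0, seed=1)
        df["knowing_ratio"] = 0.5
        with pytest.raises(ZeroVarianceError):
            mixed_anova_2x2(df)
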