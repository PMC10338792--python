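"""Study pipeline: statistics dialects and end-to-end bookkeeping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eventdfa import (
    CohortDesign,
    StudyAnalysis,
    StudyConfig,
    build_summary_tables,
    generate_cohort,
    ols_regression,
    run_condition_analysis,
    wilcoxon_signed_rank,
)
from eventdfa.exceptions import (
    DegenerateTestError,
    InsufficientDataError,
    SingularFitError,
)
from eventdfa.study import records_frame


def exact_signed_rank_p(d):
    """Exhaustive two-sided signed-rank p for small n (enumeration oracle)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    mu = n * (n + 1) / 4
    stat_obs = abs(w_obs - mu)
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if abs(w - mu) >= stat_obs - 1e-12:
            count += 1
    return count / total


class TestWilcoxon:
    def test_antisymmetry(self):
        x = [1.0, 3.0, 2.5, 4.0, 6.0, 5.0]
        y = [2.0, 1.0, 3.0, 3.5, 4.0, 7.0]
        z1, p1 = wilcoxon_signed_rank(x, y)
        z2, p2 = wilcoxon_signed_rank(y, x)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_normal_approximation_close_to_exact_at_n6(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        d = np.array([2.0, 3.0, -1.0, 4.0, 5.0, 6.0])
        _, p = wilcoxon_signed_rank(y + d, y)
        assert p == pytest.approx(exact_signed_rank_p(d), abs=0.05)

    def test_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.2, 1.0, size=30)
        y = rng.normal(0.0, 1.0, size=30)
        z, p = wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, correction=False, method="approx")
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_sign_follows_rank_sum_direction(self):
        x = np.arange(1.0, 11.0) + 5.0
        y = np.arange(1.0, 11.0)
        z, p = wilcoxon_signed_rank(x, y)
        assert z > 0 and p < 0.01

    def test_identical_vectors_degenerate(self):
        v = [1.0, 2.0, 3.0, 4.0, 5.0]
        with pytest.raises(DegenerateTestError):
            wilcoxon_signed_rank(v, v)

    def test_too_few_nonzero_differences(self):
        with pytest.raises(DegenerateTestError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


class TestOLS:
    def test_perfect_fit_recovered_exactly(self):
        x = np.array([0.5, 0.7, 0.9, 1.1])
        y = 0.8 - 0.6 * x
        tab = ols_regression(x, y)
        est = tab.set_index("coefficient")["Estimate"]
        assert est["Intercept"] == pytest.approx(0.8, abs=1e-12)
        assert est["Slope"] == pytest.approx(-0.6, abs=1e-12)
        assert tab["adj_R2"].iloc[1] == pytest.approx(1.0, abs=1e-9)

    def test_matches_closed_form_normal_equations(self):
        x = np.array([0.6, 0.7, 0.85, 1.0])
        y = np.array([0.30, 0.22, 0.25, 0.10])
        tab = ols_regression(x, y)
        # independent closed-form oracle
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        s2 = np.sum(resid**2) / (len(x) - 2)
        se_slope = np.sqrt(s2 / sxx)
        est = tab.set_index("coefficient")
        assert est.loc["Slope", "Estimate"] == pytest.approx(slope, rel=1e-10)
        assert est.loc["Intercept", "Estimate"] == pytest.approx(
            intercept, rel=1e-10
        )
        assert est.loc["Slope", "SE"] == pytest.approx(se_slope, rel=1e-10)

    def test_constant_predictor_rejected(self):
        with pytest.raises(SingularFitError):
            ols_regression([1.0, 1.0, 1.0, 1.0], [0.1, 0.2, 0.3, 0.4])

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            ols_regression([1.0, 2.0], [0.1, 0.2])


@pytest.fixture(scope="module")
def small_cohort():
    design = CohortDesign(
        n_subjects=8, n_sessions=2, trials_per_condition=120
    )
    return generate_cohort(design, np.random.default_rng(21))


@pytest.fixture(scope="module")
def small_config():
    return StudyConfig(ensemble_size=10, min_trials=32)


class TestPipeline:
    def test_record_bookkeeping(self, small_cohort, small_config):
        records = run_condition_analysis(
            small_cohort, small_config, np.random.default_rng(0)
        )
        df = records_frame(records)
        # 8 subjects x 2 conditions x (2 sessions + appended)
        assert len(df) == 8 * 2 * 3
        assert set(df["timescale"]) == {"session", "appended"}
        assert (df["alpha_X_sd"] >= 0).all()
        assert df["commission_rate"].between(0, 1).all()

    def test_subject_with_all_trials_pruned_excluded(self, small_config):
        design = CohortDesign(n_subjects=2, n_sessions=1, trials_per_condition=80)
        table = generate_cohort(design, np.random.default_rng(3))
        # corrupt one subject/condition: all latencies out of range
        mask = (table["subject"] == "S01") & (table["condition"] == "low")
        table.loc[mask, "rt_ms"] = np.where(
            table.loc[mask, "responded"] == 1, 2000.0, np.nan
        )
        records = records_frame(
            run_condition_analysis(table, small_config, np.random.default_rng(0))
        )
        assert records[
            (records["subject"] == "S01") & (records["condition"] == "low")
        ].empty
        assert not records[
            (records["subject"] == "S01") & (records["condition"] == "high")
        ].empty

    def test_quantile_ordering(self, small_cohort, small_config):
        results = StudyAnalysis(small_cohort, small_config).fit(seed=1)
        m = results.tables.medians
        for cond in ("low", "high"):
            assert (m[f"{cond}_q25"] <= m[f"{cond}_median"] + 1e-12).all()
            assert (m[f"{cond}_median"] <= m[f"{cond}_q75"] + 1e-12).all()

    def test_pipeline_deterministic_under_seed(self, small_cohort, small_config):
        r1 = StudyAnalysis(small_cohort, small_config).fit(seed=7)
        r2 = StudyAnalysis(small_cohort, small_config).fit(seed=7)
        pd.testing.assert_frame_equal(r1.records, r2.records)
        pd.testing.assert_frame_equal(r1.tables.wilcoxon, r2.tables.wilcoxon)

    def test_session_pairing_modes(self, small_cohort, small_config):
        records = run_condition_analysis(
            small_cohort, small_config, np.random.default_rng(2)
        )
        subj = build_summary_tables(records, "subject")
        sess = build_summary_tables(records, "session")
        n_subj = subj.wilcoxon.query("timescale == 'sessions'")["n_pairs"].iloc[0]
        n_sess = sess.wilcoxon.query("timescale == 'sessions'")["n_pairs"].iloc[0]
        assert n_sess == 2 * n_subj  # subject-session pairs vs subject means

    def test_summary_and_save(self, small_cohort, small_config, tmp_path):
        results = StudyAnalysis(small_cohort, small_config).fit(seed=3)
        text = results.summary()
        assert "Wilcoxon" in text and "OLS" in text
        results.save(tmp_path)
        for name in ("records.csv", "medians.csv", "wilcoxon.csv",
                     "regressions.csv"):
            assert (tmp_path / name).exists()


class TestNullCalibration:
    def test_no_condition_effect_rarely_rejects(self):
        # cohorts with identical conditions: alpha_X Wilcoxon |Z| < 1.96
        # in >= 90% of simulated cohorts
        rejections = 0
        n_cohorts = 20
        for s in range(n_cohorts):
            rng = np.random.default_rng(300 + s)
            alpha_low = rng.normal(1.0, 0.02, size=12)
            alpha_high = alpha_low + rng.normal(0.0, 0.02, size=12)
            z, _ = wilcoxon_signed_rank(alpha_low, alpha_high)
            rejections += abs(z) >= 1.96
        assert rejections <= 2
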