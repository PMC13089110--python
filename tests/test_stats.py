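"""Statistical battery against brute-force and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import comet_bioage as cb
from comet_bioage.errors import EstimationError, InputError
from comet_bioage.stats import (_exact_rank_sum_pvalue, _normal_rank_sum_pvalue,
                                format_report)

from conftest import analyze_cohort


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = cb.pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 1e-12

    def test_four_point_closed_form(self):
        # independent hand oracle: r = Sxy / sqrt(Sxx Syy), p from t with 2 df
        x = np.array([1.0, 2.0, 4.0, 7.0])
        y = np.array([3.0, 1.0, 5.0, 4.0])
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        r_hand = sxy / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        t_hand = r_hand * np.sqrt(2 / (1 - r_hand**2))
        p_hand = 2 * sps.t.sf(abs(t_hand), 2)
        res = cb.pearson(x, y)
        assert res.r == pytest.approx(r_hand, abs=1e-12)
        assert res.p_value == pytest.approx(p_hand, abs=1e-12)

    def test_null_distribution_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = [cb.pearson(rng.normal(size=100), rng.normal(size=100)).p_value
              for _ in range(200)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(EstimationError):
            cb.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRankBiserial:
    def test_complete_dominance(self):
        assert cb.rank_biserial([1, 2], [3, 4]) == -1.0
        assert cb.rank_biserial([3, 4], [1, 2]) == 1.0

    def test_direct_pair_count(self):
        assert cb.rank_biserial([1, 3], [2, 4]) == pytest.approx(-0.5)

    def test_identical_groups_are_null(self):
        assert cb.rank_biserial([1, 2, 3], [1, 2, 3]) == 0.0

    @given(st.lists(st.integers(0, 20), min_size=1, max_size=8),
           st.lists(st.integers(0, 20), min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_dominance(self, a, b):
        brute = np.mean([np.sign(x - y) for x in a for y in b])
        assert cb.rank_biserial(a, b) == pytest.approx(brute, abs=1e-12)

    def test_u_statistic_identity_with_ties(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 5, 30).astype(float)
        b = rng.integers(0, 5, 40).astype(float)
        u = sps.mannwhitneyu(a, b, alternative="two-sided").statistic
        assert cb.rank_biserial(a, b) == pytest.approx(2 * u / (30 * 40) - 1, abs=1e-12)


class TestWilcoxonRankSum:
    def test_minimum_w_and_exact_one_sided_p(self):
        res = cb.wilcoxon_rank_sum([1, 2], [3, 4], alternative="less")
        assert res.W == 3.0  # minimum attainable rank sum
        assert res.p_value == pytest.approx(1 / 6)
        assert res.method == "exact"

    def test_identical_multisets_symmetric(self):
        res = cb.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.rank_biserial == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_w_in_attainable_range(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n_a, n_b = rng.integers(1, 15, 2)
            res = cb.wilcoxon_rank_sum(rng.normal(size=n_a), rng.normal(size=n_b))
            lo = n_a * (n_a + 1) / 2
            assert lo <= res.W <= lo + n_a * n_b

    @pytest.mark.parametrize("n_a,n_b,tol", [(3, 3, 0.04), (3, 5, 0.04),
                                             (4, 4, 0.04), (5, 6, 0.04),
                                             (6, 6, 0.02)])
    def test_exact_and_approximation_agree(self, n_a, n_b, tol):
        # exhaustive over every attainable rank sum; at 6-vs-6 the
        # continuity-corrected approximation is within 0.02 everywhere,
        # smaller splits are within the verified 0.04 worst case
        from itertools import combinations
        n = n_a + n_b
        ranks = np.arange(1.0, n + 1)
        for w in sorted({sum(c) for c in combinations(ranks, n_a)}):
            p_exact = _exact_rank_sum_pvalue(ranks, n_a, w, "two-sided")
            p_norm = _normal_rank_sum_pvalue(w, n_a, n_b, np.ones(n),
                                             "two-sided")
            assert abs(p_exact - p_norm) <= tol

    def test_exact_p_matches_scipy_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.permutation(20)[:5].astype(float)
            b = rng.permutation(50)[:6].astype(float) + 0.5
            res = cb.wilcoxon_rank_sum(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_tie_corrected_approximation_matches_scipy(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 6, 30).astype(float)
        b = rng.integers(0, 6, 35).astype(float)
        res = cb.wilcoxon_rank_sum(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            cb.wilcoxon_rank_sum([], [1.0])


class TestChiSquared:
    def test_exact_independence_is_zero(self):
        margins_r = np.array([10, 20, 30.0])
        margins_c = np.array([5, 15.0])
        table = np.outer(margins_r, margins_c) / margins_c.sum()
        stat, df, p = cb.chi_squared(table)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        stat, df, p = cb.chi_squared([[10, 20], [20, 10]])
        assert stat == pytest.approx(20 / 3, abs=1e-12)
        assert df == 1

    def test_uniform_3x3(self):
        stat, df, _ = cb.chi_squared(np.full((3, 3), 7.0))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 4

    def test_hand_formula_on_random_table(self):
        rng = np.random.default_rng(5)
        table = rng.integers(5, 40, (3, 4)).astype(float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        stat_hand = ((table - expected) ** 2 / expected).sum()
        stat, df, _ = cb.chi_squared(table)
        assert stat == pytest.approx(stat_hand, abs=1e-10)
        assert df == 6

    def test_zero_marginal_rejected(self):
        with pytest.raises(InputError):
            cb.chi_squared([[0, 0], [5, 10]])


class TestDescribeCohorts:
    def test_synthetic_cohort_matches_config(self, small_cohort):
        participants, _, amyloid, _ = small_cohort
        labels = cb.build_cohort_table(participants, amyloid)
        table = cb.describe_cohorts(participants, labels)
        assert table.loc["CU", "n"] == 60
        assert table.loc["symptomatic", "n"] == 80
        assert table.loc["CU", "age_mean"] == pytest.approx(75.3, abs=3.0)
        assert table.loc["symptomatic", "pct_female"] == pytest.approx(44.4, abs=15.0)
        assert table.loc["CU", "cdrsb_median"] == 0.0

    def test_single_subject_cohort_reports_na_sd(self):
        participants = pd.DataFrame({
            "id": ["a"], "age_at_mri": [70.0], "sex": ["female"],
            "education": [16], "icv": [1.4e6], "diagnosis": ["CU"],
            "scanner_field": ["3T"], "cdrsb": [0.0], "apoe4_count": [0],
        })
        labels = pd.DataFrame({"amyloid_status": ["negative"], "cohort": ["CU"],
                               "age_group": ["average"]},
                              index=pd.Index(["a"], name="participant_id"))
        table = cb.describe_cohorts(participants, labels)
        assert table.loc["CU", "n"] == 1
        assert np.isnan(table.loc["CU", "age_sd"])

    def test_empty_cohort_no_crash(self):
        participants = pd.DataFrame(columns=["id", "age_at_mri", "sex", "education",
                                             "icv", "diagnosis", "scanner_field"])
        labels = pd.DataFrame(columns=["amyloid_status", "cohort", "age_group"],
                              index=pd.Index([], name="participant_id"))
        table = cb.describe_cohorts(participants, labels)
        assert (table["n"] == 0).all()


class TestPrimaryAnalysis:
    def test_report_schema_and_null_cu(self):
        res = analyze_cohort(cb.SyntheticConfig(n_cu=120, n_mci=100, n_dementia=60,
                                                seed=23))
        report = cb.run_primary_analysis(res["comet"], res["bag"], res["labels"],
                                         res["participants"])
        analyses = set(report["analysis"])
        for name in ("comet_vs_bag_pearson", "comet_by_bio_age_group",
                     "comet_by_chron_age_group", "cu_mean_cortical_w",
                     "cu_mean_mtl_w", "cu_mean_comet"):
            assert name in analyses
        assert set(report["cohort"]) == {"symptomatic", "dementia", "CU"}
        cu_means = report.loc[report["analysis"].str.startswith("cu_mean"), "statistic"]
        assert (cu_means.abs() < 1e-10).all()
        # text rendering covers every row
        text = format_report(report)
        assert text.count("\n") >= len(report)

    def test_strong_coupling_detected_with_fixed_sign_convention(self):
        cfg = cb.SyntheticConfig(coupling_rho=0.6, seed=31)
        res = analyze_cohort(cfg)
        report = cb.run_primary_analysis(res["comet"], res["bag"], res["labels"],
                                         res["participants"])
        row = report.loc[(report["analysis"] == "comet_vs_bag_pearson")
                         & (report["cohort"] == "symptomatic")].iloc[0]
        assert row["statistic"] > 0.3
        assert row["p_value"] < 1e-4
        wil = report.loc[(report["analysis"] == "comet_by_bio_age_group")
                         & (report["cohort"] == "symptomatic")].iloc[0]
        # decelerated listed first: lower CoMeT there means negative effect size
        assert wil["group_a"] == "decelerated"
        assert wil["effect_size"] < 0

    def test_insufficient_groups_reported_not_crashed(self):
        res = analyze_cohort(cb.SyntheticConfig(n_cu=30, n_mci=4, n_dementia=0,
                                                seed=37))
        report = cb.run_primary_analysis(res["comet"], res["bag"], res["labels"],
                                         res["participants"])
        dem = report.loc[(report["cohort"] == "dementia")
                         & (report["analysis"] == "comet_by_bio_age_group")].iloc[0]
        assert "not computable" in dem["note"]
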