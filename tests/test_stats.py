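import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from echostruct.cohort import attach_derived, clinical_preset, simulate_cohort
from echostruct.stats import (
    chi_square_test,
    cuzick_trend,
    icc_reproducibility,
    kruskal_wallis,
    ols_standardized,
    pearson_r,
    run_clinical_analysis,
    standardize,
    tertile_assign,
    two_sample_t,
    write_analysis_bundle,
)


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_clear_separation(self):
        res = two_sample_t([1, 2, 3], [101, 102, 103])
        assert res.p_value < 0.001

    def test_zero_pooled_variance(self):
        with pytest.raises(ValueError, match="pooled variance"):
            two_sample_t([5, 5, 5], [5, 5, 5])

    def test_matches_permutation_oracle(self, rng):
        x = rng.standard_normal(8) + 0.8
        y = rng.standard_normal(8)
        res = two_sample_t(x, y)
        pooled = np.concatenate([x, y])
        obs = abs(res.statistic)
        b = 20_000
        count = 0
        for _ in range(b):
            perm = rng.permutation(pooled)
            t = two_sample_t(perm[:8], perm[8:]).statistic
            count += abs(t) >= obs - 1e-12
        perm_p = count / b
        assert abs(res.p_value - perm_p) < 0.02

    def test_matches_scipy_pooled(self, rng):
        x, y = rng.standard_normal(12), rng.standard_normal(15) + 0.3
        res = two_sample_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)


class TestChiSquare:
    def test_proportional_table(self):
        res = chi_square_test([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_diagonal_table_hand_value(self):
        # expected cells all 5 -> chi2 = 4 * (10-5)^2/5 = 20
        res = chi_square_test([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1

    def test_permutation_invariance(self):
        t = [[7, 3], [2, 9]]
        base = chi_square_test(t).statistic
        assert chi_square_test([[3, 7], [9, 2]]).statistic == pytest.approx(base)
        assert chi_square_test([[2, 9], [7, 3]]).statistic == pytest.approx(base)

    def test_empty_table(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [0, 0]])


class TestOlsStandardized:
    def test_perfect_fit_degenerate(self, rng):
        x = rng.standard_normal(30)
        with pytest.raises(ValueError, match="degenerate"):
            ols_standardized(2.0 * standardize(x), x)

    def test_null_coefficient(self, rng):
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        res = ols_standardized(y, x)
        assert abs(res.coefficient) < 3 * res.se

    def test_known_slope_recovery(self, rng):
        coefs, ses = [], []
        for _ in range(300):
            x = rng.standard_normal(60)
            y = 2.0 * standardize(x) + rng.standard_normal(60)
            res = ols_standardized(y, x)
            coefs.append(res.coefficient)
            ses.append(res.se)
        se_of_mean = np.std(coefs, ddof=1) / math.sqrt(len(coefs))
        assert abs(np.mean(coefs) - 2.0) < 3 * se_of_mean

    def test_affine_invariance_of_predictor(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50) + 0.5 * x
        a = ols_standardized(y, x)
        b = ols_standardized(y, 37.0 * x - 11.0)
        assert a.coefficient == pytest.approx(b.coefficient)
        assert a.se == pytest.approx(b.se)
        assert a.p_value == pytest.approx(b.p_value)

    def test_covariate_adjustment_changes_fit(self, rng):
        x = rng.standard_normal(80)
        c = x + rng.standard_normal(80)
        y = c + rng.standard_normal(80)
        unadj = ols_standardized(y, x)
        adj = ols_standardized(y, x, covariates=c[:, None])
        assert adj.coefficient != pytest.approx(unadj.coefficient)

    def test_collinear_design(self, rng):
        x = rng.standard_normal(40)
        with pytest.raises(ValueError, match="collinear"):
            ols_standardized(rng.standard_normal(40), x, covariates=x[:, None])

    def test_zero_variance_predictor(self):
        with pytest.raises(ValueError, match="variance"):
            ols_standardized([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0])

    def test_logistic_option(self, rng):
        x = rng.standard_normal(200)
        p = 1 / (1 + np.exp(-standardize(x)))
        y = (rng.random(200) < p).astype(float)
        res = ols_standardized(y, x, logistic=True)
        assert res.model == "logistic"
        assert res.coefficient > 0


class TestTertiles:
    def test_balanced_one_to_nine(self):
        groups = tertile_assign(np.arange(1, 10))
        assert np.bincount(groups)[1:].tolist() == [3, 3, 3]
        assert groups.min() == 1 and groups.max() == 3

    def test_all_equal_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            tertile_assign(np.full(9, 4.0))

    def test_ties_go_to_lower_tertile(self):
        groups = tertile_assign(np.array([1, 1, 1, 1, 2, 2, 3, 3, 3]))
        # cut values are 1 and 2: all the 1s stay in tertile 1
        assert (groups[:4] == 1).all()

    def test_unique_values_give_balanced_tertiles(self, rng):
        # without ties the nearest-rank cuts are exact: n divisible by 3
        # splits into equal thirds regardless of order
        for _ in range(20):
            values = rng.permutation(rng.standard_normal(60))
            sizes = np.bincount(tertile_assign(values), minlength=4)[1:]
            assert sizes.tolist() == [20, 20, 20]

    def test_tied_imbalance_counting_oracle(self, rng):
        # group sizes deviate from n/3 only through values tied with a cut
        for _ in range(50):
            values = rng.integers(0, 20, size=60).astype(float)
            groups = tertile_assign(values)
            sizes = np.bincount(groups, minlength=4)[1:]
            c1 = np.sort(values)[math.ceil(60 * 100 / 3.0 / 100) - 1]
            c2 = np.sort(values)[math.ceil(60 * 200 / 3.0 / 100) - 1]
            # independent counting oracle for each tertile size
            expect = [
                int((values <= c1).sum()),
                int(((values > c1) & (values <= c2)).sum()),
                int((values > c2).sum()),
            ]
            assert sizes.tolist() == expect
            n_tied = int((values == c1).sum() + (values == c2).sum())
            assert abs(expect[0] - 20) <= n_tied and abs(expect[2] - 20) <= n_tied


def exhaustive_cuzick_moments(values, groups):
    """Exact permutation mean/var of T = sum(score * midrank) by enumeration."""
    ranks = sps.rankdata(values)
    levels = np.unique(groups)
    scores = np.array([np.searchsorted(levels, g) + 1 for g in groups], dtype=float)
    ts = [float(np.sum(scores * np.asarray(perm))) for perm in itertools.permutations(ranks)]
    ts = np.asarray(ts)
    return ts.mean(), ts.var(ddof=0)


class TestCuzickTrend:
    def test_perfect_trend(self):
        values = np.arange(30, dtype=float)
        groups = np.repeat([1, 2, 3], 10)
        res = cuzick_trend(values, groups)
        assert res.statistic > 0
        assert res.p_value < 0.05

    def test_reversed_trend_negative_z(self):
        values = np.arange(30, dtype=float)[::-1]
        groups = np.repeat([1, 2, 3], 10)
        assert cuzick_trend(values, groups).statistic < 0

    def test_exact_permutation_moments_no_ties(self, rng):
        values = rng.standard_normal(8)
        groups = np.array([1, 1, 1, 2, 2, 3, 3, 3])
        res = cuzick_trend(values, groups)
        mu, var = exhaustive_cuzick_moments(values, groups)
        ranks = sps.rankdata(values)
        scores = np.array([g for g in groups], dtype=float)
        t_obs = float(np.sum(scores * ranks))
        z_oracle = (t_obs - mu) / math.sqrt(var)
        assert res.statistic == pytest.approx(z_oracle, abs=1e-10)

    def test_exact_permutation_moments_with_ties(self, rng):
        values = rng.integers(0, 4, size=8).astype(float)
        if np.ptp(values) == 0:
            values[0] += 1
        groups = np.array([1, 1, 2, 2, 2, 3, 3, 3])
        res = cuzick_trend(values, groups)
        mu, var = exhaustive_cuzick_moments(values, groups)
        ranks = sps.rankdata(values)
        t_obs = float(np.sum(groups.astype(float) * ranks))
        z_oracle = (t_obs - mu) / math.sqrt(var)
        assert res.statistic == pytest.approx(z_oracle, abs=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError, match="tied"):
            cuzick_trend(np.full(9, 2.0), np.repeat([1, 2, 3], 3))
        with pytest.raises(ValueError, match="2 ordered groups"):
            cuzick_trend(np.arange(5.0), np.ones(5))


def kruskal_oracle(groups):
    """Independent hand-rank arithmetic for the tie-corrected H statistic."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = pooled.size
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


class TestKruskalWallis:
    def test_identical_values(self):
        res = kruskal_wallis([3.0, 3.0], [3.0, 3.0], [3.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_fully_separated_3_4_3_hand_value(self):
        # complete separation of sizes (3, 4, 3): rank arithmetic gives
        # H = 12/110 * (3*3.5^2 + 0 + 3*3.5^2) = 8.018...
        g1 = np.array([1.0, 2.0, 3.0])
        g2 = np.array([10.0, 11.0, 12.0, 13.0])
        g3 = np.array([20.0, 21.0, 22.0])
        res = kruskal_wallis(g1, g2, g3)
        assert res.statistic == pytest.approx(8.018181818, abs=1e-8)
        assert res.statistic == pytest.approx(kruskal_oracle([g1, g2, g3]))

    def test_matches_hand_rank_oracle_with_ties(self, rng):
        for _ in range(30):
            groups = [
                rng.integers(0, 6, size=int(rng.integers(3, 8))).astype(float)
                for _ in range(3)
            ]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            res = kruskal_wallis(*groups)
            assert res.statistic == pytest.approx(kruskal_oracle(groups), abs=1e-9)

    def test_permutation_null_uniform_p(self, rng):
        # under within-pool reshuffles, p should be roughly uniform
        pool = rng.standard_normal(30)
        ps = []
        for _ in range(400):
            perm = rng.permutation(pool)
            ps.append(kruskal_wallis(perm[:10], perm[10:20], perm[20:]).p_value)
        assert 0.25 < np.mean(ps) < 0.75

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0, 3.0, 4.0, 5.0])


class TestPearson:
    def test_perfect_lines(self):
        x = np.arange(10.0)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_three_point_hand_value(self):
        # closed-form on (1,3.2), (2,8.1), (3,23.3)
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([3.2, 8.1, 23.3])
        sx = x - x.mean()
        sy = y - y.mean()
        expect = float(np.sum(sx * sy) / math.sqrt(np.sum(sx**2) * np.sum(sy**2)))
        assert pearson_r(x, y) == pytest.approx(expect)
        assert expect == pytest.approx(0.9589, abs=0.0005)

    def test_too_short(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [3, 4])


class TestIcc:
    def test_perfect_agreement(self, rng):
        col = rng.standard_normal(20)
        ratings = np.column_stack([col, col])
        assert icc_reproducibility(ratings).statistic == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        ratings = rng.standard_normal((200, 2))
        assert abs(icc_reproducibility(ratings).statistic) < 0.15

    def test_variance_components_recovery(self, rng):
        sigma_b, sigma_e = 1.0, 0.5
        target = sigma_b**2 / (sigma_b**2 + sigma_e**2)
        estimates = []
        for _ in range(100):
            subj = rng.normal(0, sigma_b, size=(100, 1))
            ratings = subj + rng.normal(0, sigma_e, size=(100, 3))
            estimates.append(icc_reproducibility(ratings).statistic)
        se = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(np.mean(estimates) - target) < 3 * se

    def test_matches_pingouin_icc2(self, rng):
        pg = pytest.importorskip("pingouin")
        ratings = rng.normal(0, 1, size=(15, 1)) + rng.normal(0, 0.7, size=(15, 3))
        mine = icc_reproducibility(ratings).statistic
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 3),
                "reader": np.tile(np.arange(3), 15),
                "score": ratings.ravel(),
            }
        )
        ref = pg.intraclass_corr(
            data=long, targets="subject", raters="reader", ratings="score"
        )
        # ICC(A,1) = two-way random, absolute agreement, single rating = ICC(2,1)
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert mine == pytest.approx(icc2, abs=1e-6)

    def test_missing_cells_rejected(self, rng):
        ratings = rng.standard_normal((10, 2))
        ratings[3, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            icc_reproducibility(ratings)

    def test_minimum_size(self, rng):
        with pytest.raises(ValueError):
            icc_reproducibility(rng.standard_normal((4, 2)))


@pytest.fixture(scope="module")
def cohort_table():
    return attach_derived(simulate_cohort(clinical_preset(seed=17)))


class TestClinicalAnalysisGrid:
    def test_panels_present(self, cohort_table):
        res = run_clinical_analysis(cohort_table)
        assert set(res) == {
            "group_comparison",
            "status_regression",
            "bp_regression",
            "tertile_trend",
        }
        assert {"unadjusted", "adjusted"} == set(res["status_regression"]["model"])
        assert set(res["tertile_trend"]["bp_measure"]) == {"sbp", "dbp", "map"}

    def test_missing_columns_reported(self, cohort_table):
        with pytest.raises(KeyError, match="group"):
            run_clinical_analysis(cohort_table.drop(columns=["group"]))

    def test_no_covariates_equals_unadjusted(self, cohort_table):
        res = run_clinical_analysis(cohort_table, covariates=())
        sr = res["status_regression"]
        un = sr[sr["model"] == "unadjusted"].reset_index(drop=True)
        ad = sr[sr["model"] == "adjusted"].reset_index(drop=True)
        assert np.allclose(un["coefficient"], ad["coefficient"])
        assert np.allclose(un["p"], ad["p"])

    def test_large_n_group_effect_pattern(self):
        # microstructure indices separate the groups much more strongly
        # than LV mass does (mirroring the published status-regression shape)
        params = clinical_preset(n_control=300, n_hypertensive=300, seed=23)
        table = attach_derived(simulate_cohort(params))
        res = run_clinical_analysis(table)
        sr = res["status_regression"]
        un = sr[sr["model"] == "unadjusted"].set_index("predictor")
        assert un.loc["sic", "p"] < 0.001
        assert un.loc["msi", "p"] < 0.001
        assert abs(un.loc["lv_mass", "coefficient"]) < abs(un.loc["sic", "coefficient"])

    def test_null_cohort_calibration(self):
        # identical group parameters -> significance fraction near alpha
        base = clinical_preset(seed=0)
        control = base.groups["control"]
        from echostruct.cohort import CohortParams, GroupParams

        ps = []
        for rep in range(40):
            params = CohortParams(
                groups={
                    "a": GroupParams(n=30, columns=control.columns, p_female=0.5),
                    "b": GroupParams(n=30, columns=control.columns, p_female=0.5),
                },
                seed=1000 + rep,
            )
            table = attach_derived(simulate_cohort(params))
            res = run_clinical_analysis(table)
            ps.extend(res["group_comparison"].query("variable != 'sex'")["p"].tolist())
        frac = float(np.mean(np.asarray(ps) < 0.05))
        assert frac < 0.12

    def test_bundle_writer(self, cohort_table, tmp_path):
        res = run_clinical_analysis(cohort_table)
        csv = tmp_path / "tidy.csv"
        js = tmp_path / "bundle.json"
        write_analysis_bundle(res, csv_path=csv, json_path=js)
        tidy = pd.read_csv(csv)
        assert set(tidy["panel"]) == set(res)
        import json

        payload = json.loads(js.read_text())
        assert set(payload) == set(res)
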