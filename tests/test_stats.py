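import numpy as np
import pandas as pd
import pytest

from bbhmap import (
    HemorrhageRiskModel,
    chi_squared,
    cohort_summary,
    kruskal_wallis,
    logistic_fit,
    pearson_r,
)

# 2x2 tables from a published 450-patient biopsy series (hemorrhage vs not,
# against one characteristic at a time), with their printed X^2 values
PRINTED_TABLES = {
    "basal_ganglia": ([[30, 50], [84, 286]], 7.61),
    "hgg": ([[47, 33], [167, 203]], 4.89),
    "lgg": ([[7, 73], [80, 290]], 6.99),
    "sex": ([[41, 39], [199, 171]], 0.17),
}


class TestChiSquared:
    @pytest.mark.parametrize("name", list(PRINTED_TABLES))
    def test_reproduces_printed_values(self, name):
        table, expected = PRINTED_TABLES[name]
        x2, df, p = chi_squared(np.array(table))
        assert round(x2, 2) == pytest.approx(expected, abs=0.005)
        assert df == 1

    def test_homogeneous_table_is_zero(self):
        x2, df, p = chi_squared(np.full((2, 2), 10))
        assert x2 == 0.0 and p == pytest.approx(1.0)

    def test_transpose_and_permutation_invariant(self, rng):
        t = rng.integers(1, 60, size=(3, 4))
        x2, df, _ = chi_squared(t)
        assert chi_squared(t.T)[0] == pytest.approx(x2)
        perm = t[rng.permutation(3)][:, rng.permutation(4)]
        assert chi_squared(perm)[0] == pytest.approx(x2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_squared(np.array([[0, 0], [5, 7]]))


class TestKruskalWallis:
    def test_matches_rank_formula(self):
        groups = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6])]
        h, p = kruskal_wallis(groups)
        # direct rank-sum formula, no ties: H = 12/(N(N+1)) sum n_i Rbar_i^2 - 3(N+1)
        ranks = {1: 1, 2: 2, 3: 3, 4: 4, 5: 5, 6: 6}
        r1, r2 = (1 + 2 + 3) / 3, (4 + 5 + 6) / 3
        expected = 12 / (6 * 7) * (3 * r1**2 + 3 * r2**2) - 3 * 7
        assert h == pytest.approx(expected, abs=1e-12)

    def test_identical_groups_zero(self):
        h, p = kruskal_wallis([[3.0, 3.0, 3.0], [3.0, 3.0]])
        assert (h, p) == (0.0, 1.0)

    @pytest.mark.parametrize("transform", [np.exp, lambda x: x**3, lambda x: 5 * x - 2])
    def test_invariant_under_monotone_transform(self, transform, rng):
        groups = [rng.normal(size=8), rng.normal(1.0, 1.0, size=6)]
        h0, _ = kruskal_wallis(groups)
        h1, _ = kruskal_wallis([transform(g) for g in groups])
        assert h1 == pytest.approx(h0, abs=1e-12)


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(5.0)
        assert pearson_r(x, x)[0] == pytest.approx(1.0)

    def test_perfect_negative_affine(self):
        x = np.arange(6.0)
        assert pearson_r(x, -2 * x + 3)[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        r, _ = pearson_r(x, y)
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r(np.ones(5), np.arange(5.0))


def logistic_grid_oracle(y, x):
    """Brute-force likelihood maximisation on a shrinking (b0, b1) grid."""
    def ll(b0, b1):
        eta = b0 + b1 * x
        return float(y @ eta - np.logaddexp(0, eta).sum())

    c0, c1, half = 0.0, 0.0, 8.0
    for _ in range(18):
        b0s = np.linspace(c0 - half, c0 + half, 21)
        b1s = np.linspace(c1 - half, c1 + half, 21)
        vals = np.array([[ll(a, b) for b in b1s] for a in b0s])
        i, j = np.unravel_index(vals.argmax(), vals.shape)
        c0, c1 = b0s[i], b1s[j]
        half *= 0.35
    return c0, c1, ll(c0, c1)


class TestLogistic:
    def test_eight_point_fit_matches_grid_search(self):
        x = np.array([-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0])
        y = np.array([0, 0, 1, 0, 1, 0, 1, 1])
        fit = logistic_fit(y, {"x": x})
        b0, b1, ll = logistic_grid_oracle(y, x)
        assert fit.intercept == pytest.approx(b0, abs=1e-3)
        assert fit.coefficients["x"] == pytest.approx(b1, abs=1e-3)
        assert fit.log_likelihood == pytest.approx(ll, abs=1e-3)

    def test_null_predictor_has_small_coefficient(self, rng):
        n = 20_000
        x = rng.random(n) < 0.5
        y = (rng.random(n) < 0.3).astype(int)
        fit = logistic_fit(y, {"x": x.astype(float)})
        assert abs(fit.coefficients["x"]) < 0.05
        assert fit.nagelkerke_r2 < 0.01

    def test_model_chi2_nonnegative_and_monotone_in_predictors(self, rng):
        n = 400
        x1 = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x1))).astype(int)
        f1 = logistic_fit(y, {"x1": x1})
        f2 = logistic_fit(y, {"x1": x1, "noise": rng.normal(size=n)})
        assert f1.model_chi2 >= 0
        assert f2.log_likelihood >= f1.log_likelihood - 1e-8
        assert 0 <= f1.nagelkerke_r2 <= 1

    def test_complete_separation_flagged(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = (x > 0).astype(int)
        with pytest.warns(UserWarning, match="separation"):
            fit = logistic_fit(y, {"x": x})
        assert not fit.converged

    def test_sklearn_estimator_wrapper(self, rng):
        n = 500
        X = pd.DataFrame({"a": rng.normal(size=n)})
        y = (rng.random(n) < 1 / (1 + np.exp(-X["a"]))).astype(int)
        model = HemorrhageRiskModel().fit(X, y)
        assert model.coef_.shape == (1,)
        proba = model.predict_proba(X)
        assert proba.shape == (n, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert model.get_params() == {"feature_names": None}


def _fixture_cohort():
    """Cohort table with the published marginal 2x2 counts for the deep
    (basal-ganglia) target row: 30/50 hemorrhage, 84/286 without."""
    rows = []
    def block(n, region, bbh):
        for _ in range(n):
            rows.append({
                "age": 60.0, "sex": "f", "system": "frame", "histology": "HGG",
                "target_region": region, "bbh": bbh,
                "bbh_volume_ml": 1.0 if bbh else 0.0,
                "bbh_location": "intralesional" if bbh else "none",
                "symptomatic": False, "sensorimotor_deficit": False,
                "aphasia": False, "reduced_vigilance": False,
                "revision": False, "persistent_deficit": False,
            })
    block(30, "basal_ganglia", True)
    block(50, "frontal", True)
    block(84, "basal_ganglia", False)
    block(286, "frontal", False)
    return pd.DataFrame(rows)


class TestCohortSummary:
    def test_bg_row_reproduces_printed_chi2(self):
        out = cohort_summary(_fixture_cohort())
        row = out["patients"].set_index("row").loc["target basal_ganglia"]
        assert round(row["statistic"], 2) == 7.61

    def test_zero_bbh_cohort_skips_comparisons(self):
        df = _fixture_cohort()
        df["bbh"] = False
        df["bbh_volume_ml"] = 0.0
        df["bbh_location"] = "none"
        out = cohort_summary(df)
        assert out["notes"]
        assert out["patients"]["statistic"].isna().all()
        counts = out["hemorrhage"].set_index("feature")["count"]
        assert counts["symptomatic hemorrhage"] == 0

    def test_categorical_percentages_sum_to_cohort(self):
        out = cohort_summary(_fixture_cohort())
        pat = out["patients"].set_index("row")
        region_rows = [r for r in pat.index if r.startswith("target ")]
        assert sum(pat.loc[r, "total"] for r in region_rows) == 450

    def test_diagnostic_yield(self):
        df = _fixture_cohort()
        df.loc[:3, "histology"] = "inconclusive"
        out = cohort_summary(df)
        assert out["diagnostic_yield"] == pytest.approx((450 - 4) / 450)
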