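"""Mixed-model machinery and selection gradients."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oryzaqg import (
    combine_components,
    estimate_differentials,
    fit_lmm,
    gradients_from_differentials,
    janzen_stern_factor,
    linear_gradients,
    logistic_gradients,
    quadratic_gradients,
)
from oryzaqg.selection import SelectionGradients


def _blocked_data(n=300, n_blocks=3, block_sd=2.0, slope=0.5, seed=0):
    rng = np.random.default_rng(seed)
    blocks = rng.integers(0, n_blocks, n)
    block_eff = rng.normal(0, block_sd, n_blocks)
    x = rng.normal(size=n)
    y = 1.0 + slope * x + block_eff[blocks] + rng.normal(size=n)
    X = pd.DataFrame({"const": 1.0, "x": x})
    return y, X, blocks


class TestFitLmm:
    def test_zero_block_variance_equals_ols(self):
        y, X, blocks = _blocked_data(block_sd=0.0, seed=1)
        fit = fit_lmm(y, X, blocks)
        ols = np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0]
        np.testing.assert_allclose(fit.params.to_numpy(), ols, atol=1e-6)

    def test_slope_recovered_within_two_se(self):
        y, X, blocks = _blocked_data(seed=2)
        fit = fit_lmm(y, X, blocks)
        assert abs(fit.params["x"] - 0.5) < 2 * fit.bse["x"]
        assert fit.sigma2_group > 0.5  # planted block variance 4

    def test_optimizer_matches_brute_force_grid(self):
        y, X, blocks = _blocked_data(seed=3)
        fit = fit_lmm(y, X, blocks)
        # independent oracle: evaluate the REML criterion on a dense grid
        codes = pd.factorize(blocks)[0]
        Z = np.zeros((len(y), codes.max() + 1))
        Z[np.arange(len(y)), codes] = 1.0
        d, U = np.linalg.eigh(Z @ Z.T)
        yt, Xt = U.T @ y, U.T @ X.to_numpy()
        n, p = Xt.shape

        def crit(lam):
            v = 1 + lam * np.clip(d, 0, None)
            Xw = Xt / v[:, None]
            XtVX = Xt.T @ Xw
            beta = np.linalg.solve(XtVX, Xw.T @ yt)
            r = yt - Xt @ beta
            s2 = (r @ (r / v)) / (n - p)
            return 0.5 * ((n - p) * np.log(s2) + np.log(v).sum() + np.linalg.slogdet(XtVX)[1])

        grid = 10.0 ** np.linspace(-6, 6, 2000)
        best_grid = min(crit(l) for l in grid)
        lam_fit = fit.sigma2_group / fit.sigma2_resid
        assert crit(lam_fit) <= best_grid + 1e-6

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm

        y, X, blocks = _blocked_data(n=200, seed=4)
        fit = fit_lmm(y, X, blocks)
        ref = sm.MixedLM(y, X, groups=blocks).fit(reml=True)
        np.testing.assert_allclose(fit.params["x"], ref.params["x"], atol=1e-5)
        np.testing.assert_allclose(fit.bse["x"], ref.bse["x"], atol=1e-4)

    def test_rank_deficient_design_names_columns(self):
        y, X, blocks = _blocked_data(seed=5)
        X = X.assign(x2=X["x"] * 2.0)
        with pytest.raises(ValueError, match="x2"):
            fit_lmm(y, X, blocks)


class TestDifferentials:
    def test_no_block_structure_equals_sample_covariance(self):
        rng = np.random.default_rng(6)
        z = pd.DataFrame({"T1": rng.normal(size=100)})
        z["T1"] = (z["T1"] - z["T1"].mean()) / z["T1"].std(ddof=1)
        w = 1 + 0.4 * z["T1"] + rng.normal(0, 0.3, 100)
        res = estimate_differentials(z, w, np.zeros(100, dtype=int))
        slope = np.polyfit(z["T1"], w, 1)[0]
        assert res.loc["T1", "S"] == pytest.approx(slope, abs=1e-8)

    def test_constant_fitness_gives_zero_differentials(self):
        z = pd.DataFrame({"T1": np.linspace(-1, 1, 20)})
        res = estimate_differentials(z, np.ones(20), np.zeros(20, dtype=int))
        assert res.loc["T1", "S"] == 0.0
        assert res.loc["T1", "C"] == 0.0

    def test_recovery_over_replicates(self):
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(100 + rep)
            z = pd.DataFrame({"T1": rng.normal(size=200)})
            z["T1"] = (z["T1"] - z["T1"].mean()) / z["T1"].std(ddof=1)
            w = 1 + 0.3 * z["T1"] + rng.normal(0, 0.4, 200)
            res = estimate_differentials(z, w, rng.integers(0, 5, 200))
            if abs(res.loc["T1", "S"] - 0.3) < 2 * res.loc["T1", "se_S"]:
                hits += 1
        assert hits >= 45


class TestLinearGradients:
    def test_identity_p_matrix_gives_beta_equals_s(self):
        # closed form: P = I  ->  beta = P^-1 S = S
        P = pd.DataFrame(np.eye(2), index=["A", "B"], columns=["A", "B"])
        S = pd.Series([0.3, -0.1], index=["A", "B"])
        np.testing.assert_allclose(gradients_from_differentials(P, S), S)

    def test_closed_form_two_traits(self):
        P = pd.DataFrame([[1, 0.5], [0.5, 1]], index=["A", "B"], columns=["A", "B"])
        S = pd.Series([0.3, 0.0], index=["A", "B"])
        beta = gradients_from_differentials(P, S)
        np.testing.assert_allclose(beta, [0.4, -0.2], atol=1e-12)

    def test_regression_route_agrees_with_p_inverse_s(self):
        # algebraic identity without random effects
        rng = np.random.default_rng(8)
        raw = rng.multivariate_normal([0, 0, 0], [[1, 0.4, 0.1], [0.4, 1, 0.2], [0.1, 0.2, 1]], 400)
        z = pd.DataFrame(raw, columns=["A", "B", "C"])
        z = (z - z.mean()) / z.std(ddof=1)
        w = 1 + 0.2 * z["A"] - 0.3 * z["C"] + rng.normal(0, 0.3, 400)
        grads = linear_gradients(z, w, np.zeros(400, dtype=int))
        S = grads.table["S"]
        beta_ps = gradients_from_differentials(grads.P, S)
        np.testing.assert_allclose(grads.beta, beta_ps, atol=1e-8)


class TestQuadraticGradients:
    def test_identity_p_gives_gamma_equals_c(self):
        rng = np.random.default_rng(9)
        z = pd.DataFrame({"A": rng.normal(size=500)})
        z["A"] = (z["A"] - z["A"].mean()) / z["A"].std(ddof=1)
        w = 1 - 0.2 * z["A"] ** 2 + rng.normal(0, 0.1, 500)
        diffs = estimate_differentials(z, w, np.zeros(500, dtype=int))
        gamma = quadratic_gradients(z, w, np.zeros(500, dtype=int))
        # single standardized trait: P ~ 1, so gamma ~ C
        assert gamma.loc["A", "A"] == pytest.approx(diffs.loc["A", "C"], rel=1e-6)

    @pytest.mark.parametrize("double,expected", [(False, -0.2), (True, -0.4)])
    def test_stabilizing_surface_doubling_convention(self, double, expected):
        ests = []
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            z = pd.DataFrame({"A": rng.normal(size=400)})
            z["A"] = (z["A"] - z["A"].mean()) / z["A"].std(ddof=1)
            w = 1 - 0.2 * z["A"] ** 2 + rng.normal(0, 0.1, 400)
            g = quadratic_gradients(z, w, np.zeros(400, dtype=int), double_diagonal=double)
            ests.append(g.loc["A", "A"])
        assert np.mean(ests) == pytest.approx(expected, abs=0.05)

    def test_constant_fitness_gives_zero_gamma(self):
        z = pd.DataFrame({"A": np.linspace(-2, 2, 50), "B": np.cos(np.linspace(0, 3, 50))})
        gamma = quadratic_gradients(z, np.ones(50), np.zeros(50, dtype=int))
        np.testing.assert_allclose(gamma.to_numpy(), 0.0, atol=1e-10)
        np.testing.assert_allclose(gamma.to_numpy(), gamma.to_numpy().T)


class TestLogisticGradients:
    def test_constant_probability_limit(self):
        # with W == 0.5 everywhere, the average-gradient factor is 0.25/0.5
        assert janzen_stern_factor(np.full(100, 0.5)) == pytest.approx(0.5)

    def test_transform_matches_average_gradient_oracle(self):
        rng = np.random.default_rng(10)
        z = pd.DataFrame({"A": rng.normal(size=500)})
        z["A"] = (z["A"] - z["A"].mean()) / z["A"].std(ddof=1)
        eta = 0.3 + 0.8 * z["A"]
        success = (rng.random(500) < 1 / (1 + np.exp(-eta))).astype(float)
        grads = logistic_gradients(z, success)
        # oracle: recompute the average gradient from the fitted slope
        import statsmodels.api as sm

        X = sm.add_constant(z)
        res = sm.GLM(success, X, family=sm.families.Binomial()).fit()
        W = res.predict(X)
        expected = res.params["A"] * np.mean(W * (1 - W)) / np.mean(W)
        assert grads.beta["A"] == pytest.approx(expected, abs=1e-6)

    def test_null_gradients_are_small(self):
        hits = 0
        for rep in range(40):
            rng = np.random.default_rng(300 + rep)
            z = pd.DataFrame({"A": rng.normal(size=300)})
            success = (rng.random(300) < 0.7).astype(float)
            g = logistic_gradients(z, success)
            if abs(g.beta["A"]) < 2 * g.se["A"]:
                hits += 1
        assert hits >= 34  # ~95% coverage with binomial slack

    def test_requires_both_classes(self):
        z = pd.DataFrame({"A": np.linspace(-1, 1, 20)})
        with pytest.raises(ValueError, match="both classes"):
            logistic_gradients(z, np.ones(20))


class TestCombineComponents:
    def _grads(self, beta, se, component):
        table = pd.DataFrame({"beta": beta, "se": se, "p": 0.5}, index=["DTF"])
        return SelectionGradients(table=table, component=component)

    def test_zero_flowering_component_recovers_fecundity(self):
        fec = self._grads([-1.0], [0.2], "fecundity")
        flow = self._grads([0.0], [0.0], "flowering_success")
        total = combine_components(fec, flow)
        assert total.beta["DTF"] == pytest.approx(-1.0)
        assert total.se["DTF"] == pytest.approx(0.2)

    def test_summation_structure_of_components(self):
        # components summing to a strong negative gradient on flowering time
        fec = self._grads([-1.0], [0.2], "fecundity")
        flow = self._grads([-0.476], [0.093], "flowering_success")
        total = combine_components(fec, flow)
        assert total.beta["DTF"] == pytest.approx(-1.476)
        assert total.se["DTF"] == pytest.approx(0.293)

    def test_commutative(self):
        a = self._grads([-0.3], [0.1], "fecundity")
        b = self._grads([0.2], [0.05], "flowering_success")
        pd.testing.assert_frame_equal(
            combine_components(a, b).table, combine_components(b, a).table
        )

    def test_trait_mismatch_raises(self):
        a = self._grads([-0.3], [0.1], "fecundity")
        b = SelectionGradients(
            table=pd.DataFrame({"beta": [0.1], "se": [0.1], "p": [0.5]}, index=["TNR"]),
            component="flowering_success",
        )
        with pytest.raises(ValueError, match="DTF|TNR"):
            combine_components(a, b)
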