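"""Phenotypic selection analysis: differentials, gradients, fitness components.

Selection differentials S (and quadratic differentials C) come from
univariate mixed models of relative fitness on each standardized trait with
a block random intercept; linear gradients β = P⁻¹S are computed from the
joint mixed regression of fitness on all traits (numerically identical to
P⁻¹S for the point estimates, and providing SEs and p-values directly).
Gradients on the binary flowering-success component use logistic regression
with the Janzen–Stern average-gradient transformation.  Gradients for the
multiplicative total fitness are the per-component sums, with summed SEs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from oryzaqg.phenotype_prep import SelectionInputs


@dataclass
class LMMFit:
    """A linear mixed model fit with one random intercept (REML)."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    sigma2_group: float
    sigma2_resid: float
    loglik: float
    converged: bool
    df_resid: int


@dataclass
class SelectionGradients:
    """Per-trait selection gradients and differentials for one fitness component.

    ``table`` columns: beta, se, p, S, se_S, C, se_C (differentials missing
    for combined components).  ``gamma`` is the quadratic gradient matrix
    when a quadratic analysis was run.
    """

    table: pd.DataFrame
    component: str
    environment: str = ""
    gamma: pd.DataFrame | None = None
    P: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def traits(self) -> list[str]:
        return list(self.table.index)

    @property
    def beta(self) -> pd.Series:
        return self.table["beta"]

    @property
    def se(self) -> pd.Series:
        return self.table["se"]


def _design(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def fit_lmm(y, X, groups) -> LMMFit:
    """REML fit of ``y = Xβ + u_group + e`` with a single random intercept.

    The likelihood is profiled over the variance ratio λ = σ²_group/σ²_e
    and optimized in one dimension on the log scale (Brent, tol 1e−8).
    When the ratio hits the zero boundary the result equals OLS.
    """
    y = np.asarray(y, dtype=float)
    Xa, names = _design(X)
    n, p = Xa.shape
    if np.linalg.matrix_rank(Xa) < p:
        # identify (approximately) collinear columns for the error message
        bad = []
        for j in range(p):
            others = np.delete(Xa, j, axis=1)
            proj, *_ = np.linalg.lstsq(others, Xa[:, j], rcond=None)
            resid = Xa[:, j] - others @ proj
            if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(Xa[:, j]), 1.0):
                bad.append(names[j])
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad or names}")

    codes, levels = pd.factorize(np.asarray(groups))
    Z = np.zeros((n, len(levels)))
    Z[np.arange(n), codes] = 1.0
    # eigenvectors of ZZ' diagonalize V = I + λ ZZ' for every λ
    d, U = np.linalg.eigh(Z @ Z.T)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ Xa

    def neg_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        v = 1.0 + lam * d
        Xw = Xt / v[:, None]
        XtVX = Xt.T @ Xw
        beta = np.linalg.solve(XtVX, Xw.T @ yt)
        r = yt - Xt @ beta
        rss = float(r @ (r / v))
        sigma2 = rss / (n - p)
        _, logdet_XtVX = np.linalg.slogdet(XtVX)
        return 0.5 * ((n - p) * np.log(sigma2) + np.sum(np.log(v)) + logdet_XtVX)

    if len(levels) < 2:
        lam_hat, converged = 0.0, True
    else:
        res = optimize.minimize_scalar(
            neg_reml, bounds=(-16.0, 16.0), method="bounded",
            options={"xatol": 1e-8},
        )
        converged = bool(res.success)
        lam_hat = float(np.exp(res.x))
        if neg_reml(-30.0) <= res.fun:  # boundary: no block variance
            lam_hat = 0.0

    v = 1.0 + lam_hat * d
    Xw = Xt / v[:, None]
    XtVX = Xt.T @ Xw
    beta = np.linalg.solve(XtVX, Xw.T @ yt)
    r = yt - Xt @ beta
    sigma2_e = float(r @ (r / v)) / (n - p)
    cov = sigma2_e * np.linalg.inv(XtVX)
    bse = np.sqrt(np.diag(cov))
    tvals = beta / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
    _, logdet_XtVX = np.linalg.slogdet(XtVX)
    loglik = -0.5 * (
        (n - p) * (np.log(2 * np.pi * sigma2_e) + 1.0)
        + np.sum(np.log(v))
        + logdet_XtVX
    )
    return LMMFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma2_group=lam_hat * sigma2_e,
        sigma2_resid=sigma2_e,
        loglik=float(loglik),
        converged=converged,
        df_resid=n - p,
    )


def estimate_differentials(z: pd.DataFrame, w: pd.Series, blocks) -> pd.DataFrame:
    """Directional (S) and quadratic (C) selection differentials per trait.

    S_i is the slope of relative fitness on z_i in ``w ~ z_i + (1|block)``;
    C_ii is the coefficient on z_i² in ``w ~ z_i + z_i² + (1|block)``.
    """
    w = np.asarray(w, dtype=float)
    if len(w) < 3:
        raise ValueError("need at least 3 individuals for selection differentials")
    blocks = np.asarray(blocks)
    rows = {}
    for trait in z.columns:
        x = z[trait].to_numpy(dtype=float)
        mask = ~np.isnan(x) & ~np.isnan(w)
        if mask.sum() < 3:
            rows[trait] = dict.fromkeys(["S", "se_S", "p_S", "C", "se_C", "p_C"], np.nan)
            continue
        xm, wm, bm = x[mask], w[mask], blocks[mask]
        if np.ptp(wm) == 0.0:  # constant fitness: no selection
            rows[trait] = {"S": 0.0, "se_S": 0.0, "p_S": 1.0, "C": 0.0, "se_C": 0.0, "p_C": 1.0}
            continue
        Xlin = pd.DataFrame({"const": 1.0, "z": xm})
        lin = fit_lmm(wm, Xlin, bm)
        Xquad = pd.DataFrame({"const": 1.0, "z": xm, "z2": xm**2})
        quad = fit_lmm(wm, Xquad, bm)
        rows[trait] = {
            "S": lin.params["z"], "se_S": lin.bse["z"], "p_S": lin.pvalues["z"],
            "C": quad.params["z2"], "se_C": quad.bse["z2"], "p_C": quad.pvalues["z2"],
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _complete_cases(z: pd.DataFrame, w: pd.Series, blocks) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    z = z.loc[:, z.notna().any(axis=0)]
    mask = z.notna().all(axis=1) & pd.Series(np.asarray(w, dtype=float), index=z.index).notna()
    return z.loc[mask], np.asarray(w, dtype=float)[mask.to_numpy()], np.asarray(blocks)[mask.to_numpy()]


def phenotypic_correlation(z: pd.DataFrame) -> pd.DataFrame:
    """P matrix: covariance of the standardized traits (≈ correlation)."""
    return z.cov(ddof=1)


def gradients_from_differentials(P: pd.DataFrame, S: pd.Series) -> pd.Series:
    """Cross-check route: β = P⁻¹S."""
    beta = np.linalg.solve(P.to_numpy(), S.loc[P.index].to_numpy())
    return pd.Series(beta, index=P.index)


def linear_gradients(
    z: pd.DataFrame, w: pd.Series, blocks, component: str = "fecundity",
    environment: str = "",
) -> SelectionGradients:
    """Linear selection gradients β from the joint mixed regression.

    Point estimates equal β = P⁻¹S; SEs and p-values come from the joint
    fit of relative fitness on all standardized traits with a block random
    intercept.  Near-collinear traits (P condition number > 1e8) trigger a
    warning naming the most correlated pair.
    """
    zc, wc, bc = _complete_cases(z, w, blocks)
    if zc.shape[1] < 1:
        raise ValueError("no traits with complete cases")
    P = phenotypic_correlation(zc)
    cond = np.linalg.cond(P.to_numpy())
    if cond > 1e8:
        corr = zc.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        warnings.warn(
            f"P matrix near-singular (cond={cond:.2e}); "
            f"most collinear trait pair: {zc.columns[i]}, {zc.columns[j]}"
        )
    X = pd.concat([pd.Series(1.0, index=zc.index, name="const"), zc], axis=1)
    fit = fit_lmm(wc, X, bc)
    diffs = estimate_differentials(zc, pd.Series(wc, index=zc.index), bc)
    table = pd.DataFrame(
        {
            "beta": fit.params[zc.columns],
            "se": fit.bse[zc.columns],
            "p": fit.pvalues[zc.columns],
        }
    ).join(diffs)
    return SelectionGradients(
        table=table, component=component, environment=environment, P=P,
        meta={"n": len(wc), "sigma2_block": fit.sigma2_group, "condition_number": cond},
    )


def quadratic_gradients(
    z: pd.DataFrame, w: pd.Series, blocks,
    cross_terms: bool = False, double_diagonal: bool = False,
) -> pd.DataFrame:
    """Quadratic selection gradient matrix γ = P⁻¹ C P⁻¹ (symmetrized).

    C is assembled from per-trait quadratic differentials on the diagonal;
    off-diagonal (correlational) terms are filled from bilinear coefficients
    only when ``cross_terms`` is enabled.  ``double_diagonal`` applies the
    convention that doubles the fitted quadratic coefficient so that the
    diagonal estimates the curvature of the selection surface.
    """
    zc, wc, bc = _complete_cases(z, w, blocks)
    P = phenotypic_correlation(zc).to_numpy()
    traits = list(zc.columns)
    diffs = estimate_differentials(zc, pd.Series(wc, index=zc.index), bc)
    C = np.diag(diffs["C"].loc[traits].to_numpy())
    if double_diagonal:
        C = 2.0 * C
    if cross_terms:
        for a in range(len(traits)):
            for b in range(a + 1, len(traits)):
                xa, xb = zc.iloc[:, a].to_numpy(), zc.iloc[:, b].to_numpy()
                X = pd.DataFrame({"const": 1.0, "za": xa, "zb": xb, "zazb": xa * xb})
                fit = fit_lmm(wc, X, bc)
                C[a, b] = C[b, a] = fit.params["zazb"]
    Pinv = np.linalg.inv(P)
    gamma = Pinv @ C @ Pinv
    gamma = 0.5 * (gamma + gamma.T)
    return pd.DataFrame(gamma, index=traits, columns=traits)


def janzen_stern_factor(fitted_prob: np.ndarray) -> float:
    """Average-gradient factor mean[W(1−W)] / mean(W) from fitted probabilities."""
    W = np.asarray(fitted_prob, dtype=float)
    return float(np.mean(W * (1.0 - W)) / np.mean(W))


def logistic_gradients(
    z: pd.DataFrame, success: pd.Series, blocks=None,
    joint: bool = True, environment: str = "",
) -> SelectionGradients:
    """Selection gradients on a binary fitness component via logistic regression.

    Logistic slopes α are transformed to the selection-gradient scale by the
    average-gradient rule β = α · mean[W(1−W)] / mean(W), where W are the
    fitted success probabilities.  Blocks (if given) enter as fixed
    covariates.  Complete separation is flagged and the p-value set missing.
    """
    import statsmodels.api as sm

    zc = z.loc[:, z.notna().any(axis=0)]
    s = np.asarray(success, dtype=float)
    if len(np.unique(s[~np.isnan(s)])) < 2:
        raise ValueError("flowering success must have both classes present")
    mask = zc.notna().all(axis=1).to_numpy() & ~np.isnan(s)
    zc, s = zc.loc[mask], s[mask]
    parts = [pd.Series(1.0, index=zc.index, name="const")]
    trait_cols = list(zc.columns)
    if blocks is not None:
        bdum = pd.get_dummies(
            pd.Series(np.asarray(blocks)[mask], index=zc.index).astype("category"),
            prefix="block", drop_first=True, dtype=float,
        )
        parts.append(bdum)

    def _fit(cols: list[str]) -> tuple[pd.Series, pd.Series, pd.Series, np.ndarray, bool]:
        X = pd.concat([parts[0], zc[cols]] + parts[1:], axis=1)
        separated = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(s, X, family=sm.families.Binomial())
            try:
                res = model.fit(maxiter=200)
            except Exception:
                separated = True
                res = model.fit_regularized(alpha=1e-6, maxiter=500)
        W = np.asarray(res.predict(X))
        if np.any(W > 1 - 1e-10) or np.any(W < 1e-10):
            separated = separated or np.ptp(W) > 0.999999
        params = pd.Series(np.asarray(res.params), index=X.columns)
        bse = pd.Series(getattr(res, "bse", np.full(len(params), np.nan)), index=X.columns)
        pvals = pd.Series(getattr(res, "pvalues", np.full(len(params), np.nan)), index=X.columns)
        return params, bse, pvals, W, separated

    rows = {}
    if joint:
        params, bse, pvals, W, separated = _fit(trait_cols)
        factor = janzen_stern_factor(W)
        for t in trait_cols:
            rows[t] = {
                "beta": params[t] * factor,
                "se": bse[t] * factor,
                "p": np.nan if separated else pvals[t],
                "alpha": params[t],
            }
    else:
        for t in trait_cols:
            params, bse, pvals, W, separated = _fit([t])
            factor = janzen_stern_factor(W)
            rows[t] = {
                "beta": params[t] * factor,
                "se": bse[t] * factor,
                "p": np.nan if separated else pvals[t],
                "alpha": params[t],
            }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return SelectionGradients(
        table=table, component="flowering_success", environment=environment,
        meta={"n": int(mask.sum()), "joint": joint},
    )


def combine_components(
    g_fec: SelectionGradients, g_flow: SelectionGradients
) -> SelectionGradients:
    """Total-fitness gradients across multiplicative fitness components.

    β and SE are summed per trait (SEs summed, not added in quadrature —
    the convention used with a binary component); p-values are recomputed
    from the combined β/SE by a two-sided normal test.
    """
    t1, t2 = set(g_fec.traits), set(g_flow.traits)
    if t1 != t2:
        raise ValueError(f"trait sets differ between components: {sorted(t1 ^ t2)}")
    traits = g_fec.traits
    beta = g_fec.beta.loc[traits] + g_flow.beta.loc[traits]
    se = g_fec.se.loc[traits] + g_flow.se.loc[traits]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(beta / se))
    table = pd.DataFrame({"beta": beta, "se": se, "p": p})
    return SelectionGradients(
        table=table, component="total", environment=g_fec.environment,
        meta={"se_rule": "sum", "components": [g_fec.component, g_flow.component]},
    )
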