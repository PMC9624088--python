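"""Kinship, variance components and G-matrix assembly from SNP data.

The variance-component engine is an eigendecomposition-based (spectral)
REML for the single-kinship mixed model y = Xb + u + e with
u ~ (0, σ²_g K) and e ~ (0, σ²_e I): the REML likelihood is profiled over
δ = σ²_e/σ²_g and optimized in one dimension on a log grid with local
refinement, which is exact and fast at panel sizes of a few hundred.
Inside the engine K is rescaled to unit mean diagonal so that σ²_g is on
the phenotypic scale and pseudo-h² = σ²_g/(σ²_g + σ²_e) is interpretable
as the fraction of phenotypic variance tagged by the markers; this matters
for fully inbred panels, whose genomic relationship matrices have diagonal
entries near 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from oryzaqg.data_io import GenotypeMatrix

logger = logging.getLogger(__name__)

_LOG10_DELTA_BOUNDS = (-8.0, 8.0)


@dataclass
class KinshipMatrix:
    """Accession × accession genomic relationship matrix."""

    values: pd.DataFrame
    method: str
    n_markers: int

    def __post_init__(self) -> None:
        a = self.values.to_numpy()
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric")

    @property
    def accessions(self) -> list[str]:
        return list(self.values.index)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy()

    def subset(self, accessions) -> "KinshipMatrix":
        return KinshipMatrix(
            values=self.values.loc[accessions, accessions],
            method=self.method,
            n_markers=self.n_markers,
        )


@dataclass
class VarianceComponents:
    """REML variance components of the single-kinship mixed model."""

    sigma2_g: float
    sigma2_e: float
    h2: float
    loglik: float
    converged: bool

    def __post_init__(self) -> None:
        self.h2 = float(np.clip(self.h2, 0.0, 1.0))


@dataclass
class GMatrix:
    """Trait × trait additive genetic (co)variance matrix on the standardized scale.

    Diagonal entries are pseudo-heritabilities; off-diagonals are additive
    genetic covariances (co-heritabilities).  ``significant`` flags cells
    with p < 0.05; traits unmeasured in the environment are recorded in
    ``masked`` and excluded from the matrix rather than zero-filled.
    """

    values: pd.DataFrame
    significant: pd.DataFrame | None = None
    pvalues: pd.DataFrame | None = None
    environment: str = ""
    panel: str = ""
    masked: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = self.values.to_numpy(dtype=float)
        if not np.allclose(a, a.T, atol=1e-8, equal_nan=True):
            raise ValueError("G-matrix not symmetric")
        diag = np.diag(a)
        if np.any((diag < -1e-8) | (diag > 1.0 + 1e-8)):
            raise ValueError("G-matrix diagonal (heritabilities) outside [0, 1]")

    @property
    def traits(self) -> list[str]:
        return list(self.values.index)


def ld_prune(g: GenotypeMatrix, window_bp: int = 1000, seed: int | None = 0) -> GenotypeMatrix:
    """Thin markers to one randomly chosen SNP per non-overlapping window.

    The genome is partitioned per chromosome into contiguous ``window_bp``
    bins anchored at position 1 ([1, 1000], [1001, 2000], ...); one SNP is
    drawn uniformly at random from each occupied bin.
    """
    if g.n_markers == 0:
        return g
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    pos = g.markers["pos"].to_numpy()
    bins = (pos - 1) // window_bp
    for (_, _), idx in pd.DataFrame(
        {"chrom": g.markers["chrom"], "bin": bins}
    ).groupby(["chrom", "bin"], sort=False).groups.items():
        keep.append(int(rng.choice(np.asarray(idx))))
    keep = sorted(keep)
    return g.subset_markers(np.asarray(keep, dtype=int))


def vanraden_grm(g: GenotypeMatrix) -> KinshipMatrix:
    """Genomic relationship matrix K = WWᵀ / (2 Σ pᵢ(1−pᵢ)).

    W is the dosage matrix with columns centered by 2pᵢ, where pᵢ is the
    observed alternate-allele frequency.  Monomorphic markers are excluded
    (with a logged count) before computation.  Requires imputed dosages.
    """
    if np.isnan(g.dosages).any():
        raise ValueError("genotypes contain missing dosages; impute first")
    p = g.dosages.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("excluded %d monomorphic markers from GRM", n_mono)
    if poly.sum() == 0:
        raise ValueError("no polymorphic markers for GRM")
    W = g.dosages[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    K = (W @ W.T) / denom
    K = 0.5 * (K + K.T)
    return KinshipMatrix(
        values=pd.DataFrame(K, index=g.accessions, columns=g.accessions),
        method="vanraden",
        n_markers=int(poly.sum()),
    )


def genotype_pca(g: GenotypeMatrix, n_pc: int = 4) -> pd.DataFrame:
    """Principal components of the column-standardized dosage matrix.

    Returns accession scores for the top ``n_pc`` axes with the fraction of
    variance explained in ``DataFrame.attrs['explained_variance_ratio']``.
    Sign convention: the largest-magnitude loading of each axis is positive.
    """
    if n_pc > g.n_accessions - 1:
        raise ValueError(f"n_pc={n_pc} exceeds accessions-1={g.n_accessions - 1}")
    X = g.dosages.copy()
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    nonconst = sd > 0
    X = X[:, nonconst] / sd[nonconst]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_pc] * s[:n_pc]
    for j in range(n_pc):
        k = np.argmax(np.abs(Vt[j]))
        if Vt[j, k] < 0:
            scores[:, j] *= -1.0
    frac = (s**2) / np.sum(s**2)
    out = pd.DataFrame(
        scores, index=g.accessions, columns=[f"PC{i + 1}" for i in range(n_pc)]
    )
    out.attrs["explained_variance_ratio"] = frac[:n_pc]
    return out


def _normalize_kinship(K: np.ndarray) -> np.ndarray:
    scale = np.mean(np.diag(K))
    if scale <= 0:
        raise ValueError("kinship matrix has non-positive mean diagonal")
    return K / scale


def _spectral_setup(y, K, covariates):
    y = np.asarray(y, dtype=float)
    n = len(y)
    Ka = K.to_numpy() if isinstance(K, (KinshipMatrix,)) else np.asarray(K, dtype=float)
    if isinstance(Ka, pd.DataFrame):
        Ka = Ka.to_numpy()
    Ka = _normalize_kinship(Ka)
    d, U = np.linalg.eigh(Ka)
    if d.min() < -1e-6:
        raise ValueError(f"kinship matrix not PSD (min eigenvalue {d.min():.3e})")
    d = np.clip(d, 0.0, None)
    if covariates is None:
        X = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(n), C])
    return y, X, d, U


def _profiled_reml(yt, Xt, d, log10_delta: float) -> tuple[float, float]:
    """Negative REML criterion and σ̂²_g at a given log10 variance ratio δ."""
    delta = 10.0**log10_delta
    v = d + delta
    n, p = Xt.shape
    Xw = Xt / v[:, None]
    XtVX = Xt.T @ Xw
    beta = np.linalg.solve(XtVX, Xw.T @ yt)
    r = yt - Xt @ beta
    rss = float(r @ (r / v))
    sigma2_g = rss / (n - p)
    _, logdet = np.linalg.slogdet(XtVX)
    crit = 0.5 * ((n - p) * np.log(sigma2_g) + np.sum(np.log(v)) + logdet)
    return crit, sigma2_g


def reml_variance_components(y, K, covariates=None, n_grid: int = 64) -> VarianceComponents:
    """REML variance components by spectral 1-D profiling over δ = σ²_e/σ²_g.

    A coarse log₁₀ grid over [−8, 8] is followed by bounded local
    refinement; boundary solutions are clamped (δ at the upper bound maps
    to h² = 0, at the lower bound to h² = 1).
    """
    y, X, d, U = _spectral_setup(y, K, covariates)
    yt, Xt = U.T @ y, U.T @ X
    n, p = Xt.shape
    lo, hi = _LOG10_DELTA_BOUNDS

    grid = np.linspace(lo, hi, n_grid)
    crits = np.array([_profiled_reml(yt, Xt, d, g)[0] for g in grid])
    best = int(np.argmin(crits))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, n_grid - 1)]
    converged = True
    if a < b:
        res = optimize.minimize_scalar(
            lambda x: _profiled_reml(yt, Xt, d, x)[0],
            bounds=(a, b), method="bounded", options={"xatol": 1e-8},
        )
        converged = bool(res.success)
        log10_delta = float(res.x) if res.fun <= crits[best] else grid[best]
    else:
        log10_delta = grid[best]

    crit, sigma2_g = _profiled_reml(yt, Xt, d, log10_delta)
    delta = 10.0**log10_delta
    sigma2_e = delta * sigma2_g
    h2 = 1.0 / (1.0 + delta)
    # clamp hard boundaries
    if log10_delta >= hi - 1e-6:
        h2, sigma2_g = 0.0, 0.0
    elif log10_delta <= lo + 1e-6:
        h2 = 1.0
    loglik = -crit - 0.5 * (n - p) * (np.log(2 * np.pi) + 1.0)
    return VarianceComponents(
        sigma2_g=float(sigma2_g), sigma2_e=float(sigma2_e), h2=float(h2),
        loglik=float(loglik), converged=converged,
    )


def reml_loglik_naive(y, K, covariates, sigma2_g: float, sigma2_e: float) -> float:
    """Full-matrix REML log-likelihood at given variance components.

    Reference implementation via explicit V = σ²_g K + σ²_e I inversion;
    used to validate the spectral path.
    """
    y, X, _, _ = _spectral_setup(y, K, covariates)
    Ka = K.to_numpy() if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    Ka = _normalize_kinship(Ka)
    n, p = X.shape
    V = sigma2_g * Ka + sigma2_e * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, logdetV = np.linalg.slogdet(V)
    _, logdetXtViX = np.linalg.slogdet(XtViX)
    return float(
        -0.5 * (logdetV + logdetXtViX + r @ Vi @ r + (n - p) * np.log(2 * np.pi))
    )


def _align(y: pd.Series, K: KinshipMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(y, pd.Series):
        shared = [a for a in K.accessions if a in y.index and not np.isnan(y.loc[a])]
        return y.loc[shared].to_numpy(dtype=float), K.values.loc[shared, shared].to_numpy(), shared
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y)
    Ka = K.to_numpy()[np.ix_(mask, mask)]
    return y[mask], Ka, [K.accessions[i] for i in np.flatnonzero(mask)]


def _genetic_variance(y: np.ndarray, Ka: np.ndarray) -> float:
    """Genetic variance on the trait scale: pseudo-h² × phenotypic variance."""
    vc = reml_variance_components(y, Ka)
    return vc.h2 * float(np.var(y, ddof=1))


# ---------------------------------------------------------------------------
# bivariate ML engine (for the covariance significance test)

def _bivariate_negll(theta, d, xt, Y, free_cov: bool) -> float:
    if np.any(np.abs(theta) > 20.0):
        return 1e12
    if free_cov:
        lg = np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])
        off = 3
    else:
        lg = np.diag(np.exp(theta[:2]))
        off = 2
    le = np.array([[np.exp(theta[off]), 0.0], [theta[off + 1], np.exp(theta[off + 2])]])
    Vg, Ve = lg @ lg.T, le @ le.T
    # per-observation 2x2 covariance in the spectral basis
    S = Vg[None, :, :] * d[:, None, None] + Ve[None, :, :]
    det = S[:, 0, 0] * S[:, 1, 1] - S[:, 0, 1] ** 2
    if np.any(det <= 0) or np.any(S[:, 0, 0] <= 0):
        return 1e12
    inv = np.empty_like(S)
    inv[:, 0, 0] = S[:, 1, 1] / det
    inv[:, 1, 1] = S[:, 0, 0] / det
    inv[:, 0, 1] = inv[:, 1, 0] = -S[:, 0, 1] / det
    # GLS intercepts (2 fixed effects, one per trait)
    A = np.einsum("i,ijk->jk", xt**2, inv)
    b = np.einsum("i,ijk,ik->j", xt, inv, Y)
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return 1e12
    if not np.all(np.isfinite(beta)):
        return 1e12
    R = Y - np.outer(xt, beta)
    quad = np.einsum("ij,ijk,ik->", R, inv, R)
    return 0.5 * (np.sum(np.log(det)) + quad)


def _bivariate_ml_loglik(y1, y2, Ka, free_cov: bool) -> float:
    d, U = np.linalg.eigh(_normalize_kinship(Ka))
    d = np.clip(d, 0.0, None)
    Y = np.column_stack([U.T @ y1, U.T @ y2])
    xt = U.T @ np.ones(len(y1))
    vc1 = reml_variance_components(y1, Ka)
    vc2 = reml_variance_components(y2, Ka)

    def chol_params(v1, v2, c=0.0):
        l11 = np.sqrt(max(v1, 1e-4))
        l21 = c / l11
        l22 = np.sqrt(max(v2 - l21**2, 1e-4))
        return l11, l21, l22

    g11, g21, g22 = chol_params(max(vc1.h2, 0.05), max(vc2.h2, 0.05))
    e11, e21, e22 = chol_params(max(1 - vc1.h2, 0.05), max(1 - vc2.h2, 0.05))
    if free_cov:
        x0 = [np.log(g11), g21, np.log(g22), np.log(e11), e21, np.log(e22)]
    else:
        x0 = [np.log(g11), np.log(g22), np.log(e11), e21, np.log(e22)]
    res = optimize.minimize(
        _bivariate_negll, x0, args=(d, xt, Y, free_cov),
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8},
    )
    return -res.fun


def genetic_covariance(
    y1: pd.Series, y2: pd.Series, K: KinshipMatrix, test: str = "lrt"
) -> tuple[float, float]:
    """Additive genetic covariance between two traits, with a p-value.

    The point estimate uses the variance-of-the-sum identity
    cov_g = [V_g(y1+y2) − V_g(y1) − V_g(y2)] / 2 with V_g(y) = h²(y)·var(y),
    so on standardized traits cov_g is the co-heritability and
    cov_g(y, y) = h²(y) exactly.  Significance (``test='lrt'``) compares
    bivariate ML fits with free vs zero genetic covariance (χ², 1 df).
    """
    if isinstance(y1, pd.Series) and isinstance(y2, pd.Series):
        shared = [
            a for a in K.accessions
            if a in y1.index and a in y2.index
            and not (np.isnan(y1.loc[a]) or np.isnan(y2.loc[a]))
        ]
        if len(shared) < 10:
            raise ValueError(f"only {len(shared)} shared accessions (<10)")
        a1 = y1.loc[shared].to_numpy(dtype=float)
        a2 = y2.loc[shared].to_numpy(dtype=float)
        Ka = K.values.loc[shared, shared].to_numpy()
    else:
        a1, a2 = np.asarray(y1, dtype=float), np.asarray(y2, dtype=float)
        if len(a1) < 10:
            raise ValueError("need at least 10 shared accessions")
        Ka = K.to_numpy() if isinstance(K, KinshipMatrix) else np.asarray(K)

    vg_sum = _genetic_variance(a1 + a2, Ka)
    vg1 = _genetic_variance(a1, Ka)
    vg2 = _genetic_variance(a2, Ka)
    cov_g = (vg_sum - vg1 - vg2) / 2.0

    if test == "none":
        return float(cov_g), float("nan")
    ll_free = _bivariate_ml_loglik(a1, a2, Ka, free_cov=True)
    ll_null = _bivariate_ml_loglik(a1, a2, Ka, free_cov=False)
    lrt = max(2.0 * (ll_free - ll_null), 0.0)
    p = float(stats.chi2.sf(lrt, df=1))
    return float(cov_g), p


def assemble_g_matrix(
    tm, K: KinshipMatrix, environment: str = "", panel: str = "",
    traits: list[str] | None = None, alpha: float = 0.05,
) -> GMatrix:
    """Assemble the G-matrix from standardized accession LS means.

    Diagonal entries are pseudo-heritabilities from the univariate kinship
    model; off-diagonals are genetic covariances with LRT significance
    flags at p < ``alpha``.  Traits with no measurements in the environment
    are masked (excluded from the matrix).
    """
    z = tm.z if hasattr(tm, "z") else tm
    all_traits = traits or list(z.columns)
    measured = [t for t in all_traits if t in z.columns and z[t].notna().any()]
    masked = tuple(t for t in all_traits if t not in measured)

    vals = pd.DataFrame(np.nan, index=measured, columns=measured, dtype=float)
    pvals = pd.DataFrame(np.nan, index=measured, columns=measured, dtype=float)
    for t in measured:
        y, Ka, _ = _align(z[t], K)
        vc = reml_variance_components(y, Ka)
        vals.loc[t, t] = vc.h2 * float(np.var(y, ddof=1))
        pvals.loc[t, t] = np.nan
    for i, t1 in enumerate(measured):
        for t2 in measured[i + 1:]:
            cov, p = genetic_covariance(z[t1], z[t2], K)
            vals.loc[t1, t2] = vals.loc[t2, t1] = cov
            pvals.loc[t1, t2] = pvals.loc[t2, t1] = p
    # numerical guard: heritabilities live in [0, 1] by definition
    np.fill_diagonal(vals.values, np.clip(np.diag(vals.values), 0.0, 1.0))
    sig = pvals < alpha
    return GMatrix(
        values=vals, significant=sig, pvalues=pvals,
        environment=environment, panel=panel, masked=masked,
    )
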