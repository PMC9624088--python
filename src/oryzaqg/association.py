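"""Association scans: mixed-model GWAS, multiple-testing thresholds,
candidate-gene windows, and transcript–trait regressions.

The GWAS tests each marker in the kinship mixed model with principal-
component covariates, re-using the null-model variance components across
markers (the "population parameters previously determined" approximation)
so scans over hundreds of thousands of markers stay tractable.  An
optional forward-only stepwise mode adds the most significant marker as a
cofactor and rescans.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from oryzaqg.data_io import GenotypeMatrix, GeneTable
from oryzaqg.quantgen import (
    KinshipMatrix,
    _normalize_kinship,
    reml_variance_components,
)


@dataclass
class AssociationResult:
    """Per-marker association statistics for one scan."""

    table: pd.DataFrame  # columns: chrom, pos, effect, se, p
    trait: str = ""
    environment: str = ""
    panel: str = ""
    covariates: list[str] = field(default_factory=list)
    cofactors: list[int] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def hits(self, threshold: float) -> pd.DataFrame:
        t = self.table
        return t[t["p"] < threshold]


@dataclass
class MeffResult:
    """Effective number of independent tests from marker-correlation eigenvalues."""

    meff: int
    C: float
    window: int

    def __post_init__(self) -> None:
        if self.meff < 1:
            raise ValueError("Meff must be >= 1")


@dataclass
class TranscriptAssociation:
    """Transcript × trait regression slopes, p-values and overlap sets."""

    slopes: pd.DataFrame  # transcripts × traits
    pvalues: pd.DataFrame
    threshold: float
    significant: dict[str, set[str]]
    overlaps: dict[tuple[str, ...], int]


def _scan_markers(yt, Xt, Mt, v, df_resid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-marker GLS regression in the spectral basis.

    yt/Xt/Mt are the rotated response, covariates and marker columns;
    v the per-observation variances.  Each marker is residualized against
    the covariates under the GLS inner product and tested by a t-test.
    """
    w = 1.0 / v
    Xw = Xt * w[:, None]
    XtVX_inv = np.linalg.inv(Xt.T @ Xw)
    # residualize y and markers against covariates
    by = XtVX_inv @ (Xw.T @ yt)
    ry = yt - Xt @ by
    BM = XtVX_inv @ (Xw.T @ Mt)
    RM = Mt - Xt @ BM
    mm = np.einsum("ij,i,ij->j", RM, w, RM)
    my = RM.T @ (w * ry)
    yy = float(ry @ (w * ry))
    with np.errstate(invalid="ignore", divide="ignore"):
        effect = my / mm
        rss = yy - effect * my
        sigma2 = rss / df_resid
        se = np.sqrt(sigma2 / mm)
        tval = effect / se
    p = 2.0 * stats.t.sf(np.abs(tval), df=df_resid)
    bad = ~np.isfinite(tval)
    effect[bad], se[bad], p[bad] = np.nan, np.nan, np.nan
    return effect, se, p


def gwas_scan(
    g: GenotypeMatrix,
    y,
    K: KinshipMatrix | None = None,
    pcs: pd.DataFrame | np.ndarray | None = None,
    stepwise_max: int = 0,
) -> AssociationResult:
    """Single-marker mixed-model association scan.

    Variance components are estimated once under the null model (kinship
    random effect + covariates) and reused for every marker.  With
    ``stepwise_max > 0`` the scan iterates, adding the most significant
    marker as a fixed cofactor and re-estimating, up to the cap.
    Monomorphic markers receive missing p-values.
    """
    if isinstance(y, pd.Series):
        y = y.loc[g.accessions]
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y)
    y = y[mask]
    M = g.dosages[mask, :]
    n = len(y)

    cov_parts, cov_names = [], []
    if pcs is not None:
        P = pcs.to_numpy() if isinstance(pcs, pd.DataFrame) else np.asarray(pcs, dtype=float)
        cov_parts.append(P[mask])
        cov_names = (
            list(pcs.columns) if isinstance(pcs, pd.DataFrame)
            else [f"PC{i + 1}" for i in range(P.shape[1])]
        )
    X = np.column_stack([np.ones(n)] + cov_parts) if cov_parts else np.ones((n, 1))

    use_kinship = K is not None
    if use_kinship:
        Ka = K.to_numpy()[np.ix_(mask, mask)]
        if np.allclose(Ka, 0.0):
            use_kinship = False

    cofactors: list[int] = []
    for _ in range(max(stepwise_max, 0) + 1):
        Xfull = np.column_stack([X] + [M[:, [j]] for j in cofactors]) if cofactors else X
        if use_kinship:
            vc = reml_variance_components(y, Ka, covariates=Xfull[:, 1:] if Xfull.shape[1] > 1 else None)
            delta = vc.sigma2_e / vc.sigma2_g if vc.sigma2_g > 0 else np.inf
            if np.isfinite(delta):
                d, U = np.linalg.eigh(_normalize_kinship(Ka))
                d = np.clip(d, 0.0, None)
                v = d + delta
                yt, Xt, Mt = U.T @ y, U.T @ Xfull, U.T @ M
            else:
                v = np.ones(n)
                yt, Xt, Mt = y, Xfull, M
        else:
            v = np.ones(n)
            yt, Xt, Mt = y, Xfull, M
        df_resid = n - Xt.shape[1] - 1
        effect, se, p = _scan_markers(yt, Xt, Mt, v, df_resid)
        # monomorphic in the tested subset
        mono = np.nanstd(M, axis=0) == 0.0
        effect[mono], se[mono], p[mono] = np.nan, np.nan, np.nan
        for j in cofactors:
            effect[j], se[j], p[j] = np.nan, np.nan, np.nan
        if len(cofactors) >= stepwise_max:
            break
        best = int(np.nanargmin(p))
        cofactors.append(best)

    table = pd.DataFrame(
        {
            "chrom": g.markers["chrom"].to_numpy(),
            "pos": g.markers["pos"].to_numpy(),
            "effect": effect,
            "se": se,
            "p": p,
        }
    )
    return AssociationResult(
        table=table,
        covariates=cov_names,
        cofactors=cofactors,
    )


def simplem_meff(
    g: GenotypeMatrix, C: float = 0.995, window: int = 1000
) -> MeffResult:
    """Effective number of independent tests from marker correlations.

    Per chromosome, markers are processed in consecutive blocks of
    ``window``; each block contributes the smallest k whose top-k
    eigenvalues of the marker correlation matrix explain at least ``C`` of
    the total variance.  Constant markers carry no test and are skipped.
    """
    if not (0.0 < C < 1.0):
        raise ValueError(f"cumulative-variance parameter C must be in (0,1), got {C}")
    total = 0
    for chrom, grp in g.markers.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        for start in range(0, len(idx), window):
            cols = idx[start:start + window]
            block = g.dosages[:, cols]
            sd = block.std(axis=0, ddof=0)
            block = block[:, sd > 0]
            if block.shape[1] == 0:
                continue
            if block.shape[1] == 1:
                total += 1
                continue
            corr = np.corrcoef(block, rowvar=False)
            eigvals = np.linalg.eigvalsh(corr)[::-1]
            eigvals = np.clip(eigvals, 0.0, None)
            frac = np.cumsum(eigvals) / np.sum(eigvals)
            total += int(np.searchsorted(frac, C) + 1)
    return MeffResult(meff=max(total, 1), C=C, window=window)


def significance_thresholds(
    n_loci: int | None = None,
    genotypes: GenotypeMatrix | None = None,
    alpha: float = 0.05,
    C: float = 0.995,
    meff: int | None = None,
    window: int = 1000,
) -> dict:
    """Bonferroni and SimpleM significance thresholds for a scan.

    ``bonferroni = alpha / n_loci``; ``simplem = alpha / Meff`` where Meff
    is the effective number of independent tests, either supplied directly
    (e.g. from a previously computed value) or derived from the genotype
    panel's marker-correlation eigenvalues.
    """
    if not (0.0 < C < 1.0):
        raise ValueError(f"cumulative-variance parameter C must be in (0,1), got {C}")
    if n_loci is None:
        if genotypes is None:
            raise ValueError("need n_loci or a genotype panel")
        n_loci = genotypes.n_markers
    if meff is None and genotypes is not None:
        meff = simplem_meff(genotypes, C=C, window=window).meff
    out = {"bonferroni": alpha / n_loci, "meff": meff}
    out["simplem"] = alpha / meff if meff else None
    return out


def candidate_windows(
    hits: pd.DataFrame | AssociationResult,
    genes: GeneTable | pd.DataFrame,
    half_window: int = 50_000,
) -> pd.DataFrame:
    """Genes overlapping ±``half_window`` bp around each association peak.

    Intervals are 1-based inclusive; the window is clipped at position 1.
    A gene is reported when [start, end] intersects [pos − hw, pos + hw].
    Raises if hit chromosomes are absent from the gene annotation.
    """
    hdf = hits.table if isinstance(hits, AssociationResult) else hits
    gdf = genes.data if isinstance(genes, GeneTable) else genes
    hit_chroms = set(hdf["chrom"].unique())
    gene_chroms = set(gdf["chrom"].unique())
    unmatched = sorted(hit_chroms - gene_chroms)
    if unmatched:
        raise ValueError(f"hit chromosomes not in gene annotation: {unmatched}")
    rows = []
    for _, hit in hdf.iterrows():
        lo = max(int(hit["pos"]) - half_window, 1)
        hi = int(hit["pos"]) + half_window
        on_chrom = gdf[gdf["chrom"] == hit["chrom"]]
        overlap = on_chrom[(on_chrom["start"] <= hi) & (on_chrom["end"] >= lo)]
        for _, gene in overlap.iterrows():
            rows.append(
                {
                    "chrom": hit["chrom"],
                    "peak_pos": int(hit["pos"]),
                    "gene_id": gene["gene_id"],
                    "gene_start": int(gene["start"]),
                    "gene_end": int(gene["end"]),
                    "distance": int(
                        0
                        if gene["start"] <= hit["pos"] <= gene["end"]
                        else min(
                            abs(gene["start"] - hit["pos"]), abs(gene["end"] - hit["pos"])
                        )
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "peak_pos", "gene_id", "gene_start", "gene_end", "distance"],
    )


def transcript_scan(
    expression: pd.DataFrame,
    traits: pd.DataFrame,
    alpha: float = 0.05,
    relaxation: float = 10.0,
    exclude: tuple[str, ...] = ("TGW",),
) -> TranscriptAssociation:
    """Per-transcript simple regressions against each trait.

    Significance uses a relaxed Bonferroni rule: p < ``relaxation`` ×
    (alpha / n_transcripts).  Per-trait significant sets and all pairwise
    and triple overlap counts are returned.  Constant transcripts get
    missing p-values and are never significant.
    """
    shared = [a for a in expression.index if a in traits.index]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared accessions (<3)")
    E = expression.loc[shared]
    T = traits.loc[shared, [t for t in traits.columns if t not in exclude]]
    n_transcripts = E.shape[1]
    threshold = relaxation * alpha / n_transcripts

    slopes = pd.DataFrame(index=E.columns, columns=T.columns, dtype=float)
    pvals = pd.DataFrame(index=E.columns, columns=T.columns, dtype=float)
    Ea = E.to_numpy(dtype=float)
    for trait in T.columns:
        y = T[trait].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() < 3:
            continue
        yv, Ev = y[ok], Ea[ok]
        n = len(yv)
        yc = yv - yv.mean()
        Ec = Ev - Ev.mean(axis=0)
        sy = np.sqrt(np.sum(yc**2))
        sx = np.sqrt(np.sum(Ec**2, axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Ec.T @ yc) / (sx * sy)
            slope = r * sy / sx
            tval = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(tval), df=n - 2)
        const = sx == 0.0
        slope[const], p[const] = np.nan, np.nan
        slopes[trait], pvals[trait] = slope, p

    significant = {
        trait: set(pvals.index[pvals[trait] < threshold]) for trait in T.columns
    }
    overlaps: dict[tuple[str, ...], int] = {}
    for k in (2, 3):
        for combo in itertools.combinations(T.columns, k):
            inter = set.intersection(*(significant[t] for t in combo))
            overlaps[combo] = len(inter)
    return TranscriptAssociation(
        slopes=slopes, pvalues=pvals, threshold=threshold,
        significant=significant, overlaps=overlaps,
    )
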