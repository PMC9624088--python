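"""Genomic prediction: gBLUP breeding values, prediction-error variances,
and cross-environment stability ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from oryzaqg.quantgen import KinshipMatrix, _normalize_kinship, reml_variance_components


@dataclass
class BreedingValueTable:
    """Per-accession genomic breeding values with prediction-error variances.

    ``table`` columns: blup, pev, reliability (1 − PEV/σ²_g·K_ii).
    """

    table: pd.DataFrame
    sigma2_g: float
    sigma2_e: float
    environment: str = ""

    @property
    def blup(self) -> pd.Series:
        return self.table["blup"]


def gblup(y, K: KinshipMatrix, covariates=None, environment: str = "") -> BreedingValueTable:
    """Best linear unbiased prediction of additive genetic values.

    Solves û = σ²_g K V⁻¹(y − Xb̂) with V = σ²_g K + σ²_e I after REML
    estimation of the variance components; PEVs come from the prediction
    covariance σ²_g K − σ²_g K P σ²_g K with P the projection form of V⁻¹
    that accounts for fixed-effect estimation.  At h² = 0 all BLUPs are 0.
    """
    if isinstance(y, pd.Series):
        accessions = [a for a in K.accessions if a in y.index and not np.isnan(y.loc[a])]
        yv = y.loc[accessions].to_numpy(dtype=float)
        Ka = K.values.loc[accessions, accessions].to_numpy()
    else:
        yv = np.asarray(y, dtype=float)
        accessions = K.accessions
        Ka = K.to_numpy()
    Ka = _normalize_kinship(Ka)
    n = len(yv)
    X = (
        np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
        if covariates is not None
        else np.ones((n, 1))
    )
    vc = reml_variance_components(yv, Ka, covariates=X[:, 1:] if X.shape[1] > 1 else None)

    if vc.sigma2_g <= 0 or vc.h2 == 0.0:
        table = pd.DataFrame(
            {"blup": 0.0, "pev": 0.0, "reliability": 0.0},
            index=pd.Index(accessions, name="accession"),
        )
        return BreedingValueTable(table, vc.sigma2_g, vc.sigma2_e, environment)

    G = vc.sigma2_g * Ka
    V = G + vc.sigma2_e * np.eye(n)
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        warnings.warn("singular V; adding ridge")
        Vi = np.linalg.inv(V + 1e-8 * np.eye(n))
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ yv)
    r = yv - X @ beta
    u_hat = G @ Vi @ r
    # projection matrix accounting for fixed effects
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    pred_cov = G - G @ P @ G
    pev = np.clip(np.diag(pred_cov), 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        reliability = 1.0 - pev / (vc.sigma2_g * np.diag(Ka))
    table = pd.DataFrame(
        {"blup": u_hat, "pev": pev, "reliability": np.clip(reliability, 0.0, 1.0)},
        index=pd.Index(accessions, name="accession"),
    )
    return BreedingValueTable(table, vc.sigma2_g, vc.sigma2_e, environment)


def rank_accessions(
    wet, dry, precomputed_ranks: bool = False
) -> pd.DataFrame:
    """Cross-environment stability ranking of breeding values.

    Accessions are ranked within each environment in descending order of
    breeding value (best fitness = rank 1; ties averaged); the cumulative
    rank is the sum of the two per-environment ranks and the result is
    sorted ascending by it (most stable high-fitness accession first).
    With ``precomputed_ranks`` the inputs are taken as ranks directly.
    """
    wet_s = wet.blup if isinstance(wet, BreedingValueTable) else pd.Series(wet)
    dry_s = dry.blup if isinstance(dry, BreedingValueTable) else pd.Series(dry)
    shared = [a for a in wet_s.index if a in dry_s.index]
    if not shared:
        raise ValueError("no shared accessions between environments")
    wet_s, dry_s = wet_s.loc[shared].astype(float), dry_s.loc[shared].astype(float)
    if precomputed_ranks:
        wet_rank, dry_rank = wet_s, dry_s
    else:
        wet_rank = wet_s.rank(ascending=False, method="average")
        dry_rank = dry_s.rank(ascending=False, method="average")
    out = pd.DataFrame(
        {
            "wet_rank": wet_rank,
            "dry_rank": dry_rank,
            "cumulative_rank": wet_rank + dry_rank,
        }
    )
    return out.sort_values("cumulative_rank", kind="mergesort")
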