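"""Replicate-level phenotypes → analysis inputs.

Produces least-square (adjusted) accession means that account for the
incomplete-block field design, relative fitness per component, and
trait values standardized to zero mean and unit (sample) SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from oryzaqg.data_io import PhenotypeTable, DRY_ONLY_TRAITS


@dataclass
class TraitMatrix:
    """Accession × trait LS means for one environment, with standardization.

    ``ls_means`` holds adjusted accession means; ``means``/``sds`` are the
    population mean and sample SD (n−1 denominator) used to build the
    standardized matrix ``z``.
    """

    ls_means: pd.DataFrame
    environment: str
    means: pd.Series = field(default=None)  # type: ignore[assignment]
    sds: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.means is None:
            self.means = self.ls_means.mean(axis=0, skipna=True)
        if self.sds is None:
            self.sds = self.ls_means.std(axis=0, ddof=1, skipna=True)

    @property
    def z(self) -> pd.DataFrame:
        """Standardized LS means: (x − mean) / SD per trait."""
        return (self.ls_means - self.means) / self.sds

    def destandardize(self, z: pd.DataFrame) -> pd.DataFrame:
        return z * self.sds + self.means


@dataclass
class SelectionInputs:
    """Individual-level inputs for phenotypic selection analysis.

    ``z`` holds standardized trait values over the post-filter population,
    ``fitness`` the relative (fecundity) or binary (flowering success)
    fitness, and ``blocks`` the design factor for the mixed models.
    """

    z: pd.DataFrame
    fitness: pd.Series
    blocks: pd.Series
    component: str
    environment: str
    means: pd.Series = field(default=None)  # type: ignore[assignment]
    sds: pd.Series = field(default=None)  # type: ignore[assignment]


def standardize(x: pd.Series | np.ndarray) -> np.ndarray:
    """(x − mean)/SD with the n−1 (sample) SD denominator."""
    x = np.asarray(x, dtype=float)
    mask = ~np.isnan(x)
    mu = x[mask].mean()
    sd = x[mask].std(ddof=1)
    return (x - mu) / sd


def compute_ls_means(
    p: PhenotypeTable, environment: str, traits: list[str] | None = None
) -> TraitMatrix:
    """Least-square accession means from an additive accession + block model.

    Per trait the model ``y = accession + block`` is fit by least squares;
    the LS mean of an accession is its effect evaluated at the unweighted
    average of block effects.  In a balanced design this equals the
    arithmetic mean.  If accession and block are confounded for a trait
    (rank-deficient design) a warning is emitted and arithmetic means are
    used for that trait.
    """
    df = p.for_environment(environment)
    if df.empty:
        raise ValueError(f"no records for environment {environment!r}")
    traits = traits or p.trait_columns
    if environment == "wet":
        traits = [t for t in traits if t not in DRY_ONLY_TRAITS or df[t].notna().any()]
    accessions = sorted(df["accession"].unique())
    out = pd.DataFrame(index=pd.Index(accessions, name="accession"), columns=traits, dtype=float)

    for trait in traits:
        sub = df[["accession", "block", trait]].dropna()
        if sub.empty:
            continue
        if sub[trait].nunique() == 1:
            out[trait] = sub.groupby("accession")[trait].mean()
            continue
        acc_codes, acc_levels = pd.factorize(sub["accession"], sort=True)
        blk_codes, blk_levels = pd.factorize(sub["block"], sort=True)
        n, n_acc, n_blk = len(sub), len(acc_levels), len(blk_levels)
        # accession dummies (full set, no intercept) + block dummies (first dropped)
        X = np.zeros((n, n_acc + max(n_blk - 1, 0)))
        X[np.arange(n), acc_codes] = 1.0
        for j in range(1, n_blk):
            X[blk_codes == j, n_acc + j - 1] = 1.0
        coef, _, rank, _ = np.linalg.lstsq(X, sub[trait].to_numpy(dtype=float), rcond=None)
        if rank < X.shape[1]:
            warnings.warn(
                f"trait {trait}: accession confounded with block; "
                "falling back to arithmetic means"
            )
            out[trait] = sub.groupby("accession")[trait].mean()
            continue
        block_effects = np.concatenate([[0.0], coef[n_acc:]])
        ls = coef[:n_acc] + block_effects.mean()
        out.loc[list(acc_levels), trait] = ls
    return TraitMatrix(ls_means=out, environment=environment)


def prepare_selection_inputs(
    p: PhenotypeTable,
    environment: str,
    fitness_component: str,
    traits: list[str] | None = None,
) -> SelectionInputs:
    """Individual-level standardized traits and fitness for selection analysis.

    Order is fixed: for fecundity, zero-fitness individuals are dropped
    FIRST, then relative fitness w′ = w/mean(w) is computed, then traits
    are standardized over the post-filter population.  Flowering success is
    kept as a 0/1 vector with no filtering or normalization.
    """
    if fitness_component not in {"fecundity", "flowering_success"}:
        raise ValueError(f"unknown fitness component {fitness_component!r}")
    df = p.for_environment(environment)
    traits = traits or [t for t in p.trait_columns if df[t].notna().any()]

    if fitness_component == "fecundity":
        df = df[df["fecundity"].notna()]
        kept = df[df["fecundity"] > 0]
        if kept.empty:
            raise ValueError("all individuals have zero fecundity fitness")
        w = kept["fecundity"].astype(float)
        fitness = w / w.mean()
        df = kept
    else:
        df = df[df["flowering_success"].notna()]
        fitness = df["flowering_success"].astype(float)

    z = pd.DataFrame(index=df.index, columns=traits, dtype=float)
    means, sds = {}, {}
    for t in traits:
        x = df[t].astype(float)
        means[t] = x.mean(skipna=True)
        sds[t] = x.std(ddof=1, skipna=True)
        z[t] = (x - means[t]) / sds[t]
    return SelectionInputs(
        z=z,
        fitness=fitness.rename("fitness"),
        blocks=df["block"],
        component=fitness_component,
        environment=environment,
        means=pd.Series(means),
        sds=pd.Series(sds),
    )
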