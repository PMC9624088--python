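"""Synthetic panels with known truth for parameter-recovery testing.

Genotypes follow a Balding–Nichols model: ancestral allele frequencies are
uniform on (0.05, 0.95), subpopulation frequencies are Beta-distributed
around them at a configurable F_ST, and accessions are fully inbred
(dosage 0/2) with an optional residual heterozygosity rate — matching
landrace panels with two related subpopulation clusters.  Phenotypes are
polygenic: breeding values are drawn with covariance K ⊗ G via Cholesky
factors of the realized kinship and the planted G; replicate-level records
add incomplete-block effects and residual noise scaled so the planted h²
is recovered on the accession-mean scale (the quantity the pipeline
estimates).  Fecundity uses a log-link count surface (counts must be
nonnegative) driven by the planted linear/quadratic selection surface, and
flowering success is Bernoulli under a logistic surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from oryzaqg.data_io import GenotypeMatrix, PhenotypeTable, DRY_ONLY_TRAITS
from oryzaqg.quantgen import vanraden_grm, _normalize_kinship


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator.

    The planted G (``g_matrix``) is on the standardized accession-mean
    scale with heritabilities on the diagonal; ``beta_fecundity`` and
    ``beta_flowering`` are selection gradients per SD of trait.
    """

    traits: tuple[str, ...]
    h2: np.ndarray
    g_matrix: np.ndarray
    beta_fecundity: np.ndarray
    gamma: np.ndarray | None
    beta_flowering: np.ndarray
    alpha0_flowering: float
    block_sd: float
    mean_fecundity: float
    n_blocks: int
    n_plots: int
    n_reps: int
    fst: float
    seed: int
    fecundity_noise_sd: float = 0.3
    transcript_links: list[tuple[str, tuple[str, ...], float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.h2 = np.asarray(self.h2, dtype=float)
        self.g_matrix = np.asarray(self.g_matrix, dtype=float)
        if np.any((self.h2 < 0) | (self.h2 > 1)):
            raise ValueError("planted heritabilities must lie in [0, 1]")
        eig = np.linalg.eigvalsh(self.g_matrix)
        if eig.min() < -1e-8:
            raise ValueError("planted G-matrix is not positive semi-definite")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d


def desk_truth(
    n_traits: int = 5,
    h2: float | np.ndarray = 0.5,
    genetic_corr: float = 0.3,
    beta: np.ndarray | None = None,
    seed: int = 0,
    n_blocks: int = 10,
    n_plots: int = 10,
    n_reps: int = 3,
    fst: float = 0.1,
) -> SyntheticTruth:
    """A small default truth object for desk-scale runs.

    G has the given heritabilities on the diagonal and a constant genetic
    correlation off the diagonal; the fecundity surface is linear with a
    modest negative gradient on the last trait (emulating selection for
    earlier flowering) unless ``beta`` is given.
    """
    traits = tuple(f"T{i + 1}" for i in range(n_traits))
    h2v = np.full(n_traits, h2, dtype=float) if np.isscalar(h2) else np.asarray(h2, dtype=float)
    sd = np.sqrt(h2v)
    G = genetic_corr * np.outer(sd, sd)
    np.fill_diagonal(G, h2v)
    if beta is None:
        beta = np.zeros(n_traits)
        beta[-1] = -0.4
        beta[0] = 0.2
    return SyntheticTruth(
        traits=traits,
        h2=h2v,
        g_matrix=G,
        beta_fecundity=np.asarray(beta, dtype=float),
        gamma=None,
        beta_flowering=0.5 * np.asarray(beta, dtype=float),
        alpha0_flowering=2.2,
        block_sd=0.5,
        mean_fecundity=1200.0,
        n_blocks=n_blocks,
        n_plots=n_plots,
        n_reps=n_reps,
        fst=fst,
        seed=seed,
    )


def simulate_genotypes(
    n_acc: int = 130,
    n_snp: int = 5000,
    n_subpop: int = 2,
    fst: float = 0.1,
    seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
    residual_het: float = 0.0,
) -> GenotypeMatrix:
    """Inbred accession genotypes under a Balding–Nichols structure model."""
    if n_acc < 2:
        raise ValueError("need at least 2 accessions")
    if not (0.0 <= fst < 1.0):
        raise ValueError(f"fst must be in [0, 1), got {fst}")
    rng = np.random.default_rng(seed)
    chrom_lengths = chrom_lengths or {"chr1": 30_000_000, "chr2": 25_000_000}

    ancestral = rng.uniform(0.05, 0.95, size=n_snp)
    if fst > 0 and n_subpop > 1:
        a = ancestral * (1.0 - fst) / fst
        b = (1.0 - ancestral) * (1.0 - fst) / fst
        subpop_freq = rng.beta(a, b, size=(n_subpop, n_snp))
    else:
        subpop_freq = np.tile(ancestral, (max(n_subpop, 1), 1))
    membership = rng.integers(0, max(n_subpop, 1), size=n_acc)
    p_acc = subpop_freq[membership]  # (n_acc, n_snp)
    dosages = 2.0 * (rng.random((n_acc, n_snp)) < p_acc)
    if residual_het > 0:
        het_mask = rng.random((n_acc, n_snp)) < residual_het
        dosages[het_mask] = 1.0

    chroms = list(chrom_lengths)
    chrom_of = rng.integers(0, len(chroms), size=n_snp)
    rows = []
    order = []
    for ci, chrom in enumerate(chroms):
        idx = np.flatnonzero(chrom_of == ci)
        pos = np.sort(
            rng.choice(np.arange(1, chrom_lengths[chrom] + 1), size=len(idx), replace=False)
        )
        for j, p in zip(idx, pos):
            rows.append({"chrom": chrom, "pos": int(p), "ref": "A", "alt": "T", "depth": np.nan})
            order.append(j)
    order = np.asarray(order, dtype=int)
    markers = pd.DataFrame(rows).reset_index(drop=True)
    accessions = [f"ACC{i + 1:04d}" for i in range(n_acc)]
    gm = GenotypeMatrix(dosages=dosages[:, order], accessions=accessions, markers=markers)
    gm.subpopulation = membership  # truth attribute for tests
    return gm


def _breeding_values(K: np.ndarray, G: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw u (accessions × traits) with covariance K ⊗ G via Cholesky factors."""
    n, t = K.shape[0], G.shape[0]
    Lk = np.linalg.cholesky(_normalize_kinship(K) + 1e-6 * np.eye(n))
    eigval, eigvec = np.linalg.eigh(G)
    Lg = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))
    return Lk @ rng.standard_normal((n, t)) @ Lg.T


def simulate_phenotypes(
    g: GenotypeMatrix,
    truth: SyntheticTruth,
    environment: str = "dry",
    seed: int | None = None,
) -> PhenotypeTable:
    """Replicate-level phenotype and fitness records from the planted truth.

    Breeding values are drawn from the realized kinship of ``g`` and the
    planted G; per-replicate residual variance is set so the accession-mean
    (LS-mean) scale recovers the planted h².  Fecundity is a log-link count
    surface on the standardized replicate traits (with flowering failures
    giving zero filled grains); flowering success is logistic.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n_acc = g.n_accessions
    t = len(truth.traits)
    if n_acc > truth.n_blocks * truth.n_plots:
        raise ValueError("field layout too small for the accession panel")
    K = vanraden_grm(g).to_numpy()
    u = _breeding_values(K, truth.g_matrix, rng)

    resid_var = truth.n_reps * (1.0 - truth.h2) - truth.block_sd**2
    resid_sd = np.sqrt(np.clip(resid_var, 0.05, None))

    records = []
    values = []
    for rep in range(1, truth.n_reps + 1):
        block_eff = rng.normal(0.0, truth.block_sd, size=truth.n_blocks)
        assignment = rng.permutation(n_acc)
        for slot, acc_idx in enumerate(assignment):
            block = slot // truth.n_plots + 1
            y = u[acc_idx] + block_eff[block - 1] + rng.normal(0.0, resid_sd, size=t)
            records.append((g.accessions[acc_idx], environment, block, rep))
            values.append(y)
    values = np.asarray(values)
    z = (values - values.mean(axis=0)) / values.std(axis=0, ddof=1)

    lin = z @ truth.beta_fecundity
    quad = 0.5 * np.einsum("ij,jk,ik->i", z, truth.gamma, z) if truth.gamma is not None else 0.0
    eta = 1.0 + lin + quad + rng.normal(0.0, truth.fecundity_noise_sd, size=len(z))
    raw = np.exp(eta)
    fecundity = np.round(raw * truth.mean_fecundity / raw.mean()).astype(int)

    p_flower = 1.0 / (1.0 + np.exp(-(truth.alpha0_flowering + z @ truth.beta_flowering)))
    flowering = (rng.random(len(z)) < p_flower).astype(int)
    fecundity = fecundity * flowering

    df = pd.DataFrame(records, columns=["accession", "environment", "block", "replicate"])
    for j, trait in enumerate(truth.traits):
        df[trait] = values[:, j]
    if environment == "wet":
        for trait in truth.traits:
            if trait in DRY_ONLY_TRAITS:
                df[trait] = np.nan
    df["fecundity"] = fecundity
    df["flowering_success"] = flowering if environment == "dry" else 1
    df["yield_g"] = np.round(fecundity * truth.mean_fecundity**-1 * 25.0, 3)
    return PhenotypeTable(data=df, traits=truth.traits)


def simulate_qtl_trait(
    g: GenotypeMatrix,
    qtl_index: int,
    qtl_var: float = 0.2,
    h2_background: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Accession-level trait with one planted QTL (for GWAS power checks).

    The marker at ``qtl_index`` explains ``qtl_var`` of the phenotypic
    variance; an optional polygenic background adds kinship-structured
    variance ``h2_background``; the rest is i.i.d. noise.
    """
    rng = np.random.default_rng(seed)
    x = g.dosages[:, qtl_index]
    if x.std() == 0:
        raise ValueError("planted QTL marker is monomorphic")
    xs = (x - x.mean()) / x.std()
    y = np.sqrt(qtl_var) * xs
    if h2_background > 0:
        K = vanraden_grm(g).to_numpy()
        ub = _breeding_values(K, np.array([[1.0]]), rng)[:, 0]
        ub = (ub - ub.mean()) / ub.std()
        y = y + np.sqrt(h2_background) * ub
    noise_var = max(1.0 - qtl_var - h2_background, 1e-6)
    y = y + rng.normal(0.0, np.sqrt(noise_var), size=len(y))
    return pd.Series(y, index=g.accessions, name="qtl_trait")


def simulate_expression(
    truth_links: list[tuple[tuple[str, ...], float]],
    trait_matrix: pd.DataFrame,
    n_transcripts: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Transcript abundances with planted trait associations.

    ``truth_links`` is a list of (traits, r²) tuples; each plants one
    transcript that is a linear function of the (possibly multiple,
    pleiotropic) named trait columns plus noise, scaled so the squared
    correlation with each linked trait is ``r²`` (capped by how correlated
    the linked traits allow the shared signal to be).  Background
    transcripts are independent noise.  Returns the expression matrix and
    the planted transcript ids.
    """
    rng = np.random.default_rng(seed)
    for traits, r2 in truth_links:
        if not (0.0 <= r2 < 1.0):
            raise ValueError(f"r2 must be in [0, 1), got {r2}")
        missing = [t for t in traits if t not in trait_matrix.columns]
        if missing:
            raise ValueError(f"planted link references unknown traits: {missing}")
    n_acc = len(trait_matrix)
    E = rng.standard_normal((n_acc, n_transcripts))
    planted = []
    for k, (traits, r2) in enumerate(truth_links):
        Z = trait_matrix[list(traits)].to_numpy(dtype=float)
        Z = (Z - np.nanmean(Z, axis=0)) / np.nanstd(Z, axis=0)
        Z = np.nan_to_num(Z)
        signal = Z.sum(axis=1)
        signal = (signal - signal.mean()) / max(signal.std(), 1e-12)
        # scale so corr(transcript, each linked trait) ~ sqrt(r2)
        cors = np.array([np.corrcoef(signal, Z[:, j])[0, 1] for j in range(Z.shape[1])])
        alpha = min(np.sqrt(r2) / max(cors.mean(), 1e-12), 1.0)
        E[:, k] = alpha * signal + np.sqrt(1 - alpha**2) * rng.standard_normal(n_acc)
        planted.append(f"TR{k + 1:05d}")
    cols = [f"TR{j + 1:05d}" for j in range(n_transcripts)]
    return pd.DataFrame(E, index=trait_matrix.index, columns=cols), planted
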