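"""Readers, writers and quality control for phenotype, genotype and annotation data.

Coordinates are 1-based inclusive throughout (VCF/GFF convention).  Genotypes
are stored as alternate-allele dosage (0/1/2, ``nan`` = missing); phased and
unphased calls are treated identically and heterozygotes always count as 1.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Registered trait codes, in canonical order.
TRAITS: tuple[str, ...] = ("XHS", "WUE", "LOP", "TNR", "LRO", "SSC", "TGW", "DTF")

#: Traits scored only under drought (xylem sap exudation, leaf rolling).
DRY_ONLY_TRAITS: frozenset[str] = frozenset({"XHS", "LRO"})

REQUIRED_PHENOTYPE_COLUMNS = ("accession", "environment", "block", "replicate")

FITNESS_COLUMNS = ("fecundity", "flowering_success", "yield_g")


class SchemaError(ValueError):
    """An input table is missing a required column or has an invalid layout."""


class EmptyPanelError(RuntimeError):
    """Quality control or filtering removed every marker or individual."""


@dataclass
class PhenotypeTable:
    """Replicate-level phenotype and fitness records with design factors.

    One row per individual plant record: accession, environment (wet/dry),
    incomplete-block design factors, measured trait values (missing when a
    trait was not scored in that environment) and fitness components.
    """

    data: pd.DataFrame
    traits: tuple[str, ...] = TRAITS

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_PHENOTYPE_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"phenotype table missing required column(s): {missing}")
        bad = set(self.data["environment"].dropna()) - {"wet", "dry"}
        if bad:
            raise SchemaError(f"unknown environment label(s): {sorted(bad)}")
        if "flowering_success" in self.data.columns:
            vals = set(self.data["flowering_success"].dropna().unique())
            if not vals <= {0, 1, 0.0, 1.0}:
                raise SchemaError("flowering_success must be binary (0/1)")

    @property
    def trait_columns(self) -> list[str]:
        return [t for t in self.traits if t in self.data.columns]

    def for_environment(self, environment: str) -> pd.DataFrame:
        return self.data[self.data["environment"] == environment].copy()

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class GenotypeMatrix:
    """Accession × SNP alternate-allele dosage matrix with marker metadata.

    ``dosages`` holds 0/1/2 with ``nan`` for missing calls.  Marker metadata
    carries chromosome, 1-based position, ref/alt alleles and (optionally)
    the panel-summed read depth from the VCF ``DP`` field.
    """

    dosages: np.ndarray
    accessions: list[str]
    markers: pd.DataFrame  # columns: chrom, pos, ref, alt [, depth]

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.accessions), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.accessions)} accessions x {len(self.markers)} markers"
            )
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def alt_freq(self) -> np.ndarray:
        """Per-marker alternate-allele frequency among non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def het_rate(self) -> np.ndarray:
        """Per-marker observed heterozygosity among non-missing calls."""
        het = (self.dosages == 1).sum(axis=0)
        n = (~np.isnan(self.dosages)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, het / n, np.nan)

    def accession_het_fraction(self) -> np.ndarray:
        """Per-accession fraction of heterozygous calls (inbreeding check)."""
        het = (self.dosages == 1).sum(axis=1)
        n = (~np.isnan(self.dosages)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, het / n, np.nan)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[:, keep],
            accessions=list(self.accessions),
            markers=self.markers.iloc[np.asarray(keep)].reset_index(drop=True),
        )

    def subset_accessions(self, keep: Sequence[str] | np.ndarray) -> "GenotypeMatrix":
        if np.asarray(keep).dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            lookup = {a: i for i, a in enumerate(self.accessions)}
            idx = np.array([lookup[a] for a in keep])
        return GenotypeMatrix(
            dosages=self.dosages[idx, :],
            accessions=[self.accessions[i] for i in idx],
            markers=self.markers.copy().reset_index(drop=True),
        )


@dataclass
class GeneTable:
    """Gene annotation records with 1-based inclusive coordinates."""

    data: pd.DataFrame  # columns: gene_id, chrom, start, end [, strand, description]

    def __post_init__(self) -> None:
        missing = [c for c in ("gene_id", "chrom", "start", "end") if c not in self.data.columns]
        if missing:
            raise SchemaError(f"gene table missing column(s): {missing}")
        if (self.data["start"] > self.data["end"]).any():
            raise ValueError("gene table has start > end")


@dataclass
class QCConfig:
    """SNP and accession quality-control thresholds.

    Defaults follow a two-stage filtering scheme used for deep-coverage
    inbred panels: a permissive call-rate pass, removal of rare alleles, a
    panel-level depth window, a stricter call-rate pass, low observed
    marker heterozygosity, and removal of insufficiently inbred accessions.
    """

    call_rate_stage1: float = 0.80
    maf_min: float = 0.05
    depth_range: tuple[float, float] | None = (1500, 4000)
    call_rate_stage2: float = 0.90
    het_max: float = 0.10
    accession_homozygosity_min: float = 0.70
    impute: bool = True


def read_phenotypes(
    path: str | Path, trait_registry: Sequence[str] | None = None
) -> PhenotypeTable:
    """Read a delimited phenotype file into a typed :class:`PhenotypeTable`.

    With no explicit ``trait_registry`` the registered trait codes are used
    when present; otherwise every non-design, non-fitness column is treated
    as a trait (covers synthetic panels with generic trait names).
    Unparseable numeric entries in trait and fitness columns become missing
    values; the count of coerced cells is logged.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in REQUIRED_PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"phenotype file {path} missing required column(s): {missing}")
    if trait_registry is None:
        if any(t in df.columns for t in TRAITS):
            trait_registry = TRAITS
        else:
            reserved = set(REQUIRED_PHENOTYPE_COLUMNS) | set(FITNESS_COLUMNS)
            trait_registry = tuple(c for c in df.columns if c not in reserved)
    traits = tuple(t for t in trait_registry if t in df.columns)
    n_coerced = 0
    for col in list(traits) + [c for c in FITNESS_COLUMNS if c in df.columns]:
        before = df[col].notna().sum()
        df[col] = pd.to_numeric(df[col], errors="coerce")
        n_coerced += int(before - df[col].notna().sum())
    if n_coerced:
        logger.warning("coerced %d unparseable numeric cells to missing", n_coerced)
    df["block"] = df["block"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    df["accession"] = df["accession"].astype(str)
    return PhenotypeTable(data=df, traits=tuple(trait_registry))


def load_genotypes(vcf_path: str | Path) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records and non-SNP variants are excluded (count logged).
    Dosage is the count of alternate alleles; half-missing diploid calls
    are treated as missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    accessions = list(vcf.samples)
    rows: list[dict] = []
    dosage_rows: list[np.ndarray] = []
    n_excluded = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            n_excluded += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = variant.gt_types.astype(float)
        gt[gt == 3] = np.nan
        dosage_rows.append(gt)
        depth = variant.INFO.get("DP")
        rows.append(
            {
                "chrom": variant.CHROM,
                "pos": variant.POS,
                "ref": variant.REF,
                "alt": variant.ALT[0],
                "depth": np.nan if depth is None else float(depth),
            }
        )
    if n_excluded:
        logger.info("excluded %d multiallelic/non-SNP records", n_excluded)
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "depth"])
    dosages = (
        np.column_stack(dosage_rows) if dosage_rows else np.empty((len(accessions), 0))
    )
    return GenotypeMatrix(dosages=dosages, accessions=accessions, markers=markers)


def impute_mean(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-marker mean of observed calls.

    Leaves per-marker mean dosage (hence allele frequency) unchanged.
    """
    out = dosages.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_means = np.nanmean(out, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    nan_r, nan_c = np.nonzero(np.isnan(out))
    out[nan_r, nan_c] = col_means[nan_c]
    return out


def apply_snp_qc(g: GenotypeMatrix, cfg: QCConfig | None = None) -> tuple[GenotypeMatrix, dict]:
    """Apply marker and accession quality-control filters in a fixed order.

    Filter order: stage-1 call rate → MAF → depth window → stage-2 call
    rate → marker heterozygosity → accession homozygosity; missing dosages
    are then mean-imputed (if enabled).  Returns the filtered panel and a
    ledger of counts removed per rule; ledger marker counts sum to
    (input markers − output markers).
    """
    cfg = cfg or QCConfig()
    ledger: dict[str, int] = {}
    current = g

    def marker_filter(name: str, keep: np.ndarray) -> None:
        nonlocal current
        ledger[name] = int((~keep).sum())
        current = current.subset_markers(keep)

    marker_filter("call_rate_stage1", current.call_rate() >= cfg.call_rate_stage1)
    with np.errstate(invalid="ignore"):
        marker_filter("maf", current.maf() >= cfg.maf_min)
    if cfg.depth_range is not None:
        depth = current.markers["depth"].to_numpy(dtype=float)
        if np.all(np.isnan(depth)):
            warnings.warn("no DP depth information in VCF; depth filter skipped")
            ledger["depth"] = 0
        else:
            lo, hi = cfg.depth_range
            marker_filter("depth", (depth >= lo) & (depth <= hi))
    marker_filter("call_rate_stage2", current.call_rate() > cfg.call_rate_stage2)
    with np.errstate(invalid="ignore"):
        marker_filter("het_rate", current.het_rate() < cfg.het_max)

    het_acc = current.accession_het_fraction()
    keep_acc = (1.0 - het_acc) >= cfg.accession_homozygosity_min
    ledger["accessions_removed"] = int((~keep_acc).sum())
    current = current.subset_accessions(keep_acc)

    if current.n_markers == 0:
        raise EmptyPanelError("all markers removed by quality control")
    if current.n_accessions == 0:
        raise EmptyPanelError("all accessions removed by homozygosity filter")

    if cfg.impute:
        current = replace(current, dosages=impute_mean(current.dosages))
    return current, ledger


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict:
    """Write each result table to TSV plus a JSON manifest.

    The manifest records table names, row counts, the configuration hash
    and the seed, enabling byte-level reproducibility checks.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tables": {},
        "config_hash": config_hash(dict(config) if config else {}),
        "seed": seed,
    }
    for name, table in tables.items():
        path = out / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=isinstance(table.index, pd.Index) and table.index.name is not None)
        manifest["tables"][name] = {"path": path.name, "rows": int(len(table))}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_gene_table(path: str | Path) -> GeneTable:
    """Read gene annotations from GFF3 or a 4+-column BED-like TSV.

    BED input (0-based half-open) is converted to 1-based inclusive.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9 or parts[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                rows.append(
                    {
                        "gene_id": attrs.get("ID", attrs.get("gene_id", "NA")),
                        "chrom": parts[0],
                        "start": int(parts[3]),
                        "end": int(parts[4]),
                        "strand": parts[6],
                        "description": attrs.get("description", ""),
                    }
                )
        return GeneTable(pd.DataFrame(rows))
    df = pd.read_csv(path, sep="\t", header=None if _looks_headerless(path) else 0)
    if df.columns.dtype != object or "gene_id" not in df.columns:
        df = df.iloc[:, :4]
        df.columns = ["chrom", "start", "end", "gene_id"]
        df["start"] = df["start"].astype(int) + 1  # BED 0-based start
    return GeneTable(df)


def _looks_headerless(path: Path) -> bool:
    with open(path) as fh:
        first = fh.readline().split("\t")
    try:
        int(first[1])
        return True
    except (ValueError, IndexError):
        return False
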