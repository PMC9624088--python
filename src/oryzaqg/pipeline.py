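"""End-to-end orchestration of the analysis with reproducibility metadata.

Stage order: prep → grm → selection (per fitness component, then combined)
→ gmatrix → respond → gwas → transcripts → gblup.  Each stage writes its
outputs and a manifest entry; stages whose outputs already exist under the
same configuration hash are skipped on resume, so deleting an intermediate
recomputes only the downstream stages that consume it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from oryzaqg import association, breeders, prediction, quantgen, selection, simulate
from oryzaqg.data_io import (
    PhenotypeTable,
    config_hash,
    load_genotypes,
    read_phenotypes,
)
from oryzaqg.phenotype_prep import compute_ls_means, prepare_selection_inputs

logger = logging.getLogger(__name__)

STAGES = ("prep", "grm", "selection", "gmatrix", "respond", "gwas", "transcripts", "gblup")

_KNOWN_KEYS = {
    "vcf", "phenotypes", "expression", "annotation", "out_dir", "seed",
    "environment", "panel", "simulate", "n_accessions", "n_snps", "n_traits",
    "h2", "quadratic", "double_gamma", "stepwise_max", "simplem_c",
    "ld_window_bp", "meff_window", "n_pcs", "n_transcripts",
}


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run; unknown keys are rejected."""

    out_dir: str = "results"
    seed: int = 0
    environment: str = "dry"
    panel: str = "synthetic"
    vcf: str | None = None
    phenotypes: str | None = None
    expression: str | None = None
    annotation: str | None = None
    simulate: bool = True
    n_accessions: int = 100
    n_snps: int = 2000
    n_traits: int = 5
    h2: float = 0.5
    quadratic: bool = False
    double_gamma: bool = False
    stepwise_max: int = 0
    simplem_c: float = 0.995
    ld_window_bp: int = 1000
    meff_window: int = 1000
    n_pcs: int = 4
    n_transcripts: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        return config_hash(asdict(self))


def _stage_done(out: Path, stage: str, cfg_hash: str) -> bool:
    marker = out / stage / ".done"
    if not marker.exists():
        return False
    return marker.read_text().strip() == cfg_hash


def _mark_done(out: Path, stage: str, cfg_hash: str) -> None:
    (out / stage / ".done").write_text(cfg_hash)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest.

    On error the pipeline halts with the stage name and cause; outputs of
    completed stages are preserved and reused on the next invocation.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    manifest: dict = {"config_hash": cfg_hash, "seed": config.seed, "stages": {}}

    rng_seed = config.seed
    env = config.environment

    # ---- inputs --------------------------------------------------------
    if config.simulate:
        truth = simulate.desk_truth(
            n_traits=config.n_traits, h2=config.h2, seed=rng_seed,
            n_blocks=max(10, -(-config.n_accessions // 10)),
        )
        geno = simulate.simulate_genotypes(
            n_acc=config.n_accessions, n_snp=config.n_snps, seed=rng_seed
        )
        pheno = simulate.simulate_phenotypes(geno, truth, environment=env, seed=rng_seed + 1)
    else:
        if not (config.vcf and config.phenotypes):
            raise ValueError("non-simulated runs require vcf and phenotypes paths")
        geno = load_genotypes(config.vcf)
        pheno = read_phenotypes(config.phenotypes)
        truth = None

    stale = False  # once a stage reruns, everything downstream reruns too

    def run_stage(name: str, fn):
        nonlocal stale
        stage_dir = out / name
        up_to_date = _stage_done(out, name, cfg_hash) and not stale
        stage_dir.mkdir(parents=True, exist_ok=True)
        t0 = time.time()
        try:
            result = fn(stage_dir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        elapsed = time.time() - t0
        outputs = sorted(p.name for p in stage_dir.glob("*.tsv"))
        if up_to_date:
            logger.info("stage %s up to date", name)
            manifest["stages"][name] = {"skipped": True, "outputs": outputs}
        else:
            stale = True
            _mark_done(out, name, cfg_hash)
            manifest["stages"][name] = {"outputs": outputs, "elapsed_s": round(elapsed, 3)}
            logger.info("stage %s done in %.2fs (%d outputs)", name, elapsed, len(outputs))
        return result

    state: dict = {}

    def prep(d: Path):
        tm = compute_ls_means(pheno, env)
        inputs = prepare_selection_inputs(pheno, env, "fecundity")
        tm.ls_means.to_csv(d / "ls_means.tsv", sep="\t")
        tm.z.to_csv(d / "z_traits.tsv", sep="\t")
        inputs.fitness.to_frame().to_csv(d / "fitness.tsv", sep="\t")
        return {"trait_matrix": tm, "inputs": inputs}

    state.update(run_stage("prep", prep) or {})

    def grm(d: Path):
        pruned = quantgen.ld_prune(geno, window_bp=config.ld_window_bp, seed=rng_seed)
        K = quantgen.vanraden_grm(pruned)
        pcs = quantgen.genotype_pca(geno, n_pc=min(config.n_pcs, geno.n_accessions - 1))
        K.values.to_csv(d / "kinship.tsv", sep="\t")
        pcs.to_csv(d / "pcs.tsv", sep="\t")
        return {"kinship": K, "pcs": pcs}

    state.update(run_stage("grm", grm) or {})

    def sel(d: Path):
        inputs = state["inputs"]
        g_fec = selection.linear_gradients(
            inputs.z, inputs.fitness, inputs.blocks, component="fecundity", environment=env
        )
        grads = g_fec
        if env == "dry":
            flow = prepare_selection_inputs(pheno, env, "flowering_success")
            if flow.fitness.nunique() > 1:
                g_flow = selection.logistic_gradients(
                    flow.z, flow.fitness, flow.blocks, environment=env
                )
                grads = selection.combine_components(g_fec, g_flow)
                g_flow.table.to_csv(d / "gradients_flowering.tsv", sep="\t")
        if config.quadratic:
            gamma = selection.quadratic_gradients(
                inputs.z, inputs.fitness, inputs.blocks,
                double_diagonal=config.double_gamma,
            )
            gamma.to_csv(d / "gamma.tsv", sep="\t")
        g_fec.table.to_csv(d / "gradients_fecundity.tsv", sep="\t")
        grads.table.to_csv(d / "gradients.tsv", sep="\t")
        diffs = g_fec.table[[c for c in ("S", "se_S", "p_S", "C", "se_C", "p_C") if c in g_fec.table]]
        diffs.to_csv(d / "differentials.tsv", sep="\t")
        return {"gradients": grads}

    state.update(run_stage("selection", sel) or {})

    def gmat(d: Path):
        G = quantgen.assemble_g_matrix(
            state["trait_matrix"], state["kinship"], environment=env, panel=config.panel
        )
        G.values.to_csv(d / "gmatrix.tsv", sep="\t")
        G.pvalues.to_csv(d / "gmatrix_pvalues.tsv", sep="\t")
        return {"G": G}

    state.update(run_stage("gmatrix", gmat) or {})

    def respond(d: Path):
        shared = [t for t in state["G"].traits if t in state["gradients"].table.index]
        Gv = state["G"].values.loc[shared, shared]
        pred = breeders.predict_response(Gv, state["gradients"].table.loc[shared])
        pred.table.to_csv(d / "response.tsv", sep="\t")
        return {"response": pred}

    state.update(run_stage("respond", respond) or {})

    def gwas(d: Path):
        tm = state["trait_matrix"]
        trait = tm.z.columns[-1]
        y = tm.z[trait].loc[geno.accessions]
        scan = association.gwas_scan(
            geno, y, state["kinship"], state["pcs"], stepwise_max=config.stepwise_max
        )
        thr = association.significance_thresholds(
            genotypes=geno, C=config.simplem_c, window=config.meff_window
        )
        scan.table.to_csv(d / f"gwas_{trait}.tsv", sep="\t", index=False)
        with open(d / "thresholds.json", "w") as fh:
            json.dump(thr, fh, indent=2)
        return {"gwas": scan, "thresholds": thr}

    state.update(run_stage("gwas", gwas) or {})

    def transcripts(d: Path):
        tm = state["trait_matrix"]
        if config.expression:
            expr = pd.read_csv(config.expression, sep="\t", index_col=0)
        else:
            expr, _ = simulate.simulate_expression(
                [(tuple(tm.z.columns[:1]), 0.25)], tm.z,
                n_transcripts=config.n_transcripts, seed=rng_seed + 2,
            )
        scan = association.transcript_scan(expr, tm.z, exclude=())
        scan.pvalues.to_csv(d / "transcript_pvalues.tsv", sep="\t")
        overlaps = pd.DataFrame(
            [{"traits": "|".join(k), "count": v} for k, v in scan.overlaps.items()]
        )
        overlaps.to_csv(d / "overlaps.tsv", sep="\t", index=False)
        return {"transcripts": scan}

    state.update(run_stage("transcripts", transcripts) or {})

    def gblup_stage(d: Path):
        inputs = state["inputs"]
        fitness_by_acc = inputs.fitness.groupby(
            pheno.for_environment(env).loc[inputs.fitness.index, "accession"]
        ).mean()
        bv = prediction.gblup(fitness_by_acc, state["kinship"], environment=env)
        bv.table.to_csv(d / "breeding_values.tsv", sep="\t")
        ranks = prediction.rank_accessions(bv.blup, bv.blup)
        ranks.to_csv(d / "ranks.tsv", sep="\t")
        return {"breeding_values": bv}

    state.update(run_stage("gblup", gblup_stage) or {})

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
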