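"""Shared fixtures: small synthetic panels generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oryzaqg import (
    desk_truth,
    simulate_genotypes,
    simulate_phenotypes,
    vanraden_grm,
)


@pytest.fixture(scope="session")
def desk_genotypes():
    """100 inbred accessions × 1500 SNPs, two subpopulations."""
    return simulate_genotypes(n_acc=100, n_snp=1500, seed=7)


@pytest.fixture(scope="session")
def desk_kinship(desk_genotypes):
    return vanraden_grm(desk_genotypes)


@pytest.fixture(scope="session")
def desk_truth_obj():
    return desk_truth(n_traits=4, h2=0.5, seed=11, n_blocks=10, n_plots=10)


@pytest.fixture(scope="session")
def desk_phenotypes(desk_genotypes, desk_truth_obj):
    return simulate_phenotypes(desk_genotypes, desk_truth_obj, environment="dry", seed=12)


def write_vcf(path, genotypes, depth=None):
    """Write a GenotypeMatrix as a minimal VCF 4.2 text file (test helper)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.accessions),
    ]
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j in range(genotypes.n_markers):
        m = genotypes.markers.iloc[j]
        dp = None
        if depth is not None:
            dp = depth[j]
        elif "depth" in genotypes.markers.columns and not np.isnan(m.get("depth", np.nan)):
            dp = int(m["depth"])
        info = f"DP={int(dp)}" if dp is not None else "."
        gts = [
            code.get(genotypes.dosages[i, j], "./.")
            for i in range(genotypes.n_accessions)
        ]
        lines.append(
            f"{m['chrom']}\t{int(m['pos'])}\t.\t{m['ref']}\t{m['alt']}\t.\tPASS\t{info}\tGT\t"
            + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path
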