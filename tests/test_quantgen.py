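"""Kinship, LD pruning, REML variance components and G-matrix assembly."""

import numpy as np
import pandas as pd
import pytest

from oryzaqg import (
    GenotypeMatrix,
    assemble_g_matrix,
    genetic_covariance,
    genotype_pca,
    ld_prune,
    reml_variance_components,
    simulate_genotypes,
    vanraden_grm,
)
from oryzaqg.phenotype_prep import TraitMatrix
from oryzaqg.quantgen import reml_loglik_naive, _normalize_kinship
from oryzaqg.simulate import _breeding_values


def _panel(accession_rows, positions=None, chrom="chr1"):
    dosages = np.array(accession_rows, dtype=float)
    n_acc, n_snp = dosages.shape
    positions = positions or list(range(100, 100 + 100 * n_snp, 100))
    markers = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "T", "depth": np.nan}
    )
    return GenotypeMatrix(
        dosages=dosages, accessions=[f"A{i}" for i in range(n_acc)], markers=markers
    )


class TestLdPrune:
    def test_one_snp_per_kilobase_bin(self):
        g = _panel([[0, 2, 0], [2, 0, 2]], positions=[10, 500, 1500])
        out = ld_prune(g, window_bp=1000, seed=0)
        assert out.n_markers == 2  # bins [1,1000] and [1001,2000]

    def test_same_seed_is_deterministic(self, desk_genotypes):
        a = ld_prune(desk_genotypes, seed=42)
        b = ld_prune(desk_genotypes, seed=42)
        np.testing.assert_array_equal(a.markers["pos"], b.markers["pos"])

    def test_retained_count_equals_occupied_bins_oracle(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(np.arange(1, 100_001), size=300, replace=False))
        g = _panel([list(rng.integers(0, 2, 300) * 2) for _ in range(5)], positions=list(pos))
        out = ld_prune(g, window_bp=1000, seed=3)
        occupied = len({(p - 1) // 1000 for p in pos})
        assert out.n_markers == occupied


class TestVanRadenGrm:
    def test_duplicate_accessions_have_maximal_kinship(self):
        g = _panel([[0, 0, 2], [2, 2, 0], [0, 0, 2], [2, 2, 2]])
        K = vanraden_grm(g).values
        # accessions 0 and 2 are identical rows
        assert K.iloc[0, 2] == pytest.approx(K.iloc[0, 0])

    def test_single_snp_closed_form(self):
        g = _panel([[0], [2]])
        K = vanraden_grm(g).to_numpy()
        np.testing.assert_allclose(K, [[2, -2], [-2, 2]], atol=1e-12)

    def test_matches_elementwise_formula_oracle(self):
        rng = np.random.default_rng(2)
        g = _panel([list(2 * rng.integers(0, 2, 100)) for _ in range(20)])
        K = vanraden_grm(g).to_numpy()
        d = g.dosages
        p = d.mean(axis=0) / 2
        poly = (p > 0) & (p < 1)
        W = d[:, poly] - 2 * p[poly]
        denom = 2 * np.sum(p[poly] * (1 - p[poly]))
        expected = np.empty((20, 20))
        for i in range(20):
            for j in range(20):
                expected[i, j] = np.dot(W[i], W[j]) / denom
        np.testing.assert_allclose(K, expected, atol=1e-12)

    def test_symmetric_and_psd(self, desk_kinship):
        K = desk_kinship.to_numpy()
        np.testing.assert_allclose(K, K.T, atol=1e-10)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestGenotypePca:
    def test_separates_divergent_subpopulations(self):
        g = simulate_genotypes(n_acc=60, n_snp=800, fst=0.3, seed=5)
        pcs = genotype_pca(g, n_pc=2)
        pc1 = pcs["PC1"].to_numpy()
        m = g.subpopulation
        lo = max(pc1[m == 0].max(), pc1[m == 1].max())
        hi = min(pc1[m == 0].min(), pc1[m == 1].min())
        # groups fully separated along PC1 (no overlap)
        assert (pc1[m == 0].max() < pc1[m == 1].min()) or (
            pc1[m == 1].max() < pc1[m == 0].min()
        )

    def test_orthogonal_scores_and_variance_fractions(self, desk_genotypes):
        pcs = genotype_pca(desk_genotypes, n_pc=4)
        gram = pcs.to_numpy().T @ pcs.to_numpy()
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-6)
        assert pcs.attrs["explained_variance_ratio"].sum() <= 1.0 + 1e-12

    def test_too_many_components_raises(self, desk_genotypes):
        with pytest.raises(ValueError, match="n_pc"):
            genotype_pca(desk_genotypes, n_pc=desk_genotypes.n_accessions)


class TestRemlVarianceComponents:
    def test_pure_noise_gives_low_h2(self):
        g = simulate_genotypes(n_acc=200, n_snp=1500, seed=21)
        K = vanraden_grm(g)
        ests = []
        for rep in range(60):
            y = np.random.default_rng(rep).normal(size=200)
            ests.append(reml_variance_components(y, K).h2)
        assert np.mean(ests) < 0.1

    def test_planted_h2_recovered(self):
        g = simulate_genotypes(n_acc=200, n_snp=1500, seed=6)
        K = vanraden_grm(g)
        ests = []
        for rep in range(15):
            rng = np.random.default_rng(400 + rep)
            u = _breeding_values(K.to_numpy(), np.array([[0.8]]), rng)[:, 0]
            y = u + rng.normal(0, np.sqrt(0.2), 200)
            ests.append(reml_variance_components(y, K).h2)
        assert 0.7 <= np.mean(ests) <= 0.9

    def test_optimizer_attains_grid_search_optimum(self, desk_kinship):
        rng = np.random.default_rng(7)
        u = _breeding_values(desk_kinship.to_numpy(), np.array([[0.5]]), rng)[:, 0]
        y = u + rng.normal(0, np.sqrt(0.5), 100)
        vc = reml_variance_components(y, desk_kinship)
        # brute-force oracle over 1000 grid points of log10(delta)
        from oryzaqg.quantgen import _spectral_setup, _profiled_reml

        yv, X, d, U = _spectral_setup(y, desk_kinship, None)
        yt, Xt = U.T @ yv, U.T @ X
        grid = np.linspace(-8, 8, 1000)
        crits = [_profiled_reml(yt, Xt, d, x)[0] for x in grid]
        delta_fit = vc.sigma2_e / vc.sigma2_g
        fit_crit = _profiled_reml(yt, Xt, d, np.log10(delta_fit))[0]
        assert fit_crit <= min(crits) + 1e-4

    def test_spectral_equals_naive_loglik_at_random_points(self, desk_kinship):
        rng = np.random.default_rng(8)
        y = rng.normal(size=100)
        from oryzaqg.quantgen import _spectral_setup, _profiled_reml

        yv, X, d, U = _spectral_setup(y, desk_kinship, None)
        yt, Xt = U.T @ yv, U.T @ X
        n, p = Xt.shape
        for log10_delta in rng.uniform(-3, 3, 10):
            crit, s2g = _profiled_reml(yt, Xt, d, log10_delta)
            ll_spec = -crit - 0.5 * (n - p) * (np.log(2 * np.pi) + 1.0)
            ll_naive = reml_loglik_naive(y, desk_kinship, None, s2g, 10.0**log10_delta * s2g)
            assert ll_spec == pytest.approx(ll_naive, abs=1e-8)

    def test_h2_boundaries_clamped(self, desk_kinship):
        K = desk_kinship
        # noise-free genetic draws push h2 to (or near) the upper boundary
        his = []
        for rep in range(10):
            u = _breeding_values(K.to_numpy(), np.array([[1.0]]), np.random.default_rng(rep))[:, 0]
            his.append(reml_variance_components(u, K).h2)
        assert np.mean(his) > 0.8
        assert max(his) == 1.0  # boundary draw clamps exactly to 1
        # estimates always live inside [0, 1]
        for rep in range(5):
            y = np.random.default_rng(100 + rep).normal(size=100)
            vc = reml_variance_components(y, K)
            assert 0.0 <= vc.h2 <= 1.0


class TestGeneticCovariance:
    def test_self_covariance_equals_h2(self, desk_kinship):
        rng = np.random.default_rng(11)
        u = _breeding_values(desk_kinship.to_numpy(), np.array([[0.6]]), rng)[:, 0]
        y = u + rng.normal(0, np.sqrt(0.4), 100)
        y = (y - y.mean()) / y.std(ddof=1)
        vc = reml_variance_components(y, desk_kinship)
        cov, _ = genetic_covariance(y, y.copy(), desk_kinship, test="none")
        assert cov == pytest.approx(vc.h2 * np.var(y, ddof=1), abs=1e-6)

    def test_symmetric_in_arguments(self, desk_kinship):
        rng = np.random.default_rng(12)
        y1 = rng.normal(size=100)
        y2 = rng.normal(size=100)
        c12, _ = genetic_covariance(y1, y2, desk_kinship, test="none")
        c21, _ = genetic_covariance(y2, y1, desk_kinship, test="none")
        assert c12 == pytest.approx(c21, abs=1e-10)

    def test_independent_traits_have_near_zero_covariance(self):
        g = simulate_genotypes(n_acc=150, n_snp=1200, seed=13)
        K = vanraden_grm(g)
        covs = []
        for rep in range(15):
            rng = np.random.default_rng(500 + rep)
            G = np.diag([0.5, 0.5])
            u = _breeding_values(K.to_numpy(), G, rng)
            y1 = u[:, 0] + rng.normal(0, np.sqrt(0.5), 150)
            y2 = u[:, 1] + rng.normal(0, np.sqrt(0.5), 150)
            covs.append(genetic_covariance(y1, y2, K, test="none")[0])
        assert abs(np.mean(covs)) < 0.1

    def test_too_few_shared_accessions_raises(self, desk_kinship):
        y = pd.Series(np.arange(5.0), index=desk_kinship.accessions[:5])
        with pytest.raises(ValueError, match="shared accessions"):
            genetic_covariance(y, y, desk_kinship)


class TestAssembleGMatrix:
    def test_symmetry_diag_range_and_masking(self, desk_kinship):
        rng = np.random.default_rng(14)
        G_true = np.array([[0.6, 0.2], [0.2, 0.4]])
        u = _breeding_values(desk_kinship.to_numpy(), G_true, rng)
        z = pd.DataFrame(
            {
                "A": u[:, 0] + rng.normal(0, np.sqrt(0.4), 100),
                "B": u[:, 1] + rng.normal(0, np.sqrt(0.6), 100),
                "C": np.nan,  # unmeasured in this environment
            },
            index=desk_kinship.accessions,
        )
        z[["A", "B"]] = (z[["A", "B"]] - z[["A", "B"]].mean()) / z[["A", "B"]].std(ddof=1)
        tm = TraitMatrix(ls_means=z, environment="wet")
        G = assemble_g_matrix(z, desk_kinship, environment="wet")
        assert G.masked == ("C",)
        assert list(G.values.index) == ["A", "B"]
        vals = G.values.to_numpy()
        np.testing.assert_allclose(vals, vals.T, atol=1e-10)
        assert ((np.diag(vals) >= 0) & (np.diag(vals) <= 1)).all()

    def test_estimate_improves_with_panel_size(self):
        # Frobenius error of the estimated G shrinks as the panel grows
        G_true = np.array([[0.6, 0.3], [0.3, 0.6]])
        errs = {}
        for n in (100, 400):
            g = simulate_genotypes(n_acc=n, n_snp=1000, seed=15)
            K = vanraden_grm(g)
            frob = []
            for rep in range(6):
                rng = np.random.default_rng(600 + rep)
                u = _breeding_values(K.to_numpy(), G_true, rng)
                z = pd.DataFrame(
                    {
                        "A": u[:, 0] + rng.normal(0, np.sqrt(0.4), n),
                        "B": u[:, 1] + rng.normal(0, np.sqrt(0.4), n),
                    },
                    index=K.accessions,
                )
                z = (z - z.mean()) / z.std(ddof=1)
                G = assemble_g_matrix(z, K, alpha=0.05)
                frob.append(np.linalg.norm(G.values.to_numpy() - G_true))
            errs[n] = np.mean(frob)
        assert errs[400] < errs[100]
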