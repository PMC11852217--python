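import numpy as np
import pytest
from scipy import stats

from conftest import make_geno
from swinegp.gwas import (
    build_panels,
    compute_pca,
    eigen_significance,
    select_significant,
    single_snp_assoc,
    snp_pve,
    tracy_widom_sf,
)
from swinegp.simdata import SimConfig, simulate_genotypes, simulate_phenotypes


def planted_structure(n_per=100, m=1000, seed=0):
    rng = np.random.default_rng(seed)
    f1 = rng.uniform(0.1, 0.9, m)
    f2 = np.clip(f1 + rng.normal(0, 0.25, m), 0.02, 0.98)
    d = np.vstack(
        [rng.binomial(2, f1, (n_per, m)), rng.binomial(2, f2, (n_per, m))]
    ).astype(np.int8)
    return make_geno(d)


class TestPca:
    def test_planted_subpopulations_separate_on_pc1(self):
        g = planted_structure()
        pca = compute_pca(g, k=10)
        sc = pca.scores[:, 0]
        gap = abs(sc[:100].mean() - sc[100:].mean())
        within = (sc[:100].std() + sc[100:].std()) / 2
        assert gap > 3 * within
        assert pca.eigen_pvalues[0] < 0.01
        assert 0 in pca.selected

    def test_duplicate_individuals_get_identical_scores(self):
        d = np.random.default_rng(1).binomial(2, 0.4, (40, 200)).astype(np.int8)
        d[5] = d[3]
        pca = compute_pca(make_geno(d), k=5)
        assert np.allclose(pca.scores[3], pca.scores[5], atol=1e-8)

    def test_eigenvalues_descending_and_k_bound(self):
        g = planted_structure(n_per=30, m=100, seed=2)
        pca = compute_pca(g, k=10)
        assert np.all(np.diff(pca.eigenvalues) <= 1e-12)
        with pytest.raises(ValueError):
            compute_pca(g, k=1000)


class TestTracyWidom:
    def test_known_upper_quantiles(self):
        # TW1 99th percentile ~ 2.02, 95th ~ 0.98
        assert tracy_widom_sf(2.0234) == pytest.approx(0.01, abs=0.002)
        assert tracy_widom_sf(0.9793) == pytest.approx(0.05, abs=0.005)

    def test_null_lead_eigenvalue_rarely_significant(self):
        rng = np.random.default_rng(3)
        rej = 0
        reps = 40
        for _ in range(reps):
            x = rng.binomial(2, rng.uniform(0.1, 0.5, 400), (120, 400)).astype(float)
            z = (x - x.mean(0)) / np.maximum(x.std(0), 1e-9)
            lam = np.linalg.svd(z, compute_uv=False) ** 2 / 400
            p = eigen_significance(lam, n=120, m=400)
            rej += p[0] < 0.01
        assert rej / reps <= 0.1

    def test_needs_two_eigenvalues(self):
        with pytest.raises(ValueError):
            eigen_significance(np.array([1.0]), n=10, m=10)


class TestAssociation:
    def test_matches_ols_oracle_with_covariates(self):
        rng = np.random.default_rng(4)
        g = make_geno(rng.binomial(2, 0.4, (50, 10)))
        cov = rng.normal(size=(50, 2))
        y = rng.normal(size=50)
        res = single_snp_assoc(y, g, covariates=cov)
        x = g.dosages_float()
        for j in range(10):
            X = np.column_stack([np.ones(50), cov, x[:, j]])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            s2 = resid @ resid / (50 - 4)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[3, 3])
            t = beta[3] / se
            p = 2 * stats.t.sf(abs(t), 50 - 4)
            assert res.beta[j] == pytest.approx(beta[3], abs=1e-8)
            assert res.se[j] == pytest.approx(se, abs=1e-8)
            assert res.p[j] == pytest.approx(p, rel=1e-6)

    def test_perfect_predictor_snp(self):
        g = make_geno(np.random.default_rng(5).binomial(2, 0.5, (40, 3)))
        y = g.dosages_float()[:, 1] - g.dosages_float()[:, 1].mean()
        res = single_snp_assoc(y, g)
        assert res.p[1] < 1e-30
        assert res.beta[1] == pytest.approx(1.0)

    def test_null_pvalues_uniform(self):
        cfg = SimConfig(
            n_individuals=300, n_snps=1000, within_block_corr=0.0, h2=0.0,
            n_qtl=0, seed=6, fixed_effect_sd=0.0,
        )
        g = simulate_genotypes(cfg)
        y = np.random.default_rng(7).standard_normal(300)
        res = single_snp_assoc(y, g)
        assert stats.kstest(res.p, "uniform").pvalue > 0.01

    def test_monomorphic_snp_flagged(self):
        d = np.random.default_rng(8).binomial(2, 0.5, (30, 2)).astype(np.int8)
        d[:, 0] = 2
        res = single_snp_assoc(np.random.default_rng(9).normal(size=30), make_geno(d))
        assert res.p[0] == 1.0 and res.beta[0] == 0.0

    def test_pvalues_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(10)
        g = make_geno(rng.binomial(2, 0.3, (60, 20)))
        y = rng.normal(size=60)
        p1 = single_snp_assoc(y, g).p
        p2 = single_snp_assoc(3.5 * y - 7.0, g).p
        assert np.allclose(p1, p2, rtol=1e-9)


class TestPveAndSelection:
    def test_direct_formula_values(self, herd):
        _, geno, _, _ = herd
        res = single_snp_assoc(np.random.default_rng(0).normal(size=250), geno)
        res.beta = np.zeros(geno.n_snps)
        res.beta[0] = 1.0
        f = np.full(geno.n_snps, 0.5)
        pve = snp_pve(res, f, var_yc=1.0)
        assert pve[0] == pytest.approx(0.5)
        assert np.all(pve[1:] == 0.0)
        with pytest.raises(ValueError):
            snp_pve(res, f, var_yc=0.0)

    def test_qtl_pve_sums_near_one_without_noise(self):
        cfg = SimConfig(
            n_individuals=800, n_snps=150, n_qtl=5, h2=1.0, within_block_corr=0.0,
            fixed_effect_levels={}, seed=11, qtl_effect_dist="equal",
        )
        g = simulate_genotypes(cfg)
        tab, truth = simulate_phenotypes(g, cfg)
        y = tab.data["trait"].to_numpy()
        res = single_snp_assoc(y, g)
        f = np.clip(g.dosages_float().mean(0) / 2, 1e-6, 1 - 1e-6)
        pve = snp_pve(res, f, float(np.var(y, ddof=1)))
        assert pve[truth.qtl_indices].sum() == pytest.approx(1.0, abs=0.15)

    def test_select_significant(self):
        cfg = SimConfig(
            n_individuals=500, n_snps=300, n_qtl=3, h2=0.6, seed=12,
            qtl_effect_dist="equal", fixed_effect_sd=0.0,
        )
        g = simulate_genotypes(cfg)
        tab, truth = simulate_phenotypes(g, cfg)
        res = single_snp_assoc(tab.data["trait"].to_numpy(), g)
        sel = select_significant(res)  # default alpha 1e-5
        assert set(truth.qtl_indices) <= set(sel)
        assert np.all(np.diff(res.p[sel]) >= 0)

        res.p = np.full(300, 0.5)
        assert select_significant(res).size == 0


class TestPanels:
    def test_nesting_and_rank_one(self, herd):
        _, geno, table, _ = herd
        res = single_snp_assoc(table.data["trait"].to_numpy(), geno)
        p10, p20 = build_panels(res, [10, 20])
        assert set(p10.snp_indices) <= set(p20.snp_indices)
        assert p10.snp_indices[0] == np.argmin(res.p)
        assert np.array_equal(p10.genome_order(), np.sort(p10.snp_indices))

    def test_size_validation(self, herd):
        _, geno, table, _ = herd
        res = single_snp_assoc(table.data["trait"].to_numpy(), geno)
        with pytest.raises(ValueError):
            build_panels(res, [10, geno.n_snps + 1])
        with pytest.raises(ValueError):
            build_panels(res, [20, 10])
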