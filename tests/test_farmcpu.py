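"""FarmCPU scan: OLS-oracle equivalence, null calibration, selection rules."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from svrgwas import (
    FarmcpuConfig,
    SimConfig,
    farmcpu_run,
    fdr_threshold,
    fem_scan,
    rem_select,
    simulate_genotypes,
)


def ols_oracle(y, d, covars=None):
    """Independent per-SNP OLS t-test via statsmodels."""
    pv = np.empty(d.shape[1])
    eff = np.empty(d.shape[1])
    for j in range(d.shape[1]):
        X = [np.ones(len(y))]
        if covars is not None:
            X.append(covars)
        X.append(d[:, j])
        X = np.column_stack(X)
        fit = sm.OLS(y, X).fit()
        pv[j] = fit.pvalues[-1]
        eff[j] = fit.params[-1]
    return pv, eff


class TestFemScan:
    def test_matches_per_snp_ols_oracle(self, small_panel, rng):
        gm, _, _ = small_panel
        y = rng.normal(size=gm.n_samples) + 0.4 * gm.dosages[:, 10]
        p, eff = fem_scan(gm, y)
        p_or, eff_or = ols_oracle(y, gm.dosages.astype(float))
        assert np.allclose(p, p_or, atol=1e-8)
        assert np.allclose(eff, eff_or, atol=1e-8)

    def test_matches_oracle_with_covariates(self, small_panel, rng):
        gm, _, _ = small_panel
        cov = rng.normal(size=(gm.n_samples, 3))
        y = rng.normal(size=gm.n_samples) + cov @ [1.0, -0.5, 0.2]
        p, _ = fem_scan(gm, y, covariates=cov)
        p_or, _ = ols_oracle(y, gm.dosages.astype(float), covars=cov)
        assert np.allclose(p, p_or, atol=1e-8)

    def test_null_pvalues_uniform(self, rng):
        # LD-free panel so the 500 per-SNP p-values are ~independent
        cfg = SimConfig(n_genotypes=100, n_snps=500, n_chromosomes=10,
                        ld_rho=0.0, fst=0.0, n_subpops=1, seed=77)
        gm, _ = simulate_genotypes(cfg)
        y = rng.permutation(rng.normal(size=gm.n_samples))
        p, _ = fem_scan(gm, y)
        ks = stats.kstest(p[np.isfinite(p)], "uniform").statistic
        assert ks < 1.36 / np.sqrt(gm.n_snps)  # 5% critical value

    def test_constant_snp_gets_nan(self, small_panel, rng):
        gm, _, _ = small_panel
        d = gm.dosages.copy()
        d[:, 0] = 1
        gm2 = type(gm)(d, gm.snp_meta, list(gm.sample_ids))
        p, _ = fem_scan(gm2, rng.normal(size=gm.n_samples))
        assert np.isnan(p[0])

    def test_pseudo_qtn_retested_via_substitution(self, small_panel, rng):
        gm, _, _ = small_panel
        j = 25
        y = rng.normal(size=gm.n_samples) + 1.5 * gm.dosages[:, j]
        p, _ = fem_scan(gm, y, pseudo_qtns=(j,), bin_size=500_000)
        # the pseudo-QTN itself is excluded from its own covariate set,
        # so its signal is still seen
        assert p[j] < 1e-6

    def test_coding_flip_leaves_pvalue_unchanged(self, small_panel, rng):
        gm, _, _ = small_panel
        y = rng.normal(size=gm.n_samples) + 0.5 * gm.dosages[:, 5]
        p1, e1 = fem_scan(gm, y)
        d = gm.dosages.copy()
        d[:, 5] = 2 - d[:, 5]
        gm2 = type(gm)(d, gm.snp_meta, list(gm.sample_ids))
        p2, e2 = fem_scan(gm2, y)
        assert p2[5] == pytest.approx(p1[5], rel=1e-9)
        assert e2[5] == pytest.approx(-e1[5], rel=1e-9)


class TestRemSelect:
    def test_single_grid_cell_returns_top_bins(self, small_panel, rng):
        gm, _, _ = small_panel
        y = rng.normal(size=gm.n_samples)
        p = rng.uniform(size=gm.n_snps) * 0.009  # everything eligible
        cfg = FarmcpuConfig(bin_sizes_bp=(10_000_000,), qtn_counts=(3,))
        qtns, bsize = rem_select(gm, y, p, cfg)
        assert bsize == 10_000_000
        assert len(qtns) == 3
        # the global best p must be among them
        assert int(np.argmin(p)) in qtns

    def test_one_representative_per_bin(self, small_panel, rng):
        gm, _, _ = small_panel
        y = rng.normal(size=gm.n_samples)
        p = np.full(gm.n_snps, 0.009)
        p[0], p[1] = 1e-8, 1e-7  # same bin with a huge bin size
        cfg = FarmcpuConfig(bin_sizes_bp=(10**9,), qtn_counts=(1,))
        qtns, _ = rem_select(gm, y, p, cfg)
        chrom0 = gm.snp_meta.loc[0, "chrom"]
        same_chrom = gm.snp_meta[gm.snp_meta["chrom"] == chrom0].index
        picked_here = [q for q in qtns if q in set(same_chrom)]
        assert picked_here == [0]  # lower p wins the bin

    def test_planted_qtl_selected_with_high_power(self):
        hits = 0
        for rep in range(10):
            cfg = SimConfig(n_genotypes=120, n_snps=500, n_chromosomes=10,
                            n_qtl=0, seed=200 + rep)
            gm, _ = simulate_genotypes(cfg)
            rng = np.random.default_rng(300 + rep)
            j = int(rng.integers(gm.n_snps))
            x = gm.dosages[:, j].astype(float)
            if x.std() == 0:
                hits += 1
                continue
            # SNP explains ~30% of variance
            y = x + rng.normal(scale=np.sqrt(x.var() * 7 / 3), size=len(x))
            p, _ = fem_scan(gm, y)
            qtns, _ = rem_select(gm, y, p, FarmcpuConfig())
            chrom = gm.snp_meta["chrom"]
            pos = gm.snp_meta["pos"]
            near = [q for q in qtns if chrom[q] == chrom[j] and abs(pos[q] - pos[j]) < 5_000_000]
            hits += bool(near)
        assert hits >= 9


class TestFdrThreshold:
    def test_hand_bh_example(self):
        sig = fdr_threshold(np.array([0.01, 0.02, 0.2]), q=0.05)
        assert set(sig) == {0, 1}

    def test_all_ones_empty(self):
        assert fdr_threshold(np.ones(10), q=0.05).size == 0

    def test_q_one_selects_all_finite(self):
        p = np.array([0.1, 0.5, np.nan, 0.99])
        sig = fdr_threshold(p, q=1.0)
        assert set(sig) == {0, 1, 3}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fdr_threshold(np.array([]), q=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=40) ** 2
        q = 0.1
        # brute-force BH: largest k with p_(k) <= k q / m
        order = np.argsort(p)
        m = len(p)
        k_star = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * q / m:
                k_star = k
        want = set(order[:k_star])
        assert set(fdr_threshold(p, q)) == want


class TestFarmcpuRun:
    def test_single_iteration_equals_plain_scan(self, small_panel, rng):
        gm, _, _ = small_panel
        y = rng.normal(size=gm.n_samples)
        res = farmcpu_run(gm, y, FarmcpuConfig(max_iterations=1))
        p, _ = fem_scan(gm, y)
        assert np.allclose(res.pvalues, p, equal_nan=True)
        assert res.converged

    def test_null_phenotype_rarely_significant(self, small_panel):
        gm, _, _ = small_panel
        n_with_hits = 0
        for rep in range(20):
            y = np.random.default_rng(400 + rep).normal(size=gm.n_samples)
            res = farmcpu_run(gm, y)
            n_with_hits += res.significant.size > 0
        assert n_with_hits <= 3

    def test_large_effect_qtl_found_and_sharpened(self):
        found, sharper = 0, 0
        for rep in range(10):
            # LD-free panel: the single causal SNP has no proxies, so the
            # iteration either keeps it or conditions only on noise
            cfg = SimConfig(n_genotypes=150, n_snps=400, n_chromosomes=8,
                            n_qtl=0, ld_rho=0.0, fst=0.0, n_subpops=1,
                            seed=500 + rep)
            gm, _ = simulate_genotypes(cfg)
            rng = np.random.default_rng(600 + rep)
            j = 123
            x = gm.dosages[:, j].astype(float)
            y = x + rng.normal(scale=max(x.std(), 0.3), size=len(x))  # h2_snp ~ 0.5
            res = farmcpu_run(gm, y)
            p_glm, _ = fem_scan(gm, y)
            if j in set(res.significant):
                found += 1
            if res.pvalues[j] <= p_glm[j] * (1 + 1e-9):
                sharper += 1
        assert found >= 9
        assert sharper >= 9

    def test_deterministic(self, small_panel, rng):
        gm, _, truth = small_panel
        g = gm.dosages[:, truth.qtl_snp_indices].astype(float) @ truth.qtl_effects
        y = g + rng.normal(size=gm.n_samples)
        r1 = farmcpu_run(gm, y)
        r2 = farmcpu_run(gm, y)
        assert np.array_equal(r1.significant, r2.significant)
        assert np.allclose(r1.pvalues, r2.pvalues, equal_nan=True)
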