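"""QC filters against brute-force oracles; imputation and LD checks."""

import numpy as np
import pandas as pd
import pytest

from svrgwas import (
    MISSING,
    GenotypeMatrix,
    SimConfig,
    filter_samples,
    filter_snps,
    impute_markov,
    inject_missing,
    ld_decay,
    ld_r2,
    simulate_genotypes,
)


def make_matrix(dosages, positions=None, chrom="Chr01"):
    dosages = np.asarray(dosages, dtype=np.int8)
    m = dosages.shape[1]
    pos = positions if positions is not None else np.arange(1, m + 1) * 1000
    meta = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "C",
        }
    )
    return GenotypeMatrix(dosages, meta, [f"S{i}" for i in range(dosages.shape[0])])


def brute_force_filter(d, maf_min, max_het, max_missing):
    """Per-SNP keep/fail decision by direct per-column counting."""
    keep, fm, fmaf, fhet = [], 0, 0, 0
    for j in range(d.shape[1]):
        col = d[:, j]
        obs = col[col != MISSING]
        miss_frac = 1 - len(obs) / len(col)
        if miss_frac > max_missing or len(obs) == 0:
            fm += 1
            continue
        p = obs.sum() / (2 * len(obs))
        if min(p, 1 - p) < maf_min:
            fmaf += 1
            continue
        if (obs == 1).mean() > max_het:
            fhet += 1
            continue
        keep.append(j)
    return keep, fm, fmaf, fhet


class TestFilters:
    def test_no_missing_sample_filter_is_identity(self, small_panel):
        gm, _, _ = small_panel
        out, rep = filter_samples(gm, 0.5)
        assert rep.n_samples_removed == 0
        assert out.n_samples == gm.n_samples

    def test_single_over_threshold_sample_removed(self, rng):
        d = rng.integers(0, 3, size=(5, 20)).astype(np.int8)
        d[2, :12] = MISSING  # 60% missing
        gm = make_matrix(d)
        out, rep = filter_samples(gm, 0.5)
        assert rep.n_samples_removed == 1
        assert "S2" not in out.sample_ids

    def test_threshold_one_keeps_everything(self, rng):
        d = rng.integers(0, 3, size=(5, 20)).astype(np.int8)
        d[rng.random(d.shape) < 0.3] = MISSING
        gm = make_matrix(d)
        out, _ = filter_samples(gm, 1.0)
        assert out.n_samples == 5

    def test_low_maf_snp_removed(self):
        col = np.array([0] * 96 + [1] * 4, dtype=np.int8)  # MAF 0.02
        d = np.column_stack([col, np.tile([0, 1, 2, 1], 25)]).astype(np.int8)
        gm = make_matrix(d)
        out, rep = filter_snps(gm, maf_min=0.05)
        assert rep.n_snps_removed_maf == 1
        assert out.n_snps == 1

    def test_excess_heterozygosity_removed(self):
        col = np.array([1] * 51 + [0] * 25 + [2] * 24, dtype=np.int8)
        ok = np.tile([0, 1, 2, 1], 25).astype(np.int8)
        gm = make_matrix(np.column_stack([col, ok]))
        out, rep = filter_snps(gm, max_het=0.5)
        assert rep.n_snps_removed_het == 1
        assert out.n_snps == 1

    def test_monomorphic_snp_removed(self):
        d = np.column_stack([np.zeros(50), np.tile([0, 1], 25)]).astype(np.int8)
        gm = make_matrix(d)
        out, rep = filter_snps(gm)
        assert rep.n_snps_removed_maf == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_filters_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(0, 3, size=(50, 100)).astype(np.int8)
        d[rng.random(d.shape) < 0.15] = MISSING
        gm = make_matrix(d)
        keep, fm, fmaf, fhet = brute_force_filter(d, 0.05, 0.5, 0.2)
        out, rep = filter_snps(gm, 0.05, 0.5, 0.2)
        assert list(out.snp_meta.index) == list(range(len(keep)))
        assert out.n_snps == len(keep)
        assert [rep.n_snps_removed_missing, rep.n_snps_removed_maf, rep.n_snps_removed_het] == [fm, fmaf, fhet]
        want = gm.dosages[:, keep]
        assert np.array_equal(out.dosages, want)


class TestImputeMarkov:
    def test_complete_input_identity(self, small_panel):
        gm, _, _ = small_panel
        out, rep = impute_markov(gm, seed=1)
        assert rep.n_imputed == 0
        assert np.array_equal(out.dosages, gm.dosages)

    def test_observed_entries_never_altered_and_complete_output(self, small_panel):
        gm, _, _ = small_panel
        holed = inject_missing(gm, 0.1, seed=5)
        out, rep = impute_markov(holed, seed=6)
        obs = holed.dosages != MISSING
        assert np.array_equal(out.dosages[obs], holed.dosages[obs])
        assert not (out.dosages == MISSING).any()
        assert rep.n_imputed == int((~obs).sum())

    def test_deterministic_given_seed(self, small_panel):
        gm, _, _ = small_panel
        holed = inject_missing(gm, 0.2, seed=7)
        a, _ = impute_markov(holed, seed=8)
        b, _ = impute_markov(holed, seed=8)
        assert np.array_equal(a.dosages, b.dosages)

    def test_perfectly_correlated_neighbor_determines_imputation(self):
        col = np.tile([0, 1, 2], 20).astype(np.int8)
        d = np.column_stack([col, col]).astype(np.int8)
        d[5, 1] = MISSING
        gm = make_matrix(d)
        out, _ = impute_markov(gm, seed=9)
        assert out.dosages[5, 1] == out.dosages[5, 0]

    def test_imputed_marginals_match_observed(self, small_panel):
        gm, _, _ = small_panel
        holed = inject_missing(gm, 0.3, seed=10)
        out, _ = impute_markov(holed, seed=11)
        p_obs = np.ma.masked_equal(holed.dosages, MISSING).mean(axis=0).filled(np.nan) / 2
        p_imp = out.dosages.mean(axis=0) / 2
        n = gm.n_samples
        se = np.sqrt(np.maximum(p_obs * (1 - p_obs), 1e-4) / (2 * n))
        assert (np.abs(p_imp - p_obs) <= 4 * se + 0.05).mean() > 0.95

    def test_all_missing_snp_rejected(self):
        d = np.tile([0, 1, 2, 1], (10, 1)).astype(np.int8).T
        d = d.T if d.shape[0] != 10 else d
        d = np.column_stack([np.tile([0, 1], 5), np.full(10, MISSING)]).astype(np.int8)
        gm = make_matrix(d)
        with pytest.raises(ValueError, match="zero observed"):
            impute_markov(gm)


class TestLdR2:
    def test_self_correlation_is_one(self, small_panel):
        gm, _, _ = small_panel
        assert ld_r2(gm, 3, 3) == pytest.approx(1.0)

    def test_allele_flip_invariance(self, small_panel):
        gm, _, _ = small_panel
        flipped = gm.dosages.copy()
        flipped[:, 7] = 2 - flipped[:, 7]
        gm2 = GenotypeMatrix(flipped, gm.snp_meta, list(gm.sample_ids))
        assert ld_r2(gm, 3, 7) == pytest.approx(ld_r2(gm2, 3, 7), abs=1e-12)

    def test_hand_computed_zero_correlation(self):
        d = np.array([[0, 0], [1, 1], [2, 2], [0, 2], [1, 1], [2, 0]], dtype=np.int8)
        gm = make_matrix(d)
        assert ld_r2(gm, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        d = np.column_stack([np.zeros(10), np.tile([0, 1], 5)]).astype(np.int8)
        gm = make_matrix(d)
        with pytest.raises(ValueError, match="variance"):
            ld_r2(gm, 0, 1)


class TestLdDecay:
    def test_no_ld_gives_flat_near_zero_curve(self):
        cfg = SimConfig(
            n_genotypes=300, n_snps=200, n_chromosomes=2, ld_rho=0.0,
            fst=0.0, n_subpops=1, seed=31,
        )
        gm, _ = simulate_genotypes(cfg)
        curve = ld_decay(gm, max_dist_bp=10_000_000, n_bins=10)
        # background R^2 for independent SNPs is ~1/n
        assert np.nanmax(curve.mean_r2) < 0.1

    def test_geometric_chain_half_decay_distance_found(self):
        cfg = SimConfig(
            n_genotypes=500, n_snps=400, n_chromosomes=2, ld_rho=0.9,
            fst=0.0, n_subpops=1, maf_range=(0.3, 0.5), seed=32,
        )
        gm, _ = simulate_genotypes(cfg)
        curve = ld_decay(gm, max_dist_bp=5_000_000, n_bins=20)
        assert np.isfinite(curve.decay_distance_bp)
        assert 0 < curve.decay_distance_bp < 5_000_000
        # curve decreasing in the first bins
        ok = np.isfinite(curve.mean_r2)
        assert curve.mean_r2[ok][0] > np.nanmean(curve.mean_r2[ok][-3:])

    def test_duplicate_column_pulls_its_bin_up(self):
        rng = np.random.default_rng(33)
        d = rng.integers(0, 3, size=(100, 6)).astype(np.int8)
        d[:, 5] = d[:, 0]
        pos = np.array([1000, 200_000, 400_000, 600_000, 800_000, 901_000])
        gm = make_matrix(d, positions=pos)
        curve = ld_decay(gm, max_dist_bp=1_000_000, n_bins=10)
        # the duplicate pair sits at distance 900 kb -> last bin
        assert curve.mean_r2[9] > 0.9

    def test_no_pairs_in_range_rejected(self):
        rng = np.random.default_rng(34)
        d = rng.integers(0, 3, size=(50, 2)).astype(np.int8)
        gm = make_matrix(d, positions=np.array([1, 5_000_000]))
        with pytest.raises(ValueError, match="pairs"):
            ld_decay(gm, max_dist_bp=1000, n_bins=5)
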