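"""Peak clustering, flanking-region arithmetic, allelic effects and
co-localization, each against hand or brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from svrgwas import allelic_effect, colocalize, flanking_regions, peak_select
from tests.test_geno_qc import make_matrix


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "stat"])


class TestPeakSelect:
    def test_single_snp_is_its_own_peak(self):
        hits = hits_frame([("a", "Chr01", 1000, 5.0)])
        peaks = peak_select(hits, 150_000)
        assert len(peaks) == 1
        assert peaks["snp_id"].iloc[0] == "a"

    def test_nearby_snps_form_one_cluster(self):
        hits = hits_frame([("a", "Chr01", 100_000, 5.0), ("b", "Chr01", 110_000, 8.0)])
        peaks = peak_select(hits, 150_000)
        assert len(peaks) == 1
        assert peaks["snp_id"].iloc[0] == "b"  # higher statistic wins

    def test_distant_snps_stay_separate(self):
        hits = hits_frame([("a", "Chr01", 100_000, 5.0), ("b", "Chr01", 500_000, 8.0)])
        peaks = peak_select(hits, 150_000)
        assert len(peaks) == 2

    def test_lower_p_wins_when_smaller_is_better(self):
        hits = hits_frame([("a", "Chr01", 100_000, 1e-8), ("b", "Chr01", 110_000, 1e-3)])
        peaks = peak_select(hits, 150_000, higher_is_better=False)
        assert peaks["snp_id"].iloc[0] == "a"

    def test_tie_broken_by_lower_position(self):
        hits = hits_frame([("b", "Chr01", 120_000, 7.0), ("a", "Chr01", 100_000, 7.0)])
        peaks = peak_select(hits, 150_000)
        assert peaks["snp_id"].iloc[0] == "a"

    def test_empty_input_gives_empty_output(self):
        peaks = peak_select(hits_frame([]), 150_000)
        assert len(peaks) == 0


class TestFlankingRegions:
    def test_window_arithmetic(self):
        peaks = hits_frame([("a", "Chr01", 200_000, 5.0)])
        peaks["member_idx"] = [[0]]
        (r,) = flanking_regions(peaks, 150_000)
        assert (r.start, r.end) == (50_000, 350_000)

    def test_start_clipped_at_zero(self):
        peaks = hits_frame([("a", "Chr01", 100_000, 5.0)])
        peaks["member_idx"] = [[0]]
        (r,) = flanking_regions(peaks, 150_000)
        assert (r.start, r.end) == (0, 250_000)

    def test_overlapping_regions_merged(self):
        peaks = hits_frame(
            [("a", "Chr01", 200_000, 5.0), ("b", "Chr01", 400_000, 9.0)]
        )
        peaks["member_idx"] = [[0], [1]]
        regions = flanking_regions(peaks, 150_000)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (50_000, 550_000)
        assert r.peak_snp == "b"
        assert r.member_snps == [0, 1]

    @given(
        pos=st.lists(st.integers(0, 2_000_000), min_size=1, max_size=12),
        window=st.integers(0, 300_000),
    )
    def test_merged_regions_disjoint_and_cover_peaks(self, pos, window):
        peaks = hits_frame(
            [(f"s{i}", "Chr01", p, float(i)) for i, p in enumerate(sorted(set(pos)))]
        )
        peaks["member_idx"] = [[i] for i in range(len(peaks))]
        regions = flanking_regions(peaks, window)
        for a, b in zip(regions, regions[1:]):
            assert a.end < b.start  # disjoint after merging
        for _, row in peaks.iterrows():
            assert any(r.start <= row["pos"] <= r.end for r in regions)


class TestAllelicEffect:
    def test_noiseless_regression_recovers_slope(self, small_panel):
        gm, _, _ = small_panel
        y = 2.0 * gm.dosages[:, 4].astype(float) + 5.0
        eff, means = allelic_effect(gm, y, 4)
        assert eff == pytest.approx(2.0, abs=1e-12)
        classes = sorted(means)
        assert means[classes[-1]] - means[classes[0]] == pytest.approx(
            2.0 * (classes[-1] - classes[0]), abs=1e-10
        )

    def test_null_effect_within_sampling_noise(self, rng):
        n = 500
        d = rng.integers(0, 3, size=(n, 2)).astype(np.int8)
        gm = make_matrix(d)
        y = rng.normal(size=n)
        eff, _ = allelic_effect(gm, y, 0)
        x = d[:, 0].astype(float)
        se = y.std() / (x.std() * np.sqrt(n))
        assert abs(eff) < 3 * se

    def test_coding_flip_negates_effect(self, small_panel, rng):
        gm, _, _ = small_panel
        y = rng.normal(size=gm.n_samples) + gm.dosages[:, 8]
        e1, _ = allelic_effect(gm, y, 8)
        d = gm.dosages.copy()
        d[:, 8] = 2 - d[:, 8]
        gm2 = type(gm)(d, gm.snp_meta, list(gm.sample_ids))
        e2, _ = allelic_effect(gm2, y, 8)
        assert e2 == pytest.approx(-e1, abs=1e-10)

    def test_equals_cov_over_var(self, small_panel, rng):
        gm, _, _ = small_panel
        y = rng.normal(size=gm.n_samples)
        eff, _ = allelic_effect(gm, y, 12)
        x = gm.dosages[:, 12].astype(float)
        assert eff == pytest.approx(np.cov(y, x, ddof=1)[0, 1] / np.var(x, ddof=1), abs=1e-10)

    def test_monomorphic_rejected(self):
        d = np.column_stack([np.zeros(20), np.tile([0, 1], 10)]).astype(np.int8)
        gm = make_matrix(d)
        with pytest.raises(ValueError, match="monomorphic"):
            allelic_effect(gm, np.random.default_rng(0).normal(size=20), 0)


def brute_force_coloc(regions, ann):
    out = []
    for r in regions:
        for _, a in ann.iterrows():
            if a["chrom"] != r.chrom:
                continue
            ov = min(r.end, a["end"]) - max(r.start, a["start"])
            if ov > 0:
                out.append((r.chrom, r.start, a["name"], ov))
    return sorted(out)


class TestColocalize:
    def region(self, chrom, start, end, name="p"):
        from svrgwas import QtlRegion

        return QtlRegion(chrom=chrom, start=start, end=end, peak_pos=(start + end) // 2,
                         peak_snp=name, peak_statistic=1.0)

    def ann(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    def test_partial_overlap_counted(self):
        hits = colocalize(
            [self.region("Chr01", 50_000, 350_000)],
            self.ann([("Chr01", 340_000, 400_000, "qtl1")]),
        )
        assert len(hits) == 1
        assert hits[0].overlap_bp == 10_000

    def test_disjoint_no_hit(self):
        hits = colocalize(
            [self.region("Chr01", 0, 100)],
            self.ann([("Chr01", 200, 300, "x"), ("Chr02", 0, 100, "y")]),
        )
        assert hits == []

    def test_contained_annotation_full_length(self):
        hits = colocalize(
            [self.region("Chr01", 0, 1000)],
            self.ann([("Chr01", 200, 300, "x")]),
        )
        assert hits[0].overlap_bp == 100

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            colocalize([self.region("Chr01", 0, 10)], self.ann([("Chr01", 5, 2, "bad")]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        regions = [
            self.region(f"Chr{rng.integers(1, 4):02d}", int(s), int(s + rng.integers(1, 500)), f"r{i}")
            for i, s in enumerate(rng.integers(0, 5000, size=8))
        ]
        ann = self.ann(
            [
                (f"Chr{rng.integers(1, 4):02d}", int(s), int(s + rng.integers(1, 500)), f"a{i}")
                for i, s in enumerate(rng.integers(0, 5000, size=10))
            ]
        )
        got = sorted(
            (h.region.chrom, h.region.start, h.annotation_name, h.overlap_bp)
            for h in colocalize(regions, ann)
        )
        assert got == brute_force_coloc(regions, ann)
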