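"""Genotype quality control: sample/SNP filters, first-order Markov
imputation of missing calls, and pairwise LD / LD decay.

Filter rules follow common GBS practice: drop samples with excessive
missingness, then drop SNPs that are too incomplete, have minor allele
frequency below 0.05, or exceed 50% heterozygous calls. A SNP failing
several rules is attributed to the first failing rule in the order
missing -> MAF -> heterozygosity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, QcReport

__all__ = ["filter_samples", "filter_snps", "impute_markov", "ld_r2", "ld_decay", "LdDecay"]


def filter_samples(matrix: GenotypeMatrix, max_missing_fraction: float = 0.5) -> tuple[GenotypeMatrix, QcReport]:
    """Remove samples whose missing-call fraction exceeds the threshold."""
    if not (0.0 < max_missing_fraction <= 1.0):
        raise ValueError("max_missing_fraction must be in (0, 1]")
    frac = (matrix.dosages == MISSING).mean(axis=1)
    keep = np.flatnonzero(frac <= max_missing_fraction)
    if keep.size == 0:
        raise ValueError("all samples removed by missingness filter")
    report = QcReport(
        n_samples_in=matrix.n_samples,
        n_snps_in=matrix.n_snps,
        n_samples_removed=matrix.n_samples - keep.size,
    )
    out = matrix.subset_samples(keep) if keep.size < matrix.n_samples else matrix
    return out, report


def filter_snps(
    matrix: GenotypeMatrix,
    maf_min: float = 0.05,
    max_het: float = 0.5,
    max_missing: float = 0.5,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs by missingness, MAF (< maf_min) and heterozygosity (> max_het)."""
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0.0 <= max_het <= 1.0) or not (0.0 < max_missing <= 1.0):
        raise ValueError("thresholds out of range")
    d = matrix.dosages
    miss = d == MISSING
    n_obs = (~miss).sum(axis=0)
    miss_frac = miss.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, np.where(miss, 0, d).sum(axis=0) / (2.0 * np.maximum(n_obs, 1)), np.nan)
        maf = np.minimum(p, 1.0 - p)
        het = np.where(n_obs > 0, np.where(miss, 0, d == 1).sum(axis=0) / np.maximum(n_obs, 1), np.nan)

    fail_missing = (miss_frac > max_missing) | (n_obs == 0)
    fail_maf = ~fail_missing & (maf < maf_min)
    fail_het = ~fail_missing & ~fail_maf & (het > max_het)
    keep = np.flatnonzero(~(fail_missing | fail_maf | fail_het))
    if keep.size == 0:
        raise ValueError("all SNPs removed by filters")
    report = QcReport(
        n_samples_in=matrix.n_samples,
        n_snps_in=matrix.n_snps,
        n_snps_removed_missing=int(fail_missing.sum()),
        n_snps_removed_maf=int(fail_maf.sum()),
        n_snps_removed_het=int(fail_het.sum()),
    )
    return matrix.subset_snps(keep), report


def impute_markov(matrix: GenotypeMatrix, seed: int = 0) -> tuple[GenotypeMatrix, QcReport]:
    """Impute missing dosages with a first-order Markov chain along each
    chromosome (left to right by position).

    The conditional distribution of dosage_j given dosage_{j-1} is
    estimated from samples observed at both SNPs; missing values are
    drawn from that conditional (or the SNP's marginal when the chain
    has no information). Observed entries are never altered.
    """
    d = matrix.dosages.copy()
    miss = d == MISSING
    if not miss.any():
        return (
            GenotypeMatrix(d, matrix.snp_meta, list(matrix.sample_ids)),
            QcReport(n_samples_in=matrix.n_samples, n_snps_in=matrix.n_snps),
        )
    n_obs = (~miss).sum(axis=0)
    if (n_obs == 0).any():
        bad = matrix.snp_meta.loc[np.flatnonzero(n_obs == 0), "snp_id"].tolist()
        raise ValueError(f"SNPs with zero observed calls cannot be imputed: {bad[:5]}")

    rng = np.random.default_rng(seed)
    chrom = matrix.snp_meta["chrom"].to_numpy()
    cols = np.arange(matrix.n_snps)
    n_imputed = int(miss.sum())

    for c in pd.unique(chrom):
        jj = cols[chrom == c]
        # marginal draw for the leftmost SNP of the chromosome
        j = jj[0]
        obs = d[~miss[:, j], j]
        mi = np.flatnonzero(miss[:, j])
        if mi.size:
            d[mi, j] = rng.choice(obs, size=mi.size)
        for k in range(1, len(jj)):
            j, jprev = jj[k], jj[k - 1]
            mi = np.flatnonzero(miss[:, j])
            obs_mask = ~miss[:, j]
            if mi.size == 0:
                continue
            pair = ~miss[:, j] & ~miss[:, jprev]
            # 3x3 transition counts from originally-observed pairs
            counts = np.zeros((3, 3))
            if pair.any():
                np.add.at(counts, (d[pair, jprev], d[pair, j]), 1)
            marginal = d[obs_mask, j]
            prev_vals = d[mi, jprev]  # already imputed if originally missing
            for v in (0, 1, 2):
                sel = mi[prev_vals == v]
                if sel.size == 0:
                    continue
                row = counts[v]
                if row.sum() > 0:
                    probs = row / row.sum()
                    d[sel, j] = rng.choice(3, size=sel.size, p=probs)
                else:
                    d[sel, j] = rng.choice(marginal, size=sel.size)

    report = QcReport(n_samples_in=matrix.n_samples, n_snps_in=matrix.n_snps, n_imputed=n_imputed)
    return GenotypeMatrix(d, matrix.snp_meta, list(matrix.sample_ids)), report


def ld_r2(matrix: GenotypeMatrix, snp_i: int, snp_j: int) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete samples."""
    x = matrix.dosages[:, snp_i].astype(float)
    y = matrix.dosages[:, snp_j].astype(float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 3:
        raise ValueError("need >= 3 pairwise-complete samples")
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero dosage variance: R^2 undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


class LdDecay:
    """Binned intra-chromosome LD decay curve.

    Attributes
    ----------
    bin_mid : distance-bin midpoints (bp)
    mean_r2 : mean R^2 per bin (NaN for empty bins)
    decay_distance_bp : distance at which mean R^2 falls to half the
        first-bin mean (linear interpolation between bin midpoints);
        NaN when the curve never crosses that level within range.
    """

    def __init__(self, bin_mid: np.ndarray, mean_r2: np.ndarray, n_pairs: np.ndarray):
        self.bin_mid = bin_mid
        self.mean_r2 = mean_r2
        self.n_pairs = n_pairs
        self.decay_distance_bp = self._decay_distance()

    def _decay_distance(self) -> float:
        ok = np.isfinite(self.mean_r2)
        if ok.sum() < 2:
            return float("nan")
        mids = self.bin_mid[ok]
        r2 = self.mean_r2[ok]
        half = r2[0] / 2.0
        below = np.flatnonzero(r2 < half)
        if below.size == 0:
            return float("nan")
        b = below[0]
        if b == 0:
            return float(mids[0])
        x0, x1 = mids[b - 1], mids[b]
        y0, y1 = r2[b - 1], r2[b]
        if y0 == y1:
            return float(x1)
        return float(x0 + (y0 - half) / (y0 - y1) * (x1 - x0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dist_bp": self.bin_mid, "mean_r2": self.mean_r2, "n_pairs": self.n_pairs})


def ld_decay(matrix: GenotypeMatrix, max_dist_bp: int, n_bins: int = 20) -> LdDecay:
    """Mean pairwise R^2 per distance bin over intra-chromosome pairs."""
    if n_bins < 1 or max_dist_bp <= 0:
        raise ValueError("need n_bins >= 1 and max_dist_bp > 0")
    edges = np.linspace(0, max_dist_bp, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    chrom = matrix.snp_meta["chrom"].to_numpy()
    pos = matrix.snp_meta["pos"].to_numpy()
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if idx.size < 2:
            continue
        d = np.ma.masked_equal(matrix.dosages[:, idx].astype(float), MISSING)
        sd = d.std(axis=0)
        poly = np.flatnonzero((sd > 0).filled(False))
        if poly.size < 2:
            continue
        idx = idx[poly]
        d = d[:, poly]
        r = np.ma.corrcoef(d, rowvar=False)
        r2 = np.asarray(r) ** 2
        p = pos[idx]
        dist = np.abs(p[:, None] - p[None, :])
        iu = np.triu_indices(len(idx), k=1)
        dist_u, r2_u = dist[iu], r2[iu]
        keep = (dist_u <= max_dist_bp) & np.isfinite(r2_u)
        which = np.clip(np.searchsorted(edges, dist_u[keep], side="right") - 1, 0, n_bins - 1)
        np.add.at(sums, which, r2_u[keep])
        np.add.at(counts, which, 1)
    if counts.sum() == 0:
        raise ValueError("no SNP pairs within max_dist_bp")
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mids = (edges[:-1] + edges[1:]) / 2.0
    return LdDecay(mids, mean_r2, counts)
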