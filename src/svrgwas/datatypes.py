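"""Core in-memory containers shared across the pipeline.

Dosages are coded 0/1/2 copies of the alternate allele, with ``MISSING``
(-1) as the sentinel for no-calls. SNP metadata travels with the dosage
matrix so that position-aware steps (LD, binning, regions) never need a
separate lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing genotype call
MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with per-SNP metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` integer array in {0, 1, 2, MISSING}.
    snp_meta
        One row per SNP with columns ``snp_id, chrom, pos, ref, alt``;
        positions strictly increasing within each chromosome (1-based).
    sample_ids
        Sample identifiers, one per dosage row.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match dosage rows")
        if self.dosages.shape[1] != len(self.snp_meta):
            raise ValueError("snp_meta length does not match dosage columns")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages outside {0,1,2,missing}")
        for _, sub in self.snp_meta.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions not strictly increasing within chromosome")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP, computed on non-missing calls."""
        d = np.ma.masked_equal(self.dosages, MISSING)
        p = d.mean(axis=0).filled(np.nan) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[idx],
            self.snp_meta.reset_index(drop=True),
            [self.sample_ids[i] for i in np.atleast_1d(idx)],
        )

    def subset_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.snp_meta.iloc[idx].reset_index(drop=True),
            list(self.sample_ids),
        )


@dataclass
class SimTruth:
    """Ground truth of a simulation, for recovery/power tests."""

    qtl_snp_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    qtl_effects: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigma2_g: float = 0.0
    sigma2_e: float = 0.0
    sigma2_gxe: float = 0.0
    subpop_labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.qtl_snp_indices = np.asarray(self.qtl_snp_indices, dtype=int)
        self.qtl_effects = np.asarray(self.qtl_effects, dtype=float)
        if len(self.qtl_snp_indices) != len(self.qtl_effects):
            raise ValueError("qtl index / effect length mismatch")
        if min(self.sigma2_g, self.sigma2_e, self.sigma2_gxe) < 0:
            raise ValueError("variances must be non-negative")


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    sigma2_gxe: float
    mu: float
    block_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_e, self.sigma2_gxe) < 0:
            raise ValueError("variance components must be non-negative")


@dataclass
class BlupResult:
    """Per-genotype BLUPs plus the variance components behind them."""

    blups: pd.Series  # index = genotype id, values in trait units
    variance_components: VarianceComponents
    h2: float
    n_outliers_removed: int = 0


@dataclass
class QcReport:
    n_samples_in: int = 0
    n_snps_in: int = 0
    n_samples_removed: int = 0
    n_snps_removed_missing: int = 0
    n_snps_removed_maf: int = 0
    n_snps_removed_het: int = 0
    n_imputed: int = 0

    @property
    def n_snps_removed(self) -> int:
        return (
            self.n_snps_removed_missing
            + self.n_snps_removed_maf
            + self.n_snps_removed_het
        )

    def to_dict(self) -> dict:
        return {
            "n_samples_in": self.n_samples_in,
            "n_snps_in": self.n_snps_in,
            "n_samples_removed": self.n_samples_removed,
            "n_snps_removed_missing": self.n_snps_removed_missing,
            "n_snps_removed_maf": self.n_snps_removed_maf,
            "n_snps_removed_het": self.n_snps_removed_het,
            "n_imputed": self.n_imputed,
        }


@dataclass
class GwasResult:
    """Per-SNP association scan for one method x trait.

    ``stat`` is -log10(p) for FarmCPU and scaled importance (0-100) for
    the SVR scan, so that "bigger = stronger" holds for both and one
    region-extraction path serves both methods.
    """

    method: str
    table: pd.DataFrame  # snp_id, chrom, pos, effect, pvalue/importance, stat, significant
    threshold: float  # on the stat scale
    significant: np.ndarray  # SNP indices (columns of the scanned matrix)


@dataclass
class QtlRegion:
    chrom: str
    start: int  # 0-based half-open
    end: int
    peak_pos: int
    peak_snp: str
    peak_statistic: float
    member_snps: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError("malformed region interval")


@dataclass
class ColocalizationHit:
    region: QtlRegion
    annotation_name: str
    annotation_chrom: str
    annotation_start: int
    annotation_end: int
    overlap_bp: int

    def __post_init__(self) -> None:
        if self.overlap_bp <= 0:
            raise ValueError("co-localization requires positive overlap")
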