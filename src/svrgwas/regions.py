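"""Turn significant SNPs into peak-anchored QTL regions, estimate
allelic effects, and co-localize regions with interval annotations.

Coordinates are 0-based half-open internally (BED convention); VCF and
HapMap positions (1-based) are converted on ingest. The default flanking
window is 150 kbp either side of each peak, the span an LD-decay
distance of that order justifies; it can be recomputed from the data via
:func:`svrgwas.geno_qc.ld_decay`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ColocalizationHit, GenotypeMatrix, QtlRegion

__all__ = ["peak_select", "flanking_regions", "allelic_effect", "colocalize"]

DEFAULT_WINDOW_BP = 150_000


def peak_select(
    hits: pd.DataFrame,
    cluster_window_bp: int = DEFAULT_WINDOW_BP,
    higher_is_better: bool = True,
) -> pd.DataFrame:
    """Cluster significant SNPs and pick one peak per cluster.

    ``hits`` needs columns ``snp_id, chrom, pos, stat`` (one row per
    significant SNP). Consecutive significant SNPs on a chromosome more
    than ``cluster_window_bp`` apart start a new cluster; the cluster's
    peak is its best-statistic SNP, ties broken by lower position.
    Returns the peak rows with a ``member_idx`` list column. An empty
    input yields an empty frame.
    """
    required = {"snp_id", "chrom", "pos", "stat"}
    if not required.issubset(hits.columns):
        raise ValueError(f"hits must have columns {sorted(required)}")
    if hits.empty:
        return hits.assign(member_idx=pd.Series(dtype=object))
    peaks = []
    for chrom, sub in hits.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="stable")
        pos = sub["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > cluster_window_bp)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks + 1, len(sub)]
        for s, e in zip(starts, ends):
            cluster = sub.iloc[s:e]
            stat = cluster["stat"].to_numpy(float)
            best = stat.max() if higher_is_better else stat.min()
            cand = cluster[cluster["stat"] == best].sort_values("pos", kind="stable")
            peak = cand.iloc[0].copy()
            peak["member_idx"] = list(cluster.index)
            peaks.append(peak)
    return pd.DataFrame(peaks).reset_index(drop=True)


def flanking_regions(peaks: pd.DataFrame, window_bp: int = DEFAULT_WINDOW_BP) -> list[QtlRegion]:
    """+-window regions around peaks, clipped at 0 and merged when they
    overlap on one chromosome (members unioned, best-statistic peak kept)."""
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if peaks.empty:
        return []
    regions: list[QtlRegion] = []
    for _, row in peaks.iterrows():
        start = max(0, int(row["pos"]) - window_bp)
        end = int(row["pos"]) + window_bp
        regions.append(
            QtlRegion(
                chrom=str(row["chrom"]),
                start=start,
                end=end,
                peak_pos=int(row["pos"]),
                peak_snp=str(row["snp_id"]),
                peak_statistic=float(row["stat"]),
                member_snps=list(row.get("member_idx", [])),
            )
        )
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    merged: list[QtlRegion] = []
    for r in regions:
        if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
            prev = merged[-1]
            keep, other = (prev, r) if prev.peak_statistic >= r.peak_statistic else (r, prev)
            merged[-1] = QtlRegion(
                chrom=prev.chrom,
                start=min(prev.start, r.start),
                end=max(prev.end, r.end),
                peak_pos=keep.peak_pos,
                peak_snp=keep.peak_snp,
                peak_statistic=keep.peak_statistic,
                member_snps=sorted(set(prev.member_snps) | set(r.member_snps)),
            )
            del other
        else:
            merged.append(r)
    return merged


def allelic_effect(matrix: GenotypeMatrix, y: np.ndarray, snp: int) -> tuple[float, dict[int, float]]:
    """Per-alt-allele additive effect: slope of y on dosage, plus the
    mean phenotype of each dosage class."""
    x = matrix.dosages[:, snp].astype(float)
    y = np.asarray(y, dtype=float)
    ok = x >= 0
    x, yv = x[ok], y[ok]
    if np.ptp(x) == 0:
        raise ValueError("monomorphic SNP: allelic effect undefined")
    slope = float(np.cov(yv, x, ddof=1)[0, 1] / np.var(x, ddof=1))
    class_means = {int(v): float(yv[x == v].mean()) for v in np.unique(x)}
    return slope, class_means


def colocalize(regions: list[QtlRegion], annotations: pd.DataFrame) -> list[ColocalizationHit]:
    """All (region, annotation) pairs overlapping by >= 1 bp.

    ``annotations`` needs columns ``chrom, start, end, name`` in 0-based
    half-open coordinates. Output sorted by chromosome then region start
    then annotation start.
    """
    required = {"chrom", "start", "end", "name"}
    if not required.issubset(annotations.columns):
        raise ValueError(f"annotations must have columns {sorted(required)}")
    bad = annotations[annotations["start"] > annotations["end"]]
    if len(bad):
        raise ValueError(f"malformed annotation intervals (start > end) at rows: {list(bad.index)}")
    hits: list[ColocalizationHit] = []
    ann_by_chrom = {c: sub for c, sub in annotations.groupby("chrom", sort=False)}
    for region in sorted(regions, key=lambda r: (r.chrom, r.start)):
        sub = ann_by_chrom.get(region.chrom)
        if sub is None:
            continue
        for _, a in sub.sort_values("start", kind="stable").iterrows():
            overlap = min(region.end, int(a["end"])) - max(region.start, int(a["start"]))
            if overlap > 0:
                hits.append(
                    ColocalizationHit(
                        region=region,
                        annotation_name=str(a["name"]),
                        annotation_chrom=str(a["chrom"]),
                        annotation_start=int(a["start"]),
                        annotation_end=int(a["end"]),
                        overlap_bp=int(overlap),
                    )
                )
    return hits
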