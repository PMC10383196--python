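"""Synthetic genotypes and plot-level phenotypes with known ground truth.

The generator emulates the statistical structure the association pipeline
assumes: a diploid biallelic SNP panel with geometric LD along each
chromosome, subpopulation structure via Balding-Nichols allele-frequency
drift, and plot-level trait values from an additive genetic model with
environment, block, genotype-by-environment and smooth spatial-field
terms. Defaults mirror a soybean association panel: 227 genotypes,
20 chromosomes, four environments (two locations x two years) in an RCBD
with two blocks, seven subpopulations and trait heritability ~0.69.

LD model: along a chromosome each haplotype allele copies the previous
SNP's allele with probability ``ld_rho`` and is otherwise drawn fresh
from the subpopulation allele frequency. This first-order copy chain has
a closed-form decay — haplotype correlation at marker lag d is rho**d
(for comparable allele frequencies) — which makes the simulated LD
checkable analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, SimTruth

__all__ = ["SimConfig", "simulate_genotypes", "simulate_phenotypes", "inject_missing"]


@dataclass
class SimConfig:
    """Study-design parameters of the simulated panel.

    The genetic residual variance is derived from ``h2_target`` so that
    sigma2_g / (sigma2_g + sigma2_e) holds exactly in the generating
    model (plot basis). GxE and block magnitudes are conventions — the
    field design they emulate reports none — and are expressed relative
    to the genetic variance (``gxe_ratio``) or in trait units
    (``block_sd``, ``spatial_sd``, ``env_sd``).
    """

    n_genotypes: int = 227
    n_snps: int = 2000
    n_chromosomes: int = 20
    chrom_length_bp: int = 50_000_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.8  # adjacent-SNP haplotype copy probability
    n_subpops: int = 7
    fst: float = 0.1
    n_qtl: int = 5
    qtl_effect_sd: float = 1.0
    # fraction of the genetic variance carried by the planted QTL; the
    # remainder is spread over n_background small-effect SNPs
    qtl_var_fraction: float = 1.0
    n_background: int = 100
    h2_target: float = 0.69
    n_envs: int = 4
    n_blocks: int = 2
    gxe_ratio: float = 0.25  # sigma2_gxe / sigma2_g
    env_sd: float = 1.0
    block_sd: float = 0.5
    spatial_sd: float = 0.3  # trait units; smooth trend + AR(1) row noise
    mu: float = 40.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genotypes": self.n_genotypes,
            "n_snps": self.n_snps,
            "n_chromosomes": self.n_chromosomes,
            "n_subpops": self.n_subpops,
            "n_envs": self.n_envs,
            "n_blocks": self.n_blocks,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_snps < self.n_chromosomes:
            raise ValueError("n_snps must be >= n_chromosomes")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError(f"degenerate maf_range {self.maf_range}: need 0 < low < high <= 0.5")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must be in [0, 1)")
        if not (0.0 < self.h2_target < 1.0):
            raise ValueError("h2_target must be strictly inside (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_qtl < 0:
            raise ValueError("n_qtl must be >= 0")
        if not (0.0 < self.qtl_var_fraction <= 1.0):
            raise ValueError("qtl_var_fraction must be in (0, 1]")


def _split_counts(total: int, parts: int) -> np.ndarray:
    base = total // parts
    out = np.full(parts, base, dtype=int)
    out[: total - base * parts] += 1
    return out


def _sorted_positions(rng: np.random.Generator, m: int, length: int) -> np.ndarray:
    pos = np.sort(rng.integers(1, max(length, m + 1), size=m))
    # enforce strictly increasing
    for i in range(1, m):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return pos


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a dosage panel with LD and subpopulation structure.

    Returns the genotype matrix and a partial :class:`SimTruth` carrying
    subpopulation labels (QTL fields are filled by
    :func:`simulate_phenotypes`).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_genotypes, config.n_snps

    # ancestral minor-allele frequencies and Balding-Nichols drift
    p_anc = rng.uniform(*config.maf_range, size=m)
    if config.fst > 0 and config.n_subpops > 1:
        f = config.fst
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        p_sub = rng.beta(a, b, size=(config.n_subpops, m))
        p_sub = np.clip(p_sub, 1e-4, 1 - 1e-4)
    else:
        p_sub = np.tile(p_anc, (config.n_subpops, 1))

    labels = np.sort(np.arange(n) % config.n_subpops)
    hap_labels = np.repeat(labels, 2)  # two haplotypes per individual
    n_hap = 2 * n

    snps_per_chrom = _split_counts(m, config.n_chromosomes)
    haplo = np.empty((n_hap, m), dtype=np.int8)
    chrom_col = np.empty(m, dtype=object)
    pos_col = np.empty(m, dtype=int)

    j0 = 0
    for c, mc in enumerate(snps_per_chrom):
        freqs = p_sub[hap_labels][:, j0 : j0 + mc]  # (n_hap, mc)
        fresh = (rng.random((n_hap, mc)) < freqs).astype(np.int8)
        copy = rng.random((n_hap, mc)) < config.ld_rho
        block = np.empty((n_hap, mc), dtype=np.int8)
        block[:, 0] = fresh[:, 0]
        for j in range(1, mc):
            block[:, j] = np.where(copy[:, j], block[:, j - 1], fresh[:, j])
        haplo[:, j0 : j0 + mc] = block
        chrom_col[j0 : j0 + mc] = f"Chr{c + 1:02d}"
        pos_col[j0 : j0 + mc] = _sorted_positions(rng, mc, config.chrom_length_bp)
        j0 += mc

    dosages = (haplo[0::2] + haplo[1::2]).astype(np.int8)

    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    snp_meta = pd.DataFrame(
        {
            "snp_id": [f"{c}_{p}" for c, p in zip(chrom_col, pos_col)],
            "chrom": chrom_col,
            "pos": pos_col,
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
        }
    )
    sample_ids = [f"G{i + 1:04d}" for i in range(n)]
    gm = GenotypeMatrix(dosages, snp_meta, sample_ids)
    truth = SimTruth(subpop_labels=labels)
    return gm, truth


def _field_layout(rng: np.random.Generator, n_genotypes: int, n_blocks: int) -> pd.DataFrame:
    """RCBD layout: blocks are stacked row-bands, genotypes randomized within."""
    n_cols = math.ceil(math.sqrt(n_genotypes))
    n_rows_block = math.ceil(n_genotypes / n_cols)
    rows, cols, geno, block = [], [], [], []
    for b in range(n_blocks):
        order = rng.permutation(n_genotypes)
        for k, g in enumerate(order):
            rows.append(b * n_rows_block + k // n_cols)
            cols.append(k % n_cols)
            geno.append(g)
            block.append(b)
    return pd.DataFrame({"geno_idx": geno, "block": block, "row": rows, "col": cols})


def _spatial_field(rng: np.random.Generator, rows: np.ndarray, cols: np.ndarray, sd: float) -> np.ndarray:
    """Smooth low-order polynomial surface plus AR(1) row noise, scaled to sd."""
    if sd <= 0:
        return np.zeros(len(rows))
    r = (rows - rows.mean()) / max(rows.std(), 1e-9)
    c = (cols - cols.mean()) / max(cols.std(), 1e-9)
    coef = rng.normal(size=5)
    surface = coef[0] * r + coef[1] * c + coef[2] * r * r + coef[3] * c * c + coef[4] * r * c
    # AR(1) along columns within each physical row
    phi = 0.7
    ar = np.zeros(len(rows))
    for rv in np.unique(rows):
        idx = np.flatnonzero(rows == rv)
        idx = idx[np.argsort(cols[idx])]
        e = rng.normal(size=len(idx))
        for k in range(1, len(idx)):
            e[k] += phi * e[k - 1]
        ar[idx] = e
    f = surface + 0.5 * ar / max(ar.std(), 1e-9) * max(surface.std(), 1e-9)
    f = f - f.mean()
    s = f.std()
    return f / s * sd if s > 0 else f


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, SimTruth]:
    """Plot-level trait values over the simulated panel.

    One record per genotype x environment x block on a field grid, with
    additive QTL effects, fixed environment/block effects, iid normal
    GxE, a smooth spatial field per environment, and iid residual noise
    scaled so the generating plot-basis heritability equals
    ``config.h2_target`` exactly.
    """
    config.validate()
    if config.n_qtl > genotypes.n_snps:
        raise ValueError("n_qtl exceeds number of SNPs")
    if genotypes.missing_mask().any():
        raise ValueError("genotypes must be complete (impute first)")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = genotypes.n_samples

    if config.n_qtl > 0:
        qtl_idx = np.sort(rng.choice(genotypes.n_snps, size=config.n_qtl, replace=False))
        effects = rng.normal(0.0, config.qtl_effect_sd, size=config.n_qtl)
        g = genotypes.dosages[:, qtl_idx].astype(float) @ effects
        g = g - g.mean()
        if config.qtl_var_fraction < 1.0 and np.var(g) > 0:
            # polygenic background: many small-effect SNPs carrying the
            # rest of the genetic variance (not tracked as planted QTL)
            n_bg = config.n_background or 100
            pool = np.setdiff1d(np.arange(genotypes.n_snps), qtl_idx)
            bg_idx = rng.choice(pool, size=min(n_bg, pool.size), replace=False)
            bg_eff = rng.normal(0.0, 1.0, size=bg_idx.size)
            g_bg = genotypes.dosages[:, bg_idx].astype(float) @ bg_eff
            g_bg = g_bg - g_bg.mean()
            if np.var(g_bg) > 0:
                f = config.qtl_var_fraction
                target = np.var(g, ddof=1) * (1.0 - f) / f
                g_bg *= math.sqrt(target / np.var(g_bg, ddof=1))
                g = g + g_bg
    else:
        qtl_idx = np.empty(0, dtype=int)
        effects = np.empty(0)
        g = np.zeros(n)

    sigma2_g = float(np.var(g, ddof=1)) if n > 1 else 0.0
    if sigma2_g > 0:
        sigma2_e = sigma2_g * (1.0 - config.h2_target) / config.h2_target
    else:
        sigma2_e = 1.0
    sigma2_gxe = config.gxe_ratio * sigma2_g

    env_eff = rng.normal(0.0, config.env_sd, size=config.n_envs)
    block_eff = rng.normal(0.0, config.block_sd, size=(config.n_envs, config.n_blocks))
    gxe = rng.normal(0.0, math.sqrt(sigma2_gxe), size=(n, config.n_envs)) if sigma2_gxe > 0 else np.zeros((n, config.n_envs))

    frames = []
    for e in range(config.n_envs):
        lay = _field_layout(rng, n, config.n_blocks)
        rows = lay["row"].to_numpy(float)
        cols = lay["col"].to_numpy(float)
        spatial = _spatial_field(rng, rows, cols, config.spatial_sd)
        gi = lay["geno_idx"].to_numpy()
        eps = rng.normal(0.0, math.sqrt(sigma2_e), size=len(lay))
        y = (
            config.mu
            + env_eff[e]
            + block_eff[e, lay["block"].to_numpy()]
            + g[gi]
            + gxe[gi, e]
            + spatial
            + eps
        )
        frames.append(
            pd.DataFrame(
                {
                    "genotype": [genotypes.sample_ids[i] for i in gi],
                    "env": f"E{e + 1}",
                    "block": lay["block"].map(lambda b: f"B{b + 1}"),
                    "row": lay["row"],
                    "col": lay["col"],
                    "value": y,
                }
            )
        )
    pheno = pd.concat(frames, ignore_index=True)
    truth = SimTruth(
        qtl_snp_indices=qtl_idx,
        qtl_effects=effects,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        sigma2_gxe=sigma2_gxe,
        subpop_labels=np.empty(0, dtype=int),
    )
    return pheno, truth


def inject_missing(genotypes: GenotypeMatrix, missing_rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set a seeded random fraction of calls to missing."""
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    if missing_rate == 0.0:
        return GenotypeMatrix(genotypes.dosages.copy(), genotypes.snp_meta, list(genotypes.sample_ids))
    rng = np.random.default_rng(seed)
    mask = rng.random(genotypes.dosages.shape) < missing_rate
    d = genotypes.dosages.copy()
    d[mask] = MISSING
    return GenotypeMatrix(d, genotypes.snp_meta, list(genotypes.sample_ids))
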