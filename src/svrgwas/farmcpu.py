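"""FarmCPU: fixed and random model circulating probability unification.

The scan alternates two models until the pseudo-QTN set stabilises:

* FEM — for every SNP j, ordinary least squares of the phenotype on
  [intercept, structure covariates, pseudo-QTN dosages, dosage_j]; the
  p-value comes from the t statistic of the SNP coefficient. Pseudo-QTNs
  within one bin of the tested SNP are dropped from the design so a SNP
  is never tested against itself.
* REM — y = u + e with cov(u) proportional to a VanRaden kinship built
  from candidate pseudo-QTNs only. Candidates are the per-bin best SNPs
  from the previous FEM; a grid over (bin size, QTN count) is scored by
  the single-component REML likelihood and the best cell's QTN set is
  kept for the next FEM.

Significance is declared by Benjamini-Hochberg FDR on the final scan.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GenotypeMatrix

__all__ = ["FarmcpuConfig", "FarmcpuResult", "fem_scan", "rem_select", "farmcpu_run", "fdr_threshold"]

log = logging.getLogger(__name__)


@dataclass
class FarmcpuConfig:
    bin_sizes_bp: tuple[int, ...] = (500_000, 5_000_000, 50_000_000)
    qtn_counts: tuple[int, ...] = (5, 10, 15)
    max_iterations: int = 10
    fdr_q: float = 0.05
    # eligibility guard: only SNPs at or below this p-value may become
    # pseudo-QTNs (matches reference FarmCPU implementations; keeps the
    # null case from recruiting noise SNPs as covariates)
    qtn_p_threshold: float = 0.01
    # iteration gate: circulation only starts if the first scan's minimum
    # p-value is at or below this; None -> 0.01/m (Bonferroni at 0.01),
    # the reference implementations' default
    p_threshold: float | None = None

    def validate(self) -> None:
        if not self.bin_sizes_bp or not self.qtn_counts:
            raise ValueError("bin_sizes_bp and qtn_counts must be non-empty")
        if not (0.0 < self.fdr_q < 1.0):
            raise ValueError("fdr_q must be in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class FarmcpuResult:
    pvalues: np.ndarray
    effects: np.ndarray
    pseudo_qtns_per_iteration: list[tuple[int, ...]]
    significant: np.ndarray
    n_iterations: int
    converged: bool
    threshold_bin_size: int | None = None
    extra: dict = field(default_factory=dict)


def _chrom_codes(matrix: GenotypeMatrix) -> np.ndarray:
    return matrix.snp_meta["chrom"].astype("category").cat.codes.to_numpy()


def _ols_snp_pvalue(y: np.ndarray, base: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Exact OLS t-test of x added to the base design (small, per-SNP)."""
    design = np.column_stack([base, x])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        return np.nan, np.nan
    resid = y - design @ coef
    df = len(y) - rank
    if df <= 0:
        return np.nan, np.nan
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.pinv(design.T @ design)
    se = np.sqrt(max(sigma2 * xtx_inv[-1, -1], 0.0))
    if se == 0:
        return np.nan, float(coef[-1])
    t = coef[-1] / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(max(p, np.finfo(float).tiny)), float(coef[-1])


def fem_scan(
    matrix: GenotypeMatrix,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    pseudo_qtns: tuple[int, ...] = (),
    bin_size: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP fixed-effect scan with pseudo-QTN covariates.

    Returns (pvalues, effects); SNPs that equal an included pseudo-QTN
    get p = 1 by convention, SNPs whose design is singular (constant or
    collinear dosage) get p = NaN and are treated as non-significant.
    """
    y = np.asarray(y, dtype=float)
    d = matrix.dosages.astype(float)
    n, m = d.shape
    if len(y) != n:
        raise ValueError("phenotype length does not match samples")
    if np.any(d < 0):
        raise ValueError("fem_scan requires complete genotypes")
    pseudo_qtns = tuple(int(j) for j in pseudo_qtns)

    parts = [np.ones((n, 1))]
    if covariates is not None and np.size(covariates):
        parts.append(np.asarray(covariates, dtype=float).reshape(n, -1))
    if pseudo_qtns:
        parts.append(d[:, pseudo_qtns])
    base = np.column_stack(parts)

    # fast path: project everything on the full base once
    q, r = np.linalg.qr(base)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0]))))
    y_r = y - q @ (q.T @ y)
    x_r = d - q @ (q.T @ d)
    sxx = np.einsum("ij,ij->j", x_r, x_r)
    sxy = x_r.T @ y_r
    syy = float(y_r @ y_r)
    df = n - rank - 1
    if df <= 0:
        raise ValueError("design has no residual degrees of freedom")

    pvals = np.full(m, np.nan)
    effects = np.full(m, np.nan)
    scale = np.maximum(np.einsum("ij,ij->j", d, d), 1.0)
    ok = sxx > 1e-9 * scale
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(ok, sxy / np.where(ok, sxx, 1.0), np.nan)
        rss = syy - beta**2 * np.where(ok, sxx, 0.0)
        sigma2 = np.maximum(rss, 0.0) / df
        tstat = beta / np.sqrt(np.maximum(sigma2 / np.where(ok, sxx, 1.0), np.finfo(float).tiny))
    pvals[ok] = np.maximum(2.0 * stats.t.sf(np.abs(tstat[ok]), df), np.finfo(float).tiny)
    effects[ok] = beta[ok]

    if pseudo_qtns:
        # columns exactly equal to an included pseudo-QTN are "tested
        # against themselves": p = 1 by convention, wherever they sit
        dq = d[:, list(pseudo_qtns)]
        for j in np.flatnonzero(~ok):
            if np.any(np.all(dq == d[:, [j]], axis=0)):
                pvals[j] = 1.0

    # redo SNPs whose design must exclude nearby pseudo-QTNs
    if pseudo_qtns:
        chrom = _chrom_codes(matrix)
        pos = matrix.snp_meta["pos"].to_numpy()
        qtn_arr = np.array(pseudo_qtns, dtype=int)
        window = bin_size if bin_size is not None else 0
        near = np.zeros(m, dtype=bool)
        for jq in qtn_arr:
            near |= (chrom == chrom[jq]) & (np.abs(pos - pos[jq]) <= window)
        fixed_part = parts[0] if len(parts) == 2 else np.column_stack(parts[:-1])
        for j in np.flatnonzero(near):
            # substitution rule: pseudo-QTNs within the window (including
            # SNP j itself when it is one) leave the covariate set, so a
            # pseudo-QTN is re-tested rather than tested against itself
            keep = qtn_arr[(chrom[qtn_arr] != chrom[j]) | (np.abs(pos[qtn_arr] - pos[j]) > window)]
            base_j = np.column_stack([fixed_part, d[:, keep]]) if keep.size else fixed_part
            # SNP identical to any still-included pseudo-QTN -> p = 1
            if keep.size and np.any(np.all(d[:, keep] == d[:, [j]], axis=0)):
                pvals[j] = 1.0
                effects[j] = np.nan
                continue
            pvals[j], effects[j] = _ols_snp_pvalue(y, base_j, d[:, j])
        n_nan = int(np.sum(np.isnan(pvals)))
        if n_nan:
            log.debug("fem_scan: %d SNPs with singular design (p=NaN)", n_nan)
    return pvals, effects


def _reml_kinship(y: np.ndarray, K: np.ndarray) -> tuple[float, float, float]:
    """Single-random-effect REML: y = mu + u + e, u ~ N(0, K sg2).

    Profiles the variance ratio on the eigenbasis of K; returns
    (sigma2_g, sigma2_e, restricted log-likelihood).
    """
    n = len(y)
    vals, vecs = np.linalg.eigh((K + K.T) / 2.0)
    vals = np.maximum(vals, 0.0)
    yt = vecs.T @ y
    xt = vecs.T @ np.ones(n)

    def neg_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        dvec = lam * vals + 1.0
        w = 1.0 / dvec
        xwx = np.sum(xt * xt * w)
        if xwx <= 0:
            return np.inf
        beta = np.sum(xt * yt * w) / xwx
        r = yt - xt * beta
        rss = np.sum(r * r * w)
        sigma2 = rss / (n - 1)
        if sigma2 <= 0:
            return np.inf
        ll = -0.5 * (
            (n - 1) * np.log(2 * np.pi * sigma2)
            + np.sum(np.log(dvec))
            + np.log(xwx)
            + (n - 1)
        )
        return -ll

    res = optimize.minimize_scalar(neg_reml, bounds=(-12.0, 12.0), method="bounded",
                                   options={"xatol": 1e-6})
    lam = float(np.exp(res.x))
    dvec = lam * vals + 1.0
    w = 1.0 / dvec
    xwx = np.sum(xt * xt * w)
    beta = np.sum(xt * yt * w) / xwx
    r = yt - xt * beta
    sigma2_e = float(np.sum(r * r * w) / (n - 1))
    return lam * sigma2_e, sigma2_e, float(-res.fun)


def _qtn_kinship(d: np.ndarray) -> np.ndarray | None:
    """VanRaden-style relationship from the pseudo-QTN dosages alone
    (unlike the genome-wide kinship, a single SNP is acceptable here)."""
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        return None
    z = d[:, poly] - 2.0 * p[poly]
    k = z @ z.T / (2.0 * np.sum(p[poly] * (1.0 - p[poly])))
    return (k + k.T) / 2.0


def _bin_candidates(matrix: GenotypeMatrix, pvalues: np.ndarray, bin_size: int) -> np.ndarray:
    """Per-(chromosome, bin) lowest-p SNP, ordered by ascending p."""
    chrom = _chrom_codes(matrix)
    pos = matrix.snp_meta["pos"].to_numpy()
    ok = np.isfinite(pvalues)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return np.empty(0, dtype=int)
    bins = chrom[idx].astype(np.int64) * (2**40) + pos[idx] // bin_size
    order = idx[np.argsort(pvalues[idx], kind="stable")]
    bins_sorted = chrom[order].astype(np.int64) * (2**40) + pos[order] // bin_size
    _, first = np.unique(bins_sorted, return_index=True)
    reps = order[np.sort(first)]
    return reps[np.argsort(pvalues[reps], kind="stable")]


def rem_select(
    matrix: GenotypeMatrix,
    y: np.ndarray,
    pvalues: np.ndarray,
    config: FarmcpuConfig,
) -> tuple[tuple[int, ...], int]:
    """Choose the pseudo-QTN set by REML likelihood over the (bin size,
    QTN count) grid. Returns (sorted QTN indices, winning bin size)."""
    config.validate()
    y = np.asarray(y, dtype=float)
    best: tuple[float, tuple[int, ...], int] | None = None
    for bin_size in config.bin_sizes_bp:
        cands = _bin_candidates(matrix, pvalues, bin_size)
        cands = cands[pvalues[cands] <= config.qtn_p_threshold]
        if cands.size == 0:
            continue
        for count in config.qtn_counts:
            t = min(count, cands.size)
            if t < count:
                warnings.warn(
                    f"only {cands.size} candidate bins for requested {count} pseudo-QTNs; shrinking",
                    stacklevel=2,
                )
            sel = np.sort(cands[:t])
            K = _qtn_kinship(matrix.dosages[:, sel].astype(float))
            if K is None:
                continue
            _, _, ll = _reml_kinship(y, K)
            if best is None or ll > best[0]:
                best = (ll, tuple(int(s) for s in sel), bin_size)
    if best is None:
        return (), int(config.bin_sizes_bp[0])
    return best[1], best[2]


def fdr_threshold(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up; returns indices of significant SNPs.

    NaN p-values are excluded from the ranking and never significant.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if not (0.0 < q <= 1.0):
        raise ValueError("q must be in (0, 1]")
    ok = np.flatnonzero(np.isfinite(p))
    if ok.size == 0:
        return np.empty(0, dtype=int)
    reject, *_ = multipletests(p[ok], alpha=q, method="fdr_bh")
    return ok[reject]


def farmcpu_run(
    matrix: GenotypeMatrix,
    y: np.ndarray,
    config: FarmcpuConfig | None = None,
    covariates: np.ndarray | None = None,
) -> FarmcpuResult:
    """Iterate FEM and REM until the pseudo-QTN set repeats."""
    config = config or FarmcpuConfig()
    config.validate()
    y = np.asarray(y, dtype=float)

    pvals, effects = fem_scan(matrix, y, covariates=covariates)
    history: list[tuple[int, ...]] = [()]
    seen = {frozenset()}
    converged = config.max_iterations == 1
    bin_size: int | None = None
    n_iter = 1
    p_gate = config.p_threshold if config.p_threshold is not None else 0.01 / matrix.n_snps
    if np.nanmin(pvals) > p_gate:
        converged = True  # nothing genome-wide suggestive: stay with the plain scan
    while not converged and n_iter < config.max_iterations:
        qtns, bin_size = rem_select(matrix, y, pvals, config)
        if frozenset(qtns) in seen:
            converged = True
            break
        seen.add(frozenset(qtns))
        history.append(qtns)
        pvals, effects = fem_scan(
            matrix, y, covariates=covariates, pseudo_qtns=qtns, bin_size=bin_size
        )
        n_iter += 1

    significant = fdr_threshold(pvals, config.fdr_q)
    return FarmcpuResult(
        pvalues=pvals,
        effects=effects,
        pseudo_qtns_per_iteration=history,
        significant=significant,
        n_iterations=n_iter,
        converged=converged,
        threshold_bin_size=bin_size,
    )
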