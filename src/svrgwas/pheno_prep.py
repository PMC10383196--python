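"""Plot-level phenotype preparation: spatial adjustment, outlier removal,
mixed-model BLUPs and heritability.

The workflow mirrors standard field-trial practice for an RCBD grown in
several environments: Papadakis nearest-neighbour adjustment of plot
values, removal of gross outliers on standardized residuals, then a
mixed model

    value ~ mu + env + block(env) (fixed) + genotype + genotype:env (random)

fitted by REML. Broad-sense heritability is reported on a plot basis,
H2 = sigma2_G / (sigma2_G + sigma2_E); the entry-mean variant (residual
variance divided by the number of replicated plots per genotype) is
available behind a flag.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .datatypes import BlupResult, VarianceComponents

__all__ = ["nna_adjust", "detect_outliers", "fit_blup", "heritability"]

REQUIRED_COLS = ("genotype", "env", "block", "row", "col", "value")


def _check_cols(plots: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLS if c not in plots.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")


def nna_adjust(plots: pd.DataFrame, neighborhood_radius: int = 1) -> pd.DataFrame:
    """Papadakis nearest-neighbour spatial adjustment, per environment.

    Each plot's residual from its env-block mean is regressed on the
    mean residual of its rook neighbours (same row within
    ``neighborhood_radius`` columns, same column within that many rows);
    the fitted trend is subtracted from the raw value. Plots without
    neighbours are returned unchanged.
    """
    _check_cols(plots)
    if neighborhood_radius < 1:
        raise ValueError("neighborhood_radius must be >= 1")
    out = plots.copy()
    adjusted = out["value"].to_numpy(float).copy()

    for env, sub in out.groupby("env", sort=False):
        coords = sub[["row", "col"]].drop_duplicates()
        if len(coords) <= 1 and len(sub) > 1:
            raise ValueError(f"no spatial information in env {env!r}: all plots share one coordinate")
        block_means = sub.groupby("block")["value"].transform("mean")
        resid = (sub["value"] - block_means).to_numpy(float)
        rows = sub["row"].to_numpy()
        cols = sub["col"].to_numpy()
        lookup: dict[tuple[int, int], list[int]] = {}
        for i, (r, c) in enumerate(zip(rows, cols)):
            lookup.setdefault((r, c), []).append(i)

        cov = np.full(len(sub), np.nan)
        for i, (r, c) in enumerate(zip(rows, cols)):
            neigh: list[float] = []
            for d in range(1, neighborhood_radius + 1):
                for rr, cc in ((r - d, c), (r + d, c), (r, c - d), (r, c + d)):
                    for j in lookup.get((rr, cc), ()):
                        if np.isfinite(resid[j]):
                            neigh.append(resid[j])
            if neigh:
                cov[i] = float(np.mean(neigh))

        ok = np.isfinite(cov) & np.isfinite(resid)
        if ok.sum() >= 3 and np.nanstd(cov[ok]) > 0:
            slope = float(np.polyfit(cov[ok], resid[ok], 1)[0])
        else:
            slope = 0.0
        idx = sub.index.to_numpy()
        adj = sub["value"].to_numpy(float).copy()
        adj[ok] = adj[ok] - slope * cov[ok]
        adjusted[out.index.get_indexer(idx)] = adj

    out["value"] = adjusted
    return out


def detect_outliers(plots: pd.DataFrame, z_cut: float = 3.5) -> tuple[pd.DataFrame, int]:
    """Flag gross outliers on standardized env-block residuals.

    Flagged plot values are set to missing (NaN), following the
    convention of treating detected outliers as missing data points.
    Returns the edited table and the number of plots flagged.
    """
    _check_cols(plots)
    if not (z_cut > 0):
        raise ValueError("z_cut must be > 0")
    if plots["value"].notna().sum() < 10:
        raise ValueError("need at least 10 plots with data for outlier detection")
    out = plots.copy()
    resid = out["value"] - out.groupby(["env", "block"])["value"].transform("mean")
    sd = resid.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return out, 0
    if np.isinf(z_cut):
        return out, 0
    flag = (resid.abs() / sd) > z_cut
    flag = flag.fillna(False)
    out.loc[flag, "value"] = np.nan
    return out, int(flag.sum())


def fit_blup(plots: pd.DataFrame, trait: str = "value", entry_mean_h2: bool = False) -> BlupResult:
    """REML fit of the plot-level mixed model; returns genotype BLUPs.

    Environment and block-within-environment are fixed; genotype and
    genotype-by-environment are random. Raises if the design is
    degenerate (a single genotype) or the optimizer fails to converge.
    """
    _check_cols(plots)
    data = plots.dropna(subset=["value"]).copy()
    genotypes = data["genotype"].unique()
    if len(genotypes) < 2:
        raise ValueError("need >= 2 genotypes to separate genetic variance")
    if len(data) < len(genotypes) + 2:
        raise ValueError("not enough observations for REML")

    n_env = data["env"].nunique()
    fixed = "value ~ 1"
    if n_env > 1:
        fixed += " + C(env)"
    if data.groupby("env")["block"].nunique().max() > 1:
        fixed += " + C(env):C(block)" if n_env > 1 else " + C(block)"

    vc = {"gxe": "0 + C(env)"} if n_env > 1 else None
    model = smf.mixedlm(fixed, data, groups=data["genotype"], re_formula="1", vc_formula=vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True, method="lbfgs", maxiter=200)
        if not fit.converged:
            fit = model.fit(reml=True, method="powell", maxiter=500)
    if not fit.converged:
        raise RuntimeError(f"REML did not converge for trait {trait!r}")

    sigma2_g = max(float(np.asarray(fit.cov_re)[0, 0]), 0.0)
    sigma2_gxe = max(float(fit.vcomp[0]), 0.0) if vc else 0.0
    sigma2_e = max(float(fit.scale), 0.0)
    if sigma2_g + sigma2_e <= 0:
        raise RuntimeError(f"degenerate variance components for trait {trait!r}")

    mu = float(fit.predict(data).mean())
    re = fit.random_effects
    u = pd.Series({g: float(re[g].iloc[0]) for g in genotypes}, name=trait)
    blups = (mu + u).reindex(sorted(genotypes))

    block_effects = {
        name: float(val)
        for name, val in fit.fe_params.items()
        if "block" in name.lower() or "env" in name.lower()
    }
    vcomp = VarianceComponents(
        sigma2_g=sigma2_g, sigma2_e=sigma2_e, sigma2_gxe=sigma2_gxe, mu=mu,
        block_effects=block_effects,
    )
    if entry_mean_h2:
        n_rep = data.groupby("genotype").size().mean()
        h2 = sigma2_g / (sigma2_g + sigma2_e / n_rep)
    else:
        h2 = heritability(vcomp)
    return BlupResult(blups=blups, variance_components=vcomp, h2=h2)


def heritability(vc: VarianceComponents) -> float:
    """Plot-basis broad-sense heritability sigma2_G/(sigma2_G+sigma2_E)."""
    denom = vc.sigma2_g + vc.sigma2_e
    if denom <= 0:
        raise ValueError("sigma2_g + sigma2_e must be > 0")
    return vc.sigma2_g / denom
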