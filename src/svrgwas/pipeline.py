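"""End-to-end pipeline: simulate/load -> phenotype prep -> genotype QC ->
population structure -> GWAS (FarmCPU and/or SVR) -> QTL regions, plus a
method-comparison benchmark over replicated simulations.

Every stochastic stage is seeded from the single pipeline seed, so a run
is reproducible bit-for-bit from its manifest (seed + config).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .datatypes import GenotypeMatrix, GwasResult, SimTruth
from .farmcpu import FarmcpuConfig, farmcpu_run
from .geno_qc import filter_samples, filter_snps, impute_markov
from .pheno_prep import detect_outliers, fit_blup, nna_adjust
from .popstruct import kinship_vanraden, structure_covariates
from .regions import DEFAULT_WINDOW_BP, colocalize, flanking_regions, peak_select
from .simdata import SimConfig, inject_missing, simulate_genotypes, simulate_phenotypes
from .svr_gwas import SvrConfig, svr_gwas_run

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "results/run"
    genotype_path: str | None = None  # None -> simulate
    phenotype_path: str | None = None
    annotation_path: str | None = None
    traits: tuple[str, ...] = ("value",)
    methods: tuple[str, ...] = ("farmcpu", "svr")
    seed: int = 0
    # module configs
    sim: SimConfig = field(default_factory=SimConfig)
    farmcpu: FarmcpuConfig = field(default_factory=FarmcpuConfig)
    svr: SvrConfig = field(default_factory=SvrConfig)
    # QC thresholds
    max_missing_sample: float = 0.5
    maf_min: float = 0.05
    max_het: float = 0.5
    max_missing_snp: float = 0.5
    # phenotype prep
    nna_radius: int = 1
    outlier_z: float = 3.5
    # structure / regions
    structure_k: int = 7
    region_window_bp: int = DEFAULT_WINDOW_BP

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.name == "sim":
                v = SimConfig(**v)
            elif f.name == "farmcpu":
                v = FarmcpuConfig(**{k: tuple(x) if isinstance(x, list) else x for k, x in v.items()})
            elif f.name == "svr":
                v = SvrConfig(**v)
            elif isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
        return cls(**kwargs)

    def fingerprint(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # where results land does not change them
        blob = json.dumps(d, sort_keys=True, default=enc)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _result_table(matrix: GenotypeMatrix, method: str, stat: np.ndarray,
                  raw: np.ndarray, threshold: float, sig: np.ndarray,
                  effects: np.ndarray | None = None) -> pd.DataFrame:
    tab = matrix.snp_meta[["snp_id", "chrom", "pos"]].copy()
    tab["method"] = method
    tab["raw"] = raw
    tab["stat"] = stat
    tab["effect"] = effects if effects is not None else np.nan
    tab["threshold"] = threshold
    tab["significant"] = False
    tab.loc[tab.index[sig], "significant"] = True
    return tab


def run_gwas_method(
    method: str,
    matrix: GenotypeMatrix,
    y: np.ndarray,
    covariates: np.ndarray | None,
    farmcpu_cfg: FarmcpuConfig,
    svr_cfg: SvrConfig,
) -> GwasResult:
    """One association scan, normalized into a shared result schema
    (``stat`` is -log10 p for FarmCPU, scaled importance for SVR)."""
    if method == "farmcpu":
        res = farmcpu_run(matrix, y, farmcpu_cfg, covariates=covariates)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = -np.log10(res.pvalues)
        if res.significant.size:
            thr = float(np.nanmin(stat[res.significant]))
        else:
            thr = float("inf")
        tab = _result_table(matrix, method, stat, res.pvalues, thr, res.significant, res.effects)
        return GwasResult(method=method, table=tab, threshold=thr, significant=res.significant)
    if method == "svr":
        res = svr_gwas_run(matrix.dosages.astype(float), y, svr_cfg)
        tab = _result_table(
            matrix, method, res.scaled_importance, res.raw_importance,
            res.threshold_scaled, res.significant,
        )
        return GwasResult(
            method=method, table=tab, threshold=res.threshold_scaled, significant=res.significant
        )
    raise ValueError(f"unknown GWAS method {method!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; writes all result files under
    ``config.out_dir`` and returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "seed": config.seed,
        "config_fingerprint": config.fingerprint(),
        "stages": {},
    }

    stage = "input"
    try:
        truth: SimTruth | None = None
        if config.genotype_path is None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            gm, truth = simulate_genotypes(sim)
            pheno, ptruth = simulate_phenotypes(gm, sim, seed=config.seed + 1)
            ptruth.subpop_labels = truth.subpop_labels
            truth = ptruth
            if sim.missing_rate > 0:
                gm = inject_missing(gm, sim.missing_rate, seed=config.seed + 2)
            sio.write_vcf(gm, out / "genotypes.vcf")
            pheno.to_csv(out / "phenotypes.csv", index=False)
            sio.write_json(
                {
                    "qtl_snp_indices": truth.qtl_snp_indices,
                    "qtl_effects": truth.qtl_effects,
                    "sigma2_g": truth.sigma2_g,
                    "sigma2_e": truth.sigma2_e,
                    "sigma2_gxe": truth.sigma2_gxe,
                    "subpop_labels": truth.subpop_labels,
                },
                out / "truth.json",
            )
            traits = ("value",)
        else:
            gm = sio.read_genotypes(config.genotype_path)
            if config.phenotype_path is None:
                raise ValueError("phenotype_path required with genotype_path")
            pheno = sio.read_phenotypes(config.phenotype_path)
            traits = config.traits
        manifest["stages"]["input"] = {"n_samples": gm.n_samples, "n_snps": gm.n_snps}

        stage = "pheno_prep"
        blups: dict[str, pd.Series] = {}
        prep_info = {}
        for trait in traits:
            cols = dict(value=trait) if trait != "value" else {}
            tab = pheno.rename(columns={v: k for k, v in cols.items()}) if cols else pheno
            tab = nna_adjust(tab, config.nna_radius)
            tab, n_out = detect_outliers(tab, config.outlier_z)
            res = fit_blup(tab, trait=trait)
            res.n_outliers_removed = n_out
            blups[trait] = res.blups
            prep_info[trait] = {
                "h2": res.h2,
                "sigma2_g": res.variance_components.sigma2_g,
                "sigma2_e": res.variance_components.sigma2_e,
                "sigma2_gxe": res.variance_components.sigma2_gxe,
                "n_outliers_removed": n_out,
            }
        blup_tab = pd.DataFrame(blups)
        blup_tab.index.name = "genotype"
        blup_tab.to_csv(out / "blups.csv", float_format="%.8g")
        manifest["stages"]["pheno_prep"] = prep_info

        stage = "geno_qc"
        gm_s, rep_s = filter_samples(gm, config.max_missing_sample)
        gm_f, rep_f = filter_snps(gm_s, config.maf_min, config.max_het, config.max_missing_snp)
        gm_i, rep_i = impute_markov(gm_f, seed=config.seed + 3)
        qc = rep_s.to_dict()
        qc.update({k: v for k, v in rep_f.to_dict().items() if "snps_removed" in k})
        qc["n_imputed"] = rep_i.n_imputed
        qc["n_snps_retained"] = gm_i.n_snps
        sio.write_json(qc, out / "qc_report.json")
        sio.write_vcf(gm_i, out / "genotypes.qc.vcf")
        manifest["stages"]["geno_qc"] = qc

        stage = "popstruct"
        k = min(config.structure_k, gm_i.n_samples)
        Q = structure_covariates(gm_i, k=k)
        Q.to_csv(out / "structure_covariates.csv", float_format="%.8g")
        sio.write_kinship_tsv(kinship_vanraden(gm_i), gm_i.sample_ids, out / "kinship.tsv")

        stage = "gwas"
        ann = sio.read_annotations(config.annotation_path) if config.annotation_path else None
        gwas_info = {}
        for trait in traits:
            y = blups[trait].reindex(gm_i.sample_ids)
            if y.isna().any():
                raise ValueError(f"missing BLUPs for samples: {list(y.index[y.isna()])[:5]}")
            yv = y.to_numpy(float)
            for method in config.methods:
                fcfg = dataclasses.replace(config.farmcpu)
                scfg = dataclasses.replace(config.svr, seed=config.seed + 10)
                res = run_gwas_method(method, gm_i, yv, Q.to_numpy(), fcfg, scfg)
                sio.write_gwas_tsv(res.table, out / f"gwas_{method}_{trait}.tsv")

                stage = "regions"
                sig_tab = res.table[res.table["significant"]]
                peaks = peak_select(sig_tab, config.region_window_bp)
                regions = flanking_regions(peaks, config.region_window_bp)
                sio.write_regions_bed(regions, out / f"regions_{method}_{trait}.bed")
                info = {
                    "n_significant": int(res.significant.size),
                    "n_regions": len(regions),
                    "threshold": res.threshold,
                }
                if ann is not None:
                    hits = colocalize(regions, ann)
                    hits_tab = pd.DataFrame(
                        [
                            {
                                "chrom": h.region.chrom,
                                "region_start": h.region.start,
                                "region_end": h.region.end,
                                "peak_snp": h.region.peak_snp,
                                "annotation": h.annotation_name,
                                "overlap_bp": h.overlap_bp,
                            }
                            for h in hits
                        ]
                    )
                    hits_tab.to_csv(out / f"coloc_{method}_{trait}.tsv", sep="\t", index=False)
                    info["n_coloc_hits"] = len(hits)
                if truth is not None and truth.qtl_snp_indices.size:
                    rec, nfp = _recall_fp(gm_i, res.significant, gm, truth, config.region_window_bp)
                    info["planted_qtl_recall"] = rec
                    info["false_positives"] = nfp
                gwas_info[f"{method}_{trait}"] = info
                stage = "gwas"
        manifest["stages"]["gwas"] = gwas_info
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (config {config.fingerprint()}): {err}"
        ) from err

    manifest["runtime_s"] = round(time.time() - t0, 2)
    sio.write_json(manifest, out / "manifest.json")
    return manifest


def _recall_fp(
    gm_qc: GenotypeMatrix,
    significant: np.ndarray,
    gm_orig: GenotypeMatrix,
    truth: SimTruth,
    window_bp: int,
) -> tuple[float, int]:
    """Fraction of planted QTL with a significant SNP within window_bp,
    and the count of significant SNPs near no QTL."""
    if truth.qtl_snp_indices.size == 0:
        return float("nan"), int(significant.size)
    qtl_chrom = gm_orig.snp_meta["chrom"].to_numpy()[truth.qtl_snp_indices]
    qtl_pos = gm_orig.snp_meta["pos"].to_numpy()[truth.qtl_snp_indices]
    sig_chrom = gm_qc.snp_meta["chrom"].to_numpy()[significant]
    sig_pos = gm_qc.snp_meta["pos"].to_numpy()[significant]
    hit = 0
    near_any = np.zeros(len(significant), dtype=bool)
    for qc_, qp in zip(qtl_chrom, qtl_pos):
        near = (sig_chrom == qc_) & (np.abs(sig_pos - qp) <= window_bp)
        if near.any():
            hit += 1
        near_any |= near
    return hit / len(qtl_pos), int((~near_any).sum())


def benchmark(
    sim: SimConfig,
    n_reps: int = 10,
    methods: tuple[str, ...] = ("farmcpu", "svr"),
    farmcpu_cfg: FarmcpuConfig | None = None,
    svr_cfg: SvrConfig | None = None,
    window_bp: int = DEFAULT_WINDOW_BP,
    seed: int = 0,
    use_blup: bool = True,
) -> pd.DataFrame:
    """Planted-QTL recall and false positives per method over replicated
    simulations. Returns one row per (replicate, method)."""
    if sim.n_qtl == 0:
        pass  # null benchmark: recall is NaN, false positives reported
    farmcpu_cfg = farmcpu_cfg or FarmcpuConfig()
    svr_cfg = svr_cfg or SvrConfig()
    rows = []
    for rep in range(n_reps):
        rep_seed = seed + 1000 * rep
        cfg = dataclasses.replace(sim, seed=rep_seed)
        gm, _ = simulate_genotypes(cfg)
        pheno, truth = simulate_phenotypes(gm, cfg, seed=rep_seed + 1)
        if use_blup:
            res = fit_blup(nna_adjust(pheno))
            y = res.blups.reindex(gm.sample_ids).to_numpy(float)
        else:
            y = pheno.groupby("genotype")["value"].mean().reindex(gm.sample_ids).to_numpy(float)
        Q = structure_covariates(gm, k=min(sim.n_subpops, gm.n_samples))
        largest = (
            int(truth.qtl_snp_indices[np.argmax(np.abs(truth.qtl_effects))])
            if truth.qtl_snp_indices.size
            else None
        )
        for method in methods:
            scfg = dataclasses.replace(svr_cfg, seed=rep_seed + 2)
            res_m = run_gwas_method(method, gm, y, Q.to_numpy(), farmcpu_cfg, scfg)
            recall, nfp = _recall_fp(gm, res_m.significant, gm, truth, window_bp)
            row = {
                "rep": rep,
                "method": method,
                "n_significant": int(res_m.significant.size),
                "recall": recall,
                "false_positives": nfp,
            }
            if largest is not None:
                chrom = gm.snp_meta["chrom"].to_numpy()
                pos = gm.snp_meta["pos"].to_numpy()
                sig = res_m.significant
                row["largest_qtl_hit"] = bool(
                    np.any(
                        (chrom[sig] == chrom[largest])
                        & (np.abs(pos[sig] - pos[largest]) <= window_bp)
                    )
                )
            rows.append(row)
    return pd.DataFrame(rows)
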