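"""Simulate the study panel: 227 genotypes x 2,000 SNPs on 20 chromosomes
with LD, seven subpopulations, and plot-level trait values (four
environments x two blocks, RCBD) at a generating heritability of 0.69.

Writes genotypes (VCF + HapMap), phenotypes (CSV) and the ground-truth
sidecar under results/panel/.
"""

import sys
from pathlib import Path

import numpy as np

from svrgwas import SimConfig, inject_missing, simulate_genotypes, simulate_phenotypes
from svrgwas import io as sio

OUT = Path("results/panel")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2023


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(missing_rate=0.02, seed=SEED)
    gm, gtruth = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(gm, cfg, seed=SEED + 1)
    gm_obs = inject_missing(gm, cfg.missing_rate, seed=SEED + 2)

    sio.write_vcf(gm_obs, OUT / "genotypes.vcf")
    sio.write_hapmap(gm_obs, OUT / "genotypes.hmp.txt")
    pheno.to_csv(OUT / "phenotypes.csv", index=False)
    sio.write_json(
        {
            "qtl_snp_indices": truth.qtl_snp_indices,
            "qtl_effects": truth.qtl_effects,
            "sigma2_g": truth.sigma2_g,
            "sigma2_e": truth.sigma2_e,
            "sigma2_gxe": truth.sigma2_gxe,
            "subpop_labels": gtruth.subpop_labels,
            "seed": SEED,
        },
        OUT / "truth.json",
    )

    maf = gm.maf()
    print(f"panel: {gm.n_samples} genotypes x {gm.n_snps} SNPs "
          f"on {gm.snp_meta['chrom'].nunique()} chromosomes")
    print(f"MAF: median {np.median(maf):.3f}, range {maf.min():.3f}-{maf.max():.3f}")
    print(f"planted QTL at SNP indices {truth.qtl_snp_indices.tolist()} "
          f"with effects {np.round(truth.qtl_effects, 3).tolist()}")
    print(f"generating h2 = {truth.sigma2_g / (truth.sigma2_g + truth.sigma2_e):.3f}")
    print(f"wrote {OUT}/genotypes.vcf, genotypes.hmp.txt, phenotypes.csv, truth.json")


if __name__ == "__main__":
    main()
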