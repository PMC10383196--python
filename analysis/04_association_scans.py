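"""Run both association scans on the BLUPs over the QC'd panel:

* FarmCPU — iterative fixed/random model circulation with pseudo-QTN
  covariates and Benjamini-Hochberg FDR at q = 0.05;
* SVR-mediated GWAS — cross-validated linear-SVR variable importance
  (5-fold x 10 repetitions), 0-100 scaling, and a 200-permutation global
  empirical threshold at alpha = 0.05.

Structure covariates are the top 6 PCs (K = 7 subpopulations). Writes
one results TSV per method under results/gwas/ sharing a single schema.
"""

from pathlib import Path

import pandas as pd

from svrgwas import FarmcpuConfig, SvrConfig, structure_covariates
from svrgwas import io as sio
from svrgwas.pipeline import run_gwas_method

QC = Path("results/qc")
PREP = Path("results/prep")
OUT = Path("results/gwas")
SEED = 11


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gm = sio.read_genotypes(QC / "genotypes.qc.vcf")
    blups = pd.read_csv(PREP / "blups.csv", index_col=0)
    y = blups["value"].reindex(gm.sample_ids).to_numpy(float)
    Q = structure_covariates(gm, k=7)

    fcfg = FarmcpuConfig(fdr_q=0.05)
    scfg = SvrConfig(n_permutations=200, alpha=0.05, seed=SEED)
    for method in ("farmcpu", "svr"):
        res = run_gwas_method(method, gm, y, Q.to_numpy(), fcfg, scfg)
        sio.write_gwas_tsv(res.table, OUT / f"gwas_{method}.tsv")
        sig = res.table[res.table["significant"]]
        print(f"{method}: {len(sig)} significant SNPs "
              f"on chromosomes {sorted(sig['chrom'].unique())}")

    print(f"wrote {OUT}/gwas_farmcpu.tsv and gwas_svr.tsv")


if __name__ == "__main__":
    main()
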