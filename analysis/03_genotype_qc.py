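"""Genotype quality control: drop samples with > 50% missing calls, drop
SNPs by missingness / MAF < 0.05 / heterozygosity > 50%, impute the
remaining gaps with the first-order Markov model, and summarize LD decay
along the genome.

Reads results/panel/genotypes.vcf; writes the QC'd VCF, a QC report and
the binned LD-decay curve under results/qc/.
"""

from pathlib import Path

from svrgwas import filter_samples, filter_snps, impute_markov, ld_decay
from svrgwas import io as sio

PANEL = Path("results/panel")
OUT = Path("results/qc")
SEED = 77


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gm = sio.read_genotypes(PANEL / "genotypes.vcf")
    print(f"input: {gm.n_samples} samples x {gm.n_snps} SNPs")

    gm, rep_s = filter_samples(gm, max_missing_fraction=0.5)
    gm, rep_f = filter_snps(gm, maf_min=0.05, max_het=0.5, max_missing=0.5)
    gm, rep_i = impute_markov(gm, seed=SEED)

    report = {
        "n_samples_removed": rep_s.n_samples_removed,
        "n_snps_removed_missing": rep_f.n_snps_removed_missing,
        "n_snps_removed_maf": rep_f.n_snps_removed_maf,
        "n_snps_removed_het": rep_f.n_snps_removed_het,
        "n_imputed": rep_i.n_imputed,
        "n_samples_retained": gm.n_samples,
        "n_snps_retained": gm.n_snps,
    }
    sio.write_json(report, OUT / "qc_report.json")
    sio.write_vcf(gm, OUT / "genotypes.qc.vcf")

    curve = ld_decay(gm, max_dist_bp=10_000_000, n_bins=25)
    curve.to_frame().to_csv(OUT / "ld_decay.tsv", sep="\t", index=False,
                            float_format="%.5g")

    print(f"samples removed: {rep_s.n_samples_removed}; SNPs removed "
          f"(missing/MAF/het): {rep_f.n_snps_removed_missing}/"
          f"{rep_f.n_snps_removed_maf}/{rep_f.n_snps_removed_het}")
    print(f"imputed {rep_i.n_imputed} calls; retained {gm.n_snps} SNPs")
    print(f"LD half-decay distance: {curve.decay_distance_bp / 1000:.0f} kb")
    print(f"wrote {OUT}/genotypes.qc.vcf, qc_report.json, ld_decay.tsv")


if __name__ == "__main__":
    main()
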