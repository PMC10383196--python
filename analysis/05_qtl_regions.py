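"""Turn each method's significant SNPs into peak-anchored QTL regions
(+-150 kb flanking windows, merged when overlapping), estimate the
allelic effect of every peak SNP, and co-localize the regions with the
planted-QTL truth intervals as a synthetic annotation track.

Reads results/gwas/ and results/panel/truth.json; writes region BEDs,
peak-effect tables and co-localization hits under results/regions/.
"""

import json
from pathlib import Path

import pandas as pd

from svrgwas import allelic_effect, colocalize, flanking_regions, peak_select
from svrgwas import io as sio

PANEL = Path("results/panel")
QC = Path("results/qc")
GWAS = Path("results/gwas")
PREP = Path("results/prep")
OUT = Path("results/regions")
WINDOW = 150_000


def truth_annotations(gm_meta: pd.DataFrame) -> pd.DataFrame:
    """Synthetic annotation intervals: +-50 kb around each planted QTL
    (stand-in for an external QTL/gene track, which a real analysis
    would read from BED/GFF3)."""
    truth = json.loads((PANEL / "truth.json").read_text())
    rows = []
    for k, j in enumerate(truth["qtl_snp_indices"]):
        chrom = gm_meta.loc[j, "chrom"]
        pos = int(gm_meta.loc[j, "pos"])
        rows.append((chrom, max(0, pos - 50_000), pos + 50_000, f"planted_qtl_{k + 1}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gm = sio.read_genotypes(QC / "genotypes.qc.vcf")
    y = (
        pd.read_csv(PREP / "blups.csv", index_col=0)["value"]
        .reindex(gm.sample_ids)
        .to_numpy(float)
    )
    panel_gm = sio.read_genotypes(PANEL / "genotypes.vcf")
    ann = truth_annotations(panel_gm.snp_meta)

    for method in ("farmcpu", "svr"):
        tab = pd.read_csv(GWAS / f"gwas_{method}.tsv", sep="\t")
        sig = tab[tab["significant"]]
        peaks = peak_select(sig, WINDOW)
        regions = flanking_regions(peaks, WINDOW)
        sio.write_regions_bed(regions, OUT / f"regions_{method}.bed")

        effects = []
        snp_lookup = {sid: j for j, sid in enumerate(gm.snp_meta["snp_id"])}
        for r in regions:
            j = snp_lookup[r.peak_snp]
            eff, class_means = allelic_effect(gm, y, j)
            effects.append(
                {"peak_snp": r.peak_snp, "chrom": r.chrom,
                 "region_start": r.start, "region_end": r.end,
                 "allelic_effect": eff,
                 **{f"mean_dosage_{k}": v for k, v in class_means.items()}}
            )
        pd.DataFrame(effects).to_csv(OUT / f"peak_effects_{method}.tsv",
                                     sep="\t", index=False, float_format="%.5g")

        hits = colocalize(regions, ann)
        print(f"{method}: {len(regions)} regions, "
              f"{len(hits)} co-localized with planted-QTL intervals")
        with open(OUT / f"coloc_{method}.tsv", "w") as fh:
            fh.write("chrom\tregion_start\tregion_end\tpeak_snp\tannotation\toverlap_bp\n")
            for h in hits:
                fh.write(f"{h.region.chrom}\t{h.region.start}\t{h.region.end}"
                         f"\t{h.region.peak_snp}\t{h.annotation_name}\t{h.overlap_bp}\n")

    print(f"wrote region BEDs, peak-effect and co-localization tables to {OUT}")


if __name__ == "__main__":
    main()
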