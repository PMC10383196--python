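"""Readers and writers for the formats the pipeline touches.

Genotypes: VCF (read via cyvcf2, written as plain text) and the HapMap
tab dialect (11 leading columns, IUPAC or allele-pair genotype codes).
Phenotypes: delimited plot tables. Annotations: BED / GFF3 via pyranges,
normalized to 0-based half-open intervals. Results: TSV tables sharing
one schema across GWAS methods, BED for regions, JSON for QC reports and
run manifests.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, QtlRegion

log = logging.getLogger(__name__)

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
_IUPAC_REV = {v: k for k, v in _IUPAC.items()}

HAPMAP_COLS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Dispatch on format ('vcf' or 'hapmap'; inferred from suffix)."""
    path = Path(path)
    if fmt is None:
        if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
            fmt = "vcf"
        elif path.suffix in (".hmp", ".txt") or path.name.endswith(".hmp.txt"):
            fmt = "hapmap"
        else:
            raise ValueError(f"cannot infer genotype format from {path.name!r}")
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "hapmap":
        return read_hapmap(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _finalize_matrix(
    dosages: list[list[int]],
    meta_rows: list[tuple],
    sample_ids: list[str],
    n_multi: int,
) -> GenotypeMatrix:
    if n_multi:
        log.info("skipped %d multiallelic sites", n_multi)
    meta = pd.DataFrame(meta_rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    for _, sub in meta.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"unsorted or duplicated positions on {sub['chrom'].iloc[0]}")
    d = np.array(dosages, dtype=np.int8).T if dosages else np.empty((len(sample_ids), 0), dtype=np.int8)
    return GenotypeMatrix(d, meta, sample_ids)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Biallelic SNPs from a VCF; GT mapped to alt-allele dosage."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    dosages: list[list[int]] = []
    meta_rows: list[tuple] = []
    n_multi = 0
    code = {0: 0, 1: 1, 3: 2, 2: MISSING}  # cyvcf2 gt_types
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        row = [code[int(t)] for t in v.gt_types]
        sid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        meta_rows.append((sid, v.CHROM, int(v.POS), v.REF, v.ALT[0]))
        dosages.append(row)
    vcf.close()
    return _finalize_matrix(dosages, meta_rows, sample_ids, n_multi)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=svrgwas\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(matrix.snp_meta["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.sample_ids) + "\n")
        for j, row in matrix.snp_meta.iterrows():
            calls = "\t".join(gt[int(x)] for x in matrix.dosages[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_hapmap(path: str | Path) -> GenotypeMatrix:
    """HapMap dialect: 11 leading columns then one genotype column per
    sample; accepts IUPAC single-letter or two-letter genotype codes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if len(df.columns) < 12:
        raise ValueError("HapMap file needs 11 metadata columns plus samples")
    sample_ids = list(df.columns[11:])
    dosages: list[list[int]] = []
    meta_rows: list[tuple] = []
    n_multi = 0
    for _, row in df.iterrows():
        alleles = str(row.iloc[1]).split("/")
        if len(alleles) != 2:
            n_multi += 1
            continue
        ref, alt = alleles
        row_d: list[int] = []
        for g in row.iloc[11:]:
            g = str(g).upper()
            if g in ("NN", "N", "--", "NA"):
                row_d.append(MISSING)
                continue
            if len(g) == 1:
                pair = _IUPAC_REV.get(g)
                if pair is None:
                    row_d.append(MISSING)
                    continue
                pair = "".join(sorted(pair)) if len(pair) == 2 else list(pair)[0] * 2
            elif len(g) == 2:
                pair = g
            else:
                row_d.append(MISSING)
                continue
            row_d.append(sum(1 for a in pair if a == alt) if set(pair) <= {ref, alt} else MISSING)
        meta_rows.append((str(row.iloc[0]), str(row.iloc[2]), int(row.iloc[3]), ref, alt))
        dosages.append(row_d)
    return _finalize_matrix(dosages, meta_rows, sample_ids, n_multi)


def write_hapmap(matrix: GenotypeMatrix, path: str | Path) -> None:
    rows = []
    for j, meta in matrix.snp_meta.iterrows():
        ref, alt = meta["ref"], meta["alt"]
        codes = {0: ref + ref, 1: ref + alt, 2: alt + alt, MISSING: "NN"}
        row = [meta["snp_id"], f"{ref}/{alt}", meta["chrom"], str(meta["pos"]),
               "+", "NA", "NA", "NA", "NA", "NA", "NA"]
        row += [codes[int(x)] for x in matrix.dosages[:, j]]
        rows.append(row)
    out = pd.DataFrame(rows, columns=HAPMAP_COLS + list(matrix.sample_ids))
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    need = {"genotype", "env", "block", "row", "col"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df


def read_annotations(path: str | Path) -> pd.DataFrame:
    """BED or GFF3 intervals, normalized to chrom/start/end/name
    (0-based half-open)."""
    import pyranges as pr

    path = Path(path)
    name = path.name.lower()
    if name.endswith((".bed", ".bed.gz")):
        gr = pr.read_bed(str(path))
        df = gr.df
        out = pd.DataFrame(
            {
                "chrom": df["Chromosome"].astype(str),
                "start": df["Start"].astype(int),
                "end": df["End"].astype(int),
                "name": df["Name"].astype(str) if "Name" in df else df.index.astype(str),
            }
        )
    elif name.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")):
        gr = pr.read_gff3(str(path))
        df = gr.df
        label = None
        for cand in ("ID", "Name", "gene_id"):
            if cand in df.columns:
                label = df[cand].astype(str)
                break
        out = pd.DataFrame(
            {
                "chrom": df["Chromosome"].astype(str),
                "start": df["Start"].astype(int),
                "end": df["End"].astype(int),
                "name": label if label is not None else df.index.astype(str),
            }
        )
    else:
        raise ValueError(f"unknown annotation format: {path.name!r}")
    bad = out[out["start"] > out["end"]]
    if len(bad):
        raise ValueError(f"malformed intervals at rows {list(bad.index)}")
    return out


def write_gwas_tsv(result_table: pd.DataFrame, path: str | Path) -> None:
    result_table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_regions_bed(regions: list[QtlRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.peak_snp}\t{r.peak_statistic:.6g}\n")


def write_kinship_tsv(k: np.ndarray, sample_ids: list[str], path: str | Path) -> None:
    pd.DataFrame(k, index=sample_ids, columns=sample_ids).to_csv(
        path, sep="\t", float_format="%.8g"
    )


def read_kinship_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float), list(df.index)


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
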