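"""Genomic relatedness and population-structure covariates for GWAS.

Kinship uses VanRaden's method 1: K = Z Z' / (2 * sum p_j (1 - p_j))
with Z the allele-frequency-centred dosage matrix. Structure covariates
are either the top k-1 principal components of the centred dosages, or
an imported admixture-proportion (Q) matrix with the last column dropped
to avoid collinearity — in a GWAS the covariates only need to absorb
stratification, not infer ancestry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix

__all__ = ["kinship_vanraden", "structure_covariates", "import_q"]


def kinship_vanraden(matrix: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """VanRaden genomic relationship matrix from complete 0/1/2 dosages."""
    d = matrix.dosages if isinstance(matrix, GenotypeMatrix) else np.asarray(matrix)
    d = d.astype(float)
    if np.any(d < 0):
        raise ValueError("kinship requires complete (imputed) genotypes")
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need >= 2 polymorphic SNPs for kinship")
    z = d[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    k = z @ z.T / denom
    return (k + k.T) / 2.0


def structure_covariates(matrix: GenotypeMatrix, k: int = 7) -> pd.DataFrame:
    """Top k-1 principal components of centred dosages as GWAS cofactors.

    Columns are mean-centred; the sign of each component is fixed so the
    largest-magnitude loading is positive, making the result invariant
    (not just up to sign) under sample reordering.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = matrix.n_samples
    if k - 1 >= n:
        raise ValueError(f"k-1={k - 1} components require more than {n} samples")
    d = matrix.dosages.astype(float)
    if np.any(d < 0):
        raise ValueError("structure covariates require complete genotypes")
    z = d - d.mean(axis=0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    pcs = u[:, : k - 1] * s[: k - 1]
    for j in range(pcs.shape[1]):
        load = vt[j]
        if load[np.argmax(np.abs(load))] < 0:
            pcs[:, j] = -pcs[:, j]
    pcs = pcs - pcs.mean(axis=0)
    df = pd.DataFrame(pcs, index=matrix.sample_ids, columns=[f"PC{i + 1}" for i in range(k - 1)])
    df.attrs["method"] = "pca"
    return df


def import_q(q: pd.DataFrame, sample_ids: list[str], tol: float = 1e-6) -> pd.DataFrame:
    """Use an externally computed admixture Q matrix as covariates.

    Rows are matched to ``sample_ids`` by index; row sums must be ~1;
    the last column is dropped (the proportions are collinear) and the
    remaining columns mean-centred.
    """
    missing = [s for s in sample_ids if s not in q.index]
    if missing:
        raise ValueError(f"Q matrix missing sample IDs: {missing[:10]}")
    qq = q.loc[sample_ids].astype(float)
    rs = qq.sum(axis=1)
    bad = rs[(rs - 1.0).abs() > max(tol, 1e-3)]
    if len(bad):
        raise ValueError(f"Q rows do not sum to 1 (admixture proportions): {list(bad.index[:10])}")
    if qq.shape[1] < 2:
        raise ValueError("Q matrix needs >= 2 ancestry columns")
    out = qq.iloc[:, :-1]
    out = out - out.mean(axis=0)
    out.attrs["method"] = "imported"
    return out
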