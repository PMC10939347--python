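"""Kinship (KING-robust) and genotype PCA for a clone panel.

The within-pair robust kinship estimator is

    phi = (N_het,het - 2 N_opp) / (N_het(i) + N_het(j))

where N_het,het counts sites heterozygous in both samples, N_opp sites with
opposite homozygotes and N_het(x) heterozygous sites in sample x. It is
robust to population structure, which matters here because the panel mixes
near-identical clones with an unrelated outgroup. phi = 0.5 for a sample
against itself, ~0.25 for parent-offspring, ~0 for unrelated individuals.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core import GenotypeMatrix, HET, HOMALT, HOMREF, MISSING


def king_kinship(gi: np.ndarray, gj: np.ndarray) -> float:
    """KING-robust within-pair kinship between two genotype-code vectors.

    Vectors use the package's codes (0 homref, 1 het, 2 homalt, -1 missing);
    sites missing in either sample are ignored. Returns NaN (with a warning)
    when neither sample has a heterozygous site.
    """
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    if gi.shape != gj.shape:
        raise ValueError("genotype vectors differ in length")
    ok = (gi != MISSING) & (gj != MISSING)
    gi, gj = gi[ok], gj[ok]
    n_hh = int(((gi == HET) & (gj == HET)).sum())
    n_opp = int(
        (((gi == HOMREF) & (gj == HOMALT)) | ((gi == HOMALT) & (gj == HOMREF))).sum()
    )
    n_het_i = int((gi == HET).sum())
    n_het_j = int((gj == HET).sum())
    denom = n_het_i + n_het_j
    if denom == 0:
        warnings.warn("no heterozygous sites in either sample; kinship undefined", stacklevel=2)
        return math.nan
    return (n_hh - 2.0 * n_opp) / denom


def kinship_matrix(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric samples x samples KING-robust kinship matrix.

    The diagonal holds self-kinship (0.5 for any sample carrying
    heterozygous sites).
    """
    n = matrix.n_samples
    phi = np.full((n, n), math.nan)
    for i in range(n):
        for j in range(i, n):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                phi[i, j] = phi[j, i] = king_kinship(matrix.gt[:, i], matrix.gt[:, j])
    return pd.DataFrame(phi, index=matrix.samples, columns=matrix.samples)


def genotype_pca(
    matrix: GenotypeMatrix,
    k: int = 2,
    scale: bool = False,
) -> tuple:
    """PCA of the samples on dosage-coded (0/1/2) genotypes.

    Complete-case sites only; missing codes are rejected. Columns are mean
    centered; with ``scale`` they are additionally divided by
    sqrt(2 p (1 - p)) with p the alt-allele frequency (monomorphic columns
    are dropped). Returns (coordinates DataFrame, explained-variance
    fractions).
    """
    if (matrix.gt == MISSING).any():
        raise ValueError("PCA requires complete-case sites; filter missing genotypes first")
    X = matrix.gt.T.astype(float)  # samples x sites dosage
    if X.shape[1] < X.shape[0]:
        warnings.warn("fewer polymorphic sites than samples; PCA is rank-deficient", stacklevel=2)
    if scale:
        p = X.mean(axis=0) / 2.0
        keep = (p > 0) & (p < 1)
        X = X[:, keep]
        p = p[keep]
        X = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    k = min(k, max(1, min(X.shape) - 1)) if min(X.shape) > 1 else 1
    pca = PCA(n_components=k)
    coords = pca.fit_transform(X)
    df = pd.DataFrame(
        coords, index=matrix.samples, columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
    )
    return df, pca.explained_variance_ratio_.copy()
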