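"""Principal-component covariates from a SNP dosage matrix.

Genomic structure enters the growth model as the first few PC scores of a
biallelic dosage matrix (rows = clonal genotypes, columns = variants,
values 0/1/2 or fractional).  The PCA is on the column-centered, unscaled
matrix (covariance PCA); axis signs are fixed so the largest-magnitude
variant loading on each axis is positive.  When PC scores are supplied
directly in the genotype table this module is bypassed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, DimensionError, InsufficientDataError


@dataclass
class GenotypeMatrix:
    genotype_ids: list
    dosages: np.ndarray  # (n_genotypes, n_variants)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise DimensionError("dosages must be a 2-D matrix")
        if self.dosages.shape[0] < 2 or self.dosages.shape[1] < 1:
            raise DimensionError("need >= 2 genotypes and >= 1 variant")
        if len(self.genotype_ids) != self.dosages.shape[0]:
            raise DimensionError("genotype_ids length must match dosage rows")
        if not np.isfinite(self.dosages).all():
            raise DegenerateInputError("dosage matrix contains missing/non-finite values")


@dataclass
class PCScores:
    genotype_ids: list
    scores: np.ndarray  # (n_genotypes, n_axes)
    explained_variance_fraction: np.ndarray


def read_genotype_matrix(path) -> GenotypeMatrix:
    """Read a plain matrix CSV whose first column is ``genotype_id``."""
    df = pd.read_csv(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    return GenotypeMatrix(genotype_ids=ids, dosages=df.iloc[:, 1:].to_numpy(float))


def compute_pc_scores(g: GenotypeMatrix, n_axes: int) -> PCScores:
    """Project genotypes onto the leading eigenvectors of the centered
    dosage covariance.

    Scores are raw projections (not eigenvalue-rescaled); each column sums
    to zero.  Axes are ordered by decreasing eigenvalue and oriented so the
    largest-magnitude loading is positive.
    """
    n, p = g.dosages.shape
    max_axes = min(n - 1, p)
    if n_axes < 1 or n_axes > max_axes:
        raise DimensionError(f"n_axes must be in [1, {max_axes}] for a {n}x{p} matrix")
    centered = g.dosages - g.dosages.mean(axis=0)
    total_var = float(np.sum(centered**2)) / (n - 1)
    if total_var == 0.0:
        raise DegenerateInputError("dosage matrix has zero variance after centering")
    # economy SVD: centered = U S V^T; scores = U S, loadings = columns of V
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = n_axes
    scores = u[:, :k] * s[:k]
    loadings = vt[:k]
    # deterministic sign: largest-|loading| entry positive on each axis
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            scores[:, j] *= -1.0
            loadings[j] *= -1.0
    evf = (s[:k] ** 2 / (n - 1)) / total_var
    return PCScores(
        genotype_ids=list(g.genotype_ids),
        scores=scores,
        explained_variance_fraction=evf,
    )


def structure_climate_correlation(pcs: PCScores, genotypes: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each PC axis with home MCMT.

    ``genotypes`` is a genotype table (as in :class:`TrialDataset`) with a
    ``home_mcmt`` column indexed by genotype id.  Returns a frame with one
    row per axis: (axis, r, n).
    """
    ids = [i for i in pcs.genotype_ids if i in genotypes.index]
    if len(ids) < 3:
        raise InsufficientDataError("need >= 3 genotypes shared between PC scores and genotype table")
    pos = {g: i for i, g in enumerate(pcs.genotype_ids)}
    rows = [pos[i] for i in ids]
    home = genotypes.loc[ids, "home_mcmt"].to_numpy(float)
    out = []
    for axis in range(pcs.scores.shape[1]):
        r = stats.pearsonr(pcs.scores[rows, axis], home).statistic
        out.append({"axis": axis + 1, "r": float(r), "n": len(ids)})
    return pd.DataFrame(out)
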