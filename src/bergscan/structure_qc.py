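"""Cohort-level structure and QC: LD pruning, genotype PCA, relatedness.

PCA uses the Patterson scaling convention: per-SNP centering by twice the
pooled allele frequency and scaling by the binomial standard deviation
sqrt(2p(1-p)), with missing dosages mean-imputed (zero after centering).
Relatedness is a standardized genotype-covariance estimator; ~1 for
duplicates, ~0.5 for first-degree relatives, ~0 for unrelated pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix

logger = logging.getLogger(__name__)


def ld_prune(
    gm: GenotypeMatrix,
    r2_max: float = 0.1,
    window: int = 50,
    step: int = 10,
) -> np.ndarray:
    """Greedy sliding-window LD pruning on squared dosage correlation.

    Within each window of ``window`` SNPs (advancing by ``step``), the later
    SNP of any pair with pairwise-complete r^2 > ``r2_max`` is dropped,
    scanning left to right; deterministic. Monomorphic SNPs correlate with
    nothing. Returns the retained site indices.
    """
    if not (0 <= r2_max <= 1):
        raise ValueError("r2_max must be in [0, 1]")
    n_sites = gm.n_sites
    keep = np.ones(n_sites, dtype=bool)
    d = gm.dosage.astype(float)
    d[d < 0] = np.nan
    for start in range(0, max(n_sites - 1, 1), step):
        stop = min(start + window, n_sites)
        idx = np.flatnonzero(keep[start:stop]) + start
        if idx.size < 2:
            if stop == n_sites:
                break
            continue
        r2 = _pairwise_r2_matrix(d[idx])
        for ai in range(idx.size):
            if not keep[idx[ai]]:
                continue
            hit = r2[ai, ai + 1:] > r2_max
            if hit.any():
                keep[idx[ai + 1:][hit]] = False
        if stop == n_sites:
            break
    return np.flatnonzero(keep)


def _pairwise_r2_matrix(block: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared correlation between the rows of ``block``
    (NaN marks missing). Undefined pairs (no shared data or zero variance)
    get r^2 = 0."""
    finite = np.isfinite(block)
    x = np.where(finite, block, 0.0)
    f = finite.astype(float)
    n = f @ f.T
    sx = x @ f.T
    sxx = (x * x) @ f.T
    sxy = x @ x.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        var_i = n * sxx - sx**2
        var_j = var_i.T
        r2 = cov**2 / (var_i * var_j)
    r2 = np.where((n >= 2) & (var_i > 0) & (var_j > 0), r2, 0.0)
    return r2


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray  # percent per component
    loadings: np.ndarray | None = None


def pca_genotypes(gm: GenotypeMatrix, n_components: int = 2) -> PCAResult:
    """Genotype PCA with Patterson scaling and mean imputation."""
    if gm.n_samples < 2 or gm.n_sites < 2:
        raise ValueError("need at least 2 samples and 2 SNPs")
    d = gm.dosage.astype(float)
    d[d < 0] = np.nan
    p = np.nanmean(d, axis=1) / 2.0
    informative = (p > 0) & (p < 1)
    d = d[informative]
    p = p[informative]
    if d.shape[0] == 0:
        raise ValueError("no polymorphic sites for PCA")
    scale = np.sqrt(2 * p * (1 - p))
    z = (d - 2 * p[:, None]) / scale[:, None]
    z = np.where(np.isfinite(z), z, 0.0)  # mean imputation after centering

    # eigendecomposition of the sample covariance via SVD of z / sqrt(sites)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eigvals = s**2
    total = eigvals.sum()
    if total <= 0:
        raise ValueError("zero-variance genotype matrix")
    n_components = min(n_components, s.size)
    coords = vt[:n_components].T * s[:n_components]
    frac = 100.0 * eigvals[:n_components] / total
    coord_df = pd.DataFrame(
        coords,
        index=gm.samples if gm.samples else range(gm.n_samples),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return PCAResult(coordinates=coord_df, variance_fraction=np.round(frac, 2),
                     loadings=u[:, :n_components])


def pairwise_relatedness(
    gm: GenotypeMatrix, flag_threshold: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardized genotype-covariance relatedness for every sample pair.

    r_ij = mean over usable sites of
    (g_i - 2p)(g_j - 2p) / (2p(1-p)), using sites polymorphic in the pooled
    sample where both samples are called. Returns (pair table, flagged
    pairs with r >= ``flag_threshold``).
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if gm.n_sites < 100:
        logger.warning("pairwise_relatedness: fewer than 100 SNPs; noisy estimates")
    d = gm.dosage.astype(float)
    d[d < 0] = np.nan
    # pooled frequency over all called samples; the estimator carries an
    # O(1/m) downward bias from p-hat absorbing the pair's covariance, so
    # it is meant for cohort-scale screening, not tiny panels
    p = np.nanmean(d, axis=1) / 2.0
    use = (p > 0) & (p < 1)
    d = d[use]
    p = p[use]
    z = (d - 2 * p[:, None]) / np.sqrt(2 * p * (1 - p))[:, None]
    names = gm.samples if gm.samples else [str(i) for i in range(gm.n_samples)]

    rows = []
    n = gm.n_samples
    finite = np.isfinite(z)
    for i in range(n):
        for j in range(i + 1, n):
            ok = finite[:, i] & finite[:, j]
            if not ok.any():
                rows.append((names[i], names[j], np.nan, 0))
                continue
            r = float(np.mean(z[ok, i] * z[ok, j]))
            rows.append((names[i], names[j], r, int(ok.sum())))
    table = pd.DataFrame(rows, columns=["sample_1", "sample_2", "relatedness", "n_sites"])
    flagged = table.loc[table["relatedness"] >= flag_threshold].reset_index(drop=True)
    if len(flagged):
        logger.info("pairwise_relatedness: %d pairs at or above %.2f",
                    len(flagged), flag_threshold)
    return table, flagged
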