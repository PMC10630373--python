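"""Per-site and windowed population-genetic statistics.

Implements the Weir–Cockerham two-population variance-components F_ST
estimator, nucleotide diversity pi, absolute divergence Dxy, Tajima's D,
per-individual inbreeding coefficients F_IS, and hypergeometric projection
of site-frequency spectra. Missing genotypes are handled per-site complete
case throughout; no imputation is performed.

Windowed F_ST uses the ratio-of-averages ("weighted") form: summed a
components over summed a+b+c, which is the convention of the classic
VCFtools-style windowed scans. Negative per-window values are reported as
computed, never clamped, so empirical percentile thresholds see the full
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import GenotypeMatrix, assign_windows

__all__ = [
    "group_site_counts",
    "site_fst_components",
    "windowed_fst",
    "windowed_pi",
    "windowed_dxy",
    "windowed_tajimas_d",
    "individual_fis",
    "tajima_constants",
    "project_sfs",
]


def group_site_counts(gm: GenotypeMatrix, idx: np.ndarray):
    """Per-site (n, p, h) for a group of sample columns.

    Returns ``n`` = called diploid individuals, ``p`` = non-reference allele
    frequency and ``h`` = observed heterozygote frequency among called
    individuals (NaN where the group has no calls).
    """
    d = gm.dosage[:, idx]
    called = d >= 0
    n = called.sum(axis=1)
    alt = np.where(called, d, 0).sum(axis=1)
    het = (d == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return n.astype(float), p, h


def site_fst_components(n1, p1, h1, n2, p2, h2):
    """Weir–Cockerham variance components (a, b, c) and per-site F_ST.

    Inputs are per-site arrays: ``n_i`` in diploid individuals, ``p_i``
    allele frequencies, ``h_i`` observed heterozygote frequencies. Sites
    where either population has no calls, where nbar <= 1, or that are
    monomorphic in the pooled sample are unusable: components are NaN there.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)

    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0

    usable = (n1 > 0) & (n2 > 0) & (nbar > 1) & (pbar > 0) & (pbar < 1)
    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom != 0, a / denom, np.nan)
    return a, b, c, fst


def _fst_components_for_groups(gm: GenotypeMatrix, group1, group2):
    idx1 = np.asarray(group1, dtype=int)
    idx2 = np.asarray(group2, dtype=int)
    if idx1.size < 2 or idx2.size < 2:
        raise ValueError("each group needs at least 2 individuals")
    if set(idx1.tolist()) & set(idx2.tolist()):
        raise ValueError("groups must be disjoint")
    n1, p1, h1 = group_site_counts(gm, idx1)
    n2, p2, h2 = group_site_counts(gm, idx2)
    return site_fst_components(n1, p1, h1, n2, p2, h2)


def per_site_fst(gm: GenotypeMatrix, group1, group2) -> np.ndarray:
    """Per-site Weir–Cockerham F_ST for two groups of sample columns."""
    return _fst_components_for_groups(gm, group1, group2)[3]


def _window_frame(windows: pd.DataFrame, n_snps, stat, kind: str) -> pd.DataFrame:
    out = windows[["scaffold", "start", "end"]].copy().reset_index(drop=True)
    out["mid"] = (out["start"] + out["end"]) // 2
    out["n_snps"] = np.asarray(n_snps, dtype=np.int64)
    out["stat"] = np.asarray(stat, dtype=float)
    out.attrs["kind"] = kind
    return out


def _window_sums(widx: np.ndarray, values: np.ndarray, n_windows: int):
    """Sum `values` per window, ignoring NaNs; returns (sums, counts)."""
    ok = (widx >= 0) & np.isfinite(values)
    sums = np.bincount(widx[ok], weights=values[ok], minlength=n_windows)
    counts = np.bincount(widx[ok], minlength=n_windows)
    return sums, counts


def windowed_fst(
    gm: GenotypeMatrix,
    group1,
    group2,
    variants: pd.DataFrame,
    windows: pd.DataFrame,
) -> pd.DataFrame:
    """Windowed Weir–Cockerham F_ST (ratio of averages: sum a / sum a+b+c).

    Windows with no usable site get NaN. ``n_snps`` counts usable sites.
    """
    a, b, c, _ = _fst_components_for_groups(gm, group1, group2)
    denom = a + b + c
    # exclude sites where the ratio is undefined because a+b+c == 0
    usable = np.isfinite(denom) & (denom != 0)
    a = np.where(usable, a, np.nan)
    denom = np.where(usable, denom, np.nan)

    widx = assign_windows(variants, windows)
    nw = len(windows)
    a_sum, n_used = _window_sums(widx, a, nw)
    d_sum, _ = _window_sums(widx, denom, nw)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where((n_used > 0) & (d_sum != 0), a_sum / d_sum, np.nan)
    return _window_frame(windows, n_used, stat, "fst")


def _site_pi(p: np.ndarray, n_alleles: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity 2p(1-p) * n/(n-1), n in alleles."""
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * p * (1.0 - p) * n_alleles / np.maximum(n_alleles - 1.0, 1e-300)
    return np.where(n_alleles >= 2, pi, np.nan)


def windowed_pi(
    gm: GenotypeMatrix,
    group,
    variants: pd.DataFrame,
    windows: pd.DataFrame,
    normalization: str = "per_bp",
) -> pd.DataFrame:
    """Windowed nucleotide diversity.

    ``per_bp`` divides the summed per-site diversity by the window length
    (assumes unlisted positions are invariant); ``per_variant_site`` divides
    by the number of usable variant sites.
    """
    idx = np.asarray(group, dtype=int)
    if idx.size < 2:
        raise ValueError("group needs at least 2 individuals")
    n, p, _ = group_site_counts(gm, idx)
    pi_s = _site_pi(p, 2.0 * n)
    return _normalized_window_stat(pi_s, variants, windows, normalization, "pi")


def windowed_dxy(
    gm: GenotypeMatrix,
    group1,
    group2,
    variants: pd.DataFrame,
    windows: pd.DataFrame,
    normalization: str = "per_bp",
) -> pd.DataFrame:
    """Windowed absolute divergence: per-site p1(1-p2) + p2(1-p1)."""
    idx1 = np.asarray(group1, dtype=int)
    idx2 = np.asarray(group2, dtype=int)
    if idx1.size == 0 or idx2.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, p1, _ = group_site_counts(gm, idx1)
    n2, p2, _ = group_site_counts(gm, idx2)
    d_s = p1 * (1 - p2) + p2 * (1 - p1)
    d_s = np.where((n1 > 0) & (n2 > 0), d_s, np.nan)
    return _normalized_window_stat(d_s, variants, windows, normalization, "dxy")


def _normalized_window_stat(per_site, variants, windows, normalization, kind):
    if normalization not in ("per_bp", "per_variant_site"):
        raise ValueError(f"unknown normalization {normalization!r}")
    widx = assign_windows(variants, windows)
    nw = len(windows)
    sums, counts = _window_sums(widx, np.asarray(per_site, dtype=float), nw)
    if normalization == "per_bp":
        length = (windows["end"] - windows["start"]).to_numpy(dtype=float)
        stat = sums / length
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    stat = np.where(counts > 0, stat, np.where(normalization == "per_bp", 0.0, np.nan))
    return _window_frame(windows, counts, stat, kind)


@dataclass(frozen=True)
class TajimaConstants:
    """Normalizing constants of Tajima's D for sample size n (alleles)."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    if n < 4:
        raise ValueError("Tajima constants require n >= 4 alleles")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def windowed_tajimas_d(
    gm: GenotypeMatrix,
    group,
    variants: pd.DataFrame,
    windows: pd.DataFrame,
) -> pd.DataFrame:
    """Windowed Tajima's D with constants at nominal n = 2m alleles.

    Per-site complete-case k-hat; windows with no usable segregating site
    (or a vanishing variance term) are NA.
    """
    idx = np.asarray(group, dtype=int)
    m = idx.size
    if 2 * m < 4:
        raise ValueError("Tajima's D needs at least 2 diploid individuals")
    const = tajima_constants(2 * m)
    n, p, _ = group_site_counts(gm, idx)
    seg = (p > 0) & (p < 1) & (n * 2 >= 2)
    pi_s = np.where(seg, _site_pi(p, 2.0 * n), np.nan)

    widx = assign_windows(variants, windows)
    nw = len(windows)
    k_sum, s_count = _window_sums(widx, pi_s, nw)
    S = s_count.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = const.e1 * S + const.e2 * S * (S - 1)
        d = (k_sum - S / const.a1) / np.sqrt(var)
    d = np.where((S > 0) & (var > 0), d, np.nan)
    return _window_frame(windows, s_count, d, "tajimas_d")


def individual_fis(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-individual inbreeding coefficient F = (O_hom - E_hom)/(N - E_hom).

    Expected homozygosity per usable site is 1 - 2p(1-p) * 2n/(2n-1), with p
    and n taken from all called samples at the site. Sites monomorphic in
    the pooled sample are uninformative and skipped; sites where the focal
    individual is missing do not contribute to its O, E or N.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    called = gm.called()
    n = called.sum(axis=1).astype(float)
    alt = np.where(called, gm.dosage, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * np.maximum(n, 1)), np.nan)
    informative = (p > 0) & (p < 1) & (2 * n >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_site = 1.0 - 2.0 * p * (1 - p) * (2 * n) / np.maximum(2 * n - 1, 1e-300)
    e_site = np.where(informative, e_site, 0.0)
    use = informative[:, None] & called

    o_hom = ((gm.dosage != 1) & use).sum(axis=0).astype(float)
    e_hom = (e_site[:, None] * use).sum(axis=0)
    n_used = use.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (o_hom - e_hom) / (n_used - e_hom)
    f = np.where(np.abs(n_used - e_hom) > 1e-12, f, np.nan)
    return pd.DataFrame(
        {"sample": gm.samples, "n_sites": n_used.astype(int),
         "o_hom": o_hom, "e_hom": e_hom, "fis": f}
    )


# ---------------------------------------------------------------------------
# SFS projection
# ---------------------------------------------------------------------------

def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def projection_matrix(n: int, m: int) -> np.ndarray:
    """Hypergeometric downsampling matrix P[j, k] = P(k of m | j of n)."""
    if m > n:
        raise ValueError("cannot project to a larger sample size")
    j = np.arange(n + 1)[:, None]
    k = np.arange(m + 1)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = (
            _log_comb(j, k) + _log_comb(n - j, m - k) - _log_comb(n, m)
        )
    valid = (k <= j) & (m - k <= n - j)
    out = np.where(valid, np.exp(logp), 0.0)
    return out


def project_sfs(spectrum: np.ndarray, m: int) -> np.ndarray:
    """Project a spectrum over allele counts 0..n down to 0..m by
    hypergeometric resampling; total mass is conserved."""
    phi = np.asarray(spectrum, dtype=float)
    n = phi.size - 1
    if m > n:
        raise ValueError(f"cannot project n={n} up to m={m}")
    if m < 2:
        raise ValueError("target sample size must be >= 2")
    if np.any(phi < 0):
        raise ValueError("spectrum must be non-negative")
    if m == n:
        return phi.copy()
    return phi @ projection_matrix(n, m)
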