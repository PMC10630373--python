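"""Phenotype/climate validation of candidate SNPs.

Computes the subspecies-level non-reference allele-frequency matrix at
candidate SNPs, Pearson correlations with body mass and seasonal
temperatures, simple linear regressions with influence diagnostics,
per-site F_ST summaries with fixed-SNP fractions, a seeded partial Mantel
test, and Ward clustering of individual genotypes at the focal SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io_formats import GenotypeMatrix
from .outlier_candidates import ComparisonSpec
from .popgen_stats import per_site_fst

logger = logging.getLogger(__name__)


def subspecies_allele_freqs(
    gm: GenotypeMatrix,
    panel: pd.DataFrame,
    snp_index: np.ndarray | None = None,
) -> pd.DataFrame:
    """Non-reference allele frequency, SNP x subspecies, over called alleles
    within each subspecies (NaN where a subspecies has no calls at a SNP)."""
    if snp_index is None:
        snp_index = np.arange(gm.n_sites)
    snp_index = np.asarray(snp_index, dtype=int)
    sub_order = panel["subspecies"].drop_duplicates().tolist()
    cols = {}
    for sub in sub_order:
        names = panel.loc[panel["subspecies"] == sub, "sample"].tolist()
        if not names:
            raise ValueError(f"subspecies {sub} has no samples")
        idx = gm.sample_index(names)
        d = gm.dosage[np.ix_(snp_index, idx)]
        called = d >= 0
        n = 2.0 * called.sum(axis=1)
        alt = np.where(called, d, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cols[sub] = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return pd.DataFrame(cols, index=snp_index)


def subspecies_means(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-subspecies mean mass, temperatures and coordinates."""
    return panel.groupby("subspecies", sort=False).agg(
        mass_g=("mass_g", "mean"),
        winter_temp_c=("winter_temp_c", "mean"),
        summer_temp_c=("summer_temp_c", "mean"),
        latitude=("latitude", "mean"),
        longitude=("longitude", "mean"),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return np.nan
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def correlate_and_select(
    freqs: pd.DataFrame,
    panel: pd.DataFrame,
    r_min: float = 0.90,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-SNP Pearson r of subspecies-level frequency against subspecies
    mean mass and temperatures; select focal SNPs with r vs mass > r_min
    (positive orientation: the non-reference allele tracks larger mass).

    Returns (association table indexed like ``freqs``, selected SNP index
    array). SNPs with zero-variance frequency vectors are skipped.
    """
    means = subspecies_means(panel)
    subs = [s for s in freqs.columns if s in means.index]
    if len(subs) < 3:
        raise ValueError("need at least 3 subspecies with data")
    mass = means.loc[subs, "mass_g"].to_numpy()
    wtemp = means.loc[subs, "winter_temp_c"].to_numpy()
    stemp = means.loc[subs, "summer_temp_c"].to_numpy()
    F = freqs[subs].to_numpy(dtype=float)

    n_skipped = 0
    rows = []
    for i in range(F.shape[0]):
        f = F[i]
        ok = np.isfinite(f)
        if ok.sum() < 3 or np.nanstd(f) == 0:
            n_skipped += 1
            rows.append((np.nan, np.nan, np.nan))
            continue
        rows.append(
            (_pearson(f, mass), _pearson(f, wtemp), _pearson(f, stemp))
        )
    if n_skipped:
        logger.info("correlate_and_select: skipped %d zero-variance/sparse SNPs",
                    n_skipped)
    assoc = pd.DataFrame(
        rows, columns=["r_mass", "r_winter_temp", "r_summer_temp"],
        index=freqs.index,
    )
    selected = assoc.index.to_numpy()[
        np.nan_to_num(assoc["r_mass"].to_numpy(), nan=-2.0) > r_min
    ]
    return assoc, selected


def snp_regressions(freq: np.ndarray, response: np.ndarray) -> dict:
    """OLS of response (mass or temperature) on allele frequency with
    diagnostics: slope, intercept, 95% CI, R^2, F(1, k-2), p, leverage and
    Cook's distance per point."""
    import statsmodels.api as sm

    x = np.asarray(freq, dtype=float)
    y = np.asarray(response, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 points")
    X = sm.add_constant(x)
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("singular design (constant frequency)")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    infl = fit.get_influence()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "slope_ci_low": float(ci[1, 0]),
        "slope_ci_high": float(ci[1, 1]),
        "r_squared": float(fit.rsquared),
        "f_stat": float(fit.fvalue),
        "df_num": int(fit.df_model),
        "df_den": int(fit.df_resid),
        "p_value": float(fit.f_pvalue),
        "leverage": infl.hat_matrix_diag,
        "cooks_d": infl.cooks_distance[0],
        "residuals": fit.resid,
    }


def per_site_fst_summary(
    gm: GenotypeMatrix,
    panel: pd.DataFrame,
    comparisons: list[ComparisonSpec],
    snp_index: np.ndarray,
    variants: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    fixed_threshold: float = 0.95,
) -> dict:
    """Per-SNP per-comparison Weir-Cockerham F_ST at focal SNPs, plus per
    gene the fraction of SNPs with F_ST above ``fixed_threshold``."""
    snp_index = np.asarray(snp_index, dtype=int)
    if snp_index.size == 0:
        raise ValueError("focal SNP set is empty")
    sub = gm.take_sites(snp_index)
    per_snp = pd.DataFrame(index=snp_index)
    n_na = 0
    for comp in comparisons:
        g1 = _group_columns(gm, panel, comp.group_a)
        g2 = _group_columns(gm, panel, comp.group_b)
        fst = per_site_fst(sub, g1, g2)
        n_na += int(np.sum(~np.isfinite(fst)))
        per_snp[comp.name] = fst
    comp_names = [c.name for c in comparisons]
    per_snp["mean_fst"] = per_snp[comp_names].mean(axis=1)
    per_snp["min_fst"] = per_snp[comp_names].min(axis=1)
    per_snp["max_fst"] = per_snp[comp_names].max(axis=1)

    gene_rows = []
    if genes is not None:
        pos0 = variants["pos"].to_numpy()[snp_index] - 1
        scafs = variants["scaffold"].to_numpy()[snp_index]
        for _, g in genes.iterrows():
            inside = (scafs == g["scaffold"]) & (pos0 >= g["start"]) & (pos0 < g["end"])
            if not inside.any():
                continue
            row = {"gene_id": g["gene_id"], "n_snps": int(inside.sum())}
            for name in comp_names:
                vals = per_snp.loc[per_snp.index[inside], name].to_numpy()
                defined = np.isfinite(vals)
                row[f"fixed_frac_{name}"] = (
                    float((vals[defined] > fixed_threshold).mean())
                    if defined.any() else np.nan
                )
                row[f"mean_fst_{name}"] = float(np.nanmean(vals)) if defined.any() else np.nan
            gene_rows.append(row)
    return {
        "per_snp": per_snp,
        "per_gene": pd.DataFrame(gene_rows),
        "n_undefined": n_na,
    }


def _group_columns(gm: GenotypeMatrix, panel: pd.DataFrame, subspecies) -> np.ndarray:
    names = panel.loc[panel["subspecies"].isin(list(subspecies)), "sample"].tolist()
    return gm.sample_index(names)


# ---------------------------------------------------------------------------
# Partial Mantel test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MantelResult:
    r: float
    n_perm: int
    p_value: float
    seed: int


def _lower(mat: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(mat.shape[0], k=-1)
    return mat[i, j]


def _partial_r(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    r_ab = _pearson(a, b)
    r_ac = _pearson(a, c)
    r_bc = _pearson(b, c)
    if abs(r_ac) >= 1 - 1e-12 or abs(r_bc) >= 1 - 1e-12:
        raise ValueError("partial correlation undefined: |r| = 1 with covariate")
    return (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))


def partial_mantel(
    genetic: np.ndarray,
    phenotype: np.ndarray,
    geographic: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
) -> MantelResult:
    """Partial Mantel test of genetic vs phenotype distance controlling for
    geographic distance.

    The null is generated by jointly permuting rows and columns of the
    genetic matrix; the one-tailed p-value for a positive association is
    (1 + #{perm >= observed}) / (1 + n_perm).
    """
    mats = [np.asarray(m, dtype=float) for m in (genetic, phenotype, geographic)]
    k = mats[0].shape[0]
    if k < 4:
        raise ValueError("need at least 4 objects")
    for m in mats:
        if m.shape != (k, k):
            raise ValueError("distance matrices must have identical shapes")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrices must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrices must have zero diagonal")
    genetic, phenotype, geographic = mats
    b = _lower(phenotype)
    c = _lower(geographic)
    observed = _partial_r(_lower(genetic), b, c)

    zb = (b - b.mean()) / b.std()
    zc = (c - c.mean()) / c.std()
    r_bc = float(np.mean(zb * zc))
    denom_bc = 1.0 - r_bc**2

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        a = _lower(genetic[np.ix_(perm, perm)])
        za = (a - a.mean()) / a.std()
        r_ab = float(np.mean(za * zb))
        r_ac = float(np.mean(za * zc))
        stat = (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * denom_bc)
        count += stat >= observed
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r=float(observed), n_perm=n_perm, p_value=float(p), seed=seed)


def distance_matrices(
    freqs: pd.DataFrame, panel: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Build the three Mantel matrices at subspecies level: Euclidean
    distance between non-reference allele-frequency vectors, absolute
    difference of mean mass, and Euclidean geographic distance on
    coordinates."""
    means = subspecies_means(panel)
    subs = [s for s in freqs.columns if s in means.index]
    F = freqs[subs].to_numpy(dtype=float)
    k = len(subs)
    genetic = np.zeros((k, k))
    for i in range(k):
        for j in range(i):
            ok = np.isfinite(F[:, i]) & np.isfinite(F[:, j])
            genetic[i, j] = genetic[j, i] = float(
                np.sqrt(np.sum((F[ok, i] - F[ok, j]) ** 2))
            )
    mass = means.loc[subs, "mass_g"].to_numpy()
    phenotype = np.abs(mass[:, None] - mass[None, :])
    coords = means.loc[subs, ["latitude", "longitude"]].to_numpy()
    geographic = np.sqrt(
        ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    )
    return genetic, phenotype, geographic, subs


# ---------------------------------------------------------------------------
# Focal-region SNPs and Ward clustering
# ---------------------------------------------------------------------------

def focal_region_snps(
    variants: pd.DataFrame,
    focal_index: np.ndarray,
    retained_index: np.ndarray | None = None,
    flank: int = 3,
) -> np.ndarray:
    """Expand focal SNPs by up to ``flank`` nearest retained SNPs on each
    side, truncated at scaffold ends and at adjacent focal SNPs;
    deduplicated union sorted by position."""
    focal_index = np.asarray(focal_index, dtype=int)
    if retained_index is None:
        retained_index = np.arange(len(variants))
    retained_index = np.asarray(retained_index, dtype=int)
    focal_set = set(focal_index.tolist())
    scafs = variants["scaffold"].to_numpy()

    out: set[int] = set(focal_index.tolist())
    by_scaf: dict[str, np.ndarray] = {}
    for scaf in np.unique(scafs[focal_index]):
        by_scaf[scaf] = retained_index[scafs[retained_index] == scaf]
    for fi in focal_index:
        row = by_scaf[scafs[fi]]
        k = int(np.searchsorted(row, fi))
        # downstream: nearest retained SNPs after the focal one
        for j in range(k + 1, min(k + 1 + flank, row.size)):
            if row[j] in focal_set:
                break
            out.add(int(row[j]))
        # upstream
        for j in range(k - 1, max(k - 1 - flank, -1), -1):
            if row[j] in focal_set:
                break
            out.add(int(row[j]))
    return np.array(sorted(out), dtype=int)


def genotype_ward_tree(
    gm: GenotypeMatrix,
    variants: pd.DataFrame,
    snp_index: np.ndarray,
) -> dict:
    """Ward minimum-variance clustering of individuals on their dosage
    vectors at the focal-region SNPs.

    Distances are pairwise-complete Euclidean, scaled by
    sqrt(total sites / shared sites) to correct for missingness; samples
    with no called focal SNP are excluded with a warning. Returns the
    linkage matrix, a Newick string with branch lengths derived from merge
    heights, the leaf order, and a per-sample genotype table for heatmap
    rendering.
    """
    snp_index = np.asarray(snp_index, dtype=int)
    d = gm.dosage[snp_index].astype(float)
    d[d < 0] = np.nan
    informative = ~np.all(np.isnan(d), axis=1)
    d = d[informative]
    has_calls = ~np.all(np.isnan(d), axis=0)
    if not has_calls.all():
        dropped = [s for s, ok in zip(gm.samples, has_calls) if not ok]
        logger.warning("genotype_ward_tree: excluding samples with no calls: %s",
                       dropped)
    d = d[:, has_calls]
    samples = [s for s, ok in zip(gm.samples, has_calls) if ok]
    n_samp = d.shape[1]
    if n_samp < 2:
        raise ValueError("need at least 2 samples with called focal SNPs")
    total_sites = d.shape[0]

    dist = np.zeros((n_samp, n_samp))
    for i in range(n_samp):
        diff = d[:, [i]] - d
        shared = (~np.isnan(diff)).sum(axis=0).astype(float)
        ss = np.nansum(diff**2, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist[i] = np.sqrt(ss * np.where(shared > 0, total_sites / shared, np.nan))
    dist[np.arange(n_samp), np.arange(n_samp)] = 0.0
    if np.isnan(dist).any():
        raise ValueError("some sample pairs share no called focal SNPs")

    Z = linkage(squareform(dist, checks=False), method="ward")
    newick = _linkage_to_newick(Z, samples)
    leaf_order = _leaf_order(Z, samples)
    ref = variants["ref"].to_numpy()[snp_index][informative]
    alt = variants["alt"].to_numpy()[snp_index][informative]
    allele_codes = {0: "ref/ref", 1: "ref/alt", 2: "alt/alt"}
    heat_rows = []
    for j, s in enumerate(samples):
        for i in range(total_sites):
            g = d[i, j]
            calls = allele_codes.get(int(g), "./.") if np.isfinite(g) else "./."
            a1, a2 = (
                (ref[i], ref[i]) if g == 0 else
                (ref[i], alt[i]) if g == 1 else
                (alt[i], alt[i]) if g == 2 else (".", ".")
            )
            heat_rows.append((s, int(i), a1, a2, calls))
    heatmap = pd.DataFrame(
        heat_rows, columns=["sample", "snp", "allele_1", "allele_2", "genotype"]
    )
    return {"linkage": Z, "newick": newick, "samples": samples,
            "leaf_order": leaf_order, "heatmap": heatmap,
            "distance_matrix": dist}


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Newick with branch lengths = parent merge height - child height."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + len(Z) - 1] + ";"


def _leaf_order(Z: np.ndarray, labels: list[str]) -> list[str]:
    from scipy.cluster.hierarchy import leaves_list

    return [labels[i] for i in leaves_list(Z)]
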