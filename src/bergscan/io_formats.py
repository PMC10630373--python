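"""Readers, writers, site filters, and coordinate conventions.

All interval arithmetic in this package is 0-based half-open. VCF and GFF3
positions (1-based) are converted on read and back-converted on write. The
two central in-memory containers are:

* a *variant table* — a :class:`pandas.DataFrame` with columns ``scaffold``,
  ``pos`` (1-based, as in the VCF), ``ref``, ``alt`` and optional
  ``mean_depth``, one row per retained biallelic SNP;
* a :class:`GenotypeMatrix` — sites x samples non-reference allele dosages
  (0/1/2) with ``-1`` marking missing calls, row-parallel to the variant
  table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

VARIANT_COLUMNS = ["scaffold", "pos", "ref", "alt", "mean_depth"]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class GenotypeMatrix:
    """Diploid non-reference allele dosages, sites x samples.

    ``dosage[i, j]`` is the number of non-reference alleles carried by
    sample ``j`` at site ``i`` (0, 1 or 2), or ``-1`` if the genotype call
    is missing.
    """

    dosage: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (sites x samples)")
        if self.samples and self.dosage.shape[1] != len(self.samples):
            raise ValueError(
                f"dosage has {self.dosage.shape[1]} columns but "
                f"{len(self.samples)} sample ids were given"
            )

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[1]

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosage >= 0

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of samples with a missing call."""
        return 1.0 - self.called().mean(axis=1)

    def take_sites(self, index) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage[index], self.samples)

    def take_samples(self, index) -> "GenotypeMatrix":
        idx = np.asarray(index)
        return GenotypeMatrix(
            self.dosage[:, idx], [self.samples[i] for i in idx] if self.samples else []
        )

    def sample_index(self, names) -> np.ndarray:
        """Column indices for a list of sample ids (order preserved)."""
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in names if s not in lookup]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing}")
        return np.array([lookup[s] for s in names], dtype=int)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> tuple[pd.DataFrame, GenotypeMatrix, list[str]]:
    """Read a VCF into (variant table, GenotypeMatrix, sample list).

    Multiallelic and non-SNP records are dropped (count logged). Dosage is
    the count of alternate alleles; half-calls and ``./.`` become missing.
    Phased and unphased separators are both accepted (cyvcf2 handles both).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise FormatError("duplicate sample ids in VCF header")

    scaffolds: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    depth: list[float] = []
    rows: list[np.ndarray] = []
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_dropped += 1
            continue
        gt = v.gt_types  # 0=hom-ref, 1=het, 2=hom-alt, 3=unknown (gts012)
        if gt is None:
            raise FormatError("VCF record lacks GT field")
        g = np.asarray(gt, dtype=np.int8)
        g[g == 3] = MISSING
        rows.append(g)
        scaffolds.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        site_depth = _site_mean_depth(v, len(samples))
        depth.append(site_depth)
    if n_dropped:
        logger.info("read_vcf: dropped %d multiallelic/non-SNP records", n_dropped)

    variants = pd.DataFrame(
        {
            "scaffold": pd.Series(scaffolds, dtype=str),
            "pos": pd.Series(pos, dtype=np.int64),
            "ref": ref,
            "alt": alt,
            "mean_depth": depth,
        }
    )
    _check_sorted(variants)
    dos = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return variants, GenotypeMatrix(dos, samples), samples


def _site_mean_depth(v, n_samples: int) -> float:
    """Mean per-sample depth; FORMAT/DP preferred, INFO/DP / n otherwise."""
    try:
        dp = v.format("DP")
    except Exception:
        dp = None
    if dp is not None:
        dp = np.asarray(dp, dtype=float).ravel()
        dp = dp[(dp >= 0) & np.isfinite(dp)]
        if dp.size:
            return float(dp.mean())
    info_dp = v.INFO.get("DP")
    if info_dp is not None:
        return float(info_dp) / n_samples
    return math.nan


def _check_sorted(variants: pd.DataFrame) -> None:
    for scaf, grp in variants.groupby("scaffold", sort=False):
        p = grp["pos"].to_numpy()
        if np.any(np.diff(p) <= 0):
            raise FormatError(
                f"positions not strictly increasing on scaffold {scaf}"
            )


def write_vcf(path, variants: pd.DataFrame, gm: GenotypeMatrix,
              scaffold_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCF v4.2 with GT (and DP when mean_depth present)."""
    has_depth = "mean_depth" in variants.columns and variants["mean_depth"].notna().any()
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bergscan\n")
        if scaffold_lengths:
            for scaf, length in scaffold_lengths.items():
                fh.write(f"##contig=<ID={scaf},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_depth:
            fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        n = gm.n_samples
        depths = variants["mean_depth"].to_numpy() if has_depth else None
        scafs = variants["scaffold"].to_numpy()
        poss = variants["pos"].to_numpy()
        refs = variants["ref"].to_numpy()
        alts = variants["alt"].to_numpy()
        for i in range(len(variants)):
            if depths is not None and np.isfinite(depths[i]):
                info = f"DP={int(round(depths[i] * n))}"
            else:
                info = "."
            gts = "\t".join(gt_code[int(g)] for g in gm.dosage[i])
            fh.write(
                f"{scafs[i]}\t{poss[i]}\t.\t{refs[i]}\t{alts[i]}\t.\tPASS\t"
                f"{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------

def pooled_allele_stats(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (called allele count, non-reference allele frequency), pooled
    over all samples, complete-case."""
    called = gm.called()
    n_alleles = 2 * called.sum(axis=1)
    alt = np.where(called, gm.dosage, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return n_alleles, p


def filter_sites(
    variants: pd.DataFrame,
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    depth_min: float = 2.0,
    depth_max: float = 50.0,
    miss_max: float = 0.20,
) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Apply the standard site filters: minor-allele frequency, mean depth
    and missingness.

    MAF is computed over called alleles pooled across all samples. The depth
    rule is applied only at sites where a mean depth is available; when no
    site has depth the rule is skipped with a warning. Order is preserved,
    so the operation is idempotent.
    """
    if not (0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if depth_min > depth_max:
        raise ValueError("depth_min > depth_max")
    if not (0 <= miss_max <= 1):
        raise ValueError("miss_max must be in [0, 1]")

    n_alleles, p = pooled_allele_stats(gm)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1 - p)
    keep = (n_alleles > 0) & (maf >= maf_min)
    keep &= gm.missing_fraction() <= miss_max

    if "mean_depth" in variants.columns:
        depth = variants["mean_depth"].to_numpy(dtype=float)
        have_depth = np.isfinite(depth)
        if not have_depth.any():
            logger.warning("filter_sites: no depth information; depth filter skipped")
        else:
            keep &= ~have_depth | ((depth >= depth_min) & (depth <= depth_max))
    else:
        logger.warning("filter_sites: no depth column; depth filter skipped")

    if not keep.any():
        logger.warning("filter_sites: all sites removed")
    logger.info(
        "filter_sites: retained %d / %d sites", int(keep.sum()), gm.n_sites
    )
    return variants.loc[keep].reset_index(drop=True), gm.take_sites(keep)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(path) -> pd.DataFrame:
    """Read BED4+ or GFF3 gene features into a unified gene table.

    Returns a DataFrame with columns ``gene_id, scaffold, start, end,
    strand``; intervals are 0-based half-open (GFF3's 1-based closed
    coordinates are converted). Duplicate gene ids and inverted intervals
    are rejected with the offending line number.
    """
    genes = []
    fmt = None  # decided from the first data line
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if fmt is None:
                fmt = "gff3" if len(fields) >= 8 and fields[6] in "+-." else "bed"
            if fmt == "bed":
                if len(fields) < 4:
                    raise FormatError(f"line {lineno}: BED needs >=4 columns")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: non-integer BED coordinates") from exc
                rec = dict(
                    gene_id=fields[3],
                    scaffold=fields[0],
                    start=start,
                    end=end,
                    strand=fields[5] if len(fields) > 5 else ".",
                )
            else:
                if len(fields) < 9:
                    raise FormatError(f"line {lineno}: GFF3 needs 9 columns")
                if fields[2].lower() != "gene":
                    continue
                try:
                    start, end = int(fields[3]) - 1, int(fields[4])
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: non-integer GFF3 coordinates") from exc
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                gene_id = attrs.get("ID") or attrs.get("Name")
                if gene_id is None:
                    raise FormatError(f"line {lineno}: gene feature lacks ID attribute")
                rec = dict(
                    gene_id=gene_id,
                    scaffold=fields[0],
                    start=start,
                    end=end,
                    strand=fields[6],
                )
            if rec["start"] >= rec["end"]:
                raise FormatError(
                    f"line {lineno}: start >= end for gene {rec['gene_id']}"
                )
            genes.append(rec)
    df = pd.DataFrame(genes, columns=["gene_id", "scaffold", "start", "end", "strand"])
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"duplicate gene ids: {dups}")
    return df


def write_gene_bed(path, genes: pd.DataFrame) -> None:
    genes[["scaffold", "start", "end", "gene_id", "strand"]].assign(
        score=0
    )[["scaffold", "start", "end", "gene_id", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def make_windows(scaffold_lengths: dict[str, int], size: int = 50_000) -> pd.DataFrame:
    """Tile each scaffold with non-overlapping windows of ``size`` bp
    anchored at coordinate 0; the last (possibly partial) window is kept and
    flagged."""
    if size <= 0:
        raise ValueError("window size must be positive")
    recs = []
    for scaf, length in scaffold_lengths.items():
        for start in range(0, int(length), size):
            end = min(start + size, int(length))
            recs.append((scaf, start, end, end - start < size))
    return pd.DataFrame(recs, columns=["scaffold", "start", "end", "partial"])


def assign_windows(variants: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Window row index for each variant (-1 when no window covers it)."""
    out = np.full(len(variants), -1, dtype=np.int64)
    win_by_scaf = {
        scaf: grp for scaf, grp in windows.groupby("scaffold", sort=False)
    }
    for scaf, grp in variants.groupby("scaffold", sort=False):
        w = win_by_scaf.get(scaf)
        if w is None:
            continue
        starts = w["start"].to_numpy()
        ends = w["end"].to_numpy()
        pos0 = grp["pos"].to_numpy() - 1  # to 0-based
        j = np.searchsorted(starts, pos0, side="right") - 1
        ok = (j >= 0) & (pos0 < ends[np.clip(j, 0, len(ends) - 1)])
        out[grp.index.to_numpy()[ok]] = w.index.to_numpy()[j[ok]]
    return out


# ---------------------------------------------------------------------------
# Sample metadata and stat tracks
# ---------------------------------------------------------------------------

PANEL_COLUMNS = [
    "sample", "subspecies", "mass_g", "winter_temp_c", "summer_temp_c",
    "latitude", "longitude", "size_class",
]


def read_sample_metadata(path) -> pd.DataFrame:
    """Read the sample panel TSV (sample id, subspecies, body mass,
    winter/summer temperature, coordinates, size class)."""
    panel = pd.read_csv(path, sep="\t", dtype={"sample": str, "subspecies": str})
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    if panel["sample"].duplicated().any():
        dups = panel.loc[panel["sample"].duplicated(), "sample"].tolist()
        raise FormatError(f"duplicate sample ids in metadata: {dups}")
    if panel["subspecies"].nunique() < 2:
        raise FormatError("panel must contain at least 2 subspecies")
    return panel


def check_panel_covers(panel: pd.DataFrame, samples: list[str]) -> None:
    absent = sorted(set(samples) - set(panel["sample"]))
    if absent:
        raise FormatError(f"samples missing from metadata panel: {absent}")


def write_sample_metadata(path, panel: pd.DataFrame) -> None:
    panel[PANEL_COLUMNS].to_csv(path, sep="\t", index=False)


TRACK_COLUMNS = ["scaffold", "start", "end", "mid", "n_snps", "stat"]


def write_track(track: pd.DataFrame, path) -> None:
    """Write a windowed statistic track as TSV (scaffold, start, end, mid,
    n_snps, stat)."""
    out = track.copy()
    if "mid" not in out.columns:
        out["mid"] = (out["start"] + out["end"]) // 2
    out[TRACK_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_track(path) -> pd.DataFrame:
    track = pd.read_csv(path, sep="\t", dtype={"scaffold": str})
    missing = [c for c in TRACK_COLUMNS if c not in track.columns]
    if missing:
        raise FormatError(f"track missing columns: {missing}")
    return track
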