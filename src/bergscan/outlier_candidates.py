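"""Shared-outlier candidate-gene calling from windowed F_ST tracks.

Per pairwise comparison, windows in the extreme upper tail of the windowed
F_ST distribution are called elevated; genes within a margin of an elevated
window are hits; the candidate set is the genes hit in every between-size
comparison and in no control comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonSpec:
    """One pairwise subspecies comparison.

    ``role`` is ``between_size`` for large-vs-smaller comparisons that
    define candidates, or ``control`` for within-size comparisons used to
    exclude background differentiation.
    """

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    role: str = "between_size"

    def __post_init__(self):
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"comparison {self.name}: groups overlap")
        if self.role not in ("between_size", "control"):
            raise ValueError(f"comparison {self.name}: unknown role {self.role!r}")


def track_filter(track: pd.DataFrame, min_snps: int = 10,
                 min_windows: int = 4) -> pd.DataFrame:
    """Drop windows with fewer than ``min_snps`` SNPs, then scaffolds left
    with fewer than ``min_windows`` windows."""
    if "n_snps" not in track.columns:
        raise ValueError("track lacks n_snps column")
    kept = track.loc[track["n_snps"] >= min_snps]
    sizes = kept.groupby("scaffold")["start"].transform("size")
    kept = kept.loc[sizes >= min_windows].reset_index(drop=True)
    if kept.empty:
        logger.warning("track_filter: no windows survive")
    return kept


def elevated_windows(track: pd.DataFrame, percentile: float = 99.9):
    """Windows with value >= the empirical percentile (linear interpolation
    between order statistics) of all defined window values.

    Returns (elevated windows, threshold).
    """
    values = track["stat"].to_numpy(dtype=float)
    defined = np.isfinite(values)
    if not defined.any():
        raise ValueError("all window values undefined")
    threshold = float(np.percentile(values[defined], percentile))
    elevated = track.loc[defined & (values >= threshold)].reset_index(drop=True)
    if len(elevated) == defined.sum():
        logger.info("elevated_windows: degenerate track, all windows elevated")
    return elevated, threshold


def genes_near_windows(genes: pd.DataFrame, windows: pd.DataFrame,
                       margin: int = 50_000) -> set[str]:
    """Genes whose interval intersects any elevated window expanded by
    ``margin`` on both sides (half-open interval intersection)."""
    hits: set[str] = set()
    win_by_scaf = {s: g for s, g in windows.groupby("scaffold", sort=False)}
    unmatched_scaffolds = set()
    for scaf, grp in genes.groupby("scaffold", sort=False):
        w = win_by_scaf.get(scaf)
        if w is None:
            unmatched_scaffolds.add(scaf)
            continue
        ws = np.maximum(w["start"].to_numpy() - margin, 0)
        we = w["end"].to_numpy() + margin
        gs = grp["start"].to_numpy()[:, None]
        ge = grp["end"].to_numpy()[:, None]
        overlap = (gs < we[None, :]) & (ws[None, :] < ge)
        hit = overlap.any(axis=1)
        hits.update(grp.loc[hit, "gene_id"])
    if unmatched_scaffolds:
        logger.info(
            "genes_near_windows: %d gene scaffolds absent from window track",
            len(unmatched_scaffolds),
        )
    return hits


@dataclass
class CandidateReport:
    """Outcome of the shared-outlier candidate-gene intersection."""

    per_comparison: dict = field(default_factory=dict)
    shared_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    candidates: list[str] = field(default_factory=list)
    control_overlap: list[str] = field(default_factory=list)

    def membership_matrix(self) -> pd.DataFrame:
        return self.shared_table

    def summary(self) -> str:
        lines = [
            f"comparisons: {len(self.per_comparison)}",
        ]
        for name, info in self.per_comparison.items():
            lines.append(
                f"  {name} ({info['role']}): threshold={info['threshold']:.4g}, "
                f"{info['n_elevated']} elevated windows, {len(info['hits'])} gene hits"
            )
        lines.append(f"final candidates ({len(self.candidates)}): "
                     + ", ".join(self.candidates))
        lines.append(f"control overlaps ({len(self.control_overlap)}): "
                     + ", ".join(self.control_overlap))
        return "\n".join(lines)


def candidate_gene_set(
    hits_per_comparison: dict[str, set[str]],
    comparisons: list[ComparisonSpec],
    min_shared: int = 2,
) -> CandidateReport:
    """Intersect gene hits across comparisons.

    Shared table: genes hit in at least ``min_shared`` between-size
    comparisons. Final candidates: genes hit in all between-size comparisons
    and in no control comparison; genes excluded only by a control overlap
    are reported separately.
    """
    by_name = {c.name: c for c in comparisons}
    between = [c.name for c in comparisons if c.role == "between_size"]
    controls = [c.name for c in comparisons if c.role == "control"]
    if not between:
        raise ValueError("need at least one between_size comparison")
    unknown = set(hits_per_comparison) - set(by_name)
    if unknown:
        raise ValueError(f"hits for unknown comparisons: {sorted(unknown)}")

    all_genes = sorted(set().union(*hits_per_comparison.values()) if hits_per_comparison else set())
    rows = []
    for gene in all_genes:
        row = {"gene_id": gene}
        for name in between + controls:
            row[name] = gene in hits_per_comparison.get(name, set())
        row["n_between"] = sum(row[n] for n in between)
        row["n_control"] = sum(row[n] for n in controls)
        rows.append(row)
    table = pd.DataFrame(rows, columns=["gene_id", *between, *controls,
                                        "n_between", "n_control"])
    shared = table.loc[table["n_between"] >= min_shared].reset_index(drop=True)
    in_all = table["n_between"] == len(between)
    no_control = table["n_control"] == 0
    candidates = table.loc[in_all & no_control, "gene_id"].tolist()
    control_overlap = table.loc[in_all & ~no_control, "gene_id"].tolist()

    report = CandidateReport(
        shared_table=shared,
        candidates=sorted(candidates),
        control_overlap=sorted(control_overlap),
    )
    return report


def candidate_snps(
    variants: pd.DataFrame,
    gm: GenotypeMatrix,
    genes: pd.DataFrame,
    candidate_ids: list[str],
) -> np.ndarray:
    """Row indices of SNPs lying within a candidate gene interval (no
    margin; gene intervals 0-based half-open, VCF pos 1-based)."""
    if not candidate_ids:
        raise ValueError("candidate gene list is empty")
    sel = genes.loc[genes["gene_id"].isin(candidate_ids)]
    keep = np.zeros(len(variants), dtype=bool)
    pos0 = variants["pos"].to_numpy() - 1
    scafs = variants["scaffold"].to_numpy()
    for _, g in sel.iterrows():
        keep |= (scafs == g["scaffold"]) & (pos0 >= g["start"]) & (pos0 < g["end"])
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        logger.warning("candidate_snps: no SNPs in candidate genes")
    return idx
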