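"""Workflow orchestration: discovery scan and validation stages.

``run_scan`` executes site filtering, windowed F_ST per comparison, the
scaffold/window track filter, percentile outlier calling, gene-hit lookup
and the shared/control-excluded candidate-gene intersection, and also emits
diversity tracks per subspecies and comparison. ``run_validate`` takes a
candidate report and executes the validation stage: candidate SNP
extraction, subspecies allele-frequency matrix, correlation-based focal SNP
selection, regressions, per-site F_ST summaries, the partial Mantel test,
focal-region expansion, Ward clustering and a CLR sweep scan around the
candidate genes.

Every threshold is an explicit named field of :class:`RunConfig`; a run
writes its outputs under a fixed directory layout together with a manifest
(config snapshot, input checksums, seed, output inventory).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats, popgen_stats, outlier_candidates, sweep_clr, validation
from .io_formats import GenotypeMatrix
from .outlier_candidates import ComparisonSpec, CandidateReport

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and stage thresholds of a pipeline run."""

    vcf: str = ""
    genes: str = ""
    metadata: str = ""
    outdir: str = "bergscan_run"
    comparisons: list[dict] = field(default_factory=list)
    # site filters
    maf_min: float = 0.05
    depth_min: float = 2.0
    depth_max: float = 50.0
    miss_max: float = 0.20
    # windowed scan
    window_size: int = 50_000
    min_snps_per_window: int = 10
    min_windows_per_scaffold: int = 4
    outlier_percentile: float = 99.9
    gene_margin: int = 50_000
    min_shared: int = 2
    # validation
    r_min: float = 0.90
    fixed_threshold: float = 0.95
    mantel_permutations: int = 9999
    flank: int = 3
    # CLR scan
    clr_grid_spacing: int = 200
    clr_alpha_points: int = 40
    clr_folded: bool = True
    sweep_percentile: float = 99.0
    clr_region_halfwidth: int = 500_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def comparison_specs(self) -> list[ComparisonSpec]:
        specs = [
            ComparisonSpec(
                name=c["name"],
                group_a=tuple(c["group_a"]),
                group_b=tuple(c["group_b"]),
                role=c.get("role", "between_size"),
            )
            for c in self.comparisons
        ]
        if not any(s.role == "between_size" for s in specs):
            raise ValueError("config needs at least one between_size comparison")
        return specs


def default_comparisons() -> list[dict]:
    """The four between-size and two within-size (control) pairings of the
    discovery panel."""
    return [
        {"name": "maxima_vs_merrilli", "group_a": ["maxima"], "group_b": ["merrilli"],
         "role": "between_size"},
        {"name": "maxima_vs_rufina", "group_a": ["maxima"], "group_b": ["rufina"],
         "role": "between_size"},
        {"name": "sanaka_vs_merrilli", "group_a": ["sanaka"], "group_b": ["merrilli"],
         "role": "between_size"},
        {"name": "sanaka_vs_rufina", "group_a": ["sanaka"], "group_b": ["rufina"],
         "role": "between_size"},
        {"name": "maxima_vs_sanaka", "group_a": ["maxima"], "group_b": ["sanaka"],
         "role": "control"},
        {"name": "merrilli_vs_rufina", "group_a": ["merrilli"], "group_b": ["rufina"],
         "role": "control"},
    ]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, config: RunConfig):
        self.payload = {
            "config": asdict(config),
            "inputs": {},
            "outputs": [],
            "seed": config.seed,
        }

    def add_input(self, name, path):
        self.payload["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def add_output(self, path):
        self.payload["outputs"].append(str(path))

    def write(self, path):
        Path(path).write_text(json.dumps(self.payload, indent=1, default=str))


def _load_inputs(config: RunConfig):
    variants, gm, samples = io_formats.read_vcf(config.vcf)
    genes = io_formats.read_gene_annotation(config.genes)
    panel = io_formats.read_sample_metadata(config.metadata)
    io_formats.check_panel_covers(panel, samples)
    panel = panel.set_index("sample").loc[samples].reset_index()
    return variants, gm, genes, panel


def _subspecies_columns(gm: GenotypeMatrix, panel: pd.DataFrame, names) -> np.ndarray:
    samples = panel.loc[panel["subspecies"].isin(list(names)), "sample"].tolist()
    if not samples:
        raise ValueError(f"no samples for subspecies {list(names)}")
    return gm.sample_index(samples)


def _scaffold_lengths_from_vcf(path) -> dict[str, int]:
    lengths = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            if line.startswith("##contig"):
                inner = line.strip()[len("##contig=<"):-1]
                kv = dict(p.split("=", 1) for p in inner.split(","))
                if "ID" in kv and "length" in kv:
                    lengths[kv["ID"]] = int(kv["length"])
    return lengths


def run_scan(config: RunConfig) -> dict:
    """Discovery workflow: filters, windowed statistics, outlier windows,
    candidate genes. Writes tracks/ and candidates/ under the run directory
    and returns the in-memory results."""
    outdir = Path(config.outdir)
    (outdir / "tracks").mkdir(parents=True, exist_ok=True)
    (outdir / "candidates").mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config)
    for name in ("vcf", "genes", "metadata"):
        manifest.add_input(name, getattr(config, name))

    variants, gm, genes, panel = _load_inputs(config)
    n_before = len(variants)
    variants, gm = io_formats.filter_sites(
        variants, gm, config.maf_min, config.depth_min, config.depth_max,
        config.miss_max,
    )
    logger.info("scan: %d of %d sites pass filters", len(variants), n_before)

    lengths = _scaffold_lengths_from_vcf(config.vcf)
    if not lengths:
        lengths = (
            variants.groupby("scaffold")["pos"].max().astype(int).to_dict()
        )
    windows = io_formats.make_windows(lengths, config.window_size)

    specs = config.comparison_specs()
    tracks: dict[str, pd.DataFrame] = {}
    hits: dict[str, set] = {}
    per_comparison: dict[str, dict] = {}
    elevated_by_comparison: dict[str, pd.DataFrame] = {}
    for spec in specs:
        g1 = _subspecies_columns(gm, panel, spec.group_a)
        g2 = _subspecies_columns(gm, panel, spec.group_b)
        track = popgen_stats.windowed_fst(gm, g1, g2, variants, windows)
        tracks[spec.name] = track
        io_formats.write_track(track, outdir / "tracks" / f"fst_{spec.name}.tsv")
        manifest.add_output(outdir / "tracks" / f"fst_{spec.name}.tsv")

        filtered = outlier_candidates.track_filter(
            track, config.min_snps_per_window, config.min_windows_per_scaffold
        )
        elevated, threshold = outlier_candidates.elevated_windows(
            filtered, config.outlier_percentile
        )
        gene_hits = outlier_candidates.genes_near_windows(
            genes, elevated, config.gene_margin
        )
        hits[spec.name] = gene_hits
        elevated_by_comparison[spec.name] = elevated
        per_comparison[spec.name] = {
            "role": spec.role,
            "threshold": threshold,
            "n_elevated": len(elevated),
            "hits": sorted(gene_hits),
        }
        logger.info(
            "scan %s: threshold %.4f, %d elevated windows, %d gene hits",
            spec.name, threshold, len(elevated), len(gene_hits),
        )

    report = outlier_candidates.candidate_gene_set(hits, specs, config.min_shared)
    report.per_comparison = per_comparison

    # diversity tracks per subspecies and per comparison
    for sub in panel["subspecies"].unique():
        cols = _subspecies_columns(gm, panel, [sub])
        if cols.size < 2:
            continue
        pi = popgen_stats.windowed_pi(gm, cols, variants, windows)
        io_formats.write_track(pi, outdir / "tracks" / f"pi_{sub}.tsv")
        manifest.add_output(outdir / "tracks" / f"pi_{sub}.tsv")
        taj = popgen_stats.windowed_tajimas_d(gm, cols, variants, windows)
        io_formats.write_track(taj, outdir / "tracks" / f"tajimas_d_{sub}.tsv")
        manifest.add_output(outdir / "tracks" / f"tajimas_d_{sub}.tsv")
    for spec in specs:
        g1 = _subspecies_columns(gm, panel, spec.group_a)
        g2 = _subspecies_columns(gm, panel, spec.group_b)
        dxy = popgen_stats.windowed_dxy(gm, g1, g2, variants, windows)
        io_formats.write_track(dxy, outdir / "tracks" / f"dxy_{spec.name}.tsv")
        manifest.add_output(outdir / "tracks" / f"dxy_{spec.name}.tsv")

    report.shared_table.to_csv(
        outdir / "candidates" / "gene_membership.tsv", sep="\t", index=False
    )
    (outdir / "candidates" / "summary.txt").write_text(report.summary() + "\n")
    manifest.add_output(outdir / "candidates" / "gene_membership.tsv")
    manifest.add_output(outdir / "candidates" / "summary.txt")
    manifest.write(outdir / "manifest_scan.json")

    return {
        "variants": variants,
        "genotypes": gm,
        "genes": genes,
        "panel": panel,
        "windows": windows,
        "tracks": tracks,
        "elevated": elevated_by_comparison,
        "report": report,
        "scaffold_lengths": lengths,
    }


def run_validate(config: RunConfig, scan: dict | None = None,
                 report: CandidateReport | None = None) -> dict:
    """Validation workflow on the candidate report of a scan."""
    if scan is None:
        scan = run_scan(config)
    if report is None:
        report = scan["report"]
    outdir = Path(config.outdir) / "validation"
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config)

    if not report.candidates:
        logger.warning("run_validate: empty candidate set; nothing to validate")
        return {"report": report, "skipped": True}

    variants = scan["variants"]
    gm = scan["genotypes"]
    genes = scan["genes"]
    panel = scan["panel"]
    specs = config.comparison_specs()
    between = [s for s in specs if s.role == "between_size"]

    snp_idx = outlier_candidates.candidate_snps(
        variants, gm, genes, report.candidates
    )
    logger.info("validate: %d candidate SNPs in %d genes",
                snp_idx.size, len(report.candidates))

    freqs = validation.subspecies_allele_freqs(gm, panel, snp_idx)
    assoc, selected = validation.correlate_and_select(freqs, panel, config.r_min)

    means = validation.subspecies_means(panel)
    sub_cols = [s for s in freqs.columns if s in means.index]
    reg_rows = []
    for i in selected:
        f = freqs.loc[i, sub_cols].to_numpy(dtype=float)
        for response, label in (
            (means.loc[sub_cols, "mass_g"].to_numpy(), "mass_g"),
            (means.loc[sub_cols, "winter_temp_c"].to_numpy(), "winter_temp_c"),
            (means.loc[sub_cols, "summer_temp_c"].to_numpy(), "summer_temp_c"),
        ):
            res = validation.snp_regressions(f, response)
            reg_rows.append(
                {
                    "snp_index": int(i),
                    "scaffold": variants["scaffold"].iloc[i],
                    "pos": int(variants["pos"].iloc[i]),
                    "response": label,
                    "slope": res["slope"],
                    "intercept": res["intercept"],
                    "ci_low": res["slope_ci_low"],
                    "ci_high": res["slope_ci_high"],
                    "r_squared": res["r_squared"],
                    "f_stat": res["f_stat"],
                    "df": f"({res['df_num']},{res['df_den']})",
                    "p_value": res["p_value"],
                    "max_cooks_d": float(np.max(res["cooks_d"])),
                }
            )
    regressions = pd.DataFrame(reg_rows)

    fst_summary = validation.per_site_fst_summary(
        gm, panel, between, snp_idx, variants, genes,
        config.fixed_threshold,
    )

    genetic, phenotype, geographic, subs = validation.distance_matrices(freqs, panel)
    mantel = validation.partial_mantel(
        genetic, phenotype, geographic, config.mantel_permutations, config.seed
    )

    focal_idx = snp_idx[np.isin(snp_idx, selected)]
    tree = None
    if focal_idx.size:
        region_idx = validation.focal_region_snps(
            variants, focal_idx, flank=config.flank
        )
        tree = validation.genotype_ward_tree(gm, variants, region_idx)
        (outdir / "ward_tree.nwk").write_text(tree["newick"] + "\n")
        tree["heatmap"].to_csv(outdir / "genotype_heatmap.tsv", sep="\t", index=False)
        manifest.add_output(outdir / "ward_tree.nwk")
        manifest.add_output(outdir / "genotype_heatmap.tsv")

    clr_tracks, clr_calls = _clr_on_candidate_contigs(
        config, scan, report, variants, gm, panel
    )

    assoc_out = assoc.copy()
    assoc_out.insert(0, "pos", variants["pos"].to_numpy()[assoc.index])
    assoc_out.insert(0, "scaffold", variants["scaffold"].to_numpy()[assoc.index])
    assoc_out["selected"] = np.isin(assoc.index.to_numpy(), selected)
    assoc_out.to_csv(outdir / "snp_associations.tsv", sep="\t")
    regressions.to_csv(outdir / "regressions.tsv", sep="\t", index=False)
    fst_summary["per_snp"].to_csv(outdir / "focal_fst.tsv", sep="\t")
    fst_summary["per_gene"].to_csv(outdir / "gene_fixed_fractions.tsv",
                                   sep="\t", index=False)
    (outdir / "mantel.json").write_text(json.dumps(asdict(mantel), indent=1))
    for name in ("snp_associations.tsv", "regressions.tsv", "focal_fst.tsv",
                 "gene_fixed_fractions.tsv", "mantel.json"):
        manifest.add_output(outdir / name)
    if clr_tracks is not None:
        clr_out = pd.concat(clr_tracks.values(), ignore_index=True)
        clr_out.to_csv(outdir / "clr_track.tsv", sep="\t", index=False)
        manifest.add_output(outdir / "clr_track.tsv")
    manifest.write(Path(config.outdir) / "manifest_validate.json")

    return {
        "report": report,
        "snp_index": snp_idx,
        "freqs": freqs,
        "associations": assoc_out,
        "selected": selected,
        "regressions": regressions,
        "fst_summary": fst_summary,
        "mantel": mantel,
        "tree": tree,
        "clr_tracks": clr_tracks,
        "clr_calls": clr_calls,
    }


def _clr_on_candidate_contigs(config, scan, report, variants, gm, panel):
    """CLR scan over the candidate contigs, restricted to a window of
    ``clr_region_halfwidth`` around the candidate genes, using the pooled
    discovery panel; sweep calls report flagged positions and the per-contig
    maximum."""
    genes = scan["genes"]
    cand = genes.loc[genes["gene_id"].isin(report.candidates)]
    if cand.empty:
        return None, None
    rng = np.random.default_rng(config.seed)
    tracks: dict[str, pd.DataFrame] = {}
    for scaf, grp in cand.groupby("scaffold"):
        lo = max(int(grp["start"].min()) - config.clr_region_halfwidth, 0)
        hi = int(grp["end"].max()) + config.clr_region_halfwidth
        on_scaf = (
            (variants["scaffold"] == scaf)
            & (variants["pos"] - 1 >= lo)
            & (variants["pos"] - 1 < hi)
        )
        idx = np.flatnonzero(on_scaf.to_numpy())
        if idx.size < 10:
            continue
        sub_variants = variants.iloc[idx].reset_index(drop=True)
        sub_gm = gm.take_sites(idx)
        # pool the discovery (large + smaller) panels for the region scan
        discovery = panel.loc[
            panel["size_class"].isin(["large", "smaller"]), "sample"
        ].tolist()
        cols = sub_gm.sample_index(discovery)
        try:
            background = sweep_clr.background_sfs(sub_gm, cols, config.clr_folded)
        except ValueError:
            continue
        sites = sweep_clr.prepare_sweep_sites(
            sub_gm, cols, sub_variants, background, rng
        )
        if len(sites) < 2:
            continue
        track = sweep_clr.clr_scan(
            sites, background, config.clr_grid_spacing,
            alpha_grid=None, bounds=(lo, hi),
        )
        track.insert(0, "scaffold", scaf)
        tracks[scaf] = track
    if not tracks:
        return None, None
    combined = pd.concat(tracks.values(), ignore_index=True)
    calls = sweep_clr.sweep_calls(combined, config.sweep_percentile)
    return tracks, calls


def run_all(config: RunConfig) -> dict:
    scan = run_scan(config)
    out = run_validate(config, scan=scan)
    out["scan"] = scan
    return out
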