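"""Synthetic multi-population genotype datasets with planted truth.

The generator emulates the study design the scan pipeline targets: nine
subspecies panels (two large- and two smaller-bodied discovery populations
plus five small-bodied validation populations) whose body masses correlate
negatively with winter and summer temperature. Neutral divergence follows
the Balding-Nichols model: each subspecies' allele frequency at a site is
Beta-distributed around an ancestral frequency with variance parameter F.
Planted candidate genes carry SNPs whose subspecies frequencies follow a
logistic shift proportional to the subspecies body-mass z-score, so the
non-reference allele tracks larger mass. Sweep regions push site
frequencies in the large-bodied subspecies toward near-fixation with a
configurable distortion probability, skewing the local SFS and reducing
diversity. Genotypes are binomial draws from subspecies frequencies with
uniform missingness; sites are independent (no LD).

A single-population neutral coalescent window simulator is included as a
calibration oracle for the diversity and SFS estimators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .io_formats import GenotypeMatrix

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SubspeciesConfig:
    name: str
    n_individuals: int
    mean_mass_g: float
    sd_mass_g: float
    winter_temp_c: float
    summer_temp_c: float
    latitude: float
    longitude: float
    size_class: str  # large / smaller / small


def default_subspecies() -> list[SubspeciesConfig]:
    """Nine-panel default: masses and winter/summer temperatures chosen so
    mass and temperature are strongly negatively related across panels,
    with two large, two smaller and five small subspecies."""
    rows = [
        # name, n, mass, sd, wintT, sumT, lat, lon, class
        ("maxima", 12, 46.9, 2.0, -2.1, 10.3, 57.0, -156.0, "large"),
        ("sanaka", 8, 44.9, 2.0, -1.5, 9.8, 55.3, -162.7, "large"),
        ("rufina", 12, 27.5, 1.5, 2.5, 13.5, 54.0, -130.3, "smaller"),
        ("merrilli", 8, 25.9, 1.5, 3.9, 15.1, 55.0, -131.7, "smaller"),
        ("gouldii", 10, 19.8, 1.0, 8.6, 16.5, 38.0, -122.8, "small"),
        ("heermanni", 8, 20.5, 1.0, 8.3, 18.4, 37.5, -121.9, "small"),
        ("maxillaris", 6, 19.2, 1.0, 8.9, 17.4, 38.2, -122.3, "small"),
        ("pusillula", 9, 17.9, 1.0, 9.4, 16.8, 37.6, -122.1, "small"),
        ("samuelis", 6, 18.4, 1.0, 9.1, 16.2, 38.1, -122.4, "small"),
    ]
    return [SubspeciesConfig(*r) for r in rows]


@dataclass
class PlantedGene:
    gene_id: str
    scaffold: str
    start: int
    end: int


@dataclass
class SweepRegion:
    scaffold: str
    center: int
    width: int
    distortion: float


@dataclass
class SimConfig:
    """Full specification of one synthetic dataset.

    The defaults are the package's reference study conditions: 24 scaffolds
    of 20 Mb (~9600 50-kb windows, enough for the 99.9th-percentile outlier
    rule to leave room above every planted window), neutral SNP density
    4e-4/bp, heterogeneous per-subspecies Balding-Nichols divergence
    (island populations drift hardest, within-size pairs far less diverged
    than between-size pairs), five planted genes at effect size beta = 3,
    two sweep regions, and 15% missing genotypes.
    """

    seed: int = 0
    subspecies: list[SubspeciesConfig] = field(default_factory=default_subspecies)
    n_scaffolds: int = 24
    scaffold_length: int = 20_000_000
    snp_density: float = 4e-4
    # per-subspecies Balding-Nichols divergence; a scalar applies one F to
    # every subspecies
    fst: float | dict[str, float] = field(
        default_factory=lambda: {
            "maxima": 0.12, "sanaka": 0.10, "rufina": 0.05, "merrilli": 0.04,
            "gouldii": 0.06, "heermanni": 0.06, "maxillaris": 0.06,
            "pusillula": 0.06, "samuelis": 0.06,
        }
    )
    n_planted_genes: int = 5
    gene_length: int = 30_000
    gene_snp_density: float = 1.4e-3
    beta: float = 3.0
    causal_p0_range: tuple[float, float] = (0.3, 0.5)
    n_sweep_regions: int = 2
    sweep_width: int = 80_000
    sweep_distortion: float = 0.9
    n_decoy_genes: int = 45
    # per-call missing probability; at 0.10 the binomial tail of per-site
    # missingness stays almost entirely below the pipeline's 20% site
    # filter, so filtering removes few sites outright
    missing_rate: float = 0.10
    mean_depth: float = 7.0

    def __post_init__(self):
        for f in self.fst_by_subspecies().values():
            if not (0 < f < 1):
                raise ValueError("fst must be in (0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")

    def fst_by_subspecies(self) -> dict[str, float]:
        if isinstance(self.fst, dict):
            missing = [s.name for s in self.subspecies if s.name not in self.fst]
            if missing:
                raise ValueError(f"fst dict lacks subspecies: {missing}")
            return {s.name: float(self.fst[s.name]) for s in self.subspecies}
        return {s.name: float(self.fst) for s in self.subspecies}

    @property
    def scaffold_names(self) -> list[str]:
        return [f"scaffold_{i + 1}" for i in range(self.n_scaffolds)]

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {s: self.scaffold_length for s in self.scaffold_names}


@dataclass
class TruthTable:
    planted_genes: list[PlantedGene]
    causal_snps: pd.DataFrame  # scaffold, pos, p0, true_r_mass
    sweep_regions: list[SweepRegion]
    fst: float | dict

    def to_json(self, path) -> None:
        payload = {
            "fst": self.fst,
            "planted_genes": [asdict(g) for g in self.planted_genes],
            "sweep_regions": [asdict(s) for s in self.sweep_regions],
            "causal_snps": self.causal_snps.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_genes=[PlantedGene(**g) for g in payload["planted_genes"]],
            causal_snps=pd.DataFrame(payload["causal_snps"]),
            sweep_regions=[SweepRegion(**s) for s in payload["sweep_regions"]],
            fst=payload["fst"],
        )


def _mass_zscores(subspecies: list[SubspeciesConfig]) -> np.ndarray:
    mass = np.array([s.mean_mass_g for s in subspecies])
    return (mass - mass.mean()) / mass.std()


def _logit(p):
    return np.log(p / (1 - p))


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


def plan_features(config: SimConfig, rng: np.random.Generator):
    """Place planted genes, decoy genes and sweep regions.

    Planted genes sit on the first three scaffolds, aligned inside a single
    50-kb window; sweep regions on the last two scaffolds; decoys anywhere
    at least 200 kb from planted features.
    """
    genes: list[PlantedGene] = []
    scafs = config.scaffold_names
    host_scafs = [scafs[i % 3] for i in range(config.n_planted_genes)]
    per_scaf_counter: dict[str, int] = {}
    for i, scaf in enumerate(host_scafs):
        slot = per_scaf_counter.get(scaf, 0)
        per_scaf_counter[scaf] = slot + 1
        window_start = 1_000_000 + slot * 1_000_000  # distinct 50 kb windows
        start = window_start + 10_000
        end = start + config.gene_length
        if end > config.scaffold_length:
            raise ValueError("planted gene outside scaffold")
        genes.append(PlantedGene(f"planted_{i + 1}", scaf, start, end))

    sweeps: list[SweepRegion] = []
    for i in range(config.n_sweep_regions):
        scaf = scafs[-(i + 1)]
        center = config.scaffold_length // 2
        sweeps.append(
            SweepRegion(scaf, center, config.sweep_width, config.sweep_distortion)
        )

    decoys = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        occupied.setdefault(g.scaffold, []).append((g.start, g.end))
    for s in sweeps:
        occupied.setdefault(s.scaffold, []).append(
            (s.center - s.width // 2, s.center + s.width // 2)
        )
    while len(decoys) < config.n_decoy_genes:
        scaf = scafs[int(rng.integers(len(scafs)))]
        start = int(rng.integers(0, config.scaffold_length - config.gene_length))
        end = start + config.gene_length
        clash = any(
            start - 200_000 < oe and os < end + 200_000
            for os, oe in occupied.get(scaf, [])
        )
        if clash:
            continue
        occupied.setdefault(scaf, []).append((start, end))
        decoys.append(PlantedGene(f"decoy_{len(decoys) + 1}", scaf, start, end))
    return genes, decoys, sweeps


def simulate_dataset(
    config: SimConfig, outdir=None
) -> dict:
    """Generate one dataset; optionally write VCF/BED/TSV/truth JSON.

    Returns a dict with the in-memory variant table, genotype matrix,
    sample panel, gene table, truth table and (if ``outdir`` given) the
    file paths.
    """
    rng = np.random.default_rng(config.seed)
    subs = config.subspecies
    z_mass = _mass_zscores(subs)
    genes, decoys, sweeps = plan_features(config, rng)

    # --- site positions per scaffold --------------------------------------
    recs = []
    for scaf in config.scaffold_names:
        n_neutral = rng.poisson(config.scaffold_length * config.snp_density)
        pos = rng.integers(1, config.scaffold_length + 1, size=n_neutral)
        for g in genes:
            if g.scaffold != scaf:
                continue
            extra = rng.poisson((g.end - g.start) * config.gene_snp_density)
            pos = np.concatenate(
                [pos, rng.integers(g.start + 1, g.end + 1, size=extra)]
            )
        pos = np.unique(pos)
        recs.append((scaf, pos))

    # --- frequencies, genotypes -------------------------------------------
    n_samples = sum(s.n_individuals for s in subs)
    sample_names = []
    sample_sub = []
    for s in subs:
        for i in range(s.n_individuals):
            sample_names.append(f"{s.name}_{i + 1:02d}")
            sample_sub.append(s.name)

    all_variants = []
    all_dosage = []
    causal_rows = []
    gene_intervals = {
        scaf: [(g.start, g.end) for g in genes if g.scaffold == scaf]
        for scaf in config.scaffold_names
    }
    sweep_by_scaf = {s.scaffold: s for s in sweeps}
    sub_masses = np.array([s.mean_mass_g for s in subs])

    for scaf, pos in recs:
        m = pos.size
        pos0 = pos - 1
        causal = np.zeros(m, dtype=bool)
        for gs, ge in gene_intervals.get(scaf, []):
            causal |= (pos0 >= gs) & (pos0 < ge)

        p0 = rng.uniform(0.05, 0.95, size=m)
        lo, hi = config.causal_p0_range
        p0[causal] = rng.uniform(lo, hi, size=int(causal.sum()))

        freqs = np.empty((m, len(subs)))
        f_by_sub = config.fst_by_subspecies()
        for j, s in enumerate(subs):
            F = f_by_sub[s.name]
            a_shape = p0 * (1 - F) / F
            b_shape = (1 - p0) * (1 - F) / F
            freqs[:, j] = rng.beta(a_shape, b_shape)
        # planted-gene SNPs: deterministic logistic mass track
        if causal.any():
            base = _logit(p0[causal])[:, None]
            freqs[causal] = _invlogit(base + config.beta * z_mass[None, :])

        sweep = sweep_by_scaf.get(scaf)
        if sweep is not None:
            half = sweep.width // 2
            in_region = (pos0 >= sweep.center - half) & (pos0 < sweep.center + half)
            for j, s in enumerate(subs):
                if s.size_class != "large":
                    continue
                eps = 1.0 / (2 * s.n_individuals)
                hit = in_region & (rng.random(m) < sweep.distortion)
                freqs[hit, j] = np.where(freqs[hit, j] >= 0.5, 1 - eps, eps)

        dosage = np.empty((m, n_samples), dtype=np.int8)
        col = 0
        for j, s in enumerate(subs):
            k = s.n_individuals
            dosage[:, col:col + k] = rng.binomial(
                2, freqs[:, j][:, None], size=(m, k)
            ).astype(np.int8)
            col += k
        if config.missing_rate > 0:
            mask = rng.random(dosage.shape) < config.missing_rate
            dosage[mask] = io_formats.MISSING

        ref_idx = rng.integers(0, 4, size=m)
        alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
        depth = rng.gamma(20.0, config.mean_depth / 20.0, size=m)
        all_variants.append(
            pd.DataFrame(
                {
                    "scaffold": scaf,
                    "pos": pos.astype(np.int64),
                    "ref": _BASES[ref_idx],
                    "alt": _BASES[alt_idx],
                    "mean_depth": np.round(depth, 2),
                }
            )
        )
        all_dosage.append(dosage)
        if causal.any():
            true_freqs = freqs[causal]
            for row_pos, fvec in zip(pos[causal], true_freqs):
                r = np.corrcoef(fvec, sub_masses)[0, 1]
                causal_rows.append((scaf, int(row_pos), float(r)))

    variants = pd.concat(all_variants, ignore_index=True)
    gm = GenotypeMatrix(np.vstack(all_dosage), sample_names)

    # --- metadata ----------------------------------------------------------
    panel_rows = []
    col = 0
    for s in subs:
        masses = rng.normal(s.mean_mass_g, s.sd_mass_g, size=s.n_individuals)
        for i in range(s.n_individuals):
            panel_rows.append(
                (
                    sample_names[col], s.name, round(float(masses[i]), 1),
                    s.winter_temp_c, s.summer_temp_c, s.latitude, s.longitude,
                    s.size_class,
                )
            )
            col += 1
    panel = pd.DataFrame(panel_rows, columns=io_formats.PANEL_COLUMNS)

    gene_table = pd.DataFrame(
        [
            (g.gene_id, g.scaffold, g.start, g.end, "+")
            for g in [*genes, *decoys]
        ],
        columns=["gene_id", "scaffold", "start", "end", "strand"],
    ).sort_values(["scaffold", "start"]).reset_index(drop=True)

    causal_df = pd.DataFrame(causal_rows, columns=["scaffold", "pos", "true_r_mass"])
    truth = TruthTable(
        planted_genes=genes,
        causal_snps=causal_df,
        sweep_regions=sweeps,
        fst=config.fst,
    )

    result = {
        "variants": variants,
        "genotypes": gm,
        "panel": panel,
        "genes": gene_table,
        "truth": truth,
        "scaffold_lengths": config.scaffold_lengths,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "genotypes.vcf",
            "bed": outdir / "genes.bed",
            "metadata": outdir / "samples.tsv",
            "truth": outdir / "truth.json",
        }
        io_formats.write_vcf(paths["vcf"], variants, gm, config.scaffold_lengths)
        io_formats.write_gene_bed(paths["bed"], gene_table)
        io_formats.write_sample_metadata(paths["metadata"], panel)
        truth.to_json(paths["truth"])
        result["paths"] = paths
    return result


def simulate_sweep_scaffold(
    seed: int | np.random.Generator,
    n_individuals: int = 25,
    length: int = 1_000_000,
    n_snps: int = 2000,
    sweep: bool = True,
    center: int | None = None,
    width: int = 80_000,
    distortion: float = 0.9,
    missing_rate: float = 0.0,
    scaffold: str = "sweep_scaffold",
) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Single-population scaffold for CLR calibration.

    Site frequencies are uniform on (0.05, 0.95); inside the sweep region
    (center +/- width/2) each site is pushed to near-fixation (frequency
    1/(2n) or 1 - 1/(2n), keeping its direction) with probability
    ``distortion``, mimicking the frequency skew and diversity loss of a
    recent sweep. Genotypes are Binomial(2, freq) draws.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if center is None:
        center = length // 2
    pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_snps, replace=False))
    freq = rng.uniform(0.05, 0.95, size=n_snps)
    if sweep:
        half = width // 2
        eps = 1.0 / (2 * n_individuals)
        in_region = (pos - 1 >= center - half) & (pos - 1 < center + half)
        hit = in_region & (rng.random(n_snps) < distortion)
        freq[hit] = np.where(freq[hit] >= 0.5, 1 - eps, eps)
    dosage = rng.binomial(2, freq[:, None], size=(n_snps, n_individuals)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = io_formats.MISSING
    ref_idx = rng.integers(0, 4, size=n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_snps)) % 4
    variants = pd.DataFrame(
        {
            "scaffold": scaffold,
            "pos": pos.astype(np.int64),
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "mean_depth": np.nan,
        }
    )
    gm = GenotypeMatrix(
        dosage, [f"ind_{i + 1}" for i in range(n_individuals)]
    )
    return variants, gm


# ---------------------------------------------------------------------------
# Neutral coalescent window simulator (calibration oracle)
# ---------------------------------------------------------------------------

def simulate_coalescent_window(
    n: int, theta: float, seed: int | np.random.Generator = 0
) -> tuple[int, np.ndarray]:
    """Single-population neutral coalescent with infinite-sites mutation.

    Coalescence times are exponential with rate C(k,2) (time in units of 2N
    generations); mutations fall on branches as Poisson(theta/2 x length).
    Returns (segregating site count, haplotype matrix S x n of 0/1 derived
    states).
    """
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    # active lineages: (leaf set, branch start time)
    lineages: list[tuple[frozenset, float]] = [
        (frozenset([i]), 0.0) for i in range(n)
    ]
    t = 0.0
    branches: list[tuple[frozenset, float]] = []  # (carriers, branch length)
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        (set_j, start_j) = lineages.pop(j)
        (set_i, start_i) = lineages.pop(i)
        branches.append((set_i, t - start_i))
        branches.append((set_j, t - start_j))
        lineages.append((set_i | set_j, t))

    sites = []
    for carriers, length in branches:
        n_mut = rng.poisson(theta / 2.0 * length)
        for _ in range(n_mut):
            row = np.zeros(n, dtype=np.int8)
            row[list(carriers)] = 1
            sites.append(row)
    if sites:
        hap = np.vstack(sites)
        order = rng.permutation(len(sites))
        hap = hap[order]
    else:
        hap = np.zeros((0, n), dtype=np.int8)
    return hap.shape[0], hap


def haplotypes_to_genotypes(hap: np.ndarray) -> GenotypeMatrix:
    """Pair consecutive haplotypes into diploid dosages (n must be even)."""
    s, n = hap.shape
    if n % 2:
        raise ValueError("need an even haplotype count")
    d = (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8)
    return GenotypeMatrix(d, [f"ind_{i + 1}" for i in range(n // 2)])


# ---------------------------------------------------------------------------
# Truth evaluation
# ---------------------------------------------------------------------------

def truth_eval(
    truth: TruthTable,
    candidate_genes: list[str] | None = None,
    selected_snps: pd.DataFrame | None = None,
    sweep_argmax: pd.DataFrame | None = None,
    r_min: float = 0.90,
) -> dict:
    """Recovery metrics of a pipeline run against the planted truth.

    ``selected_snps`` needs columns scaffold, pos; ``sweep_argmax`` needs
    scaffold, pos. Focal-SNP sensitivity is measured against the causal
    SNPs whose population-level freq-mass r exceeds ``r_min`` (others are
    not expected to pass the selection rule).
    """
    out: dict = {}
    if candidate_genes is not None:
        planted = {g.gene_id for g in truth.planted_genes}
        found = set(candidate_genes)
        tp = len(found & planted)
        out["gene_sensitivity"] = tp / len(planted) if planted else np.nan
        out["gene_precision"] = tp / len(found) if found else np.nan
    if selected_snps is not None:
        causal = set(
            zip(truth.causal_snps["scaffold"], truth.causal_snps["pos"])
        )
        strong = truth.causal_snps.loc[truth.causal_snps["true_r_mass"] > r_min]
        strong_set = set(zip(strong["scaffold"], strong["pos"]))
        sel = set(zip(selected_snps["scaffold"], selected_snps["pos"]))
        unknown = sel - causal
        if selected_snps.attrs.get("universe_is_causal", False) and unknown:
            raise ValueError("selected SNP ids not present in truth table")
        out["focal_sensitivity"] = (
            len(sel & strong_set) / len(strong_set) if strong_set else np.nan
        )
        out["focal_false_selection_rate"] = (
            len(sel - causal) / len(sel) if sel else 0.0
        )
        out["focal_in_causal"] = sel <= causal
    if sweep_argmax is not None:
        errors = []
        argmax_by_scaf = {
            r["scaffold"]: r["pos"] for _, r in sweep_argmax.iterrows()
        }
        for s in truth.sweep_regions:
            if s.scaffold in argmax_by_scaf:
                errors.append(abs(int(argmax_by_scaf[s.scaffold]) - s.center))
        out["sweep_localization_error_bp"] = (
            float(np.median(errors)) if errors else np.nan
        )
    return out
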