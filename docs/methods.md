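# Methods

This note documents the statistical machinery in `bergscan`, the choices
made where conventions differ between tools, and what the synthetic-data
generator does and does not emulate.

## Data model and conventions

All interval arithmetic is 0-based half-open; VCF and GFF3 coordinates are
converted on read and back-converted on write. Genotypes are diploid
non-reference dosages (0/1/2) with missing calls carried explicitly; every
estimator is per-site complete-case — no imputation or phasing is performed
anywhere in the package. Windows tile each scaffold from coordinate 0 in
non-overlapping blocks (default 50 kb); a partial terminal window is kept
and flagged so downstream filters can drop it if desired.

Site filters follow the common short-read resequencing defaults: biallelic
SNPs only, pooled minor-allele frequency ≥ 0.05 (computed over called
alleles across the full cohort, before any split into populations), mean
site depth within [2, 50] when depth is available (FORMAT/DP preferred,
INFO/DP divided by the sample count otherwise; the rule is skipped with a
warning when neither exists), and per-site missingness ≤ 20%.

## Windowed divergence statistics

Per-site Weir–Cockerham variance components for two populations
(r = 2) are computed from per-population called sample sizes `n_i`
(diploids), allele frequencies `p_i` and observed heterozygote frequencies
`h_i`:

    n̄ = (n1+n2)/2          n_c = (2n̄ − Σn_i²/(2n̄))
    p̄ = Σ n_i p_i / (2n̄)   s² = Σ n_i (p_i−p̄)² / n̄   h̄ = Σ n_i h_i / (2n̄)
    a  = (n̄/n_c) [ s² − (p̄(1−p̄) − s²/2 − h̄/4)/(n̄−1) ]
    b  = (n̄/(n̄−1)) [ p̄(1−p̄) − s²/2 − (2n̄−1)/(4n̄) h̄ ]
    c  = h̄/2

The windowed statistic is the ratio of averages Σa / Σ(a+b+c) over usable
sites (both populations called, n̄ > 1, polymorphic in the pooled pair).
Negative window values are reported as computed, never clamped, so the
empirical percentile threshold sees the full distribution. Sites where
a+b+c = 0 are excluded from the window sums.

Nucleotide diversity uses the unbiased per-site heterozygosity
`2p(1−p)·n/(n−1)` (n in called alleles) and absolute divergence the
between-population mismatch `p1(1−p2) + p2(1−p1)`. Both offer two window
normalizations: per-bp (divide by window length; assumes unlisted positions
are invariant, appropriate for whole-genome variant tables) and
per-variant-site (divide by the usable variant count). Per-bp is the
default; the per-variant-site option exists because divergence magnitudes
in the 0.3–0.9 range reported by typical candidate-region tables are only
obtainable under variant-site normalization.

Tajima's D per window uses the classic normalizing constants at the
nominal sample size n = 2m alleles (m group members), with the pairwise
estimator accumulated per-site complete-case. With high missingness the
nominal-n constants are an approximation; the simulation tests run at
complete data where it is exact, and the neutral-calibration check bounds
the residual bias (mean window D within ±0.15 of 0 at n = 20, θ = 10).

Per-individual inbreeding coefficients are method-of-moments:
F = (O_hom − E_hom)/(N − E_hom), with the per-site expected homozygosity
`1 − 2p(1−p)·2n/(2n−1)` computed from all called samples, restricted to
sites polymorphic in the pooled sample and called in the focal individual.

## SFS projection and the background spectrum

Spectra are projected to smaller sample sizes by hypergeometric
downsampling, Φ_m(k) = Σ_j Φ_n(j)·C(j,k)C(n−j,m−k)/C(n,m), which conserves
mass exactly and composes (n→m→k equals n→k). The empirical background
spectrum for the sweep scan takes each polymorphic site's complete-case
allele count, projects it to the modal complete-case n, and accumulates
expected class counts. Projection only goes downward, so the few sites
whose complete-case n falls below the modal n cannot contribute and are
dropped with a logged count; at the missingness levels the package targets
(≤20%) this loses only the worst-covered tail of sites. The spectrum is
folded by default because the reference assemblies these scans run on are
conspecific, not ancestral; internally a symmetrized unfolded spectrum
backs the projection algebra, which is exact for all folded quantities
derived from it.

## Composite likelihood ratio sweep scan

The sweep model follows the classic composite-likelihood construction: a
lineage sampled at distance d from a sweep centre escapes the sweep with
probability p_e = 1 − exp(−α·d), where α is the sweep intensity per bp.
Conditional on e of n lineages escaping, the ancestral sample of size e+1
(the escapees plus the single swept ancestor) is drawn from the background
spectrum projected to e+1; the swept ancestor is derived with probability
k/(e+1), in which case the n−e hitchhiking lineages are also derived. The
e = n term uses the background projected to n directly. The resulting site
distribution sums to 1 over counts 0..n for all parameters.

At each grid position X (default spacing 200 bp, the window granularity of
the standard implementation of this scan) the statistic is

    CLR(X) = 2 [ max_α Σ_i log P(b_i | n_i, |x_i−X|, α) − Σ_i log Φ(b_i | n_i) ],

floored at zero. Both the sweep and the null likelihood are conditioned on
polymorphism (renormalized over classes 1..n−1), since monomorphic sites
are not in the data. α is profiled over a log-spaced grid (default 40
points spanning α·median(d) from 1e-2 to 1e3); grid search keeps the scan
deterministic. Sites with varying complete-case n use per-n cached
transition matrices; sites with n above the background's sample size are
hypergeometrically downsampled (seeded), the sampling analogue of the
projection used everywhere else.

Numerics: the scan quantizes u = log(α·d) onto 4096 bins spanning the
e=0-dominated regime (α·d < 1e-8) to full escape (α·d > 40), precomputing
per-class conditional log-likelihoods per bin. Relative resolution is
~0.3% in α·d, which perturbs total log-likelihoods by ≲0.1 — orders of
magnitude below the CLR signals of interest — while making the scan ~50×
faster than direct evaluation. Binomial escape weights inside the table are
computed in log space, so no underflow occurs at any α·d.

Sweep calls report all grid positions above the track's 99th percentile
plus the per-scaffold argmax (first position on ties), the convention of
treating each contig's maximum as the likely sweep location.

## Outlier windows and candidate genes

Windowed F_ST tracks are first filtered (windows with <10 usable SNPs,
then scaffolds left with <4 windows). The elevated threshold is the
empirical 99.9th percentile (linear interpolation between order statistics)
of the remaining window values, inclusive (≥), so the defining order
statistic is itself elevated. A gene is hit by a comparison if its interval
intersects any elevated window expanded by 50 kb on both sides (half-open
intersection). The shared table lists genes hit in ≥2 between-size
comparisons; final candidates are genes hit in *all* between-size
comparisons and *no* control comparison, with control overlaps reported
separately. Candidate SNPs are the retained variants lying strictly within
candidate gene intervals (no margin).

## Validation stage

Subspecies-level non-reference allele frequencies at candidate SNPs are
computed over called alleles within each subspecies. Pearson correlations
of each SNP's frequency vector against subspecies mean mass and mean
winter/summer temperature use subspecies-level points — matching the
(1, k−2) regression degrees of freedom such studies report — and the focal
set is the SNPs with signed r > 0.90 (the positive orientation encodes
"non-reference allele tracks larger mass"). Simple OLS regressions (via
statsmodels) report slope, intercept, 95% CI, R², F, p, leverage and
Cook's distance per subspecies point.

The partial Mantel test uses the textbook partial correlation of
lower-triangle entries, r_AB·C = (r_AB − r_AC·r_BC)/√((1−r_AC²)(1−r_BC²)),
with a one-tailed null built by jointly permuting rows and columns of the
genetic matrix and p = (1 + #{perm ≥ obs})/(1 + n_perm) (9999 permutations
by default, seeded). The three matrices are the package's own definition
where the convention is open: Euclidean distance between subspecies
allele-frequency vectors on the candidate contigs, absolute difference in
mean mass, and Euclidean distance on coordinates. The observed statistic
is cross-checked against R vegan's `mantel.partial` in the test suite.

Focal regions add up to 3 retained SNPs on each side of a focal SNP,
truncated at scaffold ends and adjacent focal SNPs. Ward clustering of
individuals at the focal-region SNPs runs on pairwise-complete Euclidean
dosage distances scaled by √(total sites / shared sites) to correct for
missingness, agglomerated by the Lance–Williams Ward update
(scipy.cluster.hierarchy), and is exported as Newick with branch lengths
from merge heights plus a per-sample two-allele genotype table for heatmap
rendering. Clustering entities are individuals: the validation narrative
describes clusters of individuals grouped by size class, and a tree over
8 SNPs would not expose that structure.

## Structure and QC

Genotype PCA uses the binomial (unit-variance) scaling: centre by 2p̂,
scale by √(2p̂(1−p̂)), mean-impute missing entries after centring, and
eigendecompose via SVD; variance fractions are eigenvalue shares in
percent. LD pruning slides a 50-SNP window in 10-SNP steps and greedily
drops the later SNP of any pair with pairwise-complete r² above the
threshold (default 0.1), deterministically left to right. Relatedness is
the standardized genotype covariance, mean over usable sites of
(g_i−2p)(g_j−2p)/(2p(1−p)) with pooled p; it is ≈1 for duplicates, ≈0.5
for first-degree pairs, ≈0 for unrelated pairs, and carries an O(1/m)
downward bias from estimating p in-sample, so it is a cohort-scale
screening statistic (the tests exercise it at m ≈ 80–100). Pairs at or
above 0.5 are flagged but never removed — downstream analyses keep the
full cohort.

## Synthetic data: what it emulates

The generator produces the full input bundle (VCF, BED, metadata TSV) plus
a machine-readable truth table. Its default configuration is the package's
reference study condition set:

- **Cohort**: nine subspecies — two large-bodied (~45–47 g) and two
  smaller-bodied (~26–28 g) discovery panels, five small (~18–21 g)
  validation panels — 6–12 diploid individuals each, with winter and
  summer temperatures strongly negatively related to mass across panels.
- **Neutral divergence**: Balding–Nichols per subspecies — allele
  frequency ~ Beta(p0(1−F)/F, (1−p0)(1−F)/F) around an ancestral
  p0 ~ U(0.05, 0.95). F is per-subspecies (defaults 0.10–0.12 for the
  large island panels, 0.04–0.06 elsewhere), reflecting the strongly
  heterogeneous pairwise divergence such cohorts show: within-size
  control pairs are far less differentiated than between-size pairs.
- **Planted genes**: five 30-kb genes, each inside a single 50-kb window
  on the first three scaffolds, with 45 decoy genes elsewhere. Every SNP
  in a planted gene is causal: its subspecies frequency is the
  deterministic logistic track inv-logit(logit(p0) + β·z_mass) with β = 3
  and the subspecies mass z-score, so the non-reference allele rises with
  mass. Causal p0 is drawn from the mid-range U(0.3, 0.5), where the
  logistic link yields population-level freq–mass correlations ≈ 0.99 —
  the regime in which an r > 0.90 selection rule is expected to recover
  essentially all causal SNPs.
- **Sweeps**: two 80-kb regions on gene-free scaffolds where, within the
  large-bodied subspecies, each site's frequency is pushed to 1/(2n) or
  1−1/(2n) (keeping its direction) with probability 0.9 — a hard-sweep
  SFS skew plus diversity loss.
- **Genome**: 24 scaffolds × 20 Mb (≈9600 50-kb windows) at SNP density
  4e-4/bp (≈190k SNPs, ~19 per window), genic density 1.4e-3. The window
  count matters: a 99.9th-percentile outlier rule can only place every
  planted window above threshold if the number of retained windows is
  large relative to 1000 × (planted windows); the density keeps nearly
  all windows above the 10-SNP analysis filter.
- **Missingness**: genotype calls dropped uniformly at 10% (within the
  10–20% band modern resequencing panels show); at this rate almost no
  site exceeds the 20% per-site missingness filter, so filtering does not
  silently delete planted signal.
- **Genotypes**: Binomial(2, freq) per individual; per-site mean depth
  ~ Gamma with mean 7×.

What it does **not** emulate: linkage disequilibrium between neutral sites
(sites are independent given subspecies frequencies), mutation-model
realism (random ref/alt bases), genotyping error structure correlated with
depth, admixture or gene flow between panels, and within-subspecies
geographic structure. Passing tests therefore demonstrate estimator
correctness and pipeline recovery under the assumed frequency model — not
robustness to LD, batch effects or call-rate artefacts in real data.

A separate single-population neutral coalescent simulator (exponential
coalescence times at rate C(k,2), Poisson(θ/2 × branch length) infinite-
sites mutations) serves as the calibration oracle for the diversity,
Tajima and SFS estimators; it is cross-checked against msprime in the test
suite. The sweep-scaffold helper simulates one population (25 diploids,
1 Mb, 2000 SNPs by default) with uniform site frequencies and the same
frequency-push sweep distortion, for CLR power and localization studies.

## Reference problem sizes

The acceptance-level checks run at: Balding–Nichols recovery with 2×50
individuals and 20k SNPs (plus 5k-SNP runs over F ∈ {0.05, 0.1, 0.2,
0.4}); 1000 coalescent replicates (n = 20, θ = 10) for Watterson/pairwise
calibration, 800 windows for Tajima's D and ~2100 pooled low-θ sites for
the 1/k spectrum check; 50 paired sweep/neutral scans (1 Mb, 2000 SNPs,
evaluation grid 2 kb — localization tolerance is 50 kb, so the default
200-bp grid adds nothing at this scale); the full nine-subspecies fixture
end to end; 20 mass-shuffle replicates; and 1000 null partial Mantel
simulations at 199 permutations. The null permutation scheme for the
shuffle check permutes individual mass labels.

## Known limitations

- Tajima's D with heavy missingness uses nominal-n constants
  (approximation documented above).
- The CLR scan treats distance physically (bp); no recombination map or
  background-selection correction.
- The relatedness estimator's small-cohort bias (O(1/m)) is not corrected;
  it screens, it does not estimate pedigrees.
- The elevated-window threshold is computed after the scaffold/window
  filter; tracks filtered differently will shift thresholds slightly.
- Windowed F_ST sampling noise at ≲15 usable SNPs per window produces a
  long upper tail under strong drift; outlier calling at the 99.9th
  percentile is only as sharp as the window SNP counts allow.
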