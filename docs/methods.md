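# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the design decisions behind
`svrgwas`, in the spirit of a package's model documentation. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Phenotype model and preparation

Field trials are assumed to be randomized complete block designs grown
in several environments, one plot per genotype × environment × block on
a (row, column) grid.

**Spatial adjustment (Papadakis NNA).** Per environment, each plot's
residual from its block mean is regressed on the mean residual of its
rook neighbours (±`radius` plots along the row and along the column,
default radius 1); the fitted component is subtracted from the raw
value. Plots with no neighbours are returned unchanged; an environment
in which every plot shares one coordinate is an error (there is no
spatial information to use). This first-order Papadakis variant removes
smooth fertility trends and part of serially correlated row noise; it
does not model anisotropy or fit a full spatial covariance (use a
dedicated spatial package if that is needed).

**Outliers.** Plots whose standardized residual from env-block means
exceeds `z_cut` (default 3.5) in absolute value are set to missing.
Under clean Gaussian data this flags ≲0.05% of plots. The cut is a
convention; protocols differ in the literature and the exact rule used
by any given study is rarely printed.

**Mixed model.** REML via `statsmodels` MixedLM:

    value ~ env + block(env)            (fixed)
          + genotype + genotype:env     (random, iid)

Environment enters as a fixed effect even though a strict reading of
the plot model `Y = μ + Ax + Bz + Ci + ε` contains only block, genotype
and GxE terms: with trials laid out as an RCBD per environment, block
contrasts are only meaningful within an environment, so blocks are
nested in environments and the environment main effect must be in the
design. With a single environment the GxE term is dropped (it would be
confounded with genotype).

Outputs: genotype BLUPs (fixed-effect grand mean + shrunken genotype
effect), variance components (floored at zero), and plot-basis
heritability **H² = σ²G/(σ²G + σ²E)** — deliberately *not* divided by
the number of replicates and *not* including σ²GxE in the denominator,
matching the plot-basis definition; an entry-mean variant
(`entry_mean_h2=True`) divides σ²E by the mean replicate count.
Non-convergence raises an error naming the trait rather than returning
a half-fitted model.

## Genotype QC

Dosages are 0/1/2 copies of the alternate allele, −1 for missing
(written as `./.` in VCF, `NN` in HapMap). Filters, in attribution
order missing → MAF → heterozygosity:

* samples with missing fraction > 0.5 (configurable; panels genotyped
  by GBS routinely lose ~10% of samples this way),
* SNPs with missing fraction > 0.5,
* SNPs with MAF < 0.05 (computed on non-missing calls),
* SNPs with > 50% heterozygous calls (het = fraction of non-missing
  calls equal to dosage 1; an excess indicates paralogy or calling
  artifacts in a selfing species).

**Markov imputation.** Missing calls are drawn from the empirical
conditional distribution of dosage_j given dosage_{j−1}, estimated from
samples observed at both SNPs, sweeping each chromosome left to right;
the leftmost SNP (or an empty conditional cell) falls back to the SNP's
observed marginal. The imputer is single-pass and deliberately simple —
it exploits adjacent-marker LD, not haplotype phasing; a SNP with zero
observed calls is an error (filter first). Observed entries are never
altered, and a seed makes the draws reproducible.

**LD.** Pairwise R² is the squared Pearson correlation of dosages over
pairwise-complete samples (undefined, and an error, for a monomorphic
SNP). `ld_decay` bins intra-chromosome pairs by distance and reports
the half-initial decay distance: the interpolated distance at which the
binned mean R² falls to half the first bin's mean. When the curve never
crosses that level — e.g. simulated data with no LD, where the curve is
flat at the ~1/n background — the distance is reported as NaN
(censored) rather than a fabricated number.

## Population structure

Kinship is VanRaden method 1, `K = ZZ' / (2 Σ p_j(1−p_j))` with Z the
allele-frequency-centred dosages; the precise kinship family rarely
changes GWAS cofactor behaviour, and this is the default of the common
GWAS packages. Structure covariates are the top k−1 principal
components of centred dosages (k defaults to 7 subpopulations), each
mean-centred, with signs fixed by the largest loading so results do not
depend on sample order. An externally computed admixture Q matrix can
be imported instead (rows matched by sample ID, row sums validated
≈ 1, last column dropped against collinearity): in the GWAS the
covariates only absorb stratification, so PCs are an adequate stand-in
for a model-based ancestry estimate.

## FarmCPU

Implemented from scratch:

* **FEM.** For each SNP, OLS of the phenotype on [intercept, structure
  covariates, pseudo-QTN dosages, SNP dosage]; p-value from the t
  statistic of the SNP coefficient. The scan is vectorized by
  projecting all SNPs onto the orthogonal complement of the base design
  once per iteration; only SNPs within one bin of a pseudo-QTN need an
  individual refit. *Substitution rule:* pseudo-QTNs within `bin_size`
  of the tested SNP — including the tested SNP itself — leave the
  covariate set, so a pseudo-QTN is re-tested rather than tested
  against itself. A SNP identical to a still-included pseudo-QTN gets
  p = 1 by convention; a singular design yields p = NaN (excluded from
  FDR ranking, never significant).
* **REM.** Candidate pseudo-QTNs are the per-(chromosome, bin) lowest-p
  SNPs with p ≤ 0.01 (`qtn_p_threshold`); for each cell of the grid
  bin sizes {0.5, 5, 50} Mb × QTN counts {5, 10, 15}, a VanRaden-style
  kinship over the selected SNPs defines `y = μ + u + e`, fitted by
  single-component REML on the eigenbasis of K (variance ratio profiled
  by bounded scalar minimization, tolerance 1e−6 on log λ). The best
  restricted likelihood picks the set. Fewer candidate bins than the
  requested count shrinks the count with a warning.
* **Circulation.** Iteration 1 is the plain covariate-adjusted scan;
  circulation only starts if its minimum p-value reaches `p_threshold`
  (default 0.01/m, the Bonferroni-style gate of the reference
  implementations) — without the gate, a pure-null panel recruits
  noise SNPs as covariates and the FDR guarantee degrades. The loop
  stops when a pseudo-QTN set repeats (cycle detection over all past
  sets) or at `max_iterations` (default 10; the result then carries
  `converged=False`).
* **Significance.** Benjamini–Hochberg step-up at q = 0.05 over the
  final scan's non-NaN p-values.

## SVR-mediated GWAS

An ε-SVR (`scikit-learn`, default linear kernel, C = 1, ε = 0.1 —
hyperparameters are exposed in `SvrConfig` since published uses rarely
report them) is fitted on column-standardized dosages. Importance is
|w_j| with `w = Σ_i α_i x_i` from the dual solution; for the optional
rbf kernel the analogue is the RMS of the kernel-gradient ∂f/∂x_j over
training points. The reported raw importance is the mean over a
5-fold × 10-repetition cross-validation with seeded fold assignment;
zero-variance SNPs get importance 0 with a warning. Scores are min–max
scaled to [0, 100] (an all-equal vector scales to all zeros).

**Global empirical threshold.** The phenotype is permuted
`n_permutations` times (default 1000; the calibration and power
analyses in the test suite and acceptance script use 200 to keep their
many replicates tractable), the importance recomputed, and the maximum
over SNPs recorded; the threshold is the (1 − α) empirical quantile
(`numpy` "higher" method, so α = 1 returns the minimum) of those
maxima. Two calibration choices matter:

* *Null maxima are maxima of the same statistic.* Each permutation runs
  one CV repetition (`perm_cv_repeats=1`, n_folds fits) rather than a
  single full-data fit: a single fit's maximum over thousands of SNPs
  is stochastically larger than a CV-averaged maximum, and measuring
  both under the null showed the single-fit scheme pushes the threshold
  above every observed score — family-wise error collapses to zero and
  so does power. `perm_cv_repeats=0` restores the cheaper single-fit
  economy; `perm_cv_repeats=n_repeats` the full observed scheme.
* *One scale for both sides.* Null maxima stay on the raw scale and the
  threshold is mapped through the ORIGINAL min–max scaling; rescaling
  within each permutation would force every null maximum to 100.

α defaults to 0.05. (One published description of this threshold prints
α = 0.5; the parameter is configurable and nothing in the code asserts
either value as the intended one.) A permutation fit reuses a
precomputed linear Gram matrix, which makes the ~10³ fits per scan
cheap.

## Regions and co-localization

Coordinates are 0-based half-open internally; VCF/HapMap positions
(1-based) are converted on ingest and BED conventions on output.
Significant SNPs more than `cluster_window_bp` apart start new
clusters; each cluster's best-statistic SNP (ties → lower position) is
its peak; regions are peak ± 150 kb clipped at zero, and overlapping
same-chromosome regions are merged (members unioned, best peak kept) so
downstream QTL lookup is deterministic. The 150 kb default matches an
LD-decay-distance-sized window and can be replaced by the measured
half-decay distance. Co-localization reports every (region, annotation)
pair with ≥ 1 bp overlap; allelic effects are the OLS slope of the
phenotype on dosage plus per-dosage-class means.

## Synthetic data

The generator reproduces the structure the pipeline assumes, with
defaults chosen once to mirror a soybean association panel: 227
genotypes, 2,000 SNPs on 20 chromosomes of 50 Mb (2,000 keeps the test
suite fast; the marker density, not the count, is what the methods see),
MAF ∈ [0.05, 0.5], K = 7 subpopulations at FST = 0.1, four
environments × two blocks, trait mean 40 with H² = 0.69.

* **Genotypes.** Ancestral allele frequencies are uniform on the MAF
  range; subpopulation frequencies drift by the Balding–Nichols Beta
  model at the configured FST. Along each chromosome, each haplotype
  allele copies the previous SNP's allele with probability `ld_rho`
  (default 0.8) and is otherwise drawn fresh — a first-order copy chain
  whose haplotype correlation at marker lag d is ρ^d, i.e. mean R² of
  ρ^(2d), giving an analytically checkable geometric LD decay. This is
  a deliberate trade of coalescent realism for a closed form: LD decays
  per *marker*, so with sparse markers it extends further in bp than in
  a real panel, and recombination hot/cold spots, selection, dominance
  and epistasis are absent. Consequences: significant SNPs megabases
  from a planted QTL can be genuine LD tags, so the benchmark's
  "false positives within > 150 kb" column overstates noise discoveries.
* **Phenotypes.** Genetic values are additive over `n_qtl` planted QTL
  with N(0, `qtl_effect_sd`²) effects; optionally the planted QTL carry
  only `qtl_var_fraction` of the genetic variance, the rest spread over
  `n_background` (default 100) small-effect SNPs — this is how the
  power analyses make the planted loci realistically partial. The
  residual variance is set from the realized genetic variance so that
  σ²G/(σ²G + σ²E) equals `h2_target` *exactly in the generating model*.
  GxE is iid normal per genotype × environment with σ²GxE = 0.25·σ²G,
  and block effects have sd 0.5 — magnitudes are conventions, since
  field studies rarely publish them. The spatial field per environment
  is a random quadratic surface plus AR(1, φ = 0.7) row noise scaled to
  `spatial_sd` (default 0.3 trait units, ≈ 30–40% of the residual sd —
  a visible but not dominant trend); it is exactly the kind of signal
  Papadakis adjustment is meant to remove, and the part it does not
  remove is why recovered H² sits slightly below the generating value.
* **Missingness** is injected completely at random at `missing_rate`;
  the Markov imputer's conditional tables are estimated from what
  remains.

Everything is reproducible from a single integer seed. What passing
tests on these panels do *not* show: behaviour under informative
missingness, genotyping error, non-Gaussian trait distributions, or
real-genome LD; the generator is a harness for the statistics, not a
population-genetic simulator.

## Numerical choices and edge cases

* REML (both MixedLM and the eigen-based REM fitter) floors variance
  components at zero; the REM profile is optimized on log λ ∈ [−12, 12].
* The FEM fast path declares a projected SNP collinear when its
  residual sum of squares falls below 1e−9 of its raw scale; p-values
  are floored at the smallest positive float to keep −log10 finite.
* BH excludes NaN p-values from ranking; an empty p-value vector is an
  error, an all-NaN vector yields an empty significant set.
* Min–max scaling of an all-equal importance vector returns zeros with
  a warning instead of 0/0.
* Interval merging treats regions as closed on both ends for the merge
  test (`start ≤ prev.end`), so windows sharing a single bp merge.
* The pipeline manifest records the seed and a SHA-256 fingerprint of
  the configuration (output directory excluded); reruns with one seed
  are byte-identical across all result files (the manifest itself
  carries wall-clock runtime).

## Problem sizes used by the checks

The test suite and acceptance script simulate at 100–250 genotypes ×
300–2,000 SNPs with 15–200 replicates per property, and the SVR
permutation count in replicated analyses is 200; these sizes were
chosen as the smallest at which the Monte-Carlo bands around each
property are tight enough to be meaningful.

## Known limitations

* The Markov imputer ignores genotype likelihoods and phase.
* FarmCPU's grid is the conventional one; no data-driven bin-size
  adaptation beyond the REML grid search.
* The rbf-kernel importance is a sensitivity heuristic, not the Weston
  weight bound, and is quadratic in sample count.
* `fit_blup` assumes one residual variance across environments.
* Co-localization requires a user-supplied annotation file; no
  database retrieval is attempted.
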