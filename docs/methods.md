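# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the validation studies behind `envgxe`.

## The analysis problem

A national trial panel of vegetatively propagated (clonal) autotetraploid
varieties is observed for plot yield across locations and years, with SNP
dosages coded 0–4. Each clone originated in one breeding program and spent
roughly three field seasons under selection at that program's home site
before entering the trial. Three questions are asked of such a panel:

1. How much of the genetic variance for yield is GxE (`pheno`)?
2. Did early selection enrich alleles associated with the home
   environment (`gwas` + `pipeline`, envGWAS)?
3. Which loci modulate yield response to measured environmental gradients
   (`norms` + regression GWAS), and are any of these rising in frequency
   over trial years (GPSM)?

## Yield model and variance decomposition

Plot yield (kg) follows

    γ = μ + Y + L + YL + g + gY + gL + gYL + ε

with year, location and year-by-location fixed and the four genetic terms
random and independent. The fixed part is equivalent to one mean per
(location, year) trial, so the fixed design used internally is the trial
indicator matrix. Estimation is REML:

- Replicate plots within a (clone, location, year) cell are collapsed to
  cell means. Within-cell contrasts are pure-error contrasts; they enter
  the restricted likelihood in closed form as
  `(N − C)·log σ²_e + SSW/σ²_e`, while the C cell means carry the genetic
  structure with covariance
  `σ²_g A_g + σ²_gY A_gY + σ²_gL A_gL + σ²_gYL I + σ²_e diag(1/r)`.
  This is an exact reformulation, not an approximation.
- Components are parametrized as ratios to σ²_e; σ²_e profiles out
  analytically. The 4-dimensional criterion is minimized by L-BFGS-B with
  analytic gradients and a lower bound of zero, so negative proposals are
  projected to the boundary and reported components are never negative.
- Fully balanced layouts (every clone in every trial with equal
  replication) dispatch to a Kronecker form — the cell covariance is
  I_clones ⊗ B with B only trials × trials — reducing each likelihood
  evaluation from O(C³) to O(C·t²). The optimum is identical; the test
  suite checks the two paths against each other and against an
  independent dense record-level likelihood.
- Identifiability: σ²_gYL separates from σ²_e only when some cells have
  replicate plots. With one plot per cell the fitter warns and the gYL
  estimate absorbs both terms.

Genetic proportions are reported as σ²_x / (σ²_g+σ²_gY+σ²_gL+σ²_gYL) × 100
(the denominator excludes ε); shares of total phenotypic variance are
reported alongside.

Yield records are filtered to strictly positive values before any
analysis. Normalization for the reaction-norm stage divides each plot
yield by its trial mean and takes the natural log, giving relative
performance centred on zero within every trial; trials with a single
record are excluded (no within-trial contrast exists).

## Mixed-model association engine

All scans share one machinery:

- **MAF filter**: allele frequency is mean dosage / 4; markers with folded
  frequency below 0.01 (default) are removed.
- **Kinship**: K = ZZ′/c from marker-centred dosages, c chosen so the mean
  diagonal is exactly 1.
- **Null model**: y = Xβ + u + ε with Cov(u) = σ²_poly K. REML over the
  single variance ratio λ = σ²_poly/σ²_e by bounded 1-D optimization on
  log λ, using the eigendecomposition of K. The rotation is cached.
- **Marker tests (P3D)**: with λ fixed, each marker test is weighted least
  squares in the rotated basis. The residual scale is re-estimated per
  marker and the Wald statistic referred to a t distribution with
  n − p − 1 df; in the K = I limit this is exactly the textbook OLS
  t-test. Markers monomorphic on the tested clones are flagged with p = 1.
  LOD = −log10(p).
- **Covariates**: none by default — kinship absorbs relatedness, and
  adding principal components is optional (`n_pcs`) for panels with
  overt stratification.
- **Genome-wide threshold**: the effective number of tests M_eff is
  computed from eigenvalues of the marker correlation matrix per
  chromosome and summed; threshold LOD = −log10(α/M_eff), ties counted as
  significant. The default estimator is Galwey's (Σ√λ)²/Σλ. The Li–Ji
  count I(λ≥1)+(λ−⌊λ⌋) is available but not default: its jump at integer
  λ makes a duplicated marker whose sample eigenvalue lands just below 2
  count as ~2 tests, so it fails the basic requirement that perfect LD
  collapses to one effective test; Galwey's form is continuous and exactly
  duplication-invariant, and the two agree closely otherwise (1681 vs 1733
  on 2,000 independent markers × 300 clones). Bonferroni (M_eff = M) is
  also available.
- **PVE by backward elimination**: all significant markers enter one
  whitened fixed-effects model; a marker's PVE is the drop in model R²
  when it alone is removed (×100). Collinear sets are pruned greedily,
  dropping the member with the smaller marginal effect. Report tables
  print the per-trait cumulative PVE as the 1-dp-rounded sum of per-marker
  PVEs (the additivity convention of published marker tables); the joint
  R² is carried separately.

### envGWAS specifics

The reverse regression treats the environmental descriptor as the
response and dosage as the regressor; this is valid because dosages are
essentially error-free while the environment is noisy. Case–control
program scans use a 0/1 response in the same linear machinery (first-order
approximation to the logistic model); only programs contributing at least
⌈0.10 × panel⌉ clones are scanned, which reproduces a cutoff of 84 on a
panel of 840. Latitude and longitude run as two separate univariate
responses. Latitude effects convert to distance at 111 km per degree;
longitude conversion is refused because a degree of longitude shrinks with
latitude.

### Reaction norms

Per clone, OLS of normalized log yield on the trial's growing-season value
of one variable; clones with fewer than 3 (default) distinct environmental
values, or zero environmental variance, are excluded with a reason. 95%
CIs use the t distribution with n − 2 df. Because per-clone slopes are
noisy, `slope_summary` reports the fraction of CIs containing zero — in
realistic designs most do, which is why the regression GWAS treats slope
error as response measurement error (reducing power, not inflating false
positives). Per-genotype OLS is equivalent to a joint model with
genotype-specific slopes when the design is balanced.

### Cross-analysis overlap

Significant-marker pairs from two analyses are matched on the same
chromosome (string comparison) within a base-pair window, inclusive at
both ends; positions are 1-based. Default windows: 1, 2, 5 Mb.

## Synthetic-trial generator

The generator emulates a US national chip-trial panel; its defaults are
the package's study conditions.

- **Sites**: 13 default sites with the real trial/selection-network
  coordinates; daily climate parameters derive from coordinates (warmer
  south, wetter east) with a seasonal temperature cycle (amplitude 8 °C,
  part of the climate parameters — setting it and the daily SDs to zero
  yields a flat series). Growing-season windows are unknown for the real
  programs; the default is day-of-year 135–258 for all sites and is
  configurable per site.
- **Genotypes**: dosages are Binomial(4, p) per marker and clone
  (autotetraploid HWE, independent markers). Base frequencies draw from a
  scaled Beta(0.75, 0.75) on [0.05, 0.95]. An environmental-cline QTL
  shifts its per-program frequency linearly in the standardized program
  covariate, clipped to [0.005, 0.995]. Default panel 300 clones × 3,000
  markers × 12 chromosomes (about 1/5 of the real panel so tests run in
  minutes); studies scale up as stated below.
- **Weather**: Gaussian daily temperatures around the seasonal cycle
  (tmin clipped to tmax), zero-inflated exponential precipitation in cm,
  optional masking of a fraction of days to exercise fallback imputation.
- **Yields**: the additive model above, in kg, with configurable fixed
  effects giving several-fold differences between trial means. A floor at
  1% of the trial mean guarantees positivity for the log step; floored
  records are flagged. A planted reaction-norm QTL can act on two scales:
  `raw` adds dosage·β·E kg (the literal additive model), `log` multiplies
  yield by exp(dosage·β·(E − Ē)) so that β is exactly the slope on the
  normalized log scale that the analysis estimates. Power studies use the
  log scale; the raw scale is kept for the additive-model unit checks.
- **Submission years**: uniform over 2010–2022 (configurable). A GPSM QTL
  resamples its dosages from Binomial(4, p₀ + Δ·(year − year₀)), clipped
  with a warning; other markers carry no trend.
- Identical seed and configuration reproduce all outputs byte for byte.

What the generator does **not** emulate: linkage disequilibrium between
markers (markers are independent), pedigree structure between clones
within or across programs, the multi-year phenotypic selection funnel
itself (the cline is its stand-in outcome), spatial field trends, and
heterogeneous error variances across trials. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to LD-confounding or family structure in real panels.

## Validation studies (`envgxe.validation`)

Problem sizes are the package's chosen study conditions:

- **Oracle agreement**: on an 18-clone panel the P3D scan is compared
  marker-by-marker with a dense-inverse GLS; max |Δp| is ~1e-15.
- **Null calibration**: 200 panels of 300 clones × 2,000 markers with a
  heritable (h² = 0.5) polygenic response and no QTL; family-wise error at
  the M_eff-adjusted 5% threshold and KS uniformity of marker p-values.
- **Power / recovery**: environmental cline 0.15 at 500 clones (response:
  weather-derived 3-year minTemp averages; oracle effect
  cov(E, d)/var(d) from the generator's frequencies); reaction-norm QTL
  β = 0.05 at 500 clones across 8 trials spanning 10 °C with two replicate
  plots; GPSM trend 0.02/yr at 800 clones over 2010–2022. 50 replicates
  each.
- **Transience**: strong env-cline and GPSM QTL planted on different
  chromosomes (400 clones, 30 replicates); the 1-Mb overlap of the two
  significant sets should be empty in nearly all replicates.
- **Variance-component recovery**: 500 clones × 16 trials (4 locations ×
  4 years) × 2 replicates — 16 trials rather than the minimal 8 because
  the spurious absorption of variance by the zero components shrinks with
  the number of trials per clone; recovery of a 1:1 g:gYL mix and of a
  GxE-dominated mix (g 27.6 / gY 5.6 / gL 22.7 / gYL 34.1% of genetic
  variance) is checked to ±5 points.

## Known limitations

- Additive gene action only (dosage 0–4 enters linearly); no dominance or
  general tetraploid gene-action scans.
- No multi-QTL model selection; PVE conditions only on the significant
  set.
- Reaction norms are linear by construction; curvature in real
  yield–environment relationships is not modelled.
- The case–control linear approximation can inflate PVE for rare
  programs (small effective case counts).
- Missing dosages are not imputed (mean-fill with a logged count is the
  only handling); array-version imputation is out of scope.
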