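# Methods

This note records the statistical models, the default parameters, the
numerical choices and the known limitations of each pipeline stage.
Everything stated here is computed by the code in `src/ionogwas/` and
exercised by the test suite; no empirical claims beyond that are made.

## 1. Synthetic data generator (`ionogwas.sim`)

**Genotypes.** Ancestral ALT-allele frequencies for `K_ancestral`
source populations follow the Balding–Nichols construction: marker
base frequency `p0 ~ Uniform(0.1, 0.9)`, population frequency
`f_kj ~ Beta(p0 (1-F)/F, (1-p0)(1-F)/F)` with divergence
`F = allele_freq_divergence` (default 0.2).  Admixture proportions are
Dirichlet with concentration 0.3 (default), giving mostly-assigned
individuals with some gradients.  Each individual draws two alleles at
its mixed frequency `p_ij = Σ_k q_ik f_kj`; a heterozygous draw is
collapsed to a random homozygote with probability `1 − het_retention`
(default retention 0.05), the fair-coin collapse preserving the
marginal allele frequency — the limiting behavior of repeated selfing.
Missing calls are injected uniformly at `missing_rate`.  Dosages are
stored as int8 with −1 as the missing sentinel; markers are sorted by
(chromosome, position) with chromosome as an ordered categorical.

**Trial.** The default design is 2 years × 4 replicates × 10
sub-blocks × 16 plots with every genotype planted once per replicate
at a randomized plot.  For each trait the genotype-level genetic value
is `u = L z` with `L` the Cholesky factor of the realized (VanRaden)
kinship; the column is standardized so the *realized* genetic variance
equals the requested `σ²_g` (without standardization the near-inbred
diagonal of K, ≈ 2, would inflate it).  Planted QTLs are specified by
marker index and either a fixed effect size or a variance fraction; in
the latter case the effect is solved from
`β² Var(x) = vf (σ²_g + σ²_e) / (1 − Σ vf)`.  Flowering time is a
separate polygenic trait (mean 70, SD 5) that can leak into ion traits
through per-trait slopes, and trait residuals can be drawn with an
arbitrary correlation matrix.  Year, replicate and sub-block effects
are independent normals with configurable SDs.

**Scope.** The generator reproduces the *structure* of a two-season
ionomics trial at desk scale (default 150 genotypes × 5000 markers
versus hundreds of thousands in a real panel).  It does not model
linkage disequilibrium decay along the chromosome (markers are
exchangeable within a population-structure stratum), genotype×year
interaction beyond the additive year effect, spatial field trends, or
assay-specific measurement error; LD-dependent behavior (pruning,
block building) is therefore tested on hand-constructed correlated
toys as well.

## 2. Genotype QC (`ionogwas.genotypes`)

Filters, applied in pipeline order: markers with missingness ≥ 50% or
MAF < 5% are removed; samples with call rate < 80% are removed; after
imputation, markers whose *pre-imputation* heterozygote frequency
exceeds 0.12 are removed (a guard against paralogous mis-mapping in a
selfing crop; an empirical 95th-percentile mode is available).  All
filters are idempotent.  VCF input is restricted to biallelic SNPs
(others are counted and skipped); the writer emits minimal VCFv4.2
text.

## 3. Ancestry and imputation (`ionogwas.ancestry`)

The sNMF-style model factorizes `X = G/2 ≈ Q F` with `Q` rows on the
probability simplex and `F ∈ [0,1]`.  Fitting uses block projected
gradient with exact `1/L` step sizes (L from the spectral norm of the
fixed block's Gram matrix) and an EM-style fill of unobserved entries,
which makes the masked training loss monotonically non-increasing —
this is the monotone variant of alternating nonnegative least squares
with simplex projection.  `K` is selected by masked cross-entropy
(binomial deviance on a 5% random holdout of observed entries) over
`K = 1..10` with 10 random restarts by default.

Imputation fills a missing call with the most probable genotype class
under inbreeding-adjusted probabilities
`P(0) = (1−p)² + f p (1−p)`, `P(1) = 2 p (1−p)(1−f)`,
`P(2) = p² + f p (1−p)` where `p = Σ_k q_ik f_kj` and `f` is the
panel-wide inbreeding coefficient estimated from the heterozygote
deficit.  Plain rounding of `2p` to the nearest class
(`mode="round"`) systematically over-predicts heterozygotes on a
selfing panel and is kept only as an explicit option.

## 4. Trait model (`ionogwas.phenotypes`)

Per trait-year, plots are screened by an iterative standardized
residual rule (`|r| > Φ⁻¹(1 − α/2n)`), genotypes seen fewer than twice
are dropped, and BLUEs are the genotype marginal means of
`Trait = rep + rep:subblock + genotype`, computed through the
Moore–Penrose inverse of the normal equations and averaged over the
observed (replicate, sub-block) cells; genotype contrasts are estimable
under a connected design and independent of the generalized inverse
chosen.  The test suite checks the means against an independent
statsmodels fit to 1e-8.

Variance components refit genotype as random: after rotating onto an
orthonormal basis of the fixed-effect null space, the single ratio
`γ = σ²_g/σ²_e` is profiled out of the REML likelihood via the
eigendecomposition of the projected genotype covariance, leaving a
bounded one-dimensional minimization (log-scale, ±12).  Generalized
heritability uses the Cullis form
`H² = 1 − v̄_BLUP / (2 σ²_g)` with the mean pairwise BLUP
prediction-error variance from the full mixed-model equations.  At low
heritability the REML estimate of `σ²_g` is boundary-censored at 0, so
the sampling distribution of H² is left-skewed and its mean sits
slightly below the design value (≈ 0.22–0.24 at a 0.3 design point
with 100 genotypes); this is a property of the estimator, not a bug.

Normality is gated by Shapiro–Wilk at `0.05 / n_traits` (Bonferroni
over the trait family, default 17); failing vectors get a profile-ML
Box-Cox transform on a λ grid `[-2, 2]` in steps of 0.01, with an
automatic shift for non-positive values.

## 5. Association engines (`ionogwas.assoc`)

All engines test one marker at a time with a Wald t-test and mark
monomorphic markers untested.

* **EMMA-style** — `y = Xb + s g_j + u + e`, `u ~ N(0, σ²_g K)` with
  VanRaden kinship.  The variance ratio δ is REML-estimated on the
  null model through the eigendecomposition of K (coarse log-grid then
  Brent), and either reused for every marker (P3D/EMMAX mode, default)
  or re-estimated per marker (`mode="exact"`).  With `K = I` the scan
  reduces exactly to OLS.
* **LFMM-style** — OLS per marker with the top principal components of
  the centered dosage matrix as covariates; 0 factors is simple
  regression.
* **CMLM-style** — average-linkage clustering on the kinship distance
  `d_ij = K_ii + K_jj − 2K_ij` into `⌈√n⌉` groups (default); the
  compressed kinship replaces K in the EMMA-style scan.  `n_groups = n`
  recovers the uncompressed scan exactly.
* **BLINK-style** — iterative pseudo-QTN conditioning: each round runs
  a fixed-effect scan conditioned on the current pseudo-QTN set,
  builds an LD-filtered candidate pool (pairwise r² < 0.7, entry
  threshold Bonferroni 0.05/m — a loose entry cut lets the BIC forward
  search exploit max-of-m selection bias and plant pseudo-QTNs under
  the null), and re-selects the set by greedy BIC forward search (max
  10).  The current pseudo-QTNs seed the pool (they are collinear with
  the conditioned scan and would otherwise oscillate).  At the fixed
  point the final scan conditions each marker on the selected set
  minus the marker's own LD block (r² ≥ 0.7), so a selected causal
  marker still receives a p-value.

## 6. Aggregation (`ionogwas.aggregate`)

Per-scan significance thresholds are Benjamini–Hochberg at q = 0.05
computed on an LD-pruned independent marker set (sliding windows of 50
markers, step 5, removal at r² > 0.5, per chromosome) and applied to
all markers; with zero BH discoveries the threshold falls back to
`q/M` with M the independent-set size.  The BH threshold is the
largest passing order statistic and is applied inclusively
(`p ≤ p_(k)`), matching the rejection set of the standard procedure.
Seasons are combined per method with Fisher's statistic
`−2(ln p₁ + ln p₂) ~ χ²₄` (two p-values, hence 4 df).  A marker is a
consensus MTA when ≥ 2 engines flag it within one season and its
Fisher-combined p passes the combined-scale BH threshold for at least
one of the flagging engines; markers are tagged by supporting season
("2021"/"2022"/"all").  Consensus markers form QTL blocks as connected
components of the r² > 0.75 graph per trait and chromosome, padded by
25 kb (floored at 1) and named `<Ion>_<Cont|Res><chrom>-<ordinal>`.
The flowering-residual pass reruns everything on OLS residuals of
BLUE ~ flowering time (requiring ≥ 90% coverage) and cross-tags
overlapping content/residual blocks.

## 7. Reporting (`ionogwas.reporting`)

Candidate genes come from a GFF3 screen of the QTL window; genes
outside the window are reported with the signed distance from the top
marker to the nearest gene edge (upstream/downstream).  Allele-class
summaries use the most frequent class as reference and report percent
differences with a two-sided Wilcoxon rank-sum test (classes under 3
members are counted but untested).  The genomic inflation factor is
the median observed χ² over its null median.  Manhattan/QQ exports are
plain tables (cumulative coordinate, alternation index, expected vs
observed −log10 p) for any plotting frontend.

## Numerical and engineering choices

* Dense linear algebra throughout (panels here are ≤ thousands of
  markers per eigendecomposition); scans are vectorized across markers
  via QR residualization.
* All stochastic routines take explicit integer seeds and use
  `numpy.random.default_rng`; fixed-seed runs are byte-identical.
* scipy provides the distributions, hierarchical clustering and
  optimization primitives; cyvcf2/gffutils handle the standard
  formats; the REML profiles, the factorization, the Cullis H², the
  conditioning scan and the consensus machinery are implemented here.

## Limitations

* Single-marker models only; no epistasis, no multi-trait mixed
  models, no genotype×environment interaction terms beyond the
  per-season analyses.
* P3D reuses the null variance ratio per marker; for markers of very
  large effect the exact mode is the reference (the test suite bounds
  the difference on null panels).
* The compressed-kinship and pseudo-QTN engines inherit their known
  biases (group-boundary effects; greedy model selection) and are
  deliberately used only inside the multi-engine consensus.
* Without simulated LD decay, pruning on purely admixture-structured
  panels retains nearly all markers; consensus thresholds on such
  panels are correspondingly conservative.
* The BH/consensus chain controls the FDR per scan, not the
  family-wise probability of any false QTL block; on a fully null
  study about a quarter of seeds produce one (small) spurious block,
  consistent with q = 0.05 across eight correlated scans.
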