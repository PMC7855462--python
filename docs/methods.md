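# Methods

## Data model and adjustment

The pipeline targets an inbred (fully homozygous) diversity panel:
genotype calls are minor-allele counts in {0, 2}, with heterozygous calls
(1) accepted throughout for generality. Marker QC follows a fixed,
order-dependent chain: (1) remove every marker with a missing call in any
accession (accessions are never dropped), (2) remove markers with minor
allele frequency below 0.01 — a deliberately permissive threshold that
keeps rare alleles in the model, (3) prune near-duplicate markers: within
a 50-bp window on the same chromosome, scanning left to right, a marker is
removed when its allele counts have |Pearson r| ≥ 0.999 with any kept
marker to its left. Each step is idempotent. The pruning rule is stated in
terms of |r| of centered allele counts, so allele phase and the 0/2 versus
0/1 coding are irrelevant; the later marker by position is always the one
removed.

Replicate-level phenotypes are adjusted with the design model

    value = Genotype + x + y + image_position + sowing_block + error

with Genotype fixed (cell-means coding, so BLUEs stay on the observed
scale) and the four design factors as independent random intercepts. The
spatial coordinates are treated as categorical row/column factors, not
continuous trends. Variance components are estimated with the same AI-REML
core as the genomic models, using Z Z′ covariance structure per factor; a
factor with fewer than two levels at a timepoint is dropped with a
warning, and degenerate components are clamped at zero with a boundary
flag rather than silently removed. When the genotype means already fit the
data exactly (noise-free input) the GLS solution collapses to the plain
replicate means and is computed directly. Exclusion of timepoints by
coefficient of variation is study-specific and therefore exposed as a
caller decision, not a default filter.

## Relationship matrices

The GRM is G = W W′/m with w_i = (z_i − 2p_i)/√(2p_i(1−p_i)); allele
frequencies come from the full analyzed panel (training and test folds
together), matching the usual build-once-then-split GBLUP workflow.
Monomorphic markers are excluded before scaling (the scale factor would
divide by zero) and the error names the offending markers. For a feature,
G_f is built from the feature's marker columns and G_r from the
complement, each scaled by its own marker count, which gives the exact
identity m_f·G_f + m_r·G_r = m·G used as a structural test. Feature
markers lost in QC simply do not contribute; there is no re-mapping.

A consequence of the inbred 0/2 coding is that E[w²] = 4pq/(2pq) = 2, so
the GRM diagonal averages ~2 and the model-scale variance σ²g is about
half the genetic variance per accession. The reported heritabilities keep
the conventional formulas h² = σ²g/(σ²g + σ²e) and
h²_f = σ²f/(σ²f + σ²r + σ²e); for comparisons against a simulated
variance ratio var(g)/(var(g) + σ²e), `evaluation.observed_scale_h2`
rescales σ²g by the mean GRM diagonal so that like is compared with like.

## Mixed models and AI-REML

All models are y = Xβ + Σ_k u_k + ε with V = Σ_k σ²_k K_k + σ²e I and
intercept-only fixed effects (the design factors having been absorbed into
the BLUEs). The restricted likelihood is maximized by average-information
updates (score from the projection matrix P, AI matrix ½·y′PK_iPK_jPy),
with:

* **Starting values** — the phenotypic variance split equally across all
  components, each kinship's share divided by its mean diagonal.
* **Step control** — a proposed step that lowers the restricted likelihood
  is halved up to 10 times; if no AI step improves, a single EM-REML step
  (guaranteed ascent) is tried before declaring a stationary point. The
  accepted-step sequence therefore never decreases the likelihood.
* **Boundaries** — negative proposals are clamped to a floor of
  10⁻⁸ × var(y); a genetic component stuck at the floor for 3 consecutive
  iterations is fixed at exactly 0, flagged, and the remainder refit. At
  termination any component still at the floor is likewise reported as 0
  (it is statistically indistinguishable from it) and the solution
  recomputed without it. The residual may sit at the floor but is never
  zeroed, keeping V positive definite.
* **Convergence** — the largest parameter change relative to the
  phenotypic variance must fall below 10⁻⁵ on a full (unhalved) step;
  stopping because no direction improves the likelihood also counts as
  convergence (a boundary optimum). The iteration cap is 100.

Test-set genomic values are predicted conditional on training phenotypes:
ĝ_k(test) = σ²_k K_k[test, train] V_train⁻¹ (y_train − Xβ̂), summed over
components. On small instances this reproduces the ridge-regression
marker-effect formulation (effects W′(WW′ + λI)⁻¹(y − μ̂) with
λ = m σ²e/σ²g) to numerical precision, which the tests assert at 10⁻⁸.

Adaptive MultiBLUP tiles each chromosome with 10-kb windows stepping
half a window. Each window's markers are jointly tested against the
phenotype with an OLS F-test (centered markers versus intercept-only; the
simplest joint test with an exact small-sample null — the region-scanning
literature does not pin down one statistic, so this is a documented
choice). Windows with p < 10⁻⁵ seed regions; runs of adjacent or
overlapping significant windows are merged when the merged region's
Bonferroni-adjusted p (multiplier = number of windows tested genome-wide)
stays below 0.05, otherwise the windows stand alone. If no window is
significant the all-marker group is returned, making the model collapse to
GBLUP. Windows whose marker count exhausts the residual degrees of freedom
are reported as untestable (p = 1) rather than tested on zero degrees of
freedom.

## Evaluation

Cross-validation uses k = 8 folds repeated 10 times by default; fold
assignment is a seeded permutation, fold sizes differ by at most one, and
the identical split list is reused for every model compared. REML is refit
inside every training fold (predicting conditional on training phenotypes
requires training-fold variance estimates; reusing full-data components
would leak information). A fold whose training fit lands on a heritability
boundary (total h² within 10⁻³ of 0 or 1 — undetermined or over-estimated
genomic variance) is discarded and counted, so accuracies + discards
always equal folds × repeats.

Feature models are compared to the all-marker GBLUP benchmark at the same
timepoint by: the likelihood ratio LR = 2(ℓ_GFBLUP − ℓ_GBLUP) with
p = ½ P(χ²₁ > LR) (p = 1 at LR = 0), a two-sided Wilcoxon–Mann–Whitney
test on the accuracy samples (exact enumeration when both samples have
≤ 12 untied values, normal approximation with tie correction otherwise),
and percent gain defined on medians. Benjamini–Hochberg FDR runs over the
full features × timepoints family. A record passes the filters when
0.01 < h²_f < 0.99 (outside this window the feature variance is
undetermined or over-estimated), p_LRT < 0.05, and the Wilcoxon test at
0.05 with the GFBLUP median higher; the unadjusted-p "informative" flag
and the FDR-based significance are carried separately. The filters are
applied to the full-data fit, not per fold. The correlation between the
feature and remainder components is computed as the Pearson correlation of
the full-data BLUPs f̂ and r̂ across accessions — one defensible reading
of a quantity the source analyses never define precisely.

Two caveats on the likelihood-ratio test. First, the ½δ₀ + ½χ²₁ mixture
is the asymptotic null for testing σ²f = 0 against the remainder-only
model, where the parameter sits on the boundary. The scan's reported LR
uses the all-marker GBLUP as its reference fit — the convention of the
genomic-feature literature — but GBLUP is an *interior* constraint of
GFBLUP (it fixes σ²f/σ²r = m_f/m_r), so mixture p-values against that
reference are anti-conservative by roughly a factor of two. The
calibration test therefore simulates the null with no feature variance
and uses the remainder-only reference, where the mixture is correct;
empirical type-I error is checked against the 5% level under 1000
simulated null panels. Second, tiny negative LR values can arise from
finite optimizer tolerance; they are clamped to zero, and a nesting
violation beyond tolerance raises.

Gene-set utilities: the 2×2 overlap test is a 1-d.o.f. chi-square without
continuity correction; GO enrichment is a one-sided Fisher exact test per
term with BH FDR across terms. Ontology up-propagation follows `is_a` and
`part_of` edges only, ignores evidence codes, and is idempotent; marker
membership in a gene is positional (chromosome match and
orf_start ≤ pos ≤ orf_end, 1-based inclusive, strand ignored), with
isoform records merged to their union interval.

## Synthetic data

The generator emulates the statistical structure of the motivating study
population without attempting coalescent realism:

* **Genotypes** — ~500-bp mean marker spacing; each LD block
  (`ld_block_span`, default 10 kb) shares a latent ancestral haplotype
  with block allele frequency drawn uniformly from `maf_range`
  (default 0.01–0.5); markers copy the block haplotype with a 5%
  per-marker mutation probability, producing elevated adjacent-marker |r|
  at O(nm) cost. All genotypes are homozygous 0/2. Defaults
  (344 accessions, 200k markers, 5 chromosomes) mirror the emulated
  panel; tests and the acceptance script state the smaller sizes they run
  at.
* **Features** — gene ORFs of 0.5–5 kb placed uniformly; gene groups of
  sizes drawn from `feature_size_range`, sampled with replacement across
  groups so features overlap like real GO/co-expression sets.
* **Traits** — causal effects are normal with per-marker scale
  1/√(2pq), so each causal marker contributes equal expected variance
  and the architecture matches the GRM scaling; realized component
  variances are rescaled exactly to the targets implied by `h2_target`
  (accession-scale var(g)/(var(g)+σ²e)) and `hf2_share`, which makes
  heritability analytically controllable. The number of causal markers
  placed inside the feature is round(n_causal × hf2_share).
* **Design and time** — replicate counts per accession uniform on
  1..n_replicates (the replicate distribution of the emulated experiment
  is not published); plants laid out on a grid round-robin with 12 plants
  per camera image and 4 equal sowing blocks; one additive N(0, sd²) draw
  per factor level. Genetic values and plant-level residuals evolve across
  timepoints as stationary AR(1) processes with parameter
  `serial_correlation` (default 0.9, matching the high correlation between
  subsequent measurements on imaging platforms), so with design SDs at
  zero the adjacent-timepoint phenotype correlation is ≈ the parameter.

What the generator does **not** emulate: population structure and kinship
gradients of a real diversity panel, recombination maps, allele-frequency
spectra under selection, genotype-by-environment interaction, dominance or
epistasis (the fitted models are purely additive), and spatial trends
beyond exchangeable row/column effects. Passing tests therefore
demonstrate internal correctness and statistical calibration of the
machinery under a known additive architecture — not that any particular
real gene set improves prediction for a real trait.

## Problem sizes and numerical choices

Monte-Carlo checks run at sizes chosen to make their tolerances
meaningful on one CPU: heritability recovery at n = 500 over 200
replicates (tolerance ±0.05 around 0.5); grid-search REML equivalence at
n = 8 with a 10⁻³ grid on the variance ratio; LRT calibration at n = 250
over 1000 null panels (99% binomial band around 0.05); planted-feature
recovery at n = 400 with 20 decoy features over 50 repeats (≥90%
top-rank requirement); the gain–heritability trend at n = 400 with
8-fold × 4-repeat CV and several simulated traits per heritability level,
where replicates with a non-positive baseline median (percent gain
undefined) are excluded. Relative accuracy gain is a noisy quantity at
low heritability — single-architecture draws can swing it by tens of
percentage points, which is why the trend test averages over trait
replicates and only asserts the sign of the Spearman correlation.

Known limitations: AI-REML convergence is declared on parameter change,
so likelihood-flat ridges (e.g. noise-free phenotypes) may report
boundary optima rather than iterate to the cap; the Wilcoxon exact path
requires untied samples; `h2_target = 1` requires `residual_sd = 0` and
vice versa; and the MultiBLUP group F-test treats markers as fixed
regressors, which is conservative for windows with more markers than
observations (reported untestable rather than approximated).
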