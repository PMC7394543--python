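# Methods

## The model

`twinlipid` analyses sample-by-lipid abundance matrices measured on
monozygotic (MZ) and dizygotic (DZ) twin pairs. The classical twin design
decomposes the variance of a trait into additive genetic (A), shared
environmental (C) and unique environmental (E) components: MZ co-twins
share all segregating genetic variation, DZ co-twins half of it on
average, and both kinds of pair are assumed to share their rearing
environment equally. A pair's two trait values are bivariate normal with
common variance `a² + c² + e²` and within-pair covariance `a² + c²` (MZ)
or `0.5·a² + c²` (DZ). Narrow-sense heritability is
`h² = a² / (a² + c² + e²)`.

Fitting is by maximum likelihood on the path coefficients `(a, c, e)`
(their squares are the variance components, so non-negativity is free).
The likelihood is evaluated from per-zygosity sufficient statistics
(`n`, `Σ(x₁+x₂)`, `Σ(x₁²+x₂²)`, `Σx₁x₂`) with the grand mean profiled
analytically — a single free mean per trait, shared across zygosity
groups (means equality across zygosity is assumed, not tested). This
makes one objective evaluation O(1) in the number of pairs, which is what
allows the 500-replicate calibration studies to run in minutes.

Submodels AE, CE and E drop paths; the significance of the additive
component is the likelihood-ratio test of ACE against CE. The default
reference is χ²₁; because the tested variance sits on its boundary, a
50:50 mixture of a point mass at zero and χ²₁ is available
(`boundary_mixture=True`) and is the reference used in the calibration
study, where it holds the type-I error near the nominal level while the
plain χ²₁ reference is conservative. Confidence intervals for h² are
profile-likelihood intervals (the h² values at which twice the likelihood
drop reaches the χ²₁ critical value), clipped to [0, 1]; a delta-method
interval would misbehave at the boundary that near-zero-heritability
lipids occupy.

### Bivariate Cholesky model

Cross-trait genetic (r_g), shared-environment (r_c), unique-environment
(r_e) and phenotypic (r_p) correlations come from the bivariate Cholesky
parameterisation: A, C and E are each `L Lᵀ` for a free 2×2
lower-triangular factor, which keeps the implied 4×4 pair covariance
positive semidefinite by construction. `r_g = A₁₂ / √(A₁₁ A₂₂)`, and
likewise for the others. When a component's variance is numerically zero
the corresponding correlation is undefined and reported as absent rather
than zero. Exactly duplicated traits make the 4×4 covariance singular and
the likelihood unbounded; this case is detected and returns the
degenerate fit (all cross-trait correlations 1, margins equal to the
univariate fit).

### Sex heterogeneity and age moderation

The sex-heterogeneity model gives males and females separate path
coefficients; opposite-sex DZ pairs covary through the cross-product
`0.5·a_m·a_f + c_m·c_f`. Means are sex-specific in both the
heterogeneity and the constrained homogeneity model, so the
likelihood-ratio test has 3 degrees of freedom (the paths only). No
separate "scalar vs non-scalar" variants are fitted.

The age-moderation (gene-by-environment) model writes each path as
linear in age centred at the sample mean, `a(t) = a₀ + a₁t` etc.; age is
pair-shared, so each pair contributes a bivariate normal with its own
implied covariance. `h²(age)` is evaluated on a grid spanning the
observed ages, and moderation is tested by a 3-df LRT against the plain
ACE model, which the moderation model nests exactly at
`a₁ = c₁ = e₁ = 0`.

### Optimisation

All fits use seeded multi-start L-BFGS-B, each solution polished by a
bounded Nelder-Mead pass. The polish matters: non-positive-definite
covariances return −∞ (so the optimiser can probe the boundary without
exceptions), which makes the objective cliff-edged near singular
configurations, and gradient-based line searches can stall against the
cliff; the simplex recovers. Numerical nesting (e.g. the moderation fit
at least matching ACE) is enforced by refitting from the nested solution
when violated.

`falconer_h2 = 2(rMZ − rDZ)` (clipped to [0, 1]), with intraclass
correlations computed by double-entry Pearson, is kept solely as an
independent moment-estimator cross-check of the likelihood machinery.

## Preprocessing

Shorthand lipid names over the classes Cer, CE, DG, LPC, PC, PE, PI, SM,
TG are parsed in both chain-separator dialects ("/" and "_") and both
carbons/double-bond separators (":" and "_"), with d (sphingoid), e
(ether) and p (plasmalogen) chain marks; formatting round-trips in the
original dialect.

Peak-table QC follows the rules a targeted lipidomics workflow applies to
LipidSearch-style output: abundances are normalised per sample by the
class internal-standard area; identifications are retained when the rej
flag is 0, average peak quality exceeds 0.75, the coefficient of
variation across repeated QC-standard injections is below 0.4, and the
lipid is present in every declared alignment batch (the batch count is a
configuration value, not hard-coded to four). Duplicate identifications
(same annotation, m/z within 5 ppm, retention time within ±0.5 min) are
resolved by lowest CV, then highest average peak quality, then highest
average m-score; residual exact ties keep the first by input order and
are logged as ambiguous. Filtering is idempotent and every exclusion is
written to an audit log with the violated rule. The CV < 0.4 rule uses
QC-injection CV (within-cohort CV can be reported separately); which of
the two a given laboratory protocol intends is ambiguous, and the choice
is configurable through which rows carry the `is_qc` flag.

Group sums add lipids within a class and within class × saturation
(saturated = 0 double bonds over all chains, monounsaturated = 1,
polyunsaturated ≥ 2). LDL-C is the Friedewald estimate
`TC − HDL-C − TG/2.2` (mmol/L); negative estimates are returned but
flagged with a warning rather than nulled.

Traits are residualised by OLS on the covariates (age, sex, education,
BMI, lipid-lowering medication, smoking, batch, APOE ε4 status by
default; categorical covariates dummy-coded, rows with missing values
dropped and reported) and then rank-based inverse-normal transformed,
`Φ⁻¹((r − c)/(n − 2c + 1))` with Blom offset `c = 3/8` by default
(configurable) and average ranks for ties. The order — adjust first,
transform second — restores approximate normality of the adjusted trait
and removes batch separation.

## Omics association

Lipid–expression association fits, per (lipid, probe), a linear mixed
model with the lipid residual as response, the standardized probe
residual as fixed effect and a random intercept per twin pair — the only
clustering in the design (a family-level grouping would be the fallback
in cohorts with non-twin relatives). Models are fitted by ML, not REML,
so likelihoods are comparable across nested fits. The Wald statistic is
referred to a t distribution with `n − 2` degrees of freedom — a
conservative small-sample choice relative to the normal reference. A
random-effect variance that collapses to the boundary degenerates the
fit to OLS, which is returned flagged. Significance is Bonferroni at
`α / m` where `m` is the probe count of the supplied matrix — recomputed
from the input, never hard-coded.

Variance explained by a probe set is summarised by McFadden
(`1 − ll_full/ll_null`) and Nagelkerke
(`(1 − (L₀/L₁)^{2/n}) / (1 − L₀^{2/n})`) pseudo-r², both from ML fits of
the null (intercept + random pair intercept) versus full model, clipped
to [0, 1]. Both are always reported since they answer slightly different
normalisation conventions; they agree in rank order. Probe sets are
chosen by L1-penalized (lasso) regression on the Bonferroni-significant
probes, penalty selected by seeded 10-fold cross-validation at the
minimum-CV penalty; exactly collinear probes keep at least one member,
with the survivor following the coordinate-descent ordering.

Genome-wide average methylation (GWAM) is the per-sample unweighted mean
of CpG beta values over a retained-probe mask (supporting exclusion of
sex-chromosome, SNP-containing and cross-reactive probes). Each lipid is
regressed on the standardized GWAM by OLS with a McFadden pseudo-r²; the
slope is invariant to adding a constant to all betas. GWAM is computed
from raw masked betas by default; a covariate-residualised mode is
available by passing residualised betas. Targeted site-level CpG
associations (restricted by a gene→CpG proximity map) reuse the same
regression machinery and flag unadjusted p < 0.05 as "suggestive" — the
targeted design exists precisely to avoid an epigenome-wide correction
burden, so these calls are screening-level only.

## Reporting

Triglycerides are stratified by saturation class and by total carbon
number (low ≤ 48, medium 49–55, high ≥ 56; "56+" is read as ≥ 56 and
"< 49" as ≤ 48). Transcripts are binned per stratum by how many lipids
of that stratum they hit (1–2, 3–8, > 8); bins per stratum sum to the
stratum's distinct transcript count. The heritable-versus-non-heritable
comparison partitions significantly associated transcripts into
unique-heritable / unique-non-heritable / shared (a disjoint cover of the
union) with positive/inverse direction tallies per set. The cohort table
compares MZ and DZ members with Welch t tests for continuous variables
(pooled-variance optional; Welch is the default because it reproduces
printed cohort statistics exactly) and Pearson χ² without continuity
correction for categorical ones; it accepts either raw values or printed
(mean, SD, n) summaries. Percentages are rounded to one decimal.

## Synthetic data

The generator emulates the study conditions the pipeline targets: a
default cohort of 75 MZ and 55 DZ pairs aged uniformly 69–93, ~65%
female, DZ pairs opposite-sex with probability 0.5; 60 lipids of unit
total variance with fractions `(a², c², e²) = (0.4, 0.1, 0.5)` by
default; 500 expression probes and 1000 CpG sites (full-scale array
dimensions of ~36k probes and ~421k CpGs are reachable by configuration
but are not defaults — the defaults keep test runs under a minute).
Traits are built from standard-normal genetic/shared/unique latent
factors (DZ genetic latents `√½·common + √½·individual`), with optional
cross-lipid correlation matrices applied to the latents (r_g, and
optionally r_c / r_e); the realised latents are stored in the truth
object so bivariate estimates can be checked against the empirical
correlation of the generating draws. Sex-specific paths or age-moderated
paths switch generation to direct per-pair covariance sampling (one
lipid at a time; cross-lipid correlations are not supported in those
modes).

Expression probes are Gaussian noise plus planted `beta × lipid`
signals. Methylation betas are inverse-logit transforms of Gaussian
latents (per-probe baseline N(0, 1.5), within-probe noise SD 0.5 — the
shape of a typical beta-value distribution, since no generative model is
canonical for beta values); a per-sample global factor correlated with a
chosen lipid shifts a configurable fraction of probes, inducing a
GWAM–lipid association of configured sign. Covariates (education, BMI,
smoking, lipid-lowering medication, APOE ε4, batch) are drawn from
plausible older-cohort distributions chosen once and documented here;
they are package choices, not estimates.

The raw peak fixture is constructed, not sampled: its QC-injection
triples are symmetric `{m−d, m, m+d}` so each CV is exact, and it
contains by construction a duplicate trio (CVs 0.1/0.2/0.3), a CV ≥ 0.4
lipid, a peak-quality ≤ 0.75 lipid, a rejected identification and a
lipid absent from one batch, with the surviving set enumerated by hand
and frozen.

What the generator does not emulate: heavy-tailed and skewed abundance
distributions (traits are generated Gaussian; the INT step is exercised
with log-normal inputs in the unit tests instead), missingness,
batch-by-intensity interactions, realistic linkage between lipid classes
and probe annotation, or cell-type composition. Passing tests therefore
demonstrate correctness of the estimators under the stated generative
model, not robustness to every artefact of real LC-MS or array data.

## Validation studies and problem sizes

`twinlipid.benchmarks` fixes the designs used by the test suite and the
reproduction script: h² recovery over `(a², c²) ∈ {0, .2, .4, .6} × {0, .2}`
at 2000 pairs/group (3 replicates per cell, mean absolute error);
ML-vs-Falconer agreement at 5000 pairs/group; profile-CI coverage over
500 replicates at 500 pairs/group; type-I error of the five tests (h²
LRT with the boundary mixture at 200 pairs/group, sex-heterogeneity and
age-moderation LRTs at 200 pairs/group, 500 replicates each; mixed-model
association at 200 samples and GWAM regression at 135 samples, 500
replicates each); genetic-correlation recovery for planted
r_g ∈ {0, 0.5, 0.9} at 5000 pairs/group; and Nagelkerke-vs-analytic-R²
on a planted single-probe model at n = 1000. Sub-seeds are derived from
one master seed via `SeedSequence`, so every study is independently
reproducible.

## Known limitations

* No dominance (ADE) or >2-trait Cholesky models; no SNP-based or
  extended-pedigree heritability.
* The sex-pooled ACE fit includes opposite-sex DZ pairs as ordinary DZ
  pairs (configurable upstream by filtering), which assumes no sex
  difference in paths — the heterogeneity model is the check on that
  assumption.
* The mixed-model Wald df choice (`n − 2`) is simple rather than
  Satterthwaite; at the design sizes used the difference is negligible,
  and the calibration study verifies the realised type-I error.
* Lasso selection with correlated probes is not selection-consistent;
  selected sets should be read as predictive, not causal.
* McFadden pseudo-r² for continuous responses depends on the response
  scale through the null likelihood; it is comparable across lipids here
  only because all traits are INT-standardised.
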