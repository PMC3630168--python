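# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic cohort does and does not
emulate, and the numerically delicate choices.

## The scientific setting

The analysis chain targets a candidate-gene cohort design: N ≈ 187
mothers genotyped at three biallelic SNPs (two in the oxytocin peptide
gene region, one in the oxytocin receptor gene), assessed for the
quality of care they received in their own childhood (nine questionnaire
dimensions from the Childhood Trauma Questionnaire, Parental Bonding
Instrument, and a Life History Calendar), screened for depressive
symptoms with the CES-D (0–60; 16 is the conventional clinical cut-off)
prenatally and at six months postpartum, and video-coded for maternal
behavior during a 20-minute (1200 s) free-play interaction. The
scientific questions are (i) whether genotype moderates the association
between early care and adult outcomes (G×E), and (ii) whether the G×E
effect on caregiving behavior runs *through* postpartum mood
(genotype-moderated mediation).

## Genotype QC

Minor-allele frequency is (n_het + 2·n_hom_minor)/2n, re-oriented from
the data if the nominal minor allele is in fact the commoner one (the
label is reported alongside so tables remain stable). Hardy–Weinberg is
the 1-df Pearson χ² of observed vs expected genotype counts under allele
frequencies estimated from the same sample, without continuity
correction; `hwe_exact_test` provides the conditional exact test as an
alternative. Two-locus haplotype frequencies come from the standard EM
algorithm over unphased genotypes: only double heterozygotes are
phase-ambiguous and are split cis/trans in proportion to the current
haplotype frequencies; the update is iterated to a 1e-8 max frequency
change (cap 1000 iterations). The EM log-likelihood is non-decreasing
and the result is invariant to subject order. It starts at linkage
equilibrium; the one pathological case (every subject double-
heterozygous) is non-identifiable and is broken by a deterministic
+1e-6 perturbation of p_AB, with a warning flag. Missing genotypes are
dropped pairwise per locus pair, so per-SNP genotyping rates can differ.
LD summaries use D = p_AB − p_A·p_B, D′ = |D|/D_max with the
sign-appropriate bound, r² = D²/(p_A p_a p_B p_b), and χ² = 2n·r² (1 df).
For biallelic loci r² ≤ D′² always; this is asserted property-wise.

## Early-care-quality composite

PCA is computed on the correlation matrix (the nine dimensions sit on
different scales; the source analysis does not state the choice) of
complete cases (≥ 30 required). Two components are retained by design —
no eigenvalue-above-1 rule — and rotated by quartimax. Quartimax
maximizes Σλ⁴; because communalities are rotation-invariant this is
equivalent to minimizing Σ(2λᵢλⱼ)² over column pairs, which for one pair
has the closed-form optimum 4θ = π − atan2(B, A) with u = a² − b²,
v = 2ab, A = (Σv² − Σu²)/2, B = Σuv. Pairwise sweeps repeat until the
criterion gains < 1e-9. The leading rotated component (larger sum of
squared loadings) is the composite; its sign is fixed so the CTQ
abuse/neglect dimensions load negatively — higher score = better early
care — since a PCA sign is otherwise arbitrary. Scores use the
regression method (weights R⁻¹Λ on standardized data) and are
standardized over scored subjects. A pure-noise guard flags the fit if
the top eigenvalue does not clear a Marchenko–Pastur-style null bound.

Subjects with incomplete questionnaires are not scored by the PCA;
their *composite* is then filled by stochastic regression single
imputation (fitted value from the nine original dimensions plus Gaussian
noise at the residual sd), matching the order of the source procedure:
factor first, impute the derived dimension. Predictor cells missing
inside the imputation model are mean-filled for prediction only; a
subject with no observed predictors at all is left missing and flagged.

## Multiple imputation and pooling

Behavioral outcomes and incomplete covariates are multiply imputed by
predictive mean matching: per imputation, regression parameters are
drawn from the approximate posterior (σ²* from the scaled inverse-χ²
draw, β* ~ N(β̂, σ²*(XᵀX)⁻¹)); predicted means use β̂ for observed cases
and β* for missing ones; each missing value copies a donor drawn
uniformly from the 5 observed cases with nearest predicted means
(distance ties broken by subject order, donor choice by the seeded RNG).
Imputed values therefore always lie in the observed support, and with no
missing data the layer is an exact identity. "Ten iterations" is read as
m = 10 imputations (the convention of the toolkit the procedure
originates from), configurable. Pooling follows Rubin: averaged
coefficients, total covariance U̅ + (1 + 1/m)B, t-tests on Rubin's
large-sample df capped at the residual df (reducing to the complete-data
test when B = 0). The overall fit statistic is the mean over imputations
of the LR χ² against the intercept-only model, which is what the
averaged-fit convention reports; the mean per-imputation overall F is
emitted alongside, since source tables are inconsistent about which of
the two they print.

## G×E regressions

Orienting-away counts are transformed ln(x+1) — the +1 accommodates
zeros, which a bare log would not — and instrumental-care durations by
√x; vocalizing and sensitivity are left untransformed (normally
distributed by construction and by report). Infant activity is the sum
of reaching, smiling and crying durations. Behaviors present (> 0) in
fewer than 15% of mothers are dropped (inclusive boundary: exactly 15%
is kept). Models are OLS per imputation with intercept, dominant-coded
genotype G, care composite E, covariates, and G×E, pooled as above.
Backward elimination removes one covariate at a time — the one whose
single-term removal F-test (identically the squared pooled t) has the
largest p-value above 0.05 — and refits until all remaining covariates
are significant; G, E and G×E are never candidates. Genotype main-effect
ANOVAs are fitted as OLS with indicator coding, which is the same model.
Two-sided tests throughout, no multiple-testing correction (none is
applied in the source design); all p-values are reported so readers can
adjust.

## Moderated mediation

Both equations are fitted by OLS on listwise-complete, non-imputed data
(the source design choice; an MI-integrated variant is out of scope).
The mediator is centered at 16, so the genotype main effect is read at
the clinical cut-off. Because each equation is saturated in
genotype interactions, the pooled-model simple effects equal separate
per-genotype fits exactly — asserted against that stratified oracle at
1e-8. The decomposition identities (indirect = first·second, total =
direct + indirect) hold by construction to machine precision on every
fit and every bootstrap resample.

Bootstrap inference is nonparametric case resampling of subjects
(stratified resampling is deliberately not the default; the source
procedure does not stratify), refitting both equations per resample —
vectorized via batched normal equations, with a condition-number guard.
Resamples with a degenerate genotype group (< 3 members) or an
ill-conditioned design are redrawn; more than 10% failures aborts with a
diagnostic. Intervals are bias-corrected (BC) percentile intervals:
z₀ = Φ⁻¹(fraction of draws strictly below the point estimate), clipped
to (0.5/n_boot, 1 − 0.5/n_boot) to keep the normal quantile finite, and
bounds at Φ(2z₀ ± z_{α/2}). BC rather than BCa is used because the
source procedure states bias correction only; a zero-variance statistic
collapses the interval to the point estimate. Same seed ⇒ identical
intervals.

## The synthetic cohort

The generator's defaults are the study conditions: n = 187; MAFs
0.31/0.50/0.50 (the third locus's frequency is taken from its genotype
counts, whose printed frequency label is internally inconsistent in the
source and is flagged rather than reproduced); D′ = 0.79 between the two
*OXT* SNPs via the implied four-haplotype distribution under random
mating, third locus independent; missing-data rates 14% (behavior), 9%
(parity), 14% (education), 12% (CES-D), deleted completely at random —
MCAR is an assumption, chosen because it matches what the downstream
imputation machinery assumes and keeps recovery tests interpretable.
A standard-normal latent care factor drives six of nine questionnaire
dimensions with loadings ±√0.6 (leading correlation eigenvalue ≈ 4, i.e.
a 4/9 variance share); sexual abuse and the two LHC dimensions default
to pure noise because the source names only six high-loading dimensions
out of nine.

Planted outcome structure: postnatal CES-D follows the first-stage
equation with the published-scale coefficients (a1 = −7.98, a2 = −0.72,
a3 = 5.62; intercept 0 on the centered scale, i.e. raw mean 16 at
average care — plausible for a clinic-recruited perinatal sample, and
with the right-skewed noise the median sits below the cut-off);
√instrumental care follows the outcome equation (b1 = −3.77, b2 = 0.26,
b3 = −0.26, b4 = 7.91, b5 = −0.11; intercept 12 ≈ 144 s of instrumental
care), plus a 2.8-per-sd infant-activity effect so covariate retention
is exercised. Both outcomes draw from a Gamma distribution with mean
equal to the (floored at 0.5) linear predictor and constant sd 9. This
is the one deliberate departure from the obvious "Gaussian then clip"
construction: clipping at zero censors the conditional mean and biases
planted-coefficient recovery by more than the 10% band at these effect
sizes, whereas the Gamma construction keeps the analysis-scale
regression exactly linear in expectation while still producing
nonnegative, right-skewed outcomes that the ln/√ transforms visibly
normalize. Residual sd 9 matches the depression-model scale. Prenatal
CES-D shares a rank correlation of 0.60 with postnatal scores; the
config value is interpreted on the Spearman scale and converted to the
latent Pearson scale by 2·sin(πρ/6). Sensitivity is simulated with no
planted genetic effect (a null finding in the source), as are
vocalizing and orienting.

What the generator does *not* emulate: item-level questionnaire
responses (only dimension scores), genotyping error and missing calls
(genotypes are complete unless explicitly configured), non-MCAR
missingness, measurement unreliability in behavior coding, population
stratification, and any nonlinearity beyond the outcome floors. Passing
recovery tests therefore demonstrate that the estimators are correct
under the assumed data-generating structure, not that the structure is
true of real cohorts.

## Problem sizes in the test suite

Deterministic oracles run on small fixtures (20-subject EM vs a
0.001-step grid over the one free haplotype frequency). Monte-Carlo
checks use: 200 cohorts of n = 158 for parameter recovery and
interaction type-I error; 300 replicates of n = 500 with 1000 bootstrap
draws each for BC coverage of the indirect effect; n = 20000 single
cohorts for MAF/D′ convergence; 200 replicates for HWE rejection rate
and imputation coverage. These sizes put binomial noise well inside the
asserted bands while keeping the default suite quick to run.

## Known limitations

- The imputation model is a fixed linear model per variable (no chained
  equations across many incomplete variables); variables are imputed
  from a designated predictor set, not from each other.
- Genotypes are never imputed.
- No robust/sandwich errors or mixed models; no haplotype-based
  regression models; no >2-locus haplotype inference.
- BCa (acceleration) is not implemented; BC only, per the source
  procedure.
- The mediation stage requires complete cases and does not integrate
  with the MI layer.
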