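# Methods

`prosmark` re-implements, as a tested pipeline on synthetic data, the
analysis design of tissue-microarray (TMA) biomarker studies of prostate
cancer aggressiveness: quantify immunostaining per spot, model time to
post-prostatectomy biochemical failure (BF), select a multibiomarker
signature under missing data, and evaluate its discrimination with
time-dependent ROC methods. This note records the models, the conventions
chosen where the design was genuinely open, and what the synthetic data do
and do not establish.

## Staining quantification

Brightfield IHC intensity is nonlinear in chromogen amount; optical density
(OD) is linear. Pixels are transformed per channel as

    OD = -log10((I + 1) / 256),

the +1 guarding log(0) and making saturated white exactly OD 0 (results are
bit-reproducible under this convention). The OD vector of each pixel is
unmixed into hematoxylin/DAB/residual concentrations by inverting the 3x3
stain matrix (Ruifrok–Johnston color deconvolution); default stain vectors
are the published H-DAB values, overridable because real scanners and stain
lots differ. Negative concentrations are clamped to zero after inversion.

Region metrics follow the `AvgOD * %Pos` convention: **AvgOD is the mean DAB
OD over all region pixels** (not positive pixels only — this keeps the score
bounded and monotone in both factors) and %Pos is on a 0–100 scale, so the
score is bounded by 100·ODmax. The default positivity threshold is OD 0.15;
vendor thresholds are unpublished, so it is a named, overridable parameter.
Nuclear metrics use the nucleus as the unit of analysis (per-nucleus mean
OD; a nucleus is positive iff its mean passes the threshold). Microvessel
morphometrics treat vessel labels as filled components; perimeter is the
count of 4-connected boundary edge steps (a convention that must be fixed
for reproducibility; it equals 2(w+h) on w×h rectangles). Empty regions
yield missing-flagged results, never silent zeros — on TMAs a lost core is
missing data, not zero staining.

## Endpoint and cohort rules

BF is the date of the first PSA ≥ 0.2 ng/mL drawn at least 42 days
(inclusive) after prostatectomy that is confirmed by **any** later PSA
> 0.2 ng/mL — confirmation need not be the immediately next draw, and the
6-week clock applies to the index value only. Failure-free subjects are
censored at last contact. Time is in years (days/365.25). Eligible Gleason
patterns are 3+3, 3+4, 4+3, 4+4, 4+5; predominant-pattern-5 tumors and
subjects with fewer than two post-operative PSA values are excluded with
machine-readable reasons. Derived covariates: primary pattern group
(3: 3+3, 3+4; 4: 4+3, 4+4, 4+5) and the composite non-localized indicator
(pT3 ∨ pN1 ∨ pR1). Spot-level metrics are averaged over non-missing spots;
a subject with all spots lost is missing for that marker. Run-to-run
concordance uses Pearson correlation on doubly observed subjects by default
(Spearman by flag), missing-flagged below n=3.

## Survival modelling

Cox proportional-hazards models are fit by damped Newton–Raphson on the
partial likelihood with Efron (default) or Breslow tie handling;
convergence at max|score| < 1e-9 or relative log-likelihood change < 1e-10;
covariance is the inverse observed information. Monotone likelihoods
(separation) are detected both by coefficient divergence and by the linear
predictor reaching the numerical clip range, and reported as non-converged
with a diagnostic rather than raised. Continuous biomarkers are reported as
hazard ratios **per 1 SD**, with the SD computed on the complete-case
subset of that fit (self-consistent with the per-marker N of the screens);
CIs use z = 1.959964. Univariate screens fit each marker alone on its
complete cases; adjusted screens add pre-operative PSA, age, primary
pattern group and the non-localized indicator, unpenalized.

## Imputation and selection

Missingness (TMA core loss) is handled by chained equations: m = 10
completed datasets, 10 sweeps, each incomplete biomarker regressed on all
other biomarkers plus the event indicator and the Nelson–Aalen cumulative
hazard at the subject's follow-up time (the standard survival-compatible
predictor set). Draws are predictive mean matching (type-1, 5 donors) by
default, Bayesian normal draws as an alternative; observed values are never
altered. Within-sweep visit order is the dataset column order, fixed.

Selection runs an L1-penalized Cox model per completed dataset, solved by
iteratively-reweighted least squares with soft-threshold coordinate descent
(Breslow weights), warm-started along a 100-point log grid from λ_max (the
smallest λ with an all-zero solution, computed from the score at β = 0)
down to 0.001·λ_max; biomarkers are standardized internally and penalized,
clinicopathologic covariates may enter unpenalized. The "best k" of one
dataset is the **first k distinct markers to enter the path**; simultaneous
entrants at one grid point are ordered by coefficient magnitude at entry.
Counts of top-2/3/4/5 membership across the m datasets form the selection
tally; the final signature ranks markers by top-3 count with ties broken by
top-2, top-4, top-5 counts and finally name (deterministic).

## Discrimination

Time-dependent discrimination at horizons of 3 and 5 years uses the IPCW
cumulative/dynamic AUC: cases fail by t (weight 1/G(T−)), controls survive
past t (weight 1/G(t)), G the Kaplan–Meier estimate of the censoring
distribution; tied scores count 1/2. With no censoring the estimator
reduces exactly to the Mann–Whitney AUC, which provides an exact-rational
test oracle. Signature AUCs fit a Cox model on the signature and score by
the linear predictor; the cross-validation-adjusted variant refits per
event-stratified fold (10 by default) and pools out-of-fold scores before
computing one AUC. Both are averaged over the m imputations. Confidence
intervals are percentile bootstrap (B = 1000 default) resampling subjects
with the **same index set across imputations** (respecting the imputation
structure); the p-value inverts the bootstrap distribution around 0.5 with
a 1/(B+1) continuity guard. Degenerate resamples (no cases or controls) are
dropped and counted, with a warning above 10%.

## Weighted-voting gene signature

For each training expression study the per-gene signal-to-noise statistic
sx = (μ_NA − μ_A)/(σ_NA + σ_A) is computed on per-gene z-scored data
(positive = higher in non-aggressive tumors); each study's informative set
is the union of the 500 most-positive and 500 most-negative sx genes; genes
informative in every training study are ranked by |sample-size-weighted
mean sx|. An n-gene model votes v = sx_w·(g − b) per gene with boundary
b = 0 on standardized data (class-mean midpoint available when labels are
present); the specimen label is the sign of Σv, with V = 0 reported as
indeterminate and counted as an error. Validation studies never contribute
to sx. Model sizes of 46 and 11 mirror the two stages of the original
cross-study procedure.

## Synthetic data: what it emulates and what it does not

The cohort generator draws standard-normal biomarkers with exchangeable
correlation (default ρ = 0.2) from a shared latent factor, applies
configured per-SD log hazard ratios in a Weibull proportional-hazards model
(shape 1.3, scale 30 y — sparse, late failures consistent with a ~14% event
fraction and multi-year median time to failure), and calibrates a uniform
administrative censoring window by bisection to the target event fraction
(default 13.75%). Spot values add N(0, 0.25²) noise to the subject's latent
value; per-marker MCAR whole-core loss rates are drawn from 6–30%. PSA
series are built on a 90-day visit schedule so the BF rule recovers the
simulated event time to within one visit interval; a 0.55-year censoring
floor guarantees every subject the two post-operative values eligibility
requires. Default planted effects (per-SD HRs 2.01, 1.76, 1.46 on three
markers) mirror the magnitudes typical of the strongest markers in studies
of this design.

Not emulated: informative censoring, non-proportional hazards, measurement
batch effects, MNAR core loss, inter-marker correlation structure beyond
exchangeable, and real staining morphology (spot images are geometric
phantoms). Passing recovery tests therefore demonstrates the statistical
machinery is correct and calibrated under the assumed data-generating law,
not that the signature would validate clinically.

A note on "null" markers: with exchangeable correlation and planted
signals, the shared factor makes nominally null markers genuinely
prognostic (marginal HR ≈ 1.5 at ρ = 0.2). Planted-recovery tests
therefore use ρ = 0, where nulls are true nulls; ρ = 0.2 remains the
default for realistic end-to-end runs, where partial tally spreading —
as seen in real data — is expected.

## Problem sizes and numerical choices in the test suite

Operating-characteristic checks are run at sizes chosen to be informative
while keeping the suite practical: Cox-vs-brute-force agreement on 200
random datasets of n ≤ 8 (tolerance 1e-6 on the maximized partial
log-likelihood); planted-signature recovery over 100 replicates at n = 500;
type-I error of the univariate screen over 1000 null replicates at n = 160;
bootstrap coverage over 200 replicates at n = 200 with B = 200 and a 100k
Monte-Carlo population defining the true AUC; CV-optimism comparison over
100 replicates at n = 80 with 30 null markers; weighted-voting recovery
over 50 replicates at the original study sizes (21 + 58 training, 28
validation). All simulations are seeded and deterministic.

## Known limitations

- The Lasso path uses Breslow tie weights inside IRLS regardless of the tie
  option of plain fits (standard practice; ties are measure-zero in the
  simulated data).
- PMM with few observed values falls back to fewer donors than requested.
- The bootstrap p-value has resolution 1/(B+1); at B = 1000 the smallest
  reportable two-sided p is ~0.001.
- `validate_config` accepts an empty file as the full default configuration
  (seed 0); an explicit `seed: null` is an error when stochastic stages are
  enabled.
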