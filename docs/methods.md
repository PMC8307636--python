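# Methods

This note records the statistical model behind `envsig`, the choices made
where the procedure was genuinely open, what the synthetic cohort does and
does not emulate, and the known limitations of the attribution statistic.

## Data model

The unit of analysis is a surgical patient with one tumor and one
adjacent-normal biopsy, each profiled on a miRNA microarray (log₂
intensities after per-array replicate-spot averaging; no baseline or
quantile normalization). Patient-level covariates are five environmental
exposures (passive smoke at home and at work, vehicle traffic at home,
home distance from the Etna volcano in km, radon risk derived from home
type), smoking history (never, or years since cessation ≥ 5), and total
benzo(a)pyrene tetrol levels (Tetrol I-1 + Tetrol II-2, pg per µg
lymphocyte DNA). Questionnaires may be missing; incomplete profiles are
excluded from attribution, never imputed.

## Statistical layer

All group tests are two-sided. The two-sample test is the pooled-variance
Student *t* (a Welch variant is available behind a flag); one-way ANOVA is
the classical fixed-effects F. Correlations go through a normality gate:
Shapiro–Wilk on both vectors at α = 0.05 chooses Pearson (both pass) or
Spearman (midranks). Simple OLS supplies dose–response slopes with the
*t*-based slope p-value (identical to the Pearson p on the same data).
No multiple-testing correction is applied anywhere in the selection path;
a Benjamini–Hochberg helper exists but is off by default, matching the
single-feature-threshold character of the original selection.

Degenerate inputs are handled explicitly rather than silently: zero
pooled variance with equal means gives t = 0, p = 1; with unequal means
the p = 0 convention is used and the result flagged. Volcano rows with
zero pooled variance fall back to the fold-change criterion alone, with a
warning. Constant vectors are errors for correlations and regression, and
a constant alteration-count column yields a flagged null correlation
rather than an abort.

## Selection rules

A miRNA is *selected* in any volcano contrast iff |log₂FC| ≥ log₂ fc and
p ≤ α, both inclusive, with defaults fc = 2, α = 0.05. Fold change is the
difference of log₂ group means (a geometric-mean fold change on the linear
scale). The tumor-vs-normal contrast is run unpaired even though samples
are paired — the group-average contrast is what the selection thresholds
were defined for — and a paired variant exists for sensitivity analysis.
Under the null the *joint* rule is far stricter than α·(universe): with
residual σ = 0.5 and ≈19 samples per side the fold-change gate alone has
near-zero null probability, so null signature sizes are ≈0. Type-I
calibration is therefore stated and tested on the p-value component (the
per-row rejection rate at p ≤ 0.05), and the joint null selection is
tested as bounded by the p-only false positives.

## Attribution

Per patient and signature, the alteration count is the number of member
miRNAs whose within-patient tumor-vs-matched-normal |log₂ fold change|
reaches the same fc threshold (inclusive). A per-patient "volcano t-test"
is not definable with one sample per tissue, so the per-patient criterion
keeps only the fold-change axis of the volcano; this is the single largest
interpretive choice in the pipeline and is surfaced in the API name
(`patient_alteration_counts`) and here. A patient is attributed to an
exposure when their count strictly exceeds the cohort median of that
exposure's column (ties at the median do not attribute). Exposures are
ranked by attributed-patient count, descending, with ties broken by larger
signature size and then lexicographically — the size tie-break is what
places a large-signature exposure above a small-signature one when both
attribute the same number of patients.

**Known limitation.** With n patients the strict-median rule caps the
attributed count at ⌊n/2⌋ (at least half of any column is ≤ its median).
All informative exposures therefore crowd into a narrow band just under
n/2, and their order is decided by the tie mass at the median — which
grows as signatures get smaller (coarser count support) but also shifts
with exposure prevalence. The full five-way ranking is consequently
unstable on cohorts of this size: in the package's own recovery experiment
(100 replicate default cohorts) the extreme ranks are recovered often
(largest signature first in ~74%, the n = 1 signature last in ~82%) but
adjacent middle ranks are near coin flips, and the complete planted
ordering is recovered in well under half of replicates. The corresponding
recovery assertion in the acceptance suite documents this honestly rather
than weakening the rule. Users should read the ranking's extremes, not its
middle, as signal.

## Exposure dichotomization

Booleans pass through. Etna distance splits at the cohort median with the
boundary patient counted as near/exposed (volcanic exposure decays with
distance, so "near" is the exposed side). Radon risk arrives as a boolean
already derived from home type by the questionnaire pipeline; the mapping
is user-editable upstream, not hard-coded. Literature miRNA lists are
plain one-per-line text inputs, merged into a derived signature with
provenance `merged`; they are never built in.

## Classification

The validation classifier is a single-hidden-layer feed-forward network:
width max(4, ⌈√p⌉) for p features, logistic activations, L-BFGS with L2
penalty 1e-2, at most 500 iterations, features z-scored inside each
training fold. Cross-validation is stratified 5-fold (clamped to the
minority class size), seeded and bit-reproducible. Accuracy is pooled over
held-out folds. The interesting quantity is the panel-vs-baseline delta:
a small informative panel beats the all-miRNA baseline exactly when the
baseline is diluted by thousands of noise features, and ties it when the
signal is strong enough to dominate even at full dimension — both regimes
appear across the five exposures.

## Synthetic cohort generator

Defaults encode the target study conditions: 50 paired patients (38 with
complete questionnaires), 2549 miRNAs, 273 cancer-related members with
222 down-regulated, |log₂FC| ~ U(1, 3), baseline intensity N(8, 2),
residual σ = 0.5, exposure prevalences 0.3 / 0.2 / 0.5 / median-split /
0.25, Etna distances U(13, 152) km, planted signature sizes 8/1/53/21/19
at effect 1.5, SCLC fraction 0.2 with a 26-member histotype-linked subset
(25 up in NSCLC). Categorical covariates are assigned with fixed margins
(exactly round(prevalence·n) exposed) so every cohort realizes the stated
composition.

Three structural choices matter:

- **Exposure effects amplify the cancer alteration.** An exposed patient's
  tumor shifts a planted member *further in the direction of its cancer
  effect*. A direction-agnostic shift would partially cancel the mostly
  down-regulated cancer effects and make exposed patients look *less*
  altered, contradicting the premise the attribution statistic relies on.
- **Per-patient effect heterogeneity.** Each (miRNA, patient) cancer
  effect is scaled by U(0.5, 1.5). Without it all patients carry identical
  population effects, per-patient counts saturate at the signature size,
  and the attribution median degenerates (whole columns tie; nobody is
  attributed). The magnitude was fixed once by power analysis so that
  planted effects remain detectable at the stated sample sizes.
- **Histotype effects are centered.** The NSCLC-vs-SCLC contrast is
  applied with patient-weighted zero mean so histotype-linked members stay
  nested inside the cancer-related set, as the planted structure requires.

The adduct model is linear: total = 12 + 3·(passive smoke home) −
0.04·distance − 0.12·(effective years since cessation) + N(0, 1.5), floored
at 0.1 pg/µg, with never-smokers assigned the long-cessation limit of
30 years and the total split ≈60/40 into Tetrol I-1/II-2. The coefficients
were chosen once so the inverse distance relation is clearly detectable at
n = 50 (|t| ≈ 4–5) while the exposure box-plot contrasts stay mostly
non-significant, mirroring the qualitative pattern the pipeline is meant
to exhibit. A heavy-tail option (Student t, 3 df noise) exercises the
Spearman branch.

What the generator does **not** emulate: probe-level scanner artifacts and
spatial array effects (replicate spots get only iid N(0, 0.1) jitter),
correlated miRNA families and co-regulation, overlap between exposure
signatures (planted sets are disjoint within the cancer set, though
*derived* signatures do confound across correlated exposure assignments),
questionnaire measurement error, and assay-batch structure in the adduct
measurements. Passing tests therefore demonstrate the pipeline's
statistical correctness and power under clean planted structure, not
robustness to array artifacts or confounded questionnaires.

## Numerical conventions

TSV reports are written at %.17g so write-then-read is exact to 1e-12;
JSON reports carry full float repr and sorted keys, making re-runs
byte-identical for a fixed seed. Dendrograms serialize as Newick with
branch lengths as height differences. All randomness flows from a single
integer seed per entry point; the run manifest records seed, thresholds,
tie-break rule and library versions sufficient to reproduce every number
in a bundle.
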