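# Methods

## Scope and data model

The package analyses centroided negative-ion REIMS spectra restricted to
m/z 600–1000, the window containing the glycerophospholipids (GPLs) and
triglycerides (TGs) that distinguish rectal tissue types. A spectrum
carries `patient_id` and `sample_id` because the statistical unit of the
validation is the patient: several spectra per tissue sample and several
samples per patient make spectrum-wise cross-validation leak patient-level
information, which leave-one-patient-out (LOPO) folding avoids.

Binning uses half-open intervals `[low + k·w, low + (k+1)·w)` with
default width w = 0.1 Th (4000 bins). The width is not dictated by the
underlying protocol; 0.1 Th matches time-of-flight peak-position stability
while keeping matrices desk-scale, and it is configurable everywhere. The
upper edge (m/z 1000) is exclusive, so no peak can be double-counted and a
peak at exactly 1000 is discarded. Statistical property checks in the test
suite and parts of the acceptance script run at w = 1 Th (400 bins), a
problem size at which hundreds of model fits complete in seconds; the
pipeline is width-agnostic by construction.

## Quality statistic

The gate statistic is `median(top-20 peak intensities) / median(all
in-range intensities)`, with peaks taken as strict local maxima of the raw
(pre-normalisation) intensity sequence. The peak-picking rule is a package
decision: local maxima are the natural reading for centroided traces, with
a fallback to the 20 largest raw intensities when fewer than 20 maxima
exist (flat or sparse signal). A zero overall median is replaced by the
smallest nonzero intensity so the statistic stays finite. Spectra with a
value strictly below 1500 are excluded; a value exactly equal to 1500 is
kept. Contamination and insufficient-target-tissue exclusions are
metadata flags supplied by the caller — they encode visual/histological
judgements that cannot be computed from a spectrum. In streaming
(in-vivo) mode the gate only warns, because in-vivo signal levels differ
systematically from ex-vivo acquisition.

## Preprocessing

Rows are TIC-normalised (divided by their total ion count) so spectra are
comparable as relative abundances, then transformed by
`x → log10(1 + S·x)` with S = 10⁴. The transform is monotone, maps empty
bins to exactly zero, is approximately linear below 1/S and logarithmic
above it, stabilising the variance of the normalised scale. Centering is
the only further scaling applied before modelling (no Pareto or
unit-variance weighting); the log transform is treated as the variance
treatment.

## OPLS-DA

Classes are one-hot encoded; X and Y are mean-centred. Orthogonal
components are extracted one at a time: a NIPALS pass on the current
(X, Y) gives a loading p; the orthogonal weight is p minus its projection
onto an orthonormal basis of the current XᵀY column span, normalised. The
resulting score t_o = X w_o satisfies Yᵀt_o = 0 *exactly*, so orthogonal
scores are decorrelated from every class indicator up to floating-point
error — this is asserted as an invariant, not just observed. X is deflated
by t_o p_oᵀ and the basis recomputed before the next component. Predictive
components then come from the standard two-block NIPALS recursion on the
filtered X (convergence tolerance 1e-10 on the score vector, at most 500
iterations per component, non-convergence recorded in `fit_meta`).

Defaults are `n_pred = n_classes − 1` and `n_orth = 1`, the common
chemometrics convention; both are configuration options. Multi-class
problems use a single model with one-hot Y rather than one-vs-rest. All
component signs follow a fixed convention (largest-magnitude weight
element positive), making every fit bit-for-bit reproducible.

Classification happens in predictive score space: the pooled within-class
covariance of training scores is regularised by adding
`1e-8 · trace/dim` to the diagonal (guarding the one-component/two-class
degeneracy) and the Mahalanobis distance to each class centroid is
computed; the nearest centroid wins, exact ties breaking lexicographically
by label. Pooled rather than per-class covariance is a package decision:
with as few as 36 spectra in the smallest class, per-class covariances in
score space would be poorly conditioned.

With `n_orth = 0` the predictive scores coincide with plain NIPALS PLS-DA;
the test suite verifies this against scikit-learn's independent NIPALS
implementation to 1e-6 on random instances (the library is used only as a
cross-check, never as the implementation).

## Validation

LOPO-CV refits everything inside each fold — binning, TIC, log, centring
and the model — and predicts every spectrum of the held-out patient. Folds
whose training set retains fewer than two classes are skipped with a
warning. The binary disease (tumour or adenoma) versus no-disease (normal)
task is realised by refitting a dedicated two-class model per fold
(default), or by collapsing three-class predictions post hoc; both are
exposed because summary accuracies of the two variants differ and either
reading is defensible. A sample-level rule calls a tissue sample diseased
iff any of its spectra is predicted diseased, trading specificity for
negative predictive value.

Diagnostic metrics use disease as the positive class and report
percentages; metrics with an empty denominator are NaN (undefined), never
zero. `reconstruct_from_summary` inverts rounded published sensitivity/
specificity plus class totals into integer cell counts with
round-half-to-even; because printed percentages are 1-dp roundings of
integer ratios, the rounded product recovers the exact counts whenever the
printed precision permits, and the reconstructed table then over-determines
accuracy, PPV and NPV as a consistency check.

## Discriminant features

Each bin of the preprocessed matrix gets a one-way fixed-effects ANOVA
across tissue classes (F with (C−1, N−C) degrees of freedom, computed from
between/within sums of squares; zero-variance bins get p = 1), followed by
Benjamini–Hochberg step-up adjustment and a significance cutoff of
adjusted p ≤ 0.05. "Benjamini" is read as Benjamini–Hochberg, the standard
choice absent further qualification. The ANOVA runs on all bins of the
matrix the classifier sees (normalised, logged). Significant bins are
annotated against a three-column lipid mass table within a configurable
tolerance; the shipped table is generated from the synthetic template
library and is explicitly a synthetic stand-in, not measured lipid masses.

## Synthetic cohorts

Template j of tissue class c in a spectrum from patient p has intensity

    I_j = exp(base_j + scale·δ_{j,c} + u_p + ε),   ε ~ N(0, σ_spec)

with a scalar patient effect u_p ~ N(0, σ_pat) and class offsets δ
(tumour offsets ~ N(0, 0.9) on ~35% of templates; adenoma offsets are
0.7× the tumour offset plus noise, making adenoma intermediate and
preferentially confused with tumour). Defaults: σ_pat = 0.3,
σ_spec = 0.45, baseline level 1.0 with 1200 exponential baseline points
scattered uniformly over the axis, `scale = 1`. Peaks are rendered at
centroids jittered by 0.01 Th. The template library is 40 GPL ([650, 850)),
20 TG ([850, 1000)) and 20 other peaks at fixed pseudo-random centroids.

The patient effect is a single scalar — an overall signal-yield shift that
multiplies peaks *and* baseline alike. TIC normalisation therefore removes
it, which is what keeps per-bin tests calibrated on null cohorts
(`scale = 0`): p-values are KS-uniform and the realized false-discovery
proportion at BH 0.05 averages ≈ 0.06 over 50 seeds. The trade-off is
deliberate and documented: a scalar yield effect does not create
patient-specific *profiles*, so on these synthetic cohorts patient-wise
and spectrum-wise cross-validation are of similar difficulty, whereas on
real data LOPO is strictly harder. Passing tests therefore demonstrate
correctness of the machinery, not the size of the patient-effect penalty
on real spectra.

Low-signal acquisitions are injected by attenuating template peaks 1000×
and raising the baseline 10×, then attenuating further until the QC
statistic is below threshold — guaranteeing the gate has true positives.

The study-shaped design reproduces the printed cohort: 47 patients and 77
samples (30 tumour patients with one tumour and one normal sample each, 12
adenoma patients, 5 normal-only patients) yielding 266 spectra
(109/36/121). Per-sample spectrum counts are not published and are
distributed as evenly as the totals allow. Effect sizes were calibrated
once so that binary LOPO accuracy exceeds 90%, then frozen; the realized
values (≈99% binary, ≈94% three-class) are cleaner than real tissue data
because the generator omits isotope envelopes, adducts, chimeric burns and
histology mislabelling.

Known small-sample behaviour: under the null, LOPO accuracy falls *below*
chance for very small cohorts (≈38% at 3 patients/class) because removing
a patient makes their own class's centroid estimate noisier — the familiar
holdout-induced anti-learning artifact. Null-calibration checks therefore
run at 10 patients/class × 4 spectra on a class-balanced two-class design,
where the artifact is within Monte-Carlo error and the majority-class rate
(50%) equals the equal-prior classifier's null accuracy.

## Layer indicator and streaming

The GPL:TG ratio sums TIC-normalised intensity over the GPL window
([650, 850)) and TG window ([850, 1000)); ratio > 2 calls mucosa,
< 0.5 submucosa, between them mixed, a zero TG sum yields a capped ratio
(10⁶) and both-zero an undefined call. Windows and thresholds ship as
configuration defaults calibrated once on the synthetic layer templates
(mucosa ≈ 17, mixed ≈ 1.3, submucosa ≈ 0.3); on real spectra they would
be re-tuned against annotated dissections. Streaming recognition loads a
saved model archive (versioned JSON), processes burns statelessly in
order — so splitting a stream changes nothing but indices — and emits per
burn the class prediction, layer call, SNR flag and a final summary with
class counts and the longest consecutive run of disease calls.

## Reproducibility and problem sizes

Every stochastic component takes an explicit seed; a single global seed
fans out to stage seeds by fixed offsets. The acceptance script runs the
full analysis in well under a minute: study-shaped cohort at 0.1 Th bins
(three LOPO runs over 47 folds), null calibration at 1 Th bins over 20
seeds, 50-seed layer ordering, and a 100-burn stream. The test suite
covers the same ground at the same or smaller sizes in ≈15 s.
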