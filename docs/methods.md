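# Methods

## Measurement model

A scoliotic curve is measured from four or more observer-placed
landmarks: two per candidate endplate. Each endplate line has a signed
tilt θ ∈ (−90°, 90°) with respect to the image horizontal, computed in
image coordinates (origin top-left, y downward, continuous sub-pixel
positions; positive tilt = the endplate descends left-to-right on
screen). Tilt is invariant to swapping the two landmarks and to
uniform scaling. Exactly vertical endplate lines are rejected:
endplates are near-horizontal structures and |tilt| < 90° is a type
invariant.

The end vertebrae are selected automatically as the candidates with
maximum |tilt| in the cranial and caudal lists (ties within 1e-9°
break by listing order, i.e. the observer's selection order). The Cobb
angle is |θ_cranial − θ_caudal| ∈ [0°, 180°), identical to the
classical angle between the perpendiculars to the endplates, and is
rounded half-away-from-zero to one decimal only when the final
`CurveMeasurement` is constructed — never inside intermediate
geometry. The 0.1° quantum reflects the instrument's reporting scale.

When DICOM pixel spacing is anisotropic, landmark coordinates are
scaled to millimetres before tilt computation; the image itself is
never resampled for measurement.

### Viewing transforms

Contrast is standard linear window/level (the radiology default; the
transfer function is clamped, monotone, with half-up rounding of
output levels, so the displayed level maps to mid-grey). Zoom is a
continuous crop-and-magnify with an exact bijective coordinate
mapping; landmarks picked in a zoomed view are stored in source
coordinates, so the only error a zoomed pick can carry is the view's
own quantisation, which shrinks as 1/factor. Neither transform can
alter a measured angle — this measurement/display separation is
asserted by tests as the package's central safety property.

## Reliability pipeline

Error distributions are defined per comparison id over one method's
rows of the study table:

- intra-group `AxAy` (e.g. `E1E2`): per curve, the mean over the
  group's observers of the absolute difference between that observer's
  round-x and round-y angles;
- inter-group `ExNy`: per curve, the absolute difference between the
  expert and novice group means at the named rounds;
- pooled `E`, `N`, `EN`: per curve, the mean of the three pairwise
  round values.

Errors are absolute, not signed: signed round-to-round differences
average near zero by construction and cannot express the 1.7–2.5°
error magnitudes these studies report. MBE is therefore the mean of
absolute per-curve errors (for method agreement, of signed per-curve
method differences, whose near-zero mean is the Bland–Altman bias).

Outlier pruning is a single-pass Tukey-fence filter
(Q1 − 1.5·IQR, Q3 + 1.5·IQR) applied to each comparison's error
distribution — not to raw measurements — so the retained count
`gl = n_curves − removed` matches the per-distribution bookkeeping.
Quartiles use linear interpolation by default; Tukey hinges are
available via `quartile_method="hinges"` since conventions differ
between statistics packages. Normality is screened per distribution
with Shapiro–Wilk at α = 0.05; constant input is reported as a gate
failure with p = NaN rather than an error.

`SE = SD/√gl` and `MDC95 = 1.96·√2·SE`. Note this MDC95 is built on
the standard error of the sample, not on the classical test-retest
`SEM = SD·√(1−ICC)`; the two differ roughly by a factor √gl. The
sample-SE convention is what the summary tables this pipeline mirrors
actually use (their SE and MDC95 columns re-derive from SD and gl
under it), and reports produced here should be read with that
convention in mind.

### ICC(2,1)

Two-way random effects, absolute agreement, single measure, from the
two-way ANOVA mean squares:

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

with the McGraw–Wong F-based 95% CI using Satterthwaite degrees of
freedom. Incomplete matrices are rejected (no silent listwise
deletion). Degenerate cases: a matrix with no error and no column
variance returns CI = (ICC, ICC); when the Satterthwaite approximation
collapses (possible at strongly negative agreement), the affected
bound falls back to the ICC domain limit (−1 or 1) so the CI always
brackets the point estimate. The implementation is cross-checked in
tests against an explicit sums-of-squares oracle (1e-9) and against
pingouin's ICC(A,1) as an independent reference.

ICC rater matrices per comparison (the studies this mirrors never
state them; the report is explicit): intra-group pairwise rows use
curves × 2 group-mean rounds, pooled intra rows curves × 3 group-mean
rounds, inter-group rows curves × 2 group means, and method agreement
curves × 2 method means. Matrices are built from unpruned
measurements, consistent with pruning being an error-distribution
operation.

### Method agreement

Each curve is summarised per method by the mean of all its
measurements (8 observers × 3 rounds = 24 when complete). Bland–Altman
(bias, limits of agreement = bias ± 1.96·SD of the signed differences)
and ICC(2,1) with the two methods as raters run on those paired means;
SEM and MDC95 come from the signed difference distribution after
pruning.

Group-level inference follows the same pattern as the observer
studies: one-way ANOVA with Tukey HSD (family-wise 95%) across the
four pooled intra-group distributions, and an independent two-sample
t-test between the software and manual pooled inter-group
distributions. p-values are reported raw; Tukey supplies the only
multiplicity adjustment.

## Synthetic study generator

The generator emulates a standard absolute-reliability protocol:
35 curves drawn uniformly within six severity strata (9 in 11–20°,
11 in 21–35°, 6 in 36–40°, 4 in 41–50°, 3 in 51–55°, 2 in 56–70°; the
open-ended top class is capped at 70°, configurable), 4 expert + 4
novice observers, 3 rounds, software and manual methods — 1680
measurements, 210 per observer.

Each measurement is `truth + bias(observer, method) +
N(0, σ(group, method))`, rounded to 0.1°, independent across curves,
observers, rounds and methods. Default noise levels are anchored to
published group-level mean absolute round-pair errors through the
folded-normal closed form (E|X₁−X₂| = 2σ/√π for X ~ N(·, σ²)):
σ = MBE·√π/2, giving σ ≈ 1.52° (expert/software), 1.68°
(novice/software), 1.89° (expert/manual), 2.22° (novice/manual).
Observer and method biases default to zero: the studies being
emulated report near-zero method bias, no observer-level components
are published, and zero bias keeps the variance-component prediction
ICC = σ_b²/(σ_b² + σ_w²/4) exact for the group-mean rater matrices
(σ_b² is the analytic variance of the stratified-uniform truth
mixture, ≈ 190 deg²; the /4 reflects 4-observer averaging).

What the generator does **not** emulate: observer-specific systematic
bias (real inter-group errors are partly systematic, so simulated
inter-group MBEs run lower than published ones at the same noise
levels), learning or fatigue across rounds, heteroscedastic noise
growing with curve severity, correlated errors from shared end-vertebra
mis-selection, and gross recording blunders (real outliers are often
transcription errors; simulated ones are just Gaussian tails, which is
why simulated removal fractions — a small percentage — only
distributionally resemble reported ones). Passing tests therefore
validate the pipeline's arithmetic and its estimator behaviour under a
clean generative model, not the field error structure of human
observers.

Phantom radiographs render tilted bright rectangles (16-bit,
background 0, body ~3000, optional Gaussian mottle) with exact corner
landmarks, written as standard DICOM; re-picking landmarks from
rendered pixels recovers the prescribed Cobb angle to <1° at ≥200 px
endplate width, and the exact landmarks recover it to the 0.1°
rounding quantum.

## Determinism and problem sizes

All randomness flows through one `numpy` Generator per run, seeded
from a single master seed; a fixed seed makes the entire study table
byte-stable. Monte-Carlo checks use 200 replicate studies for the
variance-component recovery (3 Monte-Carlo-SE tolerance), 1000 random
matrices for the ICC oracle equivalence, and 8 replicates per size for
the MDC95 ∝ 1/√n scaling check over n ∈ {10, 35, 100} — sizes at
which each check's sampling error is far below the effect it measures.

## Known limitations

- The CI construction for ICC(2,1) is asymptotic and fragile for
  strongly negative agreement (see fallback above); negative-ICC data
  is outside the intended use (agreement studies).
- `cobb_between` returns |Δtilt| ∈ [0°, 180°), which equals the
  perpendicular construction for all realistic curves; it is
  rotation-invariant only while both endplates stay within the
  near-horizontal domain, which the endplate type enforces.
- The session schema stores landmarks, not pixels; there is no
  automatic vertebra detection, by design — landmark placement is the
  human contribution the reliability analysis quantifies.
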