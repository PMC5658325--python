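# Methods

## The measurement model

A competitive lateral-flow strip for 25(OH)D₃ produces two colorimetric
lines whose darkness is read densitometrically. The control line verifies
flow and conjugate activity; the test line carries the analyte-dependent
signal, which *decreases* with concentration because sample analyte blocks
the conjugate's binding sites. The readout is

T/C = depth(test) / depth(control),

where *depth* is the baseline-relative darkening of each line trough on the
1-D intensity profile, **not** the raw pixel minimum. This choice is forced
by the physics of the readout: pixel intensities are bounded in [0, 1], so
ratios of raw trough values can never much exceed 1, yet a competitive
assay at zero analyte legitimately reads T/C ≈ 4–6 (the fitted intercepts
of the modeled assay are 3.98 in buffer and 5.69 in serum). Ratios of
background-subtracted depths reproduce those values naturally and make the
statistic invariant to global intensity offset and to exposure scaling.

## Signal extraction

The chain is fixed as: crop (registration-based ROI from config; the
cassette locates the strip, the software does not search for it) →
grayscale (BT.601 weights 0.299/0.587/0.114) → 2-D Gaussian denoise
(reflective boundaries) → per-column median across the strip width →
running 1-D median along the flow axis → line detection → ratio.

Lines are local minima with topographic prominence ≥ `min_prominence`; of
the qualifying minima, the pair whose separation is within ±25% of the
configured expectation and whose summed prominence is largest is retained,
the upstream member being the test line (a flag flips this for mirrored
optics). A lone qualifying minimum is resolved by a rule that exploits the
assay logic: the control line must always develop, while the test line may
honestly vanish at high analyte. So a single peak with room for a test line
upstream at the expected separation is treated as the control; the test
depth is then measured in its expected window and flagged `weak_test`
(T/C → 0). A single peak *without* such room means the control region
produced nothing: the strip failed, and a missing-control error is raised.

**Baseline.** Each line's background is estimated locally: the median of
the profile over the annulus 1.5–3 line-widths away on each side of the
peak (excluding both line windows), averaged over the two sides. The
symmetric average cancels a linear illumination gradient exactly — a single
global out-of-window median, the obvious alternative, leaves a bias of
roughly `slope × (distance between line and profile center)`, which we
measured at ~3% of T/C under a 0.003 intensity/mm gradient. The per-side
median keeps robustness to speckle. Offset and scale invariance of T/C are
preserved.

Defaults (all config-exposed; none are assay intrinsics): Gaussian σ = 2 px,
median window = 5 px, prominence floor = 0.02 intensity units, expected
separation 80 px at 20 px/mm, minimum acceptable control depth 0.01. They
were chosen to pass the noiseless simulator round trip with wide margins
and are expected to need retuning per reader hardware.

## Calibration

Two families, one shared forward implementation used by both the fitting
code and the simulator:

- linear `tc = a·x + b`, fit by ordinary least squares (`numpy.polyfit`);
  `a < 0` for this assay. The working range is narrow enough in serum and
  blood that the published device calibrations are linear.
- four-parameter logistic `tc = d + (a−d)/(1+(x/c)^b)` with upper asymptote
  `a` (T/C at zero analyte), lower asymptote `d`, inflection `c` (nmol/L)
  and slope exponent `b`; decreasing and uniquely invertible on `(d, a)`
  when `a > d, b > 0`. Fit by bounded nonlinear least squares
  (`scipy.optimize.least_squares`) with `a₀ = max(tc)`, `d₀ = min(tc)`,
  `c₀ = median(conc)`, `b₀ = 1`, bounds `b, c > 0`, and tight (1e-12)
  tolerances; non-convergence or a degenerate solution (e.g. straight-line
  input) is surfaced through the `converged` diagnostic, never as an
  exception or a silent success.

Inversion is closed-form: `x = (tc − b)/a` and
`x = c·((a−d)/(tc−d) − 1)^{1/b}`. A T/C outside the invertible range yields
a **censored** estimate (`<0` below the range, `>upper-limit` above it)
rather than an error, matching clinical "< LoQ" reporting; classification
consumes censored values when the limit is decisive and returns
*indeterminate* otherwise. The forward/inverse pair is an identity to 1e-9
relative over the quantifiable range; below ~0.5 nmol/L on the 4PL the T/C
sits within ~1e-9 of the upper asymptote and double precision cannot
express the identity (the subtraction `tc − d` has lost the digits), so
the package makes no accuracy claim there.

Replicate handling: strips are run in duplicate per level; the default
fitting mode averages replicates per concentration (per-strip mode is
available). Weighted (1/y²) least squares is available by config but off by
default. Precision is reported as the per-level coefficient of variation,
100·sd/mean with n−1 sd.

The canonical serum-calibrator design
(`calibration.SERUM_CALIBRATOR_LEVELS`: 0, 10, 20, 30, 42.5, 55, 70, 85,
100, 125, 150 nmol/L, two strips per level) places half its levels at or
below ~55 nmol/L because a competitive curve with inflection near 26 nmol/L
carries most of its Fisher information there. Under 5% replicate CV this
design recovers the inflection within 15% in ≥ 90% of seeded simulations;
an evenly spaced 8-level design does not (~85–88%), which is why the denser
panel is the package default.

## The simulator

`render_strip` draws the cassette window: uniform background (default 0.85)
plus an optional linear illumination gradient, minus two line troughs
modeled as rectangles (1 mm wide) convolved with a Gaussian (σ = 0.1 mm)
— reproducing the smooth minima of real intensity plots without asserting
any reagent-spreading physics — plus i.i.d. Gaussian pixel noise, clipped
to [0, 1]. The test trough depth is `control_depth × tc_ratio_true`
(default control depth 0.12), encoding the competitive polarity. The
printed strip layout is followed: 25 mm membrane, 1 mm lines "separated by
3 mm", read here as edge-to-edge and hence 4 mm center-to-center
(`line_separation_mm` is configurable for the other reading). Resolution
defaults to 20 px/mm with a 60-px strip width — an uncalibrated but
plausible figure for a 5 MP close-focus camera; neither resolution, line
contrast, nor noise level is published for the real reader, so all are free
parameters. A parameter set whose noiseless troughs would clip at 0 is
refused rather than rendered: a saturated strip is unquantifiable and would
silently corrupt round-trip statistics.

`simulate_cohort` draws concentrations from a configurable sampler
(uniform / truncated-normal / lognormal / grid), maps them through a
calibration model, and perturbs the T/C multiplicatively by a Gaussian with
relative sd `replicate_cv` (the published assay's CVs range from ~0.05% to
~17% depending on level and matrix; cohort defaults use the 5–10% middle of
that range). Fixed seeds give bit-identical images and cohorts.

**What the simulator does not emulate** — and hence what passing round-trip
tests do not establish about real strips: membrane texture and wicking
nonuniformity, curved or vignetted illumination, line-shape asymmetry and
batch drift, chemical cross-reactivity, and matrix effects. The simulator
validates the *software* chain, not the assay chemistry.

**Bit depth.** All internal math is float in [0, 1]; quantization happens
only at export (8-bit PNG, 16-bit TIFF). On the flat high-concentration
tail of the 4PL the dose-response slope is ~1e-3 T/C per nmol/L, so even
the 1/255 quantization step of 8-bit export costs several nmol/L there;
sub-0.5 nmol/L end-to-end round trips therefore require 16-bit export,
which the tests use. PNG stays the CLI default because real 8-bit reader
output is the realistic case.

## Evaluation statistics

The AUC is the tie-corrected Mann–Whitney statistic; its variance is
DeLong's structural-components estimator (sample variances of the
per-subject placement values, scaled by class sizes) with a normal 95% CI
truncated to [0, 1]. The empirical ROC groups tied scores into single
vertices so its trapezoidal area equals the tie-corrected statistic
identically. A stratified bootstrap (resampling within class, percentile
CI) is provided alongside the closed form because iteration-count-based
AUC reporting is common for this assay class and the two interpretations
cannot be reconciled; reports label both. ROC scores default to the negated
predicted concentration (lower concentration ⇒ more deficient ⇒ positive
class) and can be switched to raw T/C.

Diagnostic accuracy is correctly-classified over total, carried as an exact
rational alongside the percentage. RMSE is in nmol/L. `binormal_scores`
generates validation cohorts with a known generative AUC via the
equal-variance binormal identity AUC = Φ(Δμ/√2).

## Problem sizes in the test suite

Simulation-backed tests use: 20-strip noiseless round-trip grids; 500-fit
Monte Carlo for 4PL recovery; 1000-member cohorts for CV recovery; 5000
pairs for RMSE recovery; 25 cohorts of n = 200 for binormal AUC recovery;
200 random cohorts (n ≤ 50) for the exact DeLong-versus-pair-counting
check. These sizes put Monte-Carlo standard errors well inside the asserted
brackets while keeping the full suite in seconds.

## Known limitations

- Line detection assumes exactly two lines at a known separation; cassettes
  with additional reference marks need the ROI to exclude them.
- The censored-above estimate uses the calibration's recorded concentration
  range as its reporting limit; a model saved without a range yields an
  unbounded (indeterminate for classification) censored result.
- The 4PL fit is unweighted by default; strongly heteroscedastic data may
  prefer the 1/y² option, though on the canonical design it did not improve
  inflection recovery.
- Boundary classification (exactly 50 or 75 nmol/L → insufficient) follows
  the strict reading of the guideline wording; the constants are
  config-overridable where a different convention is in force.
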