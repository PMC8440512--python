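# Methods

This note documents the models and procedures implemented in `animakin`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and the limits of what the synthetic tests show.

## Recording model and quality control

A recording holds per-frame centroid positions (pixels) and rotation
angles (degrees in [0, 360)) for the red and blue triangles, a frame rate
(nominal 133 Hz), a canvas size, a word label and animator/animation ids.
Timestamps must be strictly increasing and positions must lie on the
canvas; violations are reported with the offending frame index.

Quality control operationalizes a screen that was originally visual, as a
deterministic rule: a recording passes when (a) its duration is at least
`min_duration_s` (default 22.5 s, half the 45 s task window) and (b) the
union of canvas quadrants visited by the two triangles' centroids exceeds
`min_quadrants` (default 2 of the 4 equal quadrants). Boundary points are
assigned to the lower-index (left/top) quadrant. The decision depends only
on the visited-quadrant set and the duration, so it is invariant to
uniform time shifts. The 22.5 s default is this package's stand-in for
"sufficient length", not an empirically derived rule.

## Smooth differentiation

Speed, acceleration and jerk require first, second and third derivatives
of noisy positional data; naive differencing multiplies the noise at each
step. Each differentiation applies an antisymmetric FIR kernel. The
default is the Savitzky–Golay first-derivative kernel of window 11 and
polynomial order 3 (`scipy.signal.savgol_coeffs(11, 3, deriv=1)`, sign
adjusted so the first moment is +1). Any kernel satisfying the contract —
antisymmetry (exact zero on constants, hence on any uniform offset) and
unit first moment (exact derivatives of polynomials up to the design
order in the interior) — can be supplied via `DifferentiatorSpec`. Edges
are handled by replicating the boundary samples, which biases edge
derivative estimates toward zero; each pass contaminates `half_width`
samples per end, so consumers that need clean interior values (the AFSD
stage) trim `2 * half_width` samples per end.

Derivatives are computed per frame index and converted to physical units
by `frame_rate**k * px_to_mm` for the k-th derivative. The default pixel
pitch 0.2475 mm/px is the WACOM Cintiq 22HD active width (475.2 mm) over
its 1920-px horizontal resolution; it is configurable.

Means are taken over frames first, then averaged across the two
triangles. The simultaneous-movement proportion applies its 0.01
threshold to raw speeds in pixels/frame, before unit conversion, as the
defining formula is written in raw speed units. Mean rotation uses the
minimal signed circular difference of successive angles (a step from 359°
to 1° contributes 2°); the default is the unweighted mean of the two
triangles' values, with a movement-weighted variant behind a flag because
the verbal description and the printed formula of this quantity disagree.

## Angular-frequency spectral density

Per triangle: velocities from the smooth filter give the tangent angle
phi = atan2(vy, vx); its filtered derivative is the angular rate, and
|dphi|/v is the absolute instantaneous curvature. Frames are retained as
"curved movement" when speed > 0.01 px/frame and |dphi| > 1e-4 rad/frame;
stationary and straight segments carry no curvature signal and are
excluded. The retained fraction is the triangle's curved-movement weight.
theta is the cumulative unsigned angular displacement over retained
frames; a trajectory must span at least 2*pi of theta (one full tracing)
to be analyzable, and fewer than 32 curved frames raises a degeneracy
error.

Log speed is linearly interpolated onto 4096 uniform theta samples. A
second-order polynomial trend is removed — this both removes slow drift
(e.g. fatigue) and closes the endpoints for the FFT. The one-sided FFT
amplitude spectrum (2|X_k|/N) is indexed by angular frequency
nu_k = 2*pi*k / span(theta), i.e. cycles per full tracing, linearly
interpolated onto the fixed grid of 1001 uniform points on [0.02, 10],
and normalized to unit trapezoidal area. A detrended signal with standard
deviation below 1e-4 (the level of numerical-differentiation noise in
log-speed units) is flagged degenerate and replaced by the uniform
unit-area density; degenerate spectra carry zero weight in combination
and should be excluded from group tests. Because a multiplicative speed
change adds a constant to log speed, which the detrend removes, the
spectrum is invariant to overall speed scale.

Red and blue densities are combined as a weighted mean with the
curved-movement weights (preserving unit area), and summarized as
trapezoidal areas in nine fixed bins — 0.21–1.49, 1.61–2.39, 2.64–2.87,
3.04–3.40, 3.91–4.27, 4.79–5.19, 6.19–6.68, 7.6–7.93, 8.75–10 — with bin
edges interior to grid cells handled by linear interpolation. The bins do
not tile the grid, so the nine areas sum to less than 1.

"One-sided amplitude spectrum of the real detrended signal" is this
package's reading of an asymmetrical FFT; interpolation is linear and no
window is applied. These are pinned choices, tested by tolerance-based
properties (planted frequency recovered within ±0.15 for nu in 1..9), not
bit-level contracts.

## Cluster-corrected F-test

Group differences in spectral density across the five words are tested
pointwise with the one-way F statistic at each grid point. Points
exceeding the pointwise critical value F(1-alpha; k-1, N-k) form maximal
contiguous candidate clusters; the cluster statistic is the cluster mass
(sum of F over the run; extent is available as an option). The null
reference is the distribution of the maximal cluster statistic over
`n_boot` label resamples — permutation by default (exact exchangeability
under the null), bootstrap resampling with replacement behind a flag. A
cluster's p-value uses the add-one correction (1 + #{null >= stat}) /
(1 + n_boot), which makes the test slightly conservative and valid at
finite `n_boot`; significance is p <= alpha. Fixed seeds give
bit-identical results. Calibration measured here: over 200 exchangeable
five-group datasets (20 spectra per group, 101-point grid, 500 resamples)
the family-wise rate of reporting any significant cluster is ~4–6%,
within binomial error of the nominal 5%.

## Scoring and preprocessing

Accuracy = target rating − mean of the four non-target ratings, in
[−9, 9] on 1–10 scales and invariant to permutation of the non-targets.
Similarity differences are |stimulus − observer production| on raw
(untransformed) feature means; the difference column is then preprocessed
like any predictor. Preprocessing order per column: optional log or sqrt
transform (an automated rule proposes log for skew > 1 and strictly
positive, sqrt for skew > 1 and non-negative), winsorization at
median ± 3 × (1.4826 × MAD) — the normal-consistent scaled MAD, constant
configurable — then z-scoring on the pooled analysis sample without
stratification. Winsorization is idempotent (the clipped output yields
the same bounds) and every step is recorded in per-column provenance.

## Hierarchical Bayesian regression

The confirmatory model regresses accuracy on z-scored jerk, z-scored jerk
difference, the mental-state factor and all interactions up to the
three-way term. The mental condition is the reference level, so the
`nonmental` dummy is the mental-vs-non-mental contrast and plain slopes
are mental-condition effects; the net non-mental jerk slope is the sum of
the reference slope and the interaction offset (with the package's
generative defaults, −1.03 + 1.65 = 0.62). Random structure: intercepts
for subject and animation, slopes for jerk and jerk × non-mental by
animation and for jerk difference by subject, each as an independent
variance component (no random-effect correlations — a simplification of a
fully maximal structure, chosen because independent components keep every
conditional conjugate).

Inference is by a blocked Gibbs sampler: the model is a Gaussian linear
mixed model with normal(0, 10) coefficient priors and inverse-gamma(0.5,
0.5) priors on the residual and random-effect variances, so all
conditionals are exact draws (fixed-effect block, per-group random
effects, variances). Defaults: 4 chains × 5000 iterations including 1000
warmup. Reported per fixed effect: posterior mean, central 95% credible
interval, P(coef > 0), and split-R-hat (via arviz); a fit with any R-hat
above 1.05 is flagged unconverged rather than raising. The sampler has no
accept/reject step, so the divergence count is structurally zero and is
reported for interface completeness. Parameter recovery is verified
against synthetic studies with known coefficients (95% CrI coverage
compatible with nominal across seeded replicates) and cross-checked
against REML point estimates from `statsmodels` MixedLM on matching
designs.

The two similarity models (acceleration difference + rotation difference,
and rotation difference + jerk difference, each with the mental-state
interactions and subject/animation intercepts) are fitted the same way;
a variance-inflation-factor report for the full difference-score set is
emitted alongside, since acceleration and jerk differences are typically
near-collinear and motivate the model split.

## Shadow-feature selection and the final forest

Because the forest stage cannot model random effects, trial rows are
averaged per animation (items-based analysis) and observer-relative
difference scores are dropped. Selection then follows the shadow-feature
scheme: each round appends a permuted copy of every feature, fits a
random-forest regressor (500 trees, 10 candidate variables per split by
default; scikit-learn backend), and computes permutation importances
(5 repeats). A feature scores a hit when its importance exceeds the
maximal shadow importance; a two-sided binomial test of hits against
chance at p < 0.01 classifies features as confirmed or rejected, with
undecided features tentative after `max_rounds` (default 100; the
procedure stops early once all features are decided). Shadow features are
never confirmed — they exist only as the null reference. Per-feature
permutation streams are keyed by feature name, so decisions do not depend
on column order. The final forest is trained on a 70% split of the items
and evaluated by held-out R² plus the regression p-value of predicted vs
observed.

## Synthetic data

`gen_pure_frequency_trajectory` inverts the AFSD construction: the
tangent angle advances uniformly through `tracings` full turns (default
10 per 45 s) while speed is `base_speed * exp(sum_i A_i sin(nu_i theta +
phi_i))`, positions are integrated, optionally jittered with Gaussian
positional noise, and scaled isotropically into the canvas (isotropic
scaling only shifts log speed, which the detrend removes). Planted
frequencies are recovered by the spectral pipeline within ±0.15.

`gen_study` emulates the study design: animators (default 51) produce one
45 s, 133 Hz recording per word with word-conditioned trajectory
parameters (fighting fast/jerky with high-frequency content, following
slow and low-frequency, seducing elliptical, surprising pentagon-band,
mocking intermediate) and per-person lognormal speed/amplitude
variability; observers (default 37) produce their own animations and each
rate eight exemplars per word, one drawn from each of eight speed
percentile bins of the word's stimulus pool. Latent trial accuracy is
X·beta + subject intercept + item intercept + residual, with X built from
the z-scored stimulus jerk, z-scored observer-animator jerk difference
and the non-mental dummy exactly as the analysis constructs it. The
generative coefficient defaults (jerk −1.03 in the mental reference
condition, +1.65 interaction offset, −0.38 jerk difference, +2.54
non-mental; subject/item SD 0.5, residual SD 1) mirror the qualitative
structure the task exhibits. Ratings encode the latent accuracy as
target = clip(5 + accuracy, 1, 10) with near-constant non-target ratings
(SD 0.1), so the accuracy score recovers the latent value up to clipping;
the clipping rate and all effects are recorded in the ground-truth
record. This additive-Gaussian-with-clipping rating model is an invented
stand-in for human rating behaviour — its parameters are exposed, not
estimated.

`gen_null_spectra` draws exchangeable five-group unit-area spectra as
`exp` of smooth random Fourier series with 1/k-decaying harmonics, for
calibrating the cluster test.

What the synthetic data do not emulate: goal-directed interaction between
the two triangles, intentional structure, pauses and hesitations, touch
artifacts, or realistic rating responses. Passing tests therefore
demonstrate correctness of the measurement and inference machinery under
known generative structure, not validity of scientific conclusions on
human data.

## Problem sizes and determinism

The test suite and the acceptance script run reduced problem sizes chosen
to exercise the full code paths at comfortable desk scale: recovery tests
use 8 s recordings, 12-animator/40-observer cohorts and 2 × 1500-iteration
chains; calibration uses 100–200 null datasets of 5 × 20 spectra on a
101-point grid with 300–500 resamples; forest tests use 100–300 trees.
Full-scale defaults (45 s, 133 Hz, 51/37 cohorts, 4 × 5000 chains, 500
trees, 1000 resamples) remain the package defaults. All stochastic
components accept seeds and are bit-reproducible given one.
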