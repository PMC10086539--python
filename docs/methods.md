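# Methods

This note documents the models, numerical choices, and known limitations of
`strikelab`. It is written for a user deciding whether the pipeline's
assumptions fit their data, and for a maintainer wondering why a default is
what it is.

## The measurement model

A trial couples two instruments. The force plate reports the force the
animal exerts on the platform, sampled at `force_rate` (default 1 kHz) in
the sensor frame (Fx, Fy horizontal; Fz vertical). The overhead camera
yields digitized head and tail coordinates at `video_rate` (default
500 Hz) in pixels, converted to meters by a fixed `scale_m_per_px`. The
camera's trigger pulse is recorded in the force stream; its sample index
(`trigger_force_sample`) defines a common clock with t = 0 at the trigger
and video frame 0 aligned to it. Synchronization only relabels timestamps;
no signal is resampled.

All strike variables are computed in the strike-aligned frame. The strike
direction θ is the direction of net head travel over the first
`n_frames_direction` (default 10) video frames after onset; both the
sensor and digitization axes are rotated by θ with the planar rotation

    x' =  x cos θ + y sin θ
    y' = -x sin θ + y cos θ

so the strike direction maps to +x′ (fore–aft), y′ is lateral, and the
vertical channel is untouched. The direction is measured on the smoothed
head path rather than the raw digitized points: the 10-frame displacement
is only a few millimeters, and at realistic digitization noise (~0.5 mm
per coordinate) the raw two-point estimate has ~0.2 rad of error versus
~0.04 rad for the smoothed one. The sensor and camera frames are assumed
co-registered up to a fixed, known rotation (`sensor_camera_rotation`,
default 0), which is folded into the force rotation only.

Sign conventions: fore–aft force is positive in the propulsive sense (the
ground pushing the snake along the strike direction); the slip ratio uses
its magnitude. Tail displacement is signed, negative meaning rearward
recoil; its reported "maximum" is the extremum of largest magnitude with
the sign kept.

## Smoothing and differentiation

Every channel is fitted with a cubic smoothing spline and differentiated
analytically; finite differences of raw samples are never used. Splines
rather than a Butterworth filter because a strike is a non-cyclic
transient: forward–backward filtering assumes quasi-periodic context and
rings at the record ends, exactly where the strike sits.

The smoothing parameter λ matters more than any other number in the
pipeline, because the measurands are extrema of first and second
derivatives. With `lam=None` (the default) λ is chosen per channel by the
discrepancy principle: the noise SD is estimated from robust second
differences (median absolute deviation of y_{i+1} − 2y_i + y_{i−1},
scaled by √6 — insensitive to the brief transient because most of the
record is quiescent), and λ is solved (Brent's method on log λ) so that
the fit's residual RMS equals that estimate. A record whose noise
estimate is effectively zero is interpolated. Generalized
cross-validation was evaluated for this role and rejected: on
quiescent-plus-transient records scipy's GCV systematically over-smooths
(on noiseless test kinematics it left a 0.64 mm residual, biasing peak
velocity by −2 %, peak acceleration by −9 %, and onset by −6 ms; on noisy
force channels it left a residual 25× the true noise, flattening the
force peak). Any channel's λ can be fixed explicitly via the
`lam_force` / `lam_kin` configuration fields.

## Event detection

The strike window is defined on the fore–aft head-velocity signal,
evaluated from the kinematic spline on a 1 kHz grid.

*Onset*: first time v exceeds max(5 % of its global peak, 0.05 m s⁻¹) and
stays above for ≥ 10 ms, backtracked along the rising edge to the most
recent local minimum or non-positive sample. Records whose peak velocity
is below 0.1 m s⁻¹ raise a "no strike detected" error. All four thresholds
are configuration fields.

*End of forward progress*: first non-positive velocity after the
post-onset peak, with the crossing linearly interpolated.

Both estimates are then refined by a quadratic-root extrapolation at the
10 %-of-peak crossing: a strike-like velocity profile leaves and rejoins
zero tangentially (locally v ≈ k(t − t₀)²), so t₀ = t_c − 2v(t_c)/v̇(t_c)
recovers the true root from a point on the edge where smoothing bias is
small. The refinement is guarded (max with the backtracked onset, min with
the interpolated end crossing) so that steep, non-tangential edges — where
the plain crossing is already right — are unaffected. Without the
refinement, smoothing smear biased onset ~3 ms early and the end ~3 ms
late at realistic noise; with it, noiseless windows are recovered to
within 2 ms and noisy ones to within 10 ms in 99 % of seeded replicates.

## Strike variables

"Maximum" follows peak semantics: the largest interior local maximum of
the smoothed channel inside the window (`scipy.signal.find_peaks`),
falling back to the window maximum with a flag when no interior peak
exists. Force maxima are taken from the splined channels on the 1 kHz
window grid; total force is the per-sample vector norm √(F_FA² + F_lat² +
F_V²), so its maximum dominates every component's by construction.

Vertical force is not tared by default — reported vertical maxima include
the resting body weight, which is how whole-animal vertical loadings in
the 1.5–1.7 BW range arise. `tare_vertical` subtracts the pre-onset mean
when a dynamic-only reading is wanted.

The FA/V ratio is computed per sample as |F_FA|/F_V; samples with F_V
below 0.05 BW are excluded from both the numerator and denominator of the
slip percentage and counted in a flag, because the ratio is numerically
meaningless near zero vertical load. The slip percentage is the share of
remaining window samples with ratio > µ.

The fore–aft impulse is the trapezoidal integral of the *raw* (unsmoothed)
fore–aft channel over the window — trapezoidal integration is already a
noise-averaging operation, and integrating the raw samples keeps the
impulse independent of the smoothing choice. Fractional window endpoints
are handled by integrating the piecewise-linear interpolant exactly, which
makes impulses additive over adjacent windows to rounding error.

## Momentum budget

The continuous animal is reduced to two point masses: a "head" carrying
`head_fraction` of total mass moving with the head marker, and a "tail"
carrying the rest moving with the tail marker. Over a window [a, b] the
budget is

    residual = m_h Δv_h + m_t Δv_t − ∫ F_FA dt ,

with velocities from the kinematic splines and the impulse integrated
exactly from the force spline. The residual is always reported: it is the
model error of the two-mass reduction (plus any trunk–substrate friction),
not a quantity to be hidden. By default the budget window is the
momentum-delivery phase, onset to peak head velocity — over the full
strike window the head starts and ends at rest and the budget degenerates
to 0 ≈ 0. The tail-momentum fraction −m_tΔv_t / (m_hΔv_h) classifies the
strike as ground-dominated (< 0.25), tail-dominated (> 0.75), or mixed;
the cut-offs are arguments. There is no accepted anatomical head/tail
mass split for a two-point reduction of a snake; the split is therefore a
required, explicit input (the CLI flag `--momentum-split h:t`), defaulting
nowhere.

## The synthetic-trial generator

The generator exists so that every pipeline stage has an oracle. It
emulates the trial structure above with a mechanistic model and, for
calibration, a direct-profile mode.

*Mechanistic mode* (`generate_two_mass_trial`): the head mass follows a
minimum-jerk trajectory x(τ) = D(10τ³ − 15τ⁴ + 6τ⁵), τ = t/T, along a
configurable azimuth. Minimum-jerk was chosen for its closed-form extrema
— peak speed 1.875·D/T, peak acceleration (10/√3)·D/T² ≈ 5.7735·D/T² —
which turn recovery tests into exact arithmetic. The horizontal plate
force is the total horizontal momentum rate F_FA = m_h a_h + m_t a_t.
In the walled setup the tail is stationary (a_t = 0). In the open setup
the tail acceleration is solved per sample as the minimal rearward recoil
that keeps |F_FA| ≤ (1 − `slip_margin`)·µ·F_V — the inertial-appendage
strategy in its simplest form. The margin (default 2 %) keeps the capped
ratio strictly below threshold so that sensor noise only rarely carries
samples across it; with no margin the ratio sits exactly at µ and noise
flips essentially a fair coin per sample. A configurable plausibility
bound on tail acceleration (default 500 m s⁻², roughly five head-peak
accelerations) turns physically absurd cap demands into an explicit
infeasibility error naming the binding sample. Vertical force is m·g plus
a half-sine overshoot (default peak 0.5 BW), so vertical maxima land near
1.5 BW as in whole-animal strike recordings.

Default scenario: D = 0.21 m, T = 0.118 s, mass 0.586 kg, µ = 0.30,
head mass fraction 0.3, giving peak head speed 3.34 m s⁻¹ and peak
acceleration 87 m s⁻² — typical published strike magnitudes. Published
mean strike distance, duration, and peak speed are not mutually consistent
under a min-jerk profile (real strikes end at prey contact, not at a
symmetric velocity return); the default favors realistic speed and
acceleration, and duration-calibration runs set T explicitly. The
head-mass fraction has no measured value for these animals; 0.3 is a
configurable assumption. Noise is additive i.i.d. Gaussian — 0.01 N per
force channel (sensor resolution scale) and 0.5 mm per digitized
coordinate (~1 px at the emulated overhead-camera scale). Real sensor
noise is mildly autocorrelated and digitization errors are heavier-tailed;
nothing in the pipeline depends on the noise being exactly Gaussian, but
passing recovery tests here does not certify behavior under, e.g.,
marker-swap digitization blunders, out-of-plane head motion, or platform
resonance, none of which the generator emulates.

*Direct-profile mode* (`generate_direct_profile_trial`): per-axis force
profiles are named closed forms (half-sine, trapezoid, piecewise-constant,
constant) with stated amplitudes and supports, so peak forces, impulses
(half-sine: 2F₀T/π), and slip fractions are exact by construction rather
than emergent. This is the mode used to calibrate recovery against
published summary values.

*Cohort mode* (`generate_cohort`): per-trial metric values drawn from the
two-factor mixed model (grand mean ± setup effect/2 + individual random
effect + setup×individual interaction + residual), used to calibrate the
statistics layer at the study's design size (4 individuals, ~6 trials per
setup cell).

Determinism: all randomness flows through one seeded generator per trial;
identical scenario + seed reproduces traces bit for bit, and the
`simulate → run → stats` CLI chain is byte-reproducible under a fixed
seed.

## Statistics

Each variable is analyzed with the classical two-factor mixed-model
ANOVA: setup fixed, individual and setup×individual random, replicate
trials within cells. For balanced data the expected-mean-squares rules
give F_setup = MS_setup/MS_interaction on (1, b−1) df and
F_interaction = MS_interaction/MS_error; the random individual effect is
also tested against MS_interaction (the unrestricted-model convention,
matching what REML fitters report for balanced designs). Mildly
unbalanced designs fall back to the unweighted-means approximation (cell
means, harmonic-mean cell size); results then carry `balanced=False` and
should be treated as approximate — strongly unbalanced designs deserve a
dedicated REML fit outside this package. Cells with fewer than two trials
are an error, not a silent df adjustment.

Variance homogeneity uses the Brown–Forsythe variant of Levene's test
(one-way ANOVA on |y − group median|), delegated to
`scipy.stats.levene(center="median")`. Because "greater variation in one
setup than the other" admits two groupings, both are reported: setups
pooled across individuals, and all setup×individual cells. Note the
cells variant degenerates (infinite F) when every cell has exactly two
observations, since |y − median| is then identical within each cell.

Multiplicity is controlled per family (each test type across variables)
with the Holm step-down procedure via
`statsmodels.stats.multitest.multipletests(method="holm")`: sort the m
p-values ascending, reject while p_(i) ≤ α/(m − i + 1), adjusted
p-values are the running maximum of (m − i + 1)·p_(i) capped at 1. Holm
always rejects a superset of Bonferroni and a subset of the uncorrected
tests.

Monte-Carlo calibration (in the test suite): under the null at the design
size, both the ANOVA setup test and Brown–Forsythe reject at 4–5 % at
α = 0.05 over 1000 replicates, and the null p-value distribution passes a
Kolmogorov–Smirnov uniformity check.

## Problem sizes

Tests and the acceptance script run single trials of ~0.5 s of record
(≈ 520 force samples, 260 video frames), 500-replicate event-detection
and 1000-replicate statistical calibrations, and a 2-individual × 2-trial
CLI round trip; the full suite completes in about a minute on one core.
These sizes were chosen as the smallest at which the calibrated quantities
are grid-resolved (e.g., the slip-percentage construction uses a
10 000-sample window so the target fraction is representable exactly).

## Known limitations

- Two point masses cannot represent momentum carried by the mid-body or
  shed through trunk–substrate friction; the budget residual absorbs both.
- 2D dorsal-view kinematics only; vertical head motion is invisible and
  would inflate apparent accelerations if present.
- The FA/V slip criterion is quasi-static Coulomb friction; no stick–slip
  dynamics, no torque/center-of-pressure analysis (torques are parsed but
  unused).
- The unbalanced-ANOVA path is an approximation, not Satterthwaite/REML.
- Pixel scale is a trusted input; there is no camera calibration or DLT
  reconstruction.
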