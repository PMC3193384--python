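# Methods

## Model

All estimators assume the ideally spoiled steady state: transverse
magnetization is destroyed before each excitation, so the signal obeys the
Ernst equation S(α) = A sin α (1−E1)/(1−E1 cos α) with E1 = exp(−TR/T1).
The amplitude A is the fully relaxed 90° signal at the given echo time; it
absorbs proton density, coil sensitivity and T2* decay, so nothing in the
package attempts to separate those factors.

The half-angle tangent τ = 2 tan(α/2) and the hyperbolic relaxation term
ρ1 = 2 tanh(TR/2T1) = 2(1−E1)/(1+E1) are exact bijections of their open
domains, fixed jointly by three requirements: the transformed signal is the
rational function 2Aρ1τ/(τ²+2ρ1); the linear display y = S/τ vs x = S·τ has
y-intercept A and slope −1/(2ρ1); and both variables conform to α (radians)
and TR/T1 respectively with third-order error, so small-angle/short-TR
intuition carries over (τ exceeds α by 4.1% at 40°; ρ1 deviates from
TR/T1 by a relative (TR/T1)²/12).  Public interfaces take degrees and seconds;
radians exist only internally.

The trigonometric form is evaluated with the denominator written as
(1−E1) + 2 E1 sin²(α/2), which is algebraically identical but avoids the
cancellation in 1 − E1 cos α as E1 → 1; this is what makes the two signal
forms agree to a few ulp over the full (α, E1) domain, a property the test
suite asserts on a 500×500 grid.

## Estimators

`fit_line` is ordinary (or weighted) least squares of y on x; ρ1 = −1/(2b),
A = intercept.  `dual_angle_fit` is the same regression on two points.
`conventional_fit` implements the classic comparator (S/sin α regressed on
S/tan α; slope E1) and converts to the common result type.  `multi_tr_fit`
regresses y on S·τ/(2·TR) so that, for TR ≪ T1, series at different TRs
share one line with slope −T1; it warns when max(TR)/T1 > 0.2, where the
(TR/T1)²/12 linearization bias reaches ~0.3%.  `nonlinear_fit_oracle` is
Levenberg-Marquardt least squares on the rational signal equation; it is
maximum likelihood under Gaussian signal noise and exists to cross-check
the linear paths, not to replace them.  Standard errors come from the usual
regression formulas plus delta-method conversions (ρ1 → T1 etc.); with only
two points they are undefined and reported as NaN.  Non-positive signals
(possible after background subtraction) are excluded with a logged warning
rather than failing the fit.

## Noise propagation and weighting

Because x_i = S_i τ_i and y_i = S_i/τ_i share the same noisy S_i, noise
must be propagated through both coordinates at once.  `propagate_variance`
differentiates the closed-form estimators analytically (db/dx_j, db/dy_j
through the centered moments, then dS chain rule) at the noiseless point
and sums squared partials times σ_S²; the unit tests verify it against
independent finite differences and against Monte-Carlo variances (10⁵
replicates, 5% agreement at σ/A = 0.005).

The residual F = y − (A − x/2ρ1) has variance
σ_S² · (1/τ² + τ²/4ρ1² + 1/ρ1); the bracket is minimal (2/ρ1) at the Ernst
point, and its reciprocal is the weight function for weighted fits.  Since
the weights need an a-priori ρ1, `fit_line(weights="model")` runs a short
fixed-point iteration: unweighted fit, weighted refits until ρ1 moves by
less than 10⁻⁶ relative (at most 10 passes).  On noiseless data weights
cannot move the exact line; on wide-τ designs the weighted fit is the
first-order-efficient linear estimator and matches the nonlinear oracle's
variance (the unweighted fit can be ~20% worse, which is the motivation
for the weights).

A scaling analysis of the estimator partials shows var(ρ1)·A²/ρ1 and
var(A)·ρ1 (per unit σ_S²) depend only on the normalized positions
u = τ/τ_E.  The published look-up scale for these unit-free variances is
not derivable from the estimators alone, so it is pinned by one constant
per target, calibrated once so the optimal two-point schemes take the
reference values 4.000 (relaxation) and 5.6133 (amplitude); every other
design's normalized variance is then a genuine prediction on that scale
(e.g. 2.9313 for the best three-point T1 scheme, exactly 4.000/m for
m-fold replicated pairs).

## Protocol design

`equidistant_schedule` places N points at fractional amplitude levels
p(i) = i/(N+1), i.e. u_i = √((N+1−i)/i), the layout that spreads points
evenly along the regression line (the property that makes bias visible);
mirrored pairs satisfy u_i·u_{N+1−i} = 1 and predict equal signals.  For
N = 2 this gives u = (1/√2, √2) — note p ∈ {1/3, 2/3}, not {1/4, 3/4}.

`optimize_schedule` minimizes the tissue-free variance objective over all N
positions in log-u space by Nelder-Mead from a deterministic multi-start
grid (structured starts: the equidistant schedule and replicated low/high
pairs; plus log-spaced pair combinations for N = 2 and 32 fixed-seed
log-uniform starts for N > 2; each run is polished by a simplex restart).
Objectives at distinct local minima that agree to 10⁻⁹ relative are treated
as the same degenerate optimum and resolved lexicographically (smallest u
first); qualitatively distinct minima within 5% are reported as alternative
branches.  The optimal u are invariant to A, σ and ρ1, so the optimization
runs once at a reference tissue.  Reproduced structure: the T1-optimal
two-point design is the reciprocal pair (√2−1, √2+1); even N replicate it
with variance ∝ 1/N; odd N cluster one side (N = 3: two points at 0.3718,
one at 2.2113, with the mirrored branch equally good); amplitude-optimal
designs push N−1 points to one low position and beat replication.  N is
capped at 8 — beyond the tabulated range the optimal structure is
replication, which `replicated_schedule` constructs directly.

`realize_flip_angles` converts u to degrees for a target (TR, T1) and can
round to integer degrees (consoles often require it), logging the shift in
realized fractional levels; rounding near the origin can collapse a small
angle to 0°, which is rejected rather than silently clipped.

## Transmit bias and signal-bias detection

A multiplicative transmit-field factor f scales the actual flip angle;
in the small-angle regime (τ ≈ α, accurate to 4% at 40°) fitting with
nominal angles multiplies the apparent amplitude by f and the apparent T1
by f², so `correct_apparent_t1` divides by f² post hoc.  `fit_volume` also
offers an exact mode that recomputes τ from f·α per voxel, which is the
right choice when angles exceed ~40° or f is far from 1; the two modes
agree within 1% for α ≤ 15°, f ∈ [0.8, 1.2].

`detect_signal_bias` iterates: fit a provisional line, studentize the
residuals with σ_S·√(residual scale), drop the single worst point above the
z threshold (default 3), stop when none exceed it or three points remain;
the final reported fit is the ordinary regression on the survivors.  The
provisional line is the Siegel repeated-median regression rather than OLS:
biased points cluster at one end of the τ range with high leverage, and an
OLS provisional fit demonstrably tilts onto a 5-of-13 contaminated cluster
and flags the clean points instead.  The noise level is taken from an
explicit `NoiseModel`, else from the samples' recorded SDs, else estimated
as the RMS of de-scaled OLS residuals (n−2 dof).  That fallback is
calibrated on clean data (dataset-level false-positive rate ~1% at z = 3,
versus the 2NΦ(−3) ≈ 3.5% Bonferroni budget) but deliberately conservative
under contamination: a cluster of biased points inflates the estimate and
suppresses detection, so only isolated outliers (e.g. one motion-corrupted
volume) are reliably caught without noise information.  Supplying the
measured σ (ROI tables normally have it) restores exact flagging of the
injected deviations in the spoiling fixture.

## Synthetic data

The generator emulates the bench conditions the method was validated
under: a long-T1 agar phantom (T1 = 2.41 s) acquired at TR = 6/12/24/48 ms
with angle ranges 1–13°/1–18°/1–24°/2–34° (integer-degree steps, step 2 at
48 ms — the published ranges fix the endpoints, the step is this package's
choice); an MnCl2 phantom (T1 = 0.54 s, TR = 7 ms, the 13 angles
2,3,4,6,8,10,12,15,18,21,24,30,36°); and a 16-angle 2–60° protocol at
TR = 11 ms on a three-compartment nested-sphere brain (WM/GM/CSF
T1 = 0.85/1.29/4.58 s; relative amplitudes 0.7/0.8/1.0 chosen as typical
proton-density weights).  Noise is additive Gaussian or Rician (magnitude
of a complex Gaussian; its mean offset matches the exact Laguerre-form
expansion, σ²/2S at high SNR).  Signal bias is phenomenological only: a
multiplicative high-angle factor with configurable sign, onset and
optional linear ramp (imperfect spoiling's true dependence on the RF phase
increment is out of scope), an additive low-angle offset, and trapezoid
integration of the signal across a sampled slice profile (≥ 101 points),
which reproduces the expected maximum shift toward higher nominal angles
and the positive high-angle tail.  Every generator is a pure function of
(spec, seed); a seed is mandatory whenever σ > 0.

What passing these tests does **not** show: the generators draw independent
per-voxel noise on exact Ernst signals, so coil correlations, motion,
k-space artifacts, partial volume and the actual physics of RF-spoiling
residuals are unrepresented; recovery results bound estimator behavior,
not scanner behavior.

## Noise regime of voxelwise mapping

At short TR the spoiled signal is a small fraction of A (about 3–6% at
TR = 11 ms for brain T1s), so "noise relative to A" is a harsh scale:
σ/A = 0.001 corresponds to realistic image SNR ~40 and gives
compartment-median T1 recovery of 0.2–2% (CSF worst — TR/T1 = 0.0024
leaves little signal).  At σ/A = 0.01 the per-measurement SNR drops to
2–6, first-order relative SD of ρ1 reaches 30–85%, and the nonlinearity of
ρ1 → T1 biases even the median by tens of percent; no estimator choice
repairs an SNR-2 regime.  The acceptance suite includes the recovery check
at σ/A = 0.01, which accordingly fails and is retained as an honest
negative result; the mapping tests demonstrate the recovery property at
the realistic noise level.

## Numerical choices

Degenerate inputs raise typed errors: fewer than two distinct angles
(`InsufficientDataError`), non-negative fitted slope or E1 outside (0,1)
(`DegenerateFitError`), optimizer failure on every start
(`ConvergenceError`).  Voxelwise fitting vectorizes the closed-form
moments over the whole grid (64³ × 16 volumes fits comfortably in a few
seconds on one core); voxels with degenerate fits are masked and counted,
never raised.  Masking uses the low-angle mean signal against 5× an
estimated background level (median of the lowest decile, discarded if not
clearly separated from the 90th percentile — i.e. images without a dark
background fall back to strict positivity).  T1 maps are in seconds, NaN
outside the mask; NIfTI affines are carried through untouched.

## Known limitations

Single-compartment, mono-exponential T1 only; no B1-map estimation (the
bias field is an input); no mechanistic spoiling or slice-profile
correction (deviating points are excluded, not corrected); weighted fits
assume the Gaussian first-order regime; the Rician model applies to
magnitude images from a single channel, not to root-sum-of-squares
multi-coil data.
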