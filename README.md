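# vfalin

Variable flip angle (VFA) T1 and amplitude mapping for spoiled gradient-echo
(FLASH/SPGR) MRI, built on the half-angle-tangent linear form of the Ernst
equation.

## The problem and the approach

The spoiled steady-state signal at flip angle α and repetition time TR is

    S(α) = A · sin α · (1 − E1) / (1 − E1 · cos α),      E1 = exp(−TR/T1),

where the amplitude A (the fully relaxed 90° signal at the echo time)
absorbs proton density and transverse decay.  Quantitative T1 mapping
estimates (A, T1) from a handful of flip angles.  Two exact substitutions,

    τ  = 2 tan(α/2)            (flip angle,   α ∈ (0, π)  →  τ ∈ (0, ∞)),
    ρ1 = 2 tanh(TR / 2T1)      (relaxation,   TR/T1       →  ρ1 ∈ (0, 2)),

turn the Ernst equation into the rational function
S = 2 A ρ1 τ / (τ² + 2ρ1).  Plotting each measurement at

    x = S·τ,   y = S/τ       gives the exact line    y = A − x / (2ρ1):

the y-intercept **is** the amplitude, the slope encodes the relaxation term
(ρ1 = −1/(2·slope)), and the signal maximum (Ernst point, τ_E = √(2ρ1))
sits halfway between the intercepts at y = A/2.  Because data that obey the
Ernst equation must be collinear in these coordinates, deviations — from
imperfect RF spoiling, slice profiles, Rician floors or motion — are
immediately visible and can be excluded before fitting.  For TR ≪ T1,
rescaling the abscissa to S·τ/(2·TR) merges acquisitions at different TRs
onto one line whose negative slope is T1 itself.

The package provides, as plain Python functions over numpy arrays:

- `transforms` — exact, vectorized maps between α/τ and TR, T1, E1, ρ1;
- `signal_model` — both signal forms (identical to a few ulp), Ernst-point
  geometry, linear coordinates, fractional signal levels;
- `estimators` — N-point linear fit (optionally variance-weighted),
  dual-angle closed form, pooled multi-TR fit, the classic S/sin-vs-S/tan
  comparator, and a Levenberg-Marquardt oracle, all returning one
  `FitResult`;
- `uncertainty` — analytic first-order propagation of image noise through
  the estimators (the noise enters x and y jointly), the correlated-error
  residual scale, and the variance-cancelling weight function;
- `protocol` — equidistant-level schedules and numerically optimized
  minimal-noise schedules (multi-start simplex over normalized positions
  u = τ/τ_E), realized as integer scanner angles on request;
- `bias` — transmit-field (B1) application/correction (apparent T1 scales
  with f²) and iterative, studentized exclusion of bias-affected points;
- `simulate` — synthetic phantoms (agar T1 = 2.41 s, MnCl2 T1 = 0.54 s, a
  three-compartment brain with WM/GM/CSF T1 = 0.85/1.29/4.58 s), Gaussian
  or Rician noise, phenomenological spoiling/slice-profile deviations;
- `mapping` — vectorized voxelwise fitting of NIfTI volume stacks with
  JSON sidecars, masking and B1 correction (post-hoc or exact).

A thin CLI (`vfalin design|fit|simulate|map`) wraps these for shell use.

## Worked example

`examples/bias_detection.py` simulates the classic failure mode — imperfect
RF spoiling depressing the signals above 15° in a short-T1 phantom series
(T1 = 0.54 s, TR = 7 ms, 13 angles) — and separates it from the transmit
bias law:

```
naive fit over all 13 angles:  T1 = 0.5731 s (truth 0.540 s)
flagged as biased (high side): [18 21 24 30 36] degrees
fit on the clean subset:       T1 = 0.5389 s
transmit bias f = 1.1: apparent T1 = 1.2110 s (= f^2 * 1.0 s); corrected = 1.0008 s
```

The naive fit is pulled 6% high by five biased points; the detector flags
exactly the injected angles and the clean-subset fit lands on the truth.
The last line verifies the f² law for a 10% transmit-field error and its
post-hoc correction.  The other examples cover protocol design
(`protocol_design.py`: the T1-optimal two-point scheme at
u = 0.4142/2.4142 with normalized variance 4.000), multi-TR pooling
(`multi_tr_pooling.py`: TR = 6–48 ms series jointly fit to T1 = 2.4100 s),
single-series fitting (`linear_fit.py`) and voxelwise mapping
(`volume_mapping.py`: WM/GM/CSF medians 0.850/1.286/4.476 s from a noisy
24³ stack).

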