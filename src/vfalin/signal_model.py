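"""Ernst signal equation in trigonometric and algebraic form.

The classic spoiled steady-state signal is

    S(alpha) = A * sin(alpha) * (1 - E1) / (1 - E1 * cos(alpha)),

with amplitude ``A`` (the fully relaxed 90-degree signal at the given echo
time, absorbing proton density and transverse decay) and ``E1 = exp(-TR/T1)``.
Under the exact substitutions ``tau = 2*tan(alpha/2)`` and
``rho1 = 2*tanh(TR/(2*T1))`` it becomes the rational function

    S(tau) = 2 * A * rho1 * tau / (tau**2 + 2*rho1),

which is maximal at the Ernst point ``tau_E = sqrt(2*rho1)`` with
``S_E = A*tau_E/2``.  Dividing by ``tau`` and rearranging yields the linear
relation

    y = A - x / (2*rho1),      x = S*tau,  y = S/tau,

so that amplitude and relaxation term appear separately as intercept and
slope.  The normalized identity ``S/(tau) / A = 1/(1 + u**2)`` with
``u = tau/tau_E`` is used throughout for fractional signal levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import VFASample
from .transforms import alpha_from_tau, tau_from_alpha

__all__ = [
    "TissueParams",
    "ErnstPoint",
    "LinearPoint",
    "ernst_signal",
    "algebraic_signal",
    "ernst_point",
    "linear_coords",
    "tau_for_level",
]


@dataclass(frozen=True)
class TissueParams:
    """Signal amplitude and algebraic relaxation term of one tissue/phantom."""

    amplitude: float
    rho1: float

    def __post_init__(self):
        if self.amplitude <= 0.0:
            raise ValueError("amplitude must be positive")
        if not 0.0 < self.rho1 < 2.0:
            raise ValueError("rho1 must lie in the open interval (0, 2)")

    @property
    def tau_e(self) -> float:
        return float(np.sqrt(2.0 * self.rho1))


@dataclass(frozen=True)
class ErnstPoint:
    """Location and height of the signal maximum in tau coordinates."""

    tau_e: float
    s_e: float
    alpha_e_deg: float


@dataclass(frozen=True)
class LinearPoint:
    """One measurement in linear-plot coordinates x = S*tau, y = S/tau."""

    x: float
    y: float
    weight: float = 1.0


def ernst_signal(amplitude, alpha_deg, e1):
    """Classic Ernst equation ``A*sin(a)*(1-E1)/(1-E1*cos(a))``.

    The denominator is evaluated as ``(1-E1) + 2*E1*sin(a/2)**2``, which is
    algebraically identical but free of the catastrophic cancellation the
    literal form suffers when ``E1 -> 1`` at small flip angles; the result
    agrees with `algebraic_signal` to a few ulp over the whole domain.
    """
    a = np.asarray(alpha_deg, dtype=float)
    e = np.asarray(e1, dtype=float)
    amp = np.asarray(amplitude, dtype=float)
    if np.any(amp <= 0.0):
        raise ValueError("amplitude must be positive")
    if np.any(a <= 0.0) or np.any(a >= 180.0):
        raise ValueError("flip angle must lie in the open interval (0, 180) degrees")
    if np.any(e <= 0.0) or np.any(e >= 1.0):
        raise ValueError("e1 must lie in the open interval (0, 1)")
    half = np.deg2rad(a) / 2.0
    sh = np.sin(half)
    s = amp * (2.0 * sh * np.cos(half)) * (1.0 - e) / ((1.0 - e) + 2.0 * e * sh * sh)
    return s if s.ndim else float(s)


def algebraic_signal(amplitude, tau, rho1):
    """Algebraic Ernst equation ``2*A*rho1*tau / (tau**2 + 2*rho1)``.

    Identical (exactly, not approximately) to `ernst_signal` under the
    half-angle-tangent and hyperbolic-tangent substitutions.
    """
    t = np.asarray(tau, dtype=float)
    r = np.asarray(rho1, dtype=float)
    amp = np.asarray(amplitude, dtype=float)
    if np.any(amp <= 0.0):
        raise ValueError("amplitude must be positive")
    if np.any(t <= 0.0):
        raise ValueError("tau must be positive")
    if np.any(r <= 0.0) or np.any(r >= 2.0):
        raise ValueError("rho1 must lie in the open interval (0, 2)")
    s = 2.0 * amp * r * t / (t * t + 2.0 * r)
    return s if s.ndim else float(s)


def ernst_point(tissue: TissueParams) -> ErnstPoint:
    """Signal maximum: ``tau_E = sqrt(2*rho1)``, ``S_E = A*tau_E/2``.

    In linear-plot coordinates the Ernst point sits exactly halfway between
    the intercepts: ``S_E/tau_E = A/2``.
    """
    tau_e = tissue.tau_e
    s_e = algebraic_signal(tissue.amplitude, tau_e, tissue.rho1)
    return ErnstPoint(tau_e, float(s_e), alpha_from_tau(tau_e))


def linear_coords(sample, weight: float = 1.0) -> LinearPoint:
    """Transform one measurement to linear-plot coordinates.

    Accepts a :class:`~vfalin.data.VFASample` or an ``(alpha_deg, signal)``
    pair.  Noiseless model samples are exactly collinear in these
    coordinates, with slope ``-1/(2*rho1)`` and y-intercept ``A``.
    """
    if isinstance(sample, VFASample):
        alpha_deg, signal = sample.alpha_deg, sample.signal
    else:
        alpha_deg, signal = sample
    if signal < 0.0:
        raise ValueError("signal must be non-negative")
    if weight < 0.0:
        raise ValueError("weight must be non-negative")
    tau = tau_from_alpha(alpha_deg)
    return LinearPoint(signal * tau, signal / tau, weight)


def tau_for_level(p, tau_e):
    """tau at which the ordinate ``S/tau`` equals the fraction ``p`` of A.

    Inverts ``p = 1/(1 + u**2)`` with ``u = tau/tau_E``:
    ``tau = tau_E * sqrt((1-p)/p)``.  The Ernst point is the half-amplitude
    level ``p = 1/2``.
    """
    p_ = np.asarray(p, dtype=float)
    if np.any(p_ <= 0.0) or np.any(p_ >= 1.0):
        raise ValueError("fractional level p must lie in the open interval (0, 1)")
    t = np.asarray(tau_e, dtype=float) * np.sqrt((1.0 - p_) / p_)
    return t if t.ndim else float(t)
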