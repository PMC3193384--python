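"""Exact substitutions between scanner-facing and algebraic variables.

The spoiled gradient-echo (FLASH/SPGR) steady state is governed by the flip
angle ``alpha`` and the saturation factor ``E1 = exp(-TR/T1)``.  Two exact
nonlinear substitutions turn the trigonometric Ernst equation into a low-order
rational function:

* the half-angle tangent of the flip angle, ``tau = 2*tan(alpha/2)``, which
  maps ``alpha in (0, 180 deg)`` onto ``(0, inf)`` and conforms to ``alpha``
  (in radians) with a third-order error, and
* the hyperbolic-tangent relaxation term ``rho1 = 2*tanh(TR/(2*T1))``,
  equivalently ``2*(1-E1)/(1+E1)``, which maps ``TR/T1 in (0, inf)`` onto
  ``(0, 2)`` and conforms to ``TR/T1`` for short TR.

All public functions accept degrees (the unit scanners and protocols quote)
and are vectorized over numpy arrays.  Domain violations raise ``ValueError``
naming the admissible interval; the endpoints are excluded and available only
as mathematical limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "tau_from_alpha",
    "alpha_from_tau",
    "rho1_from_relaxation",
    "relaxation_from_rho1",
    "rho1_from_e1",
    "e1_from_rho1",
    "e1_rho1_convert",
    "AngleSpec",
    "RelaxationSpec",
]


def _asfloat(x):
    return np.asarray(x, dtype=float)


def tau_from_alpha(alpha_deg):
    """Half-angle tangent variable ``tau = 2*tan(alpha/2)``.

    Parameters
    ----------
    alpha_deg : float or array_like
        Flip angle in degrees, in the open interval (0, 180).

    Returns
    -------
    tau : float or ndarray
        Dimensionless, strictly increasing in ``alpha_deg``; ``tau -> inf``
        as ``alpha_deg -> 180``.
    """
    a = _asfloat(alpha_deg)
    if np.any(a <= 0.0) or np.any(a >= 180.0):
        raise ValueError("flip angle must lie in the open interval (0, 180) degrees")
    tau = 2.0 * np.tan(np.deg2rad(a) / 2.0)
    return tau if tau.ndim else float(tau)


def alpha_from_tau(tau):
    """Flip angle in degrees from ``tau``; exact inverse of `tau_from_alpha`."""
    t = _asfloat(tau)
    if np.any(t <= 0.0):
        raise ValueError("tau must be positive (flip angle in (0, 180) degrees)")
    a = np.rad2deg(2.0 * np.arctan(t / 2.0))
    return a if a.ndim else float(a)


def rho1_from_relaxation(tr, t1):
    """Algebraic relaxation term ``rho1 = 2*tanh(TR/(2*T1))``.

    Equals ``2*(1-E1)/(1+E1)`` with ``E1 = exp(-TR/T1)`` and lies in (0, 2)
    for any positive TR and T1.  For ``TR << T1`` it conforms to ``TR/T1``
    with relative error ``(TR/T1)**2 / 12``.
    """
    tr_ = _asfloat(tr)
    t1_ = _asfloat(t1)
    if np.any(tr_ <= 0.0):
        raise ValueError("tr must be positive (seconds)")
    if np.any(t1_ <= 0.0):
        raise ValueError("t1 must be positive (seconds)")
    r = 2.0 * np.tanh(tr_ / (2.0 * t1_))
    return r if r.ndim else float(r)


def relaxation_from_rho1(rho1, tr):
    """T1 in seconds from the relaxation term: ``T1 = TR / (2*artanh(rho1/2))``."""
    r = _asfloat(rho1)
    tr_ = _asfloat(tr)
    if np.any(r <= 0.0) or np.any(r >= 2.0):
        raise ValueError("rho1 must lie in the open interval (0, 2)")
    if np.any(tr_ <= 0.0):
        raise ValueError("tr must be positive (seconds)")
    t1 = tr_ / (2.0 * np.arctanh(r / 2.0))
    return t1 if t1.ndim else float(t1)


def rho1_from_e1(e1):
    """``rho1 = 2*(1 - E1)/(1 + E1)`` for ``E1 in (0, 1)``."""
    e = _asfloat(e1)
    if np.any(e <= 0.0) or np.any(e >= 1.0):
        raise ValueError("e1 must lie in the open interval (0, 1)")
    r = 2.0 * (1.0 - e) / (1.0 + e)
    return r if r.ndim else float(r)


def e1_from_rho1(rho1):
    """``E1 = (2 - rho1)/(2 + rho1)`` for ``rho1 in (0, 2)``."""
    r = _asfloat(rho1)
    if np.any(r <= 0.0) or np.any(r >= 2.0):
        raise ValueError("rho1 must lie in the open interval (0, 2)")
    e = (2.0 - r) / (2.0 + r)
    return e if e.ndim else float(e)


def e1_rho1_convert(value, direction):
    """Convert between E1 and rho1.

    ``direction`` is ``"e1_to_rho1"`` or ``"rho1_to_e1"``.  Both maps are the
    same Moebius bijection applied to its respective open domain.
    """
    if direction == "e1_to_rho1":
        return rho1_from_e1(value)
    if direction == "rho1_to_e1":
        return e1_from_rho1(value)
    raise ValueError("direction must be 'e1_to_rho1' or 'rho1_to_e1'")


@dataclass(frozen=True)
class AngleSpec:
    """A flip angle together with its half-angle-tangent variable."""

    alpha_deg: float
    tau: float

    @classmethod
    def from_alpha(cls, alpha_deg: float) -> "AngleSpec":
        return cls(float(alpha_deg), tau_from_alpha(alpha_deg))

    @classmethod
    def from_tau(cls, tau: float) -> "AngleSpec":
        return cls(alpha_from_tau(tau), float(tau))


@dataclass(frozen=True)
class RelaxationSpec:
    """Mutually consistent relaxation quantities for one (TR, T1) pair.

    Attributes
    ----------
    tr : repetition time, seconds
    t1 : longitudinal relaxation time, seconds
    r1 : relaxation rate 1/T1, 1/s
    e1 : exp(-TR/T1), dimensionless, in (0, 1)
    rho1 : algebraic relaxation term, dimensionless, in (0, 2)
    """

    tr: float
    t1: float
    r1: float
    e1: float
    rho1: float

    @classmethod
    def from_tr_t1(cls, tr: float, t1: float) -> "RelaxationSpec":
        rho1 = rho1_from_relaxation(tr, t1)
        return cls(float(tr), float(t1), 1.0 / float(t1), float(np.exp(-tr / t1)), rho1)

    @classmethod
    def from_rho1(cls, rho1: float, tr: float) -> "RelaxationSpec":
        t1 = relaxation_from_rho1(rho1, tr)
        return cls.from_tr_t1(tr, t1)
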