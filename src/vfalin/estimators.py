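"""Fitting procedures for variable flip angle data.

All estimators operate on the linear form of the algebraic Ernst equation:
plotting ``y = S/tau`` against ``x = S*tau`` places ideal measurements on the
line ``y = A - x/(2*rho1)``, so ordinary least squares recovers the amplitude
``A`` as intercept and the relaxation term ``rho1 = -1/(2*slope)``.

Provided estimators:

* :func:`fit_line` -- N-point (optionally weighted) regression at a single TR,
* :func:`dual_angle_fit` -- the exact two-point closed form,
* :func:`multi_tr_fit` -- pooled regression over several short TRs with
  abscissa ``S*tau/(2*TR)``, yielding T1 directly as the negative slope,
* :func:`conventional_fit` -- the classic ``S/sin`` on ``S/tan`` comparator
  whose slope is ``E1``,
* :func:`nonlinear_fit_oracle` -- Levenberg-Marquardt least squares on the
  rational signal equation, used to corroborate the linear estimators.

:func:`batch_fit_line` exposes the same closed-form regression vectorized
over many signal rows (Monte-Carlo replicates, image voxels).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .data import SignalSet, VFASample
from .exceptions import DegenerateFitError, InsufficientDataError
from .transforms import e1_from_rho1, relaxation_from_rho1, rho1_from_e1

__all__ = [
    "FitResult",
    "fit_line",
    "dual_angle_fit",
    "multi_tr_fit",
    "conventional_fit",
    "nonlinear_fit_oracle",
    "batch_fit_line",
]

logger = logging.getLogger("vfalin")

MAX_WEIGHT_PASSES = 10
WEIGHT_RTOL = 1e-6
#: multi-TR validity limit on max(TR)/T1 before the short-TR linearization
#: error ((TR/T1)**2/12 relative in rho1) stops being negligible
SHORT_TR_LIMIT = 0.2


@dataclass
class FitResult:
    """Common result of every estimator.

    Attributes
    ----------
    amplitude, amplitude_se : signal amplitude A (a.u.) and standard error
    rho1, rho1_se : algebraic relaxation term (dimensionless); NaN when the
        samples span several TRs (multi-TR mode)
    t1, t1_se : longitudinal relaxation time, seconds
    e1 : exp(-TR/T1), derived; NaN in multi-TR mode
    slope : fitted slope in the estimator's own regression coordinates
    residuals : per-sample ordinate residuals (included samples; NaN elsewhere)
    included : per-sample inclusion flags
    n_used : number of samples entering the regression
    tr_s : the common TR in seconds, or None when TR varies
    method : estimator name
    converged, n_iter : iteration diagnostics (nonlinear oracle, weighting)
    """

    amplitude: float
    rho1: float
    t1: float
    e1: float
    slope: float
    amplitude_se: float
    rho1_se: float
    t1_se: float
    residuals: np.ndarray
    included: np.ndarray
    n_used: int
    tr_s: Optional[float]
    method: str
    converged: bool = True
    n_iter: Optional[int] = None
    weights: Optional[np.ndarray] = None


def _coerce(samples) -> SignalSet:
    if isinstance(samples, SignalSet):
        return samples
    return SignalSet.from_samples(list(samples))


def _inclusion_mask(samples: SignalSet) -> np.ndarray:
    included = samples.signal > 0.0
    n_dropped = int(np.sum(~included))
    if n_dropped:
        logger.warning(
            "excluding %d non-positive signal(s) from the fit", n_dropped
        )
    return included


def _wls(x, y, w):
    """Weighted least squares returning slope, intercept and their SEs."""
    n = len(x)
    sw = np.sum(w)
    xm = np.sum(w * x) / sw
    ym = np.sum(w * y) / sw
    cx = x - xm
    sxx = np.sum(w * cx * cx)
    if sxx <= 0.0:
        raise InsufficientDataError("all abscissa values coincide; need >= 2 distinct")
    sxy = np.sum(w * cx * (y - ym))
    b = sxy / sxx
    a = ym - b * xm
    r = y - (a + b * x)
    dof = n - 2
    if dof > 0:
        s2 = np.sum(w * r * r) / dof
        var_b = s2 / sxx
        var_a = s2 * (1.0 / sw + xm * xm / sxx)
        cov_ab = -s2 * xm / sxx
    else:
        var_b = var_a = cov_ab = np.nan
    return b, a, r, np.sqrt(var_b), np.sqrt(var_a), cov_ab


def _result_from_line(b, a, r, se_b, se_a, residuals, included, tr, method,
                      n_iter=None, weights=None) -> FitResult:
    if not np.isfinite(b) or b >= 0.0:
        raise DegenerateFitError(
            f"fitted slope {b:.3g} is non-negative: implies a non-physical "
            "relaxation term (rho1 <= 0)"
        )
    rho1 = -1.0 / (2.0 * b)
    rho1_se = se_b / (2.0 * b * b) if np.isfinite(se_b) else np.nan
    if rho1 >= 2.0:
        raise DegenerateFitError(
            f"fitted rho1 = {rho1:.3g} >= 2 lies outside the physical range (0, 2)"
        )
    t1 = relaxation_from_rho1(rho1, tr)
    u = np.arctanh(rho1 / 2.0)
    dt1_drho1 = -tr / (4.0 * u * u * (1.0 - rho1 * rho1 / 4.0))
    t1_se = abs(dt1_drho1) * rho1_se if np.isfinite(rho1_se) else np.nan
    return FitResult(
        amplitude=float(a),
        rho1=float(rho1),
        t1=float(t1),
        e1=float(e1_from_rho1(rho1)),
        slope=float(b),
        amplitude_se=float(se_a),
        rho1_se=float(rho1_se),
        t1_se=float(t1_se),
        residuals=residuals,
        included=included,
        n_used=int(np.sum(included)),
        tr_s=float(tr),
        method=method,
        n_iter=n_iter,
        weights=weights,
    )


def fit_line(samples, weights: Union[None, str, Sequence[float]] = None) -> FitResult:
    """Least-squares line through ``(S*tau, S/tau)`` at a single TR.

    Parameters
    ----------
    samples : SignalSet or sequence of VFASample
        Measurements sharing one TR with at least two distinct flip angles.
    weights : None, array_like, or ``"model"``
        ``None`` for ordinary least squares; an explicit non-negative weight
        per sample; or ``"model"`` for the variance-cancelling weights of the
        correlated-error analysis, applied by a short fixed-point iteration
        (unweighted fit, then weighted refits until rho1 stabilizes) because
        the weights require an a-priori relaxation estimate.
    """
    ss = _coerce(samples)
    if not ss.single_tr:
        raise ValueError(
            "samples span several TR values; use multi_tr_fit for mixed-TR data"
        )
    included = _inclusion_mask(ss)
    if np.sum(included) < 2 or len(np.unique(ss.tau[included])) < 2:
        raise InsufficientDataError("need >= 2 samples with distinct flip angles")
    tau = ss.tau[included]
    s = ss.signal[included]
    x = s * tau
    y = s / tau
    tr = float(ss.tr_s[0])

    if isinstance(weights, str):
        if weights != "model":
            raise ValueError("weights must be None, an array, or 'model'")
        # fixed-point iteration on the a-priori rho1 the weights require
        from .uncertainty import weight_function  # local import; no cycle at runtime

        res = fit_line(ss, weights=None)
        rho1 = res.rho1
        for it in range(MAX_WEIGHT_PASSES):
            w_full = np.zeros(len(ss))
            w_full[included] = weight_function(tau, rho1)
            res = fit_line(ss, weights=w_full)
            if abs(res.rho1 - rho1) <= WEIGHT_RTOL * abs(rho1):
                rho1 = res.rho1
                break
            rho1 = res.rho1
        res.method = "fit_line[model-weighted]"
        res.n_iter = it + 1
        return res

    if weights is None:
        w = np.ones_like(x)
        w_report = None
    else:
        w_all = np.asarray(weights, dtype=float)
        if len(w_all) != len(ss):
            raise ValueError("weights must match the number of samples")
        if np.any(w_all < 0.0) or not np.any(w_all > 0.0):
            raise ValueError("weights must be non-negative and not all zero")
        w = w_all[included]
        w_report = w_all

    b, a, r, se_b, se_a, _ = _wls(x, y, w)
    residuals = np.full(len(ss), np.nan)
    residuals[included] = r
    return _result_from_line(
        b, a, r, se_b, se_a, residuals, included, tr,
        "fit_line" if weights is None else "fit_line[weighted]",
        weights=w_report,
    )


def dual_angle_fit(s1: VFASample, s2: VFASample) -> FitResult:
    """Exact two-point solution; identical to :func:`fit_line` on the pair.

    In closed form ``rho1 = (x1 - x2) / (2*(y2 - y1))`` with the linear-plot
    coordinates of the two samples.
    """
    if s1.tau == s2.tau:
        raise InsufficientDataError("dual-angle fit needs two distinct flip angles")
    if s1.tr != s2.tr:
        raise ValueError("dual-angle samples must share one TR")
    y1, y2 = s1.signal / s1.tau, s2.signal / s2.tau
    if y1 == y2:
        raise DegenerateFitError("equal ordinates S/tau: slope is zero")
    return fit_line(SignalSet.from_samples([s1, s2]))


def multi_tr_fit(samples) -> FitResult:
    """Pooled short-TR regression of ``S/tau`` on ``S*tau/(2*TR)``.

    For ``TR << T1`` the relaxation term conforms to ``TR/T1``, so scaling
    the abscissa by ``1/(2*TR)`` merges acquisitions at different TR onto a
    single line whose negative slope is T1 itself (in seconds).  A validity
    warning is emitted when ``max(TR)/T1`` exceeds ``SHORT_TR_LIMIT``.
    """
    ss = _coerce(samples)
    included = _inclusion_mask(ss)
    if np.sum(included) < 2:
        raise InsufficientDataError("need >= 2 samples with distinct flip angles")
    tau = ss.tau[included]
    s = ss.signal[included]
    tr = ss.tr_s[included]
    x = s * tau / (2.0 * tr)
    y = s / tau
    w = np.ones_like(x)
    b, a, r, se_b, se_a, _ = _wls(x, y, w)
    if not np.isfinite(b) or b >= 0.0:
        raise DegenerateFitError(
            f"fitted slope {b:.3g} is non-negative: implies a non-physical T1"
        )
    t1 = -b
    if np.max(tr) / t1 > SHORT_TR_LIMIT:
        warnings.warn(
            f"max(TR)/T1 = {np.max(tr) / t1:.2f} exceeds the short-TR regime "
            f"(TR/T1 <= {SHORT_TR_LIMIT}); the pooled linearization is biased",
            stacklevel=2,
        )
    residuals = np.full(len(ss), np.nan)
    residuals[included] = r
    single = bool(np.all(tr == tr[0]))
    if single:
        from .transforms import rho1_from_relaxation

        rho1 = rho1_from_relaxation(float(tr[0]), t1)
        e1 = e1_from_rho1(rho1)
        tr_out = float(tr[0])
    else:
        rho1 = e1 = np.nan
        tr_out = None
    return FitResult(
        amplitude=float(a),
        rho1=float(rho1),
        t1=float(t1),
        e1=float(e1),
        slope=float(b),
        amplitude_se=float(se_a),
        rho1_se=np.nan,
        t1_se=float(se_b),
        residuals=residuals,
        included=included,
        n_used=int(np.sum(included)),
        tr_s=tr_out,
        method="multi_tr_fit",
    )


def conventional_fit(samples) -> FitResult:
    """Classic comparator: regression of ``S/sin(a)`` on ``S/tan(a)``.

    The slope is ``E1`` and the intercept ``A*(1 - E1)``; results are
    converted into the common :class:`FitResult`.  Residuals are reported in
    the ``S/sin`` ordinate of this estimator's own coordinates.
    """
    ss = _coerce(samples)
    if not ss.single_tr:
        raise ValueError("conventional fit requires a single TR")
    included = _inclusion_mask(ss)
    if np.sum(included) < 2 or len(np.unique(ss.alpha_deg[included])) < 2:
        raise InsufficientDataError("need >= 2 samples with distinct flip angles")
    rad = np.deg2rad(ss.alpha_deg[included])
    s = ss.signal[included]
    x = s / np.tan(rad)
    y = s / np.sin(rad)
    tr = float(ss.tr_s[0])
    b, a, r, se_b, se_a, cov_ab = _wls(x, y, np.ones_like(x))
    if not 0.0 < b < 1.0:
        raise DegenerateFitError(
            f"fitted slope E1 = {b:.3g} outside (0, 1): non-physical relaxation"
        )
    e1 = b
    amplitude = a / (1.0 - e1)
    t1 = -tr / np.log(e1)
    rho1 = rho1_from_e1(e1)
    # delta method through A = a/(1-E1), including the (a, b) covariance
    dA_da = 1.0 / (1.0 - e1)
    dA_db = a / (1.0 - e1) ** 2
    if np.isfinite(se_a):
        var_amp = (dA_da * se_a) ** 2 + (dA_db * se_b) ** 2 + 2 * dA_da * dA_db * cov_ab
        amplitude_se = np.sqrt(max(var_amp, 0.0))
        t1_se = abs(tr / (e1 * np.log(e1) ** 2)) * se_b
        rho1_se = 4.0 / (1.0 + e1) ** 2 * se_b
    else:
        amplitude_se = t1_se = rho1_se = np.nan
    residuals = np.full(len(ss), np.nan)
    residuals[included] = r
    return FitResult(
        amplitude=float(amplitude),
        rho1=float(rho1),
        t1=float(t1),
        e1=float(e1),
        slope=float(b),
        amplitude_se=float(amplitude_se),
        rho1_se=float(rho1_se),
        t1_se=float(t1_se),
        residuals=residuals,
        included=included,
        n_used=int(np.sum(included)),
        tr_s=tr,
        method="conventional_fit",
    )


def _raw_signal(amplitude, tau, rho1):
    # unguarded rational form so the optimizer may roam outside the domain
    return 2.0 * amplitude * rho1 * tau / (tau * tau + 2.0 * rho1)


def nonlinear_fit_oracle(samples, init: Optional[Sequence[float]] = None) -> FitResult:
    """Levenberg-Marquardt fit of the rational signal equation.

    Serves as an independent cross-check of the linear estimators (both seek
    the same least-squares optimum in signal space for noiseless data).
    ``init`` is ``(amplitude, rho1)``; a moment-based default is used
    otherwise.  Non-convergence is flagged on the result, never silent.
    """
    ss = _coerce(samples)
    if not ss.single_tr:
        raise ValueError("nonlinear oracle requires a single TR")
    included = _inclusion_mask(ss)
    if np.sum(included) < 2:
        raise InsufficientDataError("need >= 2 samples")
    tau = ss.tau[included]
    s = ss.signal[included]
    tr = float(ss.tr_s[0])
    if init is None:
        y = s / tau
        a0 = float(np.max(y))
        rho0 = float(np.clip(tau[np.argmax(s)] ** 2 / 2.0, 1e-4, 1.999))
        init = (a0, rho0)

    def resid(theta):
        return _raw_signal(theta[0], tau, theta[1]) - s

    sol = least_squares(resid, np.asarray(init, dtype=float), method="lm",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    n_iter = int(sol.njev) if sol.njev is not None else int(sol.nfev) // 3
    amplitude, rho1 = float(sol.x[0]), float(sol.x[1])
    converged = bool(sol.success)
    if not converged:
        logger.warning("nonlinear oracle did not converge: %s", sol.message)
    dof = len(s) - 2
    if dof > 0 and converged:
        s2 = 2.0 * sol.cost / dof
        jtj = sol.jac.T @ sol.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
            amplitude_se, rho1_se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            amplitude_se = rho1_se = np.nan
    else:
        amplitude_se = rho1_se = np.nan
    in_domain = 0.0 < rho1 < 2.0
    t1 = relaxation_from_rho1(rho1, tr) if in_domain else np.nan
    e1 = e1_from_rho1(rho1) if in_domain else np.nan
    residuals = np.full(len(ss), np.nan)
    residuals[included] = -resid(sol.x)
    return FitResult(
        amplitude=amplitude,
        rho1=rho1,
        t1=float(t1),
        e1=float(e1),
        slope=-1.0 / (2.0 * rho1) if in_domain else np.nan,
        amplitude_se=float(amplitude_se),
        rho1_se=float(rho1_se),
        t1_se=np.nan,
        residuals=residuals,
        included=included,
        n_used=int(np.sum(included)),
        tr_s=tr,
        method="nonlinear_fit_oracle",
        converged=converged,
        n_iter=n_iter,
    )


def batch_fit_line(tau, signals, tr=None, multi_tr=False):
    """Vectorized closed-form regression over many signal rows.

    Parameters
    ----------
    tau : ndarray
        Half-angle-tangent values, shape ``(N,)`` or broadcastable to
        ``signals`` (per-row tau, e.g. per-voxel transmit-bias correction).
    signals : ndarray
        Signal magnitudes with the measurement axis last, shape ``(..., N)``.
    tr : ndarray or float, optional
        Repetition times; required with ``multi_tr=True`` (abscissa becomes
        ``S*tau/(2*TR)`` and T1 is the negative slope) and for T1 conversion
        in single-TR mode.
    multi_tr : bool
        Select the pooled short-TR parameterization.

    Returns
    -------
    dict with arrays ``amplitude``, ``rho1``, ``t1``, ``slope``, ``valid``
    (finite, physical fits) broadcast over the leading axes.
    """
    s = np.asarray(signals, dtype=float)
    t = np.asarray(tau, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = s * t
        if multi_tr:
            if tr is None:
                raise ValueError("multi_tr=True requires tr")
            x = x / (2.0 * np.asarray(tr, dtype=float))
        y = s / t
        n = s.shape[-1]
        xm = np.mean(x, axis=-1, keepdims=True)
        ym = np.mean(y, axis=-1, keepdims=True)
        cx = x - xm
        sxx = np.sum(cx * cx, axis=-1)
        sxy = np.sum(cx * (y - ym), axis=-1)
        b = sxy / sxx
        a = ym[..., 0] - b * xm[..., 0]
        valid = np.isfinite(b) & (b < 0.0)
        if multi_tr:
            t1 = -b
            rho1 = np.full_like(b, np.nan)
        else:
            rho1 = np.where(valid, -1.0 / (2.0 * b), np.nan)
            valid &= (rho1 > 0.0) & (rho1 < 2.0)
            if tr is not None:
                t1 = np.asarray(tr, dtype=float) / (
                    2.0 * np.arctanh(np.clip(rho1, 1e-300, 2.0 - 1e-12) / 2.0)
                )
            else:
                t1 = np.full_like(b, np.nan)
        t1 = np.where(valid, t1, np.nan)
        rho1 = np.where(valid, rho1, np.nan)
        a = np.where(np.isfinite(a), a, np.nan)
    return {"amplitude": a, "rho1": rho1, "t1": t1, "slope": b, "valid": valid,
            "n": n}
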