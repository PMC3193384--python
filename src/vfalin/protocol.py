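"""Flip-angle schedule design for VFA acquisitions.

Two design families are provided:

* :func:`equidistant_schedule` places N points at equidistant fractional
  levels ``p(i) = i/(N+1)`` of the amplitude on the linear plot, i.e. at
  normalized positions ``u_i = sqrt((N+1-i)/i)``.  These schedules sample the
  regression line evenly -- the layout that makes signal bias visible -- and
  obey the reciprocal symmetry ``u_i = 1/u_{N+1-i}`` (equal predicted
  signals for mirrored pairs).
* :func:`optimize_schedule` minimizes the first-order noise propagation into
  either the relaxation term or the amplitude over all N positions by
  multi-start derivative-free local optimization.  For the relaxation target
  and even N the optimum is an exact replication of the optimal dual-angle
  pair (variance scaling as 1/N); for the amplitude target the best schemes
  cluster N-1 points at a single low position.

:func:`realize_flip_angles` converts normalized positions into scanner flip
angles for a concrete (TR, target T1), optionally rounding to integer
degrees and reporting the realized fractional levels.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from .exceptions import ConvergenceError
from .signal_model import TissueParams
from .transforms import alpha_from_tau, rho1_from_relaxation, tau_from_alpha
from .uncertainty import (
    NoiseModel,
    VariancePrediction,
    _invariant_amp,
    _invariant_rho1,
    _polished_minimize,
    _REF_TISSUE,
    propagate_variance,
)

__all__ = ["Schedule", "equidistant_schedule", "optimize_schedule",
           "realize_flip_angles", "replicated_schedule"]

logger = logging.getLogger("vfalin")

MAX_N = 8
#: start-grid bounds for normalized positions in the multi-start search
U_MIN, U_MAX = 0.05, 20.0
#: alternative local minima within this relative objective margin are kept
BRANCH_MARGIN = 0.05


@dataclass
class Schedule:
    """A planned set of normalized flip-angle positions.

    Attributes
    ----------
    n : number of measurements
    target : design objective, ``"rho1"`` (relaxation/T1) or ``"amplitude"``
    u_ratios : normalized positions tau/tau_E, ascending
    flip_angles_deg : realized angles (after `realize_flip_angles`), else None
    tau_e : Ernst tau of the realization target, else None
    p_levels : fractional S/tau amplitude levels 1/(1+u**2)
    predicted : first-order variance prediction at unit noise, reference tissue
    objective : minimized tissue-free objective value (optimized schedules)
    alternatives : qualitatively distinct near-optimal schedules
    """

    n: int
    target: str
    u_ratios: np.ndarray
    flip_angles_deg: Optional[np.ndarray] = None
    tau_e: Optional[float] = None
    predicted: Optional[VariancePrediction] = None
    objective: Optional[float] = None
    alternatives: List["Schedule"] = field(default_factory=list)

    def __post_init__(self):
        self.u_ratios = np.sort(np.asarray(self.u_ratios, dtype=float))
        if self.n < 2:
            raise ValueError("a schedule needs n >= 2 measurements")
        if len(self.u_ratios) != self.n or np.any(self.u_ratios <= 0.0):
            raise ValueError("u_ratios must be n positive values")

    @property
    def p_levels(self) -> np.ndarray:
        return 1.0 / (1.0 + self.u_ratios**2)


def _predict(u: np.ndarray) -> VariancePrediction:
    return propagate_variance(u * _REF_TISSUE.tau_e, _REF_TISSUE, NoiseModel(1.0))


def equidistant_schedule(n: int, tau_e: Optional[float] = None) -> Schedule:
    """Schedule at equidistant fractional levels ``p(i) = i/(n+1)``."""
    if n < 2:
        raise ValueError("need n >= 2 measurements")
    i = np.arange(1, n + 1, dtype=float)
    u = np.sqrt((n + 1.0 - i) / i)
    sched = Schedule(n=n, target="rho1", u_ratios=u, tau_e=tau_e)
    sched.predicted = _predict(sched.u_ratios)
    return sched


def replicated_schedule(n: int, target: str = "rho1") -> Schedule:
    """m-fold replication of the optimal dual-angle scheme for even n.

    This is the symmetric branch of the optimized designs; for the
    relaxation target it is also the global optimum, with variance exactly
    1/m of the two-point minimum.
    """
    if n < 2 or n % 2:
        raise ValueError("replicated schedules require even n >= 2")
    base = optimize_schedule(2, target=target)
    u = np.repeat(base.u_ratios, n // 2)
    sched = Schedule(n=n, target=target, u_ratios=u)
    sched.predicted = _predict(sched.u_ratios)
    sched.objective = _objective_for(target)(u)
    return sched


def _objective_for(target: str):
    if target in ("rho1", "t1"):
        return lambda u: _invariant_rho1(u, _REF_TISSUE)
    if target == "amplitude":
        return lambda u: _invariant_amp(u, _REF_TISSUE)
    raise ValueError("target must be 'rho1' (or 't1') or 'amplitude'")


def _start_grid(n: int, n_random: int) -> List[np.ndarray]:
    """Deterministic multi-start positions in u-space."""
    starts: List[np.ndarray] = [equidistant_schedule(n).u_ratios]
    pair = np.array([np.sqrt(3.0) / 3.0, np.sqrt(3.0)])  # generic low/high pair
    if n % 2 == 0:
        starts.append(np.repeat(pair, n // 2))
    else:
        starts.append(np.concatenate([np.repeat(pair[:1], n - 1), pair[1:]]))
        starts.append(np.concatenate([pair[:1], np.repeat(pair[1:], n - 1)]))
    grid = np.geomspace(U_MIN, U_MAX, 8)
    if n == 2:
        starts.extend(np.array(c) for c in itertools.combinations(grid, 2))
    else:
        rng = np.random.default_rng(20110322)  # fixed: the start grid is part of the method
        z = rng.uniform(np.log(U_MIN), np.log(U_MAX), size=(n_random, n))
        starts.extend(np.exp(np.sort(z, axis=1)))
    return starts


def optimize_schedule(
    n: int,
    target: str = "rho1",
    tissue: Optional[TissueParams] = None,
    starts: Optional[Sequence[Sequence[float]]] = None,
    n_random_starts: int = 32,
) -> Schedule:
    """Minimal-noise schedule by multi-start local optimization.

    Minimizes the tissue-free first-order variance of the chosen target over
    all ``n`` normalized positions (optimized in log-u space with a
    derivative-free simplex from a deterministic start grid).  The optimal
    positions are invariant to amplitude, noise level and relaxation term;
    ``tissue`` only affects the attached absolute variance prediction.
    Qualitatively distinct local minima within 5% of the best objective are
    returned on ``Schedule.alternatives``.
    """
    if not 2 <= n <= MAX_N:
        raise ValueError(f"n must lie in [2, {MAX_N}]")
    obj_u = _objective_for(target)
    fun = lambda z: obj_u(np.exp(z))
    if starts is None:
        starts = _start_grid(n, n_random_starts)
    minima = []
    for u0 in starts:
        u0 = np.asarray(u0, dtype=float)
        sol = _polished_minimize(fun, np.log(u0))
        if np.isfinite(sol.fun):
            minima.append((float(sol.fun), np.sort(np.exp(sol.x))))
    if not minima:
        raise ConvergenceError(
            f"no start converged for n={n}, target={target}; "
            f"tried {len(list(starts))} starts"
        )
    # tie-break: objectives equal to ~1e-9 relative are the same minimum up to
    # floating noise; among those prefer the lexicographically smallest u
    fmin = min(f for f, _ in minima)
    tied = [(f, u) for f, u in minima if f <= fmin * (1.0 + 1e-9)]
    tied.sort(key=lambda m: tuple(np.round(m[1], 6)))
    best_f, best_u = tied[0]
    minima.sort(key=lambda m: (m[0], tuple(np.round(m[1], 6))))

    # cluster near-optimal local minima into qualitatively distinct branches
    branches = [(best_f, best_u)]
    for f, u in minima:
        if f > best_f * (1.0 + BRANCH_MARGIN):
            continue
        if not any(np.allclose(u, bu, atol=2e-3) for _, bu in branches):
            branches.append((f, u))

    target_name = "rho1" if target == "t1" else target
    tissue_pred = tissue if tissue is not None else _REF_TISSUE

    def _mk(f, u):
        s = Schedule(n=n, target=target_name, u_ratios=u, objective=f)
        s.predicted = propagate_variance(
            u * tissue_pred.tau_e, tissue_pred, NoiseModel(1.0)
        )
        return s

    main = _mk(best_f, best_u)
    main.alternatives = [_mk(f, u) for f, u in branches[1:]]
    return main


def realize_flip_angles(
    schedule: Schedule, tr: float, t1_target: float, integer_round: bool = False
) -> Schedule:
    """Convert normalized positions into flip angles for a (TR, T1) target.

    Computes ``tau_E`` from the target relaxation, maps ``u*tau_E`` to
    degrees, and optionally rounds to whole degrees (MR consoles often
    accept only integer flip angles), logging the shift in the realized
    fractional levels.
    """
    rho1 = rho1_from_relaxation(tr, t1_target)
    tau_e = float(np.sqrt(2.0 * rho1))
    taus = schedule.u_ratios * tau_e
    angles = alpha_from_tau(taus)
    u_real = schedule.u_ratios
    if integer_round:
        rounded = np.round(angles)
        if np.any(rounded <= 0.0) or np.any(rounded >= 180.0):
            raise ValueError("rounded flip angles fall outside (0, 180) degrees")
        u_real = tau_from_alpha(rounded) / tau_e
        shift = 1.0 / (1.0 + u_real**2) - schedule.p_levels
        logger.info(
            "integer rounding shifted fractional levels by up to %.4f",
            float(np.max(np.abs(shift))),
        )
        angles = rounded
    if np.any(angles <= 0.0) or np.any(angles >= 180.0):
        raise ValueError("realized flip angles fall outside (0, 180) degrees")
    out = replace(schedule, flip_angles_deg=angles, tau_e=tau_e,
                  u_ratios=u_real, alternatives=[])
    if len(np.unique(u_real)) >= 2:
        out.predicted = propagate_variance(
            u_real * tau_e, TissueParams(1.0, rho1), NoiseModel(1.0)
        )
    else:
        out.predicted = None  # single repeated angle: no variance prediction
    return out
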