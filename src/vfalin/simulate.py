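"""Synthetic VFA data with the noise and bias structure of bench experiments.

Generates spoiled gradient-echo signal sets and image-volume stacks from
known ground truth so every estimator, design and bias tool in the package
can be validated without any acquisition.  The built-in phantoms mirror the
validation conditions the method was developed under:

* ``agar``     -- long-T1 gel (T1 = 2.41 s), near-ideal spoiling; acquired at
  several short TRs (6/12/24/48 ms) for pooled multi-TR fitting,
* ``mncl2``    -- MnCl2 solution (T1 = 0.54 s), TR = 7 ms, 13 angles 2-36
  degrees, the setting in which imperfect RF spoiling bends the high-angle
  end of the line,
* ``brain3c``  -- three-compartment brain (WM/GM/CSF T1 = 0.85/1.29/4.58 s),
  TR = 11 ms, 16 angles 2-60 degrees, for voxelwise mapping tests.

Noise is additive Gaussian or Rician (magnitude of a complex Gaussian);
signal bias is emulated phenomenologically: a multiplicative high-angle
deviation (imperfect spoiling; sign, onset and ramp are parameters since the
real effect varies with the RF phase increment), an additive low-angle
offset, or numeric integration of the Ernst signal across a slice profile.
All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from .bias import BiasField, apply_transmit_bias
from .data import SignalSet
from .signal_model import TissueParams, algebraic_signal
from .transforms import rho1_from_relaxation, tau_from_alpha
from .uncertainty import NoiseModel

__all__ = [
    "PhantomSpec",
    "DeviationSpec",
    "generate_vfa_signals",
    "slice_profile_signal",
    "generate_phantom_volumes",
    "gaussian_profile",
    "agar_phantom",
    "mncl2_phantom",
    "brain3c_phantom",
    "EXP1_PROTOCOL",
    "EXP3_PROTOCOL",
    "EXP4_PROTOCOL",
    "protocol_preset",
]

MAX_VOXELS = 64**3


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth T1/amplitude structure, scalar or labelled 3D grid.

    For scalar phantoms ``t1_s`` and ``amplitude`` are floats.  For labelled
    phantoms ``labels`` is an integer grid (0 = background) and
    ``compartments`` maps label -> (t1_s, amplitude).
    """

    name: str
    t1_s: Union[float, Dict[int, float]]
    amplitude: Union[float, Dict[int, float]] = 1.0
    labels: Optional[np.ndarray] = None
    compartments: Optional[Dict[int, Tuple[float, float]]] = None

    def __post_init__(self):
        if self.labels is None:
            if self.t1_s <= 0.0:
                raise ValueError("t1_s must be positive")
            if self.amplitude <= 0.0:
                raise ValueError("amplitude must be positive")
        else:
            if not self.compartments:
                raise ValueError("labelled phantoms need a compartments map")
            for lab, (t1, amp) in self.compartments.items():
                if t1 <= 0.0 or amp <= 0.0:
                    raise ValueError(f"compartment {lab}: t1 and amplitude must be positive")

    def parameter_maps(self) -> Tuple[np.ndarray, np.ndarray]:
        """(t1_map, amplitude_map) over the label grid (NaN/0 in background)."""
        if self.labels is None:
            raise ValueError("scalar phantom has no label grid")
        t1_map = np.zeros(self.labels.shape, dtype=float)
        amp_map = np.zeros(self.labels.shape, dtype=float)
        for lab, (t1, amp) in self.compartments.items():
            sel = self.labels == lab
            t1_map[sel] = t1
            amp_map[sel] = amp
        return t1_map, amp_map


@dataclass(frozen=True)
class DeviationSpec:
    """Phenomenological departure from the ideal flip-angle dependence.

    kind
        ``"none"``; ``"high_angle_multiplicative"`` (signal scaled by
        ``1 + magnitude`` above ``onset_alpha_deg``; imperfect-spoiling
        emulation -- magnitude may be negative and may ramp linearly with
        angle above onset); ``"low_angle_offset"`` (additive ``magnitude``
        in signal units at or below ``onset_alpha_deg``); or
        ``"slice_profile"`` (signal integrated across ``profile``).
    """

    kind: str = "none"
    magnitude: float = 0.0
    onset_alpha_deg: float = 15.0
    ramp: bool = False
    profile: Optional[np.ndarray] = None

    def __post_init__(self):
        kinds = ("none", "high_angle_multiplicative", "low_angle_offset", "slice_profile")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.kind == "slice_profile" and self.profile is None:
            raise ValueError("slice_profile deviation needs a sampled profile")


def agar_phantom() -> PhantomSpec:
    """Long-T1 agar gel phantom (T1 = 2.41 s)."""
    return PhantomSpec("agar", t1_s=2.41, amplitude=1.0)


def mncl2_phantom() -> PhantomSpec:
    """MnCl2 solution phantom (T1 = 0.54 s)."""
    return PhantomSpec("mncl2", t1_s=0.54, amplitude=1.0)


def brain3c_phantom(shape: Tuple[int, int, int] = (24, 24, 24)) -> PhantomSpec:
    """Three-compartment brain: nested spheres of CSF, WM and GM.

    T1 values are the in-vivo reference points (WM 0.85 s, GM 1.29 s,
    CSF 4.58 s); the relative amplitudes (0.7/0.8/1.0) are typical
    proton-density-like weights.  Labels: 1 = WM, 2 = GM, 3 = CSF,
    0 = background.
    """
    zz, yy, xx = np.meshgrid(*(np.linspace(-1.0, 1.0, s) for s in shape), indexing="ij")
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    labels = np.zeros(shape, dtype=np.int16)
    labels[r < 0.85] = 2   # cortical GM shell
    labels[r < 0.60] = 1   # WM
    labels[r < 0.25] = 3   # central CSF (ventricle)
    return PhantomSpec(
        "brain3c",
        t1_s=0.0,
        amplitude=0.0,
        labels=labels,
        compartments={1: (0.85, 0.7), 2: (1.29, 0.8), 3: (4.58, 1.0)},
    )


#: acquisition presets: (tr_s, flip angles in degrees)
EXP1_PROTOCOL: Tuple[Tuple[float, Tuple[int, ...]], ...] = (
    (0.006, tuple(range(1, 14))),
    (0.012, tuple(range(1, 19))),
    (0.024, tuple(range(1, 25))),
    (0.048, tuple(range(2, 35, 2))),
)
EXP3_PROTOCOL: Tuple[float, Tuple[int, ...]] = (
    0.007, (2, 3, 4, 6, 8, 10, 12, 15, 18, 21, 24, 30, 36)
)
EXP4_PROTOCOL: Tuple[float, Tuple[int, ...]] = (
    0.011, (2, 4, 6, 8, 10, 12, 15, 18, 21, 24, 28, 32, 36, 40, 50, 60)
)


def protocol_preset(name: str):
    """Return a named acquisition preset (``exp1``, ``exp3`` or ``exp4``)."""
    presets = {"exp1": EXP1_PROTOCOL, "exp3": EXP3_PROTOCOL, "exp4": EXP4_PROTOCOL}
    if name not in presets:
        raise ValueError(f"unknown protocol preset '{name}'; choose from {sorted(presets)}")
    return presets[name]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _add_noise(signal: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    if noise.sigma_s == 0.0:
        return signal
    if noise.kind == "gaussian":
        return signal + rng.normal(0.0, noise.sigma_s, size=signal.shape)
    n1 = rng.normal(0.0, noise.sigma_s, size=signal.shape)
    n2 = rng.normal(0.0, noise.sigma_s, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def _apply_deviation(signal, alphas, deviation: DeviationSpec, amplitude, t1, tr):
    if deviation.kind == "none":
        return signal
    a = np.asarray(alphas, dtype=float)
    if deviation.kind == "high_angle_multiplicative":
        hit = a > deviation.onset_alpha_deg
        factor = np.ones_like(a)
        if deviation.ramp:
            span = max(float(np.max(a)) - deviation.onset_alpha_deg, 1e-12)
            factor[hit] = 1.0 + deviation.magnitude * (a[hit] - deviation.onset_alpha_deg) / span
        else:
            factor[hit] = 1.0 + deviation.magnitude
        return signal * factor
    if deviation.kind == "low_angle_offset":
        out = signal.copy()
        out[a <= deviation.onset_alpha_deg] += deviation.magnitude
        return out
    # slice_profile: replace each ideal signal by its profile integral
    return np.array([
        slice_profile_signal(
            alpha, deviation.profile,
            TissueParams(amplitude, rho1_from_relaxation(tr_i, t1)), tr_i,
        )
        for alpha, tr_i in zip(a, np.broadcast_to(tr, a.shape))
    ])


def generate_vfa_signals(
    phantom: PhantomSpec,
    alphas_deg: Sequence[float],
    tr_s,
    noise: Optional[NoiseModel] = None,
    deviation: Optional[DeviationSpec] = None,
    seed: Optional[int] = None,
    bias_field: Optional[BiasField] = None,
) -> SignalSet:
    """Simulate one region-of-interest VFA series from a scalar phantom.

    ``signals = model(actual angles) x deviation + noise``; the actual angle
    is ``f * nominal`` when a transmit bias field is given, while the
    returned sample table carries the nominal angles (as a scanner would).
    A seed is mandatory whenever the noise level is nonzero, making every
    draw reproducible.
    """
    if phantom.labels is not None:
        raise ValueError("use generate_phantom_volumes for labelled phantoms")
    alphas = np.asarray(alphas_deg, dtype=float)
    tr = np.asarray(tr_s, dtype=float)
    if tr.ndim == 0:
        tr = np.full_like(alphas, float(tr))
    noise = noise or NoiseModel(0.0)
    deviation = deviation or DeviationSpec()
    if noise.sigma_s > 0.0 and seed is None:
        raise ValueError("a seed is mandatory for any nonzero noise level")
    actual = alphas if bias_field is None else apply_transmit_bias(alphas, bias_field)
    rho1 = rho1_from_relaxation(tr, phantom.t1_s)
    signal = algebraic_signal(phantom.amplitude, tau_from_alpha(actual), rho1)
    signal = _apply_deviation(
        np.atleast_1d(signal), actual, deviation, phantom.amplitude, phantom.t1_s, tr
    )
    signal = _add_noise(signal, noise, _rng(seed))
    sd = np.full_like(alphas, noise.sigma_s) if noise.sigma_s > 0.0 else None
    return SignalSet(alphas, tr, np.clip(signal, 0.0, None), sd)


def gaussian_profile(n: int = 201, fwhm: float = 0.6, floor: float = 0.0) -> np.ndarray:
    """Gaussian-tapered relative flip-angle profile across slice position."""
    z = np.linspace(-1.0, 1.0, n)
    sig = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return floor + (1.0 - floor) * np.exp(-(z**2) / (2.0 * sig**2))


MIN_PROFILE_POINTS = 101


def slice_profile_signal(alpha_nominal_deg: float, profile, tissue: TissueParams, tr: float) -> float:
    """Ernst signal integrated across a slice excitation profile.

    ``profile`` samples the relative flip angle across slice position on a
    uniform grid; it is resampled to at least 101 points and the signal
    ``S(f(z) * alpha)`` averaged by the trapezoid rule.  A boxcar profile of
    ones reproduces the nonselective signal exactly.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise ValueError("profile must be a 1-D sampling with >= 2 points")
    if np.any(p < 0.0):
        raise ValueError("profile values must be non-negative")
    if not np.any(p > 0.0):
        raise ValueError("profile must not be identically zero")
    if len(p) < MIN_PROFILE_POINTS:
        zc = np.linspace(0.0, 1.0, MIN_PROFILE_POINTS)
        p = np.interp(zc, np.linspace(0.0, 1.0, len(p)), p)
    z = np.linspace(0.0, 1.0, len(p))
    alphas = p * float(alpha_nominal_deg)
    e1 = float(np.exp(-tr / _t1_from_tissue(tissue, tr)))
    s = np.where(alphas > 0.0,
                 _ernst_unchecked(tissue.amplitude, alphas, e1),
                 0.0)
    return float(np.trapezoid(s, z) / np.trapezoid(np.ones_like(z), z))


def _t1_from_tissue(tissue: TissueParams, tr: float) -> float:
    from .transforms import relaxation_from_rho1

    return relaxation_from_rho1(tissue.rho1, tr)


def _ernst_unchecked(amplitude, alpha_deg, e1):
    rad = np.deg2rad(np.asarray(alpha_deg, dtype=float))
    return amplitude * np.sin(rad) * (1.0 - e1) / (1.0 - e1 * np.cos(rad))


def generate_phantom_volumes(
    phantom: PhantomSpec,
    alphas_deg: Sequence[float],
    tr_s: float,
    noise: Optional[NoiseModel] = None,
    bias_field: Optional[BiasField] = None,
    seed: Optional[int] = None,
    max_voxels: int = MAX_VOXELS,
):
    """Simulate an image-volume stack (one volume per flip angle).

    Per-voxel signals follow the algebraic Ernst equation with the voxel's
    (T1, amplitude) and transmit-bias factor; Gaussian or Rician noise is
    drawn independently per voxel and volume.  Returns a
    :class:`~vfalin.mapping.VolumeStack`.
    """
    from .mapping import VolumeStack  # deferred: mapping imports estimators

    if phantom.labels is None:
        raise ValueError("generate_phantom_volumes needs a labelled phantom")
    shape = phantom.labels.shape
    if int(np.prod(shape)) > max_voxels:
        raise ValueError(
            f"phantom geometry {shape} exceeds the configured cap of {max_voxels} voxels"
        )
    alphas = np.asarray(alphas_deg, dtype=float)
    noise = noise or NoiseModel(0.0)
    if noise.sigma_s > 0.0 and seed is None:
        raise ValueError("a seed is mandatory for any nonzero noise level")
    t1_map, amp_map = phantom.parameter_maps()
    inside = t1_map > 0.0
    rho1 = np.zeros(shape)
    rho1[inside] = rho1_from_relaxation(tr_s, t1_map[inside])

    if bias_field is None:
        f = np.ones(shape)
    else:
        f = np.broadcast_to(np.asarray(bias_field.f, dtype=float), shape).copy()

    data = np.zeros(shape + (len(alphas),), dtype=float)
    actual = f[..., None] * alphas[None, None, None, :]
    if np.any(actual >= 180.0):
        raise ValueError("biased flip angle reaches 180 degrees or more")
    tau = 2.0 * np.tan(np.deg2rad(actual) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = 2.0 * amp_map[..., None] * rho1[..., None] * tau / (tau**2 + 2.0 * rho1[..., None])
    s[~inside] = 0.0
    data[...] = _add_noise(s, noise, _rng(seed))
    np.clip(data, 0.0, None, out=data)
    return VolumeStack(
        data=data,
        alpha_deg=alphas,
        tr_s=np.full(len(alphas), float(tr_s)),
        affine=np.eye(4),
    )
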