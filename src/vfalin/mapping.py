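"""Voxelwise T1/amplitude mapping of image-volume stacks.

A :class:`VolumeStack` holds one 3D signal volume per flip angle together
with per-volume acquisition metadata (flip angle, TR) and the grid affine.
:func:`fit_volume` evaluates the closed-form linear regression of
``S/tau`` on ``S*tau`` (or ``S*tau/(2*TR)`` in multi-TR mode) for all voxels
in one vectorized pass, with optional transmit-bias (B1) correction either
exactly (per-voxel tau from the actual flip angle) or post hoc on the
small-angle approximation (T1 divided by f**2, amplitude by f).

I/O uses NIfTI (via nibabel) plus a JSON sidecar listing per-volume
``alpha_deg`` and ``tr_s``; the grid affine is carried through untouched and
never resampled.  Missing values in parameter maps are NaN.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import nibabel as nib
import numpy as np

from .bias import BiasField
from .estimators import batch_fit_line
from .exceptions import InsufficientDataError
from .transforms import tau_from_alpha

__all__ = ["VolumeStack", "ParameterMaps", "fit_volume",
           "read_stack", "write_stack", "write_maps", "read_maps"]

logger = logging.getLogger("vfalin")

SIDECAR_FIELDS = ("alpha_deg", "tr_s")
#: mask threshold: low-angle mean signal must exceed k times the background
DEFAULT_BACKGROUND_K = 5.0


@dataclass
class VolumeStack:
    """Ordered 3D signal volumes with per-volume acquisition metadata."""

    data: np.ndarray            # (X, Y, Z, V)
    alpha_deg: np.ndarray       # (V,)
    tr_s: np.ndarray            # (V,)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.alpha_deg = np.atleast_1d(np.asarray(self.alpha_deg, dtype=float))
        self.tr_s = np.atleast_1d(np.asarray(self.tr_s, dtype=float))
        if self.data.ndim != 4:
            raise ValueError("data must be a 4-D array (x, y, z, volume)")
        v = self.data.shape[-1]
        if len(self.alpha_deg) != v or len(self.tr_s) != v:
            raise ValueError(
                "per-volume metadata length must equal the number of volumes"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def single_tr(self) -> bool:
        return bool(np.all(self.tr_s == self.tr_s[0]))


@dataclass
class ParameterMaps:
    """Fitted parameter maps; NaN marks voxels outside the mask."""

    t1: np.ndarray              # seconds
    amplitude: np.ndarray       # a.u.
    mask: np.ndarray            # bool
    nfit: np.ndarray            # measurements used per voxel
    se: Dict[str, np.ndarray] = field(default_factory=dict)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def _estimate_background(low_mean: np.ndarray) -> float:
    """Background level: median of the lowest-decile voxels.

    Returns 0 when the lowest decile is not clearly separated from the bulk
    of the image (no detectable dark background), in which case the caller
    falls back to a strict positivity mask.
    """
    flat = low_mean[np.isfinite(low_mean)]
    if not len(flat):
        return 0.0
    lowest = flat[flat <= np.percentile(flat, 10.0)]
    bg = float(np.median(lowest)) if len(lowest) else 0.0
    if bg > 0.25 * np.percentile(flat, 90.0):
        return 0.0
    return bg


def fit_volume(
    stack: VolumeStack,
    b1: Optional[BiasField] = None,
    b1_mode: str = "posthoc",
    alpha_max: Optional[float] = None,
    alpha_min: Optional[float] = None,
    multi_tr: bool = False,
    mask: Optional[np.ndarray] = None,
    background_k: float = DEFAULT_BACKGROUND_K,
) -> ParameterMaps:
    """Closed-form voxelwise regression of a VFA volume stack.

    Parameters
    ----------
    stack : VolumeStack
    b1 : optional transmit-bias field (scalar or grid matching the volumes)
    b1_mode : ``"posthoc"`` divides fitted T1 by f**2 (and amplitude by f;
        valid in the small-angle regime) -- ``"exact"`` computes per-voxel
        tau from the actual flip angle ``f*alpha`` before fitting
    alpha_min, alpha_max : optional angle-subset selection, degrees (e.g.
        exclude high angles identified as bias-affected)
    multi_tr : pool volumes at different short TRs (T1 = negative slope)
    mask : optional boolean inclusion grid; by default voxels whose
        low-angle mean signal exceeds ``background_k`` times the estimated
        background are fitted
    """
    sel = np.ones(stack.n_volumes, dtype=bool)
    if alpha_max is not None:
        sel &= stack.alpha_deg <= alpha_max
    if alpha_min is not None:
        sel &= stack.alpha_deg >= alpha_min
    if np.sum(sel) < 2:
        raise InsufficientDataError("angle subset leaves fewer than 2 volumes")
    data = stack.data[..., sel]
    alphas = stack.alpha_deg[sel]
    trs = stack.tr_s[sel]
    if not multi_tr and not np.all(trs == trs[0]):
        raise ValueError("volumes span several TRs; use multi_tr=True")

    if mask is None:
        low = alphas <= np.median(alphas)
        low_mean = data[..., low].mean(axis=-1)
        bg = _estimate_background(low_mean)
        mask = low_mean > background_k * bg if bg > 0.0 else low_mean > 0.0
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape[:3]:
        raise ValueError("mask shape must match the volume grid")

    if b1 is not None and b1_mode == "exact":
        f = np.broadcast_to(np.asarray(b1.f, dtype=float), data.shape[:3])
        actual = f[..., None] * alphas
        if np.any(actual[mask] >= 180.0):
            raise ValueError("biased flip angle reaches 180 degrees or more")
        tau = 2.0 * np.tan(np.deg2rad(actual) / 2.0)
    else:
        tau = tau_from_alpha(alphas)

    res = batch_fit_line(tau, data, tr=trs if multi_tr else float(trs[0]),
                         multi_tr=multi_tr)
    valid = res["valid"] & mask
    n_degenerate = int(np.sum(mask & ~res["valid"]))
    if n_degenerate:
        logger.info("masked out %d voxel(s) with degenerate fits", n_degenerate)

    t1 = np.where(valid, res["t1"], np.nan)
    amplitude = np.where(valid, res["amplitude"], np.nan)
    if b1 is not None and b1_mode == "posthoc":
        f = np.broadcast_to(np.asarray(b1.f, dtype=float), data.shape[:3])
        t1 = t1 / f**2
        amplitude = amplitude / f
    elif b1 is not None and b1_mode != "exact":
        raise ValueError("b1_mode must be 'posthoc' or 'exact'")

    nfit = np.where(valid, int(np.sum(sel)), 0)
    return ParameterMaps(
        t1=t1, amplitude=amplitude, mask=valid, nfit=nfit,
        affine=stack.affine.copy(),
    )


def write_stack(stack: VolumeStack, path) -> Path:
    """Write a stack as one 4D NIfTI plus a JSON sidecar.

    The sidecar (same name, ``.json``) lists per-volume ``alpha_deg`` and
    ``tr_s``; write-then-read round trips are lossless.
    """
    path = Path(path)
    nib.save(nib.Nifti1Image(stack.data, stack.affine), str(path))
    sidecar = _sidecar_path(path)
    meta = {"volumes": [
        {"alpha_deg": float(a), "tr_s": float(t)}
        for a, t in zip(stack.alpha_deg, stack.tr_s)
    ]}
    sidecar.write_text(json.dumps(meta, indent=1))
    return path


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_stack(path, sidecar: Optional[Union[str, Path]] = None) -> VolumeStack:
    """Read a 4D NIfTI (or list of 3D NIfTIs) plus its JSON sidecar."""
    if isinstance(path, (list, tuple)):
        imgs = [nib.load(str(p)) for p in path]
        data = np.stack([np.asarray(i.dataobj, dtype=float) for i in imgs], axis=-1)
        affine = imgs[0].affine
        if sidecar is None:
            raise ValueError("a sidecar path is required for a list of volumes")
    else:
        path = Path(path)
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError("expected a 4-D NIfTI (x, y, z, volume)")
        affine = img.affine
        sidecar = sidecar or _sidecar_path(path)
    meta = json.loads(Path(sidecar).read_text())
    if "volumes" not in meta:
        raise ValueError("sidecar is missing required field: volumes")
    vols = meta["volumes"]
    if len(vols) != data.shape[-1]:
        raise ValueError(
            f"sidecar lists {len(vols)} volumes but the image has {data.shape[-1]}"
        )
    for i, v in enumerate(vols):
        missing = [k for k in SIDECAR_FIELDS if k not in v]
        if missing:
            raise ValueError(
                f"sidecar volume {i} is missing field(s): {', '.join(missing)}"
            )
    return VolumeStack(
        data=data,
        alpha_deg=np.array([v["alpha_deg"] for v in vols], dtype=float),
        tr_s=np.array([v["tr_s"] for v in vols], dtype=float),
        affine=affine,
    )


def write_maps(maps: ParameterMaps, prefix) -> Dict[str, Path]:
    """Write parameter maps as NIfTI files ``<prefix>_{t1,amplitude,...}.nii``.

    A JSON sidecar records units and the missing-value convention.
    """
    prefix = Path(prefix)
    out: Dict[str, Path] = {}
    layers = {
        "t1": maps.t1, "amplitude": maps.amplitude,
        "mask": maps.mask.astype(np.uint8), "nfit": maps.nfit.astype(np.int16),
    }
    for key, arr in layers.items():
        p = prefix.parent / f"{prefix.name}_{key}.nii"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), maps.affine), str(p))
        out[key] = p
    meta = {"units": {"t1": "s", "amplitude": "a.u."}, "missing_value": "NaN"}
    (prefix.parent / f"{prefix.name}_maps.json").write_text(json.dumps(meta, indent=1))
    return out


def read_maps(prefix) -> ParameterMaps:
    """Reload parameter maps written by :func:`write_maps`."""
    prefix = Path(prefix)
    arrays = {}
    for key in ("t1", "amplitude", "mask", "nfit"):
        img = nib.load(str(prefix.parent / f"{prefix.name}_{key}.nii"))
        arrays[key] = np.asarray(img.dataobj, dtype=float)
        affine = img.affine
    return ParameterMaps(
        t1=arrays["t1"],
        amplitude=arrays["amplitude"],
        mask=arrays["mask"].astype(bool),
        nfit=arrays["nfit"].astype(int),
        affine=affine,
    )
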