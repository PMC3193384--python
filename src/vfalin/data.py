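"""Sample containers and tabular I/O for variable flip angle measurements.

A :class:`VFASample` is one (flip angle, TR, signal) measurement; a
:class:`SignalSet` is an ordered collection held as numpy arrays, the common
currency of all estimators.  Tables are delimited text with header columns
``alpha_deg``, ``tr_s``, ``signal`` and optionally ``sd`` (per-measurement
signal standard deviation, arbitrary units).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .transforms import tau_from_alpha

__all__ = ["VFASample", "SignalSet", "read_table", "write_table"]

TABLE_COLUMNS = ("alpha_deg", "tr_s", "signal")


@dataclass(frozen=True)
class VFASample:
    """One spoiled gradient-echo measurement.

    Attributes
    ----------
    alpha_deg : nominal flip angle, degrees, in (0, 180)
    tr : repetition time, seconds
    signal : mean signal magnitude, arbitrary units (non-negative)
    sd : optional signal standard deviation, arbitrary units
    """

    alpha_deg: float
    tr: float
    signal: float
    sd: Optional[float] = None

    def __post_init__(self):
        if not 0.0 < self.alpha_deg < 180.0:
            raise ValueError("alpha_deg must lie in the open interval (0, 180)")
        if self.tr <= 0.0:
            raise ValueError("tr must be positive (seconds)")
        if self.signal < 0.0:
            raise ValueError("signal must be non-negative")

    @property
    def tau(self) -> float:
        return tau_from_alpha(self.alpha_deg)


@dataclass
class SignalSet:
    """Ordered collection of VFA measurements as flat arrays."""

    alpha_deg: np.ndarray
    tr_s: np.ndarray
    signal: np.ndarray
    sd: Optional[np.ndarray] = None

    def __post_init__(self):
        self.alpha_deg = np.atleast_1d(np.asarray(self.alpha_deg, dtype=float))
        self.signal = np.atleast_1d(np.asarray(self.signal, dtype=float))
        tr = np.asarray(self.tr_s, dtype=float)
        if tr.ndim == 0:
            tr = np.full_like(self.alpha_deg, float(tr))
        self.tr_s = tr
        if self.sd is not None:
            sd = np.asarray(self.sd, dtype=float)
            if sd.ndim == 0:
                sd = np.full_like(self.alpha_deg, float(sd))
            self.sd = sd
        n = len(self.alpha_deg)
        if len(self.tr_s) != n or len(self.signal) != n:
            raise ValueError("alpha_deg, tr_s and signal must have equal length")
        if self.sd is not None and len(self.sd) != n:
            raise ValueError("sd must match the number of samples")
        if np.any(self.alpha_deg <= 0.0) or np.any(self.alpha_deg >= 180.0):
            raise ValueError("alpha_deg must lie in the open interval (0, 180)")
        if np.any(self.tr_s <= 0.0):
            raise ValueError("tr_s must be positive (seconds)")

    def __len__(self) -> int:
        return len(self.alpha_deg)

    def __iter__(self) -> Iterator[VFASample]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i) -> "VFASample | SignalSet":
        if isinstance(i, (int, np.integer)):
            return VFASample(
                float(self.alpha_deg[i]),
                float(self.tr_s[i]),
                float(self.signal[i]),
                None if self.sd is None else float(self.sd[i]),
            )
        return SignalSet(
            self.alpha_deg[i],
            self.tr_s[i],
            self.signal[i],
            None if self.sd is None else self.sd[i],
        )

    @property
    def tau(self) -> np.ndarray:
        return tau_from_alpha(self.alpha_deg)

    @property
    def single_tr(self) -> bool:
        return bool(np.all(self.tr_s == self.tr_s[0]))

    @classmethod
    def from_samples(cls, samples: Sequence[VFASample]) -> "SignalSet":
        samples = list(samples)
        sds = [s.sd for s in samples]
        return cls(
            np.array([s.alpha_deg for s in samples]),
            np.array([s.tr for s in samples]),
            np.array([s.signal for s in samples]),
            None if any(v is None for v in sds) else np.array(sds, dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"alpha_deg": self.alpha_deg, "tr_s": self.tr_s, "signal": self.signal}
        )
        if self.sd is not None:
            df["sd"] = self.sd
        return df


def read_table(path) -> SignalSet:
    """Read a VFA measurement table from delimited text.

    The delimiter (comma, tab or whitespace) is sniffed automatically.
    Required columns: ``alpha_deg``, ``tr_s``, ``signal``; optional: ``sd``.
    """
    df = pd.read_csv(Path(path), sep=None, engine="python")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing required column(s): {', '.join(missing)}")
    sd = df["sd"].to_numpy(dtype=float) if "sd" in df.columns else None
    return SignalSet(
        df["alpha_deg"].to_numpy(dtype=float),
        df["tr_s"].to_numpy(dtype=float),
        df["signal"].to_numpy(dtype=float),
        sd,
    )


def write_table(samples: SignalSet, path, sep: str = "\t") -> None:
    """Write a `SignalSet` as delimited text with a header row."""
    samples.to_frame().to_csv(Path(path), sep=sep, index=False)
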