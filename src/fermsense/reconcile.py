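"""Signal reconciliation: median + moving-average filtering and TCD calibration.

Raw channels are reconciled by a centred median filter followed by a centred
moving average, both over a 20-minute window (5 samples at 5-minute
sampling, the window in samples being rounded up to the nearest odd count).
Edge windows shrink symmetrically so every grid point keeps a value.  The
median stage removes lone probe spikes; the average stage smooths what
remains.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .simulate import ProcessTimeSeries

__all__ = [
    "FilterSpec",
    "TcdCalibration",
    "reconcile",
    "filter_signal",
    "calibrate_tcd",
    "fit_tcd_calibration",
]


@dataclass(frozen=True)
class FilterSpec:
    window_minutes: float = 20.0
    sample_interval_minutes: float = 5.0
    stages: tuple = ("median", "moving_average")

    def __post_init__(self) -> None:
        if self.window_minutes < self.sample_interval_minutes:
            raise ValueError("window must be at least one sampling interval")
        for s in self.stages:
            if s not in ("median", "moving_average"):
                raise ValueError(f"unknown filter stage {s!r}")

    @property
    def window_samples(self) -> int:
        """Window width in samples, forced odd for a centred window."""
        k = round(self.window_minutes / self.sample_interval_minutes)
        return k if k % 2 == 1 else k + 1


def _centred_pass(x: np.ndarray, k: int, reduce) -> np.ndarray:
    """One centred filtering pass; edge windows shrink symmetrically."""
    n = x.size
    half = k // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = reduce(x[i - h : i + h + 1])
    return out


def filter_signal(x, spec: FilterSpec | None = None) -> np.ndarray:
    """Apply the configured filter stages in order to a 1-d signal."""
    spec = spec or FilterSpec()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-d signal")
    k = spec.window_samples
    if k > x.size:
        raise ValueError(
            f"filter window of {k} samples exceeds series length {x.size}"
        )
    for stage in spec.stages:
        reduce = np.median if stage == "median" else np.mean
        x = _centred_pass(x, k, reduce)
    return x


def reconcile(
    series: ProcessTimeSeries, channels: list[str], spec: FilterSpec | None = None
) -> ProcessTimeSeries:
    """Return a copy of the series with the named channels filtered."""
    spec = spec or FilterSpec()
    frame = series.frame.copy()
    for ch in channels:
        if ch not in frame:
            raise KeyError(f"channel {ch!r} not present in series")
        frame[ch] = filter_signal(frame[ch].to_numpy(), spec)
    return ProcessTimeSeries(frame, dict(series.meta))


@dataclass(frozen=True)
class TcdCalibration:
    """Linear AU -> g/L calibration for the turbidity probe."""

    gain: float                  # g/L per AU
    offset: float = 0.0          # g/L
    media_label: str = ""
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("calibration gain must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TcdCalibration":
        with open(path) as fh:
            return cls(**json.load(fh))


def calibrate_tcd(series: ProcessTimeSeries, cal: TcdCalibration) -> np.ndarray:
    """Biomass estimate (g/L) from the AU channel, clipped below at zero."""
    if "tcd_au" not in series.frame:
        raise KeyError("series has no tcd_au channel")
    au = series.frame["tcd_au"].to_numpy()
    return np.maximum(cal.gain * au + cal.offset, 0.0)


def fit_tcd_calibration(
    au_values, cdw_values, media_label: str = ""
) -> TcdCalibration:
    """Least-squares line cdw = gain·AU + offset from paired samples."""
    au = np.asarray(au_values, dtype=float)
    cdw = np.asarray(cdw_values, dtype=float)
    if au.size != cdw.size or au.size < 3:
        raise ValueError("need at least 3 paired (AU, CDW) points")
    if np.ptp(au) < 1e-12:
        raise ValueError("AU values are constant; calibration is degenerate")
    a = np.vstack([au, np.ones_like(au)]).T
    (gain, offset), res, *_ = np.linalg.lstsq(a, cdw, rcond=None)
    sst = float(np.sum((cdw - cdw.mean()) ** 2))
    ssr = float(res[0]) if res.size else float(np.sum((a @ [gain, offset] - cdw) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")
    return TcdCalibration(float(gain), float(offset), media_label, r2)
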