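"""Sensor-channel containers, scaling and resampling.

A gait session is a uniformly sampled four-channel record: weight-normalized
vertical load (body-weight units, BW) plus thigh, knee and ankle angles in
degrees.  Sign convention follows the target device: thigh extension, knee
flexion and ankle dorsiflexion are positive.  All downstream stages assume a
200 Hz rate, so arbitrary-rate recordings are linearly resampled first.

Network inputs are squashed into [0, 1] with an affine rule

    v_n = (v / g_v + 5) / 10

where the gain ``g_v`` is 1 for the load channel and 36 for angle channels.
A zero load therefore maps to 0.5 and one body weight to 0.6, while angles in
+/-180 degrees land in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

TARGET_RATE = 200.0
ANGLE_CHANNELS = ("thigh", "knee", "ankle")
CHANNELS = ("f_z",) + ANGLE_CHANNELS

__all__ = [
    "TARGET_RATE",
    "CHANNELS",
    "ANGLE_CHANNELS",
    "GaitSeries",
    "ScalingSpec",
    "scale_signal",
    "unscale_signal",
    "normalize_load",
    "resample",
    "remove_bias",
    "read_session_csv",
    "write_session_csv",
]


@dataclass(frozen=True)
class ScalingSpec:
    """Gains and affine constants of the input-scaling rule."""

    load_gain: float = 1.0
    angle_gain: float = 36.0
    offset: float = 5.0
    divisor: float = 10.0

    def __post_init__(self) -> None:
        if self.load_gain <= 0 or self.angle_gain <= 0:
            raise ValueError("scaling gains must be strictly positive")

    def gain(self, kind: str) -> float:
        if kind == "load":
            return self.load_gain
        if kind == "angle":
            return self.angle_gain
        raise ValueError(f"unknown channel kind {kind!r}; expected 'load' or 'angle'")


DEFAULT_SCALING = ScalingSpec()


@dataclass(frozen=True)
class GaitSeries:
    """Uniformly sampled four-channel gait record.

    Parameters
    ----------
    rate : float
        Sampling rate in samples per second.
    f_z : ndarray
        Weight-normalized vertical load (BW).  Typically >= 0; values above
        1 BW occur during dynamic loading and are kept as recorded.
    thigh, knee, ankle : ndarray
        Joint angles in degrees.
    """

    rate: float
    f_z: np.ndarray
    thigh: np.ndarray
    knee: np.ndarray
    ankle: np.ndarray

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        arrays = {}
        n = None
        for name in CHANNELS:
            a = np.asarray(getattr(self, name), dtype=float)
            if a.ndim != 1:
                raise ValueError(f"channel {name!r} must be one-dimensional")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if n is None:
                n = a.shape[0]
            elif a.shape[0] != n:
                raise ValueError("all channels must have the same length")
            arrays[name] = a
        for name, a in arrays.items():
            object.__setattr__(self, name, a)

    def __len__(self) -> int:
        return self.f_z.shape[0]

    @property
    def duration(self) -> float:
        """Session duration in seconds (n samples at ``rate``)."""
        return len(self) / self.rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self)) / self.rate

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(name)
        return getattr(self, name)

    def as_matrix(self) -> np.ndarray:
        """Stack channels as an (n, 4) matrix in (f_z, thigh, knee, ankle) order."""
        return np.column_stack([getattr(self, c) for c in CHANNELS])

    def scaled_matrix(self, spec: ScalingSpec = DEFAULT_SCALING) -> np.ndarray:
        """Network-ready (n, 4) matrix with every channel scaled into [0, 1]."""
        cols = [scale_signal(self.f_z, "load", spec)]
        cols += [scale_signal(getattr(self, c), "angle", spec) for c in ANGLE_CHANNELS]
        return np.column_stack(cols)


def scale_signal(v, kind: str, spec: ScalingSpec = DEFAULT_SCALING):
    """Scale a raw channel value into the network's [0, 1] input range.

    ``v_n = (v / g + 5) / 10`` with gain ``g`` of 1 (load) or 36 (angle), so a
    load of 0 BW maps to 0.5 and 1 BW to 0.6.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("scale_signal: input contains non-finite values")
    out = (v / spec.gain(kind) + spec.offset) / spec.divisor
    return out if out.ndim else float(out)


def unscale_signal(v_n, kind: str, spec: ScalingSpec = DEFAULT_SCALING):
    """Exact inverse of :func:`scale_signal`."""
    v_n = np.asarray(v_n, dtype=float)
    if not np.all(np.isfinite(v_n)):
        raise ValueError("unscale_signal: input contains non-finite values")
    out = (v_n * spec.divisor - spec.offset) * spec.gain(kind)
    return out if out.ndim else float(out)


def normalize_load(raw_load, body_weight: float):
    """Divide a raw vertical force by the user's body weight (same units)."""
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    raw_load = np.asarray(raw_load, dtype=float)
    out = raw_load / body_weight
    return out if out.ndim else float(out)


def resample(series: GaitSeries, target_rate: float = TARGET_RATE) -> GaitSeries:
    """Linearly resample every channel onto a uniform ``target_rate`` grid.

    Duration is preserved to within one sample period.  Linear interpolation
    is exact on constants and loses <1% amplitude on gait-band sinusoids at
    these rates, so no anti-alias filter is applied.
    """
    n = len(series)
    if n < 2:
        raise ValueError("resample requires at least two samples")
    if series.rate == target_rate:
        return series
    t_src = np.arange(n) / series.rate
    n_out = int(round((n - 1) * target_rate / series.rate)) + 1
    t_out = np.arange(n_out) / target_rate
    t_out = np.minimum(t_out, t_src[-1])  # guard the last grid point
    kw = {
        name: np.interp(t_out, t_src, series.channel(name)) for name in CHANNELS
    }
    return GaitSeries(rate=target_rate, **kw)


def remove_bias(series: GaitSeries, baseline: Mapping[str, float]) -> GaitSeries:
    """Subtract per-channel angular offsets; the load channel is untouched.

    ``baseline`` maps angle-channel names to the offset (degrees) to remove,
    e.g. the channel mean over a quiet-standing window.
    """
    unknown = set(baseline) - set(ANGLE_CHANNELS)
    if unknown:
        raise ValueError(f"baseline offsets given for non-angle channels: {sorted(unknown)}")
    kw = {"f_z": series.f_z}
    for name in ANGLE_CHANNELS:
        kw[name] = series.channel(name) - float(baseline.get(name, 0.0))
    return GaitSeries(rate=series.rate, **kw)


def standing_baseline(series: GaitSeries, start: int = 0, stop: int | None = None) -> dict:
    """Per-angle-channel means over a quiet-standing window [start, stop)."""
    sl = slice(start, stop)
    return {name: float(np.mean(series.channel(name)[sl])) for name in ANGLE_CHANNELS}


# -- CSV session format ------------------------------------------------------
# Columns: time, fz, thigh, knee, ankle; header required; '.' decimal, UTF-8.

_CSV_COLUMNS = ["time", "fz", "thigh", "knee", "ankle"]


def read_session_csv(path, rate: float | None = None) -> GaitSeries:
    """Read a session CSV; the rate is declared or inferred from ``time``."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"session CSV {path} is missing columns {missing}")
    if rate is None:
        dt = np.diff(df["time"].to_numpy(dtype=float))
        if dt.size == 0 or np.any(dt <= 0):
            raise ValueError("cannot infer sampling rate from the time column")
        rate = 1.0 / float(np.median(dt))
    return GaitSeries(
        rate=rate,
        f_z=df["fz"].to_numpy(dtype=float),
        thigh=df["thigh"].to_numpy(dtype=float),
        knee=df["knee"].to_numpy(dtype=float),
        ankle=df["ankle"].to_numpy(dtype=float),
    )


def write_session_csv(series: GaitSeries, path, extra: Mapping[str, np.ndarray] | None = None) -> None:
    """Write a session CSV, optionally with extra aligned columns
    (e.g. ``phase_bin``, ``phase_pct``, ``phase_pred``; NaN -> empty field)."""
    data = {
        "time": series.time,
        "fz": series.f_z,
        "thigh": series.thigh,
        "knee": series.knee,
        "ankle": series.ankle,
    }
    if extra:
        for k, v in extra.items():
            v = np.asarray(v)
            if v.shape[0] != len(series):
                raise ValueError(f"extra column {k!r} is not aligned with the series")
            data[k] = v
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")
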