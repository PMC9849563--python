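"""Evaluation of phase predictions and gait trajectories.

Three families of quantities:

* coefficient of determination (R^2) of the predictions in the scaled polar
  space (p'_x, p'_y), per component and averaged;
* circular phase-error summaries (mean / median / interquartile range, in
  percent of the gait cycle);
* stride-normalized median trajectories (101 points over 0-100% of the
  cycle, with 25th/75th percentile bands) and Pearson correlations between
  them, used to compare gait shapes across datasets or devices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

from . import phase as phase_mod
from .signals import CHANNELS, GaitSeries

__all__ = [
    "EvalReport",
    "r_squared",
    "phase_error_summary",
    "median_trajectory",
    "MedianTrajectory",
    "pearson_median_correlation",
]

N_GRID = 101  # phase points 0, 1, ..., 100 %


def r_squared(actual, predicted):
    """R^2 of scaled polar predictions, per component and averaged.

    Standard 1 - SS_res/SS_tot on each of (p'_x, p'_y); returns
    ``(mean, (r2_x, r2_y))``.  Raises if a target component has zero
    variance (R^2 undefined).
    """
    A = np.asarray(actual, dtype=float)
    P = np.asarray(predicted, dtype=float)
    if A.shape != P.shape or A.ndim != 2 or A.shape[1] != 2 or A.shape[0] < 2:
        raise ValueError("expected matching (N, 2) arrays with N >= 2")
    ss_tot = ((A - A.mean(axis=0)) ** 2).sum(axis=0)
    if np.any(ss_tot == 0.0):
        raise ValueError("R^2 undefined: a target component has zero variance")
    ss_res = ((A - P) ** 2).sum(axis=0)
    per = 1.0 - ss_res / ss_tot
    return float(per.mean()), (float(per[0]), float(per[1]))


def phase_error_summary(actual, predicted) -> dict:
    """Circular-error statistics over jointly labelled samples.

    Returns mean / median / 25th / 75th percentile of the circular distance
    (percent of cycle) between the two phase series; sentinel (NaN) samples
    in either series are excluded.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError("phase series must be aligned")
    mask = phase_mod.is_labeled(a) & phase_mod.is_labeled(p)
    if not mask.any():
        raise ValueError("no overlapping labelled samples")
    err = phase_mod.circular_error(a[mask], p[mask])
    return {
        "mean_error": float(np.mean(err)),
        "median_error": float(np.median(err)),
        "q25_error": float(np.percentile(err, 25)),
        "q75_error": float(np.percentile(err, 75)),
        "n_samples": int(mask.sum()),
    }


@dataclass(frozen=True)
class MedianTrajectory:
    """Stride-normalized channel statistics on the 0-100% grid."""

    grid: np.ndarray                  # (101,) phase percentages
    median: dict                      # channel -> (101,)
    q25: dict
    q75: dict
    n_strides: int

    def channel(self, name: str) -> np.ndarray:
        return self.median[name]


def median_trajectory(series: GaitSeries, heel_strikes) -> MedianTrajectory:
    """Pointwise median (and quartiles) of strides normalized to 101 points.

    Each complete stride (between consecutive heel strikes) is linearly
    interpolated onto the 0-100% grid; statistics are taken pointwise
    across strides.
    """
    hs = np.asarray(heel_strikes, dtype=int)
    if hs.size < 2:
        raise ValueError("need at least one complete stride (two heel strikes)")
    grid = np.linspace(0.0, 100.0, N_GRID)
    frac = grid / 100.0
    stacks = {c: [] for c in CHANNELS}
    if hs[0] < 0 or hs[-1] >= len(series) or np.any(np.diff(hs) <= 0):
        raise ValueError("heel strikes must be increasing and within the series")
    for h0, h1 in zip(hs[:-1], hs[1:]):
        src = np.arange(h0, h1 + 1)
        pos = h0 + frac * (h1 - h0)
        for c in CHANNELS:
            stacks[c].append(np.interp(pos, src, series.channel(c)[h0 : h1 + 1]))
    med, q25, q75 = {}, {}, {}
    for c in CHANNELS:
        M = np.vstack(stacks[c])
        med[c] = np.median(M, axis=0)
        q25[c] = np.percentile(M, 25, axis=0)
        q75[c] = np.percentile(M, 75, axis=0)
    return MedianTrajectory(grid=grid, median=med, q25=q25, q75=q75, n_strides=hs.size - 1)


def pearson_median_correlation(a: MedianTrajectory, b: MedianTrajectory) -> dict:
    """Pearson r per channel between two 101-point median trajectories."""
    out = {}
    for c in CHANNELS:
        x, y = a.median[c], b.median[c]
        if x.shape != (N_GRID,) or y.shape != (N_GRID,):
            raise ValueError("median trajectories must be on the 101-point grid")
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            raise ValueError(f"channel {c!r} has zero variance; Pearson r undefined")
        out[c] = float(pearsonr(x, y).statistic)
    return out


@dataclass
class EvalReport:
    """Aggregated evaluation of a prediction run."""

    r2_mean: float
    r2_x: float
    r2_y: float
    mean_error: float
    median_error: float
    q25_error: float
    q75_error: float
    n_samples: int
    per_mode: dict = field(default_factory=dict)

    @classmethod
    def from_polar_and_phase(cls, actual_polar, predicted_polar, actual_pct, predicted_pct,
                             per_mode: dict | None = None) -> "EvalReport":
        r2_mean, (r2_x, r2_y) = r_squared(actual_polar, predicted_polar)
        summ = phase_error_summary(actual_pct, predicted_pct)
        return cls(r2_mean=r2_mean, r2_x=r2_x, r2_y=r2_y, per_mode=per_mode or {}, **summ)

    def to_dict(self) -> dict:
        d = {
            "r2_mean": self.r2_mean,
            "r2_x": self.r2_x,
            "r2_y": self.r2_y,
            "mean_error": self.mean_error,
            "median_error": self.median_error,
            "q25_error": self.q25_error,
            "q75_error": self.q75_error,
            "n_samples": self.n_samples,
        }
        if self.per_mode:
            d["per_mode"] = self.per_mode
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_csv(self, path) -> None:
        d = self.to_dict()
        d.pop("per_mode", None)
        with open(path, "w") as fh:
            fh.write(",".join(d.keys()) + "\n")
            fh.write(",".join(str(v) for v in d.values()) + "\n")
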