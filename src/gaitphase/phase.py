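"""Continuous gait-phase labels and their polar representation.

The gait cycle runs from one heel strike (0%) to the next heel strike of the
same leg (100%).  Between consecutive heel strikes the phase percentage grows
linearly in time and is quantized to a 0.5% grid; samples before the first or
after the last heel strike have undefined phase and carry a NaN sentinel.

Because the 100% -> 0% wrap is a discontinuity that a regression target
should not contain, the percentage p_c is mapped onto the unit circle,

    theta = 2*pi*p_c/100,   (p_x, p_y) = (cos theta, sin theta),

and each component is affinely squashed into [0.4, 0.6] via p' = (p + 5)/10
to match the target device's data conventions.  Prediction error is measured
as circular distance in percent of cycle, min(|d|, 100 - |d|) in [0, 50].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "PHASE_STEP",
    "SENTINEL",
    "label_continuous_phase",
    "quantize_phase",
    "to_polar",
    "scale_phase",
    "unscale_phase",
    "from_polar",
    "circular_error",
    "is_labeled",
]

PHASE_STEP = 0.5  # percent of cycle
SENTINEL = np.nan


def is_labeled(phase: np.ndarray) -> np.ndarray:
    """Boolean mask of samples with a defined phase label."""
    return np.isfinite(np.asarray(phase, dtype=float))


def quantize_phase(p_c):
    """Snap percentages to the 0.5% grid (ties toward zero) and wrap 100 -> 0."""
    p = np.asarray(p_c, dtype=float)
    # round-half-down: ceil(x - 0.5) on the grid index scale
    idx = np.ceil(p / PHASE_STEP - 0.5)
    out = np.mod(idx * PHASE_STEP, 100.0)
    return out if out.ndim else float(out)


def label_continuous_phase(heel_strikes, n_samples: int) -> np.ndarray:
    """Per-sample phase percentages from heel-strike indices.

    For h_k <= t < h_{k+1}: p_c(t) = 100*(t - h_k)/(h_{k+1} - h_k), quantized
    to 0.5%.  Samples outside any complete stride get NaN.  Fewer than two
    heel strikes yields an all-sentinel series.
    """
    hs = np.asarray(heel_strikes, dtype=int)
    if hs.size and (np.any(np.diff(hs) <= 0) or hs[0] < 0 or hs[-1] >= n_samples):
        raise ValueError("heel strikes must be strictly increasing and within range")
    out = np.full(n_samples, SENTINEL, dtype=float)
    for h0, h1 in zip(hs[:-1], hs[1:]):
        t = np.arange(h0, h1)
        out[h0:h1] = quantize_phase(100.0 * (t - h0) / (h1 - h0))
    return out


def to_polar(p_c):
    """Map phase percentages onto the unit circle; out-of-range wraps mod 100."""
    theta = 2.0 * np.pi * (np.asarray(p_c, dtype=float) % 100.0) / 100.0
    p_x, p_y = np.cos(theta), np.sin(theta)
    if np.ndim(p_c) == 0:
        return float(p_x), float(p_y)
    return p_x, p_y


def scale_phase(p):
    """Squash a polar component from [-1, 1] into [0.4, 0.6]: p' = (p + 5)/10."""
    out = (np.asarray(p, dtype=float) + 5.0) / 10.0
    return out if out.ndim else float(out)


def unscale_phase(p_s):
    """Inverse of :func:`scale_phase`."""
    out = np.asarray(p_s, dtype=float) * 10.0 - 5.0
    return out if out.ndim else float(out)


def from_polar(px_s, py_s, center_tol: float = 1e-12):
    """Recover phase percentages from scaled polar coordinates.

    The point need not lie on the circle (network outputs rarely do); only
    the angle matters.  A point at the circle centre (0.5, 0.5) has no
    defined angle: scalar input raises, array input gets the NaN sentinel.
    """
    p_x = unscale_phase(px_s)
    p_y = unscale_phase(py_s)
    r = np.hypot(p_x, p_y)
    scalar = np.ndim(p_x) == 0
    if scalar:
        if r <= center_tol:
            raise ValueError("phase undefined at the circle centre (0.5, 0.5)")
        return float(np.mod(np.arctan2(p_y, p_x), 2.0 * np.pi) * 100.0 / (2.0 * np.pi))
    p_c = np.mod(np.arctan2(p_y, p_x), 2.0 * np.pi) * 100.0 / (2.0 * np.pi)
    p_c = np.where(r <= center_tol, SENTINEL, p_c)
    return p_c


def circular_error(actual, predicted):
    """Circular distance between phases, in percent of cycle, in [0, 50]."""
    d = np.abs(np.asarray(actual, dtype=float) - np.asarray(predicted, dtype=float)) % 100.0
    out = np.minimum(d, 100.0 - d)
    return out if out.ndim else float(out)
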