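"""Streaming stance/swing segmentation of the vertical load.

Discrete gait events are extracted from the weight-normalized vertical load
alone, with a smoothed-buffer peak detector in the z-score family: a ring
buffer of ``lag`` exponentially smoothed load values summarises the recent
past, and each new sample is labelled stance when it exceeds a fixed load
threshold ``F_th`` or when the load is rising relative to the buffer mean.
A persistence pass then removes label bursts shorter than ``p_hist`` samples
(25 ms at 200 Hz with defaults), which sensor interference produces.

Heel strikes are the swing->stance transitions of the refined labels and
anchor 0% of the gait cycle downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SegmentationParams",
    "SegmentationState",
    "segment_step",
    "extract_phases",
    "refine",
    "find_heel_strikes",
]

_EQ_TOL = 1e-9  # swing-equality comparison; exact float equality is fragile


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the load segmenter.

    F_th : stance load threshold in BW (a sample above it is always stance).
    lag : length of the smoothed-load ring buffer.
    influence : weight of the newest sample in the exponential smoother.
    p_hist : minimum persistence, in samples, of a label segment.
    """

    F_th: float = 0.2
    lag: int = 8
    influence: float = 0.01
    p_hist: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.F_th < 1.0:
            raise ValueError("F_th must lie in (0, 1)")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if not 0.0 <= self.influence <= 1.0:
            raise ValueError("influence must lie in [0, 1]")
        if self.p_hist < 1:
            raise ValueError("p_hist must be >= 1")


@dataclass
class SegmentationState:
    """Ring buffer of the last ``lag`` smoothed load values (zero-initialized)."""

    filtered: np.ndarray

    @classmethod
    def initial(cls, params: SegmentationParams) -> "SegmentationState":
        return cls(filtered=np.zeros(params.lag, dtype=float))


def segment_step(f_z: float, state: SegmentationState, params: SegmentationParams = SegmentationParams()):
    """Label one load sample as swing (0) or stance (1) and update the state.

    The sample is clamped to [0, 1] BW first.  If it equals the buffer mean
    (within 1e-9 — during true swing both are exactly 0) the sample is swing
    and enters the buffer raw; otherwise it is stance when above ``F_th`` or
    when at/above the buffer mean (rising load), swing when below, and the
    buffer receives the exponentially smoothed value.
    """
    filt = state.filtered
    if filt.shape[0] != params.lag:
        raise ValueError("state buffer length does not match params.lag")
    f = min(max(float(f_z), 0.0), 1.0)
    mean = float(filt.mean())
    prev = filt[-1]
    filt[:-1] = filt[1:]
    if abs(f - mean) <= _EQ_TOL:
        label = 0
        filt[-1] = f
    else:
        if f > params.F_th:
            label = 1
        elif f >= mean:  # increasing vertical load
            label = 1
        else:
            label = 0
        filt[-1] = params.influence * f + (1.0 - params.influence) * prev
    return label, state


def extract_phases(load: np.ndarray, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Run the streaming segmenter over a load series and refine the labels.

    Returns a binary stance/swing array of the same length as ``load``.
    """
    load = np.asarray(load, dtype=float)
    if load.ndim != 1 or load.size == 0:
        raise ValueError("load must be a non-empty 1-D array")
    state = SegmentationState.initial(params)
    raw = np.empty(load.size, dtype=np.int8)
    for t in range(load.size):
        raw[t], state = segment_step(load[t], state, params)
    return refine(raw, params.p_hist)


def refine(raw: np.ndarray, p_hist: int = 5) -> np.ndarray:
    """Persistence filter: absorb label segments no longer than ``p_hist``.

    At every label change the preceding segment is committed if it lasted
    more than ``p_hist`` samples; otherwise it is relabelled with the
    incoming label and fuses with the following segment (the segment start is
    not advanced, so consecutive short runs keep merging until persistence is
    reached).  The trailing segment is flushed with its own label.
    """
    raw = np.asarray(raw)
    if raw.size == 0:
        return raw.astype(np.int8)
    if not np.isin(raw, (0, 1)).all():
        raise ValueError("labels must be 0 (swing) or 1 (stance)")
    n = raw.size
    out = np.full(n, -1, dtype=np.int8)
    p_past = int(raw[0])
    count = 0
    idx_bgn = 0
    for t in range(n):
        p_current = int(raw[t])
        if p_current != p_past:
            idx_fin = t - 1
            if count > p_hist:
                out[idx_bgn : idx_fin + 1] = p_past
                idx_bgn = t
                count = 1
            else:
                out[idx_bgn : idx_fin + 1] = p_current
                count += 1
        else:
            count += 1
        p_past = p_current
    out[idx_bgn:] = p_past  # flush the trailing segment
    return out


def find_heel_strikes(refined: np.ndarray) -> np.ndarray:
    """Indices of swing->stance transitions (heel strikes), strictly increasing."""
    refined = np.asarray(refined)
    if refined.size == 0:
        return np.empty(0, dtype=int)
    if not np.isin(refined, (0, 1)).all():
        raise ValueError("labels must be 0 (swing) or 1 (stance)")
    rising = np.flatnonzero((refined[1:] == 1) & (refined[:-1] == 0)) + 1
    return rising.astype(int)
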