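"""Synthetic gait sessions with known ground-truth phase.

Generates four-channel sessions (vertical load + thigh/knee/ankle angles)
from periodic stride templates for level-ground walking (LGW) and stair
ascent (SA), so the whole pipeline can be exercised and scored against an
exact phase reference.

Templates are low-order Fourier series (<= 8 harmonics) over normalized
stride phase, fitted to hand-designed keypoint curves with the field's
canonical shapes: a double-bump stance load that is zero in swing, a swing
knee-flexion peak, stance ankle dorsiflexion followed by push-off
plantarflexion, and for SA a flexed-contact, single-peak-load pattern.  The
load channel is additionally gated to exactly zero over the swing fraction
(truncated Fourier series ring; ground contact does not).  Sign convention:
thigh extension, knee flexion, ankle dorsiflexion positive.

Stride-to-stride variability (cadence and amplitude jitter, additive sensor
noise) and systematic sensor-configuration offsets (motion-capture-like vs
goniometer-like angle baselines, several degrees RMS) are controlled by
:class:`NoiseSpec`.  Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .phase import label_continuous_phase
from .signals import ANGLE_CHANNELS, CHANNELS, GaitSeries, TARGET_RATE

__all__ = [
    "StrideTemplate",
    "NoiseSpec",
    "generate_session",
    "make_variant",
    "make_prosthesis_like",
]

MODES = ("LGW", "SA")
_N_HARMONICS = 8
_SWING_LOAD_EPS = 0.05  # invariant: load below this throughout swing
_IMPACT_RATE = 30.0     # BW/s minimum loading rate at contact (impact transient)
_IMPACT_CAP = 0.45      # BW level where the impact ramp hands over to the curve


def _fourier_fit(values: np.ndarray) -> np.ndarray:
    """First ``_N_HARMONICS`` complex Fourier coefficients of a periodic
    signal sampled on a uniform grid (coefficient 0 is the mean)."""
    spec = np.fft.rfft(values) / values.size
    return spec[: _N_HARMONICS + 1]


def _fourier_eval(coeffs: np.ndarray, phi: np.ndarray) -> np.ndarray:
    k = np.arange(coeffs.size)
    basis = np.exp(2j * np.pi * np.outer(phi, k))
    return np.real(basis @ (2.0 * coeffs)) - np.real(coeffs[0])


def _keypoint_curve(points: list[tuple[float, float]], grid: np.ndarray) -> np.ndarray:
    pts = sorted(points)
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if x[0] != 0.0:
        raise ValueError("keypoints must start at phase 0")
    x = np.append(x, 1.0)
    y = np.append(y, y[0])  # periodic closure
    return CubicSpline(x, y, bc_type="periodic")(grid)


@dataclass(frozen=True)
class StrideTemplate:
    """Periodic stride shape for one ambulation mode.

    fourier : per-channel complex Fourier coefficients over stride phase
        (channels ``f_z``/``thigh``/``knee``/``ankle``; angles in degrees,
        load in BW).
    swing_fraction : trailing fraction of the cycle with the foot in the air.
    duration : nominal stride duration in seconds.
    """

    mode: str
    fourier: dict
    swing_fraction: float
    duration: float

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if not 0.2 < self.swing_fraction < 0.6:
            raise ValueError("swing_fraction must lie in (0.2, 0.6)")

    @property
    def stance_fraction(self) -> float:
        return 1.0 - self.swing_fraction

    def evaluate(self, phi: np.ndarray) -> dict:
        """Channel values at normalized phases ``phi`` (wrapped mod 1)."""
        phi = np.asarray(phi, dtype=float) % 1.0
        out = {c: _fourier_eval(self.fourier[c], phi) for c in CHANNELS}
        # gate the load: exactly zero in swing, cosine rolloff at stance end
        st = self.stance_fraction
        roll = 0.06
        mask = np.ones_like(phi)
        mask[phi >= st] = 0.0
        edge = (phi >= st - roll) & (phi < st)
        mask[edge] = 0.5 * (1.0 + np.cos(np.pi * (phi[edge] - (st - roll)) / roll))
        out["f_z"] = np.maximum(out["f_z"] * mask, 0.0)
        # heel-strike impact transient: a truncated Fourier series cannot
        # carry the near-instantaneous loading of initial contact, so weight
        # acceptance is floored at a realistic loading rate for the first
        # few percent of the cycle
        attack = np.minimum(_IMPACT_RATE * self.duration * phi, _IMPACT_CAP)
        early = phi < 0.1 * self.stance_fraction
        out["f_z"][early] = np.maximum(out["f_z"][early], attack[early])
        return out

    @classmethod
    def level_walking(cls) -> "StrideTemplate":
        """LGW: double-bump stance load, ~60/40 stance/swing, 1.10 s stride."""
        stance = 0.60
        grid = np.linspace(0.0, 1.0, 512, endpoint=False)
        s = np.clip(grid / stance, 0.0, 1.0)
        # steep loading ramp: real GRF passes 0.2 BW within ~15 ms of contact
        load = np.where(
            grid < stance,
            1.08 * (np.sin(np.pi * s) + 0.42 * np.sin(3 * np.pi * s) + 0.12 * np.sin(5 * np.pi * s)),
            0.0,
        )
        fourier = {
            "f_z": _fourier_fit(load),
            "thigh": _fourier_fit(
                _keypoint_curve(
                    [(0.0, -25), (0.3, -5), (0.5, 10), (0.6, 12), (0.75, -10), (0.9, -27)], grid
                )
            ),
            "knee": _fourier_fit(
                _keypoint_curve(
                    [(0.0, 5), (0.12, 18), (0.4, 5), (0.6, 35), (0.72, 62), (0.85, 30)], grid
                )
            ),
            "ankle": _fourier_fit(
                _keypoint_curve(
                    [(0.0, 0), (0.07, -6), (0.45, 10), (0.6, -4), (0.68, -16), (0.85, 0)], grid
                )
            ),
        }
        return cls(mode="LGW", fourier=fourier, swing_fraction=1.0 - stance, duration=1.10)

    @classmethod
    def stair_ascent(cls) -> "StrideTemplate":
        """SA: flexed contact, single-peak load, ~65/35 stance/swing, 1.40 s."""
        stance = 0.65
        grid = np.linspace(0.0, 1.0, 512, endpoint=False)
        s = np.clip(grid / stance, 0.0, 1.0)
        load = np.where(
            grid < stance,
            1.02 * (np.sin(np.pi * s) + 0.30 * np.sin(3 * np.pi * s) + 0.10 * np.sin(5 * np.pi * s)),
            0.0,
        )
        fourier = {
            "f_z": _fourier_fit(load),
            "thigh": _fourier_fit(
                _keypoint_curve([(0.0, -45), (0.4, -5), (0.6, 5), (0.8, -35)], grid)
            ),
            "knee": _fourier_fit(
                _keypoint_curve([(0.0, 60), (0.5, 10), (0.65, 25), (0.78, 92)], grid)
            ),
            "ankle": _fourier_fit(
                _keypoint_curve([(0.0, 8), (0.35, 18), (0.55, 12), (0.68, -12), (0.85, 5)], grid)
            ),
        }
        return cls(mode="SA", fourier=fourier, swing_fraction=1.0 - stance, duration=1.40)

    @classmethod
    def for_mode(cls, mode: str) -> "StrideTemplate":
        if mode == "LGW":
            return cls.level_walking()
        if mode == "SA":
            return cls.stair_ascent()
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


@dataclass(frozen=True)
class NoiseSpec:
    """Variability model for synthetic sessions.

    cadence_cv : fractional SD of stride duration across strides.
    amplitude_cv : fractional SD of per-stride channel amplitude.
    sensor_noise_sd : additive white-noise SD per channel (BW / degrees).
    variant_offset_sd : per-angle-channel SD (degrees) of the systematic
        offset separating sensor variants (motion-capture vs goniometer);
        defaults follow typical inter-system RMS differences of several
        degrees (thigh > knee > ankle).
    """

    cadence_cv: float = 0.05
    amplitude_cv: float = 0.05
    sensor_noise_sd: dict = field(
        default_factory=lambda: {"f_z": 0.01, "thigh": 0.5, "knee": 0.5, "ankle": 0.5}
    )
    variant_offset_sd: dict = field(
        default_factory=lambda: {"thigh": 6.2, "knee": 4.3, "ankle": 3.7}
    )

    def __post_init__(self) -> None:
        vals = [self.cadence_cv, self.amplitude_cv]
        vals += list(self.sensor_noise_sd.values()) + list(self.variant_offset_sd.values())
        if any(v < 0 for v in vals):
            raise ValueError("noise magnitudes must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(
            cadence_cv=0.0,
            amplitude_cv=0.0,
            sensor_noise_sd={c: 0.0 for c in CHANNELS},
            variant_offset_sd={c: 0.0 for c in ANGLE_CHANNELS},
        )


def generate_session(
    mode: str,
    n_strides: int,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    rate: float = TARGET_RATE,
):
    """Simulate a gait session of ``n_strides`` strides.

    Returns ``(series, phase, heel_strikes)``: the sensor record, the
    ground-truth phase percentages (NaN sentinel outside complete strides)
    and the ground-truth heel-strike sample indices.  Heel strikes coincide
    with load onset by construction.  Deterministic per seed.
    """
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")
    template = StrideTemplate.for_mode(mode)
    rng = np.random.default_rng(seed)

    jit = np.clip(rng.standard_normal(n_strides), -3.0, 3.0)
    durations = template.duration * (1.0 + noise.cadence_cv * jit)
    amp = 1.0 + noise.amplitude_cv * np.clip(
        rng.standard_normal((n_strides, len(CHANNELS))), -3.0, 3.0
    )
    starts = np.concatenate([[0.0], np.cumsum(durations)])

    n_samples = int(round(starts[-1] * rate)) + 1
    t = np.arange(n_samples) / rate
    stride_of = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, n_strides - 1)
    phi = (t - starts[stride_of]) / durations[stride_of]
    phi = np.clip(phi, 0.0, 1.0)

    values = template.evaluate(phi)
    channels = {}
    for j, name in enumerate(CHANNELS):
        v = values[name]
        scale = amp[stride_of, j]
        if name == "f_z":
            v = v * scale  # load scales multiplicatively, swing zero preserved
        else:
            mean = float(np.real(template.fourier[name][0]))
            v = mean + scale * (v - mean)
        sd = noise.sensor_noise_sd.get(name, 0.0)
        if sd > 0:
            v = v + sd * rng.standard_normal(n_samples)
        if name == "f_z":
            v = np.maximum(v, 0.0)
        channels[name] = v

    series = GaitSeries(rate=rate, **channels)
    heel_strikes = np.round(starts * rate).astype(int)
    heel_strikes = heel_strikes[heel_strikes < n_samples]
    phase = label_continuous_phase(heel_strikes, n_samples)
    return series, phase, heel_strikes


def make_variant(
    series: GaitSeries,
    variant: str,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
) -> GaitSeries:
    """Re-express a session as recorded by a different angle-sensing setup.

    Adds a per-angle-channel systematic offset (a near-constant component
    plus a slow sinusoidal wander) with RMS close to the configured variant
    SD, plus the additive sensor noise; the load channel is untouched.
    """
    if variant not in ("mocap", "goniometer"):
        raise ValueError(f"unknown variant {variant!r}; expected 'mocap' or 'goniometer'")
    rng = np.random.default_rng([seed, {"mocap": 0, "goniometer": 1}[variant]])
    t = series.time
    kw = {"f_z": series.f_z.copy()}
    for name in ANGLE_CHANNELS:
        sd = noise.variant_offset_sd.get(name, 0.0)
        v = series.channel(name).astype(float).copy()
        if sd > 0:
            sign = rng.choice([-1.0, 1.0])
            const = sign * sd * (1.0 + 0.15 * np.clip(rng.standard_normal(), -2, 2))
            period = rng.uniform(8.0, 15.0)
            wander = 0.3 * sd * np.sin(2.0 * np.pi * t / period + rng.uniform(0, 2 * np.pi))
            v = v + const + wander
        nsd = noise.sensor_noise_sd.get(name, 0.0)
        if nsd > 0:
            v = v + nsd * rng.standard_normal(v.size)
        kw[name] = v
    return GaitSeries(rate=series.rate, **kw)


def make_prosthesis_like(series: GaitSeries, flatten_ankle: float) -> GaitSeries:
    """Emulate a stiff powered-prosthesis ankle in stance.

    Within each contiguous stance segment (load >= 0.05 BW) the ankle is
    pulled toward the segment's mean by ``flatten_ankle`` in [0, 1]: 0
    leaves the series unchanged, 1 holds the stance ankle constant at its
    mean, removing the dorsiflexion/push-off excursion that an impedance
    controller tuned too stiff suppresses.
    """
    if not 0.0 <= flatten_ankle <= 1.0:
        raise ValueError("flatten_ankle must lie in [0, 1]")
    ankle = series.ankle.astype(float).copy()
    in_stance = series.f_z >= _SWING_LOAD_EPS
    if flatten_ankle > 0 and in_stance.any():
        edges = np.flatnonzero(np.diff(in_stance.astype(np.int8)))
        bounds = np.concatenate([[0], edges + 1, [len(series)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            if in_stance[a]:
                seg_mean = ankle[a:b].mean()
                ankle[a:b] = (1.0 - flatten_ankle) * ankle[a:b] + flatten_ankle * seg_mean
    return GaitSeries(
        rate=series.rate, f_z=series.f_z, thigh=series.thigh, knee=series.knee, ankle=ankle
    )
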