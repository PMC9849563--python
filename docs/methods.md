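# Methods

This note documents the models and procedures implemented in `gaitphase`,
the parameter choices that matter, and what the synthetic benchmark does
and does not establish.

## Signal model and scaling

A session is a uniformly sampled four-channel record: vertical load
normalized by body weight (BW) and thigh/knee/ankle angles in degrees
(thigh extension, knee flexion, ankle dorsiflexion positive). All
processing assumes 200 Hz; arbitrary-rate input is linearly resampled.
Linear interpolation was chosen over band-limited resampling because gait
signals live far below the Nyquist rates involved (measured amplitude loss
on a 3 Hz sinusoid resampled 1000→200 Hz is under 1 %), it is exact on
constants, and it keeps the operation trivially invertible in the tests.
Angular baselines differ between sensor setups; `remove_bias` subtracts
per-channel offsets, by default the channel means over a user-designated
quiet-standing window.

Network inputs use the affine squash `v_n = (v/g_v + 5)/10` with gain 1 for
load and 36 for angles. The anchors are load 0 → 0.5 and 1 BW → 0.6, and
±180° maps into [0, 1]. The narrow working range around 0.5 mirrors the
data conventions of the powered-prosthesis controller this representation
targets; it is not a statistical normalization. Loads above 1 BW are *not*
clipped at ingestion — only the segmenter clamps internally — because
dynamic loading legitimately exceeds body weight.

## Stance/swing segmentation

Gait events are extracted from the load alone with a streaming detector in
the smoothed-z-score family. State is a ring buffer of `lag` exponentially
smoothed load values. Each incoming sample (clamped to [0, 1] BW) is:

* swing, if it equals the buffer mean — compared with absolute tolerance
  1e-9, since during true swing both are exactly zero and exact float
  equality is fragile; the raw sample then enters the buffer;
* otherwise stance if above `F_th`, or at/above the buffer mean (rising
  load); swing if below; the buffer then receives
  `influence·f_z + (1−influence)·previous`.

Defaults `F_th = 0.2` BW, `lag = 8`, `influence = 0.01`, `p_hist = 5`. The
persistence pass walks the label sequence; at each change a segment shorter
than `p_hist + 1` samples is relabelled with the incoming label and fuses
with what follows (its start index is retained, so consecutive short runs
keep merging until persistence is reached). The trailing segment, which
the change-driven loop never reaches, is flushed with its own label so the
output is fully labelled. The refinement is idempotent (property-tested)
and removes any isolated burst of ≤ 25 ms at 200 Hz. With a zero-initialized
buffer, the first `lag` outputs simply use that state; on piecewise-constant
loads the whole pipeline reduces exactly to 0.2-BW thresholding after those
samples, which the tests exploit as an oracle.

Heel strikes are swing→stance transitions of the refined labels. Toe-offs
are implicit as the stance→swing transitions.

## Phase representation

Phase grows linearly in *time* between consecutive heel strikes — the
standard definition of a 0–100 % gait cycle — and is quantized to 0.5 %
with ties toward zero; 100 % wraps to 0 %, so labels live on the 200-point
grid {0, 0.5, …, 99.5}. Samples outside a complete stride carry a NaN
sentinel and are excluded from training and scoring: their phase is
undefined, not zero. The polar encoding `(cos θ, sin θ)`, `θ = 2π p_c/100`,
removes the wrap discontinuity that otherwise dominates regression error
near heel strike; each component is squashed to [0.4, 0.6] by
`p' = (p+5)/10` for the same device-convention reason as the inputs.
Decoding uses `atan2` and needs no projection onto the circle; the one
degenerate point is the circle centre (0.5, 0.5), which decodes to the
sentinel (arrays) or raises (scalars). Prediction error is the circular
distance `min(|Δ|, 100−|Δ|)` ∈ [0, 50] % — errors near the wrap would
otherwise be wildly overstated.

## Network and training

Architecture: input 50×4 (250 ms at 200 Hz) → Conv1D(32 filters, kernel 8,
stride 1, same padding) → LSTM(20, last step) → dense 30 → 10 → 2, sigmoid
on every trainable layer — 1,056 + 4,240 + 630 + 310 + 22 = **6,258**
parameters. The hidden dense sizes (30, 10) are fixed by that parameter
arithmetic. "Sigmoid activation" is applied Keras-style to the LSTM's
candidate and cell-output nonlinearities, with standard sigmoid recurrent
gating. The target is the scaled polar phase of the window's *last*
sample: prediction is causal, one window per sample at stride 1, with no
look-ahead, so the estimator is streaming-capable.

The engine (`gaitphase.nn`) is a vectorised NumPy implementation of the
forward pass, backpropagation through time and Adam; gradients are verified
against central finite differences in the tests. Two initialisation
choices matter for this all-sigmoid stack and are deliberate:

* Glorot-uniform limits scaled by gain 4, compensating the sigmoid's 1/4
  midpoint slope — with unit gain the activation variance decays ~4× per
  layer and the 50-step LSTM output becomes numerically constant across
  windows, leaving nothing for the dense stack to regress on;
* biases initialised to −0.5 × (column sum of incoming weights), cancelling
  the ~0.5 mean of the scaled inputs and of every sigmoid activation, which
  otherwise saturates a large fraction of units at the start of training.

The recurrent kernel is orthogonal per gate and the forget-gate bias starts
at +1. Training uses MSE, Adam (lr 10⁻³, β₁ 0.9, β₂ 0.999, ε 10⁻⁸),
batch 256, 15 epochs. The 7:3 train/validation split is made once per fit
(seeded); a `resplit_each_epoch` flag instead reshuffles membership every
epoch, which leaks validation samples across epochs and exists only for
comparison. All randomness (init, split, batch order) derives from one
seed; identical seed and data give bit-identical weights. Forward/backward
run in float32 for speed, loss accumulation in float64.

## Synthetic benchmark

The generator stands in for public motion-capture gait corpora so the
pipeline can be trained and scored against exact ground truth. Each mode
(level-ground walking, stair ascent) is a periodic template: per-channel
Fourier series (≤ 8 harmonics) over normalized stride phase, fitted to
hand-designed keypoint curves with the canonical shapes — LGW: double-bump
stance load, swing knee-flexion peak near 65 % of ~60°, stance
dorsiflexion then push-off plantarflexion; SA: flexed contact (knee ~60°,
thigh strongly flexed), single-peak load, 65/35 stance/swing vs LGW's
60/40; nominal stride durations 1.10 s (LGW) and 1.40 s (SA). Two features
are imposed outside the Fourier basis because a truncated series cannot
express them: the load is gated to exactly zero throughout swing (with a
cosine rolloff at stance end), and contact begins with an impact ramp at a
minimum loading rate of 30 BW/s up to 0.45 BW — real ground reaction
forces cross the segmenter's 0.2 BW threshold within ~15 ms of heel
strike, and without the ramp the smooth series delays detection by several
samples. Ground-truth heel strikes are the stride starts, coinciding with
load onset; the segmenter recovers them within ±3 samples (15 ms) on
noise-free sessions.

Variability defaults: stride-duration CV 5 %, per-stride amplitude CV 5 %
(angles scaled about their cycle mean, load scaled multiplicatively),
additive white sensor noise of 0.01 BW / 0.5°. Sensor-configuration
variants add a per-angle-channel systematic offset — a near-constant
component plus a slow sinusoidal wander — with RMS near configured SDs of
6.2°/4.3°/3.7° (thigh/knee/ankle), the magnitude of typical differences
between motion-capture and goniometer records of the same movement.
`make_prosthesis_like` pulls the ankle toward its per-stance-segment mean
by a factor in [0, 1]; the attenuation is applied uniformly over each
stance segment (factor 1 holds the stance ankle exactly at its mean),
emulating the too-stiff stair-ascent ankle of an impedance-controlled
prosthesis and reproducibly lowering the ankle channel's median-trajectory
Pearson correlation against natural gait.

What the generator does *not* emulate: inter-subject morphology, speed-
or height-dependent template changes, crossover steps, turning, ramps,
soft-tissue artefacts, or correlated (non-white) sensor noise. Passing the
end-to-end bar on this data shows the pipeline is correctly wired and the
network has the capacity to learn the phase map under realistic
variability — not that the same accuracy transfers to any particular real
sensor system.

## Benchmark scale and scoring

The end-to-end check trains on 300 LGW + 100 SA strides (~93k windows),
labelled by the segmentation pipeline itself (not the generator's truth),
and scores 25 held-out strides per mode against generator ground truth:
mean circular error < 5 % and pooled polar R² > 0.9. Measured values on
the shipped seeds are ≈ 1.1 % pooled error and R² ≈ 0.985 (see
`tests/test_acceptance.py`); R² is reported per polar component and
averaged, and error statistics are pooled per-sample, not per-stride.
Median trajectories interpolate each stride onto a 101-point 0–100 % grid
(both end points included, so adjacent-stride continuity is visible) before
taking pointwise medians and quartiles.

## Known limitations

* The segmenter's equality branch depends on swing load being exactly
  zero after clamping; a constant non-zero load held for thousands of
  samples eventually drives the smoothed buffer onto the input and flips
  the label — irrelevant for gait, visible in pathological fixtures.
* A fresh network decodes to *some* phase for any input (sigmoid outputs
  are never exactly at the circle centre); prediction confidence is not
  modelled.
* Quantization to 0.5 % bounds label fidelity at ±0.25 %; the network is
  trained on the quantized labels, not the underlying continuous ramp.
* The NumPy engine trains this 6k-parameter model in a few minutes on one
  CPU but does not scale to larger architectures; it supports exactly the
  conv→LSTM→dense topology used here.
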