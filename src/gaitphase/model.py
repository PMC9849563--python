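"""Conv-LSTM gait-phase regressor: model and results objects.

The estimator maps a 250 ms history (50 samples at 200 Hz) of the four
scaled sensor channels to the scaled polar phase (p'_x, p'_y).  Usage
follows the fit/results idiom of statistical modelling packages::

    model = GaitPhaseModel.from_series(series, phase_labels)
    res = model.fit()
    print(res.summary())
    pred_pct = res.predict_series(other_series)

``GaitPhaseModel`` owns the window dataset and the architecture
configuration; ``fit`` trains with Adam on mean squared error and returns a
``GaitPhaseResults`` carrying the weights, the per-epoch loss curves and
prediction helpers.  With the default configuration the network has exactly
6,258 trainable parameters (conv 1,056 + LSTM 4,240 + dense 630/310/22).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import phase as phase_mod
from .nn import Adam, ConvLSTMNet, mse_loss
from .signals import GaitSeries, ScalingSpec, DEFAULT_SCALING

__all__ = ["ModelConfig", "WindowDataset", "GaitPhaseModel", "GaitPhaseResults", "make_windows", "build_model"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults reproduce the reference architecture: 50-sample window over 4
    channels, Conv1D(32, kernel 8, stride 1, same padding), LSTM(20),
    dense 30 -> 10 -> 2, sigmoid activations on every trainable layer;
    trained 15 epochs with batch 256, Adam at lr 1e-3, MSE loss, 7:3
    train/validation split.
    """

    window: int = 50
    channels: int = 4
    conv_filters: int = 32
    conv_kernel: int = 8
    conv_stride: int = 1
    lstm_units: int = 20
    dense_sizes: tuple[int, ...] = (30, 10)
    outputs: int = 2
    epochs: int = 15
    batch_size: int = 256
    learning_rate: float = 1e-3
    train_fraction: float = 0.7
    resplit_each_epoch: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_stride != 1:
            raise ValueError("only stride-1 convolution is supported")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        object.__setattr__(self, "dense_sizes", tuple(int(s) for s in self.dense_sizes))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "dense_sizes" in d:
            d["dense_sizes"] = tuple(d["dense_sizes"])
        return cls(**d)


@dataclass(frozen=True)
class WindowDataset:
    """Sliding-window training set: inputs (N, window, 4) in [0, 1],
    targets (N, 2) scaled polar phases in [0.4, 0.6]."""

    inputs: np.ndarray
    targets: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.inputs, dtype=np.float64)
        Y = np.asarray(self.targets, dtype=np.float64)
        if X.ndim != 3 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("inputs (N, T, C) and targets (N, 2) must align")
        object.__setattr__(self, "inputs", X)
        object.__setattr__(self, "targets", Y)

    def __len__(self) -> int:
        return self.inputs.shape[0]


def make_windows(
    series: GaitSeries,
    labels: np.ndarray,
    config: ModelConfig = ModelConfig(),
    scaling: ScalingSpec = DEFAULT_SCALING,
) -> WindowDataset:
    """Cut a labelled session into causal training windows.

    One window per sample t >= window-1 whose phase label is defined: the
    input is samples [t-window+1, t] of the scaled channels, the target the
    scaled polar phase at t (the window's last sample — no look-ahead).
    """
    labels = np.asarray(labels, dtype=float)
    if len(series) != labels.shape[0]:
        raise ValueError("series and labels must have the same length")
    w = config.window
    n = len(series)
    if n < w:
        return WindowDataset(np.empty((0, w, config.channels)), np.empty((0, 2)))
    X_full = series.scaled_matrix(scaling)
    t_idx = np.arange(w - 1, n)
    t_idx = t_idx[phase_mod.is_labeled(labels[t_idx])]
    if t_idx.size == 0:
        return WindowDataset(np.empty((0, w, config.channels)), np.empty((0, 2)))
    from numpy.lib.stride_tricks import sliding_window_view

    wins = sliding_window_view(X_full, w, axis=0)        # (n-w+1, C, w)
    X = wins[t_idx - (w - 1)].transpose(0, 2, 1).copy()  # (N, w, C)
    p_x, p_y = phase_mod.to_polar(labels[t_idx])
    Y = np.column_stack([phase_mod.scale_phase(p_x), phase_mod.scale_phase(p_y)])
    return WindowDataset(X, Y)


def build_model(config: ModelConfig = ModelConfig()) -> ConvLSTMNet:
    """Instantiate the untrained network for a configuration."""
    return ConvLSTMNet(
        window=config.window,
        channels=config.channels,
        conv_filters=config.conv_filters,
        conv_kernel=config.conv_kernel,
        lstm_units=config.lstm_units,
        dense_sizes=config.dense_sizes,
        outputs=config.outputs,
        seed=config.seed,
    )


class GaitPhaseModel:
    """Gait-phase regressor bound to a window dataset.

    Parameters
    ----------
    dataset : WindowDataset
        Scaled input windows and polar targets.
    config : ModelConfig, optional
        Architecture and training hyperparameters.
    """

    def __init__(self, dataset: WindowDataset, config: ModelConfig | None = None):
        if len(dataset) == 0:
            raise ValueError("cannot build a model on an empty dataset")
        self.dataset = dataset
        self.config = config or ModelConfig()

    @classmethod
    def from_series(
        cls,
        series: GaitSeries | list[GaitSeries],
        labels: np.ndarray | list[np.ndarray],
        config: ModelConfig | None = None,
        scaling: ScalingSpec = DEFAULT_SCALING,
    ) -> "GaitPhaseModel":
        """Build the window dataset from one or more labelled sessions."""
        config = config or ModelConfig()
        if isinstance(series, GaitSeries):
            series, labels = [series], [labels]
        parts = [make_windows(s, l, config, scaling) for s, l in zip(series, labels)]
        X = np.concatenate([p.inputs for p in parts], axis=0)
        Y = np.concatenate([p.targets for p in parts], axis=0)
        return cls(WindowDataset(X, Y), config)

    def fit(self, seed: int | None = None, verbose: bool = False) -> "GaitPhaseResults":
        """Train with Adam/MSE; returns results with per-epoch loss curves.

        Deterministic given the seed (defaults to ``config.seed``): weight
        initialisation, the 7:3 split and the per-epoch shuffles all derive
        from it.  By default the split is made once; ``resplit_each_epoch``
        in the config re-shuffles train/validation membership every epoch.
        """
        cfg = self.config
        seed = cfg.seed if seed is None else int(seed)
        net = ConvLSTMNet(
            window=cfg.window,
            channels=cfg.channels,
            conv_filters=cfg.conv_filters,
            conv_kernel=cfg.conv_kernel,
            lstm_units=cfg.lstm_units,
            dense_sizes=cfg.dense_sizes,
            outputs=cfg.outputs,
            seed=seed,
        )
        rng = np.random.default_rng(seed + 1)
        X = self.dataset.inputs.astype(np.float32)
        Y = self.dataset.targets.astype(np.float32)
        n = X.shape[0]
        batch = min(cfg.batch_size, n)
        opt = Adam(net.params, lr=cfg.learning_rate)

        def split():
            order = rng.permutation(n)
            n_tr = max(1, int(round(cfg.train_fraction * n)))
            return order[:n_tr], order[n_tr:]

        tr_idx, va_idx = split()
        train_losses, val_losses = [], []
        for epoch in range(cfg.epochs):
            if cfg.resplit_each_epoch and epoch > 0:
                tr_idx, va_idx = split()
            order = tr_idx[rng.permutation(tr_idx.size)]
            ep_loss, n_seen = 0.0, 0
            for start in range(0, order.size, batch):
                sel = order[start : start + batch]
                loss, grads = net.loss_and_grads(X[sel], Y[sel])
                opt.step(net.params, grads)
                ep_loss += loss * sel.size
                n_seen += sel.size
            train_losses.append(ep_loss / max(n_seen, 1))
            if va_idx.size:
                val_losses.append(mse_loss(net.predict(X[va_idx]), Y[va_idx]))
            else:
                val_losses.append(float("nan"))
            if verbose:
                print(
                    f"epoch {epoch + 1:2d}/{cfg.epochs}  "
                    f"train mse {train_losses[-1]:.5f}  val mse {val_losses[-1]:.5f}"
                )
        return GaitPhaseResults(self, net, np.array(train_losses), np.array(val_losses), seed)


class GaitPhaseResults:
    """Fitted gait-phase regressor: weights, loss curves and predictors."""

    def __init__(self, model: GaitPhaseModel, net: ConvLSTMNet, train_losses, val_losses, seed: int):
        self.model = model
        self.net = net
        self.train_losses = np.asarray(train_losses, dtype=float)
        self.val_losses = np.asarray(val_losses, dtype=float)
        self.seed = seed

    @property
    def config(self) -> ModelConfig:
        return self.model.config

    @property
    def n_params(self) -> int:
        return self.net.count_params()

    def predict_windows(self, windows: np.ndarray) -> np.ndarray:
        """Phase percentages for pre-cut scaled windows (N, window, 4).

        Network outputs exactly at the circle centre (no defined angle) map
        to the NaN sentinel.
        """
        out = self.net.predict(np.asarray(windows, dtype=np.float32))
        return phase_mod.from_polar(out[:, 0], out[:, 1])

    def predict_series(
        self, series: GaitSeries, scaling: ScalingSpec = DEFAULT_SCALING
    ) -> np.ndarray:
        """Per-sample phase percentages for a session; the first window-1
        samples (incomplete history) get the NaN sentinel."""
        w = self.config.window
        n = len(series)
        out = np.full(n, np.nan)
        if n < w:
            return out
        from numpy.lib.stride_tricks import sliding_window_view

        X = series.scaled_matrix(scaling)
        wins = sliding_window_view(X, w, axis=0).transpose(0, 2, 1)
        out[w - 1 :] = self.predict_windows(np.ascontiguousarray(wins))
        return out

    def polar_outputs(self, windows: np.ndarray) -> np.ndarray:
        """Raw scaled polar network outputs (N, 2) for evaluation in p'-space."""
        return self.net.predict(np.asarray(windows, dtype=np.float32))

    def summary(self) -> str:
        total, per_layer = self.net.count_params(per_layer=True)
        cfg = self.config
        lines = [
            "Gait-phase conv-LSTM regression results",
            "=" * 47,
            f"windows (train+val): {len(self.model.dataset):>10d}",
            f"window length:       {cfg.window:>10d} samples (250 ms @ 200 Hz)"
            if cfg.window == 50
            else f"window length:       {cfg.window:>10d} samples",
            f"epochs / batch:      {cfg.epochs:>6d} / {cfg.batch_size}",
            f"optimiser:           Adam, lr {cfg.learning_rate}",
            f"seed:                {self.seed:>10d}",
            "-" * 47,
            "trainable parameters",
        ]
        for layer, cnt in per_layer.items():
            lines.append(f"  {layer:<10s} {cnt:>8,d}")
        lines.append(f"  {'total':<10s} {total:>8,d}")
        lines.append("-" * 47)
        lines.append(f"final train MSE:     {self.train_losses[-1]:.6f}")
        lines.append(f"final val MSE:       {self.val_losses[-1]:.6f}")
        return "\n".join(lines)

    # ----- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """Serialise config + weights + loss curves to one JSON file."""
        payload = {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "train_losses": self.train_losses.tolist(),
            "val_losses": self.val_losses.tolist(),
            "weights": {k: v.astype(float).tolist() for k, v in self.net.get_weights().items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "GaitPhaseResults":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = ModelConfig.from_dict(payload["config"])
        net = build_model(cfg)
        net.set_weights({k: np.asarray(v) for k, v in payload["weights"].items()})
        dummy = WindowDataset(
            np.zeros((1, cfg.window, cfg.channels)), np.full((1, 2), 0.5)
        )
        model = GaitPhaseModel(dummy, cfg)
        return cls(model, net, payload["train_losses"], payload["val_losses"], payload["seed"])
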