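import numpy as np
import pytest

import gaitphase as gp
from gaitphase.model import build_model, make_windows


class TestArchitecture:
    def test_default_parameter_count(self):
        net = build_model()
        total, per_layer = net.count_params(per_layer=True)
        assert total == 6258

    def test_per_layer_counts(self):
        _, per_layer = build_model().count_params(per_layer=True)
        assert per_layer["conv"] == 1056    # (8*4 + 1) * 32
        assert per_layer["lstm"] == 4240    # 4 * (32 + 20 + 1) * 20
        assert per_layer["dense0"] == 630   # (20 + 1) * 30
        assert per_layer["dense1"] == 310   # (30 + 1) * 10
        assert per_layer["dense2"] == 22    # (10 + 1) * 2

    def test_count_invariant_to_seed_and_training(self, labelled_lgw):
        assert build_model(gp.ModelConfig(seed=123)).count_params() == 6258
        series, labels = labelled_lgw
        ds = make_windows(series, labels)
        sub = gp.WindowDataset(ds.inputs[:600], ds.targets[:600])
        res = gp.GaitPhaseModel(sub, gp.ModelConfig(epochs=1, batch_size=128)).fit()
        assert res.n_params == 6258

    def test_rejects_invalid_dims(self):
        with pytest.raises(ValueError):
            gp.ModelConfig(conv_stride=2)
        from gaitphase.nn import ConvLSTMNet
        with pytest.raises(ValueError):
            ConvLSTMNet(window=4, channels=4, conv_kernel=8)


class TestMakeWindows:
    def test_window_count_fully_labelled(self):
        series = gp.GaitSeries(rate=200.0, f_z=np.full(100, 0.5), thigh=np.zeros(100),
                               knee=np.zeros(100), ankle=np.zeros(100))
        labels = np.linspace(0, 99, 100) % 100
        ds = make_windows(series, labels)
        assert len(ds) == 51  # 100 - 50 + 1

    def test_too_short_series_gives_empty(self):
        series = gp.GaitSeries(rate=200.0, f_z=np.zeros(49), thigh=np.zeros(49),
                               knee=np.zeros(49), ankle=np.zeros(49))
        assert len(make_windows(series, np.zeros(49))) == 0

    def test_sentinel_only_gives_empty(self):
        series = gp.GaitSeries(rate=200.0, f_z=np.zeros(80), thigh=np.zeros(80),
                               knee=np.zeros(80), ankle=np.zeros(80))
        assert len(make_windows(series, np.full(80, np.nan))) == 0

    def test_target_aligned_to_window_end(self, labelled_lgw):
        series, labels = labelled_lgw
        ds = make_windows(series, labels)
        t_first = 49 + np.flatnonzero(gp.phase.is_labeled(labels[49:]))[0]
        px, py = gp.to_polar(labels[t_first])
        assert ds.targets[0, 0] == pytest.approx(gp.scale_phase(px))
        assert ds.targets[0, 1] == pytest.approx(gp.scale_phase(py))
        # input window ends at t_first
        expected = series.scaled_matrix()[t_first - 49 : t_first + 1]
        assert np.allclose(ds.inputs[0], expected)

    def test_ranges(self, labelled_lgw):
        series, labels = labelled_lgw
        ds = make_windows(series, labels)
        assert ds.inputs.min() >= 0.0 and ds.inputs.max() <= 1.0
        assert ds.targets.min() >= 0.4 and ds.targets.max() <= 0.6


@pytest.fixture(scope="module")
def small_fit(labelled_lgw):
    series, labels = labelled_lgw
    ds = make_windows(series, labels)
    sub = gp.WindowDataset(ds.inputs[:1500], ds.targets[:1500])
    cfg = gp.ModelConfig(epochs=3, seed=5)
    return sub, cfg, gp.GaitPhaseModel(sub, cfg).fit()


class TestTraining:
    def test_validation_loss_improves(self, small_fit):
        _, _, res = small_fit
        assert res.val_losses[-1] < res.val_losses[0]

    def test_same_seed_identical_weights(self, small_fit):
        sub, cfg, res = small_fit
        res2 = gp.GaitPhaseModel(sub, cfg).fit()
        for k, v in res.net.params.items():
            assert np.array_equal(v, res2.net.params[k])

    def test_constant_target_converges(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0.4, 0.6, (512, 50, 4))
        Y = np.full((512, 2), 0.55)
        ds = gp.WindowDataset(X, Y)
        cfg = gp.ModelConfig(epochs=20, batch_size=64, learning_rate=5e-3, seed=1)
        res = gp.GaitPhaseModel(ds, cfg).fit()
        pred = res.net.predict(X.astype(np.float32))
        assert np.mean((pred - 0.55) ** 2) < 1e-4

    def test_empty_dataset_rejected(self):
        empty = gp.WindowDataset(np.empty((0, 50, 4)), np.empty((0, 2)))
        with pytest.raises(ValueError):
            gp.GaitPhaseModel(empty)

    def test_resplit_flag_changes_history(self, labelled_lgw):
        series, labels = labelled_lgw
        ds = make_windows(series, labels)
        sub = gp.WindowDataset(ds.inputs[:800], ds.targets[:800])
        a = gp.GaitPhaseModel(sub, gp.ModelConfig(epochs=2, seed=3)).fit()
        b = gp.GaitPhaseModel(sub, gp.ModelConfig(epochs=2, seed=3, resplit_each_epoch=True)).fit()
        assert not np.allclose(a.val_losses, b.val_losses)

    def test_summary_mentions_parameter_total(self, small_fit):
        _, _, res = small_fit
        assert "6,258" in res.summary()


class TestPrediction:
    def test_exact_polar_output_maps_to_zero_phase(self, small_fit):
        _, _, res = small_fit
        # bypass the net: the output mapping itself
        assert gp.from_polar(0.6, 0.5) == pytest.approx(0.0)

    def test_untrained_outputs_give_finite_phase(self):
        net = build_model(gp.ModelConfig(seed=8))
        X = np.random.default_rng(0).uniform(0, 1, (20, 50, 4)).astype(np.float32)
        out = net.predict(X)
        pct = gp.from_polar(out[:, 0], out[:, 1])
        assert np.all(np.isfinite(pct))

    def test_predict_series_head_is_sentinel(self, small_fit, labelled_lgw):
        _, _, res = small_fit
        series, _ = labelled_lgw
        pred = res.predict_series(series)
        assert pred.shape == (len(series),)
        assert np.all(~np.isfinite(pred[:49]))
        assert np.all(np.isfinite(pred[49:]))
        assert np.all((pred[49:] >= 0) & (pred[49:] < 100))

    def test_periodic_input_gives_periodic_prediction(self, small_fit, clean_lgw_session):
        _, _, res = small_fit
        series, _, hs = clean_lgw_session
        pred = res.predict_series(series)
        # compare predictions one stride apart (220 samples), away from edges
        a = pred[300:1000]
        b = pred[520:1220]
        err = gp.circular_error(a, b)
        assert np.median(err) < 5.0

    def test_save_load_round_trip(self, tmp_path, small_fit, labelled_lgw):
        _, _, res = small_fit
        series, _ = labelled_lgw
        path = tmp_path / "weights.json"
        res.save(path)
        back = gp.GaitPhaseResults.load(path)
        assert back.n_params == res.n_params
        p1 = res.predict_series(series)
        p2 = back.predict_series(series)
        m = np.isfinite(p1)
        assert np.allclose(p1[m], p2[m])
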