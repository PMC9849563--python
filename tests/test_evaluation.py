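import numpy as np
import pytest
from sklearn.metrics import r2_score

import gaitphase as gp
from gaitphase.evaluation import MedianTrajectory, N_GRID


class TestRSquared:
    def test_perfect_prediction(self):
        A = np.array([[0.4, 0.5], [0.6, 0.5], [0.5, 0.45]])
        mean, per = gp.r_squared(A, A)
        assert mean == pytest.approx(1.0)

    def test_mean_prediction_is_zero(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(0.4, 0.6, (50, 2))
        P = np.tile(A.mean(axis=0), (50, 1))
        mean, _ = gp.r_squared(A, P)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_case(self):
        A = np.array([[0.4, 0.5], [0.6, 0.5]])
        P = np.array([[0.5, 0.5], [0.5, 0.5]])
        # y-component has zero target variance -> undefined
        with pytest.raises(ValueError):
            gp.r_squared(A, P)
        A = np.array([[0.4, 0.45], [0.6, 0.55]])
        mean, per = gp.r_squared(A, np.array([[0.5, 0.5], [0.5, 0.5]]))
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn_on_random_data(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(0.4, 0.6, (200, 2))
        P = A + 0.01 * rng.standard_normal((200, 2))
        mean, per = gp.r_squared(A, P)
        assert per[0] == pytest.approx(r2_score(A[:, 0], P[:, 0]))
        assert per[1] == pytest.approx(r2_score(A[:, 1], P[:, 1]))
        assert mean == pytest.approx(r2_score(A, P, multioutput="uniform_average"))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gp.r_squared(np.zeros((3, 2)), np.zeros((4, 2)))


class TestPhaseErrorSummary:
    def test_identical_series_all_zero(self):
        a = np.linspace(0, 99, 200) % 100
        s = gp.phase_error_summary(a, a)
        assert s["mean_error"] == 0.0 and s["q75_error"] == 0.0

    def test_constant_offset(self):
        a = np.linspace(0, 99, 500) % 100
        s = gp.phase_error_summary(a, (a + 2.0) % 100)
        assert s["mean_error"] == pytest.approx(2.0)

    def test_wraparound_offset(self):
        a = np.linspace(0, 99, 500) % 100
        s = gp.phase_error_summary(a, (a + 98.0) % 100)
        assert s["mean_error"] == pytest.approx(2.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 100, 300)
        b = rng.uniform(0, 100, 300)
        assert gp.phase_error_summary(a, b) == gp.phase_error_summary(b, a)

    def test_sentinels_excluded(self):
        a = np.array([np.nan, 10.0, 20.0])
        b = np.array([5.0, 12.0, np.nan])
        s = gp.phase_error_summary(a, b)
        assert s["n_samples"] == 1 and s["mean_error"] == pytest.approx(2.0)

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError):
            gp.phase_error_summary(np.array([np.nan, 1.0]), np.array([1.0, np.nan]))


def _constant_series(values, n=300):
    """Series whose every channel is piecewise constant per stride."""
    arr = np.concatenate([np.full(100, v, dtype=float) for v in values])
    return gp.GaitSeries(rate=200.0, f_z=np.abs(arr), thigh=arr, knee=arr, ankle=arr)


class TestMedianTrajectory:
    def test_single_stride_resamples_to_grid(self, clean_lgw_session):
        series, _, hs = clean_lgw_session
        traj = gp.median_trajectory(series, hs[:2])
        assert traj.n_strides == 1
        assert traj.median["knee"].shape == (N_GRID,)
        src = series.knee[hs[0] : hs[1] + 1]
        assert traj.median["knee"][0] == pytest.approx(src[0])
        assert traj.median["knee"][-1] == pytest.approx(src[-1])

    def test_identical_strides_median_equals_each(self, clean_lgw_session):
        series, _, hs = clean_lgw_session
        one = gp.median_trajectory(series, hs[:2])
        many = gp.median_trajectory(series, hs[:9])
        np.testing.assert_allclose(many.median["thigh"], one.median["thigh"], atol=1e-6)

    def test_pointwise_median_of_constant_strides(self):
        series = _constant_series([1.0, 3.0, 100.0])
        traj = gp.median_trajectory(series, [0, 100, 200, 299])
        assert np.allclose(traj.median["knee"][1:-1], 3.0)

    def test_needs_a_complete_stride(self, clean_lgw_session):
        series, _, _ = clean_lgw_session
        with pytest.raises(ValueError):
            gp.median_trajectory(series, [10])

    def test_quartile_bands_order(self, noisy_lgw_session):
        series, _, hs = noisy_lgw_session
        traj = gp.median_trajectory(series, hs)
        for ch in ("f_z", "knee"):
            assert np.all(traj.q25[ch] <= traj.median[ch] + 1e-12)
            assert np.all(traj.median[ch] <= traj.q75[ch] + 1e-12)


class TestPearsonMedianCorrelation:
    def _traj(self, data):
        grid = np.linspace(0, 100, N_GRID)
        med = {c: np.asarray(data[c]) for c in ("f_z", "thigh", "knee", "ankle")}
        return MedianTrajectory(grid=grid, median=med, q25=med, q75=med, n_strides=1)

    def test_self_correlation_is_one(self, clean_lgw_session):
        series, _, hs = clean_lgw_session
        traj = gp.median_trajectory(series, hs)
        r = gp.pearson_median_correlation(traj, traj)
        for v in r.values():
            assert v == pytest.approx(1.0)

    def test_negated_is_minus_one(self):
        x = np.sin(np.linspace(0, 2 * np.pi, N_GRID))
        a = self._traj({c: x for c in ("f_z", "thigh", "knee", "ankle")})
        b = self._traj({c: -x for c in ("f_z", "thigh", "knee", "ankle")})
        for v in gp.pearson_median_correlation(a, b).values():
            assert v == pytest.approx(-1.0)

    def test_affine_invariance(self):
        x = np.cos(np.linspace(0, 2 * np.pi, N_GRID))
        a = self._traj({c: x for c in ("f_z", "thigh", "knee", "ankle")})
        b = self._traj({c: 2 * x + 7 for c in ("f_z", "thigh", "knee", "ankle")})
        for v in gp.pearson_median_correlation(a, b).values():
            assert v == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        flat = self._traj({c: np.ones(N_GRID) for c in ("f_z", "thigh", "knee", "ankle")})
        with pytest.raises(ValueError):
            gp.pearson_median_correlation(flat, flat)


class TestEvalReport:
    def test_report_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        actual = rng.uniform(0, 100, 400)
        pred = (actual + 1.5) % 100
        ax, ay = gp.to_polar(actual)
        px, py = gp.to_polar(pred)
        rep = gp.EvalReport.from_polar_and_phase(
            np.column_stack([gp.scale_phase(ax), gp.scale_phase(ay)]),
            np.column_stack([gp.scale_phase(px), gp.scale_phase(py)]),
            actual, pred,
        )
        assert rep.mean_error == pytest.approx(1.5)
        assert rep.r2_mean <= 1.0
        rep.to_json(tmp_path / "r.json")
        rep.to_csv(tmp_path / "r.csv")
        import json
        loaded = json.loads((tmp_path / "r.json").read_text())
        assert loaded["mean_error"] == pytest.approx(1.5)
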