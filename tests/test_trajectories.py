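"""Reading and preprocessing of cursor logs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import decision_landscapes as dl
from decision_landscapes.errors import (
    DegenerateTrajectoryError,
    FormatError,
    GeometryError,
    ParameterError,
    PreconditionError,
)

from conftest import make_raw_csv, straight_trajectory


class TestReader:
    def test_one_trajectory_per_trial(self, raw_log):
        path, trials = raw_log
        raws = dl.read_trajectories(path)
        assert len(raws) == len(trials)
        assert {r.trial_id for r in raws} == {"1", "2"}

    def test_missing_column_named_in_error(self, tmp_path):
        df = pd.DataFrame({"participant": ["p"], "trial": ["1"], "x": [0.0], "y": [0.0]})
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(FormatError, match="t"):
            dl.read_trajectories(path)

    def test_unsorted_timestamps_sorted_within_trial(self, tmp_path):
        ts = np.array([0.0, 0.2, 0.1, 0.3])
        path = make_raw_csv(
            tmp_path / "u.csv",
            [{"participant": "p", "trial": "1", "times": ts, "xs": ts * 2, "ys": ts * 3}],
        )
        (raw,) = dl.read_trajectories(path)
        assert np.all(np.diff(raw.times) > 0)
        # x follows its own timestamp after sorting
        np.testing.assert_allclose(raw.xs, raw.times * 2)

    def test_nonfinite_rows_rejected(self, tmp_path):
        path = make_raw_csv(
            tmp_path / "nan.csv",
            [
                {
                    "participant": "p",
                    "trial": "1",
                    "times": [0.0, 0.1, 0.2, 0.3],
                    "xs": [0.0, np.nan, 2.0, 3.0],
                    "ys": [0.0, 1.0, 2.0, 3.0],
                }
            ],
        )
        (raw,) = dl.read_trajectories(path)
        assert len(raw.times) == 3

    def test_roundtrip_through_writer(self, tmp_path):
        tr = straight_trajectory()
        vel = dl.estimate_velocity(tr)
        out = tmp_path / "pre.csv"
        dl.write_trajectories(out, [tr], [vel])
        df = pd.read_csv(out)
        assert {"participant", "trial", "t", "x", "y", "vx", "vy"} <= set(df.columns)
        np.testing.assert_allclose(df["x"], tr.xs)


class TestRescale:
    def test_fixed_points(self, geometry):
        raw = dl.RawTrajectory(
            "p",
            "1",
            times=[0.0, 1.0, 2.0],
            xs=[640.0, 1140.0, 140.0],
            ys=[900.0, 100.0, 100.0],
        )
        tr = dl.rescale(raw, geometry)
        np.testing.assert_allclose([tr.xs[0], tr.ys[0]], [0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose([tr.xs[1], tr.ys[1]], [1.0, 1.0], atol=1e-12)
        np.testing.assert_allclose([tr.xs[2], tr.ys[2]], [-1.0, 1.0], atol=1e-12)

    def test_midpoint_maps_affinely(self, geometry):
        raw = dl.RawTrajectory(
            "p", "1", times=[0.0, 1.0], xs=[640.0, (640.0 + 1140.0) / 2], ys=[900.0, 500.0]
        )
        tr = dl.rescale(raw, geometry)
        np.testing.assert_allclose([tr.xs[1], tr.ys[1]], [0.5, 0.5], atol=1e-12)

    def test_round_trip_identity(self, geometry):
        rng = np.random.default_rng(0)
        xs = rng.uniform(100, 1200, 20)
        ys = rng.uniform(50, 950, 20)
        ys[-1] = 100.0
        xs[-1] = 1140.0
        raw = dl.RawTrajectory("p", "1", np.arange(20.0), xs, ys)
        tr = dl.rescale(raw, geometry)
        # invert the affine map and compare to the device coordinates
        back_x = tr.xs * (1140.0 - 640.0) + 640.0
        back_y = tr.ys * (100.0 - 900.0) + 900.0
        np.testing.assert_allclose(back_x, xs, atol=1e-9)
        np.testing.assert_allclose(back_y, ys, atol=1e-9)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(GeometryError):
            dl.ScreenGeometry(start=(0, 0), left_target=(5, 1), right_target=(5, 1))


class TestTrim:
    def _with_static_head(self):
        ts = np.linspace(0.0, 1.0, 11)
        xs = np.concatenate([np.zeros(5), np.linspace(0.1, 1.0, 6)])
        ys = np.concatenate([np.zeros(5), np.linspace(0.1, 1.0, 6)])
        return dl.Trajectory("p", "t", ts, xs, ys, choice=1)

    def test_static_head_dropped_keeping_last(self):
        tr = dl.trim(self._with_static_head())
        assert tr.n_samples == 11 - 4
        assert tr.times[0] == 0.0
        assert tr.xs[0] == 0.0  # the last static sample is retained as origin

    def test_time_origin_reset(self):
        tr = dl.trim(self._with_static_head())
        # original sample 4 was at t = 0.4
        np.testing.assert_allclose(tr.times, np.linspace(0.0, 0.6, 7), atol=1e-12)

    def test_static_tail_dropped(self):
        ts = np.linspace(0.0, 1.0, 11)
        xs = np.concatenate([np.linspace(0.0, 1.0, 6), np.full(5, 1.0)])
        ys = xs.copy()
        tr = dl.trim(dl.Trajectory("p", "t", ts, xs, ys, choice=1))
        assert tr.n_samples == 6
        np.testing.assert_allclose(tr.xs[-1], 1.0)

    def test_moving_trajectory_only_time_shifted(self):
        tr = straight_trajectory(duration=0.5, n=21)
        shifted = dl.Trajectory("p", "t", tr.times + 3.0, tr.xs, tr.ys, choice=1)
        out = dl.trim(shifted)
        assert out.n_samples == 21
        np.testing.assert_allclose(out.times, tr.times, atol=1e-12)

    def test_static_trajectory_degenerate(self):
        tr = dl.Trajectory("p", "t", [0.0, 0.1, 0.2], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0], choice=1)
        with pytest.raises(DegenerateTrajectoryError):
            dl.trim(tr)

    def test_never_increases_sample_count(self, sim_dataset):
        for t in sim_dataset:
            assert dl.trim(t).n_samples <= t.n_samples


class TestResample:
    def test_default_yields_101_points(self, sim_dataset):
        out = dl.resample(dl.trim(sim_dataset[0]))
        assert out.n_samples == 101
        assert out.is_uniform()

    def test_endpoints_and_duration_preserved(self, sim_dataset):
        tr = dl.trim(sim_dataset[0])
        out = dl.resample(tr, 55)
        assert out.n_samples == 55
        np.testing.assert_allclose(
            [out.xs[0], out.ys[0], out.xs[-1], out.ys[-1]],
            [tr.xs[0], tr.ys[0], tr.xs[-1], tr.ys[-1]],
        )
        np.testing.assert_allclose(out.duration, tr.duration, atol=1e-12)

    def test_straight_line_stays_straight(self):
        # irregular sampling of a line resamples onto the same line
        ts = np.array([0.0, 0.05, 0.3, 0.31, 0.7, 1.0])
        tr = dl.Trajectory("p", "t", ts, 0.9 * ts, 0.8 * ts, choice=1)
        out = dl.resample(tr, 101)
        np.testing.assert_allclose(out.xs, 0.9 * out.times, atol=1e-12)
        np.testing.assert_allclose(out.ys, 0.8 * out.times, atol=1e-12)

    @given(n=st.integers(min_value=2, max_value=200))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_output_length_is_requested_count(self, n):
        out = dl.resample(straight_trajectory(n=37), n)
        assert out.n_samples == n

    def test_idempotent_on_uniform_grid(self):
        tr = straight_trajectory(n=101)
        out = dl.resample(tr, 101)
        np.testing.assert_allclose(out.xs, tr.xs, atol=1e-12)
        np.testing.assert_allclose(out.times, tr.times, atol=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            dl.resample(straight_trajectory(), 1)


class TestVelocity:
    @pytest.mark.parametrize("method", ["savgol", "finite_difference"])
    def test_linear_motion_exact(self, method):
        ts = np.linspace(0.0, 1.0, 51)
        tr = dl.Trajectory("p", "t", ts, ts.copy(), np.zeros_like(ts), choice=1)
        v = dl.estimate_velocity(tr, method=method)
        np.testing.assert_allclose(v.vxs, 1.0, atol=1e-9)
        np.testing.assert_allclose(v.vys, 0.0, atol=1e-9)

    @pytest.mark.parametrize("method", ["savgol", "finite_difference"])
    def test_constant_position_zero(self, method):
        ts = np.linspace(0.0, 1.0, 51)
        tr = dl.Trajectory("p", "t", ts, np.full_like(ts, 0.3), np.full_like(ts, 0.7), choice=1)
        v = dl.estimate_velocity(tr, method=method)
        np.testing.assert_allclose(v.vxs, 0.0, atol=1e-12)
        np.testing.assert_allclose(v.vys, 0.0, atol=1e-12)

    def test_quadratic_exact_for_savgol_order2(self):
        ts = np.linspace(0.0, 1.0, 101)
        tr = dl.Trajectory("p", "t", ts, ts**2, ts.copy(), choice=1)
        v = dl.estimate_velocity(tr, method="savgol", window=7, polyorder=2)
        np.testing.assert_allclose(v.vxs[3:-3], 2 * ts[3:-3], atol=1e-9)

    def test_nonuniform_grid_rejected(self):
        tr = dl.Trajectory("p", "t", [0.0, 0.1, 0.5], [0.0, 0.1, 0.5], [0, 0, 0], choice=1)
        with pytest.raises(PreconditionError, match="resample"):
            dl.estimate_velocity(tr)

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            dl.estimate_velocity(straight_trajectory(), window=6)


class TestMirror:
    def test_right_reference_is_identity(self):
        tr = straight_trajectory(choice=1)
        out = dl.mirror_to_canonical(tr, 1)
        assert out is tr

    def test_involution(self):
        tr = straight_trajectory(choice=1)
        out = dl.mirror_to_canonical(dl.mirror_to_canonical(tr, -1), -1)
        np.testing.assert_allclose(out.xs, tr.xs)
        assert out.choice == tr.choice

    def test_max_deviation_magnitude_preserved(self, sim_dataset):
        tr = dl.resample(dl.trim(sim_dataset[0]), 101)
        mirrored = dl.mirror_to_canonical(tr, -1)
        assert dl.max_deviation(mirrored) == pytest.approx(dl.max_deviation(tr), abs=1e-12)


def test_full_preprocessing_contract(raw_log, geometry):
    path, _ = raw_log
    for raw in dl.read_trajectories(path):
        tr, vel = dl.preprocess(raw, geometry)
        assert tr.n_samples == 101 == len(vel)
        assert np.hypot(tr.xs[0], tr.ys[0]) < 0.05
        assert np.hypot(tr.xs[-1] - tr.choice, tr.ys[-1] - 1.0) < 0.2
        assert tr.choice == np.sign(tr.xs[-1])
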