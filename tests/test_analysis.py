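"""Velocity extraction and distribution fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import beadchain as bc
from beadchain.analysis import (CalibrationResult, VelocitySample,
                                damping_calibration_sweep,
                                finite_difference_velocities,
                                fit_exponent_beta, fit_signed_exponential,
                                mean_speed, pooled_velocity_sample,
                                select_middle_tracers, tracks_from_trajectory)
from beadchain.errors import FitError, ValidationError
from beadchain.io_tracks import TrackTable
from beadchain.simulator import Trajectory


def table_from_frames(frames, xs, ys=None, frame_rate=30.0, length_unit=1.0):
    ys = ys if ys is not None else np.zeros_like(np.asarray(xs, float))
    df = pd.DataFrame({"track": 0, "frame": frames, "x": xs, "y": ys})
    return TrackTable(df, frame_rate=frame_rate, length_unit=length_unit)


class TestFiniteDifferences:
    def test_static_track_gives_zero_velocities(self):
        t = table_from_frames(np.arange(10), np.full(10, 3.7))
        v = finite_difference_velocities(t, components=("x",))["x"]
        assert v.n == 10
        assert np.allclose(v.values, 0.0)

    def test_linear_motion_recovered_exactly(self):
        a, fps = 0.25, 30.0
        frames = np.arange(20)
        t = table_from_frames(frames, a * frames / fps, frame_rate=fps)
        v = finite_difference_velocities(t, components=("x",))["x"]
        # central differences interior, one-sided ends: all exact for linear x(t)
        assert v.n == 20
        assert np.allclose(v.values, a)

    def test_gap_yields_no_spanning_sample(self):
        # 10-frame toy track missing frame 4; oracle: enumerate by hand which
        # indices have both immediate neighbours (interior) or an adjacent
        # neighbour (ends)
        frames = np.array([0, 1, 2, 3, 5, 6, 7, 8, 9])
        rng = np.random.default_rng(0)
        xs = rng.normal(size=frames.size)
        t = table_from_frames(frames, xs, frame_rate=1.0)
        v = finite_difference_velocities(t, components=("x",))["x"]
        expected = []
        expected.append(xs[1] - xs[0])            # leading one-sided
        expected.append((xs[2] - xs[0]) / 2)      # frames 0-2 around 1
        expected.append((xs[3] - xs[1]) / 2)      # frames 1-3 around 2
        # frame 3 lacks frame 4; frame 5 lacks frame 4 -> no samples
        expected.append((xs[6] - xs[4]) / 2)      # frames 5-7 around 6
        expected.append((xs[7] - xs[5]) / 2)
        expected.append((xs[8] - xs[6]) / 2)
        expected.append(xs[8] - xs[7])            # trailing one-sided
        assert v.n == len(expected) == 7
        assert np.allclose(np.sort(v.values), np.sort(expected))

    def test_single_frame_track_warns_and_yields_nothing(self):
        t = table_from_frames([0], [1.0])
        with pytest.warns(UserWarning, match="single frame"):
            v = finite_difference_velocities(t, components=("x",))["x"]
        assert v.n == 0

    def test_length_unit_scales_to_si(self):
        frames = np.arange(5)
        t = table_from_frames(frames, 2.0 * frames, frame_rate=10.0,
                              length_unit=1e-3)  # track in mm
        v = finite_difference_velocities(t, components=("x",))["x"]
        assert np.allclose(v.values, 2.0e-3 * 10.0)

    def test_convergence_to_instantaneous_with_stride(self, short_chain_run):
        # finite differences of recorded positions approach the recorded
        # instantaneous velocities as the sampling stride shrinks
        traj = short_chain_run
        p = traj.crimp_indices[1]
        rms = []
        for stride in (1, 5, 25):
            pos = traj.positions[::stride, p, 0]
            vexact = traj.velocities[::stride, p, 0]
            dtf = traj.frame_interval * stride
            vfd = (pos[2:] - pos[:-2]) / (2 * dtf)
            rms.append(float(np.sqrt(np.mean((vfd - vexact[1:-1]) ** 2))))
        assert rms[0] < rms[1] < rms[2]


class TestTracerSelection:
    def test_study_selection(self):
        assert select_middle_tracers(15, 5).tolist() == [5, 6, 7, 8, 9]

    def test_all_when_k_equals_total(self):
        assert select_middle_tracers(7, 7).tolist() == list(range(7))

    def test_too_few_tracers(self):
        with pytest.raises(ValidationError):
            select_middle_tracers(3, 5)

    def test_tie_breaks_toward_lower_index(self):
        assert select_middle_tracers(4, 1).tolist() == [1]
        assert select_middle_tracers(4, 2).tolist() == [1, 2]


class TestSignedExponential:
    def test_mle_rate_recovery(self):
        rng = np.random.default_rng(1)
        lam = 2.0
        v = rng.exponential(1 / lam, size=10_000)
        fit = fit_signed_exponential(VelocitySample(v))
        se = lam / np.sqrt(v.size)
        assert abs(fit.lambda_pos - lam) < 3 * se
        assert fit.lambda_neg is None

    def test_mirrored_sample_has_equal_rates(self):
        rng = np.random.default_rng(2)
        v = rng.exponential(0.5, size=500)
        both = np.concatenate([v, -v])
        fit = fit_signed_exponential(VelocitySample(both))
        assert fit.lambda_pos == fit.lambda_neg
        assert fit.n_pos == fit.n_neg == 500


class TestBetaFit:
    @pytest.mark.parametrize("dist,truth,band", [
        ("laplace", 1.0, (0.9, 1.1)),
        ("gaussian", 2.0, (1.85, 2.15)),
    ])
    def test_known_distribution_recovery(self, dist, truth, band):
        rng = np.random.default_rng(5)
        v = (rng.laplace(0, 0.05, 10_000) if dist == "laplace"
             else rng.normal(0, 0.05, 10_000))
        fit = fit_exponent_beta(VelocitySample(v), n_boot=50, seed=5)
        assert band[0] < fit.beta < band[1]
        assert fit.beta_ci[0] <= fit.beta <= fit.beta_ci[1]
        assert fit.alpha == pytest.approx(fit.scale ** -fit.beta)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        v = rng.laplace(0, 1.0, 5000)
        b1 = fit_exponent_beta(VelocitySample(v), n_boot=0).beta
        b2 = fit_exponent_beta(VelocitySample(1e-3 * v), n_boot=0).beta
        assert abs(b1 - b2) < 1e-6

    def test_agrees_with_independent_mle(self):
        # scipy's generalized-normal fit is an independent implementation of
        # the same family
        rng = np.random.default_rng(7)
        v = rng.laplace(0, 0.1, 8000)
        mine = fit_exponent_beta(VelocitySample(v), n_boot=0)
        centred = v - np.median(v)
        b_scipy = stats.gennorm.fit(centred, floc=0)[0]
        assert abs(mine.beta - b_scipy) < 0.02

    def test_loghist_mode(self):
        rng = np.random.default_rng(8)
        v = rng.laplace(0, 0.05, 20_000)
        fit = fit_exponent_beta(VelocitySample(v), method="loghist", n_boot=0)
        assert 0.8 < fit.beta < 1.2

    def test_degenerate_and_small_samples_rejected(self):
        with pytest.raises(FitError):
            fit_exponent_beta(VelocitySample(np.full(1000, 2.0)), n_boot=0)
        with pytest.raises(ValidationError):
            fit_exponent_beta(VelocitySample(np.random.default_rng(0)
                                             .normal(size=100)), n_boot=0)


def make_traj(velocities, dt=1e-2):
    v = np.asarray(velocities, dtype=float)
    frames, n = v.shape[:2]
    return Trajectory(
        times=dt * np.arange(frames), positions=np.zeros_like(v),
        velocities=v, kinds=["bead"] * n, radii=np.ones(n) * 1e-3,
        masses=np.ones(n), config={"timestep": dt, "record_stride": 1})


class TestMeanSpeedAndCalibration:
    def test_zero_and_constant_speed(self):
        assert mean_speed(make_traj(np.zeros((5, 2, 3)))) == 0.0
        v = np.zeros((5, 1, 3))
        v[:, 0, 0] = 0.3
        assert mean_speed(make_traj(v)) == pytest.approx(0.3)

    def test_component_restriction(self):
        v = np.zeros((4, 1, 3))
        v[:, 0, :] = [3.0, 4.0, 12.0]
        assert mean_speed(make_traj(v)) == pytest.approx(13.0)
        assert mean_speed(make_traj(v), components=("x", "y")) == pytest.approx(5.0)

    @pytest.fixture(scope="class")
    def sweep(self, ff_calibrated):
        chain = bc.ChainSpec(n_beads=2, anchor_separation=0.03)
        topo = bc.build_topology(chain, bc.BeadSpec(), ff_calibrated)
        config = bc.SimulationConfig(n_steps=4000, equilibration_steps=1000,
                                     record_stride=5, seed=3)
        factory = lambda: bc.ForcingModel("laplace", kr=ff_calibrated.kr, seed=3)
        result = damping_calibration_sweep(
            topo, ff_calibrated, factory, config,
            kv_values=[0.05, 0.1, 0.2], target_mean_speed=0.05)
        return result

    def test_sweep_monotone_decreasing(self, sweep: CalibrationResult):
        assert sweep.monotone
        speeds = sweep.table["mean_speed"].to_numpy()
        assert np.all(np.diff(speeds) < 0)

    def test_overdamped_speed_halves_when_damping_doubles(self, sweep):
        s = sweep.table.set_index("kv")["mean_speed"]
        assert s[0.05] / s[0.1] == pytest.approx(2.0, rel=0.15)
        assert s[0.1] / s[0.2] == pytest.approx(2.0, rel=0.15)

    def test_self_consistent_selection(self, sweep, ff_calibrated):
        chain = bc.ChainSpec(n_beads=2, anchor_separation=0.03)
        topo = bc.build_topology(chain, bc.BeadSpec(), ff_calibrated)
        config = bc.SimulationConfig(n_steps=4000, equilibration_steps=1000,
                                     record_stride=5, seed=3)
        factory = lambda: bc.ForcingModel("laplace", kr=ff_calibrated.kr, seed=3)
        target = float(sweep.table.set_index("kv")["mean_speed"][0.1])
        again = damping_calibration_sweep(topo, ff_calibrated, factory, config,
                                          kv_values=[0.05, 0.1, 0.2],
                                          target_mean_speed=target)
        assert again.selected_kv == 0.1

    def test_single_kv_selected(self, ff_calibrated):
        chain = bc.ChainSpec(n_beads=1, anchor_separation=0.02)
        topo = bc.build_topology(chain, bc.BeadSpec(), ff_calibrated)
        config = bc.SimulationConfig(n_steps=500, equilibration_steps=100,
                                     record_stride=5, seed=4)
        factory = lambda: bc.ForcingModel("laplace", kr=ff_calibrated.kr, seed=4)
        result = damping_calibration_sweep(topo, ff_calibrated, factory, config,
                                           kv_values=[0.07],
                                           target_mean_speed=123.0)
        assert result.selected_kv == 0.07


def test_semilog_plot_helper_runs_headless():
    import matplotlib
    matplotlib.use("Agg")
    from beadchain.analysis import plot_velocity_distribution

    rng = np.random.default_rng(12)
    sample = VelocitySample(rng.laplace(0, 0.05, 3000))
    fit = fit_exponent_beta(sample, n_boot=0)
    ax = plot_velocity_distribution([sample], [fit])
    assert ax.get_yscale() == "log"
    assert len(ax.lines) == 2


class TestSymmetryAndPooling:
    def test_transverse_symmetry_of_pooled_velocities(self, short_chain_run):
        sample = pooled_velocity_sample(
            short_chain_run, short_chain_run.crimp_indices, components=("x",))
        # blocked standard error to respect frame-to-frame correlation
        per_frame = short_chain_run.velocities[:, short_chain_run.crimp_indices, 0]
        blocks = np.array_split(per_frame.mean(axis=1), 20)
        bm = np.array([b.mean() for b in blocks])
        se = bm.std(ddof=1) / np.sqrt(len(bm))
        assert abs(sample.values.mean()) < 3 * se

    def test_tracks_round_trip_through_projection(self, short_chain_run):
        idx = short_chain_run.crimp_indices[:2]
        table = tracks_from_trajectory(short_chain_run, idx)
        assert table.n_tracks == 2
        assert len(table) == 2 * short_chain_run.n_frames
        # positions come back in mm
        assert np.allclose(
            table.data.query("track == 0")["x"].to_numpy() * table.length_unit,
            short_chain_run.positions[:, idx[0], 0])
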