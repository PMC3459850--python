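"""Analysis estimators against closed forms and synthetic ground truth."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import myxoripple as mx
from myxoripple import analysis
from myxoripple.analysis import (Kymograph, Trajectory, collision_mask,
                                 detect_crests, fit_slope_no_intercept,
                                 fraction_reversals_in_crest_collisions,
                                 predicted_wavelength, split_directions)
from myxoripple.fixtures import FixtureSpec, make_kymograph_fixture, make_trajectory_fixture


class TestPredictedWavelength:
    def test_classic_two_v_tau(self):
        # colliding crests at relative speed 2v reverse every superposition
        assert predicted_wavelength(3.0, 8.0, 0.0) == pytest.approx(48.0)

    def test_crest_width_correction(self):
        # the crest-width term brings v=3, tau=8 into the 70-80 um band
        lam = predicted_wavelength(3.0, 8.0, 12.5)
        assert lam == pytest.approx(73.0)
        assert 70.0 <= lam <= 80.0

    def test_stationary_limit(self):
        assert predicted_wavelength(0.0, 5.0, 7.0) == pytest.approx(14.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0, 20), st.floats(0.1, 40), st.floats(0, 30))
    def test_linear_structure(self, v, tau, delta):
        lam = predicted_wavelength(v, tau, delta)
        assert lam == pytest.approx(2 * v * tau + 2 * delta)
        assert predicted_wavelength(v, tau, 0.0) <= lam

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            predicted_wavelength(3.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            predicted_wavelength(-1.0, 5.0, 0.0)


class TestWavelengthEstimator:
    def test_scale_equivariance(self):
        # stretching the x-axis by c multiplies the estimate by c
        kym, _ = make_kymograph_fixture(FixtureSpec("sin_kymograph", seed=1,
                                                    params={"lambda_um": 48.0}))
        est1 = analysis.estimate_wavelength(kym)
        stretched = Kymograph(kym.data, bin_width=kym.bin_width * 1.5,
                              frame_interval=kym.frame_interval)
        est2 = analysis.estimate_wavelength(stretched)
        assert est2.wavelength / est1.wavelength == pytest.approx(1.5, rel=0.05)

    def test_flat_field_flagged_not_fabricated(self):
        kym, _ = make_kymograph_fixture(FixtureSpec("uniform_kymograph"))
        est = analysis.estimate_wavelength(kym)
        assert not est.ok and math.isnan(est.wavelength)
        assert "no dominant scale" in est.flag

    def test_requires_min_frames(self):
        kym, _ = make_kymograph_fixture(FixtureSpec("sin_kymograph",
                                                    params={"duration": 5.0}))
        with pytest.raises(ValueError, match="frames"):
            analysis.estimate_wavelength(kym)

    def test_robust_to_poisson_sampling(self):
        kym, truth = make_kymograph_fixture(
            FixtureSpec("sin_kymograph", seed=5,
                        params={"lambda_um": 72.0, "baseline": 8.0,
                                "amplitude": 3.0, "poisson": 1.0}))
        est = analysis.estimate_wavelength(kym)
        assert est.ok
        assert est.wavelength == pytest.approx(72.0, rel=0.10)


class TestOrderParameter:
    def test_uniform_poisson_near_zero(self):
        kym, _ = make_kymograph_fixture(
            FixtureSpec("uniform_kymograph", seed=2,
                        params={"baseline": 6.0, "poisson": 1.0}))
        assert analysis.order_parameter(kym) < 0.05

    def test_noiseless_sinusoid_far_above_noise_floor(self):
        kym, _ = make_kymograph_fixture(FixtureSpec("sin_kymograph", seed=1))
        op_sin = analysis.order_parameter(kym)
        kym_u, _ = make_kymograph_fixture(
            FixtureSpec("uniform_kymograph", seed=2,
                        params={"baseline": 6.0, "poisson": 1.0}))
        op_uniform = analysis.order_parameter(kym_u)
        assert op_sin > 0.15
        assert op_sin > 30 * op_uniform

    def test_monotone_with_contrast(self):
        vals = []
        for amp in (0.0, 0.5, 2.0):
            kym, _ = make_kymograph_fixture(
                FixtureSpec("sin_kymograph", seed=3,
                            params={"amplitude": amp, "baseline": 6.0,
                                    "poisson": 1.0}))
            vals.append(analysis.order_parameter(kym))
        assert vals[0] < vals[1] < vals[2]


class TestCrestDetection:
    def test_single_bin_spike_resolution_floor(self):
        data = np.zeros((30, 100))
        data[:, 40] = 50.0
        kym = Kymograph(data, bin_width=2.0, frame_interval=1.0)
        cw = analysis.estimate_crest_width(kym)
        assert cw.ok
        assert cw.width <= 2 * kym.bin_width

    def test_insufficient_crests_flagged(self):
        kym, _ = make_kymograph_fixture(FixtureSpec("uniform_kymograph"))
        cw = analysis.estimate_crest_width(kym)
        assert not cw.ok and "insufficient" in cw.flag

    def test_crest_positions_on_known_grid(self):
        kym, truth = make_kymograph_fixture(
            FixtureSpec("gaussian_crest_kymograph", seed=1,
                        params={"lambda_um": 80.0, "delta_um": 10.0, "speed": 0.0}))
        pos = detect_crests(kym.data[0], kym.bin_width)
        expected = np.arange(0.0, kym.extent_x, 80.0)
        assert len(pos) == len(expected)
        # centres sit within a bin of the construction grid (mod domain)
        d = np.abs((pos[:, None] - expected[None, :] + 240) % 480 - 240)
        assert d.min(axis=1).max() <= kym.bin_width


class TestDirectionSplitting:
    def test_pure_right_mover_separates(self):
        kym, _ = make_kymograph_fixture(
            FixtureSpec("gaussian_crest_kymograph", seed=1,
                        params={"lambda_um": 80.0, "speed": 4.0}))
        # build one-directional field directly
        nb, nf = 240, 100
        x = (np.arange(nb) + 0.5) * 2.0
        t = np.arange(nf)[:, None]
        data = 2.0 + np.cos(2 * np.pi / 60.0 * (x[None, :] - 4.0 * t))
        kym = Kymograph(data, 2.0, 1.0)
        right, left = split_directions(kym)
        assert np.mean(right ** 2) > 50 * np.mean(left ** 2)

    def test_energy_conserved(self):
        kym, _ = make_kymograph_fixture(FixtureSpec("sin_kymograph", seed=2))
        right, left = split_directions(kym)
        centered = kym.data - kym.data.mean(axis=1, keepdims=True)
        assert np.allclose(right + left, centered, atol=1e-8)


class TestCollisionFraction:
    def test_uniform_random_events_match_area_fraction(self):
        kym, _ = make_kymograph_fixture(
            FixtureSpec("gaussian_crest_kymograph", seed=4,
                        params={"lambda_um": 80.0, "delta_um": 10.0, "speed": 4.0}))
        mask = collision_mask(kym, delta=10.0)
        area_frac = mask.mean()
        rng = np.random.Generator(np.random.PCG64(7))
        n_ev = 4000
        ev = pd.DataFrame({
            "t_min": rng.uniform(kym.times[0], kym.times[-1], n_ev),
            "agent_id": rng.integers(0, 40, n_ev),
            "x_um": rng.uniform(0, kym.extent_x, n_ev)})
        frac, se = fraction_reversals_in_crest_collisions(None, ev, kym, delta=10.0)
        assert frac == pytest.approx(area_frac, abs=max(4 * se, 0.03))

    def test_events_placed_at_collisions_score_high(self):
        kym, truth = make_kymograph_fixture(
            FixtureSpec("gaussian_crest_kymograph", seed=4,
                        params={"lambda_um": 80.0, "delta_um": 10.0, "speed": 4.0}))
        period = truth["collision_period_min"]
        # tracks x_r = 80 m + 4 t and x_l = 80 n - 4 t coincide every 10 min,
        # alternating between x = 40 mod 80 (odd steps) and x = 0 mod 80
        rows = []
        for k, t in enumerate(np.arange(period, 90.0, period), start=1):
            base = 40.0 if k % 2 == 1 else 0.0
            for j, x in enumerate((base, base + 80.0, base + 160.0)):
                rows.append((t, j, x))
        ev = pd.DataFrame(rows, columns=["t_min", "agent_id", "x_um"])
        frac, _ = fraction_reversals_in_crest_collisions(None, ev, kym, delta=10.0)
        assert frac > 0.9


class TestDetectReversals:
    def test_single_frame_flicker_ignored(self):
        t = np.arange(40.0)
        x = np.cumsum(np.ones(40) * 5.0)
        x[20] -= 12.0  # one-frame backward glitch
        x[21:] -= 2.0
        tr = Trajectory(0, t, x, np.zeros(40))
        det = analysis.detect_reversals(tr, k_frames=3, v_min=1.0)
        assert len(det.times) == 0

    def test_short_trajectory_flagged(self):
        tr = Trajectory(0, np.arange(4.0), np.arange(4.0), np.zeros(4))
        det = analysis.detect_reversals(tr, k_frames=3)
        assert not det.ok

    def test_slow_legs_rejected_by_v_min(self):
        trajs, _ = make_trajectory_fixture(
            FixtureSpec("zigzag_trajectory", params={"v": 0.4, "tau": 10.0, "n": 1}))
        det = analysis.detect_reversals(trajs[0], v_min=1.0)
        assert len(det.times) == 0

    def test_pooled_principal_axis_near_x(self):
        trajs, _ = make_trajectory_fixture(
            FixtureSpec("zigzag_trajectory", seed=3,
                        params={"n": 8, "noise_sd": 0.3}))
        axis = analysis.principal_axis(trajs)
        assert abs(axis[0]) > 0.99


class TestDetectorAgainstSimulatorLog:
    def test_recall_and_precision_on_rippling_tracks(self):
        # trajectory-based reversal detection recovers the simulator's own
        # event log; 0.5-min sampling resolves the ~4-min rippling legs
        p = mx.ModelParams(domain_x=250.0, domain_y=50.0, n_agents=3000)
        rec = mx.run_simulation(p, duration=160.0, seed=21, n_tracked=60,
                                traj_interval=0.5, keep_final_state=False)
        trajs = [tr.window(80, 160) for tr in rec.trajectories()]
        ev = rec.events[(rec.events.t_min >= 80) & (rec.events.t_min <= 160)]
        tol = 2.0
        matched = found = logged = precise = 0
        for tr in trajs:
            det = analysis.detect_reversals(tr)
            true_t = ev[ev.agent_id == tr.id].t_min.to_numpy()
            logged += len(true_t)
            found += len(det.times)
            for t0 in true_t:
                if len(det.times) and np.min(np.abs(det.times - t0)) <= tol:
                    matched += 1
            for td in det.times:
                if len(true_t) and np.min(np.abs(true_t - td)) <= tol:
                    precise += 1
        assert matched / logged >= 0.95
        assert precise / found >= 0.95


class TestMSD:
    def test_zero_at_zero_lag_and_translation_rotation_invariance(self):
        trajs, _ = make_trajectory_fixture(
            FixtureSpec("brownian_trajectory", seed=3, params={"D": 5.0, "n": 20}))
        lags, msd = analysis.compute_msd(trajs, max_lag=30.0)
        assert msd[0] == 0.0
        c, s = math.cos(0.7), math.sin(0.7)
        moved = [Trajectory(tr.id, tr.t, 100 + c * tr.x - s * tr.y,
                            -50 + s * tr.x + c * tr.y) for tr in trajs]
        lags2, msd2 = analysis.compute_msd(moved, max_lag=30.0)
        assert np.allclose(msd, msd2, rtol=1e-9)

    def test_ballistic_quadratic(self):
        t = np.arange(101.0)
        trajs = [Trajectory(0, t, 3.0 * t, np.zeros_like(t))] * 10
        lags, msd = analysis.compute_msd(trajs, max_lag=50.0)
        assert np.allclose(msd[1:], 9.0 * lags[1:] ** 2, rtol=1e-9)

    def test_overlapping_vs_independent_agree_in_mean(self):
        trajs, _ = make_trajectory_fixture(
            FixtureSpec("brownian_trajectory", seed=6,
                        params={"D": 8.0, "n": 400, "duration": 150.0}))
        l1, m1 = analysis.compute_msd(trajs, max_lag=15.0, overlapping=True)
        l2, m2 = analysis.compute_msd(trajs, max_lag=15.0, overlapping=False)
        s1 = fit_slope_no_intercept(l1, m1)
        s2 = fit_slope_no_intercept(l2, m2)
        assert s1 == pytest.approx(s2, rel=0.1)


class TestNoInterceptFit:
    def test_exact_line(self):
        x = np.arange(1.0, 10.0)
        assert fit_slope_no_intercept(x, 3.0 * x) == pytest.approx(3.0)

    def test_closed_form(self):
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([2.0, 3.0, 9.0])
        assert fit_slope_no_intercept(x, y) == pytest.approx(np.sum(x * y) / np.sum(x * x))

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_slope_no_intercept([0.0, 0.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            fit_slope_no_intercept([1.0], [1.0])


class TestExternalTrajectoryTables:
    def test_generic_column_names_accepted(self):
        df = pd.DataFrame({"t": [0.0, 1.0, 2.0, 0.0, 1.0, 2.0],
                           "id": [1, 1, 1, 2, 2, 2],
                           "x": [0.0, 1.0, 2.0, 5.0, 6.0, 7.0],
                           "y": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]})
        trajs = analysis.trajectories_from_table(df)
        assert [tr.id for tr in trajs] == [1, 2]
        assert trajs[0].frame_interval == 1.0

    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            Trajectory(0, np.array([0.0, 1.0, 3.0]), np.zeros(3), np.zeros(3))
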