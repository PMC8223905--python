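"""Filtering, virtual-toe construction, and rigid-body tracking."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from proswing.containers import MarkerTrajectorySet, marker_label
from proswing.errors import DegenerateGeometryError, SeriesTooShortError
from proswing.preprocess import (
    StandingCalibration,
    build_virtual_toe,
    interpolate_gaps,
    lowpass_filter,
    rigid_transform,
    track_virtual_toe,
)
from proswing.simulate import SimConfig, generate_trial


def sine(freq, rate, n):
    return np.sin(2 * np.pi * freq * np.arange(n) / rate)


class TestLowpassFilter:
    def test_dc_gain_unity(self):
        out = lowpass_filter(np.full(500, 3.7), rate=120.0)
        assert np.allclose(out, 3.7, atol=1e-9)

    def test_passband_and_stopband_amplitudes(self):
        n, rate = 2400, 120.0
        low = lowpass_filter(sine(1.0, rate, n), rate)
        core = slice(n // 4, 3 * n // 4)
        assert abs(np.max(np.abs(low[core])) - 1.0) < 0.01
        high = lowpass_filter(sine(60.0, rate, n), rate)
        assert np.max(np.abs(high[core])) < 0.01

    def test_zero_phase_peak_unmoved(self):
        n = 600
        x = np.exp(-0.5 * ((np.arange(n) - 300) / 25.0) ** 2)
        out = lowpass_filter(x, rate=120.0)
        assert int(np.argmax(out)) == 300

    def test_idempotent_on_band_limited_signal(self):
        x = sine(1.0, 120.0, 2400)
        once = lowpass_filter(x, 120.0)
        twice = lowpass_filter(once, 120.0)
        core = slice(600, 1800)
        ratio = np.max(np.abs(twice[core])) / np.max(np.abs(once[core]))
        assert abs(ratio - 1.0) < 0.01

    def test_too_short_series_rejected(self):
        with pytest.raises(SeriesTooShortError):
            lowpass_filter(np.zeros(20), rate=120.0)


class TestVirtualToe:
    def calib(self, hee, toe, mt, foot_length=0.25, radius=0.01):
        return StandingCalibration(hee=hee, toe=toe, mt=mt,
                                   foot_length=foot_length,
                                   marker_radius=radius)

    def test_direct_construction(self):
        c = self.calib([0, 0, 0.02], [0.2, 0, 0.02], [0.15, 0.02, 0.05])
        model = build_virtual_toe(c, radius_sign=1)
        assert np.allclose(model.vtoe_calibration, [0.26, 0, 0], atol=1e-12)

    def test_zero_radius_sign(self):
        c = self.calib([0, 0, 0.02], [0.2, 0, 0.02], [0.15, 0.02, 0.05])
        model = build_virtual_toe(c, radius_sign=0)
        assert np.allclose(model.vtoe_calibration, [0.25, 0, 0], atol=1e-12)

    def test_rotation_invariant_distance(self):
        th = np.deg2rad(30)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        pts = [R @ np.array(p) for p in
               ([0, 0, 0.02], [0.2, 0, 0.02], [0.15, 0.02, 0.05])]
        model = build_virtual_toe(self.calib(*pts), radius_sign=1)
        heel_floor = np.array([pts[0][0], pts[0][1], 0.0])
        assert np.linalg.norm(model.vtoe_calibration - heel_floor) \
            == pytest.approx(0.26, abs=1e-12)

    def test_coincident_projection_rejected(self):
        c = self.calib([0, 0, 0.02], [0, 0, 0.30], [0.1, 0.05, 0.05])
        with pytest.raises(DegenerateGeometryError):
            build_virtual_toe(c)

    def test_local_coordinates_reconstruct(self):
        c = self.calib([0.1, -0.05, 0.02], [0.32, -0.03, 0.025],
                       [0.26, 0.01, 0.06])
        model = build_virtual_toe(c)
        rec = model.reconstruct(c.triad)
        assert np.linalg.norm(rec - model.vtoe_calibration) <= 1e-12


class TestRigidTransform:
    TRIAD = np.array([[0.0, 0, 0], [0.2, 0, 0.02], [0.15, 0.03, 0.05]])

    def test_identity(self):
        R, t = rigid_transform(self.TRIAD, self.TRIAD)
        assert np.allclose(R, np.eye(3), atol=1e-12)
        assert np.allclose(t, 0, atol=1e-12)

    def test_pure_translation_recovered(self):
        shift = np.array([0.1, 0.0, 0.05])
        R, t = rigid_transform(self.TRIAD, self.TRIAD + shift)
        assert np.allclose(R, np.eye(3), atol=1e-12)
        assert np.allclose(t, shift, atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_transform_recovered(self, seed):
        rng = np.random.default_rng(seed)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(-np.pi, np.pi)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R_true = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
        t_true = rng.uniform(-1, 1, 3)
        triad = rng.uniform(-0.3, 0.3, (3, 3))
        if np.linalg.norm(np.cross(triad[1] - triad[0],
                                   triad[2] - triad[0])) < 1e-3:
            return
        R, t = rigid_transform(triad, triad @ R_true.T + t_true)
        assert np.allclose(R, R_true, atol=1e-9)
        assert np.allclose(t, t_true, atol=1e-9)

    def test_collinear_triad_rejected(self):
        bad = np.array([[0.0, 0, 0], [0.1, 0, 0], [0.2, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            rigid_transform(bad, bad)


class TestTracking:
    def windows(self, output):
        rate = output.bundle.trial.rate
        side = output.config.prosthetic_side
        return [(int(round(a * rate)), int(round(b * rate)))
                for a, b in output.truth.swing_windows(side)]

    def model(self, output):
        cfg = output.config
        calib = StandingCalibration.from_markers(
            output.bundle.standing, cfg.prosthetic_side, cfg.foot_length,
            cfg.marker_radius)
        return build_virtual_toe(calib, radius_sign=cfg.radius_sign)

    def test_noise_free_tracking_matches_truth(self, noise_free_output):
        model = self.model(noise_free_output)
        win = self.windows(noise_free_output)
        vt = track_virtual_toe(noise_free_output.bundle.trial, "right",
                               model, win)
        for i0, i1 in win:
            err = np.linalg.norm(
                vt[i0:i1 + 1] - noise_free_output.truth.vtoe[i0:i1 + 1],
                axis=1)
            assert np.max(err) <= 1e-9

    def test_calibration_pose_reproduces_calibration_point(
            self, noise_free_output):
        model = self.model(noise_free_output)
        standing = noise_free_output.bundle.standing
        vt = track_virtual_toe(standing, "right", model, [(0, 0)])
        assert np.linalg.norm(vt[0] - model.vtoe_calibration) <= 1e-12

    def test_tracking_commutes_with_global_rigid_motion(
            self, noise_free_output):
        model = self.model(noise_free_output)
        win = self.windows(noise_free_output)[:1]
        trial = noise_free_output.bundle.trial
        th = 0.3
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        t = np.array([0.5, -0.2, 0.1])
        moved = trial.copy()
        moved.positions = trial.positions @ R.T + t
        vt = track_virtual_toe(trial, "right", model, win)
        vt_moved = track_virtual_toe(moved, "right", model, win)
        i0, i1 = win[0]
        expected = vt[i0:i1 + 1] @ R.T + t
        assert np.max(np.linalg.norm(vt_moved[i0:i1 + 1] - expected,
                                     axis=1)) <= 1e-9

    def test_noisy_tracking_error_bounded(self, noise_free_output):
        """0.5 mm marker noise keeps 95% of vTOE errors within 2 mm."""
        model = self.model(noise_free_output)
        win = self.windows(noise_free_output)
        clean = noise_free_output.bundle.trial
        truth = noise_free_output.truth.vtoe
        errs = []
        rng = np.random.default_rng(42)
        for _ in range(100):
            noisy = clean.copy()
            noisy.positions = noisy.positions + rng.normal(
                0.0, 0.0005, noisy.positions.shape)
            vt = track_virtual_toe(noisy, "right", model, win)
            for i0, i1 in win:
                errs.extend(np.linalg.norm(vt[i0:i1 + 1] - truth[i0:i1 + 1],
                                           axis=1))
        assert np.percentile(errs, 95) <= 0.002


class TestGaps:
    def test_short_gap_interpolated_long_gap_kept(self):
        n = 60
        t = np.arange(n) / 120.0
        pos = np.stack([np.stack([t, t**2, np.sin(t)], axis=1)], axis=1)
        mset = MarkerTrajectorySet(120.0, ["M"], pos.copy())
        mset.positions[10:13, 0, :] = np.nan
        mset.positions[30:45, 0, :] = np.nan
        mset.gaps = ~np.isfinite(mset.positions).all(axis=2)
        out = interpolate_gaps(mset, max_gap=5)
        assert not out.gaps[10:13, 0].any()
        assert np.allclose(out.positions[10:13, 0], pos[10:13, 0], atol=1e-4)
        assert out.gaps[30:45, 0].all()
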