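"""Swing metrics: leg length, toe clearance, angles, sensitivities,
normalization, features, symmetry, compensations."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from proswing import metrics
from proswing.containers import PERCENT_GRID, Stride
from proswing.errors import ProswingError
from proswing.simulate import SimConfig, generate_trial

DIR = np.array([1.0, 0.0, 0.0])


class TestEllAndTc:
    def test_vertical_alignment_distance(self):
        hip = np.array([[0.0, 0.0, 0.9]])
        vtoe = np.array([[0.0, 0.0, 0.0]])
        assert metrics.compute_ell(hip, vtoe)[0] == pytest.approx(0.9)

    def test_straight_limb_matches_geometry(self, noise_free_output):
        """Fully extended pose: ELL equals the known segment chain length."""
        cfg = noise_free_output.config
        standing = noise_free_output.bundle.standing
        hip = standing.marker("R_HJC")
        from proswing.preprocess import StandingCalibration, build_virtual_toe
        calib = StandingCalibration.from_markers(standing, "right",
                                                 cfg.foot_length,
                                                 cfg.marker_radius)
        vtoe = build_virtual_toe(calib, cfg.radius_sign).vtoe_calibration
        expected = np.linalg.norm(hip[0] - vtoe)
        assert metrics.compute_ell(hip, vtoe[None, :])[0] \
            == pytest.approx(expected, abs=1e-12)

    def test_knee_flexion_shortens_ell(self):
        lt = ls = 0.43
        hip = np.array([0.0, 0.0, 1.0])
        out = []
        for beta in (0.0, 0.3, 0.6, 0.9):
            knee = hip + lt * np.array([0, 0, -1.0])
            ankle = knee + ls * np.array([np.sin(-beta), 0, -np.cos(-beta)])
            out.append(metrics.compute_ell(hip[None], ankle[None])[0])
        assert np.all(np.diff(out) < 0)

    def test_tc_preserves_negative_heights(self):
        vtoe = np.array([[0, 0, 0.0], [0, 0, -0.003]])
        tc = metrics.compute_tc(vtoe)
        assert tc[0] == 0.0
        assert tc[1] == pytest.approx(-0.003)

    def test_tc_matches_truth_trace(self, noise_free_output):
        tr = noise_free_output.truth
        assert np.allclose(metrics.compute_tc(tr.vtoe), tr.vtoe[:, 2],
                           atol=1e-12)


class TestJointAngles:
    def chain(self, alpha, beta, hip=(0.0, 0.0, 1.0), lt=0.4, ls=0.4):
        hip = np.array(hip)
        knee = hip + lt * np.array([np.sin(alpha), 0, -np.cos(alpha)])
        phi = alpha - beta
        ankle = knee + ls * np.array([np.sin(phi), 0, -np.cos(phi)])
        toe = ankle + 0.15 * np.array([np.cos(phi), 0, np.sin(phi)])
        return hip[None], knee[None], ankle[None], toe[None]

    @pytest.mark.parametrize("alpha,beta", [
        (0.0, 0.0), (0.3, 0.0), (0.2, np.pi / 2), (-0.25, 0.6)])
    def test_angles_recovered_from_marker_geometry(self, alpha, beta):
        a, b, g = metrics.compute_joint_angles(*self.chain(alpha, beta), DIR)
        assert a[0] == pytest.approx(alpha, abs=1e-12)
        assert b[0] == pytest.approx(beta, abs=1e-12)

    def test_rigid_foot_gives_zero_dorsiflexion(self):
        hip, knee, ankle, toe = self.chain(0.1, 0.4)
        offset = metrics.standing_foot_shank_offset(knee[0], ankle[0],
                                                    toe[0], DIR)
        _, _, g = metrics.compute_joint_angles(hip, knee, ankle, toe, DIR,
                                              standing_foot_offset=offset)
        assert g[0] == pytest.approx(0.0, abs=1e-12)

    def test_simulated_knee_angle_matches_integrator(self, noise_free_output):
        tr = noise_free_output.truth
        m = tr.markers
        _, beta, _ = metrics.compute_joint_angles(
            m.marker("R_HJC"), m.marker("R_KNE"), m.marker("R_ANK"),
            m.marker("R_TOE"), DIR)
        assert np.max(np.abs(beta - tr.beta["right"])) <= 1e-6


class TestTzs:
    def test_direct_substitution(self):
        hip_s, kne_s, ank_s = metrics.compute_tzs(0.05, 0.10, 0.25, 0.30)
        assert hip_s == pytest.approx(0.25)
        assert kne_s == pytest.approx(-0.20)
        assert ank_s == pytest.approx(0.05)

    def test_toe_below_hip_zero_hip_sensitivity(self):
        hip_s, _, _ = metrics.compute_tzs(0.3, 0.1, 0.2, 0.3)
        assert hip_s == 0.0

    def test_finite_difference_oracle_random_poses(self):
        """Each sensitivity equals a central difference of toe height
        under +-1e-6 rad rotation of the distal chain about the joint."""
        rng = np.random.default_rng(7)
        h = 1e-6
        worst = 0.0
        for _ in range(200):
            alpha = rng.uniform(-0.6, 0.6)
            beta = rng.uniform(-0.2, 1.2)
            gamma = rng.uniform(-0.4, 0.4)
            lt, ls, lf = rng.uniform(0.3, 0.5, 3)

            def toe_z(da=0.0, db=0.0, dg=0.0):
                a, b, g = alpha + da, beta + db, gamma + dg
                z_k = 1.0 - lt * np.cos(a)
                phi = a - b
                z_a = z_k - ls * np.cos(phi)
                return z_a + lf * np.sin(phi + g)

            def toe_x(da=0.0, db=0.0, dg=0.0):
                a, b, g = alpha + da, beta + db, gamma + dg
                phi = a - b
                return (lt * np.sin(a) + ls * np.sin(phi)
                        + lf * np.cos(phi + g))

            phi = alpha - beta
            x_hip = 0.0
            x_kne = lt * np.sin(alpha)
            x_ank = x_kne + ls * np.sin(phi)
            x_toe = toe_x()
            s_hip, s_kne, s_ank = metrics.compute_tzs(x_hip, x_kne, x_ank,
                                                      x_toe)
            fd_hip = (toe_z(da=h) - toe_z(da=-h)) / (2 * h)
            fd_kne = (toe_z(db=h) - toe_z(db=-h)) / (2 * h)
            fd_ank = (toe_z(dg=h) - toe_z(dg=-h)) / (2 * h)
            worst = max(worst, abs(s_hip - fd_hip), abs(s_kne - fd_kne),
                        abs(s_ank - fd_ank))
        assert worst <= 1e-6


class TestNormalization:
    def test_mid_swing_percentage(self):
        t = np.arange(100, 201) / 120.0
        traces = {"x": np.linspace(0, 1, t.size)}
        out = metrics.normalize_swing(t, traces, t[0], t[-1])
        assert np.allclose(out["x"], PERCENT_GRID / 100.0, atol=1e-12)
        msw_pct = 100 * (150 / 120.0 - t[0]) / (t[-1] - t[0])
        assert msw_pct == pytest.approx(50.0)

    def test_uniform_profile_roundtrip_identity(self):
        t = np.linspace(2.0, 3.0, 101)
        y = np.sin(np.linspace(0, 3, 101))
        out = metrics.normalize_swing(t, {"y": y}, 2.0, 3.0)
        assert np.allclose(out["y"], y, atol=1e-12)

    def test_degenerate_window_rejected(self):
        with pytest.raises(ProswingError):
            metrics.normalize_swing(np.linspace(0, 0.05, 5), {"y": np.zeros(5)},
                                    0.0, 0.05)


class TestFeatures:
    def profile(self, tc=None, ell=None, beta=None, msw=50.0):
        n = 101
        grid = PERCENT_GRID.astype(float)
        zeros = np.zeros(n)
        if tc is None:
            tc = 0.05 - 0.04 * np.exp(-0.5 * ((grid - 48) / 8) ** 2)
        if ell is None:
            ell = 0.9 + 0.0005 * grid
        if beta is None:
            beta = np.deg2rad(60) * np.sin(np.pi * grid / 100)
        from proswing.containers import SwingProfile
        return SwingProfile(
            stride=Stride("right", 0, 100), grid=grid, ell=ell, tc=tc,
            alpha=zeros, beta=beta, gamma=zeros, tzs_hip=zeros + 0.1,
            tzs_kne=zeros - 0.05, tzs_ank=zeros + 0.02, msw_pct=msw)

    def extract(self, profile):
        return metrics.extract_features(profile, 0, "A", 0.0, sts_pct=50.0)

    def test_tc_minimum_timing_and_sign_convention(self):
        f = self.extract(self.profile())
        assert f.tc_min_t_pct == 48.0
        assert f.tc_min_t_rel_msw_pct == pytest.approx(-2.0)

    def test_monotone_ell_puts_max_at_end(self):
        f = self.extract(self.profile())
        assert f.ell_max_t_pct == 100.0

    def test_ke_max_searched_after_peak_flexion(self):
        grid = PERCENT_GRID.astype(float)
        # extended at onset, peak flexion mid-swing, re-extension at 90%
        beta = np.deg2rad(55) * np.sin(np.pi * np.clip(grid / 90, 0, 1))
        f = self.extract(self.profile(beta=beta))
        assert f.ke_max_t_pct == 90.0

    def test_argmin_tie_takes_earlier_frame(self):
        tc = np.full(101, 0.05)
        tc[[40, 60]] = 0.01
        f = self.extract(self.profile(tc=tc))
        assert f.tc_min_t_pct == 40.0

    def test_flagged_stride_refused(self):
        p = self.profile()
        p.stride.flags.append("uncertain_contact")
        with pytest.raises(ProswingError):
            self.extract(p)


class TestSymmetry:
    def test_equal_durations_give_fifty_percent(self):
        assert metrics.swing_time_symmetry(0.5, 0.5) == 50.0

    def test_longer_prosthetic_swing_above_fifty(self):
        assert metrics.swing_time_symmetry(0.6, 0.4) == pytest.approx(60.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 10.0), st.floats(0.01, 10.0))
    def test_complement_identity(self, a, b):
        total = (metrics.swing_time_symmetry(a, b)
                 + metrics.swing_time_symmetry(b, a))
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError):
            metrics.swing_time_symmetry(0.0, 0.5)


class TestCompensations:
    def test_constant_velocity_walking_speed(self):
        t = np.arange(600) / 120.0
        midhip = np.stack([1.2 * t, np.zeros_like(t), np.full_like(t, 0.95)],
                          axis=1)
        assert metrics.walking_speed(midhip, DIR, 120.0) \
            == pytest.approx(1.2, abs=1e-9)

    def test_zero_circumduction_lateral_distance(self):
        out = generate_trial(dataclasses.replace(SimConfig(), n_strides=3))
        f = out.truth.features[1]
        assert f.lateral_hip_ankle_at_tc_min_m == pytest.approx(0.0, abs=1e-9)

    def test_hip_hike_raises_hip_at_tc_min(self):
        base_cfg = dataclasses.replace(SimConfig(), n_strides=3)
        hike_cfg = dataclasses.replace(base_cfg, hip_hike_amplitude=0.02)
        base = generate_trial(base_cfg).truth.features[1]
        hike = generate_trial(hike_cfg).truth.features[1]
        diff = hike.hip_height_at_tc_min_m - base.hip_height_at_tc_min_m
        assert diff == pytest.approx(0.02, abs=0.002)


class TestGeometricInvariants:
    def test_ell_bounded_by_segment_chain(self, noise_free_output):
        cfg = noise_free_output.config
        tr = noise_free_output.truth
        hip = tr.markers.marker("R_HJC")
        ell = metrics.compute_ell(hip, tr.vtoe)
        from proswing.simulate import _vtoe_local
        bound = cfg.thigh_length + cfg.shank_length \
            + np.linalg.norm(_vtoe_local(cfg))
        assert np.all(ell <= bound + 1e-9)

    def test_tzs_hip_positive_when_toe_anterior(self, noise_free_output):
        tr = noise_free_output.truth
        hip = tr.markers.marker("R_HJC")
        anterior = tr.vtoe[:, 0] > hip[:, 0]
        s_hip = tr.vtoe[:, 0] - hip[:, 0]
        assert np.all(s_hip[anterior] > 0)
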