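"""Misfit metric identities, data misfit against the forward solver, and
anomaly localization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brainwave.evaluate import (
    anomaly_detection_report,
    data_misfit,
    model_misfit,
    model_misfit_channels,
    phantom_from_grids,
)
from brainwave.phantom import AnomalySpec
from brainwave.solver import solve_scattered_field


class TestModelMisfit:
    def test_perfect_reconstruction_is_zero(self):
        rng = np.random.default_rng(0)
        eps = rng.uniform(1, 90, size=(6, 6, 6))
        sig = rng.uniform(0.01, 2, size=(6, 6, 6))
        assert model_misfit((eps, sig), (eps, sig)) == 0.0

    def test_zero_reconstruction_is_100(self):
        rng = np.random.default_rng(1)
        eps = rng.uniform(1, 90, size=(6, 6, 6))
        sig = rng.uniform(0.01, 2, size=(6, 6, 6))
        z = np.zeros_like(eps)
        assert model_misfit((z, z), (eps, sig)) == pytest.approx(100.0)

    def test_two_voxel_hand_example(self):
        # truth (3, 4): all-zero recon -> 100%; recon (3, 0) -> 80%
        truth = np.array([3.0, 4.0])
        assert model_misfit(np.zeros(2), truth) == pytest.approx(100.0)
        assert model_misfit(np.array([3.0, 0.0]), truth) == pytest.approx(80.0)

    def test_zero_norm_truth_rejected(self):
        with pytest.raises(ValueError):
            model_misfit(np.ones(4), np.zeros(4))
        with pytest.raises(ValueError):
            model_misfit((np.ones(4), np.ones(4)), (np.ones(4), np.zeros(4)))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(2)
        eps_t = rng.uniform(1, 90, size=(4, 4, 4))
        sig_t = rng.uniform(0.01, 2, size=(4, 4, 4))
        eps_r = eps_t + rng.normal(size=eps_t.shape)
        sig_r = sig_t + 0.1 * rng.normal(size=sig_t.shape)
        m1 = model_misfit((eps_r, sig_r), (eps_t, sig_t))
        m2 = model_misfit((c * eps_r, c * sig_r), (c * eps_t, c * sig_t))
        assert m2 == pytest.approx(m1, rel=1e-9)

    def test_channels_weighted_equally(self):
        # an error of X% in one channel alone yields X/sqrt(2) combined
        rng = np.random.default_rng(3)
        eps = rng.uniform(1, 90, size=(5, 5, 5))
        sig = rng.uniform(0.01, 2, size=(5, 5, 5))
        bad_eps = eps * 1.10
        combined = model_misfit((bad_eps, sig), (eps, sig))
        e_only, s_only = model_misfit_channels((bad_eps, sig), (eps, sig))
        assert s_only == 0.0
        assert combined == pytest.approx(e_only / np.sqrt(2), rel=1e-9)


class TestDataMisfit:
    def test_perfect_reconstruction_near_zero(self, array, sphere_phantom):
        p = sphere_phantom(12, eps=20.0, sigma=0.5, radius=0.05)
        rec = solve_scattered_field(p, array, method="born")
        dm = data_misfit((p.eps_grid, p.sigma_grid), rec, array, p.domain_side_m)
        assert dm < 0.1

    def test_air_reconstruction_is_100(self, array, sphere_phantom):
        p = sphere_phantom(12, eps=20.0, sigma=0.5, radius=0.05)
        rec = solve_scattered_field(p, array, method="born")
        air = (np.ones_like(p.eps_grid), np.zeros_like(p.sigma_grid))
        assert data_misfit(air, rec, array, p.domain_side_m) == pytest.approx(100.0)

    def test_phase_rotation_invariance(self, array, sphere_phantom):
        # relative L2 between field sets is unchanged by a global phase
        # applied to both
        p = sphere_phantom(12, eps=20.0, sigma=0.5, radius=0.05)
        rec = solve_scattered_field(p, array, method="born")
        q = sphere_phantom(12, eps=15.0, sigma=0.3, radius=0.05)
        rec_q = solve_scattered_field(q, array, method="born")
        base = np.linalg.norm(rec_q.e_scat - rec.e_scat) / np.linalg.norm(rec.e_scat)
        phase = np.exp(1j * 0.7)
        rot = np.linalg.norm(phase * rec_q.e_scat - phase * rec.e_scat) / np.linalg.norm(
            phase * rec.e_scat
        )
        assert rot == pytest.approx(base, rel=1e-12)

    def test_anti_inverse_crime_grid(self, array, sphere_phantom):
        p = sphere_phantom(12, eps=5.0, sigma=0.1, radius=0.05)
        rec = solve_scattered_field(p, array, method="born")
        dm = data_misfit((p.eps_grid, p.sigma_grid), rec, array, p.domain_side_m,
                         eval_grid_factor=1.5)
        assert np.isfinite(dm) and dm > 0  # finer grid breaks exact agreement


class TestAnomalyDetection:
    def test_exact_reconstruction_localizes(self, base_phantom_32):
        from brainwave.phantom import insert_anomaly

        a = AnomalySpec(center_m=(0.01, 0.0, -0.005), radius_m=0.01,
                        eps_r=150.0, sigma=1.73)
        q = insert_anomaly(base_phantom_32, a)
        rep = anomaly_detection_report(
            (q.eps_grid, q.sigma_grid), (q.eps_grid, q.sigma_grid), a,
            q.domain_side_m, eps_threshold=100.0,
        )
        assert rep["detected"]
        assert rep["centroid_error_mm"] <= 1e3 * q.voxel_size_m
        assert rep["radius_error_mm"] <= 1e3 * q.voxel_size_m

    def test_uniform_brain_not_detected(self, base_phantom_32):
        p = base_phantom_32
        a = AnomalySpec(center_m=(0, 0, 0), radius_m=0.01, eps_r=150.0, sigma=1.73)
        rep = anomaly_detection_report(
            (p.eps_grid, p.sigma_grid), (p.eps_grid, p.sigma_grid), a,
            p.domain_side_m, eps_threshold=100.0,
        )
        assert rep == {"detected": False}

    def test_noisy_reconstruction_centroid_within_two_voxels(self, base_phantom_32):
        from brainwave.phantom import insert_anomaly

        a = AnomalySpec(center_m=(0.0, 0.01, 0.0), radius_m=0.01,
                        eps_r=150.0, sigma=1.73)
        q = insert_anomaly(base_phantom_32, a)
        rng = np.random.default_rng(4)
        noisy = (
            q.eps_grid + 3.0 * rng.normal(size=q.eps_grid.shape),
            q.sigma_grid + 0.05 * rng.normal(size=q.sigma_grid.shape),
        )
        rep = anomaly_detection_report(noisy, (q.eps_grid, q.sigma_grid), a,
                                       q.domain_side_m, eps_threshold=100.0)
        assert rep["detected"]
        assert rep["centroid_error_mm"] <= 2e3 * q.voxel_size_m


def test_phantom_from_grids_round_trip():
    rng = np.random.default_rng(5)
    eps = rng.uniform(1, 50, size=(10, 10, 10))
    sig = rng.uniform(0, 1, size=(10, 10, 10))
    p = phantom_from_grids(eps, sig, 0.24)
    assert p.voxel_size_m == pytest.approx(0.024)
    np.testing.assert_array_equal(p.eps_grid, eps)
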