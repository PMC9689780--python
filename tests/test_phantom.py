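"""Phantom construction, strategy transformations and the sampling menus."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brainwave.phantom import (
    ANOMALY_EPS_R,
    ANOMALY_RADII_M,
    ANOMALY_SIGMA,
    SCALE_FACTORS,
    AnomalySpec,
    build_base_phantom,
    deform_tissue_boundaries,
    insert_anomaly,
    sample_phantom,
    sample_strategy_params,
    scale_phantom,
)
from brainwave.tissues import default_tissue_table


class TestBasePhantom:
    def test_sixteen_nonempty_tissues_plus_air(self, base_phantom_64):
        labels = np.unique(base_phantom_64.label_grid)
        assert set(labels) == set(range(17))  # air + 16 tissues

    def test_deterministic(self, base_phantom_64):
        again = build_base_phantom(grid_n=64, seed=7)
        np.testing.assert_array_equal(base_phantom_64.label_grid, again.label_grid)
        np.testing.assert_array_equal(base_phantom_64.eps_grid, again.eps_grid)

    def test_corner_is_air(self, base_phantom_64):
        assert base_phantom_64.eps_grid[0, 0, 0] == 1.0
        assert base_phantom_64.sigma_grid[0, 0, 0] == 0.0

    def test_voxel_size_consistent(self, base_phantom_64):
        p = base_phantom_64
        assert p.voxel_size_m * p.grid_n == pytest.approx(p.domain_side_m, rel=1e-12)

    def test_too_coarse_grid_names_empty_tissue(self):
        with pytest.raises(ValueError, match="too coarse"):
            build_base_phantom(grid_n=16, seed=7)

    def test_grid_below_16_rejected(self):
        with pytest.raises(ValueError):
            build_base_phantom(grid_n=8, seed=7)

    def test_physical_bounds(self, base_phantom_64):
        assert base_phantom_64.eps_grid.min() >= 1.0
        assert base_phantom_64.sigma_grid.min() >= 0.0

    def test_nesting_strict(self, base_phantom_32):
        # geometric nesting: every surface strictly inside its outer neighbor
        s = base_phantom_32.surfaces
        assert np.all(np.diff(s, axis=0) < 0)
        # voxel-level: the region with label >= i+1 sits inside the filled
        # region with label >= i (radial construction guarantees it)
        lab = base_phantom_32.label_grid
        for i in range(1, 16):
            assert (lab >= i + 1).sum() < (lab >= i).sum()


class TestScale:
    def test_identity(self, base_phantom_32):
        q = scale_phantom(base_phantom_32, 1.0)
        np.testing.assert_array_equal(q.label_grid, base_phantom_32.label_grid)
        np.testing.assert_array_equal(q.eps_grid, base_phantom_32.eps_grid)

    def test_property_linearity(self, base_phantom_32):
        q = scale_phantom(base_phantom_32, 0.8)
        # muscle (tissue index 2) has eps_r 58 -> 46.4
        assert q.tissue_eps[2] == pytest.approx(0.8 * 58.0)
        assert q.tissue_sigma[2] == pytest.approx(0.8 * 0.77)

    def test_eps_floor_at_one(self, base_phantom_32):
        q = scale_phantom(base_phantom_32, 0.1)
        assert q.tissue_eps.min() >= 1.0

    def test_bounding_box_scales(self, base_phantom_64):
        def extent(p):
            idx = np.argwhere(p.label_grid > 0)
            return (idx.max(axis=0) - idx.min(axis=0) + 1).max() * p.voxel_size_m

        e1 = extent(base_phantom_64)
        e2 = extent(scale_phantom(base_phantom_64, 1.2))
        assert abs(e2 - 1.2 * e1) <= 2 * base_phantom_64.voxel_size_m

    def test_round_trip_conservation(self, base_phantom_32):
        # scale up then back down: label grids agree except within ~2 voxels
        # of a tissue boundary
        from scipy.ndimage import binary_dilation

        p = base_phantom_32
        q = scale_phantom(scale_phantom(p, 1.2), 1.0 / 1.2)
        changed = q.label_grid != p.label_grid
        # boundary voxels: where the label differs from any 6-neighbor
        interior = np.ones_like(p.label_grid, dtype=bool)
        lab = p.label_grid
        boundary = np.zeros_like(interior)
        for ax in range(3):
            d = np.diff(lab, axis=ax) != 0
            sl = [slice(None)] * 3
            sl[ax] = slice(0, -1)
            boundary[tuple(sl)] |= d
            sl[ax] = slice(1, None)
            boundary[tuple(sl)] |= d
        near_boundary = binary_dilation(boundary, iterations=2)
        assert np.all(near_boundary[changed])

    def test_exceeding_doi_rejected(self, base_phantom_32):
        with pytest.raises(ValueError, match="exceeds"):
            scale_phantom(base_phantom_32, 2.0)

    def test_nonpositive_factor_rejected(self, base_phantom_32):
        with pytest.raises(ValueError):
            scale_phantom(base_phantom_32, 0.0)


class TestDeform:
    def test_zero_sigma_is_identity(self, base_phantom_32):
        q = deform_tissue_boundaries(base_phantom_32, 0.0, seed=1)
        np.testing.assert_array_equal(q.label_grid, base_phantom_32.label_grid)

    def test_seeds_differ(self, base_phantom_32):
        a = deform_tissue_boundaries(base_phantom_32, 0.002, seed=1)
        b = deform_tissue_boundaries(base_phantom_32, 0.002, seed=2)
        assert not np.array_equal(a.label_grid, b.label_grid)

    def test_deterministic(self, base_phantom_32):
        a = deform_tissue_boundaries(base_phantom_32, 0.002, seed=5)
        b = deform_tissue_boundaries(base_phantom_32, 0.002, seed=5)
        np.testing.assert_array_equal(a.label_grid, b.label_grid)

    def test_changed_fraction_bounded(self, base_phantom_64):
        q = deform_tissue_boundaries(base_phantom_64, 0.002, seed=3)
        frac = np.mean(q.label_grid != base_phantom_64.label_grid)
        assert 0.0 < frac < 0.2

    def test_nesting_preserved(self, base_phantom_32):
        q = deform_tissue_boundaries(base_phantom_32, 0.003, seed=11)
        assert np.all(np.diff(q.surfaces, axis=0) <= 0)

    def test_negative_sigma_rejected(self, base_phantom_32):
        with pytest.raises(ValueError):
            deform_tissue_boundaries(base_phantom_32, -1e-3, seed=0)


class TestAnomaly:
    def test_voxel_count_matches_sphere_volume(self, base_phantom_64):
        p = base_phantom_64  # voxel 3.75 mm
        a = AnomalySpec(center_m=(0, 0, 0), radius_m=0.007, eps_r=120.0, sigma=1.384)
        q = insert_anomaly(p, a)
        count = int((q.label_grid == q.anomaly_label).sum())
        analytic = (4.0 / 3.0) * np.pi * a.radius_m**3 / p.voxel_size_m**3
        assert abs(count - analytic) <= 0.3 * analytic

    def test_subvoxel_sphere_claims_center_voxel(self, base_phantom_64):
        a = AnomalySpec(center_m=(0.001, 0.001, 0.001), radius_m=0.0005,
                        eps_r=90.0, sigma=1.038)
        q = insert_anomaly(base_phantom_64, a)
        assert (q.label_grid == q.anomaly_label).sum() >= 1

    def test_menu_maximum_eps(self, base_phantom_64):
        a = AnomalySpec(center_m=(0, 0, 0), radius_m=0.01, eps_r=150.0, sigma=1.73)
        q = insert_anomaly(base_phantom_64, a)
        assert q.eps_grid.max() == 150.0
        mask = q.label_grid == q.anomaly_label
        assert np.all(q.sigma_grid[mask] == 1.73)

    def test_sphere_in_air_rejected(self, base_phantom_64):
        a = AnomalySpec(center_m=(0.11, 0.11, 0.11), radius_m=0.004,
                        eps_r=90.0, sigma=1.038)
        with pytest.raises(ValueError, match="air"):
            insert_anomaly(base_phantom_64, a)

    def test_other_voxels_untouched(self, base_phantom_64):
        a = AnomalySpec(center_m=(0, 0, 0), radius_m=0.007, eps_r=120.0, sigma=1.384)
        q = insert_anomaly(base_phantom_64, a)
        mask = q.label_grid == q.anomaly_label
        np.testing.assert_array_equal(q.label_grid[~mask], base_phantom_64.label_grid[~mask])
        np.testing.assert_array_equal(q.eps_grid[~mask], base_phantom_64.eps_grid[~mask])


class TestStrategy:
    def test_factor_frequencies(self):
        draws = [sample_strategy_params(s, with_anomaly=False).factor for s in range(10_000)]
        for f in SCALE_FACTORS:
            freq = np.mean(np.isclose(draws, f))
            assert freq == pytest.approx(0.2, abs=0.02)

    def test_no_anomaly_flag(self):
        assert sample_strategy_params(3, with_anomaly=False).anomaly is None

    def test_menus_closed(self):
        for s in range(2000):
            p = sample_strategy_params(s, with_anomaly=True)
            assert p.factor in SCALE_FACTORS
            assert p.anomaly.radius_m in ANOMALY_RADII_M
            assert p.anomaly.eps_r in ANOMALY_EPS_R
            assert p.anomaly.sigma in ANOMALY_SIGMA
            assert sorted(p.order) == list(range(16))

    def test_deterministic(self):
        a = sample_strategy_params(77)
        b = sample_strategy_params(77)
        assert a.factor == b.factor
        assert a.anomaly.center_m == b.anomaly.center_m
        np.testing.assert_array_equal(a.order, b.order)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_anomaly_sphere_inside_deep_brain(self, seed):
        p = sample_strategy_params(seed, with_anomaly=True)
        c = np.linalg.norm(p.anomaly.center_m)
        assert c + 1e-12 <= 0.03 * p.factor
        assert p.anomaly.radius_m <= 0.010

    def test_sampled_phantom_chain(self, base_phantom_32):
        q, params = sample_phantom(base_phantom_32, 123, with_anomaly=True)
        assert q.provenance["scale_factor"] == params.factor
        assert q.anomalies and q.anomalies[0].radius_m in ANOMALY_RADII_M
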