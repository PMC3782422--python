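"""Geometric measurement operators: radii, length, angle, aperture, ring,
vesicle metrics."""

import dataclasses

import numpy as np
import pytest

import tubetomo as tt
from tubetomo.geometry import (aperture_diameter, detect_ring, exit_angle,
                               fit_hollow_cylinder, measure_tube_length,
                               percent_reduction, radial_profile, tube_axis,
                               vesicle_area_volume)
from tubetomo.phantoms import vesicle_enclosed_mask
from tubetomo.align import rotate_shift

CLEARANCE = 33.3 + 2.5 + 1.5    # outer capsid bound + smoothing margin, nm


class TestRadialProfile:
    def test_solid_cylinder_profile_is_flat_then_drops(self):
        n = 48
        ax = np.arange(n) - n // 2
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        solid = (np.sqrt(X**2 + Y**2) < 10).astype(np.float32)
        vol = tt.VoxelVolume(solid, 1.0)
        radii, prof = radial_profile(vol, "z")
        inside = radii < 8
        assert np.allclose(prof[inside], 1.0, atol=0.05)
        assert prof[radii > 12].max() < 0.05

    def test_hollow_cylinder_peak_inside_wall(self, small_tube_volume):
        radii, prof = radial_profile(small_tube_volume, "z", (12, 28))
        peak_r = radii[np.argmax(prof)]
        assert 2.25 < peak_r < 7.0

    def test_rotated_tube_profile_matches_upright(self, small_tube_volume):
        rot = rotate_shift(small_tube_volume, (0.0, 90.0, 0.0))
        r0, p0 = radial_profile(small_tube_volume, "z", (12, 28))
        r1, p1 = radial_profile(rot, "x", (12, 28))
        sel = r0 < 12
        assert np.allclose(p0[sel], p1[sel], atol=0.05 * p0.max())

    def test_empty_range_rejected(self, small_tube_volume):
        with pytest.raises(ValueError):
            radial_profile(small_tube_volume, "z", (20, 20))


class TestFitHollowCylinder:
    def test_analytic_box_profile_recovers_exact_radii(self):
        radii = np.arange(0, 20, 0.5)
        prof = ((radii >= 2.25) & (radii <= 7.0)).astype(float)
        fit = fit_hollow_cylinder(radii, prof)
        assert fit.r1 == pytest.approx(2.25, abs=0.3)
        assert fit.r2 == pytest.approx(7.0, abs=0.3)
        assert fit.r == pytest.approx((fit.r1 + fit.r2) / 2)

    def test_recovers_generating_radii_across_random_pairs(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            r1 = float(rng.uniform(1.5, 3.5))
            wall = float(rng.uniform(2.0, 5.0))   # >= ~2 voxels
            r2 = r1 + wall
            spec = tt.canonical_tube_spec(length=30.0)
            spec = dataclasses.replace(spec, tube=dataclasses.replace(
                spec.tube, inner_diameter=2 * r1, outer_diameter=2 * r2))
            vol = tt.rasterize_phantom(spec, 64)
            n = vol.data.shape[2]
            radii, prof = radial_profile(vol, "z", (n // 2 - 8, n // 2 + 8))
            fit = fit_hollow_cylinder(radii, prof)
            assert fit.r1 == pytest.approx(r1, abs=vol.voxel_size)
            assert fit.r2 == pytest.approx(r2, abs=vol.voxel_size)

    def test_monotone_profile_rejected(self):
        radii = np.arange(10.0)
        with pytest.raises(ValueError):
            fit_hollow_cylinder(radii, np.linspace(1, 0, 10))


class TestTubeLength:
    def test_free_tube_length_within_one_voxel(self):
        vol = tt.rasterize_phantom(tt.canonical_tube_spec(length=50.0), 96)
        L = measure_tube_length(vol)
        assert L == pytest.approx(50.0, abs=2 * vol.voxel_size)

    def test_capsid_tube_measured_from_surface(self):
        spec = tt.canonical_capsid_spec(tube_length=40.0)
        vol = tt.rasterize_phantom(spec, 192)
        L = measure_tube_length(vol, capsid_surface_radius=33.3,
                                clearance_radius=CLEARANCE)
        assert L == pytest.approx(40.0, abs=1.5)

    def test_no_tube_raises(self):
        spec = tt.canonical_capsid_spec(tube=False)
        vol = tt.rasterize_phantom(spec, 112)
        with pytest.raises(ValueError):
            measure_tube_length(vol, capsid_surface_radius=33.3,
                                clearance_radius=45.0)


class TestTubeAxisAndAngle:
    def test_zero_deflection_axis_error_below_2_degrees(self):
        spec = tt.canonical_capsid_spec(deflection_deg=0.0, tube_length=30.0)
        vol = tt.rasterize_phantom(spec, 176)
        X, Y, Z = vol.physical_coords()
        m = (vol.data > 0.3) & (np.sqrt(X**2 + Y**2 + Z**2) > CLEARANCE)
        ax = tube_axis(vol, mask=m)
        assert exit_angle(ax, [0, 0, 1]) < 2.0

    def test_20_degree_deflection_recovered(self):
        spec = tt.canonical_capsid_spec(deflection_deg=20.0, tube_length=40.0)
        vol = tt.rasterize_phantom(spec, 176)
        X, Y, Z = vol.physical_coords()
        m = (vol.data > 0.3) & (np.sqrt(X**2 + Y**2 + Z**2) > CLEARANCE)
        ax = tube_axis(vol, mask=m)
        assert exit_angle(ax, [0, 0, 1]) == pytest.approx(20.0, abs=2.0)

    def test_angle_of_axis_with_itself_is_zero(self):
        u = np.array([0.3, -0.5, 0.81])
        assert exit_angle(u, u) == 0.0

    def test_angle_folded_to_90(self):
        assert exit_angle([0, 0, 1], [0, 0, -1]) == pytest.approx(0.0)
        assert exit_angle([1, 0, 0], [0, 0, 1]) == pytest.approx(90.0)

    def test_spherical_segment_rejected(self):
        n = 48
        ax = np.arange(n) - n // 2
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        ball = (np.sqrt(X**2 + Y**2 + Z**2) < 10).astype(np.float32)
        with pytest.raises(ValueError):
            tube_axis(tt.VoxelVolume(ball, 1.0), mask=ball > 0)


@pytest.fixture(scope="module")
def decapped():
    return tt.rasterize_phantom(
        tt.canonical_capsid_spec(tube=False, decapped=True), 96)


class TestAperture:
    def test_intact_vertex_reports_zero(self):
        vol = tt.rasterize_phantom(
            tt.canonical_capsid_spec(tube=False, decapped=False), 96)
        assert aperture_diameter(vol, [0, 0, 1]) == 0.0

    def test_15_nm_aperture_recovered(self, decapped):
        d = aperture_diameter(decapped, [0, 0, 1])
        assert d == pytest.approx(15.0, abs=1.0)

    def test_estimate_invariant_under_rotation(self, decapped):
        d0 = aperture_diameter(decapped, [0, 0, 1])
        rot = rotate_shift(decapped, (0.0, 30.0, 0.0))
        u = np.array([np.sin(np.deg2rad(30)), 0, np.cos(np.deg2rad(30))])
        d1 = aperture_diameter(rot, u)
        assert d1 == pytest.approx(d0, abs=decapped.voxel_size)


class TestRing:
    def test_ringless_tube_detects_none(self):
        vol = tt.rasterize_phantom(tt.canonical_tube_spec(length=40.0), 96)
        assert detect_ring(vol) is None

    def test_18_nm_ring_recovered_near_generator_position(self):
        spec = tt.canonical_tube_spec(length=40.0, ring=True)
        vol = tt.rasterize_phantom(spec, 96)
        hit = detect_ring(vol)
        assert hit is not None
        assert hit["diameter"] == pytest.approx(18.0, abs=vol.voxel_size)
        # generator places the ring 2 nm below the tube tip
        expected_z = spec.tube.length / 2.0 - 2.0
        assert hit["z"] == pytest.approx(expected_z, abs=2 * vol.voxel_size)


class TestVesicleMetrics:
    def test_digitized_sphere_matches_analytic(self):
        n = 64
        ax = np.arange(n) - n // 2
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        ball = ((X**2 + Y**2 + Z**2) <= 20**2).astype(np.float32)
        vm = vesicle_area_volume(tt.VoxelVolume(ball, 1.0))
        assert vm.volume == pytest.approx(4 / 3 * np.pi * 20**3, rel=0.01)
        assert vm.area == pytest.approx(4 * np.pi * 20**2, rel=0.03)

    def test_identical_masks_give_zero_reduction(self):
        n = 48
        ax = np.arange(n) - n // 2
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        ball = tt.VoxelVolume(((X**2 + Y**2 + Z**2) <= 12**2)
                              .astype(np.float32), 1.0)
        red = percent_reduction(vesicle_area_volume(ball),
                                vesicle_area_volume(ball))
        assert red["area_pct"] == 0.0 and red["volume_pct"] == 0.0

    def test_map_pin_collapse_shrinks_volume_more_than_area(self):
        before = vesicle_enclosed_mask(
            tt.canonical_capsid_spec(tube=False, vesicle="icosahedral"), 96)
        after = vesicle_enclosed_mask(
            tt.canonical_capsid_spec(tube=False, vesicle="map_pin"), 96)
        red = percent_reduction(vesicle_area_volume(before),
                                vesicle_area_volume(after))
        assert red["area_pct"] > 0
        assert red["volume_pct"] > red["area_pct"]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            vesicle_area_volume(tt.VoxelVolume(np.zeros((16, 16, 16),
                                                        dtype=np.float32)))

    def test_open_mask_rejected(self):
        m = np.ones((16, 16, 16), dtype=np.float32)
        with pytest.raises(ValueError):
            vesicle_area_volume(tt.VoxelVolume(m))
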