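"""Rotations, angular grids, constrained cc, alignment, averaging, subboxing."""

import numpy as np
import pytest

import tubetomo as tt
from tubetomo.align import (AlignmentResult, SearchSchedule, angular_grid,
                            align_particle, average_wedge_compensated,
                            compose_euler, constrained_cc, invert_euler,
                            iterative_refine, rotate_shift,
                            rotation_distance_deg, subbox)
from tubetomo.tomosim import TiltGeometry, make_wedge_mask


class TestRotateShift:
    def test_identity_is_exact(self, small_tube_volume):
        out = rotate_shift(small_tube_volume, (0.0, 0.0, 0.0))
        assert np.allclose(out.data, small_tube_volume.data, atol=1e-6)

    def test_rotation_roundtrip(self, structured_tube_volume):
        e = (25.0, 40.0, -15.0)
        out = rotate_shift(rotate_shift(structured_tube_volume, e),
                           invert_euler(e))
        cc = np.corrcoef(out.data.ravel(),
                         structured_tube_volume.data.ravel())[0, 1]
        assert cc > 0.99

    def test_90_degree_rotation_permutes_voxels(self):
        # box phantom offset from center; 90 deg about y maps x->-z, z->x
        n = 16
        data = np.zeros((n, n, n), dtype=np.float32)
        data[10:13, 7:10, 8:11] = 1.0
        vol = tt.VoxelVolume(data, 1.0)
        out = rotate_shift(vol, (0.0, 90.0, 0.0))
        # exact permutation oracle: index arithmetic about center n//2
        expected = np.zeros_like(data)
        c = n // 2
        idx = np.argwhere(data > 0)
        for x, y, z in idx:
            xr = c + (z - c)
            zr = c - (x - c)
            expected[xr, y, zr] = 1.0
        assert np.allclose(out.data, expected, atol=1e-5)

    def test_pure_integer_shift_is_exact(self, structured_tube_volume):
        out = rotate_shift(structured_tube_volume, (0.0, 0.0, 0.0),
                           (2.0, -3.0, 1.0))
        ref = np.roll(structured_tube_volume.data, (2, -3, 1), axis=(0, 1, 2))
        # compare interior (roll wraps, rotate_shift zero-fills)
        sl = slice(4, -4)
        assert np.allclose(out.data[sl, sl, sl], ref[sl, sl, sl], atol=1e-5)


class TestEulerAlgebra:
    def test_compose_then_invert_is_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            e = tuple(rng.uniform(-180, 180, 3))
            d = rotation_distance_deg(compose_euler(e, invert_euler(e)),
                                      (0.0, 0.0, 0.0))
            assert d < 1e-6

    def test_composition_matches_matrix_product(self):
        from tubetomo.align import euler_to_matrix
        a, b = (10.0, 20.0, 30.0), (-40.0, 55.0, 5.0)
        m = euler_to_matrix(compose_euler(a, b))
        assert np.allclose(m, euler_to_matrix(a) @ euler_to_matrix(b))


class TestAngularGrid:
    def test_zero_cone_full_azimuth_90_sampling(self):
        grid = angular_grid(90.0, cone_aperture=0.0, azimuth_range=360.0)
        assert len(grid) == 4

    def test_contains_center(self):
        center = (33.0, 21.0, -7.0)
        grid = angular_grid(15.0, center, cone_aperture=40.0)
        dists = [rotation_distance_deg(g, center) for g in grid]
        assert min(dists) < 1e-6

    def test_halving_sampling_increases_direction_density(self):
        coarse = angular_grid(20.0, cone_aperture=60.0, azimuth_range=0.0)
        fine = angular_grid(10.0, cone_aperture=60.0, azimuth_range=0.0)
        # direction count scales roughly with 1/sampling^2 within the cone
        assert len(fine) >= 3 * len(coarse)


class TestConstrainedCC:
    def test_self_correlation_is_one(self, structured_tube_volume):
        assert constrained_cc(structured_tube_volume,
                              structured_tube_volume) == pytest.approx(
                                  1.0, abs=1e-4)

    def test_negated_volume_gives_minus_one(self, structured_tube_volume):
        neg = tt.VoxelVolume(-structured_tube_volume.data,
                             structured_tube_volume.voxel_size)
        assert constrained_cc(structured_tube_volume,
                              neg) == pytest.approx(-1.0, abs=1e-4)

    def test_independent_noise_is_near_zero(self):
        rng = np.random.default_rng(1)
        n = 32
        a = tt.VoxelVolume(rng.normal(size=(n, n, n)).astype(np.float32))
        b = tt.VoxelVolume(rng.normal(size=(n, n, n)).astype(np.float32))
        cc = constrained_cc(a, b)
        assert abs(cc) < 3.0 / np.sqrt(n**3)

    def test_symmetric_in_arguments(self, structured_tube_volume,
                                    small_tube_volume, coarse_geometry):
        w = make_wedge_mask(structured_tube_volume.data.shape,
                            coarse_geometry).mask
        c1 = constrained_cc(structured_tube_volume, small_tube_volume, w, None)
        c2 = constrained_cc(small_tube_volume, structured_tube_volume, None, w)
        assert c1 == pytest.approx(c2, abs=1e-6)

    def test_empty_wedge_intersection_rejected(self, small_tube_volume):
        zero = np.zeros(small_tube_volume.data.shape, dtype=np.float32)
        with pytest.raises(ValueError):
            constrained_cc(small_tube_volume, small_tube_volume, zero, None)


class TestAlignParticle:
    def test_known_rotation_recovered_to_final_sampling(
            self, structured_tube_volume):
        true_e = (14.0, 11.0, -9.0)
        part = rotate_shift(structured_tube_volume, true_e, (1.0, -2.0, 0.0))
        sched = SearchSchedule(cone_aperture=60, azimuth_range=360,
                               initial_sampling=15, n_refinements=3,
                               shift_limits=(3, 3, 3), lowpass_nm=None)
        res = align_particle(part, None, structured_tube_volume, sched)
        assert rotation_distance_deg(res.euler, true_e) <= sched.final_sampling
        assert res.shift == (1, -2, 0)
        assert res.cc > 0.95

    def test_pure_shift_with_identity_grid(self, structured_tube_volume):
        part = rotate_shift(structured_tube_volume, (0.0, 0.0, 0.0),
                            (2.0, 0.0, -3.0))
        sched = SearchSchedule(cone_aperture=0, azimuth_range=0,
                               initial_sampling=10, n_refinements=0,
                               shift_limits=(4, 4, 4), lowpass_nm=None)
        res = align_particle(part, None, structured_tube_volume, sched)
        assert res.shift == (2, 0, -3)

    def test_noise_particle_scores_near_null(self, structured_tube_volume):
        rng = np.random.default_rng(2)
        noise = tt.VoxelVolume(
            rng.normal(size=structured_tube_volume.data.shape)
            .astype(np.float32))
        sched = SearchSchedule(cone_aperture=0, azimuth_range=360,
                               initial_sampling=30, n_refinements=0,
                               shift_limits=(0, 0, 0), lowpass_nm=None)
        res = align_particle(noise, None, structured_tube_volume, sched)
        # null scale for the max over ~12 independent orientations
        assert res.cc < 6.0 / np.sqrt(noise.data.size)

    def test_all_zero_particle_rejected(self, structured_tube_volume):
        zero = tt.VoxelVolume(np.zeros((40, 40, 40), dtype=np.float32))
        sched = SearchSchedule()
        with pytest.raises(ValueError):
            align_particle(zero, None, structured_tube_volume, sched)

    def test_score_invariant_under_common_global_rotation(
            self, structured_tube_volume, coarse_geometry):
        g_rot = (0.0, 30.0, 0.0)
        wedge = make_wedge_mask(structured_tube_volume.data.shape,
                                coarse_geometry)
        part = tt.apply_wedge(structured_tube_volume, wedge)
        sched = SearchSchedule(cone_aperture=0, azimuth_range=0,
                               initial_sampling=10, n_refinements=0,
                               shift_limits=(0, 0, 0), lowpass_nm=None)
        res0 = align_particle(part, wedge.mask, structured_tube_volume, sched)
        from tubetomo.align import rotate_wedge_mask
        part_r = rotate_shift(part, g_rot)
        ref_r = rotate_shift(structured_tube_volume, g_rot)
        wedge_r = rotate_wedge_mask(wedge, g_rot)
        res1 = align_particle(part_r, wedge_r, ref_r, sched)
        assert res1.cc == pytest.approx(res0.cc, abs=0.02)


class TestAveraging:
    def test_full_wedge_copies_average_to_original(self,
                                                   structured_tube_volume):
        avg = average_wedge_compensated([structured_tube_volume] * 5, None)
        assert np.allclose(avg.data, structured_tube_volume.data, atol=1e-5)

    def test_wedge_coverage_sums_where_all_overlap(self, coarse_geometry):
        n = 32
        w = make_wedge_mask((n, n, n), coarse_geometry)
        total = np.zeros((n, n, n))
        for _ in range(4):
            total += w.mask
        assert total.max() == 4.0

    def test_known_orientations_average_recovers_truth(
            self, structured_tube_volume, coarse_geometry):
        rng = np.random.default_rng(5)
        parts, wedges, aligns = [], [], []
        for _ in range(8):
            e = (float(rng.uniform(0, 360)),
                 float(np.degrees(np.arccos(rng.uniform(-1, 1)))),
                 float(rng.uniform(0, 360)))
            v = rotate_shift(structured_tube_volume, e)
            w = make_wedge_mask(v.data.shape, coarse_geometry)
            parts.append(tt.apply_wedge(v, w))
            wedges.append(w)
            aligns.append(AlignmentResult(e, (0, 0, 0), 1.0))
        avg = average_wedge_compensated(parts, wedges, aligns)
        cc = np.corrcoef(avg.data.ravel(),
                         structured_tube_volume.data.ravel())[0, 1]
        assert cc > 0.97

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            average_wedge_compensated([], None)


class TestIterativeRefine:
    def test_single_iteration_equals_align_plus_average(
            self, structured_tube_volume):
        parts = [rotate_shift(structured_tube_volume, (0, 0, a))
                 for a in (0.0, 10.0)]
        sched = SearchSchedule(cone_aperture=0, azimuth_range=20,
                               initial_sampling=10, n_refinements=0,
                               shift_limits=(0, 0, 0), lowpass_nm=None)
        avg, aligns, kept = iterative_refine(parts, None,
                                             structured_tube_volume, sched,
                                             n_iter=1, keep_factor=0.0)
        manual = [align_particle(p, None, structured_tube_volume, sched)
                  for p in parts]
        for a, m in zip(aligns, manual):
            assert a.euler == m.euler and a.shift == m.shift

    def test_noise_particles_excluded_by_keep_rule(
            self, structured_tube_volume):
        rng = np.random.default_rng(8)
        parts = [rotate_shift(structured_tube_volume, (0, 0, float(a)))
                 for a in rng.uniform(0, 360, 8)]
        noise_idx = list(range(8, 12))
        for _ in noise_idx:
            parts.append(tt.VoxelVolume(
                rng.normal(scale=0.3,
                           size=structured_tube_volume.data.shape)
                .astype(np.float32)))
        sched = SearchSchedule(cone_aperture=0, azimuth_range=360,
                               initial_sampling=15, n_refinements=1,
                               shift_limits=(0, 0, 0), lowpass_nm=None)
        _, _, kept = iterative_refine(parts, None, structured_tube_volume,
                                      sched, n_iter=1, keep_factor=0.5)
        assert all(i not in kept for i in noise_idx)
        assert len(kept) >= 6


class TestSubbox:
    def test_zero_offset_same_box_is_identity(self, structured_tube_volume):
        aligns = [AlignmentResult((0.0, 0.0, 0.0), (0, 0, 0), 1.0)]
        out = subbox([structured_tube_volume], aligns, (0, 0, 0),
                     structured_tube_volume.data.shape[0])
        assert np.array_equal(out[0].data, structured_tube_volume.data)

    def test_region_exiting_box_rejected(self, structured_tube_volume):
        aligns = [AlignmentResult((0.0, 0.0, 0.0), (0, 0, 0), 1.0)]
        with pytest.raises(ValueError):
            subbox([structured_tube_volume], aligns, (30, 0, 0), 20)

    def test_tube_region_subbox_captures_tube_not_capsid(self):
        spec = tt.canonical_capsid_spec(tube_length=30.0)
        vol = tt.rasterize_phantom(spec, 176)
        aligns = [AlignmentResult((0.0, 0.0, 0.0), (0, 0, 0), 1.0)]
        # tube center sits near z = +48 nm in the reference frame
        off = int(round(48.0 / vol.voxel_size))
        out = subbox([vol], aligns, (0, 0, off), 40)[0]
        X, Y, Z = vol.physical_coords()
        tube_mask = (np.sqrt(X**2 + Y**2) < 8.5) & (Z > 34.0)
        capsid_mass = vol.data.sum() - vol.data[tube_mask].sum()
        # the subbox is dominated by tube density: its mass must be far
        # below the capsid's and concentrated on-axis
        assert out.data.sum() < 0.12 * capsid_mass
        nx = out.data.shape[0]
        axo = (np.arange(nx) - nx // 2) * vol.voxel_size
        Xs, Ys, Zs = np.meshgrid(axo, axo, axo, indexing="ij")
        on_axis = np.sqrt(Xs**2 + Ys**2) < 8.5
        assert out.data[on_axis].sum() > 0.9 * out.data.sum()
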