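"""Constrained cross-correlation alignment, wedge-weighted averaging and
pose bookkeeping."""

import numpy as np
import pytest

from conftest import correlate
from subtomo.alignment import (Pose, WedgeMask, align_reference_to_particle,
                               align_subvolume, average_aligned, centres_to_voxels,
                               extract_subvolumes, fourier_wedge_mask,
                               _hermitian_weights, refine_iteratively,
                               rescale_poses, soft_sphere_mask, wedge_occupancy)
from subtomo.errors import ParameterError, ValidationError
from subtomo.geometry import euler_to_matrix, geodesic_angle, transform_map
from subtomo.maps import DensityMap
from subtomo.particles import ParticleSet

NO_WEDGE = WedgeMask(-90.0, 89.999)
WEDGE60 = WedgeMask(-60.0, 60.0)


class TestWedgeMask:
    def test_sixty_degree_mask_covers_expected_fraction(self):
        mask = fourier_wedge_mask((64, 64, 64), WEDGE60, rfft=False)
        # measured fraction of the (kx, kz) plane angles = 120/180
        assert mask.mean() == pytest.approx(2 / 3, abs=0.05)

    def test_rotation_by_90_about_y_swaps_wedge_orientation(self):
        plain = fourier_wedge_mask((32, 32, 32), WEDGE60, rfft=False)
        rot = fourier_wedge_mask((32, 32, 32), WEDGE60,
                                 rotation=euler_to_matrix((0, 90, 0)), rfft=False)
        # axes swap: components missing near kz become missing near kx
        np.testing.assert_array_equal(rot[1:, 0, 0], ~plain[1:, 0, 0])

    def test_invalid_range_rejected(self):
        with pytest.raises(ParameterError):
            WedgeMask(30.0, 10.0)


class TestExtract:
    def test_delta_function_lands_at_subvolume_centre(self):
        data = np.zeros((32, 32, 32), dtype=np.float32)
        data[20, 12, 16] = 1.0
        tomo = DensityMap(data, 10.0)
        ps = ParticleSet.from_arrays([[200.0, 120.0, 160.0]])
        stack, kept = extract_subvolumes(tomo, ps, 8)
        assert kept.all()
        # the geometric centre of an even box sits between voxels, so the
        # unit delta splits evenly over the central 2x2x2 block
        block = stack[0][3:5, 3:5, 3:5]
        assert block.sum() == pytest.approx(1.0, abs=1e-5)
        np.testing.assert_allclose(block, 0.125, atol=1e-6)

    def test_box_60_at_4p22_angstrom_is_about_25nm(self):
        assert 60 * 4.22 == pytest.approx(253.2)  # the sub-volume edge used for microtubules

    def test_empty_set_gives_empty_stack(self):
        tomo = DensityMap(np.zeros((16, 16, 16)), 8.0)
        stack, kept = extract_subvolumes(tomo, ParticleSet.empty(), 8)
        assert stack.shape[0] == 0 and len(kept) == 0

    def test_far_outside_particle_is_skipped(self):
        tomo = DensityMap(np.zeros((16, 16, 16)), 8.0)
        ps = ParticleSet.from_arrays([[64.0, 64.0, 64.0], [4000.0, 0.0, 0.0]])
        stack, kept = extract_subvolumes(tomo, ps, 8)
        assert list(kept) == [True, False]
        assert stack.shape[0] == 1

    def test_odd_box_rejected(self):
        tomo = DensityMap(np.zeros((16, 16, 16)), 8.0)
        with pytest.raises(ParameterError):
            extract_subvolumes(tomo, ParticleSet.empty(), 9)


class TestAlignSubvolume:
    def test_self_alignment_is_identity_with_ccc_one(self, mt_map):
        pose = align_subvolume(mt_map.data, mt_map.data, NO_WEDGE, 0, 1, 20.0,
                               voxel_size=8.0)
        np.testing.assert_allclose(pose.euler, 0.0, atol=1e-9)
        np.testing.assert_allclose(pose.shift, 0.0, atol=1e-4)
        assert pose.ccc == pytest.approx(1.0, abs=1e-5)

    def test_known_rotation_and_shift_recovered_to_grid_tolerance(self, mt_map):
        rot = euler_to_matrix((20.0, 0.0, 0.0))
        moved = transform_map(mt_map.data, rot, (2.0, 0.0, 0.0))
        pose = align_subvolume(moved, mt_map.data, NO_WEDGE, (25, 0, 0), (5, 1, 1),
                               40.0, voxel_size=8.0)
        assert geodesic_angle(pose.rotation, rot) <= 2.5
        np.testing.assert_allclose(pose.shift / 8.0, [2.0, 0.0, 0.0], atol=0.5)

    def test_ccc_matches_bruteforce_recomputation_at_reported_pose(self, mt_map, rng):
        sub = (mt_map.data + 0.5 * rng.standard_normal(mt_map.shape)).astype(np.float32)
        pose = align_subvolume(sub, mt_map.data, WEDGE60, (4, 4, 4), (2, 2, 2), 16.0,
                               voxel_size=8.0)
        # independent recomputation: rotate reference, apply the shift as a
        # Fourier phase ramp, correlate outside the wedge
        shape = mt_map.shape
        mask = fourier_wedge_mask(shape, WEDGE60, rfft=True, exclude_dc=True)
        w = _hermitian_weights(shape) * mask
        rot_ref = transform_map(mt_map.data - mt_map.data.mean(), pose.rotation)
        f_ref = np.fft.rfftn(rot_ref)
        ks = [np.fft.fftfreq(shape[0])[:, None, None], np.fft.fftfreq(shape[1])[None, :, None],
              np.fft.rfftfreq(shape[2])[None, None, :]]
        phase = np.exp(-2j * np.pi * sum(k * s for k, s in zip(ks, pose.shift / 8.0)))
        f_sub = np.fft.rfftn(sub - sub.mean())
        num = np.sum(w * (f_sub * np.conj(f_ref * phase)).real)
        den = np.sqrt(np.sum(w * np.abs(f_sub) ** 2) * np.sum(w * np.abs(f_ref) ** 2))
        assert pose.ccc == pytest.approx(num / den, abs=1e-4)

    def test_pure_noise_scores_near_zero_on_average(self, mt_map):
        rng = np.random.default_rng(0)
        scores = []
        ref = mt_map.data[::2, ::2, ::2]  # 24^3 for speed
        for _ in range(100):
            noise = rng.standard_normal(ref.shape).astype(np.float32)
            pose = align_subvolume(noise, ref, WEDGE60, 0, 1, 12.0, voxel_size=16.0)
            scores.append(pose.ccc)
        # the max over translations biases the null ccc slightly positive
        assert abs(np.mean(scores)) < 0.05

    def test_alignment_is_equivariant_under_input_rotation(self, mt_map):
        base = euler_to_matrix((0.0, 10.0, 0.0))
        moved0 = transform_map(mt_map.data, base)
        p0 = align_subvolume(moved0, mt_map.data, NO_WEDGE, (12, 12, 12), (2, 2, 2),
                             8.0, voxel_size=8.0)
        extra = euler_to_matrix((0.0, 4.0, 0.0))
        moved1 = transform_map(mt_map.data, extra @ base)
        p1 = align_subvolume(moved1, mt_map.data, NO_WEDGE, (16, 16, 16), (2, 2, 2),
                             8.0, voxel_size=8.0)
        assert geodesic_angle(p1.rotation, extra @ p0.rotation) <= 3.0


class TestAverageAligned:
    def test_copies_of_wedge_limited_subvolume_average_to_itself(self, mt_map):
        mask = fourier_wedge_mask(mt_map.shape, WEDGE60, rfft=True)
        limited = np.fft.irfftn(np.fft.rfftn(mt_map.data - mt_map.data.mean()) * mask,
                                s=mt_map.shape, axes=(0, 1, 2)).astype(np.float32)
        stack = np.stack([limited] * 4)
        poses = [Pose((0, 0, 0), (0, 0, 0))] * 4
        avg = average_aligned(stack, poses, WEDGE60, 8.0)
        assert correlate(avg, limited) > 0.9999

    def test_averaging_reduces_noise_by_sqrt_n(self, mt_map, rng):
        n = 100
        sigma = 2.0
        stack = (mt_map.data[None] + sigma * rng.standard_normal((n,) + mt_map.shape)
                 ).astype(np.float32)
        poses = [Pose((0, 0, 0), (0, 0, 0))] * n
        avg = average_aligned(stack, poses, NO_WEDGE, 8.0)
        resid_one = stack[0] - stack[0].mean() - (mt_map.data - mt_map.data.mean())
        resid_avg = avg - avg.mean() - (mt_map.data - mt_map.data.mean())
        gain = resid_one.std() / resid_avg.std()
        assert gain == pytest.approx(np.sqrt(n), rel=0.2)
        assert correlate(avg, mt_map.data) > correlate(stack[0], mt_map.data)

    def test_spin_coverage_fills_the_wedge_outside_residual_region(self):
        shape = (24, 24, 24)
        poses = [Pose((0.0, 90.0, psi), (0, 0, 0)) for psi in np.arange(0, 360, 15)]
        occ = wedge_occupancy(poses, WEDGE60, shape)
        kx = np.fft.fftfreq(24)[:, None, None]
        ky = np.fft.fftfreq(24)[None, :, None]
        kz = np.fft.rfftfreq(24)[None, None, :]
        r = np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)
        unfilled = (occ == 0) & (r > 1e-6)
        # spin coverage of an in-plane filament fills all but a thin
        # residual region hugging the reference equatorial plane
        assert unfilled.mean() < 0.10
        angle_from_plane = np.degrees(np.arcsin(
            np.abs(np.broadcast_to(kz, occ.shape)[unfilled]) / r[unfilled]))
        assert angle_from_plane.max() < 5.0

    def test_zero_particles_rejected(self):
        with pytest.raises(ValidationError):
            average_aligned(np.empty((0, 8, 8, 8)), [], WEDGE60, 8.0)


class TestRefineIteratively:
    def test_zero_range_schedule_is_a_noop_on_poses(self, mt_map):
        tomo = DensityMap(np.pad(mt_map.data, 8), 8.0)
        centre = np.array(tomo.shape) / 2 * 8.0 - 4.0
        ps = ParticleSet.from_arrays([centre, centre + [8.0, 0, 0]])
        result = refine_iteratively(tomo, ps, None, [(0.0, 1.0, 0.0)], WEDGE60, 32)
        np.testing.assert_allclose(result.particles.eulers, ps.eulers, atol=1e-9)
        np.testing.assert_allclose(result.particles.shifts, 0.0, atol=1e-6)

    def test_half_sets_never_share_reference_particles(self, mt_map):
        tomo = DensityMap(np.pad(mt_map.data, 8), 8.0)
        centre = np.array(tomo.shape) / 2 * 8.0 - 4.0
        offsets = [[dx, 0.0, 0.0] for dx in (-16.0, -8.0, 0.0, 8.0)]
        ps = ParticleSet.from_arrays([centre + o for o in offsets],
                                     half=["A", "B", "A", "B"])
        result = refine_iteratively(tomo, ps, None, [(0.0, 1.0, 8.0)], WEDGE60, 32)
        ids_a = {i for e in result.audit if e.get("half") == "A" and "reference_particle_ids" in e
                 for i in e["reference_particle_ids"]}
        ids_b = {i for e in result.audit if e.get("half") == "B" and "reference_particle_ids" in e
                 for i in e["reference_particle_ids"]}
        assert ids_a and ids_b and not (ids_a & ids_b)

    def test_empty_schedule_rejected(self, mt_map):
        tomo = DensityMap(np.pad(mt_map.data, 8), 8.0)
        with pytest.raises(ParameterError):
            refine_iteratively(tomo, ParticleSet.empty(), None, [], WEDGE60, 32)


class TestRescalePoses:
    def test_bin4_to_bin2_doubles_voxel_coordinates_keeps_angstrom(self):
        ps = ParticleSet.from_arrays([[100.0, 200.0, 300.0]], [[10.0, 20.0, 30.0]])
        out = rescale_poses(ps, 4, 2)
        np.testing.assert_allclose(out.centres, ps.centres)  # Å invariant
        np.testing.assert_allclose(out.eulers, ps.eulers)
        v4 = centres_to_voxels(ps, 4.22, 4)
        v2 = centres_to_voxels(out, 4.22, 2)
        np.testing.assert_allclose(v2, 2 * v4)

    def test_identity_and_round_trip(self):
        ps = ParticleSet.from_arrays([[1.0, 2.0, 3.0]])
        assert rescale_poses(ps, 2, 2).df.equals(ps.df)
        back = rescale_poses(rescale_poses(ps, 4, 1), 1, 4)
        np.testing.assert_allclose(back.centres, ps.centres, atol=1e-12)

    def test_invalid_binning_rejected(self):
        with pytest.raises(ParameterError):
            rescale_poses(ParticleSet.empty(), 3, 1)


class TestReferenceToParticle:
    def test_reference_onto_itself_is_identity(self, mt_map):
        poses = align_reference_to_particle(mt_map, mt_map, lowpass=60.0,
                                            wedge=NO_WEDGE, coarse_step=45.0,
                                            refine_schedule=((10.0, 5.0),))
        best = poses[0]
        assert best.ccc > 0.98
        assert geodesic_angle(best.rotation, np.eye(3)) < 6.0

    def test_lowpass_removes_power_beyond_cutoff(self, mt_map):
        from subtomo.validation import lowpass_map
        filtered = lowpass_map(mt_map, 60.0)
        freqs = [np.fft.fftfreq(n, d=8.0) for n in mt_map.shape]
        r = np.sqrt(freqs[0][:, None, None] ** 2 + freqs[1][None, :, None] ** 2
                    + freqs[2][None, None, :] ** 2)
        p_orig = np.abs(np.fft.fftn(mt_map.data))[r > 1 / 60.0] ** 2
        p_filt = np.abs(np.fft.fftn(filtered.data))[r > 1 / 60.0] ** 2
        assert p_filt.sum() < 0.01 * p_orig.sum()
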