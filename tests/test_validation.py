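"""FSC, masks, resolution readout, lattice diagnostics and back-plotting."""

import numpy as np
import pytest

from conftest import correlate
from subtomo.errors import ParameterError, ShapeError
from subtomo.maps import DensityMap
from subtomo.particles import ParticleSet
from subtomo.phantoms import MicrotubulePhantomParams, make_microtubule_map
from subtomo.validation import (FSCCurve, MaskSpec, backplot, compute_fsc,
                                dominant_angular_order, fsc_to_ideal,
                                layer_line_profile, make_mask,
                                peak_axial_spacing, resolution_at,
                                rotational_power_spectrum)


class TestMakeMask:
    def test_none_is_all_ones(self):
        mask = make_mask(MaskSpec("none"), (8, 8, 8), 4.0)
        assert (mask == 1.0).all()

    def test_hard_cylinder_diameter_is_approximately_25nm(self):
        mask = make_mask(MaskSpec("cylinder_hard", radius=125.0), (64, 64, 8), 4.0)
        width = mask[:, 32, 0].sum() * 4.0  # in-plane extent in Å
        assert width == pytest.approx(250.0, abs=2 * 4.0)
        assert set(np.unique(mask)) <= {0.0, 1.0}

    def test_soft_masks_stay_in_unit_interval(self):
        mask = make_mask(MaskSpec("cylinder_soft", radius=80.0, soft_edge=40.0),
                         (32, 32, 32), 8.0)
        assert mask.min() >= 0.0 and mask.max() <= 1.0
        assert ((mask > 0) & (mask < 1)).any()  # the cosine edge exists

    def test_threshold_soft_requires_reference(self):
        with pytest.raises(ParameterError):
            make_mask(MaskSpec("threshold_soft", threshold=0.5), (8, 8, 8), 4.0)

    def test_threshold_soft_covers_reference_support(self, mt_map):
        level = 0.3 * mt_map.data.max()
        mask = make_mask(MaskSpec("threshold_soft", threshold=level, soft_edge=24.0),
                         mt_map.shape, mt_map.voxel_size, reference=mt_map)
        assert (mask[mt_map.data >= level] == 1.0).all()
        assert mask.min() >= 0.0 and mask.max() <= 1.0


class TestComputeFSC:
    def test_self_correlation_is_one_at_every_shell(self, mt_map):
        curve = compute_fsc(mt_map, mt_map)
        np.testing.assert_allclose(curve.corr, 1.0, atol=1e-10)

    def test_symmetry_in_arguments(self, mt_map, rng):
        other = DensityMap(mt_map.data + rng.standard_normal(mt_map.shape).astype(np.float32),
                           mt_map.voxel_size)
        a = compute_fsc(mt_map, other)
        b = compute_fsc(other, mt_map)
        np.testing.assert_allclose(a.corr, b.corr, atol=1e-12)

    def test_invariant_under_common_scaling(self, mt_map, rng):
        other = DensityMap(mt_map.data + rng.standard_normal(mt_map.shape).astype(np.float32),
                           mt_map.voxel_size)
        a = compute_fsc(mt_map, other)
        b = compute_fsc(DensityMap(3.0 * mt_map.data, 8.0),
                        DensityMap(3.0 * other.data, 8.0))
        np.testing.assert_allclose(a.corr, b.corr, atol=1e-5)

    def test_independent_noise_gives_near_zero_shells(self):
        rng = np.random.default_rng(0)
        curves = []
        for _ in range(20):
            a = DensityMap(rng.standard_normal((32, 32, 32)).astype(np.float32), 8.0)
            b = DensityMap(rng.standard_normal((32, 32, 32)).astype(np.float32), 8.0)
            curves.append(compute_fsc(a, b).corr)
        mean = np.mean(curves, axis=0)
        sem = np.std(curves, axis=0, ddof=1) / np.sqrt(len(curves))
        # skip DC (identical means there); every other shell within 3 SE of 0
        assert (np.abs(mean[1:]) <= 3 * np.maximum(sem[1:], 1e-3)).all()

    def test_shape_mismatch_rejected(self, mt_map):
        with pytest.raises(ShapeError):
            compute_fsc(mt_map, DensityMap(np.zeros((8, 8, 8)), 8.0))

    def test_tight_mask_inflates_null_fsc(self):
        rng = np.random.default_rng(3)
        spec = MaskSpec("cylinder_soft", radius=40.0, soft_edge=24.0)
        mask = make_mask(spec, (32, 32, 32), 8.0)
        masked_high, plain_high = [], []
        for _ in range(20):
            a = DensityMap(rng.standard_normal((32, 32, 32)).astype(np.float32), 8.0)
            b = DensityMap(rng.standard_normal((32, 32, 32)).astype(np.float32), 8.0)
            plain_high.append(compute_fsc(a, b).corr[8:].mean())
            masked_high.append(compute_fsc(a, b, mask).corr[8:].mean())
        assert np.mean(masked_high) > np.mean(plain_high)


class TestResolutionAt:
    def test_hand_interpolated_crossing(self):
        curve = FSCCurve([0.02, 0.04], [0.5, 0.1])
        res = resolution_at(curve, 0.143)
        assert res.frequency == pytest.approx(0.03785, abs=1e-5)
        assert res.resolution == pytest.approx(26.42, abs=0.01)
        assert res.crossed

    def test_flat_curve_reports_nyquist_uncrossed(self):
        curve = FSCCurve(np.linspace(0.001, 0.0625, 10), np.ones(10))
        res = resolution_at(curve, 0.143)
        assert not res.crossed
        assert res.resolution == pytest.approx(16.0, abs=1e-9)

    def test_05_crossing_is_never_beyond_0143_crossing(self):
        freq = np.linspace(0.001, 0.06, 40)
        corr = np.linspace(1.0, -0.1, 40)  # monotone decreasing
        r05 = resolution_at(FSCCurve(freq, corr), 0.5)
        r0143 = resolution_at(FSCCurve(freq, corr), 0.143)
        assert r05.frequency <= r0143.frequency

    def test_threshold_domain_checked(self):
        with pytest.raises(ParameterError):
            resolution_at(FSCCurve([0.01], [1.0]), 1.5)


class TestLatticeDiagnostics:
    @pytest.mark.parametrize("n_pf", [9, 11, 13, 16])
    def test_rotational_spectrum_recovers_protofilament_count(self, n_pf):
        params = MicrotubulePhantomParams(n_protofilaments=n_pf, length=160.0)
        density = make_microtubule_map(params, 8.0, (48, 48, 48))
        orders, power = rotational_power_spectrum(density, (70.0, 135.0))
        assert dominant_angular_order(orders, power, min_order=3, max_order=25) == n_pf

    def test_smooth_cylinder_has_no_dominant_order(self):
        x = (np.arange(48) - 23.5)[:, None] * 8.0
        y = (np.arange(48) - 23.5)[None, :] * 8.0
        wall = np.exp(-0.5 * ((np.sqrt(x ** 2 + y ** 2) - 100.0) / 15.0) ** 2)
        density = DensityMap(np.repeat(wall[:, :, None], 48, axis=2).astype(np.float32), 8.0)
        orders, power = rotational_power_spectrum(density, (70.0, 135.0))
        assert power[3:26].max() < 1e-4 * power[0]

    @pytest.mark.parametrize("spacing", [40.0, 80.0])
    def test_layer_line_peaks_at_lattice_repeat(self, spacing):
        params = MicrotubulePhantomParams(monomer_spacing=spacing, length=240.0)
        density = make_microtubule_map(params, 8.0, (64, 64, 64))
        freq, power = layer_line_profile(density)
        assert peak_axial_spacing(freq, power, min_freq=1 / 100.0) == pytest.approx(
            spacing, rel=0.06)

    def test_axially_uniform_cylinder_concentrates_at_zero_frequency(self):
        x = (np.arange(32) - 15.5)[:, None] * 8.0
        y = (np.arange(32) - 15.5)[None, :] * 8.0
        wall = np.exp(-0.5 * ((np.sqrt(x ** 2 + y ** 2) - 80.0) / 15.0) ** 2)
        density = DensityMap(np.repeat(wall[:, :, None], 32, axis=2).astype(np.float32), 8.0)
        freq, power = layer_line_profile(density)
        assert power[0] > 1e6 * power[1:].max()


class TestFscToIdeal:
    def test_ideal_versus_itself_is_unity(self, mt_map):
        curve = fsc_to_ideal(mt_map, mt_map)
        np.testing.assert_allclose(curve.corr, 1.0, atol=1e-10)


class TestBackplot:
    def test_empty_particles_give_zero_volume(self, mt_map):
        out = backplot((32, 32, 32), mt_map, ParticleSet.empty())
        assert np.abs(out.data).max() == 0

    def test_single_identity_particle_paints_padded_copy(self, mt_map):
        shape = (64, 64, 64)
        centre = (np.array(shape) - 1) / 2 * 8.0
        ps = ParticleSet.from_arrays([centre])
        out = backplot(shape, mt_map, ps, mode="sum")
        assert correlate(out.data[8:56, 8:56, 8:56], mt_map.data) > 0.999

    def test_sum_mode_accumulates_overlaps(self, mt_map):
        shape = (64, 64, 64)
        centre = (np.array(shape) - 1) / 2 * 8.0
        ps = ParticleSet.from_arrays([centre, centre], ids=[0, 1])
        summed = backplot(shape, mt_map, ps, mode="sum")
        peak = backplot(shape, mt_map, ps, mode="max")
        assert summed.data.max() == pytest.approx(2 * peak.data.max(), rel=1e-5)

    def test_unknown_mode_rejected(self, mt_map):
        with pytest.raises(ParameterError):
            backplot((16, 16, 16), mt_map, ParticleSet.empty(), mode="mean")
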