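"""Geometric fidelity of the phantom generators."""

import numpy as np
import pytest

from conftest import correlate
from subtomo.errors import GeometryError, ParameterError
from subtomo.geometry import box_centre, transform_map, euler_to_matrix
from subtomo.maps import DensityMap
from subtomo.phantoms import (MicrotubulePhantomParams, icosahedron_vertices,
                              make_icosahedral_phantom, make_microtubule_map,
                              microtubule_lattice_points, paint_blobs, render_scene)
from subtomo.validation import count_surface_maxima


def radial_profile(density: DensityMap, z_slice=None):
    """Rotationally (and axially) averaged density vs cylinder radius."""
    nx, ny, nz = density.shape
    c = box_centre(density.shape)
    x = (np.arange(nx) - c[0]) * density.voxel_size
    y = (np.arange(ny) - c[1]) * density.voxel_size
    r = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)
    plane = density.data[:, :, z_slice].mean(axis=2) if z_slice else density.data.mean(axis=2)
    edges = np.arange(0, r.max(), density.voxel_size)
    idx = np.digitize(r.ravel(), edges)
    sums = np.bincount(idx, weights=plane.ravel(), minlength=len(edges) + 2)
    counts = np.maximum(np.bincount(idx, minlength=len(edges) + 2), 1)
    return edges, (sums / counts)[1:len(edges) + 1]


def outer_half_max_radius(radii, profile):
    i_pk = int(np.argmax(profile))
    half = profile[i_pk] / 2.0
    i = i_pk
    while profile[i] > half:
        i += 1
    frac = (profile[i - 1] - half) / (profile[i - 1] - profile[i])
    return radii[i - 1] + frac * (radii[1] - radii[0])


class TestMicrotubulePhantom:
    def test_outer_diameter_at_half_maximum_is_25nm(self):
        params = MicrotubulePhantomParams(length=200.0)
        density = make_microtubule_map(params, 2.0, (160, 160, 168))
        radii, prof = radial_profile(density, z_slice=np.s_[60:108])
        diameter = 2 * outer_half_max_radius(radii, prof)
        assert diameter == pytest.approx(250.0, abs=2 * 2.0)  # within one voxel each side

    def test_lattice_self_maps_under_13_3_helical_operator(self, mt_params, mt_map):
        rise_vox = (mt_params.start_number * mt_params.monomer_spacing
                    / mt_params.n_protofilaments) / mt_map.voxel_size
        rot = euler_to_matrix((360.0 / 13, 0, 0))
        moved = transform_map(mt_map.data.astype(np.float64), rot, (0, 0, rise_vox), order=3)
        # compare the axial core: the screw operator is a symmetry of the
        # infinite lattice, so the finite ends are excluded
        core = np.s_[:, :, 20:28]
        assert correlate(moved[core], mt_map.data[core]) > 0.99

    def test_zero_length_gives_single_ring_of_13_blobs(self):
        params = MicrotubulePhantomParams(length=0.0)
        pts = microtubule_lattice_points(params)
        assert len(pts) == 13
        ring = make_microtubule_map(params, 4.0, (96, 96, 96))
        blob = paint_blobs((96, 96, 96), 4.0, [(0.0, 0.0, 0.0)], params.monomer_sigma)
        assert ring.data.sum() == pytest.approx(13 * blob.sum(), rel=1e-3)

    def test_generators_are_deterministic(self, mt_params):
        a = make_microtubule_map(mt_params, 8.0, (40, 40, 40))
        b = make_microtubule_map(mt_params, 8.0, (40, 40, 40))
        np.testing.assert_array_equal(a.data, b.data)

    def test_oversized_phantom_is_rejected(self):
        with pytest.raises(GeometryError):
            make_microtubule_map(MicrotubulePhantomParams(length=2000.0), 8.0, (32, 32, 32))

    def test_density_is_nonnegative(self, mt_map):
        assert mt_map.data.min() >= 0


class TestIcosahedralPhantom:
    def test_marked_phantom_has_12_vertex_maxima(self):
        cap = make_icosahedral_phantom(480.0, True, 14.0, (96, 96, 96))
        n = count_surface_maxima(cap, radius=480.0 + 60.0)
        assert n == 12

    def test_phantom_is_invariant_under_symmetrisation(self):
        from subtomo.symmetry import icosahedral_operators, symmetrise_map
        cap = make_icosahedral_phantom(250.0, True, 12.0, (80, 80, 80))
        sym = symmetrise_map(cap, icosahedral_operators())
        # bounded by interpolation error on a smooth map
        assert np.abs(sym.data - cap.data).max() < 0.05 * cap.data.max()

    def test_radius_480_gives_960_diameter_shell(self):
        cap = make_icosahedral_phantom(480.0, False, 12.0, (96, 96, 96))
        c = box_centre(cap.shape)
        ax = [(np.arange(n) - c[i]) * 12.0 for i, n in enumerate(cap.shape)]
        r = np.sqrt(ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
                    + ax[2][None, None, :] ** 2)
        edges = np.arange(0, 570, 12.0)
        idx = np.digitize(r.ravel(), edges)
        sums = np.bincount(idx, weights=cap.data.ravel(), minlength=len(edges) + 2)
        counts = np.maximum(np.bincount(idx, minlength=len(edges) + 2), 1)
        prof = (sums / counts)[1:len(edges) + 1]
        peak_radius = edges[np.argmax(prof)]
        assert 2 * peak_radius == pytest.approx(960.0, abs=2 * 12.0)

    def test_vertices_are_unit_and_twelve(self):
        v = icosahedron_vertices()
        assert v.shape == (12, 3)
        np.testing.assert_allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-12)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ParameterError):
            make_icosahedral_phantom(0.0, False, 8.0, (32, 32, 32))


class TestRenderScene:
    def test_empty_scene_is_zero(self):
        scene, truth = render_scene([], (16, 16, 16), 8.0)
        assert scene.data.sum() == 0
        assert len(truth) == 0

    def test_identity_pose_recentres_phantom(self, mt_map):
        centre = box_centre((64, 64, 64)) * 8.0
        scene, truth = render_scene([(mt_map, (0, 0, 0), centre)], (64, 64, 64), 8.0)
        assert scene.data[8:56, 8:56, 8:56] == pytest.approx(mt_map.data, abs=1e-4)
        assert len(truth) == 1

    def test_two_disjoint_phantoms_sum_linearly(self, mt_map):
        c = box_centre((96, 96, 96)) * 8.0
        scene, _ = render_scene(
            [(mt_map, (0, 0, 0), c + [0, 0, -190.0]),
             (mt_map, (0, 90, 0), c + [0, 0, 190.0])], (96, 96, 96), 8.0)
        assert scene.data.sum() == pytest.approx(2 * mt_map.data.sum(), rel=0.02)
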