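"""Geometry: layered icospheres, sensor packing, channel axes, offsets,
co-registration error, and the alternative (mismatched) geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import opmlaminar as om
from opmlaminar.geometry import _tangential_axes


class TestHeadGeometry:
    @pytest.mark.parametrize("sub,expected", [(2, 162), (3, 642), (4, 2562)])
    def test_icosphere_vertex_count(self, sub, expected):
        space, scalp = om.make_head_geometry(subdivisions=sub)
        assert space.white.n_vertices == expected  # 10 * 4^n + 2
        assert scalp.n_vertices == expected

    def test_exact_sphere_when_unbumped(self, small_head):
        space, _ = small_head
        radii = np.linalg.norm(space.pial.vertices, axis=1)
        assert np.allclose(radii, 72.0, atol=1e-9)

    def test_layer_separation_is_radius_difference(self, bumpy_head):
        # the bump pattern is shared across layers, so it cancels
        space, _ = bumpy_head
        sep = np.linalg.norm(space.pial.vertices, axis=1) - np.linalg.norm(
            space.white.vertices, axis=1
        )
        assert np.allclose(sep, 2.0, atol=1e-9)
        space.validate()

    def test_meshes_valid_and_normals_outward(self, bumpy_head):
        space, scalp = bumpy_head
        for mesh in (space.white, space.pial, space.mid, scalp):
            mesh.validate()
            dirs = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
            assert np.all((mesh.vertex_normals * dirs).sum(axis=1) > 0)

    def test_rejects_non_increasing_radii(self):
        with pytest.raises(ValueError, match="radii"):
            om.make_head_geometry(white_radius_mm=72, pial_radius_mm=70)

    def test_seeded_reproducibility(self):
        a, _ = om.make_head_geometry(subdivisions=2, bump_amplitude_mm=2, seed=3)
        b, _ = om.make_head_geometry(subdivisions=2, bump_amplitude_mm=2, seed=3)
        assert np.array_equal(a.pial.vertices, b.pial.vertices)


class TestPacking:
    def test_pairwise_distances_respect_minimum(self, small_head):
        # brute-force O(n^2) oracle
        _, scalp = small_head
        arr = om.pack_sensors(scalp, 40.0, seed=2)
        d = np.linalg.norm(
            arr.positions[:, None] - arr.positions[None, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 40.0

    def test_packing_is_maximal(self, small_head):
        _, scalp = small_head
        arr = om.pack_sensors(scalp, 40.0, seed=2)
        d = np.linalg.norm(
            scalp.vertices[:, None] - arr.positions[None, :], axis=-1
        )
        assert np.all(d.min(axis=1) < 40.0)  # no vertex could still be added

    def test_single_sensor_when_distance_exceeds_diameter(self, small_head):
        _, scalp = small_head
        arr = om.pack_sensors(scalp, 2 * 85.0 + 10.0, seed=0)
        assert arr.n_sensors == 1

    @pytest.mark.parametrize("d", [60.0, 40.0, 24.0])
    def test_halving_distance_never_reduces_count(self, small_head, d):
        _, scalp = small_head
        n_coarse = om.pack_sensors(scalp, d, seed=4).n_sensors
        n_fine = om.pack_sensors(scalp, d / 2, seed=4).n_sensors
        assert n_fine >= n_coarse

    def test_rejects_bad_inputs(self, small_head):
        _, scalp = small_head
        with pytest.raises(ValueError):
            om.pack_sensors(scalp, 0.0)


class TestChannelAxes:
    def test_reference_radial_gives_published_tangentials(self, small_head):
        # radial [1,0,0]: axis2 = [0,-1,0] (the [y,-x,0] rule), axis3 = r x axis2
        t1, t2 = _tangential_axes(np.array([[1.0, 0.0, 0.0]]))
        assert np.allclose(t1[0], [0.0, -1.0, 0.0], atol=1e-12)
        assert np.allclose(t2[0], [0.0, 0.0, -1.0], atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1, 1), min_size=3, max_size=3))
    def test_orthonormal_triads(self, vec):
        v = np.asarray(vec)
        n = np.linalg.norm(v)
        if n < 1e-3:
            return
        r = (v / n)[None, :]
        t1, t2 = _tangential_axes(r)
        triad = np.vstack([r, t1, t2])
        assert np.allclose(triad @ triad.T, np.eye(3), atol=1e-9)
        assert abs(float(r[0] @ t1[0])) < 1e-12

    def test_degenerate_z_radial_uses_fallback(self):
        t1, t2 = _tangential_axes(np.array([[0.0, 0.0, 1.0]]))
        triad = np.vstack([[0.0, 0.0, 1.0], t1[0], t2[0]])
        assert np.allclose(triad @ triad.T, np.eye(3), atol=1e-9)

    def test_axis_counts_and_validation(self, small_head):
        _, scalp = small_head
        arr = om.pack_sensors(scalp, 50.0, seed=0)
        for n_axes in (1, 2, 3):
            a = om.build_channel_axes(arr, n_axes)
            a.validate()
            assert a.n_channels == a.n_sensors * n_axes
        with pytest.raises(ValueError):
            om.build_channel_axes(arr, 4)


class TestOffsets:
    def test_identity_when_target_equals_current(self, small_head):
        _, scalp = small_head
        arr = om.offset_sensors(om.pack_sensors(scalp, 50.0, seed=0), scalp, 6.5)
        again = om.offset_sensors(arr, scalp, 6.5)
        assert np.allclose(arr.positions, again.positions, atol=1e-9)

    @pytest.mark.parametrize("offset", [6.5, 20.0, 30.0, 40.0])
    def test_offset_sweep_against_ray_sphere_oracle(self, small_head, offset):
        # on the exact-sphere scalp, the along-axis distance from sensor to
        # scalp solves |p - s a| = R; compare the smallest positive root
        _, scalp = small_head
        arr = om.offset_sensors(om.pack_sensors(scalp, 50.0, seed=0), scalp, offset)
        r_scalp = 85.0
        for p, a in zip(arr.positions, arr.radial_axes):
            b = -2 * p @ a
            c = p @ p - r_scalp**2
            roots = np.roots([1.0, b, c])
            s = min(r for r in roots.real if r > -1e-9)
            assert abs(s - offset) < 1e-6
        assert arr.offset_mm == offset


class TestCoregistrationError:
    def test_zero_sd_is_exact_noop(self, small_head):
        _, scalp = small_head
        arr = om.pack_sensors(scalp, 50.0, seed=0)
        new, tf = om.perturb_fiducials(arr, 0.0, seed=9)
        assert np.array_equal(new.positions, arr.positions)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(tf.translation, 0.0, atol=1e-9)

    @pytest.mark.parametrize("sd", [1.0, 4.0])
    def test_mean_squared_displacement_matches_chi2(self, small_head, sd):
        # E|displacement|^2 per fiducial = 3 sd^2
        _, scalp = small_head
        arr = om.pack_sensors(scalp, 60.0, seed=0)
        true_f = arr.fiducial_matrix()
        sq = []
        for seed in range(10_000):
            new, _ = om.perturb_fiducials(arr, sd, seed=seed)
            sq.append(((new.fiducial_matrix() - true_f) ** 2).sum(axis=1))
        mean_sq = np.mean(sq)
        assert abs(mean_sq / (3 * sd**2) - 1.0) < 0.02

    def test_axes_stay_orthonormal_and_transform_is_rigid(self, small_head):
        _, scalp = small_head
        arr = om.build_channel_axes(om.pack_sensors(scalp, 50.0, seed=0), 3)
        new, tf = om.perturb_fiducials(arr, 3.0, seed=1)
        new.validate()
        assert abs(np.linalg.det(tf.rotation) - 1.0) < 1e-9
        # sensor-to-sensor distances preserved by a rigid transform
        d_old = np.linalg.norm(arr.positions[0] - arr.positions[-1])
        d_new = np.linalg.norm(new.positions[0] - new.positions[-1])
        assert abs(d_old - d_new) < 1e-9

    def test_sd_sweep_supported(self, small_head):
        _, scalp = small_head
        arr = om.pack_sensors(scalp, 60.0, seed=0)
        for sd in (1.0, 2.0, 3.0, 4.0):
            new, _ = om.perturb_fiducials(arr, sd, seed=2)
            assert new.n_sensors == arr.n_sensors


class TestAlternativeGeometry:
    def test_identity_when_unperturbed(self, small_head):
        space, scalp = small_head
        arr = om.pack_sensors(scalp, 50.0, seed=0)
        n_dense = 10 * 4 ** (space.build_params["subdivisions"] + 1) + 2
        frac = space.white.n_vertices / n_dense
        alt_space, alt_arr = om.make_alternative_geometry(
            space, arr, sensor_jitter_sd_mm=0.0, alt_vertex_fraction=frac, seed=1
        )
        assert alt_space is space
        assert np.array_equal(alt_arr.positions, arr.positions)

    def test_default_fraction_moves_every_dipole(self, small_head):
        space, scalp = small_head
        arr = om.pack_sensors(scalp, 50.0, seed=0)
        alt_space, _ = om.make_alternative_geometry(space, arr, seed=1)
        assert alt_space.white.n_vertices != space.white.n_vertices
        # no shared exact coordinates between the two source spaces
        a = {tuple(np.round(v, 6)) for v in alt_space.pial.vertices}
        b = {tuple(np.round(v, 6)) for v in space.pial.vertices}
        assert not (a & b)
        alt_space.validate()
        alt_space.pial.validate()

    def test_jitter_sd_recovered_empirically(self, small_head):
        space, scalp = small_head
        arr = om.pack_sensors(scalp, 50.0, seed=0)
        n_dense = 10 * 4 ** (space.build_params["subdivisions"] + 1) + 2
        frac = space.white.n_vertices / n_dense
        deltas = []
        for seed in range(60):
            _, alt_arr = om.make_alternative_geometry(
                space, arr, sensor_jitter_sd_mm=1.0, alt_vertex_fraction=frac, seed=seed
            )
            deltas.append(alt_arr.positions - arr.positions)
        sd = np.concatenate(deltas).std()
        assert abs(sd - 1.0) < 0.05

    def test_rejects_bad_fraction(self, small_head):
        space, scalp = small_head
        arr = om.pack_sensors(scalp, 50.0, seed=0)
        with pytest.raises(ValueError):
            om.make_alternative_geometry(space, arr, alt_vertex_fraction=1.5)
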