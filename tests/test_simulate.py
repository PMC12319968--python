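"""Source simulation: geodesics, Gaussian patches, sinusoidal trials,
white-noise SNR control, and interfering brain-noise sources."""

import numpy as np
import pytest

import opmlaminar as om
from opmlaminar.simulate import FWHM_TO_SIGMA, signal_amplitude


def hexagon_mesh(spacing=1.0):
    """Centre vertex with a 6-ring at exactly ``spacing`` geodesic distance."""
    ang = np.linspace(0, 2 * np.pi, 7)[:-1]
    verts = np.vstack(
        [[0.0, 0.0, 0.0], np.c_[spacing * np.cos(ang), spacing * np.sin(ang), np.zeros(6)]]
    )
    faces = np.array([[0, 1 + i, 1 + (i + 1) % 6] for i in range(6)])
    normals = np.tile([0.0, 0.0, 1.0], (7, 1))
    return om.SurfaceMesh(verts, faces, normals)


class TestGeodesics:
    def test_distance_to_self_is_zero(self, small_head):
        space, _ = small_head
        idx, d = om.geodesic_distances(space.pial, 17, 20.0)
        assert d[idx == 17] == 0.0

    def test_matches_networkx_dijkstra(self):
        # brute-force oracle on a small (162-vertex) mesh
        import networkx as nx

        space, _ = om.make_head_geometry(subdivisions=2)
        mesh = space.pial
        g = nx.Graph()
        for e in mesh.edges():
            w = float(np.linalg.norm(mesh.vertices[e[0]] - mesh.vertices[e[1]]))
            g.add_edge(int(e[0]), int(e[1]), weight=w)
        ref = nx.single_source_dijkstra_path_length(g, 0, weight="weight")
        idx, d = om.geodesic_distances(mesh, 0, 60.0)
        for i, di in zip(idx, d):
            assert abs(ref[int(i)] - di) < 1e-12
        # and nothing within range was missed
        assert set(idx.tolist()) == {k for k, v in ref.items() if v <= 60.0}

    def test_graph_distance_brackets_great_circle(self, small_head):
        # chord-weighted graph paths are bounded below by the straight-line
        # distance and approximate the great-circle arc within the
        # chord-vs-arc shortening of one mesh edge (sub-percent here)
        space, _ = small_head
        mesh = space.pial
        idx, d = om.geodesic_distances(mesh, 0, 40.0)
        r = 72.0
        u0 = mesh.vertices[0] / np.linalg.norm(mesh.vertices[0])
        for i, di in zip(idx, d):
            if i == 0:
                continue
            ui = mesh.vertices[i] / np.linalg.norm(mesh.vertices[i])
            arc = r * np.arccos(np.clip(u0 @ ui, -1, 1))
            chord = np.linalg.norm(mesh.vertices[int(i)] - mesh.vertices[0])
            assert di >= chord - 1e-9
            assert di >= 0.98 * arc
            assert di <= 1.25 * arc  # detour overhead stays bounded

    def test_invalid_vertex_rejected(self, small_head):
        space, _ = small_head
        with pytest.raises(ValueError):
            om.geodesic_distances(space.pial, -1, 10.0)


class TestGaussianPatch:
    def test_sigma_from_fwhm(self, small_head):
        space, _ = small_head
        patch = om.gaussian_patch(space.pial, 10, 5.0)
        assert patch.sigma_mm == pytest.approx(2.1231, abs=1e-4)

    def test_weights_sum_to_one_and_truncate(self, small_head):
        space, _ = small_head
        patch = om.gaussian_patch(space.pial, 10, 12.0)
        assert abs(patch.weights.sum() - 1.0) < 1e-12
        _, d = om.geodesic_distances(space.pial, 10, 12.0)
        assert len(patch.vertex_indices) == len(d)  # nothing beyond one FWHM

    def test_half_maximum_at_half_width(self):
        # ring at exactly FWHM/2: unnormalised weight = exp(-(FWHM/2)^2/2s^2),
        # which is 0.5 of the centre weight by the definition of the FWHM
        # (up to the 2.355 ~ 2 sqrt(2 ln 2) rounding)
        mesh = hexagon_mesh(spacing=1.0)
        fwhm = 2.0
        patch = om.gaussian_patch(mesh, 0, fwhm)
        w = patch.dense_weights(7)
        ratio = w[1] / w[0]
        expected = np.exp(-1.0 / (2 * (fwhm * FWHM_TO_SIGMA) ** 2))
        assert ratio == pytest.approx(expected, abs=1e-12)
        assert ratio == pytest.approx(0.5, abs=1e-4)

    def test_degenerate_patch_warns(self, small_head):
        space, _ = small_head
        with pytest.warns(UserWarning, match="single vertex"):
            patch = om.gaussian_patch(space.pial, 10, 1.0)
        assert patch.weights.sum() == 1.0
        assert len(patch.vertex_indices) == 1

    def test_maximum_at_centre(self, small_head):
        space, _ = small_head
        patch = om.gaussian_patch(space.pial, 10, 12.0)
        centre_w = patch.weights[patch.vertex_indices == 10][0]
        assert centre_w == patch.weights.max()


class TestSimulateSignal:
    def test_silence_outside_active_window(self, small_setup):
        space = small_setup["space"]
        patch = om.gaussian_patch(space.pial, 100, 10.0)
        ds = om.simulate_signal(patch, small_setup["lf_pial"], n_trials=3)
        t_ms = ds.times * 1000
        outside = (t_ms < 100.0) | (t_ms >= 500.0)
        assert np.all(ds.data[:, :, outside] == 0.0)

    def test_amplitude_linearity(self, small_setup):
        space = small_setup["space"]
        patch = om.gaussian_patch(space.pial, 100, 10.0)
        a = om.simulate_signal(patch, small_setup["lf_pial"], amplitude_nam=10, n_trials=2)
        b = om.simulate_signal(patch, small_setup["lf_pial"], amplitude_nam=20, n_trials=2)
        assert np.allclose(2 * a.data, b.data)

    def test_rms_of_sinusoid_over_whole_cycles(self, small_setup):
        # 20 Hz x 400 ms = 8 whole cycles: RMS = peak / sqrt(2)
        space = small_setup["space"]
        patch = om.gaussian_patch(space.pial, 100, 10.0)
        ds = om.simulate_signal(patch, small_setup["lf_pial"], n_trials=1)
        active = (ds.times * 1000 >= 100) & (ds.times * 1000 < 500)
        # analytic per-channel amplitude from the patch-weighted lead field
        pattern = small_setup["lf_pial"].gain[:, patch.vertex_indices] @ (
            patch.weights * 10.0
        )
        chan = np.abs(pattern).argmax()
        rms = np.sqrt((ds.data[0, chan, active] ** 2).mean())
        assert rms == pytest.approx(abs(pattern[chan]) / np.sqrt(2), rel=5e-3)

    def test_rejects_super_nyquist(self, small_setup):
        space = small_setup["space"]
        patch = om.gaussian_patch(space.pial, 100, 10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            om.simulate_signal(patch, small_setup["lf_pial"], freq_hz=120.0)


class TestSensorNoise:
    def test_noise_amplitude_closed_forms(self, dataset_factory):
        ds0 = dataset_factory(snr_db=0.0)
        assert ds0.noise_record["a_noise"] == ds0.noise_record["a_signal"]
        ds2 = dataset_factory(snr_db=-20.0)
        assert ds2.noise_record["a_noise"] == pytest.approx(
            10 * ds2.noise_record["a_signal"], rel=1e-12
        )

    def test_requested_snr_recovered_empirically(self, small_setup):
        # Monte-Carlo round trip of the SNR definition at -5 dB
        space = small_setup["space"]
        patch = om.gaussian_patch(space.pial, 100, 10.0)
        base = om.simulate_signal(patch, small_setup["lf_pial"], n_trials=4)
        a_sig = signal_amplitude(base)
        snrs = []
        for seed in range(50):
            ds = om.add_noise(base, om.SnrSpec("per_trial_snr", -5.0), seed=seed)
            a_noise = (ds.data - base.data).std(axis=2).mean()
            snrs.append(20 * np.log10(a_sig / a_noise))
        assert abs(np.mean(snrs) - (-5.0)) < 0.2

    def test_trial_averaging_gain(self, small_setup):
        # averaging 200 iid-noise trials improves amplitude SNR by
        # 10 log10(200) = 23.01 dB
        space = small_setup["space"]
        patch = om.gaussian_patch(space.pial, 100, 10.0)
        base = om.simulate_signal(patch, small_setup["lf_pial"], n_trials=200)
        ds = om.add_noise(base, om.SnrSpec("per_trial_snr", -5.0), seed=3)
        a_sig = ds.noise_record["a_signal"]
        noise_avg = (ds.data - base.data).mean(axis=0)
        snr_avg = 20 * np.log10(a_sig / noise_avg.std(axis=1).mean())
        assert abs((snr_avg - (-5.0)) - 23.01) < 0.3

    def test_fixed_magnitude_mode_ignores_signal(self, small_setup):
        space = small_setup["space"]
        patch = om.gaussian_patch(space.pial, 100, 10.0)
        weak = om.simulate_signal(patch, small_setup["lf_pial"], amplitude_nam=1, n_trials=2)
        strong = om.simulate_signal(patch, small_setup["lf_pial"], amplitude_nam=100, n_trials=2)
        spec = om.SnrSpec("fixed_magnitude", 30.0, reference_amplitude=1e-3)
        a = om.add_noise(weak, spec, seed=0).noise_record["a_noise"]
        b = om.add_noise(strong, spec, seed=0).noise_record["a_noise"]
        assert a == b == pytest.approx(1e-3 * 10 ** (30 / 20), rel=1e-12)

    def test_double_noising_rejected(self, dataset_factory):
        ds = dataset_factory()
        with pytest.raises(ValueError):
            om.add_noise(ds, om.SnrSpec("per_trial_snr", -5.0))

    def test_seeded_reproducibility(self, small_setup):
        space = small_setup["space"]
        patch = om.gaussian_patch(space.pial, 100, 10.0)
        base = om.simulate_signal(patch, small_setup["lf_pial"], n_trials=3)
        a = om.add_noise(base, om.SnrSpec("per_trial_snr", -10.0), seed=5)
        b = om.add_noise(base, om.SnrSpec("per_trial_snr", -10.0), seed=5)
        assert np.array_equal(a.data, b.data)


class TestBrainNoise:
    @pytest.fixture()
    def mid_setup(self, small_setup):
        space = small_setup["space"]
        lf_mid = om.leadfield_for_surface(
            space.mid, small_setup["array"], small_setup["conductor"], "mid"
        )
        patch = om.gaussian_patch(space.pial, 100, 10.0)
        base = om.simulate_signal(patch, small_setup["lf_pial"], n_trials=5)
        return space, lf_mid, base

    def test_zero_strength_is_identity(self, mid_setup):
        space, lf_mid, base = mid_setup
        out = om.add_brain_noise(base, lf_mid, space.mid, relative_strength=0.0)
        assert np.array_equal(out.data, base.data)

    def test_band_limited_spectrum(self):
        # periodogram oracle on a long realisation: power outside 10-30 Hz
        # must be < 1% of the in-band power
        from scipy.signal import periodogram

        rng = np.random.default_rng(0)
        x = om.band_limited_noise(rng, 2**14, 200.0, (10.0, 30.0))
        f, p = periodogram(x, fs=200.0)
        inside = (f >= 10.0) & (f <= 30.0)
        assert p[~inside].sum() < 0.01 * p[inside].sum()

    def test_amplitude_scales_linearly(self, mid_setup):
        space, lf_mid, base = mid_setup
        a = om.add_brain_noise(base, lf_mid, space.mid, relative_strength=0.2, seed=4)
        b = om.add_brain_noise(base, lf_mid, space.mid, relative_strength=0.4, seed=4)
        ratio = np.linalg.norm(b.data - base.data) / np.linalg.norm(a.data - base.data)
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_coherent_flag_repeats_waveform(self, mid_setup):
        space, lf_mid, base = mid_setup
        out = om.add_brain_noise(
            base, lf_mid, space.mid, n_sources=2, seed=4, coherent_across_trials=True
        )
        added = out.data - base.data
        assert np.allclose(added[0], added[1])
        out2 = om.add_brain_noise(base, lf_mid, space.mid, n_sources=2, seed=4)
        added2 = out2.data - base.data
        assert not np.allclose(added2[0], added2[1])

    def test_too_many_sources_rejected(self, mid_setup):
        space, lf_mid, base = mid_setup
        with pytest.raises(ValueError):
            om.add_brain_noise(base, lf_mid, space.mid, n_sources=10_000)
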