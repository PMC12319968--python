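"""Simulate noisy OPM trials from a Gaussian cortical patch.

Places a 20 Hz sinusoidal patch source on the pial surface, projects it
through the lead field, and adds white sensor noise at a requested
single-trial SNR.  The printed round trip verifies the SNR definition and
the 10*log10(N) amplitude-SNR gain of trial averaging.
"""

import numpy as np

import opmlaminar as om

space, scalp = om.make_head_geometry(subdivisions=3)
arr = om.offset_sensors(
    om.build_channel_axes(om.pack_sensors(scalp, 45.0, seed=1), 1), scalp, 6.5
)
conductor = om.fit_conductor(space.pial, arr)
lf = om.leadfield_for_surface(space.pial, arr, conductor, "pial")

patch = om.gaussian_patch(space.pial, v0=100, fwhm_mm=10.0)
print(f"patch at vertex 100: {len(patch.vertex_indices)} vertices, "
      f"sigma {patch.sigma_mm:.3f} mm, weights sum {patch.weights.sum():.6f}")

base = om.simulate_signal(patch, lf, amplitude_nam=10.0, n_trials=200)
ds = om.add_noise(base, om.SnrSpec("per_trial_snr", -5.0), seed=0)
rec = ds.noise_record
print(f"A_signal {rec['a_signal']:.4f} fT, A_noise {rec['a_noise']:.4f} fT "
      f"(requested -5 dB single-trial SNR)")

a_sig = rec["a_signal"]
single = 20 * np.log10(a_sig / (ds.data[0] - base.data[0]).std(axis=1).mean())
avg = 20 * np.log10(a_sig / (ds.data - base.data).mean(axis=0).std(axis=1).mean())
print(f"empirical single-trial SNR {single:+.2f} dB; trial-averaged {avg:+.2f} dB; "
      f"gain {avg - single:.2f} dB (10*log10(200) = 23.01)")

# interfering mid-cortical brain noise, 40% of the source strength
lf_mid = om.leadfield_for_surface(space.mid, arr, conductor, "mid")
noisy = om.add_brain_noise(base, lf_mid, space.mid, n_sources=5,
                           relative_strength=0.4, seed=1)
added = noisy.data - base.data
print(f"5 brain-noise sources add {added.std():.4f} fT RMS at the sensors "
      f"(band-limited 10-30 Hz, coherent source locations across trials)")
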