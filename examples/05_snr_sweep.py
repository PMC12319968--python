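"""A small laminar-classification sweep across SNR levels.

Repeats laminar inference for several sources on each surface at two SNRs,
summarises percent-correct / percent-pial / percent-significant, and tests
the accuracy against the 50% chance level with an exact binomial test.
Full-size study sweeps use the same configuration object with more
sources, conditions, and trials.
"""

import warnings

import opmlaminar as om

warnings.filterwarnings("ignore", message="patch at vertex")

config = om.SweepConfig(
    noise_db=[-5.0, -30.0],
    spacing_mm=[45.0],
    n_sources=5,
    methods=["EBB"],
    analyses=["whole_brain", "roi"],
    n_trials=30,
    subdivisions=3,
    master_seed=42,
)
table = om.run_sweep(config)
summary = om.summarize(table)
cols = ["noise_db", "analysis", "n", "pct_correct", "pct_pial", "pct_significant"]
print(summary[cols].to_string(index=False, float_format=lambda v: f"{v:.1f}"))

print()
for snr in (-5.0, -30.0):
    sel = table[(table.noise_db == snr) & (table.analysis == "roi")]
    k = int(sel["correct"].sum())
    p = om.binomial_two_sided(k, len(sel))
    verdict = "above chance" if p < 0.05 and k > len(sel) / 2 else "not above chance"
    print(f"ROI analysis at {snr:+.0f} dB: {k}/{len(sel)} correct, "
          f"exact binomial p = {p:.4f} ({verdict})")
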