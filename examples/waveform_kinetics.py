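"""Measure waveform kinetics (FW, PP) and classify cell types.

Draws broad (excitatory-like) and narrow (fast-spiking inhibitory-like)
spike templates, resamples them with a cubic spline at 90 kHz, measures the
full width at half-maximum (FW) and trough-to-peak duration (PP), and
clusters the population into putative E and I classes.
"""

import numpy as np

from spikemap import (
    classify_ei,
    interpolate_waveform,
    make_spike_template,
    measure_kinetics,
)

fs = 18000.0
rng = np.random.default_rng(0)

kinetics, truth = [], []
for uid in range(40):
    cls = "narrow" if uid < 6 else "broad"  # ~15% fast-spiking
    wf, params = make_spike_template(cls, fs, rng, amplitude_uv=150.0)
    t_ms, dense = interpolate_waveform(wf, fs, query_hz=90000.0)
    kin = measure_kinetics(t_ms, dense, unit_id=uid)
    kinetics.append(kin)
    truth.append(cls)
    if uid < 3 or uid in (6, 7):
        print(f"unit {uid:2d} ({cls:6s}): FW = {kin.fw_ms:.3f} ms, "
              f"PP = {kin.pp_ms:.3f} ms")

results = classify_ei(kinetics, k=2, seed=0)
acc = np.mean([
    (r.label == "I") == (t == "narrow") for r, t in zip(results, truth)
])
n_i = sum(r.label == "I" for r in results)
print(f"\nk-means on standardized (FW, PP): {n_i} units labeled I, "
      f"{len(results) - n_i} labeled E; accuracy vs simulated class: {acc:.0%}")
# Narrow templates have sub-0.5 ms FW and PP; the cluster with the fastest
# time constants is labeled inhibitory, matching fast-spiking physiology.
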