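"""Optogenetic validation of cell-type labels with evoked z-scores.

Simulates spike trains under a 2 min baseline / 2 min opto-on protocol where
narrow (opsin-expressing) units quintuple their firing rate during light
delivery, scores every unit's photostimulation-evoked z-score, and
summarizes responder fractions per cell class.
"""

import numpy as np

from spikemap import (
    SimulationConfig,
    StimulusProtocol,
    evoked_zscore,
    simulate_spike_trains,
    summarize_classification,
)
from spikemap.cell_typing import CellTypeResult

protocol = StimulusProtocol(
    epochs=[("baseline", 0.0, 120.0), ("opto-on", 120.0, 240.0)],
    light_pulse_times_s=list(np.arange(120.0, 240.0, 10.0)),
    pulse_duration_ms=100.0,
)
cfg = SimulationConfig(
    duration_s=240.0, n_units=40, narrow_fraction=0.2,
    protocol=protocol, opto_gain_narrow=5.0, seed=7,
)
units = simulate_spike_trains(cfg, np.random.default_rng(7))

responses, labels = [], []
for u in units:
    r = evoked_zscore(u.times_s, protocol, unit_id=u.unit_id)
    responses.append(r)
    labels.append(CellTypeResult(u.unit_id, "I" if u.cls == "narrow" else "E", 0))
    if u.cls == "narrow" and len([x for x in labels if x.label == "I"]) <= 3:
        print(f"unit {u.unit_id:2d} (narrow, gain x5): baseline "
              f"{r.baseline_mean_hz:.2f} Hz, opto-on {r.evoked_hz:.2f} Hz, "
              f"z = {r.z:.1f} -> responder: {r.responder}")

df = summarize_classification(responses, labels)
print("\nresponder summary (z > 3 during opto-on):")
print(df.round(2))
# Opsin-gained narrow units show z-scores far above the z > 3 responder
# criterion, while unmodulated broad units almost never cross it: the evoked
# z-score cleanly separates light-driven cells from the rest.
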