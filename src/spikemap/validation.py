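"""Self-contained validation studies on synthetic ground truth.

These routines regenerate their own inputs from a seed and measure how well
the pipeline recovers known quantities: the chance level of the LDA
separability score, end-to-end unit recovery / soma localization / E-I
labeling accuracy, and optogenetic responder detection.  They are used by
the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import gc

import numpy as np

from . import match_units
from .opto_validation import StimulusProtocol, evoked_zscore
from .pipeline import PipelineConfig, sort_recording
from .synthetic_data import SimulationConfig, simulate_recording, simulate_spike_trains
from .unit_isolation import lda_separability_cv

__all__ = [
    "lda_chance_error",
    "recovery_study",
    "opto_responder_study",
]


def lda_chance_error(
    n_per_class: int = 500,
    n_seeds: int = 20,
    base_seed: int = 0,
    separation: float = 0.0,
) -> float:
    """Mean tenfold CV LDA error for two classes drawn from one 2-D Gaussian.

    With ``separation=0`` the labels carry no information, so the expected
    error is the 0.5 chance level.  Each repetition draws fresh samples and
    runs the cross-validation with its own seed.
    """
    errs = []
    for i in range(n_seeds):
        seed = (base_seed * 1009 + i) % (2**31 - 1)
        r = np.random.default_rng(seed)
        X = np.vstack([
            r.normal(0.0, 1.0, size=(n_per_class, 2)),
            r.normal([separation, 0.0], 1.0, size=(n_per_class, 2)),
        ])
        y = np.repeat([0, 1], n_per_class)
        errs.append(lda_separability_cv(X, y, folds=10, seed=seed))
    return float(np.mean(errs))


def recovery_study(
    n_seeds: int = 10,
    base_seed: int = 0,
    duration_s: float = 120.0,
) -> dict[str, float]:
    """End-to-end parameter recovery on the default simulated conditions.

    For each seed, a 16x16-grid, 20-unit, 10%-narrow recording is simulated,
    sorted with default parameters, and the accepted units are matched to
    ground truth by soma position (one-pitch tolerance).  Aggregated over
    seeds, the study reports the fraction of ground-truth units recovered,
    the fraction of matched units whose soma channel center lies within one
    pitch of the true soma, and the E/I label accuracy on matched units.
    """
    n_truth = n_matched = n_soma_ok = n_labeled = n_label_ok = 0
    for i in range(n_seeds):
        seed = (base_seed * 7919 + i) % (2**31 - 1)
        sim = SimulationConfig(duration_s=duration_s, seed=seed)
        rec, truth, _ = simulate_recording(sim)
        res = sort_recording(rec, PipelineConfig(seed=seed), in_place=True)
        est = {
            u.unit_id: (res.locations[u.unit_id].x_um, res.locations[u.unit_id].y_um)
            for u in res.accepted_units
            if u.unit_id in res.locations
        }
        matched = match_units(truth, est, tol_um=sim.pitch_um)
        by_id = {u.unit_id: u for u in truth}
        n_truth += len(truth)
        n_matched += len(matched)
        for tid, eid in matched.items():
            loc = res.locations[eid]
            t = by_id[tid]
            d_home = np.hypot(
                loc.home_col * sim.pitch_um - t.x_um,
                loc.home_row * sim.pitch_um - t.y_um,
            )
            n_soma_ok += d_home <= sim.pitch_um
            if eid in res.cell_types:
                n_labeled += 1
                want = "I" if t.cls == "narrow" else "E"
                n_label_ok += res.cell_types[eid].label == want
        del rec, res
        gc.collect()
    return {
        "recovery": n_matched / n_truth,
        "soma_within_pitch": n_soma_ok / max(n_matched, 1),
        "ei_accuracy": n_label_ok / max(n_labeled, 1),
        "n_truth": n_truth,
    }


def opto_responder_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    opto_gain: float = 5.0,
) -> dict[str, float]:
    """Responder (z > 3) rates for opsin-gained vs unmodulated units.

    Simulates spike trains under a 2 min baseline / 2 min opto-on protocol
    with ``opto_gain`` on narrow units, and scores each ground-truth train
    with the photostimulation-evoked z-score.
    """
    proto = StimulusProtocol(
        epochs=[("baseline", 0.0, 120.0), ("opto-on", 120.0, 240.0)],
        light_pulse_times_s=list(np.arange(120.0, 240.0, 10.0)),
    )
    gained, ungained = [], []
    for i in range(n_seeds):
        seed = (base_seed * 6151 + i) % (2**31 - 1)
        cfg = SimulationConfig(
            duration_s=240.0, protocol=proto, opto_gain_narrow=opto_gain, seed=seed
        )
        units = simulate_spike_trains(cfg, np.random.default_rng(seed))
        for u in units:
            r = evoked_zscore(u.times_s, proto, unit_id=u.unit_id)
            (gained if u.opto_gain > 1 else ungained).append(r.responder)
    return {
        "gained_responder_rate": float(np.mean(gained)),
        "ungained_responder_rate": float(np.mean(ungained)),
        "n_gained": len(gained),
        "n_ungained": len(ungained),
    }
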