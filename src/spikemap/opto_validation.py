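"""Optogenetic validation: PSTH, photostimulation-evoked z-score, summaries.

A step-function opsin protocol alternates baseline / opto-on / opto-off
epochs with brief (100 ms) blue-light pulses during opto-on.  Each unit's
light response is summarized as a z-score: the mean firing rate in the
response epoch expressed in SDs of the baseline rate, where baseline
variability is measured over non-overlapping 1 s bins.  Units with z > 3 are
labeled responders; comparing responder fractions across waveform-based E/I
labels validates the classification (opsin-expressing interneurons should be
strongly enriched among responders).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cell_typing import CellTypeResult

__all__ = [
    "StimulusProtocol",
    "ResponseSummary",
    "compute_psth",
    "evoked_zscore",
    "compare_psth_conditions",
    "summarize_classification",
]


@dataclass
class StimulusProtocol:
    """Ordered, non-overlapping labeled epochs plus light-pulse onsets."""

    epochs: list[tuple[str, float, float]]  # (label, t_start_s, t_end_s)
    light_pulse_times_s: list[float] = field(default_factory=list)
    pulse_duration_ms: float = 100.0

    def __post_init__(self) -> None:
        eps = sorted(self.epochs, key=lambda e: e[1])
        for (la, a0, a1), (lb, b0, b1) in zip(eps, eps[1:]):
            if a1 > b0 + 1e-12:
                raise ValueError(f"epochs {la!r} and {lb!r} overlap")
        for _, t0, t1 in eps:
            if t1 <= t0:
                raise ValueError("epoch end must exceed start")
        self.epochs = eps

    def epoch(self, label: str) -> tuple[float, float]:
        for lab, t0, t1 in self.epochs:
            if lab == label:
                return t0, t1
        raise KeyError(f"no epoch labeled {label!r}")

    @property
    def t_end_s(self) -> float:
        return self.epochs[-1][2]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StimulusProtocol":
        with open(path) as f:
            d = yaml.safe_load(f)
        return cls(
            epochs=[(e["label"], float(e["t_start_s"]), float(e["t_end_s"])) for e in d["epochs"]],
            light_pulse_times_s=[float(t) for t in d.get("light_pulse_times_s", [])],
            pulse_duration_ms=float(d.get("pulse_duration_ms", 100.0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "epochs": [
                {"label": lab, "t_start_s": t0, "t_end_s": t1} for lab, t0, t1 in self.epochs
            ],
            "light_pulse_times_s": list(map(float, self.light_pulse_times_s)),
            "pulse_duration_ms": self.pulse_duration_ms,
        }
        with open(path, "w") as f:
            yaml.safe_dump(d, f)


@dataclass
class ResponseSummary:
    """Photostimulation-evoked firing-rate change of one unit."""

    unit_id: int
    baseline_mean_hz: float
    baseline_sd_hz: float
    evoked_hz: float
    z: float  # nan sentinel when baseline SD is 0
    responder: bool


def compute_psth(
    trains: dict[int, np.ndarray],
    protocol: StimulusProtocol,
    bin_ms: float = 50.0,
    window_s: tuple[float, float] = (-1.0, 3.0),
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Peri-stimulus time histogram per unit, averaged over light pulses.

    Returns ``(bin_left_edges_s, {unit_id: rate_hz_per_bin})``.  Counts are
    aligned to each pulse onset, averaged across pulses, and scaled to Hz, so
    the PSTH integral over the window equals the mean spikes per trial.
    """
    pulses = np.asarray(protocol.light_pulse_times_s, dtype=float)
    if pulses.size == 0:
        raise ValueError("protocol has no light pulses")
    bin_s = bin_ms / 1000.0
    lo, hi = window_s
    edges = np.arange(lo, hi + bin_s / 2, bin_s)
    out: dict[int, np.ndarray] = {}
    for uid, times in trains.items():
        t = np.asarray(times, dtype=float)
        acc = np.zeros(len(edges) - 1)
        for p in pulses:
            acc += np.histogram(t - p, bins=edges)[0]
        out[uid] = acc / (pulses.size * bin_s)
    return edges[:-1], out


def epoch_rate_hz(times_s: np.ndarray, t0: float, t1: float) -> float:
    t = np.asarray(times_s)
    return float(((t >= t0) & (t < t1)).sum() / (t1 - t0))


def evoked_zscore(
    times_s: np.ndarray,
    protocol: StimulusProtocol,
    baseline_bin_s: float = 1.0,
    baseline_epoch: str = "baseline",
    response_epoch: str = "opto-on",
    unit_id: int = -1,
    z_threshold: float = 3.0,
) -> ResponseSummary:
    """Photostimulation-evoked z-score of one spike train.

    ``z = (mean rate in the response epoch - mean baseline-bin rate) / SD of
    baseline-bin rates``, with baseline rates from non-overlapping
    ``baseline_bin_s`` bins of the baseline epoch.  Responder iff
    ``z > z_threshold`` (default 3).  A zero baseline SD yields ``z = nan``
    and responder False.
    """
    b0, b1 = protocol.epoch(baseline_epoch)
    r0, r1 = protocol.epoch(response_epoch)
    n_bins = int(np.floor((b1 - b0) / baseline_bin_s))
    if n_bins < 10:
        raise ValueError("baseline epoch must contain at least 10 baseline bins")
    edges = b0 + np.arange(n_bins + 1) * baseline_bin_s
    counts, _ = np.histogram(np.asarray(times_s), bins=edges)
    base_rates = counts / baseline_bin_s
    mu, sd = float(base_rates.mean()), float(base_rates.std(ddof=1))
    evoked = epoch_rate_hz(times_s, r0, r1)
    if sd == 0:
        return ResponseSummary(unit_id, mu, sd, evoked, float("nan"), False)
    z = (evoked - mu) / sd
    return ResponseSummary(unit_id, mu, sd, evoked, float(z), bool(z > z_threshold))


def compare_psth_conditions(
    sample_a: np.ndarray, sample_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two rate samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs at least 3 observations")
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("degenerate all-tied samples; p = 1")
        return 0.0, 1.0
    res = stats.ranksums(a, b)
    return float(res.statistic), float(res.pvalue)


def summarize_classification(
    responses: list[ResponseSummary],
    labels: list[CellTypeResult],
) -> pd.DataFrame:
    """Per-label unit counts, responder counts, and percentage breakdown.

    Returns a DataFrame indexed by label with columns ``n``, ``n_responder``,
    ``pct_of_total`` (share of all classified units) and ``pct_responder``
    (responder share within the label).  Unit ids in the two lists must
    align.
    """
    resp_by_id = {r.unit_id: r for r in responses}
    lab_ids = {l.unit_id for l in labels}
    if set(resp_by_id) != lab_ids:
        raise ValueError("unit ids of responses and labels do not match")
    rows = {}
    total = len(labels)
    for lab in sorted({l.label for l in labels}):
        ids = [l.unit_id for l in labels if l.label == lab]
        n_resp = sum(resp_by_id[i].responder for i in ids)
        rows[lab] = {
            "n": len(ids),
            "n_responder": n_resp,
            "pct_of_total": 100.0 * len(ids) / total,
            "pct_responder": 100.0 * n_resp / len(ids) if ids else 0.0,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
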