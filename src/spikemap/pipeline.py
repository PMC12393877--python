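"""End-to-end orchestration: filter -> detect -> sort -> localize -> classify.

:func:`sort_recording` is the library entry point: it takes a raw recording
(and optionally a stimulation protocol) and returns a :class:`SortingResult`
bundle with putative units, soma locations, cell-type labels, optogenetic
response summaries and a QC report counting units rejected by each criterion
(SNR, LDA merging, minimum rate, amplitude decay, duplicate correlation).

:func:`run_pipeline` wraps it with file I/O for the command line: it reads a
YAML config, loads the recording, writes TSV/HDF5/JSON outputs into a run
directory and logs per-stage progress.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cell_typing, localization, opto_validation, spike_detection, unit_isolation
from .opto_validation import StimulusProtocol
from .recording_io import (
    DetectionConfig,
    Recording,
    read_recording,
    remove_artifacts,
)

__all__ = ["PipelineConfig", "SortingResult", "sort_recording", "run_pipeline"]

log = logging.getLogger("spikemap")


@dataclass
class PipelineConfig:
    """All tunable parameters of a pipeline run, with the standard defaults.

    Defaults follow the published protocol where one exists (300-5000 Hz
    order-2 Butterworth, x = 4.5 SD threshold, 2 ms refractory, -5..+5 ms
    window, 250 um soma radius, 90 kHz spline query, 100 ms correlation
    bins, z > 3 responders) and documented package choices elsewhere.
    """

    # filtering
    low_hz: float = 300.0
    high_hz: float = 5000.0
    filter_order: int = 2
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    # isolation
    k: int | str = 2
    k_max: int = 6
    merge_error_threshold: float = 0.4
    min_spikes: int = unit_isolation.MIN_SPIKES_FOR_CLUSTERING
    snr_min: float = 4.0
    min_rate_hz: float = 0.02
    n_pcs: int = 2
    # localization
    radius_um: float = 250.0
    corr_threshold: float = 0.5
    corr_bin_ms: float = 100.0
    # typing
    query_hz: float = 90000.0
    typing_k: int | str = "auto"  # Calinski-Harabasz selection over [2, k_max]
    # opto
    baseline_bin_s: float = 1.0
    z_threshold: float = 3.0
    protocol: StimulusProtocol | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            d = yaml.safe_load(f) or {}
        det = DetectionConfig(**d.pop("detection", {}))
        proto = d.pop("protocol", None)
        protocol = None
        if proto:
            protocol = StimulusProtocol(
                epochs=[(e["label"], float(e["t_start_s"]), float(e["t_end_s"])) for e in proto["epochs"]],
                light_pulse_times_s=[float(t) for t in proto.get("light_pulse_times_s", [])],
                pulse_duration_ms=float(proto.get("pulse_duration_ms", 100.0)),
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(detection=det, protocol=protocol, **d)


@dataclass
class SortingResult:
    """Outputs of a full run: tables plus the underlying unit objects."""

    units: list[unit_isolation.PutativeUnit]
    locations: dict[int, localization.SomaLocation]
    profiles: dict[int, localization.AmplitudeProfile]
    kinetics: dict[int, cell_typing.WaveformKinetics]
    cell_types: dict[int, cell_typing.CellTypeResult]
    responses: dict[int, opto_validation.ResponseSummary]
    qc: dict
    fs_hz: float = float("nan")

    @property
    def accepted_units(self) -> list[unit_isolation.PutativeUnit]:
        return [u for u in self.units if u.accepted]

    def units_table(self) -> pd.DataFrame:
        rows = []
        for u in self.units:
            loc = self.locations.get(u.unit_id)
            ct = self.cell_types.get(u.unit_id)
            kin = self.kinetics.get(u.unit_id)
            rows.append(
                {
                    "unit_id": u.unit_id,
                    "channel": u.channel,
                    "home_channel": loc.home_channel if loc else -1,
                    "x_um": loc.x_um if loc else np.nan,
                    "y_um": loc.y_um if loc else np.nan,
                    "n_spikes": u.n_spikes,
                    "rate_hz": u.rate_hz,
                    "snr": u.snr,
                    "fw_ms": kin.fw_ms if kin else np.nan,
                    "pp_ms": kin.pp_ms if kin else np.nan,
                    "label": ct.label if ct else "",
                    "flags": ",".join(sorted(u.flags)),
                    "accepted": u.accepted,
                }
            )
        return pd.DataFrame(rows)


def sort_recording(
    raw: Recording,
    cfg: PipelineConfig | None = None,
    in_place: bool = False,
) -> SortingResult:
    """Run the full unsupervised pipeline on a raw recording.

    Stages: artifact removal -> bandpass -> per-channel threshold detection
    (with light blanking when a protocol is present) -> raw waveform
    extraction -> per-channel PCA + k-means + LDA merging -> per-unit
    localization, amplitude-decay screening and cross-channel deduplication
    -> spline kinetics and E/I clustering -> optogenetic z-scores.

    Filtering is streamed channel by channel (the filtered trace is only
    needed for detection), so peak memory stays near one copy of the raw
    voltage matrix.  ``in_place=True`` additionally lets artifact removal
    overwrite the caller's voltage buffer.
    """
    cfg = cfg or PipelineConfig()
    geom = raw.geometry
    t_start = time.perf_counter()

    raw_clean, art_mask = remove_artifacts(
        raw, cfg.detection.artifact_abs_uv, copy=not in_place
    )
    dead = {int(ch) for ch in np.flatnonzero(art_mask.all(axis=1))}
    del art_mask

    from scipy import signal as _signal

    sos = _signal.butter(
        cfg.filter_order, [cfg.low_hz, cfg.high_hz], btype="bandpass",
        fs=raw.fs_hz, output="sos",
    )
    light = (
        np.asarray(cfg.protocol.light_pulse_times_s, dtype=float)
        if cfg.protocol
        else None
    )
    events: dict[int, spike_detection.ChannelEvents] = {}
    for ch in range(raw.n_channels):
        if ch in dead:
            continue
        trace = _signal.sosfiltfilt(sos, raw_clean.voltage[ch].astype(np.float64))
        ev = spike_detection.detect_channel(
            trace, raw.fs_hz, cfg.detection, ch, raw.start_time_s,
            light_times_s=light,
        )
        if ev is not None:
            events[ch] = ev
    n_events = sum(e.n_events for e in events.values())
    log.info(
        "detected %d events on %d channels in %.1fs",
        n_events, len(events), time.perf_counter() - t_start,
    )

    duration = raw.duration_s
    units: list[unit_isolation.PutativeUnit] = []
    uid = 0
    for ch, ev in sorted(events.items()):
        if ev.n_events == 0:
            continue
        ws = spike_detection.extract_waveforms(raw_clean, ev, cfg.detection.window_ms)
        if ws.n_spikes == 0:
            continue
        scores = unit_isolation.embed_waveforms_pca(ws, cfg.n_pcs)
        if scores is None:
            # too few spikes to cluster: the channel contributes one unit
            wf = ws.waveforms.astype(np.float64)
            snr = spike_detection.compute_snr(wf)[0] if ws.n_spikes >= 2 else np.nan
            rate = ws.n_spikes / duration
            flags = {"low_count"}  # below the clustering minimum: unvalidated
            if rate < cfg.min_rate_hz:
                flags.add("low_rate")
            if np.isfinite(snr) and snr < cfg.snr_min:
                flags.add("low_snr")
            units.append(
                unit_isolation.PutativeUnit(
                    uid, ch, ws.times_s, wf.mean(axis=0), snr, rate, ws.n_spikes, flags,
                    spike_indices=np.arange(ws.n_spikes),
                )
            )
            uid += 1
            continue
        labels, k, ch_score = unit_isolation.cluster_kmeans(
            scores, cfg.k, cfg.k_max, cfg.seed
        )
        cc = unit_isolation.ChannelClustering(ch, scores, labels, k, ch_score)
        if k > 1:
            cc.lda_cv_error = unit_isolation.pairwise_lda_errors(
                scores, labels, seed=cfg.seed
            )
        new_units = unit_isolation.resolve_clusters(
            cc, ws, duration, cfg.merge_error_threshold, cfg.min_rate_hz,
            cfg.snr_min, cfg.min_spikes, first_unit_id=uid,
        )
        units.extend(new_units)
        uid += len(new_units)
    log.info("isolated %d candidate units", len(units))

    locations: dict[int, localization.SomaLocation] = {}
    profiles: dict[int, localization.AmplitudeProfile] = {}
    for u in units:
        if u.n_spikes == 0 or not u.accepted:  # rejected units need no soma
            continue
        try:
            loc, prof, _ = localization.locate_unit(u, raw_clean, geom, cfg.radius_um)
        except ValueError:
            continue
        locations[u.unit_id] = loc
        if prof is not None:
            profiles[u.unit_id] = prof

    localization.consolidate_far_field(units, locations)
    localization.deduplicate_units(
        [u for u in units if u.unit_id in locations and u.accepted],
        locations, geom, cfg.radius_um, cfg.corr_threshold, cfg.corr_bin_ms,
        duration_s=duration,
    )

    kinetics: dict[int, cell_typing.WaveformKinetics] = {}
    for u in units:
        if not u.accepted:
            continue
        try:
            t_ms, wf = cell_typing.interpolate_waveform(
                u.mean_waveform, raw.fs_hz, cfg.query_hz
            )
        except ValueError:
            continue
        kinetics[u.unit_id] = cell_typing.measure_kinetics(t_ms, wf, u.unit_id)

    cell_types: dict[int, cell_typing.CellTypeResult] = {}
    valid_kin = [k for k in kinetics.values() if k.valid]
    if len(valid_kin) >= 2:
        for res in cell_typing.classify_ei(valid_kin, cfg.typing_k, cfg.k_max, cfg.seed):
            cell_types[res.unit_id] = res

    responses: dict[int, opto_validation.ResponseSummary] = {}
    if cfg.protocol is not None:
        for u in units:
            if not u.accepted:
                continue
            try:
                responses[u.unit_id] = opto_validation.evoked_zscore(
                    u.times_s, cfg.protocol, cfg.baseline_bin_s,
                    unit_id=u.unit_id, z_threshold=cfg.z_threshold,
                )
            except ValueError:
                continue

    flag_names = (
        "low_count", "low_snr", "inseparable_merged", "low_rate",
        "increasing_decay", "duplicate",
    )
    qc = {
        "n_events_detected": int(n_events),
        "n_channels_dead": len(dead),
        "n_candidate_units": len(units),
        "n_accepted_units": sum(u.accepted for u in units),
        "rejected_by": {f: int(sum(f in u.flags for u in units)) for f in flag_names},
        "runtime_s": time.perf_counter() - t_start,
    }
    return SortingResult(
        units, locations, profiles, kinetics, cell_types, responses, qc, raw.fs_hz
    )


def run_pipeline(
    config_path: str | Path | PipelineConfig,
    recording_path: str | Path | None = None,
    out_dir: str | Path = "spikemap_run",
    recording: Recording | None = None,
) -> SortingResult:
    """File-level pipeline: load config + recording, sort, write the bundle.

    Writes ``units.tsv``, ``locations.tsv``, ``types.tsv``, ``opto.tsv``
    (when a protocol is configured), spike trains in ``units.h5`` and
    ``qc_report.json`` under ``out_dir``.
    """
    cfg = (
        config_path
        if isinstance(config_path, PipelineConfig)
        else PipelineConfig.from_yaml(config_path)
    )
    if recording is None:
        if recording_path is None:
            raise ValueError("need a recording or a recording path")
        recording = read_recording(recording_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    result = sort_recording(recording, cfg)

    df = result.units_table()
    df.to_csv(out / "units.tsv", sep="\t", index=False)
    loc_rows = [
        {
            "unit_id": uid,
            "row": loc.home_row,
            "col": loc.home_col,
            "x_um": loc.x_um,
            "y_um": loc.y_um,
            "slope": result.profiles[uid].slope if uid in result.profiles else np.nan,
            "intercept": result.profiles[uid].intercept if uid in result.profiles else np.nan,
        }
        for uid, loc in sorted(result.locations.items())
    ]
    pd.DataFrame(loc_rows).to_csv(out / "locations.tsv", sep="\t", index=False)
    if result.cell_types:
        pd.DataFrame(
            [
                {
                    "unit_id": uid,
                    "fw_ms": result.kinetics[uid].fw_ms,
                    "pp_ms": result.kinetics[uid].pp_ms,
                    "label": ct.label,
                }
                for uid, ct in sorted(result.cell_types.items())
            ]
        ).to_csv(out / "types.tsv", sep="\t", index=False)
    if result.responses:
        pd.DataFrame(
            [
                {
                    "unit_id": uid,
                    "baseline_mean_hz": r.baseline_mean_hz,
                    "baseline_sd_hz": r.baseline_sd_hz,
                    "evoked_hz": r.evoked_hz,
                    "z": r.z,
                    "responder": r.responder,
                }
                for uid, r in sorted(result.responses.items())
            ]
        ).to_csv(out / "opto.tsv", sep="\t", index=False)
    import h5py

    with h5py.File(out / "units.h5", "w") as f:
        for u in result.units:
            f.create_dataset(f"units/{u.unit_id}/times_s", data=u.times_s)
    with open(out / "qc_report.json", "w") as f:
        json.dump(result.qc, f, indent=2)
    return result
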