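"""Threshold-crossing spike detection, raw-waveform extraction and cluster SNR.

Detection runs on the *filtered* trace: events are local minima below the
per-channel threshold, thinned by an absolute refractory period (successive
events closer than 2 ms are discarded, keeping the earliest by default).
Waveform snippets, however, are cut from the *unfiltered* trace around each
trough so that spike shape is not distorted by the bandpass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording_io import DetectionConfig, Recording

__all__ = [
    "ChannelEvents",
    "WaveformSet",
    "detect_spikes",
    "detect_channel",
    "extract_waveforms",
    "compute_snr",
]


@dataclass
class ChannelEvents:
    """Detected troughs on one channel (arrays aligned by event)."""

    channel: int
    samples: np.ndarray  # int, sample index of the trough
    times_s: np.ndarray  # samples / fs + start_time
    trough_uv: np.ndarray  # filtered-trace voltage at the trough (negative)
    threshold_uv: float
    sigma_uv: float

    @property
    def n_events(self) -> int:
        return len(self.samples)


@dataclass
class WaveformSet:
    """Raw waveform snippets around the detected troughs of one channel."""

    channel: int
    waveforms: np.ndarray  # n_spikes x n_samples, raw uV
    rel_time_ms: np.ndarray  # sample offsets relative to the trough
    samples: np.ndarray  # trough sample of each row in the recording
    times_s: np.ndarray
    n_dropped_edge: int = 0
    dropped_samples: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    @property
    def n_spikes(self) -> int:
        return self.waveforms.shape[0]


def _enforce_refractory(
    samples: np.ndarray, troughs: np.ndarray, refractory_samples: int, keep: str
) -> np.ndarray:
    """Indices surviving the absolute refractory rule.

    ``keep='first'`` keeps the earliest event of any violating run;
    ``keep='deepest'`` keeps the most negative trough.
    """
    if len(samples) == 0:
        return np.empty(0, dtype=np.int64)
    if keep == "first":
        kept = [0]
        last = samples[0]
        for i in range(1, len(samples)):
            if samples[i] - last >= refractory_samples:
                kept.append(i)
                last = samples[i]
        return np.asarray(kept, dtype=np.int64)
    if keep == "deepest":
        # greedy by depth: deepest events claim their refractory window first
        order = np.argsort(troughs, kind="stable")  # most negative first
        taken = np.zeros(len(samples), dtype=bool)
        blocked = np.zeros(len(samples), dtype=bool)
        for i in order:
            if blocked[i]:
                continue
            taken[i] = True
            near = np.abs(samples - samples[i]) < refractory_samples
            blocked |= near
            blocked[i] = True
        return np.flatnonzero(taken)
    raise ValueError(f"unknown refractory keep rule {keep!r}")


def detect_channel(
    trace: np.ndarray,
    fs_hz: float,
    cfg: DetectionConfig,
    channel: int = 0,
    start_time_s: float = 0.0,
    threshold_uv: float | None = None,
    sigma_uv: float = float("nan"),
    light_times_s: np.ndarray | None = None,
    refractory_keep: str = "first",
) -> ChannelEvents | None:
    """Detect events on one filtered trace (workhorse behind :func:`detect_spikes`).

    Returns ``None`` when the threshold cannot be estimated (degenerate trace).
    """
    from .recording_io import estimate_detection_threshold

    if threshold_uv is None:
        try:
            sigma_uv, threshold_uv = estimate_detection_threshold(trace, cfg.threshold_sd)
        except ValueError:
            return None
    refr = max(1, int(round(cfg.refractory_ms * fs_hz / 1000.0)))
    idx, _ = signal.find_peaks(-trace, height=-threshold_uv)
    if idx.size == 0:
        return ChannelEvents(
            channel, np.empty(0, np.int64), np.empty(0), np.empty(0),
            float(threshold_uv), float(sigma_uv),
        )
    troughs = trace[idx].astype(np.float64)
    keep = _enforce_refractory(idx, troughs, refr, refractory_keep)
    idx, troughs = idx[keep], troughs[keep]
    times = start_time_s + idx / fs_hz
    if light_times_s is not None and len(light_times_s):
        light = np.sort(np.asarray(light_times_s, dtype=float))
        blank_s = cfg.light_blank_ms / 1000.0
        j = np.searchsorted(light, times, side="right") - 1
        in_blank = (j >= 0) & (times - light[np.clip(j, 0, None)] <= blank_s)
        idx, troughs, times = idx[~in_blank], troughs[~in_blank], times[~in_blank]
    return ChannelEvents(
        channel, idx.astype(np.int64), times, troughs, float(threshold_uv), float(sigma_uv)
    )


def detect_spikes(
    filtered: Recording,
    cfg: DetectionConfig | None = None,
    thresholds_uv: dict[int, float] | None = None,
    sigmas_uv: dict[int, float] | None = None,
    light_times_s: np.ndarray | list[float] | None = None,
    refractory_keep: str = "first",
    exclude_channels: set[int] | None = None,
) -> dict[int, ChannelEvents]:
    """Detect negative threshold crossings on every channel.

    Parameters
    ----------
    filtered:
        Bandpassed recording (detection trace).
    thresholds_uv, sigmas_uv:
        Per-channel thresholds (negative, uV).  If omitted they are estimated
        per channel with :func:`~spikemap.recording_io.estimate_detection_threshold`.
    light_times_s:
        Photostimulation onsets; detections within ``cfg.light_blank_ms``
        after a pulse onset are dropped (post-light saturation transient).
    refractory_keep:
        Tie-break for events closer than the refractory period: ``"first"``
        (default) or ``"deepest"``.

    Returns
    -------
    dict mapping channel index to :class:`ChannelEvents` (time-sorted).
    """
    cfg = cfg or DetectionConfig()
    exclude = exclude_channels or set()
    light = np.asarray(light_times_s, dtype=float) if light_times_s is not None else None

    out: dict[int, ChannelEvents] = {}
    for ch in range(filtered.n_channels):
        if ch in exclude:
            continue
        thr = thresholds_uv.get(ch) if thresholds_uv is not None else None
        sig = sigmas_uv.get(ch, np.nan) if sigmas_uv else np.nan
        if thresholds_uv is not None and thr is None:
            continue
        ev = detect_channel(
            filtered.voltage[ch], filtered.fs_hz, cfg, ch, filtered.start_time_s,
            threshold_uv=thr, sigma_uv=sig, light_times_s=light,
            refractory_keep=refractory_keep,
        )
        if ev is not None:
            out[ch] = ev
    return out


def extract_waveforms(
    raw: Recording,
    events: ChannelEvents,
    window_ms: tuple[float, float] = (-5.0, 5.0),
) -> WaveformSet:
    """Cut raw (unfiltered) snippets around each detected trough.

    The snippet spans ``window_ms`` around the trough sample inclusive at
    both ends, i.e. ``round(fs*(hi-lo)/1000) + 1`` samples (181 at 18 kHz for
    the default -5..+5 ms window).  Events too close to the recording edge
    are dropped and reported in ``dropped_samples``.
    """
    lo, hi = window_ms
    if not lo < 0 < hi:
        raise ValueError("window must span the trough")
    n_pre = int(round(-lo * raw.fs_hz / 1000.0))
    n_post = int(round(hi * raw.fs_hz / 1000.0))
    n_samp = n_pre + n_post + 1
    if n_samp > raw.n_samples:
        raise ValueError("extraction window wider than the recording")
    s = events.samples
    ok = (s - n_pre >= 0) & (s + n_post < raw.n_samples)
    dropped = s[~ok]
    s = s[ok]
    wf = np.empty((len(s), n_samp), dtype=raw.voltage.dtype)
    trace = raw.voltage[events.channel]
    for i, c in enumerate(s):
        wf[i] = trace[c - n_pre : c + n_post + 1]
    rel_ms = (np.arange(n_samp) - n_pre) * 1000.0 / raw.fs_hz
    return WaveformSet(
        channel=events.channel,
        waveforms=wf,
        rel_time_ms=rel_ms,
        samples=s,
        times_s=raw.start_time_s + s / raw.fs_hz,
        n_dropped_edge=int((~ok).sum()),
        dropped_samples=dropped.astype(np.int64),
    )


def compute_snr(
    ws: WaveformSet | np.ndarray, labels: np.ndarray | None = None
) -> dict[int, float]:
    """Signal-to-noise ratio per waveform cluster.

    SNR = |trough of the mean waveform| / SD of the residuals
    (waveforms - mean), pooled over all samples and spikes of the cluster.
    Clusters with zero residual SD (identical waveforms) return ``inf``.
    """
    wf = ws.waveforms if isinstance(ws, WaveformSet) else np.asarray(ws)
    if labels is None:
        labels = np.zeros(wf.shape[0], dtype=int)
    labels = np.asarray(labels)
    out: dict[int, float] = {}
    for lab in np.unique(labels):
        w = wf[labels == lab].astype(np.float64)
        if w.shape[0] < 2:
            warnings.warn(f"cluster {lab}: fewer than 2 waveforms, SNR undefined")
            out[int(lab)] = np.nan
            continue
        mean = w.mean(axis=0)
        resid_sd = float((w - mean).std(ddof=1))
        amp = float(np.abs(mean.min()))
        out[int(lab)] = np.inf if resid_sd == 0 else amp / resid_sd
    return out
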