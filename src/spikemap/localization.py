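"""Soma-channel selection, center-of-mass localization and deduplication.

The largest negative extracellular deflection arises near the axon initial
segment, so within a 250 um radius the channel with the deepest mean-waveform
trough is taken as the putative soma channel.  Sub-pitch position is then
estimated by the center of mass of trough amplitudes on the 3x3 electrode
patch around that channel:

    r = sum_ij(i * a_ij) / sum_ij(a_ij),   c = sum_ij(j * a_ij) / sum_ij(a_ij)

with a_ij = |negative trough| on each electrode (1-based i, j; the home
channel sits at (2, 2)).  Genuine somatic signals decay with distance; units
whose amplitude *increases* away from the peak electrode are flagged.  Units
whose spike-count correlation with a nearby unit exceeds a threshold are
flagged as duplicates of the larger-amplitude unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .recording_io import ArrayGeometry, Recording
from .unit_isolation import PutativeUnit

__all__ = [
    "SomaLocation",
    "AmplitudeProfile",
    "select_soma_channel",
    "center_of_mass",
    "fit_amplitude_decay",
    "deduplicate_units",
    "consolidate_far_field",
    "unit_footprint",
    "locate_unit",
]


@dataclass
class SomaLocation:
    """Sub-pitch soma estimate for one unit."""

    unit_id: int
    home_channel: int
    home_row: int
    home_col: int
    com_offset_um: tuple[float, float]  # (d_row_um, d_col_um) from home center
    per_spike_com: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    x_um: float = float("nan")  # absolute position, col * pitch + d_col
    y_um: float = float("nan")  # absolute position, row * pitch + d_row


@dataclass
class AmplitudeProfile:
    """Mean-waveform trough amplitude versus distance from the home channel."""

    unit_id: int
    distances_um: np.ndarray
    trough_uv: np.ndarray  # |trough| magnitudes
    slope: float  # uV / um, OLS
    intercept: float  # uV
    increasing: bool  # amplitude grows away from the peak -> exclude


def unit_footprint(
    raw: Recording,
    trough_samples: np.ndarray,
    channels: np.ndarray,
    n_pre: int,
    n_post: int,
) -> dict[int, np.ndarray]:
    """Mean raw waveform of a unit on each requested channel.

    Averages the raw trace of every channel in ``channels`` over the unit's
    trough samples (edge spikes skipped), giving the unit's spatial footprint
    even on channels where it never crossed the detection threshold.
    """
    s = np.asarray(trough_samples)
    ok = (s - n_pre >= 0) & (s + n_post < raw.n_samples)
    s = s[ok]
    if s.size == 0:
        return {}
    offs = np.arange(-n_pre, n_post + 1)
    idx = s[:, None] + offs[None, :]
    return {int(ch): raw.voltage[ch][idx].mean(axis=0) for ch in channels}


def _trough(wf: np.ndarray) -> float:
    """Signed trough (minimum) of a waveform."""
    return float(np.min(wf))


def select_soma_channel(
    mean_wf_by_channel: dict[int, np.ndarray],
    geometry: ArrayGeometry,
    radius_um: float = 250.0,
) -> int:
    """Channel with the most negative mean-waveform trough within the radius.

    The search is anchored at the globally deepest channel and restricted to
    channels within ``radius_um`` of it, which keeps far-field coincidences
    from hijacking the soma assignment.
    """
    if not mean_wf_by_channel:
        raise ValueError("no channels carry this unit")
    troughs = {ch: _trough(wf) for ch, wf in mean_wf_by_channel.items()}
    anchor = min(troughs, key=troughs.get)
    allowed = set(geometry.neighbors_within(anchor, radius_um).tolist())
    in_radius = {ch: t for ch, t in troughs.items() if ch in allowed}
    return min(in_radius, key=in_radius.get)


def center_of_mass(a: np.ndarray, pitch_um: float) -> tuple[float, float]:
    """Center of mass of a 3x3 non-negative weight matrix, in um offsets.

    Weights are |negative trough| magnitudes; the home channel occupies the
    center element.  Returns ``(d_row_um, d_col_um)`` relative to the home
    channel center: ``((r - 2) * pitch, (c - 2) * pitch)`` with r, c the
    1-based row/column centroids.
    """
    a = np.asarray(a, dtype=np.float64)
    if a.shape != (3, 3):
        raise ValueError("weight matrix must be 3x3")
    if (a < 0).any():
        raise ValueError("weights must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("center of mass undefined for an all-zero matrix")
    i = np.arange(1, 4)[:, None]
    j = np.arange(1, 4)[None, :]
    r = float((i * a).sum() / total)
    c = float((j * a).sum() / total)
    return (r - 2.0) * pitch_um, (c - 2.0) * pitch_um


def com_weights(
    mean_wf_by_channel: dict[int, np.ndarray],
    home: int,
    geometry: ArrayGeometry,
) -> np.ndarray:
    """3x3 |trough| weight matrix around the home channel (0 off-array)."""
    hr, hc = geometry.channel_map[home]
    a = np.zeros((3, 3))
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            ch = geometry.channel_at(hr + di, hc + dj)
            if ch is None or ch not in mean_wf_by_channel:
                continue
            t = _trough(mean_wf_by_channel[ch])
            a[di + 1, dj + 1] = max(0.0, -t)  # positive-only waveforms weigh 0
    return a


def fit_amplitude_decay(
    mean_trough_by_channel: dict[int, float],
    home: int,
    geometry: ArrayGeometry,
    unit_id: int = -1,
) -> AmplitudeProfile | None:
    """OLS fit of |trough| amplitude versus distance from the home channel.

    A genuine somatic signal decays with distance, so the slope should be
    negative; ``increasing=True`` (slope > 0) marks the unit for exclusion.
    Returns ``None`` when fewer than 3 channels carry a measurable trough.
    """
    d, amp = [], []
    for ch, t in mean_trough_by_channel.items():
        if t < 0:
            d.append(geometry.distance_um(home, ch))
            amp.append(-t)
    if len(d) < 3:
        return None
    d_arr, amp_arr = np.asarray(d), np.asarray(amp)
    res = stats.linregress(d_arr, amp_arr)
    return AmplitudeProfile(
        unit_id=unit_id,
        distances_um=d_arr,
        trough_uv=amp_arr,
        slope=float(res.slope),
        intercept=float(res.intercept),
        increasing=bool(res.slope > 0),
    )


def locate_unit(
    unit: PutativeUnit,
    raw: Recording,
    geometry: ArrayGeometry,
    radius_um: float = 250.0,
    per_spike: bool = True,
    max_spikes_for_com: int = 500,
) -> tuple[SomaLocation, AmplitudeProfile | None, dict[int, np.ndarray]]:
    """Full localization of one unit: home channel, COM offset, decay profile.

    The unit's footprint (mean raw waveform on the 3x3 patch plus all
    channels within ``radius_um``) is computed by spike-triggered averaging,
    the soma channel re-selected within the radius, and the center of mass
    evaluated on the 3x3 trough amplitudes.  Per-spike COM offsets use
    single-spike trough amplitudes on the same patch.
    """
    fs = raw.fs_hz
    n_pre = n_post = int(round(2.0 * fs / 1000.0))  # +-2 ms is ample for troughs
    samples = np.round((unit.times_s - raw.start_time_s) * fs).astype(np.int64)
    channels = geometry.neighbors_within(unit.channel, radius_um)
    fp = unit_footprint(raw, samples, channels, n_pre, n_post)
    if not fp:
        raise ValueError(f"unit {unit.unit_id}: no in-bounds spikes to localize")
    home = select_soma_channel(fp, geometry, radius_um)
    hr, hc = geometry.channel_map[home]
    a = com_weights(fp, home, geometry)
    d_row, d_col = center_of_mass(a, geometry.pitch_um)

    per = np.empty((0, 2))
    if per_spike:
        patch = [
            geometry.channel_at(hr + di, hc + dj)
            for di in (-1, 0, 1)
            for dj in (-1, 0, 1)
        ]
        ok = (samples - n_pre >= 0) & (samples + n_post < raw.n_samples)
        s = samples[ok][:max_spikes_for_com]
        if s.size:
            offs = np.arange(-n_pre, n_post + 1)
            idx = s[:, None] + offs[None, :]
            amps = np.zeros((len(s), 9))
            for p, ch in enumerate(patch):
                if ch is None:
                    continue
                amps[:, p] = np.maximum(0.0, -raw.voltage[ch][idx].min(axis=1))
            # vectorized 3x3 center of mass per spike
            total = amps.sum(axis=1)
            good = total > 0
            if good.any():
                ii = np.repeat(np.arange(1, 4), 3).astype(float)  # row index per patch cell
                jj = np.tile(np.arange(1, 4), 3).astype(float)
                r = (amps[good] * ii).sum(axis=1) / total[good]
                c = (amps[good] * jj).sum(axis=1) / total[good]
                per = np.column_stack([(r - 2.0), (c - 2.0)]) * geometry.pitch_um

    troughs = {ch: _trough(wf) for ch, wf in fp.items()}
    profile = fit_amplitude_decay(troughs, home, geometry, unit.unit_id)
    if profile is not None and profile.increasing:
        unit.flags.add("increasing_decay")

    loc = SomaLocation(
        unit_id=unit.unit_id,
        home_channel=home,
        home_row=int(hr),
        home_col=int(hc),
        com_offset_um=(d_row, d_col),
        per_spike_com=per,
        x_um=float(hc * geometry.pitch_um + d_col),
        y_um=float(hr * geometry.pitch_um + d_row),
    )
    return loc, profile, fp


def consolidate_far_field(
    units: list[PutativeUnit],
    locations: dict[int, SomaLocation],
) -> list[int]:
    """Flag far-field images of units already represented at their soma channel.

    A unit detected on one channel whose soma channel (deepest mean-waveform
    trough within the search radius) is a *different* channel is a far-field
    image of a cell centered elsewhere.  When that soma channel hosts its own
    somatic unit (detected there, localized there), the image reports the
    same cell a second time and is flagged ``duplicate``.  Images whose soma
    channel carries no somatic unit are kept — they are the cell's only
    representation.  Returns the flagged unit ids.
    """
    somatic_channels = {
        locations[u.unit_id].home_channel
        for u in units
        if u.accepted
        and u.unit_id in locations
        and locations[u.unit_id].home_channel == u.channel
    }
    flagged = []
    for u in units:
        if not u.accepted or u.unit_id not in locations:
            continue
        home = locations[u.unit_id].home_channel
        if home != u.channel and home in somatic_channels:
            u.flags.add("duplicate")
            flagged.append(u.unit_id)
    return flagged


def _binned_counts(times_s: np.ndarray, t0: float, t1: float, bin_s: float) -> np.ndarray:
    edges = np.arange(t0, t1 + bin_s, bin_s)
    counts, _ = np.histogram(times_s, bins=edges)
    return counts


def deduplicate_units(
    units: list[PutativeUnit],
    locations: dict[int, SomaLocation],
    geometry: ArrayGeometry,
    radius_um: float = 250.0,
    corr_threshold: float = 0.5,
    bin_ms: float = 100.0,
    duration_s: float | None = None,
) -> list[tuple[int, int, float]]:
    """Flag cross-channel duplicates by spike-count correlation.

    For every unit pair whose home channels lie within ``radius_um``, the
    Pearson correlation of non-overlapping ``bin_ms`` spike counts is
    computed; if it exceeds ``corr_threshold`` the unit with the smaller
    |trough| amplitude gets a ``duplicate`` flag (the larger-amplitude unit
    is closest to the soma and survives).  At most one member of each pair
    is ever flagged.  Returns the flagged pairs as
    ``(kept_unit_id, flagged_unit_id, correlation)``.
    """
    bin_s = bin_ms / 1000.0
    t0 = min((u.times_s[0] for u in units if u.n_spikes), default=0.0)
    t1 = max((u.times_s[-1] for u in units if u.n_spikes), default=bin_s)
    if duration_s is not None:
        t1 = max(t1, t0 + duration_s)
    flagged_pairs: list[tuple[int, int, float]] = []
    by_id = {u.unit_id: u for u in units}
    counts_cache: dict[int, np.ndarray] = {}

    def counts(u: PutativeUnit) -> np.ndarray:
        if u.unit_id not in counts_cache:
            counts_cache[u.unit_id] = _binned_counts(u.times_s, t0, t1, bin_s)
        return counts_cache[u.unit_id]

    for i, ua in enumerate(units):
        for ub in units[i + 1 :]:
            ha = locations[ua.unit_id].home_channel
            hb = locations[ub.unit_id].home_channel
            if geometry.distance_um(ha, hb) > radius_um:
                continue
            ca, cb = counts(ua), counts(ub)
            if ca.std() == 0 or cb.std() == 0:
                continue
            r = float(np.corrcoef(ca, cb)[0, 1])
            if r > corr_threshold:
                amp_a = abs(float(ua.mean_waveform.min()))
                amp_b = abs(float(ub.mean_waveform.min()))
                keep, drop = (ua, ub) if amp_a >= amp_b else (ub, ua)
                if "duplicate" not in by_id[keep.unit_id].flags:
                    drop.flags.add("duplicate")
                    flagged_pairs.append((keep.unit_id, drop.unit_id, r))
    return flagged_pairs
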