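"""Recording containers, file I/O, filtering and detection-threshold estimation.

A :class:`Recording` is a dense channel x sample voltage matrix in microvolts
together with the electrode-grid geometry and the sampling rate.  The
high-density arrays this package targets are square grids (e.g. 64 x 64
electrodes at 42 um pitch sampled at 18 kHz); the geometry is kept explicit so
channel indices can always be mapped back to physical positions.

Preprocessing follows the standard extracellular workflow: a zero-phase
second-order Butterworth bandpass (300-5000 Hz) removes slow field potentials
and high-frequency noise, saturating artifacts (|v| > 500 uV) are replaced by
the channel mean, and the per-channel detection threshold is set to ``-x *
sigma`` where sigma comes from a Gaussian fit to the filtered-voltage
histogram (so that spike tails do not inflate the noise estimate).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy import optimize, signal

__all__ = [
    "ArrayGeometry",
    "Recording",
    "DetectionConfig",
    "read_recording",
    "write_recording",
    "bandpass_filter",
    "remove_artifacts",
    "estimate_detection_threshold",
]


class FormatError(ValueError):
    """A recording file is missing required fields or has the wrong layout."""


class GeometryError(ValueError):
    """Voltage matrix shape and geometry metadata disagree."""


@dataclass(frozen=True)
class ArrayGeometry:
    """Square multielectrode-array layout.

    Parameters
    ----------
    n_rows, n_cols:
        Grid dimensions.
    pitch_um:
        Center-to-center electrode spacing in micrometers.
    channel_map:
        ``(n_channels, 2)`` integer array mapping channel index to
        ``(row, col)``, 0-based.  Defaults to row-major order.
    """

    n_rows: int
    n_cols: int
    pitch_um: float
    channel_map: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.channel_map is None:
            rows, cols = np.divmod(np.arange(self.n_channels), self.n_cols)
            object.__setattr__(
                self, "channel_map", np.column_stack([rows, cols]).astype(np.int64)
            )
        else:
            cm = np.asarray(self.channel_map, dtype=np.int64)
            if cm.shape != (self.n_channels, 2):
                raise GeometryError(
                    f"channel_map shape {cm.shape} != ({self.n_channels}, 2)"
                )
            if len({(r, c) for r, c in cm}) != self.n_channels:
                raise GeometryError("channel_map positions are not unique")
            if cm[:, 0].max() >= self.n_rows or cm[:, 1].max() >= self.n_cols:
                raise GeometryError("channel_map position outside grid")
            object.__setattr__(self, "channel_map", cm)

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    def position_um(self, channel: int | np.ndarray) -> np.ndarray:
        """Physical (x, y) = (col, row) * pitch position of channel center(s)."""
        rc = self.channel_map[channel]
        return rc[..., ::-1] * self.pitch_um

    def distance_um(self, ch_a: int, ch_b: int) -> float:
        """Euclidean distance between two channel centers."""
        d = self.channel_map[ch_a] - self.channel_map[ch_b]
        return float(self.pitch_um * np.hypot(d[0], d[1]))

    def channel_at(self, row: int, col: int) -> int | None:
        """Channel index at a grid position, or None if outside the grid."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            return None
        hit = np.flatnonzero(
            (self.channel_map[:, 0] == row) & (self.channel_map[:, 1] == col)
        )
        return int(hit[0]) if hit.size else None

    def neighbors_within(self, channel: int, radius_um: float) -> np.ndarray:
        """Channels whose centers lie within ``radius_um`` (including self)."""
        d = self.channel_map - self.channel_map[channel]
        dist = self.pitch_um * np.hypot(d[:, 0], d[:, 1])
        return np.flatnonzero(dist <= radius_um + 1e-9)


@dataclass
class Recording:
    """Dense extracellular recording: channel x sample voltages in uV."""

    voltage: np.ndarray
    fs_hz: float
    geometry: ArrayGeometry
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage)
        if self.voltage.ndim != 2:
            raise ValueError("voltage must be 2-D (channels x samples)")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.voltage.shape[0] != self.geometry.n_channels:
            raise GeometryError(
                f"{self.voltage.shape[0]} channels but geometry has "
                f"{self.geometry.n_channels}"
            )

    @property
    def n_channels(self) -> int:
        return self.voltage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltage.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def copy_with(self, voltage: np.ndarray) -> "Recording":
        return Recording(voltage, self.fs_hz, self.geometry, self.start_time_s)


@dataclass
class DetectionConfig:
    """Parameters of threshold-based spike detection.

    ``threshold_sd`` is the multiplier x applied to the Gaussian-fit noise SD
    (threshold = -x * sigma).  ``refractory_ms`` discards successive events
    closer than the absolute refractory period.  ``window_ms`` is the raw
    snippet cut around each trough.  ``artifact_abs_uv`` bounds physiological
    voltages; larger deflections are treated as recording artifacts.
    ``light_blank_ms`` drops detections inside the photostimulation
    saturation transient following each light pulse.
    """

    threshold_sd: float = 4.5
    refractory_ms: float = 2.0
    window_ms: tuple[float, float] = (-5.0, 5.0)
    artifact_abs_uv: float = 500.0
    light_blank_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be positive")
        if self.refractory_ms <= 0:
            raise ValueError("refractory_ms must be positive")
        if not (self.window_ms[0] < 0 < self.window_ms[1]):
            raise ValueError("window_ms must span the trough (lo < 0 < hi)")
        if self.artifact_abs_uv <= 0:
            raise ValueError("artifact_abs_uv must be positive")


# ---------------------------------------------------------------------------
# File I/O
#
# HDF5 layout: /voltage (channels x samples, uV), /fs_hz, /start_time_s,
# /geometry/{n_rows,n_cols,pitch_um,channel_map}.  The NPZ dialect mirrors
# the same keys with "geometry/" flattened to "geometry_".
# ---------------------------------------------------------------------------

_GEOM_KEYS = ("n_rows", "n_cols", "pitch_um", "channel_map")


def _infer_dialect(path: Path) -> str:
    if path.suffix in {".h5", ".hdf5", ".hdf"}:
        return "hdf5"
    if path.suffix == ".npz":
        return "npz"
    raise FormatError(f"cannot infer dialect from suffix {path.suffix!r}")


def write_recording(rec: Recording, path: str | Path, dialect: str | None = None) -> None:
    """Write a recording to HDF5 or NPZ (voltage stored as float32 uV)."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    g = rec.geometry
    if dialect == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("voltage", data=rec.voltage.astype(np.float32))
            f["fs_hz"] = float(rec.fs_hz)
            f["start_time_s"] = float(rec.start_time_s)
            grp = f.create_group("geometry")
            grp["n_rows"], grp["n_cols"] = g.n_rows, g.n_cols
            grp["pitch_um"] = g.pitch_um
            grp["channel_map"] = g.channel_map
    elif dialect == "npz":
        np.savez(
            path,
            voltage=rec.voltage.astype(np.float32),
            fs_hz=float(rec.fs_hz),
            start_time_s=float(rec.start_time_s),
            geometry_n_rows=g.n_rows,
            geometry_n_cols=g.n_cols,
            geometry_pitch_um=g.pitch_um,
            geometry_channel_map=g.channel_map,
        )
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


def read_recording(path: str | Path, dialect: str | None = None) -> Recording:
    """Load a recording written by :func:`write_recording` (or compatible).

    Raises
    ------
    FormatError
        If a required field is missing.
    GeometryError
        If the voltage shape disagrees with the geometry metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "hdf5":
        with h5py.File(path, "r") as f:
            for key in ("voltage", "fs_hz", "geometry"):
                if key not in f:
                    raise FormatError(f"missing field {key!r} in {path}")
            for key in _GEOM_KEYS:
                if key not in f["geometry"]:
                    raise FormatError(f"missing field geometry/{key!r} in {path}")
            geom = ArrayGeometry(
                int(f["geometry/n_rows"][()]),
                int(f["geometry/n_cols"][()]),
                float(f["geometry/pitch_um"][()]),
                np.asarray(f["geometry/channel_map"]),
            )
            start = float(f["start_time_s"][()]) if "start_time_s" in f else 0.0
            return Recording(np.asarray(f["voltage"]), float(f["fs_hz"][()]), geom, start)
    if dialect == "npz":
        with np.load(path) as z:
            for key in ("voltage", "fs_hz") + tuple("geometry_" + k for k in _GEOM_KEYS):
                if key not in z:
                    raise FormatError(f"missing field {key!r} in {path}")
            geom = ArrayGeometry(
                int(z["geometry_n_rows"]),
                int(z["geometry_n_cols"]),
                float(z["geometry_pitch_um"]),
                z["geometry_channel_map"],
            )
            start = float(z["start_time_s"]) if "start_time_s" in z else 0.0
            return Recording(z["voltage"], float(z["fs_hz"]), geom, start)
    raise FormatError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def bandpass_filter(
    rec: Recording,
    low_hz: float = 300.0,
    high_hz: float = 5000.0,
    order: int = 2,
) -> Recording:
    """Zero-phase Butterworth bandpass of every channel.

    The filter is applied forward-backward (``sosfiltfilt``) so that trough
    times are not shifted by filter group delay; the effective magnitude
    response is the squared response of the ``order``-th order design.
    """
    nyq = rec.fs_hz / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high_hz={high_hz} must be below Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs_hz, output="sos")
    out = np.empty_like(rec.voltage, dtype=rec.voltage.dtype)
    for ch in range(rec.n_channels):  # channel-wise keeps peak memory low
        out[ch] = signal.sosfiltfilt(sos, rec.voltage[ch].astype(np.float64)).astype(
            rec.voltage.dtype
        )
    return rec.copy_with(out)


def remove_artifacts(
    rec: Recording, abs_uv: float = 500.0, copy: bool = True
) -> tuple[Recording, np.ndarray]:
    """Replace saturating samples (|v| strictly > ``abs_uv``) by the channel mean.

    The replacement mean is computed over the *non-flagged* samples of each
    channel.  Returns the cleaned recording and the boolean artifact mask
    (channels x samples).  A channel flagged everywhere is dead: its voltage
    is set to 0 and it stays fully flagged so downstream stages can skip it.
    With ``copy=False`` the input voltage buffer is modified in place (useful
    for large recordings).
    """
    if abs_uv <= 0:
        raise ValueError("abs_uv must be positive")
    out = rec.voltage.copy() if copy else rec.voltage
    mask = np.empty(out.shape, dtype=bool)
    for ch in range(rec.n_channels):  # channel-wise keeps temporaries small
        v = out[ch]
        m = np.abs(v) > abs_uv
        mask[ch] = m
        if m.any():
            good = ~m
            v[m] = v[good].mean() if good.any() else 0.0
    return (rec if not copy else rec.copy_with(out)), mask


def _mad_sigma(v: np.ndarray) -> float:
    med = np.median(v)
    return 1.4826 * float(np.median(np.abs(v - med)))


def estimate_detection_threshold(
    filtered_channel: np.ndarray, threshold_sd: float = 4.5
) -> tuple[float, float]:
    """Noise SD and spike threshold from a Gaussian fit to the voltage histogram.

    The histogram (Freedman-Diaconis bins) is restricted to |v| <= 3 sigma_MAD
    so that spike tails do not bias the fit, then a Gaussian
    ``A * exp(-(v - mu)^2 / (2 sigma^2))`` is least-squares fitted to the bin
    counts.  Returns ``(sigma_hat, threshold_uv)`` with
    ``threshold_uv = -threshold_sd * sigma_hat``.

    Raises
    ------
    ValueError
        On traces shorter than 1000 samples or with (near-)zero variance.
    """
    v = np.asarray(filtered_channel, dtype=np.float64).ravel()
    if v.size < 1000:
        raise ValueError("need at least 1000 samples to estimate the noise SD")
    if v.size > 200_000:  # strided subsample; the SD estimate is unaffected
        v = v[:: v.size // 200_000]
    sigma0 = _mad_sigma(v)
    if sigma0 <= 0 or not np.isfinite(sigma0):
        raise ValueError("degenerate (zero-variance) trace")
    core = v[np.abs(v - np.median(v)) <= 3.0 * sigma0]
    counts, edges = np.histogram(core, bins="fd")
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, amp, mu, sig):
        return amp * np.exp(-0.5 * ((x - mu) / sig) ** 2)

    p0 = (counts.max(), float(np.median(core)), sigma0)
    try:
        popt, _ = optimize.curve_fit(gauss, centers, counts, p0=p0, maxfev=5000)
        sigma_hat = abs(float(popt[2]))
    except RuntimeError:  # fit failure: fall back to the robust estimate
        sigma_hat = sigma0
    if not np.isfinite(sigma_hat) or sigma_hat <= 0:
        sigma_hat = sigma0
    return sigma_hat, -threshold_sd * sigma_hat
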