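"""Single-unit isolation: per-channel PCA, k-means, LDA separability, merging.

One electrode of a dense array commonly picks up several nearby cells.  The
waveforms detected on a channel are embedded with PCA, partitioned with
k-means (k = 2 by default, or chosen by the Calinski-Harabasz criterion), and
every cluster pair is scored by tenfold cross-validated linear-discriminant
classification error.  Chance corresponds to an error of 0.5: pairs whose
error is near chance are statistically inseparable and are merged back into
one putative unit; well-separated pairs remain distinct units.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import calinski_harabasz_score
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .spike_detection import WaveformSet, compute_snr

__all__ = [
    "ChannelClustering",
    "PutativeUnit",
    "embed_waveforms_pca",
    "cluster_kmeans",
    "lda_separability_cv",
    "resolve_clusters",
]

MIN_SPIKES_FOR_CLUSTERING = 20


@dataclass
class ChannelClustering:
    """PCA scores, k-means labels and pairwise LDA errors for one channel."""

    channel: int
    scores: np.ndarray  # n_spikes x n_pcs
    labels: np.ndarray  # cluster id per spike, in [0, k)
    k: int
    ch_score: float  # Calinski-Harabasz value (nan when k == 1)
    lda_cv_error: dict[tuple[int, int], float] = field(default_factory=dict)


@dataclass
class PutativeUnit:
    """A candidate single neuron: spike train plus quality metrics.

    Rejected units are never deleted; they carry QC flags (``low_rate``,
    ``low_snr``, ``low_count``, ``inseparable_merged``, ``duplicate``,
    ``increasing_decay``) so every rejection is auditable.
    """

    unit_id: int
    channel: int
    times_s: np.ndarray
    mean_waveform: np.ndarray
    snr: float
    rate_hz: float
    n_spikes: int
    flags: set[str] = field(default_factory=set)
    spike_indices: np.ndarray | None = None  # rows into the channel WaveformSet

    @property
    def accepted(self) -> bool:
        return not (self.flags - {"inseparable_merged"})


def embed_waveforms_pca(
    ws: WaveformSet | np.ndarray, n_pcs: int = 2
) -> np.ndarray | None:
    """Project waveforms onto their leading principal components.

    Waveforms are mean-centered per sample; components are ordered by
    decreasing explained variance.  Returns ``None`` (channel skipped) when
    fewer than ``MIN_SPIKES_FOR_CLUSTERING`` spikes are available.
    """
    wf = ws.waveforms if isinstance(ws, WaveformSet) else np.asarray(ws)
    if wf.shape[0] < max(n_pcs + 1, MIN_SPIKES_FOR_CLUSTERING):
        return None
    n_pcs = min(n_pcs, wf.shape[0] - 1, wf.shape[1])
    return PCA(n_components=n_pcs).fit_transform(wf.astype(np.float64))


def cluster_kmeans(
    scores: np.ndarray,
    k: int | str = 2,
    k_max: int = 6,
    seed: int | None = 0,
) -> tuple[np.ndarray, int, float]:
    """k-means partition of PCA scores; ``k="auto"`` picks k by the CH index.

    Automatic selection evaluates k in [2, k_max] and keeps the k maximizing
    the Calinski-Harabasz (between/within dispersion) score.  Each fit uses
    10 restarts and is deterministic given ``seed``.

    Returns ``(labels, k, ch_score)``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n = scores.shape[0]
    if k == "auto":
        best = None
        for kk in range(2, min(k_max, n - 1) + 1):
            labels = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit_predict(scores)
            if len(np.unique(labels)) < 2:
                continue
            ch = calinski_harabasz_score(scores, labels)
            if best is None or ch > best[2]:
                best = (labels, kk, ch)
        if best is None:
            return np.zeros(n, dtype=int), 1, float("nan")
        return best
    k = int(k)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points ({n})")
    if k == 1:
        return np.zeros(n, dtype=int), 1, float("nan")
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(scores)
    ch = calinski_harabasz_score(scores, labels) if len(np.unique(labels)) > 1 else float("nan")
    return labels, k, float(ch)


def lda_separability_cv(
    scores: np.ndarray,
    labels: np.ndarray,
    folds: int = 10,
    seed: int | None = 0,
) -> float:
    """Stratified k-fold cross-validated LDA classification error of two clusters.

    Linear discriminant analysis assumes equal class covariance; the returned
    value is ``1 - mean CV accuracy``, so 0.5 is chance (inseparable) and 0
    is perfect separation.  If one class has fewer members than ``folds`` the
    fold count is reduced with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim == 1:
        scores = scores[:, None]
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("lda_separability_cv expects exactly two classes")
    min_count = int(counts.min())
    if min_count < 2:
        raise ValueError("each class needs at least 2 members")
    if min_count < folds:
        warnings.warn(
            f"class with {min_count} members < {folds} folds; using {min_count} folds"
        )
        folds = min_count
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    acc = cross_val_score(LinearDiscriminantAnalysis(), scores, labels, cv=cv)
    return float(1.0 - acc.mean())


def pairwise_lda_errors(
    scores: np.ndarray,
    labels: np.ndarray,
    folds: int = 10,
    seed: int | None = 0,
) -> dict[tuple[int, int], float]:
    """LDA CV error for every cluster pair (pairs with a tiny class get 0.0)."""
    errors: dict[tuple[int, int], float] = {}
    for a, b in itertools.combinations(sorted(np.unique(labels).tolist()), 2):
        sel = (labels == a) | (labels == b)
        try:
            errors[(a, b)] = lda_separability_cv(scores[sel], labels[sel], folds, seed)
        except ValueError:
            errors[(a, b)] = 0.0
    return errors


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def resolve_clusters(
    cc: ChannelClustering,
    ws: WaveformSet,
    duration_s: float,
    merge_error_threshold: float = 0.4,
    min_rate_hz: float = 0.02,
    snr_min: float = 4.0,
    min_spikes: int = MIN_SPIKES_FOR_CLUSTERING,
    first_unit_id: int = 0,
) -> list[PutativeUnit]:
    """Merge inseparable clusters and build putative units for one channel.

    Cluster pairs whose LDA CV error is at or above ``merge_error_threshold``
    (near the 0.5 chance level) are merged — the discriminant cannot tell
    them apart, so they are treated as one neuron.  Each surviving group
    becomes a :class:`PutativeUnit`; units below the minimum firing rate,
    SNR or spike count are flagged (``low_rate``, ``low_snr``, ``low_count``)
    rather than dropped — a cluster with too few spikes has no reliable
    SNR/LDA statistics and cannot be validated as a neuron.
    """
    labels = np.asarray(cc.labels)
    uf = _UnionFind(np.unique(labels).tolist())
    for (a, b), err in cc.lda_cv_error.items():
        if err >= merge_error_threshold:
            uf.union(a, b)
    merged = np.array([uf.find(l) for l in labels])
    was_merged = {uf.find(l) for l in np.unique(labels)} != set(np.unique(labels).tolist())

    units: list[PutativeUnit] = []
    uid = first_unit_id
    for g in np.unique(merged):
        rows = np.flatnonzero(merged == g)
        wf = ws.waveforms[rows].astype(np.float64)
        times = ws.times_s[rows]
        snr = compute_snr(wf)[0] if len(rows) >= 2 else float("nan")
        rate = len(rows) / duration_s if duration_s > 0 else float("nan")
        flags: set[str] = set()
        if was_merged and sum(uf.find(l) == g for l in np.unique(labels)) > 1:
            flags.add("inseparable_merged")
        if rate < min_rate_hz:
            flags.add("low_rate")
        if np.isfinite(snr) and snr < snr_min:
            flags.add("low_snr")
        if len(rows) < min_spikes:
            flags.add("low_count")
        units.append(
            PutativeUnit(
                unit_id=uid,
                channel=cc.channel,
                times_s=np.sort(times),
                mean_waveform=wf.mean(axis=0),
                snr=snr,
                rate_hz=rate,
                n_spikes=len(rows),
                flags=flags,
                spike_indices=rows,
            )
        )
        uid += 1
    return units
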