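"""Spike detection, wavelet features and superparamagnetic clustering.

Detection runs on the 500-5000 Hz band-passed trace with a robust-sigma
amplitude threshold. Each 64-sample spike window is expanded into 64
coefficients of a 4-level Haar multi-resolution decomposition; the most
multimodal coefficients (largest Lilliefors normality statistic) feed a
superparamagnetic clustering (SPC) of the Potts model:

    J_ij = (1/K) * exp(-||x_i - x_j||^2 / (2 a^2))     (KNN interactions)
    p_ij = 1 - exp(-J_ij / T)                          (same-state bonding)

with Swendsen-Wang cluster dynamics across a temperature sweep; pairs whose
co-membership correlation exceeds 0.5 define the clusters at each
temperature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import signal, sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.stats import norm

from .data_model import MerRecording, ValidationError

N_WAVEFORM_SAMPLES = 64
PEAK_INDEX = 20
LOCKOUT_MS = 1.5


@dataclass
class SpcParams:
    """Superparamagnetic-clustering knobs."""

    K: int = 11
    n_iter: int = 500
    temp_start: float = 0.01
    temp_stop: float = 0.251
    temp_step: float = 0.01
    min_cluster_size: int = 20
    n_states: int = 20  # Potts q
    correlation_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.K < 1 or self.n_iter < 1:
            raise ValidationError("K and n_iter must be >= 1")
        if not (0 < self.temp_start < self.temp_stop) or self.temp_step <= 0:
            raise ValidationError("temperature grid must be increasing and positive")

    @property
    def temperatures(self) -> np.ndarray:
        return np.arange(self.temp_start, self.temp_stop, self.temp_step)


@dataclass
class SpikeSortResult:
    """Full output of the sorting stage for one site."""

    timestamps: np.ndarray
    waveforms: np.ndarray
    features: np.ndarray
    selected_coeff_idx: np.ndarray
    labels_by_temperature: Dict[float, np.ndarray]
    final_labels: np.ndarray
    chosen_temperature: Optional[float]

    @property
    def n_spikes(self) -> int:
        return self.timestamps.size


# ---------------------------------------------------------------------------
# filtering & detection
# ---------------------------------------------------------------------------

def bandpass_spike_filter(
    samples: np.ndarray, fs: float, f_lo: float = 500.0, f_hi: float = 5000.0
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (500-5000 Hz)."""
    if fs <= 2 * f_hi:
        raise ValidationError(f"fs={fs} too low for a {f_hi} Hz band edge")
    sos = signal.butter(4, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(samples, dtype=float))


def robust_sigma(filtered: np.ndarray) -> float:
    """Noise sigma estimate: median(|x|) / 0.6745."""
    return float(np.median(np.abs(filtered)) / 0.6745)


def detect_spikes(
    filtered: np.ndarray,
    fs: float,
    k_thresh: float = 4.0,
    lockout_ms: float = LOCKOUT_MS,
    theta: Optional[float] = None,
) -> np.ndarray:
    """Timestamps (s) of supra-threshold excursions, either polarity.

    One spike per contiguous excursion of |x| above k * median(|x|)/0.6745,
    registered at the excursion's absolute extremum. Excursions within the
    lockout of the previous event are suppressed; if such an excursion
    carries a larger extremum it takes over the event (the zero-phase filter
    puts side-lobes of large spikes above threshold just before the trough,
    and the event must sit on the trough, not the lobe).

    ``theta`` overrides the computed threshold — e.g. to screen a
    reconstructed background against the original trace's threshold.
    """
    x = np.asarray(filtered, dtype=float)
    if x.size == 0:
        raise ValidationError("empty input")
    if theta is None:
        theta = k_thresh * robust_sigma(x)
    above = np.abs(x) > theta
    if not above.any():
        return np.empty(0)
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        stops = np.concatenate((stops, [x.size]))
    lockout = lockout_ms / 1000.0
    out: list = []
    amps: list = []
    for s, e in zip(starts, stops):
        peak = s + int(np.argmax(np.abs(x[s:e])))
        t = peak / fs
        a = abs(x[peak])
        if out and t - out[-1] < lockout:
            if a > amps[-1]:  # bigger extremum inside the lockout takes over
                out[-1], amps[-1] = t, a
            continue
        out.append(t)
        amps.append(a)
    return np.asarray(out)


def extract_waveforms(
    filtered: np.ndarray,
    timestamps: Sequence[float],
    fs: float,
    n_samples: int = N_WAVEFORM_SAMPLES,
    peak_index: int = PEAK_INDEX,
) -> Tuple[np.ndarray, np.ndarray]:
    """64-sample windows aligned with the extremum at ``peak_index``.

    Spikes whose window would cross an edge are dropped together with their
    timestamps. Returns (waveforms, kept_timestamps).
    """
    x = np.asarray(filtered, dtype=float)
    ts = np.asarray(timestamps, dtype=float)
    rows = []
    kept = []
    for t in ts:
        i = int(round(t * fs))
        start = i - peak_index
        if start < 0 or start + n_samples > x.size:
            continue
        rows.append(x[start : start + n_samples])
        kept.append(t)
    if not rows:
        return np.empty((0, n_samples)), np.empty(0)
    return np.vstack(rows), np.asarray(kept)


# ---------------------------------------------------------------------------
# Haar features & coefficient selection
# ---------------------------------------------------------------------------

def haar_features(waveforms: np.ndarray, levels: int = 4) -> np.ndarray:
    """4-level orthonormal Haar DWT of each 64-sample waveform.

    Coefficient order: level-4 approximation (4), then details level 4 (4),
    level 3 (8), level 2 (16), level 1 (32) — 64 coefficients total. The
    orthonormal convention preserves energy (Parseval).
    """
    w = np.atleast_2d(np.asarray(waveforms, dtype=float))
    if w.shape[1] != N_WAVEFORM_SAMPLES:
        raise ValidationError(
            f"waveforms must have {N_WAVEFORM_SAMPLES} columns, got {w.shape[1]}"
        )
    a = w
    details = []
    inv_sqrt2 = 1.0 / math.sqrt(2.0)
    for _ in range(levels):
        even, odd = a[:, ::2], a[:, 1::2]
        details.append((even - odd) * inv_sqrt2)
        a = (even + odd) * inv_sqrt2
    return np.hstack([a] + details[::-1])


def lilliefors_statistic(values: np.ndarray) -> float:
    """Max |ECDF - Phi| with mean/std estimated from the sample."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    sd = x.std(ddof=1)
    if sd == 0 or n < 4:
        return 0.0
    z = (x - x.mean()) / sd
    cdf = norm.cdf(z)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


def select_coefficients(features: np.ndarray, n_select: int = 10) -> np.ndarray:
    """Indices of the ``n_select`` most non-normal coefficients.

    Multimodal (non-normal) coefficients separate spike shapes best.
    Zero-variance coefficients are excluded; with fewer than 10 spikes all
    non-constant coefficients are returned with a warning.
    """
    f = np.atleast_2d(features)
    nonconstant = np.flatnonzero(f.std(axis=0) > 0)
    if f.shape[0] < 10:
        warnings.warn("fewer than 10 spikes; returning all non-constant coefficients")
        return nonconstant
    if nonconstant.size == 0:
        warnings.warn("all coefficients constant; empty selection")
        return nonconstant
    stats = np.array([lilliefors_statistic(f[:, j]) for j in nonconstant])
    order = np.argsort(stats)[::-1][:n_select]
    return np.sort(nonconstant[order])


# ---------------------------------------------------------------------------
# superparamagnetic clustering
# ---------------------------------------------------------------------------

def knn_interactions(
    points: np.ndarray, K: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """KNN edge list (i, j), interaction strengths J_ij, and scale a.

    ``a`` is the average nearest-neighbours distance (mean distance over all
    point-to-KNN pairs). Duplicate points give J = 1/K exactly.
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    n = x.shape[0]
    K = min(K, n - 1)
    tree = cKDTree(x)
    dists, idx = tree.query(x, k=K + 1)
    dists, idx = dists[:, 1:], idx[:, 1:]  # drop self
    a = float(dists.mean())
    src = np.repeat(np.arange(n), K)
    dst = idx.reshape(-1)
    d = dists.reshape(-1)
    # undirected unique edges
    lo = np.minimum(src, dst)
    hi = np.maximum(src, dst)
    order = np.lexsort((hi, lo))
    lo, hi, d = lo[order], hi[order], d[order]
    keep = np.ones(lo.size, dtype=bool)
    keep[1:] = (lo[1:] != lo[:-1]) | (hi[1:] != hi[:-1])
    lo, hi, d = lo[keep], hi[keep], d[keep]
    if a > 0:
        J = np.exp(-(d**2) / (2.0 * a**2)) / K
    else:
        J = np.full(d.shape, 1.0 / K)
    return lo, hi, J, a


def bond_probability(J: np.ndarray, T: float) -> np.ndarray:
    """p = 1 - exp(-J/T) for same-state neighbours."""
    return 1.0 - np.exp(-np.asarray(J, dtype=float) / T)


def _components_from_edges(
    n: int, ei: np.ndarray, ej: np.ndarray, active: np.ndarray
) -> np.ndarray:
    if not active.any():
        return np.arange(n)
    g = sparse.coo_matrix(
        (np.ones(int(active.sum())), (ei[active], ej[active])), shape=(n, n)
    )
    _, labels = connected_components(g, directed=False)
    return labels


def _sizes_labels(n: int, comp: np.ndarray) -> np.ndarray:
    """Relabel components by decreasing size, 1-based; singletons get 0."""
    counts = np.bincount(comp)
    order = np.argsort(counts)[::-1]
    label_of = np.zeros(counts.size, dtype=int)
    nxt = 1
    for c in order:
        if counts[c] >= 2:
            label_of[c] = nxt
            nxt += 1
    return label_of[comp]


def spc_cluster(
    features: np.ndarray,
    params: Optional[SpcParams] = None,
    seed: Optional[int] = None,
) -> Dict[float, np.ndarray]:
    """Swendsen-Wang Potts dynamics over the temperature grid.

    At each temperature ``n_iter`` full sweeps are run (first 20% burn-in);
    the co-membership frequency of each KNN edge across the remaining
    sweeps estimates the point-point correlation, and edges above the 0.5
    threshold define the clusters. One seeded stream drives the whole
    sweep, so results are reproducible.
    """
    params = params or SpcParams()
    x = np.atleast_2d(np.asarray(features, dtype=float))
    n = x.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 spikes to cluster")
    if n <= params.K:
        warnings.warn(f"fewer points than K={params.K}; reducing to {n - 1}")
    ei, ej, J, _ = knn_interactions(x, params.K)
    rng = np.random.default_rng(seed)
    q = params.n_states
    burn_in = max(1, params.n_iter // 5)
    n_keep = params.n_iter - burn_in

    labels_by_temperature: Dict[float, np.ndarray] = {}
    for T in params.temperatures:
        p_bond = bond_probability(J, float(T))
        states = rng.integers(0, q, size=n)
        cooccur = np.zeros(ei.size)
        for sweep in range(params.n_iter):
            same = states[ei] == states[ej]
            bonded = same & (rng.random(ei.size) < p_bond)
            comp = _components_from_edges(n, ei, ej, bonded)
            # flip every SW cluster to a fresh random Potts state
            states = rng.integers(0, q, size=comp.max() + 1)[comp]
            if sweep >= burn_in:
                cooccur += comp[ei] == comp[ej]
        corr = cooccur / n_keep
        linked = corr > params.correlation_threshold
        final_comp = _components_from_edges(n, ei, ej, linked)
        labels_by_temperature[float(T)] = _sizes_labels(n, final_comp)
    return labels_by_temperature


def choose_temperature(
    labels_by_temperature: Dict[float, np.ndarray],
    min_cluster_size: int = 20,
) -> Tuple[Optional[float], np.ndarray]:
    """Temperature of the superparamagnetic plateau.

    The cluster structure is stable across the superparamagnetic phase and
    melts gradually above it, so the temperature picked is the one carrying
    the richest persistent structure: the maximal number of non-trivial
    (>= min_cluster_size) clusters, then the largest number of assigned
    points, then the highest temperature. Structure past the melting point
    is not persistent, so a temperature only competes when at least half
    the points remain assigned and its cluster count is corroborated by an
    adjacent temperature in the grid. Points outside surviving clusters are
    labelled 0. If no temperature yields a non-trivial cluster every spike
    falls back to a single unit with a warning.
    """
    if not labels_by_temperature:
        raise ValidationError("empty temperature sweep")
    temps = sorted(labels_by_temperature)
    n = labels_by_temperature[temps[0]].size
    n_clusters = []
    assigned_counts = []
    for T in temps:
        counts = np.bincount(labels_by_temperature[T])
        survivors = [c for c in range(1, counts.size) if counts[c] >= min_cluster_size]
        n_clusters.append(len(survivors))
        assigned_counts.append(int(sum(counts[c] for c in survivors)))
    best_key = None
    best_T = None
    for i, T in enumerate(temps):
        if n_clusters[i] == 0 or assigned_counts[i] < n // 2:
            continue
        persistent = (i > 0 and n_clusters[i - 1] == n_clusters[i]) or (
            i + 1 < len(temps) and n_clusters[i + 1] == n_clusters[i]
        )
        if len(temps) > 1 and not persistent:
            continue
        key = (n_clusters[i], assigned_counts[i], T)
        if best_key is None or key >= best_key:
            best_key, best_T = key, T
    if best_T is None:
        warnings.warn("no cluster reached min_cluster_size; single-unit fallback")
        return None, np.ones(n, dtype=int)
    labels = labels_by_temperature[best_T]
    counts = np.bincount(labels)
    survivors = [c for c in range(1, counts.size) if counts[c] >= min_cluster_size]
    out = np.zeros(n, dtype=int)
    for new, c in enumerate(sorted(survivors, key=lambda c: -counts[c]), start=1):
        out[labels == c] = new
    return best_T, out


# ---------------------------------------------------------------------------
# full stage
# ---------------------------------------------------------------------------

def sort_spikes(
    rec: MerRecording,
    k_thresh: float = 4.0,
    n_select: int = 10,
    params: Optional[SpcParams] = None,
    seed: Optional[int] = None,
    cluster: bool = True,
) -> SpikeSortResult:
    """Filter, detect, featurise and (optionally) cluster one site's spikes.

    With ``cluster=False`` all detected spikes are assigned to unit 1 —
    sufficient for the pooled spike-train statistics.
    """
    params = params or SpcParams()
    filtered = bandpass_spike_filter(rec.samples, rec.fs)
    ts = detect_spikes(filtered, rec.fs, k_thresh=k_thresh)
    waveforms, ts = extract_waveforms(filtered, ts, rec.fs)
    n = ts.size
    if n == 0:
        return SpikeSortResult(
            timestamps=ts,
            waveforms=waveforms,
            features=np.empty((0, N_WAVEFORM_SAMPLES)),
            selected_coeff_idx=np.empty(0, dtype=int),
            labels_by_temperature={},
            final_labels=np.empty(0, dtype=int),
            chosen_temperature=None,
        )
    feats = haar_features(waveforms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = select_coefficients(feats, n_select=n_select)
    min_size = max(params.min_cluster_size, int(math.ceil(0.02 * n)))
    if not cluster or n < 2 or sel.size == 0:
        return SpikeSortResult(
            timestamps=ts,
            waveforms=waveforms,
            features=feats,
            selected_coeff_idx=sel,
            labels_by_temperature={},
            final_labels=np.ones(n, dtype=int),
            chosen_temperature=None,
        )
    sweep = spc_cluster(feats[:, sel], params=params, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        chosen_T, final = choose_temperature(sweep, min_cluster_size=min_size)
    return SpikeSortResult(
        timestamps=ts,
        waveforms=waveforms,
        features=feats,
        selected_coeff_idx=sel,
        labels_by_temperature=sweep,
        final_labels=final,
        chosen_temperature=chosen_T,
    )
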