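"""Per-site parameter battery.

Spike-train statistics (epoch firing rates, modal interspike interval,
burst index, refractoriness-compensated local variation) and Welch-spectrum
band features (mean amplitude, maximum peak and in-band RMS) over the
canonical frequency bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import signal

from .data_model import MerRecording, SiteFeatures, ValidationError


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValidationError(f"invalid band {self.name}: [{self.f_lo}, {self.f_hi}]")

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo


#: Canonical analysis bands. ``beta`` is the union of low and high beta and
#: therefore excluded from the disjoint set used for the RMS aggregates.
CANONICAL_BANDS: Tuple[BandSpec, ...] = (
    BandSpec("low", 2.0, 7.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("low_beta", 13.0, 20.0),
    BandSpec("high_beta", 21.0, 30.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma", 31.0, 49.0),
)

DISJOINT_BANDS: Tuple[str, ...] = ("low", "alpha", "low_beta", "high_beta", "gamma")

_BAND_TO_FEATURE = {
    "low": ("Mean_low_freq", "Max_low_freq"),
    "alpha": ("Mean_Alpha", "Max_Alpha"),
    "low_beta": ("Mean_low_Beta", "Max_low_Beta"),
    "high_beta": ("Mean_high_Beta", "Max_high_Beta"),
    "beta": ("Mean_Beta", "Max_Beta"),
    "gamma": ("Mean_Gamma", "Max_Gamma"),
}


@dataclass
class IsiStats:
    """Interspike-interval statistics for one site (intervals in ms)."""

    isis: np.ndarray
    modal_isi_ms: float
    mean_rate_hz: float
    bi: float
    lvr: float
    refractoriness_ms: float
    n: int


# ---------------------------------------------------------------------------
# spike-train statistics
# ---------------------------------------------------------------------------

def spike_rates(
    timestamps: Sequence[float], duration_s: float, epoch_len_s: float = 0.5
) -> Tuple[float, float]:
    """Mean and maximum firing rate over non-overlapping epochs.

    Reuses the 0.5 s epoch grid of the artifact-removal stage. A zero-spike
    train yields (0, 0).
    """
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    ts = np.asarray(timestamps, dtype=float)
    n_epochs = max(1, int(math.floor(duration_s / epoch_len_s)))
    counts = np.zeros(n_epochs)
    if ts.size:
        idx = np.floor(ts / epoch_len_s).astype(int)
        idx = idx[(idx >= 0) & (idx < n_epochs)]
        np.add.at(counts, idx, 1.0)
    rates = counts / epoch_len_s
    return float(rates.mean()), float(rates.max())


def modal_isi(isis_ms: Sequence[float], bin_ms: float = 1.0) -> float:
    """Mode of the ISI distribution at 1 ms binning.

    Returns the centre of the most populated bin (bins anchored at 0, so an
    ISI of 10 ms falls in the [10, 11) ms bin whose centre is 10.5 ms).
    Ties break toward the smaller interval. NaN when fewer than 2 ISIs.
    """
    isis = np.asarray(isis_ms, dtype=float)
    if isis.size < 2:
        return math.nan
    idx = np.floor(isis / bin_ms).astype(int)
    counts = np.bincount(idx)
    best = int(np.argmax(counts))  # argmax takes the first (smallest) bin on ties
    return (best + 0.5) * bin_ms


def burst_index(modal_isi_ms: float, mean_rate_hz: float) -> float:
    """BI = reciprocal of the modal interval (in Hz) divided by mean rate."""
    if not (modal_isi_ms > 0) or not (mean_rate_hz > 0):
        return math.nan
    return (1000.0 / modal_isi_ms) / mean_rate_hz


def lvr(isis_ms: Sequence[float], R_ms: float = 5.0) -> float:
    """Refractoriness-compensated local variation of the ISI sequence.

    LvR = 3/(n-1) * sum_i (1 - 4 I_i I_{i+1} / (I_i + I_{i+1})^2)
                        * (1 + 4 R / (I_i + I_{i+1}))

    with intervals and R in ms. ~0 for regular trains, ~1 for Poisson.
    NaN when fewer than 2 intervals.
    """
    I = np.asarray(isis_ms, dtype=float)
    n = I.size
    if n < 2:
        return math.nan
    s = I[:-1] + I[1:]
    cross = 4.0 * I[:-1] * I[1:] / s**2
    terms = (1.0 - cross) * (1.0 + 4.0 * R_ms / s)
    return float(3.0 / (n - 1) * terms.sum())


def isi_stats(
    timestamps_s: Sequence[float], R_ms: float = 5.0, bin_ms: float = 1.0
) -> IsiStats:
    """Assemble the ISI battery from pooled spike timestamps (seconds)."""
    ts = np.sort(np.asarray(timestamps_s, dtype=float))
    isis = np.diff(ts) * 1000.0
    mean_rate = math.nan
    if isis.size:
        mean_rate = 1000.0 / isis.mean()
    mode = modal_isi(isis, bin_ms=bin_ms)
    return IsiStats(
        isis=isis,
        modal_isi_ms=mode,
        mean_rate_hz=mean_rate,
        bi=burst_index(mode, mean_rate) if not math.isnan(mode) else math.nan,
        lvr=lvr(isis, R_ms=R_ms),
        refractoriness_ms=R_ms,
        n=isis.size,
    )


# ---------------------------------------------------------------------------
# spectral features
# ---------------------------------------------------------------------------

def welch_amplitude_spectrum(
    samples: np.ndarray, fs: float, window_s: float = 1.0
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Welch PSD (1 s Hamming windows, 50% overlap) and amplitude sqrt(PSD).

    Returns (freqs, psd, amplitude). 1 Hz resolution at window_s = 1.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2 * window_s * fs:
        raise ValidationError("need at least 2 s of signal for Welch features")
    nperseg = int(round(window_s * fs))
    freqs, psd = signal.welch(
        x, fs=fs, window="hamming", nperseg=nperseg, noverlap=nperseg // 2
    )
    return freqs, psd, np.sqrt(psd)


def band_features(
    samples: np.ndarray,
    fs: float,
    bands: Sequence[BandSpec] = CANONICAL_BANDS,
    window_s: float = 1.0,
) -> Dict[str, Dict[str, float]]:
    """Per-band (mean_amplitude, max_peak, rms) from the Welch spectrum.

    mean_amplitude and max_peak are computed on the amplitude spectrum
    sqrt(PSD); rms = sqrt(mean in-band PSD × band width).
    """
    freqs, psd, amp = welch_amplitude_spectrum(samples, fs, window_s=window_s)
    out: Dict[str, Dict[str, float]] = {}
    for band in bands:
        sel = (freqs >= band.f_lo) & (freqs <= band.f_hi)
        if not sel.any():
            raise ValidationError(f"no spectral bins inside band {band.name}")
        out[band.name] = {
            "mean_amplitude": float(amp[sel].mean()),
            "max_peak": float(amp[sel].max()),
            "rms": float(math.sqrt(psd[sel].mean() * band.width)),
        }
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def site_features(
    rec: MerRecording,
    timestamps_s: Sequence[float],
    background_samples: np.ndarray,
    R_ms: float = 5.0,
    epoch_len_s: float = 0.5,
    welch_window_s: float = 1.0,
) -> SiteFeatures:
    """Assemble the 19-parameter battery for one site.

    Spike statistics are computed on the pooled (all clusters) timestamps;
    band features on the reconstructed background trace.
    """
    if rec is None or background_samples is None:
        missing = [n for n, v in (("recording", rec), ("background", background_samples)) if v is None]
        raise ValidationError(f"missing stage outputs: {missing}")
    feats = SiteFeatures()

    mean_sr, max_sr = spike_rates(timestamps_s, rec.duration_s, epoch_len_s=epoch_len_s)
    feats.Mean_SR = mean_sr
    feats.Max_SR = max_sr

    stats = isi_stats(timestamps_s, R_ms=R_ms)
    feats.ISI = stats.modal_isi_ms
    feats.BI = stats.bi
    feats.LvR = stats.lvr

    spectral = band_features(background_samples, rec.fs, window_s=welch_window_s)
    for band_name, (mean_field, max_field) in _BAND_TO_FEATURE.items():
        setattr(feats, mean_field, spectral[band_name]["mean_amplitude"])
        setattr(feats, max_field, spectral[band_name]["max_peak"])
    rms_values = [spectral[name]["rms"] for name in DISJOINT_BANDS]
    feats.Mean_RMS = float(np.mean(rms_values))
    feats.Max_RMS = float(np.max(rms_values))
    return feats
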