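"""Exogenous-artifact removal.

The trace is trimmed to 30 s, split into non-overlapping 0.5 s epochs, and
each epoch boundary is scored with the variance coefficient

    vc[k] = var(s[k]) / var(s[k-1])

Epochs whose incoming coefficient strictly exceeds 1.8 are discarded and
the surviving epochs are re-joined with short monotone piecewise-cubic
(pchip) bridges so concatenation itself does not inject artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import PchipInterpolator

from .data_model import MerRecording, ValidationError

VC_THRESHOLD = 1.8
MAX_TRACE_S = 30.0


@dataclass
class EpochArray:
    """Equal-length epochs of one trace with keep/reject bookkeeping."""

    epochs: np.ndarray  # (n_epochs, samples_per_epoch)
    epoch_len_s: float
    fs: float
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    vc: Optional[np.ndarray] = None  # length n_epochs - 1; vc[j] is the j+1'th epoch's

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 2:
            raise ValidationError("epochs must be a 2-D array")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.n_epochs, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[1]


def segment_epochs(
    rec: MerRecording, epoch_len_s: float = 0.5, max_trace_s: float = MAX_TRACE_S
) -> EpochArray:
    """Trim to 30 s, split into floor(duration/epoch_len) epochs.

    Trailing remainder samples are dropped.
    """
    if rec.duration_s < epoch_len_s:
        raise ValidationError(
            f"recording of {rec.duration_s:.3f} s shorter than one epoch ({epoch_len_s} s)"
        )
    x = rec.samples
    max_n = int(round(max_trace_s * rec.fs))
    if x.size > max_n:
        x = x[:max_n]
    spe = int(round(epoch_len_s * rec.fs))
    n_epochs = x.size // spe
    epochs = x[: n_epochs * spe].reshape(n_epochs, spe)
    return EpochArray(epochs=epochs, epoch_len_s=epoch_len_s, fs=rec.fs)


def variance_coefficients(ep: EpochArray) -> np.ndarray:
    """vc[k-1] = var(epoch k) / var(epoch k-1), population variance.

    A zero-variance predecessor makes the boundary coefficient infinite;
    zero-variance epochs are additionally flagged for rejection.
    """
    if ep.n_epochs < 2:
        raise ValidationError("need at least 2 epochs for variance coefficients")
    variances = ep.epochs.var(axis=1)  # population variance (ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vc = variances[1:] / variances[:-1]
    vc[~np.isfinite(vc)] = math.inf
    ep.vc = vc
    ep.kept_mask &= variances > 0  # degenerate epochs never survive
    return vc


def reject_epochs(ep: EpochArray, threshold: float = VC_THRESHOLD) -> EpochArray:
    """Mark epoch k rejected when its incoming vc strictly exceeds threshold.

    The first epoch has no coefficient and is kept (unless zero-variance).
    A coefficient exactly equal to the threshold keeps the epoch.
    """
    if ep.vc is None:
        variance_coefficients(ep)
    rejected = np.concatenate(([False], ep.vc > threshold))
    ep.kept_mask &= ~rejected
    return ep


def stitch_clean(
    ep: EpochArray,
    fs: Optional[float] = None,
    bridge_ms: float = 2.0,
    n_anchors: int = 5,
) -> np.ndarray:
    """Concatenate kept epochs, bridging each excision with a pchip segment.

    The bridge spans ``bridge_ms`` of synthetic samples interpolated through
    ``n_anchors`` anchor samples on each side of the junction; monotone
    Hermite interpolation guarantees no overshoot beyond the anchors.
    """
    fs = fs if fs is not None else ep.fs
    kept_idx = np.flatnonzero(ep.kept_mask)
    if kept_idx.size == 0:
        raise ValidationError("all epochs rejected; site unusable")
    if kept_idx.size == ep.n_epochs:
        return ep.epochs.reshape(-1).copy()

    n_bridge = int(round(bridge_ms / 1000.0 * fs))
    pieces = [ep.epochs[kept_idx[0]]]
    for prev, cur in zip(kept_idx[:-1], kept_idx[1:]):
        if cur == prev + 1:
            pieces.append(ep.epochs[cur])
            continue
        left = pieces[-1][-n_anchors:]
        right = ep.epochs[cur][:n_anchors]
        xs = np.concatenate(
            [
                np.arange(-n_anchors, 0, dtype=float),
                np.arange(n_bridge, n_bridge + n_anchors, dtype=float),
            ]
        )
        interp = PchipInterpolator(xs, np.concatenate([left, right]))
        bridge = interp(np.arange(0, n_bridge, dtype=float))
        pieces.append(bridge)
        pieces.append(ep.epochs[cur])
    return np.concatenate(pieces)


def clean_recording(
    rec: MerRecording,
    epoch_len_s: float = 0.5,
    threshold: float = VC_THRESHOLD,
    bridge_ms: float = 2.0,
    n_anchors: int = 5,
) -> tuple[MerRecording, EpochArray]:
    """Full artifact-removal stage for one site."""
    ep = segment_epochs(rec, epoch_len_s=epoch_len_s)
    variance_coefficients(ep)
    reject_epochs(ep, threshold=threshold)
    clean = stitch_clean(ep, fs=rec.fs, bridge_ms=bridge_ms, n_anchors=n_anchors)
    out = MerRecording(
        samples=clean, fs=rec.fs, trajectory=rec.trajectory, depth_mm=rec.depth_mm
    )
    return out, ep
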