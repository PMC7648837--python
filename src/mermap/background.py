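"""Background-activity reconstruction.

Each detected spike is excised by replacing the window 0.5 ms before to
2.5 ms after its timestamp with a 3 ms stretch of spike-free signal drawn
(seeded-uniformly) from elsewhere in the same trace, cross-faded over
0.25 ms at both edges; the patched trace is then low-pass filtered at
500 Hz (4th-order Butterworth, zero-phase).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .data_model import ValidationError

PRE_MS = 0.5
POST_MS = 2.5
FADE_MS = 0.25
DONOR_CLEARANCE_MS = 3.0
LOWPASS_HZ = 500.0


@dataclass
class BackgroundTrace:
    """Spike-free low-passed background series for one site."""

    samples: np.ndarray
    fs: float
    n_patches: int
    patch_source_offsets: np.ndarray
    seed: Optional[int]


def lowpass_background(samples: np.ndarray, fs: float, f_hi: float = LOWPASS_HZ) -> np.ndarray:
    sos = signal.butter(4, f_hi, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(samples, dtype=float))


def reconstruct_background(
    raw: np.ndarray,
    timestamps: Sequence[float],
    fs: float,
    seed: Optional[int] = None,
) -> BackgroundTrace:
    """Patch out every spike window, then low-pass at 500 Hz.

    Donor segments are chosen uniformly among starts whose 3 ms window stays
    at least 3 ms away from every spike window. Raises when spiking is so
    dense that no donor exists.
    """
    x = np.asarray(raw, dtype=float)
    if x.size == 0:
        raise ValidationError("empty trace")
    ts = np.sort(np.asarray(timestamps, dtype=float))
    n = x.size

    pre = int(round(PRE_MS / 1000.0 * fs))
    post = int(round(POST_MS / 1000.0 * fs))
    width = pre + post
    fade = max(1, int(round(FADE_MS / 1000.0 * fs)))
    clearance = int(round(DONOR_CLEARANCE_MS / 1000.0 * fs))

    if ts.size == 0:
        return BackgroundTrace(
            samples=lowpass_background(x, fs),
            fs=fs,
            n_patches=0,
            patch_source_offsets=np.empty(0, dtype=int),
            seed=seed,
        )
    if ts.min() < 0 or ts.max() * fs >= n:
        raise ValidationError("timestamps out of bounds")

    # spike windows, dilated by the clearance, define forbidden donor samples
    forbidden = np.zeros(n + 1, dtype=np.int64)
    starts = np.maximum(0, (ts * fs).round().astype(int) - pre)
    stops = np.minimum(n, (ts * fs).round().astype(int) + post)
    np.add.at(forbidden, np.maximum(0, starts - clearance), 1)
    np.add.at(forbidden, np.minimum(n, stops + clearance), -1)
    bad = np.cumsum(forbidden[:-1]) > 0

    # donor start s is eligible when [s, s+width) contains no bad sample
    csum = np.concatenate(([0], np.cumsum(bad)))
    max_start = n - width
    if max_start < 0:
        raise ValidationError("trace shorter than one patch window")
    cand = np.arange(max_start + 1)
    eligible = cand[csum[cand + width] - csum[cand] == 0]
    if eligible.size == 0:
        raise ValidationError("spiking too dense: no spike-free 3 ms donor segment")

    rng = np.random.default_rng(seed)
    patched = x.copy()
    ramp = np.linspace(0.0, 1.0, fade, endpoint=False)
    offsets = []
    for s, e in zip(starts, stops):
        w = e - s
        donor_start = int(rng.choice(eligible))
        donor = x[donor_start : donor_start + w].copy()
        if w > 2 * fade:
            donor[:fade] = (1 - ramp) * patched[s : s + fade] + ramp * donor[:fade]
            donor[-fade:] = ramp[::-1] * patched[e - fade : e] + (1 - ramp[::-1]) * donor[-fade:]
        patched[s:e] = donor
        offsets.append(donor_start)

    return BackgroundTrace(
        samples=lowpass_background(patched, fs),
        fs=fs,
        n_patches=len(offsets),
        patch_source_offsets=np.asarray(offsets, dtype=int),
        seed=seed,
    )
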