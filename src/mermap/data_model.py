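"""Core domain types shared by every pipeline stage.

Conventions fixed across the package:

* voltages are microvolts (µV)
* depths are signed millimetres relative to the planned target
  (negative = dorsal / above target, 0 = target, positive = ventral)
* trajectories are the five Ben's-Gun needle positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

TRAJECTORIES: Tuple[str, ...] = ("central", "anterior", "posterior", "medial", "lateral")

STANDARD_DEPTHS_MM: Tuple[int, ...] = tuple(range(-10, 5))  # -10 … +4 inclusive

#: The 19 automated per-site parameters, in canonical column order.
FEATURE_NAMES: Tuple[str, ...] = (
    "Mean_low_freq", "Max_low_freq",
    "Mean_Alpha", "Max_Alpha",
    "Mean_low_Beta", "Max_low_Beta",
    "Mean_high_Beta", "Max_high_Beta",
    "Mean_Beta", "Max_Beta",
    "Mean_Gamma", "Max_Gamma",
    "Mean_RMS", "Max_RMS",
    "ISI", "BI", "LvR",
    "Mean_SR", "Max_SR",
)

SiteKey = Tuple[str, int]  # (trajectory, depth_mm)


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class MerRecording:
    """One site's raw extracellular trace.

    Parameters
    ----------
    samples : np.ndarray
        Voltage series in µV.
    fs : float
        Sampling rate in Hz.
    trajectory : str
        One of ``TRAJECTORIES``.
    depth_mm : int
        Signed depth relative to target (negative above).
    """

    samples: np.ndarray
    fs: float
    trajectory: str
    depth_mm: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValidationError("samples must be a 1-D voltage series")
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if self.trajectory not in TRAJECTORIES:
            raise ValidationError(
                f"unknown trajectory {self.trajectory!r}; expected one of {TRAJECTORIES}"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MerRecording):
            return NotImplemented
        return (
            self.fs == other.fs
            and self.trajectory == other.trajectory
            and self.depth_mm == other.depth_mm
            and np.array_equal(self.samples, other.samples)
        )


@dataclass
class Session:
    """A single hemisphere's Ben's-Gun recording session.

    ``recordings`` maps ``(trajectory, depth_mm)`` to one :class:`MerRecording`;
    all recordings must share one sampling rate.
    """

    recordings: Dict[SiteKey, MerRecording] = field(default_factory=dict)
    hemisphere: str = "left"
    metadata: Dict[str, str] = field(default_factory=dict)

    def add(self, rec: MerRecording) -> None:
        key = (rec.trajectory, rec.depth_mm)
        if key in self.recordings:
            raise ValidationError(f"duplicate recording for site {key}")
        if self.recordings:
            fs0 = next(iter(self.recordings.values())).fs
            if rec.fs != fs0:
                raise ValidationError(
                    f"inconsistent sampling rate at site {key}: {rec.fs} != {fs0}"
                )
        self.recordings[key] = rec

    @property
    def fs(self) -> float:
        if not self.recordings:
            raise ValidationError("empty session has no sampling rate")
        return next(iter(self.recordings.values())).fs

    def sites(self):
        return sorted(
            self.recordings.keys(),
            key=lambda k: (TRAJECTORIES.index(k[0]), k[1]),
        )

    def validate(self) -> None:
        rates = {rec.fs for rec in self.recordings.values()}
        if len(rates) > 1:
            bad = sorted(
                k for k, r in self.recordings.items() if r.fs != self.fs
            )
            raise ValidationError(f"inconsistent fs across sites: {bad}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        return (
            self.hemisphere == other.hemisphere
            and dict(self.metadata) == dict(other.metadata)
            and set(self.recordings) == set(other.recordings)
            and all(self.recordings[k] == other.recordings[k] for k in self.recordings)
        )


@dataclass
class SiteFeatures:
    """The 19-parameter automated battery for one recording site.

    Spectral features are non-negative; Max_* dominates Mean_* within a
    band. ISI/BI/LvR are NaN ("missing") when too few spikes exist.
    """

    Mean_low_freq: float = math.nan
    Max_low_freq: float = math.nan
    Mean_Alpha: float = math.nan
    Max_Alpha: float = math.nan
    Mean_low_Beta: float = math.nan
    Max_low_Beta: float = math.nan
    Mean_high_Beta: float = math.nan
    Max_high_Beta: float = math.nan
    Mean_Beta: float = math.nan
    Max_Beta: float = math.nan
    Mean_Gamma: float = math.nan
    Max_Gamma: float = math.nan
    Mean_RMS: float = math.nan
    Max_RMS: float = math.nan
    ISI: float = math.nan
    BI: float = math.nan
    LvR: float = math.nan
    Mean_SR: float = math.nan
    Max_SR: float = math.nan

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def get(self, name: str) -> float:
        if name not in FEATURE_NAMES:
            raise KeyError(f"unknown feature {name!r}")
        return getattr(self, name)
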