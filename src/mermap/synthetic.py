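"""Synthetic Ben's-Gun session generator with full ground truth.

Each site is background Gaussian noise plus narrow-band oscillatory
components (band-limited filtered noise at configured powers) plus biphasic
spike waveforms placed at gamma-renewal spike times with a refractory dead
time. Region-dependent profiles give low firing/background in thalamus-ZI,
high firing and low-beta oscillation in STN, and high regular firing with
gamma oscillation in SNr. Exogenous artifacts (line bursts, high-variance
transients) can be injected on top, with every injected quantity recorded
in the ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .data_model import (
    STANDARD_DEPTHS_MM,
    TRAJECTORIES,
    MerRecording,
    Session,
    SiteKey,
    ValidationError,
)
from .features import CANONICAL_BANDS

REGIONS = ("thalamus_zi", "stn", "white_matter", "snr")

_BAND_EDGES = {b.name: (b.f_lo, b.f_hi) for b in CANONICAL_BANDS}


@dataclass
class RegionProfile:
    """Signal statistics of one anatomical region."""

    region: str
    firing_rate_hz: float
    n_units: int
    spike_amplitude_uv: Tuple[float, float]
    background_sigma_uv: float
    band_power_uv2: Dict[str, float]
    isi_regularity: float = 1.0  # gamma-renewal shape; 1 = Poisson-with-dead-time
    refractory_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.firing_rate_hz < 0 or self.n_units < 0:
            raise ValidationError("firing rate and unit count must be non-negative")
        lo, hi = self.spike_amplitude_uv
        if not (0 < lo <= hi):
            raise ValidationError("spike amplitude range must be positive")
        if any(p < 0 for p in self.band_power_uv2.values()):
            raise ValidationError("band powers must be non-negative")


def default_profiles() -> Dict[str, RegionProfile]:
    """Documented default region profiles.

    Spike amplitudes 70-150 µV on 2-6 µV background; STN fires faster than
    thalamus-ZI and carries its largest oscillation in low beta (13-20 Hz);
    SNr fires at least as fast as STN, regularly, with its largest
    oscillation in gamma (31-49 Hz); white matter is silent.
    """
    return {
        "thalamus_zi": RegionProfile(
            region="thalamus_zi",
            firing_rate_hz=8.0,
            n_units=1,
            spike_amplitude_uv=(70.0, 95.0),
            background_sigma_uv=4.0,
            band_power_uv2={
                "low": 0.30, "alpha": 0.20, "low_beta": 0.10,
                "high_beta": 0.08, "gamma": 0.05,
            },
            isi_regularity=2.0,
        ),
        "white_matter": RegionProfile(
            region="white_matter",
            firing_rate_hz=0.0,
            n_units=0,
            spike_amplitude_uv=(70.0, 150.0),
            background_sigma_uv=2.0,
            band_power_uv2={
                "low": 0.05, "alpha": 0.03, "low_beta": 0.03,
                "high_beta": 0.02, "gamma": 0.02,
            },
        ),
        "stn": RegionProfile(
            region="stn",
            firing_rate_hz=35.0,
            n_units=2,
            spike_amplitude_uv=(70.0, 150.0),
            background_sigma_uv=5.5,
            band_power_uv2={
                "low": 0.30, "alpha": 0.30, "low_beta": 4.00,
                "high_beta": 1.00, "gamma": 0.40,
            },
            isi_regularity=1.0,  # irregular, bursty
        ),
        "snr": RegionProfile(
            region="snr",
            firing_rate_hz=60.0,
            n_units=1,
            spike_amplitude_uv=(80.0, 150.0),
            background_sigma_uv=4.5,
            band_power_uv2={
                "low": 0.20, "alpha": 0.20, "low_beta": 0.30,
                "high_beta": 0.30, "gamma": 3.00,
            },
            isi_regularity=6.0,  # relatively regular high-rate firing
        ),
    }


# ---------------------------------------------------------------------------
# waveforms and spike trains
# ---------------------------------------------------------------------------

def spike_template(
    fs: float, n_samples: int = 64, peak_index: int = 20, unit: int = 0
) -> np.ndarray:
    """Biphasic (~1.5 ms) spike template, negative trough normalised to -1.

    Distinct ``unit`` indices give shape variants (wider repolarisation,
    shifted positive phase) so multi-unit sites produce separable clusters.
    """
    scale = fs / 24000.0
    s = np.arange(n_samples)
    w_neg = (2.4 + 1.2 * unit) * scale
    w_pos = (5.0 + 0.8 * unit) * scale
    lag = (9.0 + 2.5 * unit) * scale
    pos_gain = 0.55 - 0.15 * min(unit, 3)
    wave = -np.exp(-0.5 * ((s - peak_index) / w_neg) ** 2)
    wave += pos_gain * np.exp(-0.5 * ((s - peak_index - lag) / w_pos) ** 2)
    # detrend edges so insertion does not introduce steps
    wave -= np.linspace(wave[0], wave[-1], n_samples)
    return wave / np.abs(wave).max()


def gamma_renewal_train(
    rate_hz: float,
    duration_s: float,
    shape: float,
    refractory_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spike times from a gamma renewal process with dead time."""
    if rate_hz <= 0:
        return np.empty(0)
    mean_isi = 1.0 / rate_hz
    free = mean_isi - refractory_s
    if free <= 0:
        raise ValidationError("firing rate incompatible with refractory period")
    n_draw = int(duration_s * rate_hz * 1.5) + 50
    isis = refractory_s + rng.gamma(shape, free / shape, size=n_draw)
    times = np.cumsum(isis) - isis[0] * rng.uniform()
    return times[(times >= 0) & (times < duration_s)]


def narrowband_noise(
    n: int, fs: float, f_lo: float, f_hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance noise band-limited to [f_lo, f_hi] Hz.

    Synthesized spectrally (white noise, out-of-band rFFT bins zeroed): an
    IIR band-pass at these tiny normalized frequencies (13 Hz at 24 kHz)
    leaks edge transients that corrupt the injected band power.
    """
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


# ---------------------------------------------------------------------------
# site generation
# ---------------------------------------------------------------------------

def generate_site(
    profile: RegionProfile,
    duration_s: float,
    fs: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    trajectory: str = "central",
    depth_mm: int = 0,
) -> Tuple[MerRecording, List[np.ndarray]]:
    """Generate one site and its per-unit ground-truth spike trains.

    Spike times are reported at the template trough sample. Identical
    (profile, duration, fs, seed) reproduce bit-identical output.
    """
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    active = [f for f, p in profile.band_power_uv2.items() if p > 0]
    f_max = max((_BAND_EDGES[b][1] for b in active), default=0.0)
    if fs < 2 * f_max:
        raise ValidationError(f"fs={fs} below Nyquist for {f_max} Hz component")
    if rng is None:
        rng = np.random.default_rng(seed)

    n = int(round(duration_s * fs))
    samples = profile.background_sigma_uv * rng.standard_normal(n)
    for band_name in sorted(profile.band_power_uv2):
        power = profile.band_power_uv2[band_name]
        if power <= 0:
            continue
        f_lo, f_hi = _BAND_EDGES[band_name]
        samples += math.sqrt(power) * narrowband_noise(n, fs, f_lo, f_hi, rng)

    n_wave = max(8, int(round(64 * fs / 24000.0)))
    peak_idx = int(round(20 * fs / 24000.0))
    trains: List[np.ndarray] = []
    lo, hi = profile.spike_amplitude_uv
    for unit in range(profile.n_units):
        template = spike_template(fs, n_samples=n_wave, peak_index=peak_idx, unit=unit)
        # stratified base amplitudes keep simultaneously active units distinct
        stratum = (unit + rng.uniform(0.25, 0.75)) / profile.n_units
        base_amp = lo + stratum * (hi - lo)
        times = gamma_renewal_train(
            profile.firing_rate_hz,
            duration_s,
            profile.isi_regularity,
            profile.refractory_ms / 1000.0,
            rng,
        )
        placed = []
        for t in times:
            i = int(round(t * fs))
            start = i - peak_idx
            if start < 0 or start + n_wave > n:
                continue
            amp = base_amp * rng.uniform(0.9, 1.1)  # ±10% jitter
            samples[start : start + n_wave] += amp * template
            placed.append(i / fs)
        trains.append(np.asarray(placed))

    rec = MerRecording(samples=samples, fs=fs, trajectory=trajectory, depth_mm=depth_mm)
    return rec, trains


def inject_artifacts(
    samples: np.ndarray,
    fs: float,
    rate_per_30s: float,
    sigma_uv: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, List[Tuple[float, float]]]:
    """Add line-frequency bursts and high-variance transients (additive).

    Returns the contaminated trace and the list of disjoint artifact
    windows in seconds.
    """
    n = samples.size
    duration = n / fs
    out = samples.copy()
    n_events = rng.poisson(rate_per_30s * duration / 30.0)
    windows: List[Tuple[float, float]] = []
    attempts = 0
    while len(windows) < n_events and attempts < 20 * max(1, n_events):
        attempts += 1
        width = rng.uniform(0.2, 0.8)
        t0 = rng.uniform(0, max(duration - width, 1e-9))
        t1 = t0 + width
        if any(t0 < w1 and t1 > w0 for w0, w1 in windows):
            continue
        i0, i1 = int(t0 * fs), int(t1 * fs)
        if i1 <= i0:
            continue
        seg = np.arange(i0, i1)
        taper = np.hanning(seg.size)
        if rng.uniform() < 0.5:  # power-line burst
            out[seg] += 10.0 * sigma_uv * taper * np.sin(
                2 * np.pi * 50.0 * seg / fs + rng.uniform(0, 2 * np.pi)
            )
        else:  # broadband high-variance transient
            out[seg] += 5.0 * sigma_uv * taper * rng.standard_normal(seg.size)
        windows.append((t0, t1))
    return out, sorted(windows)


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

@dataclass
class SessionGroundTruth:
    """Generator-side truth for a synthetic session."""

    region: Dict[SiteKey, str]
    spike_trains: Dict[SiteKey, List[np.ndarray]]
    band_power: Dict[SiteKey, Dict[str, float]]
    artifact_windows: Dict[SiteKey, List[Tuple[float, float]]]
    true_target_trajectory: str
    true_target_depth_mm: int
    snr_peak_depth: Dict[str, Optional[int]]
    seed: Optional[int]

    def pooled_spikes(self, key: SiteKey) -> np.ndarray:
        trains = self.spike_trains.get(key, [])
        if not trains:
            return np.empty(0)
        return np.sort(np.concatenate(trains))


@dataclass
class GeneratorConfig:
    """Layout and scaling knobs for :func:`generate_session`.

    ``region_layout`` maps trajectory → list of (depth_lo, depth_hi, region)
    spans covering the standard depths. The target trajectory's STN span
    carries an injected low-beta power peak at ``target_depth_mm``;
    off-target trajectories are attenuated by ``offtarget_gain``.
    """

    duration_s: float = 30.0
    fs: float = 24000.0
    target_trajectory: str = "central"
    target_depth_mm: int = -1
    region_layout: Dict[str, List[Tuple[int, int, str]]] = field(default_factory=dict)
    offtarget_gain: float = 0.6
    stn_beta_scale: float = 1.0
    beta_offpeak_factor: float = 0.45
    artifact_rate_per_30s: float = 0.0
    depths: Tuple[int, ...] = STANDARD_DEPTHS_MM
    profiles: Dict[str, RegionProfile] = field(default_factory=default_profiles)

    def __post_init__(self) -> None:
        if not self.region_layout:
            self.region_layout = default_region_layout(self.target_trajectory)


def default_region_layout(target_trajectory: str) -> Dict[str, List[Tuple[int, int, str]]]:
    """Electrode-track order thalamus-ZI → white matter → STN → WM → SNr.

    The target trajectory gets the full STN span (-3…+1); the others a
    shorter span (-2…0).
    """
    layout: Dict[str, List[Tuple[int, int, str]]] = {}
    for traj in TRAJECTORIES:
        if traj == target_trajectory:
            layout[traj] = [
                (-10, -5, "thalamus_zi"),
                (-4, -4, "white_matter"),
                (-3, 1, "stn"),
                (2, 2, "white_matter"),
                (3, 4, "snr"),
            ]
        else:
            layout[traj] = [
                (-10, -4, "thalamus_zi"),
                (-3, -3, "white_matter"),
                (-2, 0, "stn"),
                (1, 2, "white_matter"),
                (3, 4, "snr"),
            ]
    return layout


def region_at(config: GeneratorConfig, trajectory: str, depth_mm: int) -> str:
    for lo, hi, region in config.region_layout[trajectory]:
        if lo <= depth_mm <= hi:
            return region
    raise ValidationError(f"no region configured at ({trajectory}, {depth_mm})")


def _stn_span(config: GeneratorConfig, trajectory: str) -> Optional[Tuple[int, int]]:
    for lo, hi, region in config.region_layout[trajectory]:
        if region == "stn":
            return lo, hi
    return None


def _site_profile(
    config: GeneratorConfig, trajectory: str, depth_mm: int
) -> Tuple[RegionProfile, str]:
    """Region profile scaled by trajectory gain and low-beta depth profile."""
    region = region_at(config, trajectory, depth_mm)
    base = config.profiles[region]
    gain = 1.0 if trajectory == config.target_trajectory else config.offtarget_gain
    powers = {b: p * gain for b, p in base.band_power_uv2.items()}
    rate = base.firing_rate_hz * gain
    if region == "stn":
        span = _stn_span(config, trajectory)
        peak = (
            config.target_depth_mm
            if trajectory == config.target_trajectory
            else (span[0] + span[1]) // 2
        )
        shape_factor = 1.0 if depth_mm == peak else config.beta_offpeak_factor
        powers["low_beta"] = (
            base.band_power_uv2["low_beta"] * gain * config.stn_beta_scale * shape_factor
        )
    if region == "snr":
        # gamma power peaks at the first (dorsal-most) SNr depth
        for lo, hi, r in config.region_layout[trajectory]:
            if r == "snr":
                if depth_mm != lo:
                    powers["gamma"] = powers["gamma"] * config.beta_offpeak_factor
                break
    return replace(base, firing_rate_hz=rate, band_power_uv2=powers), region


def generate_session(
    config: GeneratorConfig, seed: Optional[int] = None
) -> Tuple[Session, SessionGroundTruth]:
    """Generate a full 5 × 15 session with ground truth.

    Determinism: per-site RNG streams are spawned from ``seed`` in fixed
    site order, so (config, seed) fully determines every sample.
    """
    span = _stn_span(config, config.target_trajectory)
    if span is None or not (span[0] <= config.target_depth_mm <= span[1]):
        raise ValidationError(
            f"target depth {config.target_depth_mm} outside the STN span "
            f"{span} of trajectory {config.target_trajectory!r}"
        )
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(TRAJECTORIES) * len(config.depths))

    session = Session(metadata={"generator_seed": str(seed)})
    truth = SessionGroundTruth(
        region={},
        spike_trains={},
        band_power={},
        artifact_windows={},
        true_target_trajectory=config.target_trajectory,
        true_target_depth_mm=config.target_depth_mm,
        snr_peak_depth={},
        seed=seed,
    )
    i = 0
    for traj in TRAJECTORIES:
        for lo, hi, r in config.region_layout[traj]:
            if r == "snr":
                truth.snr_peak_depth[traj] = lo
        truth.snr_peak_depth.setdefault(traj, None)
        for depth in config.depths:
            rng = np.random.default_rng(children[i])
            i += 1
            profile, region = _site_profile(config, traj, depth)
            rec, trains = generate_site(
                profile,
                config.duration_s,
                config.fs,
                rng=rng,
                trajectory=traj,
                depth_mm=depth,
            )
            windows: List[Tuple[float, float]] = []
            if config.artifact_rate_per_30s > 0:
                contaminated, windows = inject_artifacts(
                    rec.samples,
                    config.fs,
                    config.artifact_rate_per_30s,
                    profile.background_sigma_uv,
                    rng,
                )
                rec = MerRecording(
                    samples=contaminated, fs=config.fs, trajectory=traj, depth_mm=depth
                )
            key: SiteKey = (traj, depth)
            session.add(rec)
            truth.region[key] = region
            truth.spike_trains[key] = trains
            truth.band_power[key] = dict(profile.band_power_uv2)
            truth.artifact_windows[key] = windows
    return session, truth


# ---------------------------------------------------------------------------
# ground-truth sidecar (structured text)
# ---------------------------------------------------------------------------

def write_ground_truth(truth: SessionGroundTruth, path) -> None:
    import json

    payload = {
        "true_target_trajectory": truth.true_target_trajectory,
        "true_target_depth_mm": truth.true_target_depth_mm,
        "snr_peak_depth": {k: v for k, v in truth.snr_peak_depth.items()},
        "seed": truth.seed,
        "sites": {
            f"{traj}:{depth}": {
                "region": truth.region[(traj, depth)],
                "band_power": truth.band_power[(traj, depth)],
                "artifact_windows": truth.artifact_windows[(traj, depth)],
                "spike_trains": [t.tolist() for t in truth.spike_trains[(traj, depth)]],
            }
            for (traj, depth) in truth.region
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_ground_truth(path) -> SessionGroundTruth:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    truth = SessionGroundTruth(
        region={},
        spike_trains={},
        band_power={},
        artifact_windows={},
        true_target_trajectory=payload["true_target_trajectory"],
        true_target_depth_mm=int(payload["true_target_depth_mm"]),
        snr_peak_depth={
            k: (int(v) if v is not None else None)
            for k, v in payload["snr_peak_depth"].items()
        },
        seed=payload.get("seed"),
    )
    for site_key, info in payload["sites"].items():
        traj, depth_str = site_key.split(":")
        key = (traj, int(depth_str))
        truth.region[key] = info["region"]
        truth.band_power[key] = {k: float(v) for k, v in info["band_power"].items()}
        truth.artifact_windows[key] = [tuple(w) for w in info["artifact_windows"]]
        truth.spike_trains[key] = [np.asarray(t) for t in info["spike_trains"]]
    return truth
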