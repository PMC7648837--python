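import numpy as np
import pytest

from mermap.data_model import MerRecording
from mermap.synthetic import GeneratorConfig, RegionProfile, default_profiles, generate_site


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def stn_profile():
    return default_profiles()["stn"]


@pytest.fixture
def two_unit_profile():
    """A 2-unit site with distinct templates for end-to-end sorting tests."""
    return RegionProfile(
        region="stn",
        firing_rate_hz=18.0,
        n_units=2,
        spike_amplitude_uv=(80.0, 130.0),
        background_sigma_uv=4.0,
        band_power_uv2={"low_beta": 1.0},
        isi_regularity=1.0,
        refractory_ms=2.0,
    )


@pytest.fixture
def stn_site(stn_profile):
    rec, trains = generate_site(stn_profile, duration_s=5.0, fs=24000.0, seed=7)
    return rec, trains


@pytest.fixture
def small_session_config():
    """Reduced-duration session config so session-level tests stay fast."""
    return GeneratorConfig(duration_s=2.5)


def make_recording(samples, fs=24000.0, trajectory="central", depth_mm=0):
    return MerRecording(
        samples=np.asarray(samples, dtype=float),
        fs=fs,
        trajectory=trajectory,
        depth_mm=depth_mm,
    )


def match_events(detected, truth, tol_s=0.5e-3):
    """(recall over lockout-isolated truth, precision over all detections)."""
    detected = np.asarray(detected, dtype=float)
    truth = np.sort(np.asarray(truth, dtype=float))
    if truth.size == 0:
        return 1.0, (0.0 if detected.size else 1.0)
    iso = []
    for i, t in enumerate(truth):
        others = np.delete(truth, i)
        if others.size == 0 or np.abs(others - t).min() >= 1.5e-3:
            iso.append(t)
    iso = np.asarray(iso)
    recall = (
        float(np.mean([np.abs(detected - t).min() <= tol_s for t in iso]))
        if detected.size and iso.size
        else 0.0
    )
    precision = (
        float(np.mean([np.abs(truth - t).min() <= tol_s for t in detected]))
        if detected.size
        else 1.0
    )
    return recall, precision
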