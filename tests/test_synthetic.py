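import numpy as np
import pytest

from mermap.data_model import ValidationError
from mermap.features import welch_amplitude_spectrum
from mermap.synthetic import (
    GeneratorConfig,
    RegionProfile,
    default_profiles,
    generate_session,
    generate_site,
    inject_artifacts,
)


class TestDefaultProfiles:
    def test_spike_amplitudes_in_quoted_range(self):
        profiles = default_profiles()
        for p in profiles.values():
            lo, hi = p.spike_amplitude_uv
            assert 70.0 <= lo <= hi <= 150.0

    def test_background_sigma_in_quoted_range(self):
        for p in default_profiles().values():
            assert 2.0 <= p.background_sigma_uv <= 6.0

    def test_white_matter_silent(self):
        assert default_profiles()["white_matter"].firing_rate_hz == 0.0

    def test_rate_ordering(self):
        p = default_profiles()
        assert p["stn"].firing_rate_hz > p["thalamus_zi"].firing_rate_hz
        assert p["snr"].firing_rate_hz >= p["stn"].firing_rate_hz

    def test_stn_band_argmax_low_beta(self):
        bp = default_profiles()["stn"].band_power_uv2
        assert max(bp, key=bp.get) == "low_beta"

    def test_snr_band_argmax_gamma(self):
        bp = default_profiles()["snr"].band_power_uv2
        assert max(bp, key=bp.get) == "gamma"


class TestGenerateSite:
    def test_determinism(self, stn_profile):
        r1, t1 = generate_site(stn_profile, 1.0, 24000.0, seed=3)
        r2, t2 = generate_site(stn_profile, 1.0, 24000.0, seed=3)
        assert np.array_equal(r1.samples, r2.samples)
        for a, b in zip(t1, t2):
            assert np.array_equal(a, b)

    def test_spike_count_renewal_expectation(self):
        # 50 Hz for 30 s -> ~1500 spikes within +-5 sd of the renewal count
        prof = RegionProfile(
            region="stn", firing_rate_hz=50.0, n_units=1,
            spike_amplitude_uv=(70.0, 150.0), background_sigma_uv=4.0,
            band_power_uv2={}, isi_regularity=1.0,
        )
        counts = [
            len(generate_site(prof, 30.0, 24000.0, seed=s)[1][0]) for s in range(12)
        ]
        # renewal count sd ~ sqrt(n * cv^2); cv < 1 for dead-time gamma
        assert all(abs(c - 1500) <= 5 * np.sqrt(1500) for c in counts)

    def test_empirical_rate_unbiased(self):
        prof = RegionProfile(
            region="snr", firing_rate_hz=30.0, n_units=1,
            spike_amplitude_uv=(70.0, 150.0), background_sigma_uv=4.0,
            band_power_uv2={}, isi_regularity=4.0,
        )
        rates = [
            len(generate_site(prof, 10.0, 24000.0, seed=s)[1][0]) / 10.0
            for s in range(100)
        ]
        se = np.std(rates) / np.sqrt(len(rates))
        assert abs(np.mean(rates) - 30.0) <= 3 * se + 0.3

    def test_pure_noise_flat_spectrum(self):
        prof = RegionProfile(
            region="white_matter", firing_rate_hz=0.0, n_units=0,
            spike_amplitude_uv=(70.0, 150.0), background_sigma_uv=3.0,
            band_power_uv2={},
        )
        rec, trains = generate_site(prof, 10.0, 24000.0, seed=5)
        assert trains == []
        freqs, psd, _ = welch_amplitude_spectrum(rec.samples, rec.fs)
        lo = psd[(freqs >= 100) & (freqs < 2000)].mean()
        hi = psd[(freqs >= 6000) & (freqs < 10000)].mean()
        assert 0.8 < lo / hi < 1.25  # white within statistical tolerance

    def test_spikes_placed_at_truth_times(self, stn_site):
        rec, trains = stn_site
        # truth trains land on the template trough: check a large negative
        # deflection at each truth sample
        for train in trains:
            idx = np.round(np.asarray(train) * rec.fs).astype(int)
            assert (rec.samples[idx] < -40).mean() > 0.95

    def test_fs_below_nyquist_errors(self, stn_profile):
        with pytest.raises(ValidationError, match="Nyquist"):
            generate_site(stn_profile, 1.0, 80.0, seed=0)


class TestGenerateSession:
    def test_site_count_and_regions(self, small_session_config):
        session, truth = generate_session(small_session_config, seed=1)
        assert len(session.recordings) == 75
        assert set(truth.region.values()) == {"thalamus_zi", "white_matter", "stn", "snr"}

    def test_target_inside_stn_span(self, small_session_config):
        _, truth = generate_session(small_session_config, seed=1)
        traj = truth.true_target_trajectory
        assert truth.region[(traj, truth.true_target_depth_mm)] == "stn"

    def test_target_outside_span_errors(self):
        with pytest.raises(ValidationError, match="outside"):
            generate_session(GeneratorConfig(duration_s=0.02, target_depth_mm=4), seed=0)

    def test_stn_low_beta_dominates_on_target_trajectory(self, small_session_config):
        _, truth = generate_session(small_session_config, seed=2)
        traj = truth.true_target_trajectory
        stn_lb = [
            truth.band_power[(traj, d)]["low_beta"]
            for (t, d), r in truth.region.items()
            if t == traj and r == "stn"
        ]
        other_lb = [
            truth.band_power[(traj, d)]["low_beta"]
            for (t, d), r in truth.region.items()
            if t == traj and r != "stn"
        ]
        assert min(stn_lb) > max(other_lb)

    def test_beta_peak_at_target_depth(self, small_session_config):
        _, truth = generate_session(small_session_config, seed=3)
        traj = truth.true_target_trajectory
        lb = {
            d: truth.band_power[(traj, d)]["low_beta"]
            for (t, d) in truth.region
            if t == traj
        }
        assert max(lb, key=lb.get) == truth.true_target_depth_mm

    def test_no_artifacts_by_default(self, small_session_config):
        _, truth = generate_session(small_session_config, seed=4)
        assert all(len(w) == 0 for w in truth.artifact_windows.values())

    def test_session_determinism(self):
        cfg = GeneratorConfig(duration_s=0.1)
        s1, _ = generate_session(cfg, seed=9)
        s2, _ = generate_session(cfg, seed=9)
        for key in s1.recordings:
            assert np.array_equal(s1.recordings[key].samples, s2.recordings[key].samples)

    def test_truth_matches_placed_waveforms_under_artifacts(self):
        # artifacts are additive: truth spike trains identical with/without
        cfg0 = GeneratorConfig(duration_s=1.0)
        cfg1 = GeneratorConfig(duration_s=1.0, artifact_rate_per_30s=5.0)
        _, t0 = generate_session(cfg0, seed=11)
        _, t1 = generate_session(cfg1, seed=11)
        for key in t0.spike_trains:
            for a, b in zip(t0.spike_trains[key], t1.spike_trains[key]):
                assert np.array_equal(a, b)
        assert any(len(w) > 0 for w in t1.artifact_windows.values())


class TestInjectArtifacts:
    def test_windows_disjoint_and_in_bounds(self, rng):
        x = rng.standard_normal(24000 * 5)
        out, windows = inject_artifacts(x, 24000.0, rate_per_30s=20.0, sigma_uv=2.0, rng=rng)
        assert out.shape == x.shape
        for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
            assert a1 <= b0
        assert all(0 <= w0 < w1 <= 5.0 for w0, w1 in windows)

    def test_zero_rate_no_windows(self, rng):
        x = rng.standard_normal(24000)
        out, windows = inject_artifacts(x, 24000.0, 0.0, 2.0, rng)
        assert windows == []
        assert np.array_equal(out, x)
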