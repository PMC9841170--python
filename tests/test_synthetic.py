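"""Generator contracts: determinism, injected power/coherence, bursts."""

import numpy as np
import pytest

from ldsb_eeg import spectral as sp
from ldsb_eeg import synthetic as syn
from ldsb_eeg.exceptions import ParameterError

DT = 0.0005


def _band_variance(x, dt, f_lo, f_hi):
    """Oracle: variance carried by the [f_lo, f_hi] band (FFT mask)."""
    spec = np.fft.rfft(x - x.mean())
    freqs = np.fft.rfftfreq(len(x), dt)
    mask = (freqs > f_lo) & (freqs <= f_hi)
    return np.sum(np.abs(spec[mask]) ** 2) / (len(x) * len(x) / 2) / 2 * 2


class TestCoherentPair:
    def test_full_coherence_gives_unit_estimate(self):
        rec = syn.coherent_pair(400.0, DT, (4, 8), 1.0, seed=1)
        est = sp.coherence(rec.samples[0], rec.samples[1], DT,
                           window_s=50.0, overlap_s=25.0)
        assert sp.band_coherence(est, sp.DEFAULT_BANDS["theta"]) > 0.97

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_zero_coherence_near_bias_floor(self, seed):
        # >= 39 Welch segments: 4-s windows over a 200-s record
        rec = syn.coherent_pair(200.0, DT, (4, 8), 0.0, seed=seed)
        est = sp.coherence(rec.samples[0], rec.samples[1], DT,
                           window_s=4.0, overlap_s=2.0, daniell_hz=0.5)
        assert est.n_segments >= 39
        assert sp.band_coherence(est, sp.DEFAULT_BANDS["theta"]) < 0.2

    @pytest.mark.parametrize("target", [0.3, 0.5, 0.8])
    def test_target_recovered_on_long_record(self, target):
        rec = syn.coherent_pair(2000.0, DT, (4, 8), target, seed=7)
        est = sp.coherence(rec.samples[0], rec.samples[1], DT)
        got = sp.band_coherence(est, sp.DEFAULT_BANDS["theta"])
        assert got == pytest.approx(target, abs=0.05)

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            syn.coherent_pair(10.0, DT, (4, 8), 1.2, seed=0)
        with pytest.raises(ParameterError):
            syn.coherent_pair(10.0, DT, (4, 8), -0.1, seed=0)
        with pytest.raises(ParameterError):
            syn.coherent_pair(10.0, DT, (500, 2000), 0.5, seed=0)


class TestGenerateRecording:
    def test_deterministic_for_fixed_seed(self):
        a, _ = syn.generate_recording(syn.WAKE_PROFILE, 60.0, seed=5)
        b, _ = syn.generate_recording(syn.WAKE_PROFILE, 60.0, seed=5)
        assert np.array_equal(a.samples, b.samples)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ParameterError):
            syn.generate_recording(syn.WAKE_PROFILE, 0.0, seed=1)

    def test_ground_truth_carries_injected_coherence(self, wake_recording):
        _, truth = wake_recording
        assert truth.theta_coherence == syn.WAKE_PROFILE.theta_coherence

    def test_power_accounting_in_clean_bands(self, sleep_recording):
        """Variance in bands free of background matches the injected
        fractions (direct FFT-band variance oracle, 10% relative)."""
        rec, truth = sleep_recording
        x = rec.eeg_pair()[0]
        total = x.var()
        for name in ("slow", "theta"):
            lo, hi = syn.GENERATOR_BANDS[name]
            got = _band_variance(x, DT, lo, hi)
            want = truth.band_variances[name]
            assert got / total == pytest.approx(want, rel=0.10)

    def test_delta_slow_power_ratio_recovered(self):
        """Slow-oscillation boost appears as the injected delta(0.1-0.5)
        power ratio in the Welch spectrum (target ~3x sleep)."""
        band = sp.DEFAULT_BANDS["delta_slow"]
        powers = {}
        for name, prof in (("sleep", syn.SLEEP_PROFILE),
                           ("obbb", syn.OBBB_PROFILE)):
            rec, _ = syn.generate_recording(prof, 600.0, seed=11)
            psd = sp.daniell_smooth(
                sp.welch_psd(rec.eeg_pair()[0], DT), 0.03)
            powers[name] = sp.band_power(psd, band)
        ratio = powers["obbb"] / powers["sleep"]
        injected = (syn.OBBB_PROFILE.slow_power_boost
                    / syn.SLEEP_PROFILE.slow_power_boost)
        assert ratio == pytest.approx(injected, rel=0.15)

    def test_burst_durations_match_profile_mean(self):
        _, truth = syn.generate_recording(syn.WAKE_PROFILE, 800.0, seed=21)
        assert len(truth.bursts) >= 200
        assert truth.burst_durations.mean() == pytest.approx(
            syn.WAKE_PROFILE.burst_mean_duration_s, rel=0.10)

    def test_bursts_non_overlapping(self, wake_recording):
        _, truth = wake_recording
        for a, b in zip(truth.bursts, truth.bursts[1:]):
            assert a[1] <= b[0]

    def test_emg_tone_scaling(self, wake_recording):
        rec, _ = wake_recording
        assert np.sqrt(np.mean(rec.emg() ** 2)) == pytest.approx(
            syn.WAKE_PROFILE.emg_tone, rel=1e-6)


class TestProfiles:
    def test_fraction_sum_validated(self):
        with pytest.raises(ParameterError):
            syn.StateProfile(state_name="wake",
                             band_powers={"theta": 0.7, "delta": 0.5},
                             theta_coherence=0.5)

    def test_coherence_range_validated(self):
        with pytest.raises(ParameterError):
            syn.StateProfile(state_name="wake", band_powers={},
                             theta_coherence=1.5)

    def test_boost_counts_toward_sum(self):
        with pytest.raises(ParameterError):
            syn.StateProfile(state_name="obbb",
                             band_powers={"slow": 0.2, "theta": 0.3},
                             theta_coherence=0.5, slow_power_boost=4.0)

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        from dataclasses import asdict

        path = tmp_path / "profiles.yaml"
        payload = {name: asdict(p)
                   for name, p in syn.default_profiles().items()}
        path.write_text(yaml.safe_dump(payload))
        loaded = syn.profiles_from_yaml(path)
        assert loaded["wake"] == syn.WAKE_PROFILE


class TestCohort:
    def test_counts_and_unique_ids(self):
        cohort = syn.generate_cohort(list(syn.default_profiles().values()),
                                     n_per_group=3, length_s=30.0, seed=1)
        assert len(cohort) == 9
        ids = [rec.subject_id for rec, _ in cohort]
        assert len(set(ids)) == 9

    def test_same_master_seed_reproduces_cohort(self):
        profs = [syn.WAKE_PROFILE, syn.SLEEP_PROFILE]
        a = syn.generate_cohort(profs, 2, 30.0, seed=9)
        b = syn.generate_cohort(profs, 2, 30.0, seed=9)
        for (ra, _), (rb, _) in zip(a, b):
            assert np.array_equal(ra.samples, rb.samples)

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            syn.generate_cohort([], 3, 30.0, seed=0)
        with pytest.raises(ParameterError):
            syn.generate_cohort([syn.WAKE_PROFILE], 1, 30.0, seed=0)


class TestConcatenate:
    def test_labels_and_bursts_shifted(self):
        a = syn.generate_recording(syn.WAKE_PROFILE, 30.0, seed=1)
        b = syn.generate_recording(syn.SLEEP_PROFILE, 30.0, seed=2)
        rec, truth = syn.concatenate_recordings([a, b])
        assert rec.duration_s == pytest.approx(60.0)
        assert truth.stage_labels == ["WAKE"] * 3 + ["NREM"] * 3
        if b[1].bursts:
            assert truth.bursts[-1][0] >= 30.0
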