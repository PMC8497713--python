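"""Filtering, resampling, epoching, rejection and EOG subtraction contracts."""

import numpy as np
import pytest
from scipy import signal

import midecode as md
from midecode.containers import ContinuousRecording
from midecode.preprocess import (
    _joint_probability_stat,
    _kurtosis_stat,
    _robust_z,
)

from conftest import make_epochs, quiet_effects, tiny_paradigm


def sine_recording(freq, rate=1000.0, dur=6.0, events=()):
    t = np.arange(int(dur * rate)) / rate
    x = np.sin(2 * np.pi * freq * t)[None, :].repeat(2, axis=0)
    return ContinuousRecording(
        samples=x,
        channel_labels=["a", "b"],
        channel_kinds=["EEG", "EEG"],
        rate=rate,
        events=np.array(events, dtype=np.int64).reshape(-1, 2),
    )


class TestBandpass:
    # the 0.2 Hz high-pass corner rings for seconds: use long signals and an
    # interior window well away from the filtfilt edge transients
    def test_deep_stopband_on_50hz(self):
        rec = sine_recording(50.0, dur=40.0)
        out = md.bandpass(rec, md.AMPLITUDE_BAND)
        mid = slice(15000, 25000)
        rms_in = np.sqrt((rec.samples[0, mid] ** 2).mean())
        rms_out = np.sqrt((out.samples[0, mid] ** 2).mean())
        assert rms_out < 0.01 * rms_in

    def test_zero_phase_no_lag(self):
        rec = sine_recording(2.0, dur=40.0)
        out = md.bandpass(rec, md.AMPLITUDE_BAND)
        mid = slice(15000, 25000)
        xc = np.correlate(out.samples[0, mid], rec.samples[0, mid], mode="full")
        lag = int(np.argmax(xc)) - (len(xc) // 2)
        assert lag == 0

    def test_passband_amplitude_matches_frequency_response(self):
        """Measured 2 Hz gain equals |H(2 Hz)|^2 of the composed
        forward-backward filter and stays within 5% of unity."""
        rec = sine_recording(2.0, dur=40.0)
        out = md.bandpass(rec, md.AMPLITUDE_BAND)
        mid = slice(15000, 25000)
        gain = out.samples[0, mid].std() / rec.samples[0, mid].std()
        sos = signal.butter(4, [0.2, 5.0], btype="bandpass", fs=1000.0, output="sos")
        _, h = signal.sosfreqz(sos, worN=[2.0], fs=1000.0)
        assert gain == pytest.approx(np.abs(h[0]) ** 2, abs=0.01)
        assert abs(gain - 1.0) < 0.05

    def test_band_edge_above_nyquist_errors(self):
        rec = sine_recording(2.0, rate=100.0)
        with pytest.raises(ValueError):
            md.bandpass(rec, md.FilterSpec(1.0, 60.0))

    def test_markers_unchanged(self):
        rec = sine_recording(2.0, events=[(100, 31), (2100, 32)])
        out = md.bandpass(rec, md.AMPLITUDE_BAND)
        assert np.array_equal(out.events, rec.events)
        assert out.n_samples == rec.n_samples


class TestResample:
    def test_six_seconds_1khz_to_200hz(self):
        rec = sine_recording(2.0, rate=1000.0, dur=6.0)
        out = md.resample(rec, 200.0)
        assert out.rate == 200.0
        assert out.n_samples == 1200

    def test_identity_when_target_equals_rate(self):
        rec = sine_recording(2.0, rate=100.0)
        out = md.resample(rec, 100.0)
        assert np.array_equal(out.samples, rec.samples)

    def test_dc_preserved(self):
        rec = sine_recording(2.0, rate=1000.0)
        rec.samples[:] = 3.5
        out = md.resample(rec, 200.0)
        assert np.allclose(out.samples[:, 10:-10], 3.5, atol=1e-6)

    def test_event_rescaling_rounds_half_away_from_zero(self):
        rec = sine_recording(2.0, rate=1000.0, events=[(12, 1), (13, 2), (2500, 3)])
        out = md.resample(rec, 200.0)  # factor 0.2: 2.4 -> 2, 2.6 -> 3, 500 -> 500
        assert out.events[:, 0].tolist() == [2, 3, 500]

    def test_upsampling_rejected(self):
        rec = sine_recording(2.0, rate=100.0)
        with pytest.raises(ValueError):
            md.resample(rec, 200.0)


class TestEpoch:
    def test_six_second_window_at_200hz(self):
        par = tiny_paradigm(rate=200.0, n_trials=6)
        rec, _ = md.generate_recording(par, quiet_effects(seed=0))
        ep = md.epoch(rec, (-4.0, 2.0))
        assert ep.data.shape[0] == 12
        assert ep.data.shape[2] == 1200
        assert ep.times[0] == pytest.approx(-4.0)

    def test_zero_markers_empty_set(self):
        rec = sine_recording(2.0)
        ep = md.epoch(rec, (-1.0, 1.0))
        assert ep.n_trials == 0
        assert ep.data.shape[1:] == (2, 2000)

    def test_window_beyond_bounds_names_trial(self):
        rec = sine_recording(2.0, events=[(100, 31)])
        with pytest.raises(ValueError, match="trial 0"):
            md.epoch(rec, (-1.0, 1.0))


class TestArtifactRejection:
    def brute_force_mask(self, eeg, amp_uv, z):
        amp = np.abs(eeg).max(axis=(1, 2)) > amp_uv
        kz = np.abs(_robust_z(_kurtosis_stat(eeg)))
        jz = np.abs(_robust_z(_joint_probability_stat(eeg)))
        return amp | (kz > z) | (jz > z)

    def test_mask_matches_brute_force_with_heavy_tailed_trial(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((12, 3, 200)) * 10.0
        data[4] = rng.standard_t(df=1.5, size=(3, 200)) * 10.0  # heavy tailed
        ep = make_epochs(data, rate=100.0)
        mask = md.mark_artifacts(ep, amp_uv=200.0, z=3.0)
        kz = np.abs(_robust_z(_kurtosis_stat(data)))
        assert mask[4] and kz[4] > 3.0
        assert np.array_equal(mask, self.brute_force_mask(data, 200.0, 3.0))

    def test_amplitude_rule_only(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((8, 3, 100)) * 10.0
        data[2, 1, 50] = 500.0
        ep = make_epochs(data, rate=100.0)
        mask = md.mark_artifacts(ep, amp_uv=200.0, z=50.0)
        assert mask.tolist() == [False, False, True] + [False] * 5

    def test_identical_trials_no_statistical_rejection(self):
        one = np.random.default_rng(2).standard_normal((1, 3, 100)) * 10
        data = np.repeat(one, 6, axis=0)
        ep = make_epochs(data, rate=100.0)
        assert not md.mark_artifacts(ep, amp_uv=200.0, z=5.0).any()

    def test_data_untouched_and_minimum_trials(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((5, 2, 50))
        ep = make_epochs(data, rate=50.0)
        before = ep.data.copy()
        md.mark_artifacts(ep, amp_uv=1.0, z=1.0)
        assert np.array_equal(ep.data, before)
        with pytest.raises(ValueError):
            md.mark_artifacts(make_epochs(data[:2], rate=50.0), 200.0, 5.0)

    def test_injected_transient_flows_through_rejection(self):
        par = tiny_paradigm(rate=160.0, n_trials=6)
        rec, gt = md.generate_recording(par, md.EffectSpec(seed=9))
        rec = md.inject_gross_artifact(rec, 7, 250.0, ground_truth=gt)
        art = md.epoch(md.bandpass(rec, md.FilterSpec(1.0, 60.0)), (-4.0, 2.0))
        mask = md.mark_artifacts(art)
        assert mask[7]
        # a 50 uV transient in another trial stays below the amplitude rule
        rec2 = md.inject_gross_artifact(rec, 2, 50.0, ground_truth=gt)
        art2 = md.epoch(md.bandpass(rec2, md.FilterSpec(1.0, 60.0)), (-4.0, 2.0))
        assert not md.mark_artifacts(art2)[2]


class TestEogSubspace:
    def calibration(self, bleed=1.0, seed=4):
        par = tiny_paradigm(rate=160.0)
        eff = quiet_effects(
            seed=seed, eog_rate_per_min=30.0, noise_sigma_uv=0.3, eeg_bleed_gain=bleed
        )
        return md.generate_eye_calibration(par, eff, duration_s=60)

    def test_artifact_locked_variance_strongly_reduced(self):
        calib = md.bandpass(self.calibration(), md.SPECTRAL_BAND)
        model = md.fit_eog_subspace(calib)
        clean = md.apply_eog_subspace(model, calib)
        from midecode.preprocess import _artifact_segments

        seg = _artifact_segments(calib)
        eeg = calib.eeg_indices()
        ratio = clean.samples[np.ix_(eeg, seg)].var() / calib.samples[
            np.ix_(eeg, seg)
        ].var()
        assert ratio < 0.10

    def test_zero_bleed_projection_near_identity(self):
        calib = md.bandpass(self.calibration(bleed=0.0), md.SPECTRAL_BAND)
        model = md.fit_eog_subspace(calib)
        p = model.projection_matrix(list(calib.channel_labels))
        assert np.abs(p - np.eye(len(calib.channel_labels))).max() < 0.05

    def test_silent_eog_leaves_eeg_unchanged(self):
        calib = md.bandpass(self.calibration(), md.SPECTRAL_BAND)
        model = md.fit_eog_subspace(calib)
        rest = self.calibration(seed=5)
        rest.samples[rest.eog_indices(), :] = 0.0
        out = md.apply_eog_subspace(model, rest)
        assert np.allclose(out.samples, rest.samples, atol=1e-12)

    def test_application_is_linear(self):
        calib = md.bandpass(self.calibration(), md.SPECTRAL_BAND)
        model = md.fit_eog_subspace(calib)
        a = self.calibration(seed=6)
        b = self.calibration(seed=8)
        summed = a.copy()
        summed.samples = a.samples + b.samples
        lhs = md.apply_eog_subspace(model, summed).samples
        rhs = md.apply_eog_subspace(model, a).samples + md.apply_eog_subspace(model, b).samples
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_missing_eog_channels_error(self):
        rec = ContinuousRecording(
            samples=np.zeros((2, 100)),
            channel_labels=["a", "b"],
            channel_kinds=["EEG", "EEG"],
            rate=100.0,
        )
        with pytest.raises(ValueError):
            md.fit_eog_subspace(rec)


class TestReferenceAndSelection:
    def test_car_zeroes_channel_mean(self):
        rng = np.random.default_rng(0)
        ep = make_epochs(rng.standard_normal((4, 5, 60)), rate=60.0)
        out = md.common_average_reference(ep)
        assert np.allclose(out.data.mean(axis=1), 0.0, atol=1e-12)

    def test_car_idempotent_and_symmetric_pair(self):
        rng = np.random.default_rng(1)
        ep = make_epochs(rng.standard_normal((3, 4, 50)), rate=50.0)
        once = md.common_average_reference(ep)
        twice = md.common_average_reference(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)
        pair = make_epochs(np.stack([np.ones((2, 30)), -np.ones((2, 30))], axis=1)[:, :, :], rate=30.0)
        assert np.allclose(md.common_average_reference(pair).data, pair.data)

    def test_single_channel_errors(self):
        ep = make_epochs(np.zeros((2, 1, 10)), rate=10.0)
        with pytest.raises(ValueError):
            md.common_average_reference(ep)

    def test_default_subset_has_31_channels(self, small_recording):
        _, rec, _ = small_recording
        ep = md.epoch(rec, (-1.0, 1.0))
        out = md.select_channels(ep, list(md.CLASSIFICATION_CHANNELS))
        assert out.n_channels == 31
        assert out.channel_labels == list(md.CLASSIFICATION_CHANNELS)

    def test_identity_and_unknown_label(self, small_recording):
        _, rec, _ = small_recording
        ep = md.epoch(rec, (-1.0, 1.0))
        same = md.select_channels(ep, list(ep.channel_labels))
        assert np.array_equal(same.data, ep.data)
        with pytest.raises(ValueError, match="XX9"):
            md.select_channels(ep, ["Cz", "XX9"])


class TestFilterResampleCommutation:
    def test_epoch_windows_agree_within_one_sample(self):
        par = tiny_paradigm(rate=1000.0, n_trials=3)
        rec, _ = md.generate_recording(par, quiet_effects(seed=0, noise_sigma_uv=2.0))
        filt = md.bandpass(rec, md.AMPLITUDE_BAND)
        # cut after resampling vs. resample each trial's own cut: compare onsets
        low = md.resample(filt, 100.0)
        ep_low = md.epoch(low, (-1.0, 1.0))
        onsets_high = rec.events[np.isin(rec.events[:, 1], [31, 32, 33, 34]), 0]
        onsets_low = low.events[np.isin(low.events[:, 1], [31, 32, 33, 34]), 0]
        assert np.all(np.abs(onsets_low - onsets_high / 10.0) <= 0.5)
        assert ep_low.data.shape[2] == 200
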