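"""Sliding amplitude features, Morlet TFR, CSP and baseline-relative band power."""

import warnings

import numpy as np
import pytest
import midecode as md
from midecode.features import CSPModel, morlet_power

from conftest import make_epochs


class TestSlidingAmplitudeFeatures:
    def test_feature_count_31_channels_1s_window_at_10hz(self):
        data = np.random.default_rng(0).standard_normal((5, 31, 60))
        ep = make_epochs(data, rate=10.0, t0=-4.0)
        fs = md.sliding_amplitude_features(ep, window_s=1.0, step_s=0.1)
        assert fs.features.shape[2] == 310
        assert len(fs.feature_index) == 310
        assert np.allclose(np.diff(fs.timepoints), 0.1)

    def test_constant_signal_gives_constant_features(self):
        ep = make_epochs(np.full((2, 3, 30), 7.5), rate=10.0)
        fs = md.sliding_amplitude_features(ep, 1.0, 0.1)
        assert np.allclose(fs.features, 7.5)

    def test_causality_of_unit_impulse(self):
        data = np.zeros((1, 1, 50))
        data[0, 0, 20] = 1.0
        ep = make_epochs(data, rate=10.0, t0=0.0)
        fs = md.sliding_amplitude_features(ep, 1.0, 0.1)
        t0 = ep.times[20]
        nonzero = np.abs(fs.features[0]).sum(axis=1) > 0
        active = fs.timepoints[nonzero]
        assert active.min() >= t0 - 1e-9
        assert active.max() < t0 + 1.0

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(40)
        m = 3
        a = make_epochs(x[None, None, : 40 - m], rate=10.0)
        b = make_epochs(x[None, None, m:], rate=10.0)
        fa = md.sliding_amplitude_features(a, 0.5, 0.1).features
        fb = md.sliding_amplitude_features(b, 0.5, 0.1).features
        assert np.allclose(fa[0, m:, :], fb[0, : fb.shape[1] - m, :])

    def test_window_longer_than_epoch_errors(self):
        ep = make_epochs(np.zeros((1, 2, 5)), rate=10.0)
        with pytest.raises(ValueError):
            md.sliding_amplitude_features(ep, 1.0, 0.1)


def random_two_class_epochs(rng, n_ch=4, n_per_class=30, n_t=80, scales=None):
    scales_a = scales[0] if scales else np.ones(n_ch)
    scales_b = scales[1] if scales else np.ones(n_ch)
    a = rng.standard_normal((n_per_class, n_ch, n_t)) * np.asarray(scales_a)[None, :, None]
    b = rng.standard_normal((n_per_class, n_ch, n_t)) * np.asarray(scales_b)[None, :, None]
    labels = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    return make_epochs(np.concatenate([a, b]), rate=100.0, labels=labels), labels


class TestCSP:
    def test_two_channel_hand_worked_case(self):
        """Class covariances diag(4,1) vs diag(1,4) give eigenvalues
        {4/5, 1/5} and axis-aligned filters."""
        rng = np.random.default_rng(0)
        ep, labels = random_two_class_epochs(
            rng, n_ch=2, n_per_class=200, n_t=100, scales=([2.0, 1.0], [1.0, 2.0])
        )
        m = md.fit_csp(ep, labels, (0.0, 1.0), k_per_class=1)
        assert np.allclose(m.eigenvalues, [0.8, 0.2], atol=0.02)
        f = m.filters / np.abs(m.filters).max(axis=1, keepdims=True)
        assert abs(f[0, 0]) > 20 * abs(f[0, 1])
        assert abs(f[1, 1]) > 20 * abs(f[1, 0])

    def test_identical_class_covariances_all_half(self):
        rng = np.random.default_rng(1)
        ep, labels = random_two_class_epochs(rng, n_ch=3, n_per_class=300, n_t=200)
        m = md.fit_csp(ep, labels, (0.0, 2.0), k_per_class=1)
        assert np.allclose(m.eigenvalues, 0.5, atol=0.02)

    def test_pooled_covariance_whitening_invariant(self):
        rng = np.random.default_rng(2)
        ep, labels = random_two_class_epochs(rng, n_ch=5, n_per_class=20, n_t=60)
        m = md.fit_csp(ep, labels, (0.0, 0.6), k_per_class=2)
        # rebuild the trace-normalized class covariances exactly as defined
        idx = ep.time_indices((0.0, 0.6))
        covs = {"A": [], "B": []}
        for t in range(ep.n_trials):
            x = ep.data[t][:, idx]
            c = x @ x.T
            covs[labels[t]].append(c / np.trace(c))
        pooled = np.mean(covs["A"], axis=0) + np.mean(covs["B"], axis=0)
        assert np.abs(m.filters @ pooled @ m.filters.T - np.eye(5)).max() < 1e-8

    def test_label_swap_mirrors_eigenvalues(self):
        rng = np.random.default_rng(3)
        ep, labels = random_two_class_epochs(
            rng, n_ch=3, n_per_class=25, n_t=50, scales=([2, 1, 1], [1, 1, 2])
        )
        m1 = md.fit_csp(ep, labels, (0.0, 0.5), k_per_class=1)
        swapped = np.where(labels == "A", "b", "a")
        m2 = md.fit_csp(ep, swapped, (0.0, 0.5), k_per_class=1)
        assert np.allclose(np.sort(m1.eigenvalues), np.sort(1 - m2.eigenvalues), atol=1e-10)

    def test_sign_convention_first_nonzero_positive(self):
        rng = np.random.default_rng(4)
        ep, labels = random_two_class_epochs(rng, n_ch=4, n_per_class=15, n_t=40)
        m = md.fit_csp(ep, labels, (0.0, 0.4), k_per_class=2)
        for row in m.filters:
            nz = row[np.abs(row) > 1e-12]
            assert nz[0] > 0

    def test_single_class_errors(self):
        ep = make_epochs(np.random.default_rng(5).standard_normal((6, 2, 30)), rate=100.0)
        with pytest.raises(ValueError):
            md.fit_csp(ep, np.array(["A"] * 6), (0.0, 0.3), 1)


def identity_csp_model(n_ch=1, labels=("ch0",)):
    eye = np.eye(n_ch)
    return CSPModel(
        filters=eye,
        eigenvalues=np.full(n_ch, 0.5),
        selected=np.arange(n_ch),
        patterns=eye,
        classes=("A", "B"),
        channel_labels=list(labels),
    )


class TestCSPLogPower:
    def test_flat_signal_relative_power_zero(self):
        # log-chi2 values have SD ~2.2, so the fixture needs many trials
        rng = np.random.default_rng(0)
        data = rng.standard_normal((400, 1, 100))
        ep = make_epochs(data, rate=10.0, t0=-5.0)
        fs = md.csp_logpower_features(
            ep, identity_csp_model(), baseline_window_s=(-4.0, -3.0), smooth_s=1.0
        )
        # stationary noise: post-baseline values fluctuate around the
        # baseline-window level (the shared reference offset cancels)
        sel = (fs.timepoints >= -4.0) & (fs.timepoints < -3.0)
        assert abs(fs.features.mean() - fs.features[:, sel, :].mean()) < 0.1

    def test_amplitude_doubling_gives_log4(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((400, 1, 120))
        data = base.copy()
        data[:, :, 60:] *= 2.0  # power x4 in the second half
        ep = make_epochs(data, rate=10.0, t0=-6.0)
        fs = md.csp_logpower_features(
            ep, identity_csp_model(), baseline_window_s=(-5.0, -2.0), smooth_s=1.0
        )
        late = fs.timepoints > 4.0
        early = (fs.timepoints >= -5.0) & (fs.timepoints < -2.0)
        jump = fs.features[:, late, :].mean() - fs.features[:, early, :].mean()
        assert jump == pytest.approx(np.log(4.0), abs=0.15)

    def test_baseline_mean_of_unsmoothed_logpower_is_zero(self):
        rng = np.random.default_rng(2)
        ep = make_epochs(rng.standard_normal((10, 1, 200)), rate=20.0, t0=-5.0)
        fs = md.csp_logpower_features(
            ep,
            identity_csp_model(),
            baseline_window_s=(-4.0, -2.0),
            smooth_s=1.0 / 20.0,  # one-sample smoother = unsmoothed
            step_s=1.0 / 20.0,
        )
        sel = (fs.timepoints >= -4.0) & (fs.timepoints < -2.0)
        assert abs(fs.features[:, sel, :].mean()) < 1e-10

    def test_moving_average_of_constant_is_constant(self):
        from midecode.features import _causal_moving_average

        x = np.full((2, 3, 50), 2.5)
        assert np.allclose(_causal_moving_average(x, 10), 2.5)

    def test_channel_mismatch_errors(self):
        ep = make_epochs(np.random.default_rng(3).standard_normal((4, 2, 50)), rate=10.0)
        with pytest.raises(ValueError):
            md.csp_logpower_features(ep, identity_csp_model(), (-1.0, 0.0))


class TestMorletTFR:
    def test_pure_sinusoid_peaks_at_carrier(self):
        t = np.arange(1200) / 200.0
        sine = np.sin(2 * np.pi * 10 * t)
        p = morlet_power(sine[None, None, :], 200.0, np.arange(1.0, 41.0), 3.0)
        assert np.arange(1, 41)[np.argmax(p[0, 0].mean(axis=1))] == 10

    def test_stationary_noise_db_centered_on_zero(self):
        rng = np.random.default_rng(0)
        ep = make_epochs(rng.standard_normal((30, 1, 1200)), rate=200.0, t0=-4.0)
        tfr = md.morlet_tfr(ep, 5.0, 30.0, 3.0, baseline_window_s=(-3.5, -2.5))
        post = tfr.times > 0.0
        assert abs(tfr.power_db[:, :, post].mean()) < 0.5
        # time-mean over the baseline window sits at 0 dB up to the small
        # arithmetic-vs-geometric mean gap of the dB transform
        base = (tfr.times >= -3.5) & (tfr.times < -2.5)
        assert np.allclose(tfr.power_db[:, :, base].mean(axis=2), 0.0, atol=0.3)

    def test_white_noise_power_flat_across_frequencies(self):
        rng = np.random.default_rng(1)
        p = morlet_power(
            rng.standard_normal((40, 1, 2400)), 200.0, np.arange(2.0, 41.0), 3.0
        )
        prof = p[:, :, :, 600:1800].mean(axis=(0, 1, 3))
        spread_db = 10 * np.log10(prof / prof.mean())
        assert np.abs(spread_db).max() < 1.0

    def test_matches_mne_baseline_relative_power(self):
        """Independent cross-check: baseline-relative dB agrees with mne's
        Morlet implementation (same FWHM anchoring) within 0.2 dB."""
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(2)
        t = np.arange(2400) / 200.0
        x = rng.standard_normal((5, 2, 2400)) * 0.5 + np.sin(2 * np.pi * 10 * t) * np.where(
            t > 6, 0.5, 1.0
        )
        freqs = np.arange(5.0, 31.0)
        n_cycles = 3.0 * 2 * np.pi / (2 * np.sqrt(2 * np.log(2)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_mne = mne.time_frequency.tfr_array_morlet(
                x, 200.0, freqs, n_cycles=n_cycles, output="power", zero_mean=True
            )
        p_own = morlet_power(x, 200.0, freqs, 3.0)

        def rel_db(p):
            early = p.mean(axis=0)[..., 400:1000].mean(-1)
            late = p.mean(axis=0)[..., 1400:2200].mean(-1)
            return 10 * np.log10(late / early)

        assert np.abs(rel_db(p_own) - rel_db(p_mne)).max() < 0.2

    def test_baseline_outside_epoch_errors(self):
        ep = make_epochs(np.random.default_rng(3).standard_normal((2, 1, 400)), rate=200.0, t0=0.0)
        with pytest.raises(ValueError):
            md.morlet_tfr(ep, 5.0, 20.0, 3.0, baseline_window_s=(-3.5, -2.5))
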