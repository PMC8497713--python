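"""Feature extraction: sliding low-frequency amplitudes, Morlet time-frequency
maps, common spatial patterns (CSP) and baseline-relative log band power.

Two feature families feed the classifiers:

* *amplitude features* — raw low-frequency (0.2–5 Hz, 10 Hz rate) channel
  amplitudes over the preceding 1 s window, one classification sample every
  100 ms (31 channels x 10 lags = 310 features per sample);
* *spectral features* — per band (μ 8–12 Hz, β 15–32 Hz), the signal is
  spatially filtered with the 2k most discriminative CSP filters, squared,
  log-transformed, referenced to the trial-set baseline mean and smoothed with
  a 1 s moving average; the μ and β blocks are concatenated (2 x 2k features).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal as sps

from .containers import EpochSet


# ---------------------------------------------------------------------------
# Sliding low-frequency amplitude features
# ---------------------------------------------------------------------------


@dataclass
class SlidingFeatureSet:
    """Trials x timepoints x (channel, lag) amplitude features.

    ``timepoints`` are the right edges of the causal windows; a feature row at
    time t contains the amplitudes of all channels at the lags covering
    (t - window, t].
    """

    features: np.ndarray
    timepoints: np.ndarray
    feature_index: list[tuple[str, int]]  # (channel label, lag in samples)
    condition: np.ndarray
    direction: np.ndarray
    rate: float


def sliding_amplitude_features(
    epochs: EpochSet, window_s: float = 1.0, step_s: float = 0.1
) -> SlidingFeatureSet:
    """Causal sliding windows of raw amplitudes.

    No sample after the window's right edge enters its feature vector, so the
    feature timeline is strictly causal and translation-equivariant.
    """
    n_lags = int(round(window_s * epochs.rate))
    if abs(n_lags - window_s * epochs.rate) > 1e-6:
        raise ValueError("window_s must be a multiple of the sample interval")
    n_t = epochs.data.shape[2]
    if n_lags > n_t:
        raise ValueError("window longer than epoch")
    step = max(1, int(round(step_s * epochs.rate)))
    ends = np.arange(n_lags - 1, n_t, step)
    n_trials, n_ch, _ = epochs.data.shape
    feats = np.empty((n_trials, len(ends), n_ch * n_lags))
    for k, e in enumerate(ends):
        feats[:, k, :] = epochs.data[:, :, e - n_lags + 1 : e + 1].reshape(n_trials, -1)
    index = [
        (epochs.channel_labels[c], lag)
        for c in range(n_ch)
        for lag in range(n_lags - 1, -1, -1)
    ]
    return SlidingFeatureSet(
        features=feats,
        timepoints=epochs.times[ends],
        feature_index=index,
        condition=epochs.condition.copy(),
        direction=epochs.direction.copy(),
        rate=epochs.rate / step,
    )


# ---------------------------------------------------------------------------
# Morlet time-frequency decomposition
# ---------------------------------------------------------------------------


@dataclass
class TimeFrequencyMap:
    """Trial-averaged wavelet power in dB relative to a baseline window."""

    power_db: np.ndarray  # channels x frequencies x time
    frequencies: np.ndarray
    times: np.ndarray
    baseline_window_s: tuple[float, float]
    channel_labels: list[str]


def _morlet_wavelet(freq: float, rate: float, fwhm_s: float, max_len: int) -> np.ndarray:
    """Complex Morlet with gaussian-envelope FWHM ``fwhm_s`` (time domain).

    The wavelet support is truncated at ±3 envelope SDs or half the signal
    length, whichever is shorter, and energy (L2) normalized so that the
    expected power of white noise is flat across frequencies.
    """
    sigma_t = fwhm_s / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = int(min(round(3.0 * sigma_t * rate), (max_len - 1) // 2))
    t = np.arange(-half, half + 1) / rate
    env = np.exp(-(t**2) / (2.0 * sigma_t**2))
    wav = env * np.exp(2j * np.pi * freq * t)
    wav -= wav.mean()  # zero mean to kill DC leakage
    return wav / np.sqrt(np.sum(np.abs(wav) ** 2))


def morlet_power(
    data: np.ndarray, rate: float, frequencies: np.ndarray, fwhm_s_at_1hz: float = 3.0
) -> np.ndarray:
    """Wavelet power of ``data`` (trials x channels x time) per frequency.

    The gaussian FWHM is anchored at ``fwhm_s_at_1hz`` for 1 Hz and scales as
    1/f (constant number of cycles ≈ 8 for the 3 s anchor).
    """
    n_trials, n_ch, n_t = data.shape
    out = np.empty((n_trials, n_ch, len(frequencies), n_t))
    flat = data.reshape(-1, n_t)
    for fi, f in enumerate(frequencies):
        wav = _morlet_wavelet(float(f), rate, fwhm_s_at_1hz / float(f), n_t)
        conv = sps.fftconvolve(flat, wav[None, :], mode="same", axes=1)
        out[:, :, fi, :] = (np.abs(conv) ** 2).reshape(n_trials, n_ch, n_t)
    return out


def morlet_tfr(
    epochs: EpochSet,
    f_min: float = 1.0,
    f_max: float = 40.0,
    fwhm_s_at_1hz: float = 3.0,
    baseline_window_s: tuple[float, float] = (-3.5, -2.5),
) -> TimeFrequencyMap:
    """Trial-averaged TFR in 1 Hz steps, dB relative to the baseline window."""
    if not (
        epochs.times[0] - 1e-9 <= baseline_window_s[0]
        and baseline_window_s[1] <= epochs.times[-1] + 1e-9
    ):
        raise ValueError("baseline window outside epoch")
    freqs = np.arange(f_min, f_max + 0.5, 1.0)
    power = morlet_power(epochs.data, epochs.rate, freqs, fwhm_s_at_1hz).mean(axis=0)
    base_idx = epochs.time_indices(baseline_window_s)
    base = power[:, :, base_idx].mean(axis=2, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("baseline power is zero for some channel/frequency")
    return TimeFrequencyMap(
        power_db=10.0 * np.log10(power / base),
        frequencies=freqs,
        times=epochs.times.copy(),
        baseline_window_s=baseline_window_s,
        channel_labels=list(epochs.channel_labels),
    )


# ---------------------------------------------------------------------------
# Common spatial patterns
# ---------------------------------------------------------------------------


@dataclass
class CSPModel:
    """Spatial filters that jointly diagonalize the two class covariances.

    Rows of ``filters`` are sorted by descending eigenvalue (class-1 variance
    fraction of the pooled covariance); ``selected`` holds k filters from each
    end of the spectrum; ``patterns`` is the pseudo-inverse of ``filters``
    (channels x filters), the forward model of each component.
    """

    filters: np.ndarray  # n_filters x n_channels
    eigenvalues: np.ndarray
    selected: np.ndarray
    patterns: np.ndarray  # n_channels x n_filters
    classes: tuple[str, str]
    channel_labels: list[str]

    @property
    def selected_filters(self) -> np.ndarray:
        return self.filters[self.selected]


def _fix_filter_signs(filters: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    out = filters.copy()
    for row in out:
        nz = np.nonzero(np.abs(row) > tol)[0]
        if nz.size and row[nz[0]] < 0:
            row *= -1.0
    return out


def fit_csp(
    epochs_band: EpochSet,
    labels: np.ndarray,
    fit_window_s: tuple[float, float] = (0.5, 1.5),
    k_per_class: int = 5,
) -> CSPModel:
    """Fit CSP on band-filtered epochs within ``fit_window_s``.

    Per-trial covariances are normalized by their trace before averaging
    within class. Filters solve the generalized eigenproblem
    C1 w = λ (C1 + C2) w; eigenvalues are the class-1 variance fraction under
    the pooled-covariance normalization M (C1 + C2) Mᵀ = I.
    """
    labels = np.asarray(labels)
    classes = tuple(sorted(np.unique(labels).tolist()))
    if len(classes) != 2:
        raise ValueError(f"CSP needs exactly two classes, got {classes}")
    idx = epochs_band.time_indices(fit_window_s)
    covs = {c: [] for c in classes}
    for t in range(epochs_band.n_trials):
        x = epochs_band.data[t][:, idx]
        c = x @ x.T
        tr = np.trace(c)
        if tr <= 0:
            raise ValueError(f"trial {t} has zero variance in the fit window")
        covs[labels[t]].append(c / tr)
    c1 = np.mean(covs[classes[0]], axis=0)
    c2 = np.mean(covs[classes[1]], axis=0)
    pooled = c1 + c2
    cond = np.linalg.cond(pooled)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "pooled covariance is rank deficient; regularize or reduce channels"
        )
    eigvals, eigvecs = linalg.eigh(c1, pooled)  # ascending, vᵀ pooled v = I
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    filters = _fix_filter_signs(eigvecs[:, order].T)
    n = len(eigvals)
    k = min(k_per_class, n // 2)
    selected = np.concatenate([np.arange(k), np.arange(n - k, n)])
    patterns = np.linalg.pinv(filters, rcond=1e-12)
    return CSPModel(
        filters=filters,
        eigenvalues=eigvals,
        selected=selected,
        patterns=patterns,
        classes=(str(classes[0]), str(classes[1])),
        channel_labels=list(epochs_band.channel_labels),
    )


# ---------------------------------------------------------------------------
# Baseline-relative CSP log band power
# ---------------------------------------------------------------------------


@dataclass
class BandPowerFeatureSet:
    """Trials x timepoints x features baseline-relative log band power."""

    features: np.ndarray
    timepoints: np.ndarray
    band_index: list[str]  # band tag per feature column
    condition: np.ndarray
    direction: np.ndarray
    rate: float


def _causal_moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Moving average over the preceding ``n`` samples along the last axis,
    with an expanding window over the first n-1 samples (keeps length and
    causality; the average of a constant is that constant)."""
    c = np.cumsum(x, axis=-1)
    out = np.empty_like(x)
    out[..., :n] = c[..., :n] / np.arange(1, n + 1)
    out[..., n:] = (c[..., n:] - c[..., :-n]) / n
    return out


def bandpower_timepoints(
    epochs_band: EpochSet, smooth_s: float = 1.0, step_s: float = 0.1
) -> np.ndarray:
    """Classification timeline of ``csp_logpower_features`` for these epochs."""
    n_smooth = max(1, int(round(smooth_s * epochs_band.rate)))
    step = max(1, int(round(step_s * epochs_band.rate)))
    ends = np.arange(n_smooth - 1, epochs_band.data.shape[2], step)
    return epochs_band.times[ends]


def csp_logpower_features(
    epochs_band: EpochSet,
    model: CSPModel,
    baseline_window_s: tuple[float, float] = (-3.5, -2.5),
    smooth_s: float = 1.0,
    band: str = "",
    step_s: float = 0.1,
) -> BandPowerFeatureSet:
    """Baseline-relative log power of the selected CSP components.

    Squared spatially filtered samples are log-transformed (natural log),
    referenced to the trial-set mean over the baseline window per feature,
    smoothed with a causal ``smooth_s`` moving average and decimated to one
    classification sample every ``step_s``.
    """
    if list(epochs_band.channel_labels) != list(model.channel_labels):
        raise ValueError("epochs channel set differs from the CSP model's")
    w = model.selected_filters  # (2k, n_ch)
    proj = np.einsum("fc,tcs->tfs", w, epochs_band.data)
    power = proj**2
    logp = np.log(np.maximum(power, 1e-300))
    base_idx = epochs_band.time_indices(baseline_window_s)
    base = power[:, :, base_idx].mean(axis=(0, 2))
    if np.any(base <= 0):
        raise ValueError("zero baseline power for some CSP component")
    # subtract log of the baseline mean power, plus the log-power offset so the
    # un-smoothed log-power averages ~0 over the baseline window
    ref = logp[:, :, base_idx].mean(axis=(0, 2))
    rel = logp - ref[None, :, None]
    n_smooth = max(1, int(round(smooth_s * epochs_band.rate)))
    smooth = _causal_moving_average(rel, n_smooth)
    step = max(1, int(round(step_s * epochs_band.rate)))
    ends = np.arange(n_smooth - 1, smooth.shape[2], step)
    feats = np.transpose(smooth[:, :, ends], (0, 2, 1))
    tags = [band] * w.shape[0]
    return BandPowerFeatureSet(
        features=feats,
        timepoints=epochs_band.times[ends],
        band_index=tags,
        condition=epochs_band.condition.copy(),
        direction=epochs_band.direction.copy(),
        rate=epochs_band.rate / step,
    )


def combine_band_features(
    a: BandPowerFeatureSet, b: BandPowerFeatureSet
) -> BandPowerFeatureSet:
    """Concatenate two band feature blocks (e.g., μ and β) along features."""
    if not np.allclose(a.timepoints, b.timepoints):
        raise ValueError("feature sets have different timelines")
    return BandPowerFeatureSet(
        features=np.concatenate([a.features, b.features], axis=2),
        timepoints=a.timepoints.copy(),
        band_index=list(a.band_index) + list(b.band_index),
        condition=a.condition.copy(),
        direction=a.direction.copy(),
        rate=a.rate,
    )
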