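"""Filtering, resampling, epoching, artifact rejection and EOG subtraction.

The preprocessing chain mirrors standard sensorimotor-EEG practice: zero-phase
Butterworth band-pass per feature family (0.2–5 Hz for low-frequency
amplitudes, 1–40 Hz for spectral features), polyphase downsampling (200 Hz for
spectral work, 10 Hz for amplitude classification), epoching into 6 s trials
aligned to the cue-movement onset, trial rejection on a separate 1–60 Hz path
(amplitude / kurtosis / joint-probability criteria), and a linear eye-artifact
subspace subtraction trained on dedicated calibration runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Union

import numpy as np
from scipy import signal, stats

from .containers import (
    CODE_TO_CONDITION_DIRECTION,
    ContinuousRecording,
    EpochSet,
)

DEFAULT_AMPLITUDE_THRESHOLD_UV = 200.0
DEFAULT_REJECTION_Z = 5.0


@dataclass
class FilterSpec:
    """Band-pass specification: 4th-order Butterworth, forward-backward."""

    low_hz: float
    high_hz: float
    order: int = 4
    zero_phase: bool = True

    def validate(self, rate: float) -> None:
        if not (0 <= self.low_hz < self.high_hz):
            raise ValueError("need 0 <= low_hz < high_hz")
        if self.high_hz >= rate / 2:
            raise ValueError(
                f"high edge {self.high_hz} Hz at or above Nyquist ({rate / 2} Hz)"
            )


# Feature-family filter presets.
AMPLITUDE_BAND = FilterSpec(0.2, 5.0)
SPECTRAL_BAND = FilterSpec(1.0, 40.0)
ARTIFACT_BAND = FilterSpec(1.0, 60.0)
MU_BAND = FilterSpec(8.0, 12.0)
BETA_BAND = FilterSpec(15.0, 32.0)


def bandpass(recording: ContinuousRecording, spec: FilterSpec) -> ContinuousRecording:
    """Zero-phase band-pass; length and markers unchanged."""
    spec.validate(recording.rate)
    if spec.low_hz == 0:
        sos = signal.butter(
            spec.order, spec.high_hz, btype="lowpass", fs=recording.rate, output="sos"
        )
    else:
        sos = signal.butter(
            spec.order,
            [spec.low_hz, spec.high_hz],
            btype="bandpass",
            fs=recording.rate,
            output="sos",
        )
    if spec.zero_phase:
        filtered = signal.sosfiltfilt(sos, recording.samples, axis=1)
    else:
        filtered = signal.sosfilt(sos, recording.samples, axis=1)
    out = recording.copy()
    out.samples = np.ascontiguousarray(filtered)
    return out


def bandpass_epochs(epochs: EpochSet, spec: FilterSpec) -> EpochSet:
    """Zero-phase band-pass applied along the time axis of an epoch tensor."""
    spec.validate(epochs.rate)
    sos = signal.butter(
        spec.order,
        [spec.low_hz, spec.high_hz],
        btype="bandpass",
        fs=epochs.rate,
        output="sos",
    )
    out = epochs.copy()
    out.data = signal.sosfiltfilt(sos, epochs.data, axis=2)
    return out


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def resample(recording: ContinuousRecording, target_hz: float) -> ContinuousRecording:
    """Polyphase resampling to ``target_hz`` (<= current rate).

    Event indices are rescaled with round-half-away-from-zero; duration is
    preserved to within one sample at the target rate.
    """
    if target_hz > recording.rate:
        raise ValueError("upsampling not supported")
    if target_hz == recording.rate:
        return recording.copy()
    frac = Fraction(target_hz / recording.rate).limit_denominator(10000)
    resampled = signal.resample_poly(
        recording.samples, frac.numerator, frac.denominator, axis=1
    )
    factor = target_hz / recording.rate
    events = recording.events.copy()
    if events.size:
        events[:, 0] = _round_half_away(events[:, 0] * factor).astype(np.int64)
        events[:, 0] = np.clip(events[:, 0], 0, resampled.shape[1] - 1)
    out = recording.copy()
    out.samples = resampled
    out.rate = float(target_hz)
    out.events = events
    return out


def epoch(recording: ContinuousRecording, window_s: tuple[float, float]) -> EpochSet:
    """Cut one epoch per cue-movement-onset marker; time 0 = onset."""
    start_s, end_s = window_s
    if start_s >= end_s:
        raise ValueError("epoch window start must precede end")
    rate = recording.rate
    i0 = int(round(start_s * rate))
    i1 = int(round(end_s * rate))
    times = np.arange(i0, i1) / rate
    onsets, conditions, directions = [], [], []
    for s, c in recording.events:
        if c in CODE_TO_CONDITION_DIRECTION:
            cond, direc = CODE_TO_CONDITION_DIRECTION[c]
            onsets.append(int(s))
            conditions.append(cond)
            directions.append(direc)
    data = np.empty((len(onsets), recording.n_channels, i1 - i0))
    for t, s in enumerate(onsets):
        lo, hi = s + i0, s + i1
        if lo < 0 or hi > recording.n_samples:
            raise ValueError(
                f"trial {t} (onset sample {s}) window {window_s} exceeds recording bounds"
            )
        data[t] = recording.samples[:, lo:hi]
    return EpochSet(
        data=data,
        times=times,
        condition=np.array(conditions),
        direction=np.array(directions),
        reject_mask=np.zeros(len(onsets), dtype=bool),
        rate=rate,
        channel_labels=list(recording.channel_labels),
        channel_kinds=list(recording.channel_kinds),
    )


# ---------------------------------------------------------------------------
# Artifact-trial rejection (computed on a separate 1-60 Hz filtered path)
# ---------------------------------------------------------------------------


def _kurtosis_stat(data_eeg: np.ndarray) -> np.ndarray:
    """Per-trial excess kurtosis averaged across channels."""
    return stats.kurtosis(data_eeg, axis=2, fisher=True, bias=True).mean(axis=1)


def _joint_probability_stat(data_eeg: np.ndarray, n_bins: int = 50) -> np.ndarray:
    """Per-trial mean negative log-likelihood under channel-wise histograms
    pooled across trials (an improbability score for unusual trials)."""
    n_trials, n_ch, n_t = data_eeg.shape
    out = np.zeros(n_trials)
    for c in range(n_ch):
        pooled = data_eeg[:, c, :].ravel()
        counts, edges = np.histogram(pooled, bins=n_bins)
        p = (counts + 1.0) / (counts.sum() + n_bins)  # Laplace floor
        idx = np.clip(np.searchsorted(edges, data_eeg[:, c, :], side="right") - 1, 0, n_bins - 1)
        out += -np.log(p[idx]).mean(axis=1)
    return out / n_ch


def _robust_z(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def mark_artifacts(
    epochs_1_60: EpochSet,
    amp_uv: float = DEFAULT_AMPLITUDE_THRESHOLD_UV,
    z: float = DEFAULT_REJECTION_Z,
) -> np.ndarray:
    """Boolean rejection mask; the data are left untouched.

    A trial is marked when (a) any EEG sample exceeds ``amp_uv`` in absolute
    value, or its (b) kurtosis or (c) joint-probability statistic lies more
    than ``z`` standard deviations from the across-trial mean. Statistics pool
    channels per trial before z-scoring (a documented interpretation; the
    estimator functions are swappable).
    """
    if epochs_1_60.n_trials < 3:
        raise ValueError("need >= 3 trials for across-trial rejection statistics")
    eeg = epochs_1_60.data[:, epochs_1_60.eeg_indices(), :]
    amp_rule = np.abs(eeg).max(axis=(1, 2)) > amp_uv
    kurt_rule = np.abs(_robust_z(_kurtosis_stat(eeg))) > z
    jp_rule = np.abs(_robust_z(_joint_probability_stat(eeg))) > z
    return amp_rule | kurt_rule | jp_rule


# ---------------------------------------------------------------------------
# Eye-artifact subspace subtraction
# ---------------------------------------------------------------------------


@dataclass
class EogSubspaceModel:
    """Linear ocular-attenuation model: EEG_clean = EEG - B @ EOG.

    ``B`` is estimated by multivariate least squares of EEG on the EOG
    channels over calibration artifact segments; the application is the
    channel-space projection I - B(EOG->EEG), which leaves artifact-free EEG
    untouched whenever the EOG channels are silent.
    """

    coefficients: np.ndarray  # (n_eeg, n_eog)
    eeg_labels: list[str]
    eog_labels: list[str]
    residual_variance_ratio: float

    def projection_matrix(self, channel_labels: list[str]) -> np.ndarray:
        """Full channels x channels projection for a matching channel set."""
        n = len(channel_labels)
        p = np.eye(n)
        try:
            eeg_idx = [channel_labels.index(l) for l in self.eeg_labels]
            eog_idx = [channel_labels.index(l) for l in self.eog_labels]
        except ValueError as e:
            raise ValueError(f"channel set does not match EOG model: {e}") from e
        for i, r in zip(eeg_idx, self.coefficients):
            p[i, eog_idx] -= r
        return p


def _artifact_segments(
    calibration: ContinuousRecording, span_s: float = 0.8
) -> np.ndarray:
    from .containers import MARKER_BLINK, MARKER_SACCADE

    n = int(round(span_s * calibration.rate))
    cols = []
    for s, c in calibration.events:
        if c in (MARKER_BLINK, MARKER_SACCADE):
            hi = min(int(s) + n, calibration.n_samples)
            cols.append(np.arange(int(s), hi))
    if not cols:
        raise ValueError("calibration recording has no artifact markers")
    return np.concatenate(cols)


def fit_eog_subspace(
    calibration: ContinuousRecording, ridge: float = 1e-3
) -> EogSubspaceModel:
    """Estimate the EOG->EEG bleed on marked calibration artifact segments.

    The regression is ridge-regularized (``ridge`` times the mean eigenvalue
    of the EOG covariance): blink and saccade time courses span only part of
    the EOG space, and an unregularized inverse amplifies noise along the
    weakly excited directions.
    """
    eog_idx = calibration.eog_indices()
    if eog_idx.size == 0:
        raise ValueError("calibration recording has no EOG channels")
    eeg_idx = calibration.eeg_indices()
    seg = _artifact_segments(calibration)
    eog = calibration.samples[np.ix_(eog_idx, seg)]
    eeg = calibration.samples[np.ix_(eeg_idx, seg)]
    eog_c = eog - eog.mean(axis=1, keepdims=True)
    eeg_c = eeg - eeg.mean(axis=1, keepdims=True)
    n = eog_c.shape[1]
    cov_oo = eog_c @ eog_c.T / n
    cov_eo = eeg_c @ eog_c.T / n
    reg = ridge * np.trace(cov_oo) / cov_oo.shape[0]
    coeff = cov_eo @ np.linalg.inv(cov_oo + reg * np.eye(cov_oo.shape[0]))
    resid = eeg_c - coeff @ eog_c
    ratio = float(resid.var() / eeg_c.var()) if eeg_c.var() > 0 else 0.0
    return EogSubspaceModel(
        coefficients=coeff,
        eeg_labels=[calibration.channel_labels[i] for i in eeg_idx],
        eog_labels=[calibration.channel_labels[i] for i in eog_idx],
        residual_variance_ratio=ratio,
    )


def apply_eog_subspace(
    model: EogSubspaceModel,
    data: Union[ContinuousRecording, EpochSet],
) -> Union[ContinuousRecording, EpochSet]:
    """Apply the ocular projection sample-wise (deterministic, linear)."""
    p = model.projection_matrix(list(data.channel_labels))
    out = data.copy()
    if isinstance(data, ContinuousRecording):
        out.samples = p @ data.samples
    else:
        out.data = np.einsum("ij,tjs->tis", p, data.data)
    return out


#: Optional channel-space cleaning hook (e.g., an externally computed ICA
#: projection): any callable mapping a channels x channels matrix consumer.
CleaningProjection = Callable[[np.ndarray], np.ndarray]


def apply_channel_projection(
    data: Union[ContinuousRecording, EpochSet], projection: np.ndarray
) -> Union[ContinuousRecording, EpochSet]:
    """Apply a user-supplied channels x channels projection (cleaning hook)."""
    projection = np.asarray(projection)
    n = len(data.channel_labels)
    if projection.shape != (n, n):
        raise ValueError(f"projection must be {n} x {n}")
    out = data.copy()
    if isinstance(data, ContinuousRecording):
        out.samples = projection @ data.samples
    else:
        out.data = np.einsum("ij,tjs->tis", projection, data.data)
    return out


# ---------------------------------------------------------------------------
# Referencing and channel selection
# ---------------------------------------------------------------------------


def common_average_reference(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean across EEG channels from each EEG channel."""
    eeg = epochs.eeg_indices()
    if eeg.size < 2:
        raise ValueError("common average reference needs >= 2 EEG channels")
    out = epochs.copy()
    out.data[:, eeg, :] -= out.data[:, eeg, :].mean(axis=1, keepdims=True)
    return out


def select_channels(epochs: EpochSet, subset: list[str]) -> EpochSet:
    """Restrict to ``subset`` in the given order."""
    missing = [s for s in subset if s not in epochs.channel_labels]
    if missing:
        raise ValueError(f"unknown channel label(s): {missing}")
    idx = [epochs.channel_labels.index(s) for s in subset]
    return EpochSet(
        data=epochs.data[:, idx, :].copy(),
        times=epochs.times.copy(),
        condition=epochs.condition.copy(),
        direction=epochs.direction.copy(),
        reject_mask=epochs.reject_mask.copy(),
        rate=epochs.rate,
        channel_labels=[epochs.channel_labels[i] for i in idx],
        channel_kinds=[epochs.channel_kinds[i] for i in idx],
    )
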