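"""Synthetic EEG/EOG generator emulating a guided center-out motor-imagery paradigm.

The generator produces continuous 61-channel EEG + 3-channel EOG recordings
with the paradigm's marker timeline: per trial a fixation cross (whose latter
part serves as the baseline), a stationary visual cue (pre-MI), and a moving
cue whose onset defines time zero of each trial. Trials belong to one of two
guidance conditions (vibrotactile+visual ``VtG`` vs. visual-only ``noVtG``)
and one of two movement directions (``right`` vs. ``up``).

Injected class structure mirrors the phenomenology of such experiments:

* a movement-related cortical potential (MRCP) — a smooth central negativity
  peaking within a second after the cue-movement onset, with
  direction-specific spatial gain and a condition-dependent depth/broadening;
* μ (8–12 Hz) and β (15–32 Hz) sensorimotor rhythms whose power drops during
  the motor-imagery window (event-related desynchronization, ERD), by a
  per-band, per-condition depth in dB;
* evoked potentials locked to the fixation cross, cue appearance and
  cue-movement onset (identical across classes);
* ocular artifacts (blinks, saccades) on the EOG channels that bleed into
  frontal EEG through a fixed mixing matrix;
* spatially correlated pink (1/f) background noise.

None of this claims biophysical realism: the model is a sum of smooth
templates and band-limited noise over gaussian scalp topographies, built so
that every downstream stage (filtering, rejection, EOG subtraction, CSP,
sLDA, pattern back-projection) has a known ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

from .containers import (
    ALL_CHANNELS,
    CONDITIONS,
    DIRECTIONS,
    EEG_CHANNELS,
    EOG_CHANNELS,
    MARKER_BLINK,
    MARKER_CUE,
    MARKER_FIXATION,
    MARKER_SACCADE,
    MOVEMENT_ONSET_CODES,
    ContinuousRecording,
    channel_positions,
)

BANDS = {"mu": (8.0, 12.0), "beta": (15.0, 32.0)}


class InvalidSpecError(ValueError):
    """Raised when a paradigm or effect specification violates its invariants."""


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass
class ParadigmSpec:
    """Trial timeline and run structure.

    Defaults reproduce the full experimental paradigm: three 40-trial runs per condition,
    7.5 s trials sampled at 1 kHz. Within a trial (times relative to the
    cue-movement onset): a 1.5 s alert precedes the fixation cross at −4 s,
    the stationary cue appears at −2 s, the cue starts moving at 0 s and the
    imagery period lasts 2 s. The classification baseline window sits inside
    the latter part of the fixation period.
    """

    n_runs_per_condition: int = 3
    n_trials_per_run: int = 40
    trial_length_s: float = 7.5
    baseline_window_s: tuple[float, float] = (-3.5, -2.5)
    pre_mi_onset_s: float = 2.0
    mi_duration_s: float = 2.0
    sampling_rate_hz: float = 1000.0
    fixation_duration_s: float = 2.0
    alert_lead_s: float = 1.5

    def __post_init__(self):
        for name in (
            "trial_length_s",
            "pre_mi_onset_s",
            "mi_duration_s",
            "sampling_rate_hz",
            "fixation_duration_s",
        ):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive")
        if self.n_runs_per_condition < 1 or self.n_trials_per_run < 1:
            raise InvalidSpecError("run/trial counts must be >= 1")
        span = (
            self.alert_lead_s
            + self.fixation_duration_s
            + self.pre_mi_onset_s
            + self.mi_duration_s
        )
        if self.trial_length_s + 1e-9 < span:
            raise InvalidSpecError("trial_length_s shorter than the sum of sub-windows")
        b0, b1 = self.baseline_window_s
        if b0 >= b1:
            raise InvalidSpecError("baseline window start must precede end")
        if b1 > -self.pre_mi_onset_s + 1e-9:
            raise InvalidSpecError("baseline must end before the pre-MI period")

    @property
    def fixation_offset_s(self) -> float:
        """Fixation-cross onset relative to the cue-movement onset."""
        return -(self.pre_mi_onset_s + self.fixation_duration_s)

    @property
    def n_trials_total(self) -> int:
        return 2 * self.n_runs_per_condition * self.n_trials_per_run


@dataclass
class EffectSpec:
    """Injected effect magnitudes. Amplitudes in μV, ERD depths in dB (<= 0).

    ``direction_topography`` maps each direction to a per-EEG-channel gain
    vector; when ``None`` a default pair of gaussian scalp profiles is used
    (``right`` centered between C1/C3 — contralateral to the imagined right
    hand — and ``up`` centered at FCz/Cz). The MRCP condition contrast is
    calibrated to grand-average magnitudes typical of this paradigm (deeper
    negativity without vibrotactile guidance, spatially broader with it);
    ERD depths default to grand-average μ peaks of around −2 dB, with
    invented β values.
    """

    mrcp_peak_amplitude_uv: dict = field(
        default_factory=lambda: {"right": -1.8, "up": -1.4}
    )
    mrcp_peak_time_s: float = 0.77
    direction_topography: Optional[dict] = None
    erd_depth_db: dict = field(
        default_factory=lambda: {
            "mu": {"VtG": -2.25, "noVtG": -2.04},
            "beta": {"VtG": -1.5, "noVtG": -1.3},
        }
    )
    ep_amplitude_uv: dict = field(
        default_factory=lambda: {"fixation": 1.5, "cue": 3.0, "movement": 3.0}
    )
    eog_rate_per_min: float = 4.0
    noise_sigma_uv: float = 4.0
    seed: int = 0
    osc_amplitude_uv: dict = field(default_factory=lambda: {"mu": 3.0, "beta": 1.5})
    mrcp_condition_scale: dict = field(
        default_factory=lambda: {"VtG": 0.45, "noVtG": 1.0}
    )
    condition_broaden: dict = field(default_factory=lambda: {"VtG": 1.3, "noVtG": 1.0})
    eeg_bleed_gain: float = 1.0

    def __post_init__(self):
        if self.noise_sigma_uv <= 0:
            raise InvalidSpecError("noise_sigma_uv must be positive")
        for band, per_cond in self.erd_depth_db.items():
            for cond, v in per_cond.items():
                if v > 0:
                    raise InvalidSpecError(
                        f"erd_depth_db[{band}][{cond}] must be <= 0 (desynchronization)"
                    )
        if self.direction_topography is not None:
            for d, vec in self.direction_topography.items():
                if len(np.asarray(vec)) != len(EEG_CHANNELS):
                    raise InvalidSpecError(
                        f"direction_topography[{d}] needs one entry per EEG channel"
                    )

    @classmethod
    def null(cls, seed: int = 0, noise_sigma_uv: float = 6.0) -> "EffectSpec":
        """All class- and window-dependent amplitudes zero: decoding at chance."""
        return cls(
            mrcp_peak_amplitude_uv={"right": 0.0, "up": 0.0},
            erd_depth_db={
                "mu": {"VtG": 0.0, "noVtG": 0.0},
                "beta": {"VtG": 0.0, "noVtG": 0.0},
            },
            ep_amplitude_uv={"fixation": 0.0, "cue": 0.0, "movement": 0.0},
            noise_sigma_uv=noise_sigma_uv,
            seed=seed,
        )


@dataclass
class GroundTruth:
    """One record per generated trial plus the specs that produced them."""

    trials: pd.DataFrame  # columns: run, condition, direction, onset_sample, reject
    paradigm: ParadigmSpec
    effects: EffectSpec


# ---------------------------------------------------------------------------
# Signal primitives
# ---------------------------------------------------------------------------


def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise, independent across rows."""
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samp)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    out = np.fft.irfft(spec * scale, n=n_samp, axis=1)
    out /= out.std(axis=1, keepdims=True)
    return out


def _narrowband_noise(
    rng: np.random.Generator, n_samp: int, band: tuple[float, float], rate: float
) -> np.ndarray:
    """Unit-variance band-limited gaussian noise (an ongoing rhythm carrier)."""
    lo, hi = band
    hi = min(hi, 0.45 * rate)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samp))
    return x / x.std()


def _gaussian_topography(
    positions: np.ndarray, center_label: str, sigma_m: float
) -> np.ndarray:
    labels = list(EEG_CHANNELS)
    c = positions[labels.index(center_label)]
    d2 = np.sum((positions - c) ** 2, axis=1)
    topo = np.exp(-d2 / (2.0 * sigma_m**2))
    return topo / topo.max()


def _mrcp_template(times: np.ndarray, peak_s: float, start_s: float, end_s: float) -> np.ndarray:
    """C1-smooth unimodal raised-cosine bump, peak value 1 at ``peak_s``."""
    out = np.zeros_like(times)
    rise = (times >= start_s) & (times < peak_s)
    fall = (times >= peak_s) & (times <= end_s)
    out[rise] = 0.5 * (1 - np.cos(np.pi * (times[rise] - start_s) / (peak_s - start_s)))
    out[fall] = 0.5 * (1 + np.cos(np.pi * (times[fall] - peak_s) / (end_s - peak_s)))
    return out


def _ep_template(times: np.ndarray) -> np.ndarray:
    """Gabor-like biphasic evoked deflection starting at t=0, ~0.35 s long."""
    t0, tau, f = 0.15, 0.05, 6.0
    return np.exp(-((times - t0) ** 2) / (2 * tau**2)) * np.sin(2 * np.pi * f * (times - t0))


def _blink_template(rate: float) -> np.ndarray:
    n = max(3, int(round(0.3 * rate)))
    return 150.0 * np.hanning(n)


def _saccade_template(rate: float) -> np.ndarray:
    """Smoothed step-and-return deflection for a horizontal saccade."""
    n = max(4, int(round(0.4 * rate)))
    ramp = int(max(1, round(0.05 * rate)))
    tpl = np.ones(n)
    tpl[:ramp] = np.linspace(0, 1, ramp)
    tpl[-ramp:] = np.linspace(1, 0, ramp)
    return 60.0 * tpl


def _add_at(x: np.ndarray, start: int, template: np.ndarray) -> None:
    """Add ``template`` into 1-D ``x`` starting at ``start``, clipped to bounds."""
    lo = max(start, 0)
    hi = min(start + len(template), len(x))
    if hi > lo:
        x[lo:hi] += template[lo - start : hi - start]


class _Mixer:
    """Montage-derived spatial structure shared by both generator entry points."""

    def __init__(self, effects: EffectSpec):
        self.pos = channel_positions(EEG_CHANNELS)
        # Spatially correlated background: exponential covariance over scalp
        # distance, Cholesky-mixed into the channel dimension.
        d = np.linalg.norm(self.pos[:, None, :] - self.pos[None, :, :], axis=2)
        cov = np.exp(-d / 0.05) + 1e-6 * np.eye(len(EEG_CHANNELS))
        self.chol = np.linalg.cholesky(cov)
        if effects.direction_topography is not None:
            self.dir_topo = {
                k: np.asarray(v, dtype=float)
                for k, v in effects.direction_topography.items()
            }
        else:
            self.dir_topo = {
                "right": _gaussian_topography(self.pos, "C3", 0.045),
                "up": _gaussian_topography(self.pos, "FCz", 0.045),
            }
        self.osc_topo = _gaussian_topography(self.pos, "CPz", 0.05)
        self.ep_topo = _gaussian_topography(self.pos, "POz", 0.05)
        # EOG -> EEG bleed columns (blink via vertical, saccades via lateral pair)
        labels = list(EEG_CHANNELS)
        frontal = np.exp(
            -np.linalg.norm(self.pos - self.pos[labels.index("Fpz")], axis=1) / 0.05
        )
        left = np.exp(
            -np.linalg.norm(self.pos - self.pos[labels.index("F7")], axis=1) / 0.05
        )
        right = np.exp(
            -np.linalg.norm(self.pos - self.pos[labels.index("F8")], axis=1) / 0.05
        )
        self.bleed = np.column_stack([0.35 * frontal, 0.12 * left, 0.12 * right])

    def broadened(self, topo_center: str, scale: float) -> np.ndarray:
        return _gaussian_topography(self.pos, topo_center, 0.05 * scale)


def _background(
    rng: np.random.Generator, mixer: _Mixer, effects: EffectSpec, n_samp: int
) -> np.ndarray:
    """Pink-noise floor for all 64 channels (EOG rows independent, half scale)."""
    x = np.empty((len(ALL_CHANNELS), n_samp))
    eeg = mixer.chol @ _pink_noise(rng, len(EEG_CHANNELS), n_samp)
    eeg /= eeg.std(axis=1, keepdims=True)
    x[: len(EEG_CHANNELS)] = effects.noise_sigma_uv * eeg
    x[len(EEG_CHANNELS) :] = 0.5 * effects.noise_sigma_uv * _pink_noise(
        rng, len(EOG_CHANNELS), n_samp
    )
    return x


def _add_ocular(
    rng: np.random.Generator,
    mixer: _Mixer,
    effects: EffectSpec,
    x: np.ndarray,
    rate: float,
    blink_starts: np.ndarray,
    saccade_starts: np.ndarray,
) -> None:
    """Blinks on EOGV, saccades on the EOGL/EOGR pair, both bleeding into EEG."""
    n_eeg = len(EEG_CHANNELS)
    iv, il, ir = n_eeg, n_eeg + 1, n_eeg + 2
    eog = np.zeros((3, x.shape[1]))
    blink = _blink_template(rate)
    sacc = _saccade_template(rate)
    # Asymmetric gains keep the three EOG channels linearly independent
    # (periocular electrodes never see a perfect mirror image).
    for s in blink_starts:
        _add_at(eog[0], int(s), blink)
        _add_at(eog[1], int(s), 0.35 * blink)
        _add_at(eog[2], int(s), 0.25 * blink)
    for s in saccade_starts:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        _add_at(eog[1], int(s), sign * sacc)
        _add_at(eog[2], int(s), -0.6 * sign * sacc)
        _add_at(eog[0], int(s), 0.15 * sign * sacc)
    x[iv] += eog[0]
    x[il] += eog[1]
    x[ir] += eog[2]
    x[:n_eeg] += effects.eeg_bleed_gain * (mixer.bleed @ eog)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def generate_recording(
    paradigm: ParadigmSpec, effects: EffectSpec
) -> tuple[ContinuousRecording, GroundTruth]:
    """Generate the full main-session recording with ground-truth labels.

    Runs alternate between conditions; directions are balanced within each
    run and shuffled by the seeded generator, which also draws the inter-trial
    gaps (0.25–0.75 s). Identical (paradigm, effects) including the seed yield
    bit-identical output.
    """
    rng = np.random.default_rng(effects.seed)
    mixer = _Mixer(effects)
    rate = paradigm.sampling_rate_hz

    # --- schedule trials -------------------------------------------------
    records = []
    t_cursor = 0.5  # lead-in seconds
    trial_len = paradigm.trial_length_s
    onset_in_trial = (
        paradigm.alert_lead_s + paradigm.fixation_duration_s + paradigm.pre_mi_onset_s
    )
    for run in range(paradigm.n_runs_per_condition):
        for cond in CONDITIONS:
            n = paradigm.n_trials_per_run
            dirs = np.array([DIRECTIONS[i % 2] for i in range(n)])
            rng.shuffle(dirs)
            for d in dirs:
                onset = t_cursor + onset_in_trial
                records.append(
                    {
                        "run": run,
                        "condition": cond,
                        "direction": str(d),
                        "onset_sample": int(round(onset * rate)),
                        "reject": False,
                    }
                )
                t_cursor += trial_len + rng.uniform(0.25, 0.75)
    total_s = t_cursor + 0.5
    n_samp = int(round(total_s * rate))
    trials = pd.DataFrame.from_records(records)

    # --- continuous components ------------------------------------------
    x = _background(rng, mixer, effects, n_samp)

    band_carriers = {
        band: _narrowband_noise(rng, n_samp, BANDS[band], rate) for band in BANDS
    }
    for band, carrier in band_carriers.items():
        amp = effects.osc_amplitude_uv.get(band, 0.0)
        if amp > 0:
            x[: len(EEG_CHANNELS)] += amp * np.outer(mixer.osc_topo, carrier)

    # --- per-trial templates ---------------------------------------------
    mrcp_t = np.arange(
        int(round(-0.3 * rate)), int(round(paradigm.mi_duration_s * rate))
    ) / rate
    mrcp_shape = _mrcp_template(
        mrcp_t, effects.mrcp_peak_time_s, -0.3, paradigm.mi_duration_s
    )
    ep_t = np.arange(0, int(round(0.35 * rate))) / rate
    ep_shape = _ep_template(ep_t)

    mi_len = int(round(paradigm.mi_duration_s * rate))
    ramp_len = min(int(round(0.25 * rate)), mi_len // 2)
    ramp = np.ones(mi_len)
    up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_len) / ramp_len))
    ramp[:ramp_len] = up
    ramp[-ramp_len:] = up[::-1]

    events = []
    n_eeg = len(EEG_CHANNELS)
    for rec in records:
        onset = rec["onset_sample"]
        cond, direc = rec["condition"], rec["direction"]
        fix = onset + int(round(paradigm.fixation_offset_s * rate))
        cue = onset - int(round(paradigm.pre_mi_onset_s * rate))
        events.append((fix, MARKER_FIXATION))
        events.append((cue, MARKER_CUE))
        events.append((onset, MOVEMENT_ONSET_CODES[(cond, direc)]))

        # MRCP: direction topography (broadened per condition), negative bump
        amp = (
            effects.mrcp_peak_amplitude_uv.get(direc, 0.0)
            * effects.mrcp_condition_scale.get(cond, 1.0)
        )
        if amp != 0.0:
            broaden = effects.condition_broaden.get(cond, 1.0)
            center = "C3" if direc == "right" else "FCz"
            base = mixer.dir_topo[direc]
            topo = base if broaden == 1.0 else np.maximum(
                base, 0.8 * mixer.broadened(center, broaden)
            )
            start = onset + int(round(-0.3 * rate))
            seg = slice(max(start, 0), min(start + len(mrcp_shape), n_samp))
            tpl = mrcp_shape[seg.start - start : seg.stop - start]
            x[:n_eeg, seg] += amp * topo[:, None] * tpl[None, :]

        # Evoked potentials (class-independent)
        for mark, key in ((fix, "fixation"), (cue, "cue"), (onset, "movement")):
            a = effects.ep_amplitude_uv.get(key, 0.0)
            if a != 0.0:
                seg = slice(max(mark, 0), min(mark + len(ep_shape), n_samp))
                tpl = ep_shape[seg.start - mark : seg.stop - mark]
                x[:n_eeg, seg] += a * mixer.ep_topo[:, None] * tpl[None, :]

        # ERD: attenuate the band carriers during MI with a condition-specific
        # spatial weight (unit at the rhythm's core, broader under VtG).
        for band, carrier in band_carriers.items():
            depth_db = effects.erd_depth_db.get(band, {}).get(cond, 0.0)
            amp_b = effects.osc_amplitude_uv.get(band, 0.0)
            if depth_db == 0.0 or amp_b == 0.0:
                continue
            g = 10.0 ** (depth_db / 20.0)  # amplitude gain < 1
            broaden = effects.condition_broaden.get(cond, 1.0)
            w = mixer.osc_topo ** (1.0 / broaden**2)  # flattening = broadening
            w = w / w.max()
            seg = slice(onset, min(onset + mi_len, n_samp))
            mod = (g - 1.0) * ramp[: seg.stop - seg.start] * carrier[seg]
            x[:n_eeg, seg] += amp_b * (mixer.osc_topo * w)[:, None] * mod[None, :]

    # --- ocular activity --------------------------------------------------
    rate_hz = effects.eog_rate_per_min / 60.0
    n_blinks = rng.poisson(rate_hz * total_s)
    n_sacc = rng.poisson(rate_hz * total_s)
    blink_starts = rng.integers(0, n_samp - int(rate), size=n_blinks)
    sacc_starts = rng.integers(0, n_samp - int(rate), size=n_sacc)
    _add_ocular(rng, mixer, effects, x, rate, blink_starts, sacc_starts)

    events_arr = np.array(sorted(events), dtype=np.int64)
    recording = ContinuousRecording(
        samples=x,
        channel_labels=list(ALL_CHANNELS),
        channel_kinds=["EEG"] * n_eeg + ["EOG"] * len(EOG_CHANNELS),
        rate=rate,
        events=events_arr,
    )
    return recording, GroundTruth(trials=trials, paradigm=paradigm, effects=effects)


def generate_eye_calibration(
    paradigm: ParadigmSpec, effects: EffectSpec, duration_s: float = 120.0
) -> ContinuousRecording:
    """Rest EEG plus a dense, marked schedule of blinks and saccades.

    Exactly ``floor(eog_rate_per_min * duration_s / 60)`` events of each type
    are placed on an even grid (with small seeded jitter), alternating blink /
    saccade in separate interleaved grids, mirroring controlled eye-artifact
    calibration runs.
    """
    if effects.eog_rate_per_min <= 0:
        raise InvalidSpecError("eog_rate_per_min must be positive for calibration")
    rng = np.random.default_rng(effects.seed + 104729)  # distinct stream
    mixer = _Mixer(effects)
    rate = paradigm.sampling_rate_hz
    n_samp = int(round(duration_s * rate))
    x = _background(rng, mixer, effects, n_samp)
    for band in BANDS:
        amp = effects.osc_amplitude_uv.get(band, 0.0)
        if amp > 0:
            x[: len(EEG_CHANNELS)] += amp * np.outer(
                mixer.osc_topo, _narrowband_noise(rng, n_samp, BANDS[band], rate)
            )

    n_events = int(effects.eog_rate_per_min * duration_s / 60.0)
    period = n_samp / max(n_events, 1)
    jitter = 0.1 * period
    blink_starts = np.clip(
        (np.arange(n_events) + 0.25) * period + rng.uniform(-jitter, jitter, n_events),
        0,
        n_samp - int(rate),
    ).astype(int)
    sacc_starts = np.clip(
        (np.arange(n_events) + 0.75) * period + rng.uniform(-jitter, jitter, n_events),
        0,
        n_samp - int(rate),
    ).astype(int)
    _add_ocular(rng, mixer, effects, x, rate, blink_starts, sacc_starts)
    events = sorted(
        [(int(s), MARKER_BLINK) for s in blink_starts]
        + [(int(s), MARKER_SACCADE) for s in sacc_starts]
    )
    return ContinuousRecording(
        samples=x,
        channel_labels=list(ALL_CHANNELS),
        channel_kinds=["EEG"] * len(EEG_CHANNELS) + ["EOG"] * len(EOG_CHANNELS),
        rate=rate,
        events=np.array(events, dtype=np.int64).reshape(-1, 2),
    )


def inject_gross_artifact(
    recording: ContinuousRecording,
    trial_index: int,
    peak_uv: float,
    ground_truth: Optional[GroundTruth] = None,
    threshold_uv: float = 200.0,
    channel: str = "Cz",
) -> ContinuousRecording:
    """Return a copy with one trial carrying a transient reaching ``peak_uv``.

    The transient (a 100 ms raised-cosine bump on ``channel``, 0.5 s after the
    trial's cue-movement onset) replaces the underlying samples so the trial's
    extreme value equals exactly ``peak_uv`` μV. When ``ground_truth`` is
    supplied, its rejection flag for the trial is set iff
    ``peak_uv > threshold_uv``.
    """
    onset_codes = set(MOVEMENT_ONSET_CODES.values())
    onsets = [s for s, c in recording.events if c in onset_codes]
    if not 0 <= trial_index < len(onsets):
        raise IndexError(f"trial_index {trial_index} out of range (n={len(onsets)})")
    out = recording.copy()
    rate = recording.rate
    ch = recording.channel_labels.index(channel)
    center = int(onsets[trial_index] + round(0.5 * rate))
    n = max(3, int(round(0.1 * rate)))
    bump = np.hanning(n) / np.hanning(n).max()
    lo = max(center - n // 2, 0)
    hi = min(lo + n, out.n_samples)
    out.samples[ch, lo:hi] = peak_uv * bump[: hi - lo]
    if ground_truth is not None:
        ground_truth.trials.loc[trial_index, "reject"] = bool(peak_uv > threshold_uv)
    return out
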