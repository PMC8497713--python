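"""Shared fixtures: small synthetic paradigms sized for fast, exact checks."""

import numpy as np
import pytest

import midecode as md


def tiny_paradigm(rate: float = 160.0, n_trials: int = 12) -> md.ParadigmSpec:
    return md.ParadigmSpec(
        n_runs_per_condition=1, n_trials_per_run=n_trials, sampling_rate_hz=rate
    )


def quiet_effects(seed: int = 0, **overrides) -> md.EffectSpec:
    """Effects with ocular bleed and evoked clutter suppressed, for clean
    single-component measurements."""
    base = dict(
        seed=seed,
        eog_rate_per_min=0.5,
        eeg_bleed_gain=0.0,
        ep_amplitude_uv={"fixation": 0.0, "cue": 0.0, "movement": 0.0},
        mrcp_peak_amplitude_uv={"right": 0.0, "up": 0.0},
        erd_depth_db={"mu": {"VtG": 0.0, "noVtG": 0.0}, "beta": {"VtG": 0.0, "noVtG": 0.0}},
        osc_amplitude_uv={"mu": 0.0, "beta": 0.0},
        noise_sigma_uv=1.0,
    )
    base.update(overrides)
    return md.EffectSpec(**base)


@pytest.fixture(scope="session")
def small_recording():
    """One run of 12 trials per condition at 160 Hz with default effects."""
    par = tiny_paradigm()
    rec, gt = md.generate_recording(par, md.EffectSpec(seed=7))
    return par, rec, gt


def make_epochs(
    data: np.ndarray,
    rate: float,
    t0: float = 0.0,
    labels=None,
    channel_labels=None,
) -> md.EpochSet:
    """Wrap a raw (trials x channels x time) array as an EpochSet."""
    n, c, t = data.shape
    labels = np.asarray(labels) if labels is not None else np.array(["A"] * n)
    channel_labels = channel_labels or [f"ch{i}" for i in range(c)]
    return md.EpochSet(
        data=data,
        times=t0 + np.arange(t) / rate,
        condition=labels,
        direction=labels,
        reject_mask=np.zeros(n, dtype=bool),
        rate=rate,
        channel_labels=list(channel_labels),
        channel_kinds=["EEG"] * c,
    )
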