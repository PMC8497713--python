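"""End-to-end analyses: simulate → preprocess → features → decode → patterns → stats.

Three decoding problems are orchestrated from one configuration:

* **direction** — right vs. up, separately per guidance condition, as a
  sliding-window accuracy time course (amplitude features; the spectral
  variant is also run and reported);
* **mi-vs-baseline** — motor imagery (0.5–1.5 s) against baseline
  (−3.5..−2.5 s), per condition and feature family, with a paired Wilcoxon
  comparison across simulated subjects;
* **condition** — VtG vs. noVtG over the whole trial, both feature families.

"Subjects" are independent seeded replicates of the generator with jittered
effect amplitudes, which is what permits group-level statistics on synthetic
data. All randomness descends from the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import decode, features, patterns, preprocess, stats, synthetic
from .containers import CLASSIFICATION_CHANNELS, CONDITIONS, EpochSet


@dataclass
class AnalysisConfig:
    """One configuration for all three analyses; defaults follow the full
    experimental protocol (7.5 s trials at 1 kHz, 3 x 40 trials per condition, 0.2–5 /
    1–40 Hz feature bands, 10 / 200 Hz classification rates, 31-channel
    sensorimotor subset, CSP fit 0.5–1.5 s with 5 filters per class)."""

    paradigm: synthetic.ParadigmSpec = field(default_factory=synthetic.ParadigmSpec)
    effects: synthetic.EffectSpec = field(default_factory=synthetic.EffectSpec)
    channel_subset: tuple[str, ...] = CLASSIFICATION_CHANNELS
    epoch_window_s: tuple[float, float] = (-4.0, 2.0)
    mi_window_s: tuple[float, float] = (0.5, 1.5)
    baseline_window_s: tuple[float, float] = (-3.5, -2.5)
    csp_fit_window_s: tuple[float, float] = (0.5, 1.5)
    amplitude_rate_hz: float = 10.0
    spectral_rate_hz: float = 200.0
    feature_window_s: float = 1.0
    feature_step_s: float = 0.1
    k_per_class: int = 5
    cv: decode.CvScheme = field(default_factory=decode.CvScheme)
    alpha: float = 0.05
    rejection_amp_uv: float = 200.0
    rejection_z: float = 5.0
    calibration_duration_s: float = 120.0
    direction_pattern_windows: tuple = ((0.6, 1.2),)
    condition_pattern_windows: tuple = ((-1.4, -0.7), (1.1, 1.6))
    n_subjects: int = 15
    families: tuple[str, ...] = ("amplitude", "spectral")
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.epoch_window_s
        for w in (self.mi_window_s, self.baseline_window_s, self.csp_fit_window_s):
            if w[0] < lo - 1e-9 or w[1] > hi + 1e-9:
                raise ValueError(f"window {w} outside epoch window {self.epoch_window_s}")
        if self.spectral_rate_hz > self.paradigm.sampling_rate_hz:
            raise ValueError("spectral_rate_hz above the acquisition rate")


def desk_scale_config(
    seed: int = 0,
    effects: Optional[synthetic.EffectSpec] = None,
    n_trials_per_run: int = 24,
    sampling_rate_hz: float = 160.0,
    n_subjects: int = 1,
) -> AnalysisConfig:
    """Reduced problem-size preset for interactive runs and calibration studies.

    One run of ``n_trials_per_run`` trials per condition at a 160 Hz
    acquisition rate (spectral features stay at the acquisition rate), with
    4-fold x 2-repeat CV — four folds keep the 12/12 class split exactly
    balanced within every fold, which avoids the pessimistic accuracy bias
    that unbalanced stratified folds introduce at small trial counts. The
    classification timeline is thinned to one sample per 200 ms. Everything
    else follows the full-scale defaults.
    """
    return AnalysisConfig(
        paradigm=synthetic.ParadigmSpec(
            n_runs_per_condition=1,
            n_trials_per_run=n_trials_per_run,
            sampling_rate_hz=sampling_rate_hz,
        ),
        effects=effects if effects is not None else synthetic.EffectSpec(seed=seed),
        spectral_rate_hz=sampling_rate_hz,
        cv=decode.CvScheme(n_folds=4, n_repeats=2, seed=seed),
        feature_step_s=0.2,
        calibration_duration_s=60.0,
        n_subjects=n_subjects,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Per-subject preprocessing
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    """Cleaned, epoched, channel-reduced data for one simulated subject."""

    amplitude: EpochSet  # 0.2-5 Hz at the amplitude classification rate
    mu: EpochSet  # 8-12 Hz at the spectral rate
    beta: EpochSet  # 15-32 Hz at the spectral rate
    n_rejected: int


def prepare_subject(config: AnalysisConfig, seed: Optional[int] = None) -> SubjectData:
    """Simulate one subject and run the full preprocessing chain."""
    effects = config.effects if seed is None else replace(config.effects, seed=seed)
    rec, _ = synthetic.generate_recording(config.paradigm, effects)
    calib = synthetic.generate_eye_calibration(
        config.paradigm, effects, duration_s=config.calibration_duration_s
    )

    # rejection mask from the separate 1-60 Hz path
    nyq_guard = 0.45 * rec.rate
    artifact_band = preprocess.FilterSpec(
        1.0, min(60.0, nyq_guard), preprocess.ARTIFACT_BAND.order
    )
    art = preprocess.epoch(preprocess.bandpass(rec, artifact_band), config.epoch_window_s)
    mask = preprocess.mark_artifacts(art, config.rejection_amp_uv, config.rejection_z)

    def branch(band: preprocess.FilterSpec, target_hz: float) -> EpochSet:
        model = preprocess.fit_eog_subspace(preprocess.bandpass(calib, band))
        clean = preprocess.apply_eog_subspace(model, preprocess.bandpass(rec, band))
        ep = preprocess.epoch(preprocess.resample(clean, target_hz), config.epoch_window_s)
        ep.reject_mask = mask.copy()
        return preprocess.select_channels(ep.retained(), list(config.channel_subset))

    amp = branch(preprocess.AMPLITUDE_BAND, config.amplitude_rate_hz)
    spectral = branch(preprocess.SPECTRAL_BAND, config.spectral_rate_hz)
    mu = preprocess.bandpass_epochs(spectral, preprocess.MU_BAND)
    beta = preprocess.bandpass_epochs(spectral, preprocess.BETA_BAND)
    return SubjectData(amplitude=amp, mu=mu, beta=beta, n_rejected=int(mask.sum()))


# ---------------------------------------------------------------------------
# Feature helpers
# ---------------------------------------------------------------------------


def _subset(ep: EpochSet, keep: np.ndarray) -> EpochSet:
    out = ep.copy()
    out.data = ep.data[keep]
    out.condition = ep.condition[keep]
    out.direction = ep.direction[keep]
    out.reject_mask = ep.reject_mask[keep]
    return out


def _bandpower_block(
    config: AnalysisConfig, ep: EpochSet, model: features.CSPModel, band: str
) -> features.BandPowerFeatureSet:
    return features.csp_logpower_features(
        ep,
        model,
        baseline_window_s=config.baseline_window_s,
        smooth_s=config.feature_window_s,
        band=band,
        step_s=config.feature_step_s,
    )


def _spectral_features(
    config: AnalysisConfig,
    mu: EpochSet,
    beta: EpochSet,
    labels: np.ndarray,
    csp_models: Optional[dict] = None,
) -> tuple[features.BandPowerFeatureSet, dict]:
    """Full-data CSP fit + band features (descriptive use: patterns only).

    Accuracy estimation never uses these — the CV paths refit CSP inside each
    training fold via the builder functions below.
    """
    models = {}
    blocks = []
    for band, ep in (("mu", mu), ("beta", beta)):
        if csp_models and band in csp_models:
            model = csp_models[band]
        else:
            model = features.fit_csp(
                ep, labels, config.csp_fit_window_s, config.k_per_class
            )
        models[band] = model
        blocks.append(_bandpower_block(config, ep, model, band))
    return features.combine_band_features(*blocks), models


def _spectral_sliding_builder(
    config: AnalysisConfig, mu: EpochSet, beta: EpochSet, labels: np.ndarray
):
    """Per-fold builder: CSP fit on training trials only, features for all."""
    labels = np.asarray(labels)

    def build(train: np.ndarray) -> np.ndarray:
        blocks = []
        for band, ep in (("mu", mu), ("beta", beta)):
            model = features.fit_csp(
                _subset(ep, np.asarray(train)),
                labels[train],
                config.csp_fit_window_s,
                config.k_per_class,
            )
            blocks.append(_bandpower_block(config, ep, model, band))
        return features.combine_band_features(*blocks).features

    return build


def _spectral_window_builder(config: AnalysisConfig, mu: EpochSet, beta: EpochSet):
    """Per-fold builder for MI-vs-baseline: window-CSP fit on training trials."""

    def build(train: np.ndarray) -> np.ndarray:
        blocks = []
        for band, ep in (("mu", mu), ("beta", beta)):
            model, _, _ = _window_csp(config, _subset(ep, np.asarray(train)))
            blocks.append(_bandpower_block(config, ep, model, band))
        return features.combine_band_features(*blocks).features

    return build


def _window_csp(
    config: AnalysisConfig, ep: EpochSet
) -> tuple[features.CSPModel, EpochSet, np.ndarray]:
    """CSP between the MI and baseline windows (pseudo-trials per window)."""
    mi_idx = ep.time_indices(config.mi_window_s)
    base_idx = ep.time_indices(config.baseline_window_s)
    n = min(len(mi_idx), len(base_idx))
    data = np.concatenate([ep.data[:, :, mi_idx[:n]], ep.data[:, :, base_idx[:n]]])
    labels = np.array(["MI"] * ep.n_trials + ["baseline"] * ep.n_trials)
    pseudo = EpochSet(
        data=data,
        times=np.arange(n) / ep.rate,
        condition=labels,
        direction=labels,
        reject_mask=np.zeros(2 * ep.n_trials, dtype=bool),
        rate=ep.rate,
        channel_labels=list(ep.channel_labels),
        channel_kinds=list(ep.channel_kinds),
    )
    model = features.fit_csp(pseudo, labels, (0.0, n / ep.rate), config.k_per_class)
    return model, pseudo, labels


def _amplitude_pattern(
    config: AnalysisConfig,
    feats: features.SlidingFeatureSet,
    labels: np.ndarray,
    window_s: tuple[float, float],
) -> patterns.ActivationPattern:
    """Activation pattern of an sLDA trained on window-averaged features."""
    sel = (feats.timepoints >= window_s[0] - 1e-9) & (feats.timepoints <= window_s[1] + 1e-9)
    if not np.any(sel):
        nearest = int(np.abs(feats.timepoints - np.mean(window_s)).argmin())
        sel = np.zeros(len(feats.timepoints), dtype=bool)
        sel[nearest] = True
    X = feats.features[:, sel, :].mean(axis=1)
    model = decode.fit_slda(X, labels)
    ch = sorted(set(c for c, _ in feats.feature_index), key=[c for c, _ in feats.feature_index].index)
    n_lags = len(feats.feature_index) // len(ch)
    return patterns.activation_pattern(
        model, X, window_s=window_s, channel_labels=ch, n_lags=n_lags
    )


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------


def _tc_report(tc: decode.AccuracyTimecourse) -> dict:
    return {
        "times_s": [float(t) for t in tc.times],
        "accuracy_pct": [float(a) for a in tc.accuracy_pct],
        "threshold_pct": float(tc.threshold_pct),
        "n_trials_effective": int(tc.n_trials_effective),
        "peak": {"time_s": float(tc.peak[0]), "accuracy_pct": float(tc.peak[1])},
    }


def _pattern_report(p: patterns.ActivationPattern) -> dict:
    return {
        "window_s": list(p.window_s) if p.window_s else None,
        "channel_labels": p.channel_labels,
        "channel_values": [float(v) for v in p.channel_values]
        if p.channel_values is not None
        else None,
        "collapse": p.collapse,
    }


def _power_diff_report(p: patterns.ChannelPowerDiff) -> dict:
    return {
        "band": p.band,
        "window_s": list(p.window_s),
        "channel_labels": p.channel_labels,
        "values": [float(v) for v in p.values],
        "classes": list(p.classes),
    }


# ---------------------------------------------------------------------------
# Analyses
# ---------------------------------------------------------------------------


def run_direction_analysis(config: AnalysisConfig) -> dict:
    """Right-vs-up decoding per condition, both feature families."""
    subject = prepare_subject(config, seed=config.seed + config.effects.seed)
    report: dict = {"analysis": "direction", "conditions": {}}
    for cond in CONDITIONS:
        entry: dict = {}
        if "amplitude" in config.families:
            amp = _subset(subject.amplitude, subject.amplitude.condition == cond)
            feats = features.sliding_amplitude_features(
                amp, config.feature_window_s, config.feature_step_s
            )
            tc = decode.sliding_accuracy(feats, amp.direction, config.cv, config.alpha)
            entry["amplitude"] = _tc_report(tc)
            entry["amplitude_patterns"] = [
                _pattern_report(_amplitude_pattern(config, feats, amp.direction, w))
                for w in config.direction_pattern_windows
            ]
        if "spectral" in config.families:
            mu = _subset(subject.mu, subject.mu.condition == cond)
            beta = _subset(subject.beta, subject.beta.condition == cond)
            tc_spec = decode.sliding_accuracy_refit(
                _spectral_sliding_builder(config, mu, beta, mu.direction),
                features.bandpower_timepoints(
                    mu, config.feature_window_s, config.feature_step_s
                ),
                mu.direction,
                config.cv,
                config.alpha,
            )
            entry["spectral"] = _tc_report(tc_spec)
        report["conditions"][cond] = entry
    return report


def _mi_vs_baseline_subject(config: AnalysisConfig, seed: int) -> dict:
    subject = prepare_subject(config, seed=seed)
    out = {}
    for cond in CONDITIONS:
        entry: dict = {}
        if "amplitude" in config.families:
            amp = _subset(subject.amplitude, subject.amplitude.condition == cond)
            feats = features.sliding_amplitude_features(
                amp, config.feature_window_s, config.feature_step_s
            )
            entry["amplitude"] = decode.fixed_window_accuracy(
                feats,
                None,
                config.mi_window_s,
                config.baseline_window_s,
                config.cv,
                config.alpha,
            )
        mu = _subset(subject.mu, subject.mu.condition == cond)
        beta = _subset(subject.beta, subject.beta.condition == cond)
        if "spectral" in config.families:
            entry["spectral"] = decode.fixed_window_accuracy_refit(
                _spectral_window_builder(config, mu, beta),
                features.bandpower_timepoints(
                    mu, config.feature_window_s, config.feature_step_s
                ),
                mu.n_trials,
                config.mi_window_s,
                config.baseline_window_s,
                config.cv,
                config.alpha,
            )
        entry["epochs"] = (mu, beta)
        out[cond] = entry
    return out


def run_mi_vs_baseline(config: AnalysisConfig) -> dict:
    """MI-vs-baseline accuracies per condition and family, across subjects."""
    rng = np.random.default_rng(config.seed)
    fams = tuple(f for f in ("amplitude", "spectral") if f in config.families)
    accs = {cond: {fam: [] for fam in fams} for cond in CONDITIONS}
    thresholds = {}
    pattern_reports = None
    for i in range(config.n_subjects):
        seed = int(rng.integers(0, 2**31 - 1))
        per_cond = _mi_vs_baseline_subject(config, seed)
        for cond in CONDITIONS:
            for fam in fams:
                accs[cond][fam].append(float(per_cond[cond][fam].accuracy_pct[0]))
                thresholds[(cond, fam)] = float(per_cond[cond][fam].threshold_pct)
        if pattern_reports is None and "spectral" in fams:
            # back-projections from the first subject
            pattern_reports = {}
            for cond in CONDITIONS:
                mu, beta = per_cond[cond]["epochs"]
                diffs = []
                for band, ep in (("mu", mu), ("beta", beta)):
                    model, pseudo, labels = _window_csp(config, ep)
                    n = len(pseudo.times)
                    diffs.append(
                        _power_diff_report(
                            patterns.csp_channel_power_diff(
                                model,
                                pseudo,
                                labels,
                                (0.0, n / pseudo.rate),
                                (0.0, n / pseudo.rate),
                                band=band,
                            )
                        )
                    )
                pattern_reports[cond] = diffs
    report: dict = {"analysis": "mi-vs-baseline", "conditions": {}, "wilcoxon": {}}
    for cond in CONDITIONS:
        report["conditions"][cond] = {
            fam: {
                "accuracies_pct": accs[cond][fam],
                "mean_accuracy_pct": float(np.mean(accs[cond][fam])),
                "threshold_pct": thresholds[(cond, fam)],
            }
            for fam in fams
        }
    for fam in fams:
        a, b = accs["VtG"][fam], accs["noVtG"][fam]
        try:
            res = stats.wilcoxon_signed_rank(a, b)
            report["wilcoxon"][fam] = {
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n_pairs": res.n_pairs,
            }
        except ValueError as e:
            report["wilcoxon"][fam] = {"error": str(e)}
    report["csp_power_patterns"] = pattern_reports
    return report


def run_condition_analysis(config: AnalysisConfig) -> dict:
    """VtG-vs-noVtG decoding over the whole trial, both feature families."""
    subject = prepare_subject(config, seed=config.seed + config.effects.seed)
    report: dict = {"analysis": "condition"}
    if "amplitude" in config.families:
        amp = subject.amplitude
        feats = features.sliding_amplitude_features(
            amp, config.feature_window_s, config.feature_step_s
        )
        tc_amp = decode.sliding_accuracy(feats, amp.condition, config.cv, config.alpha)
        report["amplitude"] = _tc_report(tc_amp)
        report["amplitude_patterns"] = [
            _pattern_report(_amplitude_pattern(config, feats, amp.condition, w))
            for w in config.condition_pattern_windows
        ]
    if "spectral" in config.families:
        _, models = _spectral_features(
            config, subject.mu, subject.beta, subject.mu.condition
        )
        tc_spec = decode.sliding_accuracy_refit(
            _spectral_sliding_builder(
                config, subject.mu, subject.beta, subject.mu.condition
            ),
            features.bandpower_timepoints(
                subject.mu, config.feature_window_s, config.feature_step_s
            ),
            subject.mu.condition,
            config.cv,
            config.alpha,
        )
        report["spectral"] = _tc_report(tc_spec)
        power_patterns = []
        for band, ep in (("mu", subject.mu), ("beta", subject.beta)):
            for w in config.condition_pattern_windows:
                power_patterns.append(
                    _power_diff_report(
                        patterns.csp_channel_power_diff(
                            models[band],
                            ep,
                            ep.condition,
                            w,
                            config.baseline_window_s,
                            band=band,
                        )
                    )
                )
        report["csp_power_patterns"] = power_patterns
    return report


def run_all(config: AnalysisConfig) -> dict:
    return {
        "direction": run_direction_analysis(config),
        "mi_vs_baseline": run_mi_vs_baseline(config),
        "condition": run_condition_analysis(config),
    }
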