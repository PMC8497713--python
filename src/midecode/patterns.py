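"""Interpretability back-projections into channel space.

A linear backward model (classifier weights) is not directly interpretable as
a scalp topography; the corresponding forward model (activation pattern) is.
For the amplitude-feature sLDA we compute

    a = Σx (Σx + λI)⁻¹ (μ₁ − μ₂) · Var{s},    s = wᵀx,

with Σx the pooled covariance of the training features, λ the model's
shrinkage coefficient and s the projected (source) estimate. For CSP features
the spatially filtered components F = M x are projected back with the
pseudo-inverse, F_ch = M⁺ F, and the per-class baseline-relative channel log
power difference P = P₁ − P₂ is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .containers import EpochSet
from .decode import ShrinkageLDAModel
from .features import CSPModel


@dataclass
class ActivationPattern:
    """Forward-model pattern for a linear classifier.

    ``values`` has the dimensionality of the classifier features;
    ``channel_values`` collapses the lag dimension per channel (rule
    configurable: rms | mean | max-abs) when the feature index is structured
    as (channel, lag).
    """

    values: np.ndarray
    window_s: Optional[tuple[float, float]]
    channel_labels: Optional[list[str]] = None
    channel_values: Optional[np.ndarray] = None
    collapse: str = "rms"


_COLLAPSE = {
    "rms": lambda a: np.sqrt(np.mean(a**2, axis=1)),
    "mean": lambda a: a.mean(axis=1),
    "max-abs": lambda a: a[np.arange(a.shape[0]), np.argmax(np.abs(a), axis=1)],
}


def activation_pattern(
    model: ShrinkageLDAModel,
    X: np.ndarray,
    window_s: Optional[tuple[float, float]] = None,
    channel_labels: Optional[list[str]] = None,
    n_lags: Optional[int] = None,
    collapse: str = "rms",
) -> ActivationPattern:
    """Haufe-style activation pattern of a fitted sLDA on its training data.

    ``X`` must be the (samples x features) training matrix. When
    ``channel_labels``/``n_lags`` describe the feature layout (channel-major,
    lag-minor), a per-channel display value is produced by the chosen
    lag-collapsing rule.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != len(model.weights):
        raise ValueError("feature dimension does not match the model")
    xc = X - X.mean(axis=0)
    sigma = (xc.T @ xc) / len(X)
    s = X @ model.weights
    var_s = float(np.var(s))
    diff = model.class_means[0] - model.class_means[1]
    lam = model.shrinkage
    a = sigma @ np.linalg.solve(sigma + lam * np.eye(sigma.shape[0]), diff) * var_s
    channel_values = None
    if channel_labels is not None and n_lags is not None:
        if len(a) != len(channel_labels) * n_lags:
            raise ValueError("feature count != n_channels * n_lags")
        channel_values = _COLLAPSE[collapse](a.reshape(len(channel_labels), n_lags))
    return ActivationPattern(
        values=a,
        window_s=window_s,
        channel_labels=channel_labels,
        channel_values=channel_values,
        collapse=collapse,
    )


@dataclass
class ChannelPowerDiff:
    """Per-channel class difference of baseline-relative log power."""

    values: np.ndarray
    band: str
    window_s: tuple[float, float]
    channel_labels: list[str]
    classes: tuple[str, str]


def csp_channel_power_diff(
    model: CSPModel,
    epochs_band: EpochSet,
    labels: np.ndarray,
    window_s: tuple[float, float],
    baseline_window_s: tuple[float, float] = (-3.5, -2.5),
    band: str = "",
) -> ChannelPowerDiff:
    """Class difference of channel power after a CSP round trip.

    The selected components F = M_sel x are projected back through the
    matching columns of the pseudo-inverse, F_ch = M⁺_sel F; per class the
    mean channel power in ``window_s`` is expressed relative to the pooled
    (class-independent) baseline power in ``baseline_window_s`` as a log
    ratio, and P = P₁ − P₂ returned — the shared reference cancels in the
    difference, which is therefore antisymmetric under a class swap. With all
    filters selected M⁺M = I, so F_ch reproduces x and P reduces to the
    direct channel power difference.
    """
    if list(epochs_band.channel_labels) != list(model.channel_labels):
        raise ValueError("epochs channel set differs from the CSP model's")
    labels = np.asarray(labels)
    win = epochs_band.time_indices(window_s)
    base = epochs_band.time_indices(baseline_window_s)
    m_sel = model.filters[model.selected]
    back = model.patterns[:, model.selected]
    f_all = np.einsum("fc,tcs->tfs", m_sel, epochs_band.data)
    f_ch_all = np.einsum("cf,tfs->tcs", back, f_all)
    p_base = (f_ch_all[:, :, base] ** 2).mean(axis=(0, 2))
    if np.any(p_base <= 0):
        raise ValueError("zero baseline power in channel back-projection")
    per_class = []
    for cls in model.classes:
        sel = labels == cls
        if not np.any(sel):
            raise ValueError(f"no trials of class {cls!r}")
        p_win = (f_ch_all[sel][:, :, win] ** 2).mean(axis=(0, 2))
        per_class.append(np.log(p_win / p_base))
    return ChannelPowerDiff(
        values=per_class[0] - per_class[1],
        band=band,
        window_s=window_s,
        channel_labels=list(epochs_band.channel_labels),
        classes=model.classes,
    )
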