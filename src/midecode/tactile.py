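"""Vibrotactile moving-stimulus amplitude mapping.

A virtual stimulus travelling between two tactors T₁ and T₂ is rendered by
amplitude modulation: the perceived location is x_v = A₂²/(A₁² + A₂²), 0 at
T₁ and 1 at T₂. The inverse adopts a constant-energy normalization
(A₁² + A₂² = const), which makes the mapping invertible and keeps the total
delivered power constant along a sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TactorPairState:
    a1: float
    a2: float

    @property
    def x_v(self) -> float:
        return virtual_position(self.a1, self.a2)


def virtual_position(a1: float, a2: float) -> float:
    """Location of the virtual stimulus in [0, 1] for amplitudes (a1, a2)."""
    denom = a1 * a1 + a2 * a2
    if denom <= 0:
        raise ValueError("virtual position undefined: both amplitudes are zero")
    return a2 * a2 / denom


def amplitudes_for_position(x_v: float, energy: float = 1.0) -> tuple[float, float]:
    """Amplitudes rendering position ``x_v`` at total squared amplitude ``energy``."""
    if not 0.0 <= x_v <= 1.0:
        raise ValueError("x_v must lie in [0, 1]")
    if energy <= 0:
        raise ValueError("energy must be positive")
    return float(np.sqrt((1.0 - x_v) * energy)), float(np.sqrt(x_v * energy))


def sweep_schedule(
    duration_s: float,
    rate_hz: float,
    gains: tuple[float, float] = (1.0, 1.0),
    energy: float = 1.0,
) -> np.ndarray:
    """Amplitude schedule for a constant-speed sweep from T₁ to T₂.

    Returns an array of rows (time_s, a1, a2) where the *commanded* position
    moves 0 → 1 linearly; per-tactor calibration gains scale the output
    amplitudes after the mapping (they model hardware sensitivity-equalization
    and do not alter the commanded position).
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration and rate must be positive")
    if min(gains) < 0:
        raise ValueError("calibration gains must be non-negative")
    n = int(round(duration_s * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    x = t / duration_s
    out = np.empty((n, 3))
    out[:, 0] = t
    for i, xv in enumerate(x):
        a1, a2 = amplitudes_for_position(float(min(xv, 1.0)), energy)
        out[i, 1] = gains[0] * a1
        out[i, 2] = gains[1] * a2
    return out
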