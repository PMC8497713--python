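"""Shared data containers and the electrode montage.

The recording unit is a channels x samples array in microvolts with a marker
table; epochs are trials x channels x samples tensors aligned to the
cue-movement onset. Both carry their channel labels and sampling rate so that
every downstream stage can validate its inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

# ---------------------------------------------------------------------------
# Montage: 61 EEG channels on the international 10/10 grid plus 3 EOG channels
# (vertical, left horizontal, right horizontal).
# ---------------------------------------------------------------------------

EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

EOG_CHANNELS: tuple[str, ...] = ("EOGV", "EOGL", "EOGR")

ALL_CHANNELS: tuple[str, ...] = EEG_CHANNELS + EOG_CHANNELS

#: Default frontocentral-to-parietal classification subset (31 channels):
#: the FC, C, CP and P rows from 5 to 6 (7 channels each) plus PO3/POz/PO4.
#: The montage rows cover the sensorimotor strip; the exact subset is a
#: documented package default and overridable everywhere it is used.
CLASSIFICATION_CHANNELS: tuple[str, ...] = (
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P5", "P3", "P1", "Pz", "P2", "P4", "P6",
    "PO3", "POz", "PO4",
)

# Marker codes. Movement-onset codes encode (condition, direction).
MARKER_FIXATION = 10
MARKER_CUE = 20
MOVEMENT_ONSET_CODES: dict[tuple[str, str], int] = {
    ("VtG", "right"): 31,
    ("VtG", "up"): 32,
    ("noVtG", "right"): 33,
    ("noVtG", "up"): 34,
}
CODE_TO_CONDITION_DIRECTION = {v: k for k, v in MOVEMENT_ONSET_CODES.items()}
MARKER_BLINK = 91
MARKER_SACCADE = 92

CONDITIONS = ("VtG", "noVtG")
DIRECTIONS = ("right", "up")


def channel_positions(labels=EEG_CHANNELS) -> np.ndarray:
    """3D scalp positions (meters) for the given 10/10 labels.

    Positions come from mne's standard 10/05 montage; EOG channels are not
    scalp electrodes and are placed at fixed periocular coordinates.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    eog_pos = {
        "EOGV": np.array([0.0, 0.11, 0.0]),
        "EOGL": np.array([-0.06, 0.10, -0.01]),
        "EOGR": np.array([0.06, 0.10, -0.01]),
    }
    out = np.empty((len(labels), 3))
    for i, lab in enumerate(labels):
        out[i] = eog_pos[lab] if lab in eog_pos else pos[lab]
    return out


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ContinuousRecording:
    """Continuous multichannel recording in microvolts.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_samples)
    channel_labels : list of str
    channel_kinds : list of {"EEG", "EOG"}
    rate : float
        Sampling rate in Hz.
    events : ndarray, shape (n_events, 2)
        Columns (sample_index, code).
    """

    samples: np.ndarray
    channel_labels: list[str]
    channel_kinds: list[str]
    rate: float
    events: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.events = np.asarray(self.events, dtype=np.int64).reshape(-1, 2)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if len(self.channel_kinds) != len(self.channel_labels):
            raise ValueError("one kind per channel required")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.events.size and (
            self.events[:, 0].min() < 0 or self.events[:, 0].max() >= self.samples.shape[1]
        ):
            raise ValueError("event sample indices out of bounds")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def eeg_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.channel_kinds) if k == "EEG"])

    def eog_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.channel_kinds) if k == "EOG"])

    def copy(self) -> "ContinuousRecording":
        return replace(
            self,
            samples=self.samples.copy(),
            channel_labels=list(self.channel_labels),
            channel_kinds=list(self.channel_kinds),
            events=self.events.copy(),
        )


@dataclass
class EpochSet:
    """Trials x channels x time tensor aligned to the cue-movement onset."""

    data: np.ndarray
    times: np.ndarray
    condition: np.ndarray
    direction: np.ndarray
    reject_mask: np.ndarray
    rate: float
    channel_labels: list[str]
    channel_kinds: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.condition = np.asarray(self.condition)
        self.direction = np.asarray(self.direction)
        self.reject_mask = np.asarray(self.reject_mask, dtype=bool)
        n = self.data.shape[0] if self.data.ndim == 3 else 0
        for arr, name in (
            (self.condition, "condition"),
            (self.direction, "direction"),
            (self.reject_mask, "reject_mask"),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} must have one entry per trial")
        if self.data.ndim == 3 and self.data.shape[2] != len(self.times):
            raise ValueError("times must match the time axis")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.rate, rtol=1e-6):
                raise ValueError("times must increase uniformly at 1/rate")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def eeg_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.channel_kinds) if k == "EEG"])

    def retained(self) -> "EpochSet":
        """Drop trials flagged in ``reject_mask``."""
        keep = ~self.reject_mask
        return EpochSet(
            data=self.data[keep],
            times=self.times.copy(),
            condition=self.condition[keep],
            direction=self.direction[keep],
            reject_mask=np.zeros(int(keep.sum()), dtype=bool),
            rate=self.rate,
            channel_labels=list(self.channel_labels),
            channel_kinds=list(self.channel_kinds),
        )

    def time_indices(self, window_s: tuple[float, float]) -> np.ndarray:
        """Sample indices whose times fall inside [start, end)."""
        start, end = window_s
        if start >= end:
            raise ValueError("window start must precede end")
        idx = np.nonzero((self.times >= start - 1e-9) & (self.times < end - 1e-9))[0]
        if idx.size == 0:
            raise ValueError(f"window {window_s} outside epoch times")
        return idx

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times=self.times.copy(),
            condition=self.condition.copy(),
            direction=self.direction.copy(),
            reject_mask=self.reject_mask.copy(),
            rate=self.rate,
            channel_labels=list(self.channel_labels),
            channel_kinds=list(self.channel_kinds),
        )
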