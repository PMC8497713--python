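"""HDF5 persistence for recordings and epoch sets, and YAML configuration.

The container layout is deliberately flat: ``samples``/``data`` in float64
microvolts, string datasets for labels and kinds, an ``events`` table of
(sample_index, code), and scalar attributes for the rate. Config files mirror
the dataclass fields of the paradigm/effect/analysis specifications.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path
from typing import Union

import h5py
import numpy as np
import pandas as pd
import yaml

from . import decode, pipeline, synthetic
from .containers import ContinuousRecording, EpochSet


def save_recording(path: Union[str, Path], rec: ContinuousRecording) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "recording"
        f.attrs["rate"] = rec.rate
        f.create_dataset("samples", data=rec.samples, compression="gzip")
        f.create_dataset("channel_labels", data=np.array(rec.channel_labels, dtype="S"))
        f.create_dataset("channel_kinds", data=np.array(rec.channel_kinds, dtype="S"))
        f.create_dataset("events", data=rec.events)


def load_recording(path: Union[str, Path]) -> ContinuousRecording:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "recording":
            raise ValueError(f"{path} is not a recording container")
        return ContinuousRecording(
            samples=f["samples"][()],
            channel_labels=[s.decode() for s in f["channel_labels"][()]],
            channel_kinds=[s.decode() for s in f["channel_kinds"][()]],
            rate=float(f.attrs["rate"]),
            events=f["events"][()],
        )


def save_epochs(path: Union[str, Path], ep: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "epochs"
        f.attrs["rate"] = ep.rate
        f.create_dataset("data", data=ep.data, compression="gzip")
        f.create_dataset("times", data=ep.times)
        f.create_dataset("condition", data=ep.condition.astype("S"))
        f.create_dataset("direction", data=ep.direction.astype("S"))
        f.create_dataset("reject_mask", data=ep.reject_mask)
        f.create_dataset("channel_labels", data=np.array(ep.channel_labels, dtype="S"))
        f.create_dataset("channel_kinds", data=np.array(ep.channel_kinds, dtype="S"))


def load_epochs(path: Union[str, Path]) -> EpochSet:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "epochs":
            raise ValueError(f"{path} is not an epochs container")
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            condition=np.array([s.decode() for s in f["condition"][()]]),
            direction=np.array([s.decode() for s in f["direction"][()]]),
            reject_mask=f["reject_mask"][()],
            rate=float(f.attrs["rate"]),
            channel_labels=[s.decode() for s in f["channel_labels"][()]],
            channel_kinds=[s.decode() for s in f["channel_kinds"][()]],
        )


def save_ground_truth(path: Union[str, Path], gt: synthetic.GroundTruth) -> None:
    gt.trials.to_csv(path, index=False)


def load_trial_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Declarative configuration
# ---------------------------------------------------------------------------

_TUPLE_FIELDS = {
    "baseline_window_s",
    "epoch_window_s",
    "mi_window_s",
    "csp_fit_window_s",
    "channel_subset",
    "direction_pattern_windows",
    "condition_pattern_windows",
}


def _build(cls, mapping: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in mapping.items():
        if k in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(tuple(w) if isinstance(w, list) else w for w in v)
        kwargs[k] = v
    return cls(**kwargs)


def config_from_mapping(mapping: dict) -> pipeline.AnalysisConfig:
    """Build an AnalysisConfig from a nested plain mapping (YAML-friendly)."""
    mapping = dict(mapping)
    parts = {}
    if "paradigm" in mapping:
        parts["paradigm"] = _build(synthetic.ParadigmSpec, mapping.pop("paradigm"))
    if "effects" in mapping:
        parts["effects"] = _build(synthetic.EffectSpec, mapping.pop("effects"))
    if "cv" in mapping:
        parts["cv"] = _build(decode.CvScheme, mapping.pop("cv"))
    return _build(pipeline.AnalysisConfig, {**mapping, **parts})


def load_config(path: Union[str, Path]) -> pipeline.AnalysisConfig:
    with open(path) as f:
        mapping = yaml.safe_load(f) or {}
    return config_from_mapping(mapping)
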