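"""File formats: epochs HDF5 schema, ROI-course CSV, JSON results, YAML config.

The epochs HDF5 layout is: datasets ``/data`` (trials x channels x time,
float), ``/times``, ``/condition_labels`` and ``/channel_types`` (string
arrays); attributes ``sfreq``, ``subject``, ``session`` and optionally
``group``.  Round-trips are lossless.  A standard FIF epochs file can
optionally be imported through MNE, mapping its channel types and event
names onto the same schema.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .rejection import EpochsSet

__all__ = [
    "read_epochs",
    "write_epochs",
    "read_epochs_fif",
    "write_courses_csv",
    "read_courses_csv",
    "write_json",
    "StudyConfig",
]

_REQUIRED_DATASETS = ("data", "times", "condition_labels", "channel_types")
_REQUIRED_ATTRS = ("sfreq", "subject", "session")


def write_epochs(epochs: EpochsSet, path) -> None:
    """Write one EpochsSet to the HDF5 layout."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        str_dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset(
            "condition_labels",
            data=[str(s) for s in epochs.condition_labels], dtype=str_dt,
        )
        f.create_dataset(
            "channel_types",
            data=[str(s) for s in epochs.channel_types], dtype=str_dt,
        )
        f.attrs["sfreq"] = float(epochs.sfreq)
        f.attrs["subject"] = epochs.subject_id
        f.attrs["session"] = epochs.session
        f.attrs["group"] = epochs.group


def read_epochs(path) -> EpochsSet:
    """Read an EpochsSet from the HDF5 layout; schema errors name the field."""
    with h5py.File(path, "r") as f:
        for ds in _REQUIRED_DATASETS:
            if ds not in f:
                raise ValueError(f"epochs file {path} is missing dataset /{ds}")
        for attr in _REQUIRED_ATTRS:
            if attr not in f.attrs:
                raise ValueError(f"epochs file {path} is missing attribute {attr!r}")
        return EpochsSet(
            subject_id=str(f.attrs["subject"]),
            session=str(f.attrs["session"]),
            group=str(f.attrs.get("group", "")),
            data=f["data"][()],
            condition_labels=np.array([s.decode() if isinstance(s, bytes) else str(s)
                                       for s in f["condition_labels"][()]]),
            channel_types=np.array([s.decode() if isinstance(s, bytes) else str(s)
                                    for s in f["channel_types"][()]]),
            times=f["times"][()],
            sfreq=float(f.attrs["sfreq"]),
        )


def read_epochs_fif(path, subject_id: str, session: str, group: str = "") -> EpochsSet:
    """Import a standard FIF epochs file (requires mne).

    Channel types come from the measurement info (``grad`` / ``mag``; other
    types are dropped) and per-trial condition labels from the event names.
    """
    import mne  # optional dependency, imported lazily

    ep = mne.read_epochs(path, preload=True, verbose="error")
    ch_types = np.array(ep.get_channel_types())
    keep = np.isin(ch_types, ("grad", "mag"))
    data = ep.get_data(copy=True)[:, keep, :]
    inv_event_id = {v: k for k, v in ep.event_id.items()}
    labels = np.array([inv_event_id[e] for e in ep.events[:, 2]])
    return EpochsSet(
        subject_id=subject_id,
        session=session,
        group=group,
        data=data,
        condition_labels=labels,
        channel_types=ch_types[keep],
        times=ep.times.copy(),
        sfreq=float(ep.info["sfreq"]),
    )


def write_courses_csv(courses: pd.DataFrame, path) -> None:
    courses.to_csv(path, index=False)


def read_courses_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj: dict, path) -> str:
    """Deterministic JSON: sorted keys, repr floats (17 significant digits).

    Returns the serialized text (also written to ``path`` if given).
    """
    text = json.dumps(obj, indent=2, sort_keys=True, default=_json_default,
                      allow_nan=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def config_hash(obj) -> str:
    """Stable hash of a configuration object for provenance stamps."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    canon = json.dumps(obj, sort_keys=True, default=_json_default)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclasses.dataclass
class StudyConfig:
    """End-to-end pipeline configuration.

    With ``epochs_paths`` empty the study is synthetic: the generator is run
    with ``simulation`` keyword overrides and the planted Words effect size.
    """

    epochs_paths: list[str] = dataclasses.field(default_factory=list)
    simulation: dict = dataclasses.field(default_factory=dict)
    effect_size: float = 0.0
    grid_points: int = 4
    window_mode: str = "auto"  # "auto" or "START:END" in seconds
    n_permutations: int = 1024
    cluster_tmin: float = 0.0
    cluster_tmax: float = 0.5
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))
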