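"""Containers and I/O for trial sets and feature matrices; configuration.

The native on-disk trial format is a flat text matrix of 64-bit floats
(one row per trial-channel, trial-major / channel-minor, ``%.17g`` so
round-trips are bit-exact) plus a JSON sidecar carrying sampling rate,
shape, labels, subjects and channel names.  EDF recordings are read
through MNE, with trial onsets supplied by the sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrialSet",
    "FeatureMatrix",
    "TrialSetFormatError",
    "ShapeMismatchError",
    "InvalidDataError",
    "UnsupportedFormatError",
    "load_trialset",
    "save_trialset",
    "save_features",
    "load_features",
    "group_triples",
    "load_config",
]


class TrialSetFormatError(ValueError):
    """Base class for trial-set I/O problems."""


class ShapeMismatchError(TrialSetFormatError):
    """Sidecar metadata disagrees with the data matrix shape."""


class InvalidDataError(TrialSetFormatError):
    """Non-finite values or inconsistent metadata lengths."""


class UnsupportedFormatError(TrialSetFormatError):
    """The data file extension is not a supported format."""


@dataclass
class TrialSet:
    """Labeled multichannel trials: (trials, channels, samples) at ``fs`` Hz."""

    data: np.ndarray
    fs: float
    labels: np.ndarray
    subjects: np.ndarray
    channel_names: list[str]
    trial_onset: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subjects = np.asarray(self.subjects)
        if self.data.ndim != 3:
            raise ShapeMismatchError("data must be (trials, channels, samples)")
        n_trials, n_channels, _ = self.data.shape
        if len(self.labels) != n_trials or len(self.subjects) != n_trials:
            raise InvalidDataError("labels/subjects length must equal n_trials")
        if len(self.channel_names) != n_channels:
            raise ShapeMismatchError("channel_names length must equal n_channels")
        if self.fs <= 0:
            raise InvalidDataError("fs must be positive")
        if not np.isfinite(self.data).all():
            raise InvalidDataError("data contains NaN or Inf")
        if self.trial_onset is None:
            self.trial_onset = np.zeros(n_trials)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def subject_subset(self, subject) -> "TrialSet":
        """Trials of one subject (or of an iterable of subjects)."""
        wanted = np.atleast_1d(subject)
        mask = np.isin(self.subjects, wanted)
        return TrialSet(
            data=self.data[mask],
            fs=self.fs,
            labels=self.labels[mask],
            subjects=self.subjects[mask],
            channel_names=list(self.channel_names),
            trial_onset=self.trial_onset[mask],
        )


@dataclass
class FeatureMatrix:
    """Per-trial feature vectors with provenance-encoding names."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    subjects: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subjects = np.asarray(self.subjects)
        if self.values.ndim != 2:
            raise ValueError("values must be (trials, features)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must equal n_features")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must equal n_trials")


def save_trialset(ts: TrialSet, data_path, meta_path) -> None:
    """Write the flat text matrix and its JSON sidecar."""
    flat = ts.data.reshape(ts.n_trials * ts.n_channels, ts.n_samples)
    np.savetxt(data_path, flat, fmt="%.17g")
    meta = {
        "format": "ddadecode-trialset-v1",
        "ordering": "trial-major, channel-minor; one row per trial-channel",
        "fs": ts.fs,
        "n_trials": ts.n_trials,
        "n_channels": ts.n_channels,
        "n_samples": ts.n_samples,
        "labels": [str(x) for x in ts.labels],
        "subjects": [str(x) for x in ts.subjects],
        "channel_names": list(ts.channel_names),
        "trial_onset": list(map(float, ts.trial_onset)),
    }
    Path(meta_path).write_text(json.dumps(meta, indent=1))


def _load_edf(data_path, meta: dict) -> TrialSet:
    import mne

    raw = mne.io.read_raw_edf(data_path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    sig = raw.get_data()
    onsets = meta.get("trial_onset")
    if onsets is None:
        raise InvalidDataError("EDF loading requires trial_onset (seconds) in the sidecar")
    trial_samples = int(round(float(meta["trial_len"]) * fs))
    trials = []
    for onset in onsets:
        start = int(round(float(onset) * fs))
        stop = start + trial_samples
        if stop > sig.shape[1]:
            raise ShapeMismatchError("trial extends past the end of the recording")
        trials.append(sig[:, start:stop])
    return TrialSet(
        data=np.stack(trials),
        fs=fs,
        labels=np.asarray(meta["labels"]),
        subjects=np.asarray(meta["subjects"]),
        channel_names=list(raw.ch_names),
        trial_onset=np.asarray(onsets, dtype=float),
    )


def load_trialset(data_path, meta_path) -> TrialSet:
    """Read a trial set from EDF or the native matrix+sidecar format.

    Raises :class:`ShapeMismatchError`, :class:`InvalidDataError` or
    :class:`UnsupportedFormatError` for the respective defects.
    """
    meta = json.loads(Path(meta_path).read_text())
    suffix = Path(data_path).suffix.lower()
    if suffix == ".edf":
        return _load_edf(data_path, meta)
    if suffix not in (".txt", ".dat", ".mat.txt", ".tsv", ""):
        raise UnsupportedFormatError(f"unsupported data format {suffix!r}")
    flat = np.loadtxt(data_path, ndmin=2)
    n_trials = int(meta["n_trials"])
    n_channels = int(meta["n_channels"])
    n_samples = int(meta["n_samples"])
    if flat.shape != (n_trials * n_channels, n_samples):
        raise ShapeMismatchError(
            f"matrix is {flat.shape}, sidecar declares "
            f"({n_trials * n_channels}, {n_samples})"
        )
    if not np.isfinite(flat).all():
        raise InvalidDataError("data contains NaN or Inf")
    return TrialSet(
        data=flat.reshape(n_trials, n_channels, n_samples),
        fs=float(meta["fs"]),
        labels=np.asarray(meta["labels"]),
        subjects=np.asarray(meta["subjects"]),
        channel_names=list(meta["channel_names"]),
        trial_onset=np.asarray(meta.get("trial_onset", np.zeros(n_trials)), dtype=float),
    )


def save_features(fm: FeatureMatrix, path) -> None:
    """Delimited table: one row per trial, columns = features + label + subject."""
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    df["label"] = fm.labels
    df["subject"] = fm.subjects
    df.to_csv(path, index=False, float_format="%.17g")


def load_features(path) -> FeatureMatrix:
    df = pd.read_csv(path, float_precision="round_trip")
    names = [c for c in df.columns if c not in ("label", "subject")]
    return FeatureMatrix(
        values=df[names].to_numpy(dtype=float) if len(df) else np.empty((0, len(names))),
        feature_names=names,
        labels=df["label"].to_numpy(),
        subjects=df["subject"].to_numpy(),
    )


def group_triples(channel_names: list[str], montage_spec="sequential") -> list[tuple[int, int, int]]:
    """Group channels into triples for joint (cross-channel) model fits.

    ``"sequential"`` yields ``floor(n/3)`` disjoint consecutive triples in
    channel order — e.g. the 6-channel F3,F4,C3,C4,P3,P4 montage gives two
    triples.  An explicit list of triples (by index or by name) is validated
    and returned verbatim, which is how montage-specific groupings such as
    a 20-triple layout over 64 channels are supplied.
    """
    n = len(channel_names)
    if n < 3:
        raise ValueError("need at least 3 channels to form a triple")
    if isinstance(montage_spec, str):
        if montage_spec != "sequential":
            raise ValueError(f"unknown montage spec {montage_spec!r}")
        return [(3 * i, 3 * i + 1, 3 * i + 2) for i in range(n // 3)]
    triples = []
    name_idx = {name: i for i, name in enumerate(channel_names)}
    for trip in montage_spec:
        if len(trip) != 3:
            raise ValueError("each triple must have exactly 3 channels")
        idx = tuple(name_idx[t] if isinstance(t, str) else int(t) for t in trip)
        if any(i < 0 or i >= n for i in idx):
            raise ValueError(f"triple {trip} out of channel range")
        triples.append(idx)
    return triples


def load_config(path) -> dict:
    """Pipeline configuration from a YAML file (empty file -> empty dict)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
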