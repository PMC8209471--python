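"""Epoched-EEG container, channel montage, and on-disk round-tripping.

An :class:`EpochSet` holds one subject's trial ensemble as a
``channels x samples x trials`` float array together with the sampling
rate, the sample index of stimulus onset, a channel montage and a group
label.  Sample ``i`` maps to time ``(i - onset_index) / fs`` seconds and
every time window downstream is half-open, ``t0 <= t < t1``.

On disk a set is a pair of files sharing a stem: ``<stem>.json`` holds
the metadata (UTF-8 JSON) and ``<stem>.dat`` the raw payload as
little-endian float64 in channel-major (C) order.  The layout is
deliberately toolbox-neutral and auditable with a hex dump.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._exceptions import FormatError, IntegrityError, ValidationError

#: The 20-channel montage used throughout: frontal, temporal, central,
#: parietal and occipital electrodes of the 10-20 system.
DEFAULT_CHANNELS = (
    "FP1", "FP2", "Fz", "F3", "F4", "F7", "T7", "T8", "C3", "C4",
    "Cz", "Pz", "P4", "P3", "F8", "P8", "P7", "Oz", "O2", "O1",
)

_META_KEYS = ("fs", "onset_index", "labels", "subject_id", "group", "shape")


@dataclass(frozen=True)
class ChannelMontage:
    """Ordered, unique channel labels. Order is significant everywhere."""

    labels: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if not labels:
            raise ValidationError("montage has no channels")
        if any(not isinstance(l, str) or not l for l in labels):
            raise ValidationError("channel labels must be non-empty strings")
        if len(set(labels)) != len(labels):
            raise ValidationError("channel labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None


@dataclass
class EpochSet:
    """One subject's epoched trials: ``channels x samples x trials``."""

    data: np.ndarray
    fs: float
    onset_index: int
    montage: ChannelMontage = field(default_factory=ChannelMontage)
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(
                f"data must be channels x samples x trials, got ndim={self.data.ndim}"
            )
        if not np.isfinite(self.data).all():
            raise ValidationError("data contains non-finite values")
        n_ch, n_samp, n_tr = self.data.shape
        if n_ch != len(self.montage):
            raise ValidationError(
                f"{n_ch} channel rows but montage has {len(self.montage)} labels"
            )
        if n_tr < 1:
            raise ValidationError("at least one trial required")
        if not (0 <= int(self.onset_index) < n_samp):
            raise ValidationError(
                f"onset_index {self.onset_index} outside [0, {n_samp})"
            )
        self.onset_index = int(self.onset_index)
        self.fs = float(self.fs)
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def times(self) -> np.ndarray:
        """Time axis in seconds; onset sample is t = 0."""
        return (np.arange(self.n_samples) - self.onset_index) / self.fs

    def window_indices(self, window: tuple[float, float]) -> np.ndarray:
        """Sample indices with ``t0 <= (i - onset)/fs < t1`` (half-open)."""
        t0, t1 = window
        if not t1 > t0:
            raise ValidationError(f"empty window {window}")
        i0 = int(np.ceil(t0 * self.fs)) + self.onset_index
        i1 = int(np.ceil(t1 * self.fs)) + self.onset_index  # exclusive
        i0, i1 = max(i0, 0), min(i1, self.n_samples)
        if i1 <= i0:
            raise ValidationError(f"window {window} contains no samples")
        return np.arange(i0, i1)


def select_channels(epochs: EpochSet, labels: list[str] | tuple[str, ...]) -> EpochSet:
    """Return a new EpochSet restricted to ``labels`` in the given order."""
    idx = [epochs.montage.index(l) for l in labels]
    return replace(
        epochs,
        data=epochs.data[idx].copy(),
        montage=ChannelMontage(tuple(labels)),
    )


def _paths(path: str | Path) -> tuple[Path, Path]:
    stem = Path(path)
    if stem.suffix in (".json", ".dat"):
        stem = stem.with_suffix("")
    return stem.with_suffix(".json"), stem.with_suffix(".dat")


def write_epochset(epochs: EpochSet, path: str | Path) -> Path:
    """Write ``epochs`` to ``<path>.json`` + ``<path>.dat``; returns the stem."""
    meta_path, dat_path = _paths(path)
    meta = {
        "fs": epochs.fs,
        "onset_index": epochs.onset_index,
        "labels": list(epochs.montage.labels),
        "subject_id": epochs.subject_id,
        "group": epochs.group,
        "shape": list(epochs.data.shape),
        "dtype": "<f8",
        "order": "channel-major",
    }
    meta_path.parent.mkdir(parents=True, exist_ok=True)
    meta_path.write_text(json.dumps(meta, indent=1), encoding="utf-8")
    np.ascontiguousarray(epochs.data, dtype="<f8").tofile(dat_path)
    return meta_path.with_suffix("")


def read_epochset(path: str | Path) -> EpochSet:
    """Read an EpochSet written by :func:`write_epochset` (bit-exact)."""
    meta_path, dat_path = _paths(path)
    if not meta_path.exists():
        raise FormatError(f"missing metadata file {meta_path}")
    try:
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"corrupt metadata in {meta_path}: {exc}") from exc
    for key in _META_KEYS:
        if key not in meta:
            raise FormatError(f"metadata {meta_path} lacks required key {key!r}")
    shape = tuple(int(s) for s in meta["shape"])
    if not dat_path.exists():
        raise IntegrityError(f"missing payload file {dat_path}")
    payload = np.fromfile(dat_path, dtype="<f8")
    expected = int(np.prod(shape))
    if payload.size != expected:
        raise IntegrityError(
            f"payload {dat_path} holds {payload.size} values, metadata promises {expected}"
        )
    return EpochSet(
        data=payload.reshape(shape),
        fs=float(meta["fs"]),
        onset_index=int(meta["onset_index"]),
        montage=ChannelMontage(tuple(meta["labels"])),
        subject_id=str(meta["subject_id"]),
        group=str(meta["group"]),
    )


def write_manifest(entries: list[dict], path: str | Path) -> Path:
    """Write a subject manifest: list of {subject_id, group, path} records."""
    path = Path(path)
    for e in entries:
        for key in ("subject_id", "group", "path"):
            if key not in e:
                raise ValidationError(f"manifest entry lacks {key!r}: {e}")
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"subjects": entries}, indent=1), encoding="utf-8")
    return path


def read_manifest(path: str | Path) -> list[dict]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing manifest {path}")
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"corrupt manifest {path}: {exc}") from exc
    if "subjects" not in doc:
        raise FormatError(f"manifest {path} lacks required key 'subjects'")
    return doc["subjects"]
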