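"""Data model and I/O for continuous and epoched EEG.

Two in-memory containers cover the whole pipeline:

* :class:`ContinuousEEG` — a channels x samples recording with event
  markers (cue onsets) carrying class labels;
* :class:`EpochedEEG` — a trials x channels x samples tensor with one
  class label per trial.

Class labels are normalised to ``{1, 2}`` at load time (1 is the
positive class throughout); ``0`` marks an event of unknown class.
Original label strings survive in the manifest ``label_map``.

On disk the native container is a directory with a ``manifest.json``
plus either human-inspectable CSV payloads (one file per trial) or a
single HDF5 tensor; the manifest ``storage`` field selects the dialect.
A reader for the MATLAB v5 files distributed by the BCI Competition
III-IVa and IV-I organisers is provided for users who download those
recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import h5py
import numpy as np
from scipy.io import loadmat

from .exceptions import ContainerError, LayoutError, ValidationError

__all__ = [
    "ContinuousEEG",
    "EpochedEEG",
    "load_native",
    "save_native",
    "load_bci_competition_mat",
]

UNKNOWN_LABEL = 0
VALID_CLASSES = (1, 2)

_MANIFEST = "manifest.json"


def _check_channel_names(names: Sequence[str], n: int) -> list[str]:
    names = [str(c) for c in names]
    if len(names) != n:
        raise ValidationError(
            f"expected {n} channel names, found {len(names)}"
        )
    if len(set(names)) != len(names):
        raise ValidationError("channel names must be unique")
    return names


@dataclass
class ContinuousEEG:
    """Continuous multichannel recording in microvolts.

    Parameters
    ----------
    data
        Array of shape ``(L, T)``: L channels by T samples.
    fs
        Sampling rate in Hz.
    channel_names
        L unique channel labels; file order is authoritative and never
        re-sorted, so selection indices stay reproducible.
    events
        Sequence of ``(sample_index, label)`` pairs; label is 1, 2 or 0
        (unknown).  Stored as an ``(E, 2)`` integer array.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    events: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError(
                f"continuous data must be 2-D (channels x samples), got ndim={self.data.ndim}"
            )
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        self.channel_names = _check_channel_names(self.channel_names, self.data.shape[0])
        ev = np.asarray(self.events, dtype=np.int64).reshape(-1, 2)
        if ev.size:
            if ev[:, 0].min() < 0 or ev[:, 0].max() >= self.data.shape[1]:
                raise ValidationError("event sample indices must lie within the recording")
            bad = set(ev[:, 1]) - {UNKNOWN_LABEL, *VALID_CLASSES}
            if bad:
                raise ValidationError(f"event labels must be in {{0, 1, 2}}, got {sorted(bad)}")
        self.events = ev

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochedEEG:
    """Cue-aligned trials in microvolts.

    ``data`` has shape ``(M, L, N)``: M trials, L channels, N samples.
    ``labels`` is a length-M vector over ``{1, 2}``.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(
                f"epoched data must be 3-D (trials x channels x samples), got ndim={self.data.ndim}"
            )
        m, l, n = self.data.shape
        if m < 1 or l < 1 or n < 2:
            raise ValidationError(f"need M>=1, L>=1, N>=2; got shape {(m, l, n)}")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        self.channel_names = _check_channel_names(self.channel_names, l)
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
        if self.labels.shape[0] != m:
            raise ValidationError(
                f"labels length {self.labels.shape[0]} does not match {m} trials"
            )
        bad = set(self.labels) - set(VALID_CLASSES)
        if bad:
            raise ValidationError(f"trial labels must be in {{1, 2}}, got {sorted(bad)}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


Dataset = Union[ContinuousEEG, EpochedEEG]


# ---------------------------------------------------------------------------
# native container
# ---------------------------------------------------------------------------

def save_native(dataset: Dataset, path: Union[str, Path], storage: str = "csv") -> None:
    """Write *dataset* to directory *path* as manifest + payload.

    ``storage='csv'`` writes one CSV per trial (continuous: one CSV),
    human-diffable; ``storage='hdf5'`` writes a single ``data.h5`` tensor.
    """
    if storage not in ("csv", "hdf5"):
        raise ValidationError(f"storage must be 'csv' or 'hdf5', got {storage!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "fs": float(dataset.fs),
        "n_channels": dataset.n_channels,
        "channel_names": list(dataset.channel_names),
        "storage": storage,
        "label_map": {"1": "class1", "2": "class2"},
    }
    if isinstance(dataset, EpochedEEG):
        manifest["kind"] = "epoched"
        manifest["n_trials"] = dataset.n_trials
        manifest["n_samples"] = dataset.n_samples
        manifest["labels"] = [int(v) for v in dataset.labels]
        if storage == "csv":
            files = []
            for m in range(dataset.n_trials):
                name = f"data_trial{m:04d}.csv"
                np.savetxt(path / name, dataset.data[m], delimiter=",", fmt="%.17g")
                files.append(name)
            manifest["data_files"] = files
        else:
            with h5py.File(path / "data.h5", "w") as f:
                f.create_dataset("data", data=dataset.data)
            manifest["data_files"] = ["data.h5"]
    else:
        manifest["kind"] = "continuous"
        manifest["n_samples"] = dataset.n_samples
        manifest["events"] = [[int(s), int(c)] for s, c in dataset.events]
        if storage == "csv":
            np.savetxt(path / "data.csv", dataset.data, delimiter=",", fmt="%.17g")
            manifest["data_files"] = ["data.csv"]
        else:
            with h5py.File(path / "data.h5", "w") as f:
                f.create_dataset("data", data=dataset.data)
            manifest["data_files"] = ["data.h5"]

    with open(path / _MANIFEST, "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
        f.write("\n")


def _load_payload(path: Path, manifest: dict) -> np.ndarray:
    storage = manifest.get("storage", "csv")
    files = manifest.get("data_files", [])
    if storage == "hdf5":
        with h5py.File(path / files[0], "r") as f:
            return np.asarray(f["data"], dtype=np.float64)
    if manifest["kind"] == "epoched":
        trials = [
            np.atleast_2d(np.loadtxt(path / name, delimiter=",", ndmin=2))
            for name in files
        ]
        return np.stack(trials, axis=0)
    return np.atleast_2d(np.loadtxt(path / files[0], delimiter=",", ndmin=2))


def load_native(path: Union[str, Path]) -> Dataset:
    """Load a native container directory, validating manifest vs payload."""
    path = Path(path)
    mf = path / _MANIFEST
    if not mf.is_file():
        raise ContainerError(f"no {_MANIFEST} found in {path}")
    with open(mf) as f:
        manifest = json.load(f)

    data = _load_payload(path, manifest)
    kind = manifest.get("kind")
    if kind == "epoched":
        expected = (manifest["n_trials"], manifest["n_channels"], manifest["n_samples"])
        if data.shape != expected:
            raise ValidationError(
                f"manifest declares shape {expected} but payload has {data.shape}"
            )
        return EpochedEEG(
            data=data,
            fs=manifest["fs"],
            channel_names=manifest["channel_names"],
            labels=np.asarray(manifest["labels"], dtype=np.int64),
        )
    if kind == "continuous":
        expected = (manifest["n_channels"], manifest["n_samples"])
        if data.shape != expected:
            raise ValidationError(
                f"manifest declares shape {expected} but payload has {data.shape}"
            )
        return ContinuousEEG(
            data=data,
            fs=manifest["fs"],
            channel_names=manifest["channel_names"],
            events=np.asarray(manifest.get("events", []), dtype=np.int64).reshape(-1, 2),
        )
    raise ContainerError(f"manifest kind must be 'epoched' or 'continuous', got {kind!r}")


# ---------------------------------------------------------------------------
# BCI-competition MAT files
# ---------------------------------------------------------------------------

def load_bci_competition_mat(path: Union[str, Path], layout: str) -> ContinuousEEG:
    """Read a BCI Competition III-IVa or IV-I calibration MAT file.

    Assumed layout (MATLAB v5, 100 Hz versions): variable ``cnt`` holding
    the continuous signal as samples x channels in units of 0.1 microvolt,
    a struct ``nfo`` with fields ``fs`` and ``clab`` (channel labels), and
    a struct ``mrk`` with fields ``pos`` (cue sample positions) and ``y``
    (class of each cue).  Competition III-IVa codes classes as 1/2 with
    NaN for unlabelled test cues; IV-I codes them as -1/+1 (mapped here to
    1/2), again NaN for unlabelled.  Any missing variable raises
    :class:`LayoutError` naming the field.
    """
    if layout not in ("iii_iva", "iv_i"):
        raise ValidationError(f"layout must be 'iii_iva' or 'iv_i', got {layout!r}")
    raw = loadmat(str(path), squeeze_me=True, struct_as_record=False)

    def need(name):
        if name not in raw:
            raise LayoutError(f"MAT file {path} lacks expected variable {name!r}")
        return raw[name]

    cnt = np.asarray(need("cnt"), dtype=np.float64)
    nfo = need("nfo")
    mrk = need("mrk")
    for obj, fields, owner in ((nfo, ("fs", "clab"), "nfo"), (mrk, ("pos", "y"), "mrk")):
        for fld in fields:
            if not hasattr(obj, fld):
                raise LayoutError(f"MAT file {path} lacks expected field {owner}.{fld}")

    fs = float(np.asarray(nfo.fs).ravel()[0])
    clab = [str(c) for c in np.atleast_1d(nfo.clab)]
    pos = np.atleast_1d(np.asarray(mrk.pos)).astype(np.int64).ravel()
    y = np.atleast_1d(np.asarray(mrk.y, dtype=np.float64)).ravel()

    labels = np.full(y.shape, UNKNOWN_LABEL, dtype=np.int64)
    if layout == "iii_iva":
        labels[y == 1] = 1
        labels[y == 2] = 2
    else:  # iv_i: -1/+1 coding
        labels[y == -1] = 1
        labels[y == 1] = 2

    # competition files store amplitudes as int16 in 0.1 uV steps
    data = 0.1 * cnt.T
    events = np.column_stack([pos, labels])
    return ContinuousEEG(data=data, fs=fs, channel_names=clab, events=events)
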