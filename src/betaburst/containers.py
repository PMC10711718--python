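"""Epoched EEG container and file round-trip support.

The whole pipeline operates on :class:`EpochSet`: a stack of fixed-length,
event-centered epochs (trials x channels x samples) together with per-epoch
metadata (participant, trial, epoch phase, condition, hand used) and the
channel-cluster montage. Epochs are centered on one of four behavioral
events (trial start, first touch, grasp completion, trial end), so the time
axis runs symmetrically around 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EPOCH_PHASES = ("start", "touch", "grasp", "end")

#: metadata columns required on every EpochSet
METADATA_COLUMNS = ("participant", "trial", "epoch_phase", "condition", "hand")


@dataclass
class EpochSet:
    """Epoched multichannel voltage data.

    Parameters
    ----------
    data : ndarray, shape (n_epochs, n_channels, n_times)
        Voltages in microvolts.
    sfreq : float
        Sampling rate in Hz.
    ch_names : list of str
        Channel labels.
    metadata : DataFrame
        One row per epoch with at least ``participant``, ``trial``,
        ``epoch_phase``, ``condition`` and ``hand`` columns.
    clusters : dict
        Mapping of cluster label (e.g. ``"C3"``, ``"C4"``) to channel labels.
    tmin : float
        Time of the first sample relative to the centering event, seconds.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    metadata: pd.DataFrame
    clusters: dict[str, list[str]] = field(default_factory=dict)
    tmin: float = -1.8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_times)")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel axis does not match ch_names")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata rows do not match number of epochs")
        missing = set(METADATA_COLUMNS) - set(self.metadata.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        for cluster, chs in self.clusters.items():
            unknown = set(chs) - set(self.ch_names)
            if unknown:
                raise ValueError(f"cluster {cluster} has unknown channels {unknown}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds relative to the centering event."""
        return self.tmin + np.arange(self.n_times) / self.sfreq

    @property
    def duration(self) -> float:
        return self.n_times / self.sfreq

    def channel_index(self, name: str) -> int:
        return self.ch_names.index(name)

    def cluster_of(self, ch_name: str) -> str | None:
        for cluster, chs in self.clusters.items():
            if ch_name in chs:
                return cluster
        return None

    def select(self, mask) -> "EpochSet":
        """Subset epochs by boolean mask or index array."""
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            sfreq=self.sfreq,
            ch_names=list(self.ch_names),
            metadata=self.metadata.iloc[mask].reset_index(drop=True)
            if mask.dtype == bool
            else self.metadata.iloc[mask].reset_index(drop=True),
            clusters={k: list(v) for k, v in self.clusters.items()},
            tmin=self.tmin,
        )


SUPPORTED_FORMATS = ("eeglab", "npz")


def export_epochs(epochs: EpochSet, path, format: str = "npz") -> Path:
    """Write an :class:`EpochSet` to disk.

    Two containers are supported: EEGLAB ``.set`` (a MATLAB file holding the
    standard EEG struct, readable by EEGLAB and MNE-Python) and ``npz`` — a
    NumPy archive for the voltages with a JSON sidecar (``<path>.json``)
    carrying sampling rate, channel labels, clusters and per-epoch events.
    """
    path = Path(path)
    if format == "npz":
        return _export_npz(epochs, path)
    if format == "eeglab":
        return _export_eeglab(epochs, path)
    raise ValueError(f"unsupported format {format!r}; choose from {SUPPORTED_FORMATS}")


def load_epochs(path, format: str = "npz") -> EpochSet:
    path = Path(path)
    if format == "npz":
        return _load_npz(path)
    if format == "eeglab":
        return _load_eeglab(path)
    raise ValueError(f"unsupported format {format!r}; choose from {SUPPORTED_FORMATS}")


def _export_npz(epochs: EpochSet, path: Path) -> Path:
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    np.savez(path, data=epochs.data)
    sidecar = {
        "sfreq": epochs.sfreq,
        "tmin": epochs.tmin,
        "ch_names": list(epochs.ch_names),
        "clusters": {k: list(v) for k, v in epochs.clusters.items()},
        "metadata": epochs.metadata.to_dict(orient="list"),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def _load_npz(path: Path) -> EpochSet:
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as archive:
        data = archive["data"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    metadata = pd.DataFrame(sidecar["metadata"])
    if metadata.empty:
        metadata = pd.DataFrame({c: [] for c in METADATA_COLUMNS})
    return EpochSet(
        data=data,
        sfreq=sidecar["sfreq"],
        ch_names=sidecar["ch_names"],
        metadata=metadata,
        clusters=sidecar["clusters"],
        tmin=sidecar["tmin"],
    )


def _export_eeglab(epochs: EpochSet, path: Path) -> Path:
    """Write the EEGLAB epoched EEG struct via scipy.io.savemat.

    Builds the minimal field set MNE's EEGLAB reader requires: per-epoch
    events at the centering sample carrying the epoch phase as event type.
    Cluster assignments and full metadata go into a JSON sidecar since the
    EEG struct has no standard slot for them.
    """
    from scipy.io import savemat

    if path.suffix != ".set":
        path = path.with_suffix(".set")
    n_ep, n_ch, n_t = epochs.data.shape
    center = int(round(-epochs.tmin * epochs.sfreq))  # sample of the event
    chanlocs = np.zeros((n_ch,), dtype=[("labels", object)])
    chanlocs["labels"] = np.array(epochs.ch_names, dtype=object)
    ev_dtype = [("type", object), ("latency", object), ("epoch", object)]
    events = np.zeros((max(n_ep, 1),), dtype=ev_dtype)
    ep_dtype = [("event", object), ("eventtype", object), ("eventlatency", object)]
    ep_struct = np.zeros((max(n_ep, 1),), dtype=ep_dtype)
    for i in range(n_ep):
        phase = str(epochs.metadata.iloc[i]["epoch_phase"])
        events[i] = (phase, float(i * n_t + center + 1), float(i + 1))
        ep_struct[i] = (float(i + 1), phase, float(epochs.tmin * 1000 + center / epochs.sfreq * 1000))
    eeg = {
        "data": np.transpose(epochs.data, (1, 2, 0)).astype(np.float64),
        "setname": "betaburst",
        "nbchan": float(n_ch),
        "pnts": float(n_t),
        "trials": float(n_ep),
        "srate": float(epochs.sfreq),
        "xmin": float(epochs.tmin),
        "xmax": float(epochs.tmin + (n_t - 1) / epochs.sfreq),
        "chanlocs": chanlocs,
        "event": events if n_ep else np.zeros((0,), dtype=ev_dtype),
        "epoch": ep_struct if n_ep else np.zeros((0,), dtype=ep_dtype),
        "icawinv": np.array([]),
        "icasphere": np.array([]),
        "icaweights": np.array([]),
        "icaact": np.array([]),
    }
    savemat(path, {"EEG": eeg}, appendmat=False)
    sidecar = {
        "clusters": {k: list(v) for k, v in epochs.clusters.items()},
        "metadata": epochs.metadata.to_dict(orient="list"),
        "tmin": epochs.tmin,
    }
    path.with_suffix(".set.json").write_text(json.dumps(sidecar, indent=1))
    return path


def _load_eeglab(path: Path) -> EpochSet:
    import mne

    if path.suffix != ".set":
        path = path.with_suffix(".set")
    sidecar = json.loads(path.with_suffix(".set.json").read_text())
    metadata = pd.DataFrame(sidecar["metadata"])
    if metadata.empty:
        # zero-trial file: MNE's epoch reader needs events, read struct directly
        from scipy.io import loadmat

        mat = loadmat(path, squeeze_me=False, appendmat=False)["EEG"][0, 0]
        n_ch = int(mat["nbchan"].item())
        n_t = int(mat["pnts"].item())
        labels = [str(l[0]) for l in mat["chanlocs"]["labels"].ravel()]
        return EpochSet(
            data=np.zeros((0, n_ch, n_t)),
            sfreq=float(mat["srate"].item()),
            ch_names=labels,
            metadata=pd.DataFrame({c: [] for c in METADATA_COLUMNS}),
            clusters=sidecar["clusters"],
            tmin=sidecar["tmin"],
        )
    raw = mne.io.read_epochs_eeglab(path, verbose="error", montage_units="mm")
    data = raw.get_data() * 1e6  # MNE converts to volts; back to µV
    return EpochSet(
        data=data,
        sfreq=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        metadata=metadata,
        clusters=sidecar["clusters"],
        tmin=sidecar["tmin"],
    )
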