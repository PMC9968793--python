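"""Session container: multichannel EEG trials with labels and block structure.

A :class:`Session` holds one BCI recording session as a trial array of
shape ``(trials, channels, samples)`` plus class labels, block indices,
the sampling rate and channel names.  Sessions round-trip through HDF5
(datasets ``/trials``, ``/labels``, ``/block_index``, ``/fs``,
``/channel_names`` and optional ``/artifact_flags``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = ["Session"]


@dataclass
class Session:
    trials: np.ndarray
    labels: np.ndarray
    blocks: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    artifact_flags: np.ndarray | None = None
    session_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.blocks = np.asarray(self.blocks, dtype=int)
        if self.trials.ndim != 3:
            raise ValueError("trials must be (n_trials, channels, samples)")
        n = self.trials.shape[0]
        if self.labels.shape != (n,) or self.blocks.shape != (n,):
            raise ValueError("labels and blocks must have one entry per trial")
        if len(self.channel_names) != self.trials.shape[1]:
            raise ValueError("channel_names must match the channel axis")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    def block_ids(self) -> list[int]:
        return sorted(set(self.blocks.tolist()))

    def select(self, idx) -> "Session":
        """Subset of trials (e.g. after artifact rejection)."""
        idx = np.asarray(idx)
        return Session(
            trials=self.trials[idx],
            labels=self.labels[idx],
            blocks=self.blocks[idx],
            fs=self.fs,
            channel_names=self.channel_names,
            artifact_flags=None
            if self.artifact_flags is None
            else self.artifact_flags[idx],
            session_id=self.session_id,
            meta=dict(self.meta),
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(Path(path), "w") as f:
            f.create_dataset("trials", data=self.trials)
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("block_index", data=self.blocks)
            f.create_dataset("fs", data=float(self.fs))
            f.create_dataset(
                "channel_names",
                data=np.array([c.encode() for c in self.channel_names]),
            )
            if self.artifact_flags is not None:
                f.create_dataset("artifact_flags", data=self.artifact_flags)
            f.attrs["session_id"] = self.session_id
            for k, v in self.meta.items():
                f.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path) -> "Session":
        with h5py.File(Path(path), "r") as f:
            flags = f["artifact_flags"][()] if "artifact_flags" in f else None
            meta = {
                k: (v.item() if hasattr(v, "item") else v)
                for k, v in f.attrs.items()
                if k != "session_id"
            }
            return cls(
                trials=f["trials"][()],
                labels=f["labels"][()],
                blocks=f["block_index"][()],
                fs=float(f["fs"][()]),
                channel_names=tuple(c.decode() for c in f["channel_names"][()]),
                artifact_flags=flags,
                session_id=str(f.attrs.get("session_id", "")),
                meta=meta,
            )
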