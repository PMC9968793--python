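"""Filtering, epoching, downsampling and Riemannian-potato-field rejection.

The standard pipeline for the performance metrics is: zero-phase 4th-order
Butterworth band-pass (8-30 Hz), crop to the central two seconds of each
trial, then one spatial covariance per epoch.  Artifact rejection uses a
field of covariance-based "potato" detectors: each potato watches a small
channel group through its own filter, computes a Riemannian reference
mean over all trials, and flags trials whose distance-to-reference
z-score exceeds a threshold.  A trial flagged by any potato is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .geometry import DEFAULT_CONFIG, GeometryConfig, distances_to, frechet_mean, trial_covariance
from .metrics import TrialCovariance
from .session import Session

__all__ = [
    "FilterSpec",
    "PotatoFieldSpec",
    "bandpass",
    "epoch_center",
    "downsample",
    "potato_field_reject",
    "session_covariances",
]


@dataclass
class FilterSpec:
    """Zero-phase Butterworth filter specification."""

    band: tuple[float, float] = (8.0, 30.0)
    order: int = 4
    btype: str = "bandpass"  # or "bandstop"

    def sos(self, fs: float) -> np.ndarray:
        low, high = self.band
        if not 0 < low < high < fs / 2:
            raise ValueError(
                f"band {self.band} invalid for sampling rate {fs} (Nyquist {fs / 2})"
            )
        return scipy.signal.butter(
            self.order, self.band, btype=self.btype, fs=fs, output="sos"
        )


def bandpass(epochs: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth filtering along the last axis."""
    spec = spec or FilterSpec()
    return scipy.signal.sosfiltfilt(spec.sos(fs), np.asarray(epochs, float), axis=-1)


def epoch_center(data: np.ndarray, fs: float, duration: float) -> np.ndarray:
    """Crop the central ``duration`` seconds of each trial.

    The window is centred on the trial midpoint; indices are 0-based and
    half-open, so a 2 s window of a 4 s trial at 250 Hz keeps samples
    250..749.
    """
    data = np.asarray(data)
    n = data.shape[-1]
    win = int(round(duration * fs))
    if win > n:
        raise ValueError(f"window of {win} samples exceeds trial length {n}")
    start = (n - win) // 2
    return data[..., start : start + win]


def downsample(epochs: np.ndarray, from_rate: float, to_rate: float) -> np.ndarray:
    """Anti-aliased decimation by an integer factor (FIR, zero phase)."""
    ratio = from_rate / to_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"rate ratio {from_rate}/{to_rate} is not an integer")
    q = int(round(ratio))
    if q == 1:
        return np.asarray(epochs, float).copy()
    return scipy.signal.decimate(
        np.asarray(epochs, float), q, ftype="fir", axis=-1, zero_phase=True
    )


# Detector layout of the potato field: five contact-loss detectors on
# channel pairs (band-passed 1-20 Hz) and three general detectors on
# channel quadruples (band-stopped 8-38 Hz).
_CONTACT_PAIRS = (
    ("F3", "C3"),
    ("P3", "Pz"),
    ("Fz", "F4"),
    ("Cz", "C4"),
    ("C4", "P4"),
)
_GENERAL_QUADS = (
    ("F3", "C3", "P3", "Pz"),
    ("Fz", "F4", "Cz", "C4"),
    ("P4", "Pz", "Fz", "F4"),
)


@dataclass
class PotatoFieldSpec:
    """Potato-field layout and decision rule.

    Each potato is ``(name, channels, FilterSpec)``.  A trial is rejected
    when any potato's distance z-score exceeds ``z_threshold``.
    Calibration is single-pass and offline: each potato's reference mean
    and distance statistics come from the subject's entire trial set.
    """

    potatoes: tuple = tuple(
        [
            (f"contact_{'-'.join(p)}", p, FilterSpec((1.0, 20.0), 4, "bandpass"))
            for p in _CONTACT_PAIRS
        ]
        + [
            (f"general_{'-'.join(q)}", q, FilterSpec((8.0, 38.0), 4, "bandstop"))
            for q in _GENERAL_QUADS
        ]
    )
    z_threshold: float = 2.5


def potato_field_reject(
    session: Session,
    spec: PotatoFieldSpec | None = None,
    config: GeometryConfig = DEFAULT_CONFIG,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Offline potato-field artifact rejection.

    Returns ``(kept_indices, report)`` where the report has one row per
    (trial, potato) with the z-score and the per-trial keep decision.
    Deterministic given the inputs; permuting the trials permutes the
    kept-index set identically.
    """
    spec = spec or PotatoFieldSpec()
    name_to_idx = {c: i for i, c in enumerate(session.channel_names)}
    n = session.n_trials
    rejected = np.zeros(n, dtype=bool)
    rows = []
    for name, channels, fspec in spec.potatoes:
        missing = [c for c in channels if c not in name_to_idx]
        if missing:
            raise ValueError(f"potato {name}: channels {missing} not in montage")
        idx = [name_to_idx[c] for c in channels]
        filtered = bandpass(session.trials[:, idx, :], session.fs, fspec)
        covs = np.stack([trial_covariance(ep, config) for ep in filtered])
        ref = frechet_mean(covs, config=config)
        d = distances_to(ref, covs)
        std = d.std()
        z = (d - d.mean()) / std if std > 0 else np.zeros_like(d)
        flagged = z > spec.z_threshold
        rejected |= flagged
        for i in range(n):
            rows.append(
                {"trial": i, "potato": name, "z": z[i], "flagged": bool(flagged[i])}
            )
    report = pd.DataFrame(rows)
    report["kept"] = ~report["trial"].map(
        dict(enumerate(rejected.tolist()))
    ).astype(bool)
    kept = np.flatnonzero(~rejected)
    return kept, report


def session_covariances(
    session: Session,
    band: tuple[float, float] = (8.0, 30.0),
    epoch_duration: float = 2.0,
    config: GeometryConfig = DEFAULT_CONFIG,
) -> list[TrialCovariance]:
    """Standard covariance pipeline: band-pass, central crop, covariance.

    Filtering runs on the full trial and the crop is taken afterwards,
    keeping filter edge effects outside the analysed window.
    """
    filtered = bandpass(session.trials, session.fs, FilterSpec(band))
    epochs = epoch_center(filtered, session.fs, epoch_duration)
    return [
        TrialCovariance(
            matrix=trial_covariance(ep, config),
            label=int(session.labels[i]),
            block=int(session.blocks[i]),
            index=i,
        )
        for i, ep in enumerate(epochs)
    ]
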