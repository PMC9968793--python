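"""CSP + regularized-LDA baseline classifier.

Common spatial patterns (CSP) finds spatial filters ``w`` extremizing the
variance ratio ``w' S1 w / w' (S1 + S2) w`` between the two class
covariances — the generalized eigenvectors of the pencil
``(S1, S1 + S2)``.  Four filters are used (two per end of the spectrum)
and the feature of an epoch is the log-variance of each filtered signal.
Classification uses linear discriminant analysis with analytic
(Ledoit-Wolf) covariance shrinkage.

Provides the classifier-based trial-wise reinforcement baseline (+1 for
a correct prediction, -1 for an incorrect one, classifier trained on all
previous blocks with a 3-fold CV choice of temporal sub-band), the
block-wise run-wise classification accuracy (RWCA, leave-one-trial-out
within a block), and interpretable CSP spatial patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .geometry import trial_covariance
from .preprocess import FilterSpec, bandpass, epoch_center
from .session import Session

__all__ = [
    "CSPModel",
    "SubbandChoice",
    "CANDIDATE_BANDS",
    "fit_csp",
    "csp_features",
    "fit_rlda",
    "select_subband",
    "classifier_reinforcement",
    "rwca",
    "csp_patterns",
]

CANDIDATE_BANDS = ((8.0, 11.0), (9.0, 13.0), (11.0, 19.0), (17.0, 30.0), (8.0, 30.0))


@dataclass
class CSPModel:
    """Fitted CSP filters (rows of ``filters``, ordered large-to-small
    generalized eigenvalue) and the class covariances they came from."""

    filters: np.ndarray  # (n_filters, channels)
    eigenvalues: np.ndarray
    class_covs: tuple[np.ndarray, np.ndarray]
    band: tuple[float, float] | None = None

    def transform(self, epochs: np.ndarray) -> np.ndarray:
        return csp_features(self.filters, epochs)


def _class_covs(epochs: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("CSP requires exactly two classes")
    covs = []
    for c in classes:
        cls_epochs = epochs[labels == c]
        if len(cls_epochs) < 2:
            raise ValueError("need at least 2 trials per class")
        covs.append(np.mean([trial_covariance(e) for e in cls_epochs], axis=0))
    return covs[0], covs[1]


def fit_csp(epochs: np.ndarray, labels: np.ndarray, n_filters: int = 4) -> CSPModel:
    """Fit CSP spatial filters on ``(trials, channels, samples)`` epochs.

    Filters are the generalized eigenvectors of ``(S1, S1 + S2)``; the
    ``n_filters`` kept are split evenly between the largest and smallest
    eigenvalues.  Rows satisfy the whitening identity
    ``W (S1 + S2) W' = I``.  A rank-deficient composite covariance is
    jittered and refit.
    """
    if n_filters % 2:
        raise ValueError("n_filters must be even")
    s1, s2 = _class_covs(np.asarray(epochs, float), np.asarray(labels))
    comp = s1 + s2
    try:
        w, v = scipy.linalg.eigh(s1, comp)
    except scipy.linalg.LinAlgError:
        comp = comp + 1e-9 * np.trace(comp) / comp.shape[0] * np.eye(comp.shape[0])
        w, v = scipy.linalg.eigh(s1, comp)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    half = n_filters // 2
    keep = np.r_[np.arange(half), np.arange(len(w) - half, len(w))]
    return CSPModel(filters=v[:, keep].T, eigenvalues=w[keep], class_covs=(s1, s2))


def csp_features(filters: np.ndarray, epochs: np.ndarray) -> np.ndarray:
    """Log-variance of each spatially filtered epoch: ``(trials, n_filters)``."""
    filtered = filters @ np.asarray(epochs, float)
    return np.log(filtered.var(axis=-1, ddof=1))


def fit_rlda(features: np.ndarray, labels: np.ndarray) -> LinearDiscriminantAnalysis:
    """Linear discriminant with analytic (Ledoit-Wolf) covariance shrinkage."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need samples from two classes")
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    lda.fit(np.asarray(features, float), labels)
    return lda


def _fit_predict(
    train_epochs, train_labels, test_epochs, n_filters: int = 4
) -> np.ndarray:
    model = fit_csp(train_epochs, train_labels, n_filters)
    lda = fit_rlda(model.transform(train_epochs), train_labels)
    return lda.predict(model.transform(test_epochs))


@dataclass
class SubbandChoice:
    band: tuple[float, float]
    cv_accuracy: dict[tuple[float, float], float] = field(default_factory=dict)


def select_subband(
    trials: np.ndarray,
    labels: np.ndarray,
    fs: float,
    bands: tuple = CANDIDATE_BANDS,
    epoch_duration: float = 2.0,
    n_folds: int = 3,
    random_state: int = 0,
) -> SubbandChoice:
    """3-fold stratified CV over candidate temporal sub-bands.

    ``trials`` are unfiltered; each band is filtered on the full trial
    before the central crop.  Ties are broken toward the widest band.
    """
    labels = np.asarray(labels)
    scores: dict[tuple[float, float], float] = {}
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=random_state)
    for band in bands:
        epochs = epoch_center(bandpass(trials, fs, FilterSpec(band)), fs, epoch_duration)
        correct = 0
        for tr, te in skf.split(epochs, labels):
            pred = _fit_predict(epochs[tr], labels[tr], epochs[te])
            correct += int(np.sum(pred == labels[te]))
        scores[band] = correct / len(labels)
    best = max(scores, key=lambda b: (scores[b], b[1] - b[0]))
    return SubbandChoice(band=best, cv_accuracy=scores)


def classifier_reinforcement(
    session: Session,
    epoch_duration: float = 2.0,
    n_filters: int = 4,
    random_state: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial +/-1 classifier reinforcement and per-block sums.

    For each block ``k >= 2`` a CSP-rLDA classifier is trained on all
    trials of blocks ``1..k-1`` (in the sub-band selected by 3-fold CV on
    that training set) and predicts each block-``k`` trial; the signal is
    +1 for a correct prediction and -1 otherwise.
    """
    blocks = session.block_ids()
    if len(blocks) < 2:
        raise ValueError("session must contain at least two blocks")
    rows = []
    for j, b in enumerate(blocks[1:], start=1):
        train_mask = np.isin(session.blocks, blocks[:j])
        test_mask = session.blocks == b
        choice = select_subband(
            session.trials[train_mask],
            session.labels[train_mask],
            session.fs,
            epoch_duration=epoch_duration,
            random_state=random_state,
        )
        spec = FilterSpec(choice.band)
        train = epoch_center(
            bandpass(session.trials[train_mask], session.fs, spec),
            session.fs, epoch_duration,
        )
        test = epoch_center(
            bandpass(session.trials[test_mask], session.fs, spec),
            session.fs, epoch_duration,
        )
        pred = _fit_predict(train, session.labels[train_mask], test, n_filters)
        true = session.labels[test_mask]
        for i, (p, t) in enumerate(zip(pred, true)):
            rows.append(
                {
                    "variant": "classifier",
                    "block": b,
                    "trial": int(np.flatnonzero(test_mask)[i]),
                    "label": int(t),
                    "prediction": int(p),
                    "signal": 1.0 if p == t else -1.0,
                    "band": f"{choice.band[0]:g}-{choice.band[1]:g}",
                }
            )
    trials_df = pd.DataFrame(rows)
    sums = (
        trials_df.groupby(["variant", "block"], as_index=False)["signal"]
        .sum()
        .rename(columns={"signal": "sum"})
    )
    return trials_df, sums


def rwca(epochs: np.ndarray, labels: np.ndarray, n_filters: int = 4) -> float:
    """Run-wise classification accuracy of one block.

    Leave-one-trial-out: the CSP filters and rLDA are refit for every
    held-out trial on the block's remaining trials.  ``epochs`` are the
    already preprocessed (band-passed, cropped) trials of the block.
    """
    epochs = np.asarray(epochs, float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("block must contain both classes")
    n = len(labels)
    correct = 0
    for i in range(n):
        mask = np.arange(n) != i
        pred = _fit_predict(epochs[mask], labels[mask], epochs[i : i + 1], n_filters)
        correct += int(pred[0] == labels[i])
    return correct / n


def csp_patterns(model: CSPModel, composite_cov: np.ndarray | None = None) -> np.ndarray:
    """Interpretable spatial patterns ``A = S W' (W S W')^{-1}``.

    ``S`` defaults to the composite covariance the model was fit on.
    Columns are scaled so the largest absolute entry of the matrix is 1.
    """
    w = model.filters
    s = composite_cov if composite_cov is not None else sum(model.class_covs)
    inner = w @ s @ w.T
    a = s @ w.T @ np.linalg.inv(inner)
    return a / np.max(np.abs(a))
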