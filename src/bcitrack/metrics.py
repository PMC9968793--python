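"""Static (block-wise) user-performance metrics.

Two metrics summarise a set of motor-imagery trials, each trial
represented by its SPD spatial covariance matrix:

* ``classDistinct`` — class separability: the Riemannian distance between
  the two class mean covariance matrices divided by the sum of the
  intra-class dispersions.
* ``classStability`` — within-class consistency of one class:
  ``1 / (1 + Phi_c)`` where ``Phi_c`` is the mean Riemannian distance of
  that class's trials from their own mean.

A subset-based variant of the dispersion (``Phi*``) averages the plain
dispersion over chronological subsets of ``N_t`` trials, damping slow
signal non-stationarities that would otherwise inflate the dispersion of
a long trial sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryConfig, DEFAULT_CONFIG, distances_to, frechet_mean, riemannian_distance

__all__ = [
    "TrialCovariance",
    "ClassState",
    "SubsetConfig",
    "interclass_dispersion",
    "intraclass_dispersion",
    "class_distinct",
    "class_distinct_from_states",
    "class_stability",
    "overall_class_stability",
    "subset_indices",
    "subset_dispersion",
]


@dataclass(frozen=True)
class TrialCovariance:
    """One trial's spatial covariance with its bookkeeping labels."""

    matrix: np.ndarray
    label: int
    block: int
    index: int


@dataclass
class ClassState:
    """Per-class mean and dispersion at a point in time."""

    class_id: int
    mean: np.ndarray
    dispersion: float
    subset_dispersion: float = np.nan
    n_trials: int = 1


@dataclass
class SubsetConfig:
    """Chronological subset splitting used by the ``Phi*`` dispersion.

    ``subset_size`` is the number of trials per subset (``N_t``, default 5).
    """

    subset_size: int = 5

    def __post_init__(self) -> None:
        if self.subset_size < 2:
            raise ValueError("subset_size must be >= 2")


def _stack(trials) -> np.ndarray:
    mats = [t.matrix if isinstance(t, TrialCovariance) else np.asarray(t) for t in trials]
    return np.stack(mats)


def interclass_dispersion(state1: ClassState, state2: ClassState) -> float:
    """Riemannian distance between the two class mean covariance matrices."""
    return riemannian_distance(state1.mean, state2.mean)


def intraclass_dispersion(
    trials, config: GeometryConfig = DEFAULT_CONFIG, init: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Fréchet mean and mean distance-to-mean of one class's trials.

    Returns ``(mean, dispersion)`` where ``dispersion`` is the average
    Riemannian distance between the class mean and the individual trial
    covariances.
    """
    mats = _stack(trials)
    if mats.shape[0] == 0:
        raise ValueError("need at least one trial")
    mean = frechet_mean(mats, config=config, init=init)
    disp = float(np.mean(distances_to(mean, mats)))
    return mean, disp


def class_stability(dispersion: float) -> float:
    """``1 / (1 + Phi_c)`` — within-class consistency, in ``(0, 1]``."""
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    return 1.0 / (1.0 + dispersion)


def overall_class_stability(stab1: float, stab2: float) -> float:
    """Session-level stability: the average of the two per-class values."""
    return (stab1 + stab2) / 2.0


def class_distinct_from_states(state1: ClassState, state2: ClassState) -> float:
    """Separability ratio from two pre-computed class states.

    ``delta_R(mean1, mean2) / (Phi_1 + Phi_2)``.  A zero denominator
    (every trial in both classes identical) is degenerate and reported
    as ``inf`` with a warning so batch evaluation can continue.
    """
    num = interclass_dispersion(state1, state2)
    den = state1.dispersion + state2.dispersion
    # distances below float-noise scale are genuine zeros (identical matrices)
    tol = 1e-12
    if num < tol:
        num = 0.0
    if den < tol:
        if num == 0.0:
            return 0.0
        warnings.warn(
            "zero intra-class dispersion in both classes: classDistinct degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.inf
    return num / den


def class_distinct(
    trials_class1, trials_class2, config: GeometryConfig = DEFAULT_CONFIG
) -> float:
    """classDistinct of two trial sets (ratio of inter- to intra-class dispersion)."""
    mean1, disp1 = intraclass_dispersion(trials_class1, config)
    mean2, disp2 = intraclass_dispersion(trials_class2, config)
    s1 = ClassState(0, mean1, disp1, n_trials=len(trials_class1))
    s2 = ClassState(1, mean2, disp2, n_trials=len(trials_class2))
    return class_distinct_from_states(s1, s2)


def subset_indices(
    n_trials: int, subset_size: int, allow_overlap_tail: bool = False
) -> list[np.ndarray]:
    """Chronological subset index sets for the ``Phi*`` dispersion.

    Trials are split in the order they were performed into disjoint
    subsets of ``subset_size``.  When ``n_trials`` is not divisible by
    ``subset_size`` and ``allow_overlap_tail`` is set, an extra final
    subset covers the most recent ``subset_size`` trials (sharing up to
    ``subset_size - 1`` trials with its predecessor); otherwise the
    remainder trials are dropped.
    """
    if n_trials < subset_size:
        raise ValueError(f"need at least {subset_size} trials, got {n_trials}")
    n_full = n_trials // subset_size
    subsets = [
        np.arange(j * subset_size, (j + 1) * subset_size) for j in range(n_full)
    ]
    if n_trials % subset_size and allow_overlap_tail:
        subsets.append(np.arange(n_trials - subset_size, n_trials))
    return subsets


def subset_dispersion(
    trials,
    cfg: SubsetConfig | None = None,
    allow_overlap_tail: bool = False,
    config: GeometryConfig = DEFAULT_CONFIG,
) -> float:
    """Subset-averaged intra-class dispersion ``Phi*``.

    ``Phi* = (1/N_s)(1/N_t) sum_j sum_i delta_R(mean(T_j), T_{j,i})``
    over chronological subsets ``T_j`` of ``N_t`` trials.  Trials must be
    passed in the order they were performed.  With fewer than ``N_t``
    trials the plain dispersion of the available trials is returned.
    """
    cfg = cfg or SubsetConfig()
    mats = _stack(trials)
    n = mats.shape[0]
    if n == 0:
        raise ValueError("need at least one trial")
    if n < cfg.subset_size:
        return intraclass_dispersion(mats, config)[1]
    total = 0.0
    subsets = subset_indices(n, cfg.subset_size, allow_overlap_tail)
    for idx in subsets:
        sub = mats[idx]
        mean = frechet_mean(sub, config=config)
        total += float(np.sum(distances_to(mean, sub)))
    return total / (len(subsets) * cfg.subset_size)
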