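"""Trial-wise metric engines and reinforcement signals.

The block-wise metrics in :mod:`bcitrack.metrics` assess performance on a
static trial set.  During online training a user needs feedback after
every trial, so three engines update classDistinct / classStability
incrementally:

* **running** — every new trial joins the set of all previously performed
  trials and the metrics are recomputed on the union.
* **sliding window** — a fixed-length FIFO queue of the most recent trials
  per class; metrics are recomputed on the queue contents only.
* **weighted average** — the post-trial class mean moves along the
  geodesic from the previous block's mean toward the queue mean
  (step ``alpha1``), and the post-trial dispersion is the convex
  combination ``(1 - alpha2) * Phi*_{k-1} + alpha2 * Phi*_k`` of the
  previous block's and the current block's subset dispersions.

The per-trial reinforcement signal for a metric is
``M'_{k,i} - M_{k-1}``: the post-trial metric minus the same metric
computed on the completed previous block.  Using the block-start value as
the reference (rather than the previous trial's value) emphasises
gradual trends over volatile trial-to-trial jumps.  Block 1 has no
reference and emits no signals.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import DEFAULT_CONFIG, GeometryConfig, frechet_mean, geodesic_power, riemannian_distance
from .metrics import (
    ClassState,
    SubsetConfig,
    TrialCovariance,
    class_distinct_from_states,
    class_stability,
    intraclass_dispersion,
    overall_class_stability,
    subset_dispersion,
)

__all__ = [
    "EngineConfig",
    "ReinforcementTrace",
    "RunningEngine",
    "SlidingEngine",
    "WeightedEngine",
    "make_engine",
    "reinforcement_signal",
    "block_reference",
    "run_session",
]

VARIANTS = ("running", "sliding_window", "weighted_average")


@dataclass
class EngineConfig:
    """Configuration of a trial-wise metric engine.

    ``alpha1`` weighs the previous-block mean against the queue mean in
    the weighted-average mean update; ``alpha2`` weighs the previous
    block's subset dispersion against the current block's.  Both default
    to 0.9.  ``queue_length`` is the per-class FIFO length (default 20,
    one block's worth of trials per class).
    """

    variant: str = "weighted_average"
    alpha1: float = 0.9
    alpha2: float = 0.9
    queue_length: int = 20
    subset: SubsetConfig = field(default_factory=SubsetConfig)
    geometry: GeometryConfig = field(default_factory=lambda: DEFAULT_CONFIG)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not (0.0 <= self.alpha1 <= 1.0 and 0.0 <= self.alpha2 <= 1.0):
            raise ValueError("alpha1 and alpha2 must lie in [0, 1]")
        if self.queue_length < self.subset.subset_size:
            raise ValueError("queue_length must be >= subset.subset_size")


def reinforcement_signal(post_trial_metric: float, block_reference: float) -> float:
    """``M'_{k,i} - M_{k-1}``: positive when the metric exceeds the
    previous block's value."""
    return post_trial_metric - block_reference


class _EngineBase:
    """Common plumbing: per-class cached states, metric assembly."""

    def __init__(self, cfg: EngineConfig):
        self.cfg = cfg
        self._states: dict[int, ClassState] = {}

    def _metrics(self) -> tuple[float, float]:
        labels = sorted(self._states)
        if len(labels) != 2:
            raise ValueError("engine needs trials from exactly two classes")
        s1, s2 = self._states[labels[0]], self._states[labels[1]]
        cd = class_distinct_from_states(s1, s2)
        cs = overall_class_stability(
            class_stability(s1.dispersion), class_stability(s2.dispersion)
        )
        return cd, cs

    @property
    def per_class_stability(self) -> dict[int, float]:
        return {c: class_stability(s.dispersion) for c, s in self._states.items()}


class RunningEngine(_EngineBase):
    """Union-of-all-trials engine: exact static recomputation per trial."""

    def __init__(self, cfg: EngineConfig):
        super().__init__(cfg)
        self._trials: dict[int, list[np.ndarray]] = {}

    def seed(self, trial: TrialCovariance) -> None:
        """Add a warm-up trial (block 1) without emitting metrics."""
        self._trials.setdefault(trial.label, []).append(trial.matrix)
        self._refresh(trial.label)

    def _refresh(self, label: int) -> None:
        mats = np.stack(self._trials[label])
        prev = self._states.get(label)
        mean, disp = intraclass_dispersion(
            mats, self.cfg.geometry, init=None if prev is None else prev.mean
        )
        self._states[label] = ClassState(label, mean, disp, n_trials=len(mats))

    def update(self, trial: TrialCovariance) -> tuple[float, float]:
        self.seed(trial)
        return self._metrics()


class SlidingEngine(_EngineBase):
    """Fixed-length most-recent-trial queue per class."""

    def __init__(self, cfg: EngineConfig):
        super().__init__(cfg)
        self._queues: dict[int, deque] = {}

    def queue_contents(self, label: int) -> list[np.ndarray]:
        return list(self._queues.get(label, []))

    def seed(self, trial: TrialCovariance) -> None:
        q = self._queues.setdefault(
            trial.label, deque(maxlen=self.cfg.queue_length)
        )
        q.append(trial.matrix)
        self._refresh(trial.label)

    def _refresh(self, label: int) -> None:
        mats = np.stack(list(self._queues[label]))
        if mats.shape[0] < 2:
            # underflow only becomes an error when metrics are requested
            self._states.pop(label, None)
            return
        prev = self._states.get(label)
        mean, disp = intraclass_dispersion(
            mats, self.cfg.geometry, init=None if prev is None else prev.mean
        )
        self._states[label] = ClassState(label, mean, disp, n_trials=len(mats))

    def update(self, trial: TrialCovariance) -> tuple[float, float]:
        self.seed(trial)
        if len(self._states) != 2:
            raise ValueError("queue underflow: fewer than 2 trials in a class")
        return self._metrics()


class WeightedEngine(_EngineBase):
    """Geodesic mean update + convex dispersion update.

    Must be told when a block starts (:meth:`start_block`) so it can
    freeze the previous block's per-class mean and subset dispersion as
    the anchors of the weighted updates.
    """

    def __init__(self, cfg: EngineConfig):
        super().__init__(cfg)
        self._queues: dict[int, deque] = {}
        self._prev_mean: dict[int, np.ndarray] = {}
        self._prev_disp: dict[int, float] = {}
        self._block_trials: dict[int, list[np.ndarray]] = {}
        self._gamma: dict[int, np.ndarray] = {}

    def seed(self, trial: TrialCovariance) -> None:
        q = self._queues.setdefault(
            trial.label, deque(maxlen=self.cfg.queue_length)
        )
        q.append(trial.matrix)

    def start_block(self, prev_block_trials: dict[int, list[np.ndarray]]) -> None:
        """Freeze previous-block state and reset current-block trial sets."""
        for label, mats in prev_block_trials.items():
            stack = np.stack(mats)
            self._prev_mean[label] = frechet_mean(stack, config=self.cfg.geometry)
            self._prev_disp[label] = subset_dispersion(
                stack, self.cfg.subset, allow_overlap_tail=False,
                config=self.cfg.geometry,
            )
        self._block_trials = {label: [] for label in prev_block_trials}
        self._gamma = {}

    def update(self, trial: TrialCovariance) -> tuple[float, float]:
        if not self._prev_mean:
            raise ValueError("missing previous-block state: call start_block first")
        label = trial.label
        self.seed(trial)
        self._block_trials.setdefault(label, []).append(trial.matrix)
        queue = np.stack(list(self._queues[label]))
        self._gamma[label] = frechet_mean(
            queue, config=self.cfg.geometry, init=self._gamma.get(label)
        )
        for c in self._prev_mean:
            if c in self._gamma:
                post_mean = geodesic_power(
                    self._prev_mean[c], self._gamma[c], self.cfg.alpha1
                )
            else:  # no trial of class c yet in this block and no queue mean
                post_mean = self._prev_mean[c]
            cur = self._block_trials.get(c, [])
            if cur:
                phi_cur = subset_dispersion(
                    np.stack(cur), self.cfg.subset, allow_overlap_tail=True,
                    config=self.cfg.geometry,
                )
            else:
                phi_cur = self._prev_disp[c]
            post_disp = (1 - self.cfg.alpha2) * self._prev_disp[c] + self.cfg.alpha2 * phi_cur
            self._states[c] = ClassState(c, post_mean, post_disp)
        return self._metrics()


def make_engine(cfg: EngineConfig) -> _EngineBase:
    return {
        "running": RunningEngine,
        "sliding_window": SlidingEngine,
        "weighted_average": WeightedEngine,
    }[cfg.variant](cfg)


@dataclass
class ReinforcementTrace:
    """Per-trial reinforcement signals and their per-block sums.

    ``trials`` columns: variant, metric, block, trial, label, post_value,
    reference, signal.  ``block_sums`` columns: variant, metric, block, sum.
    """

    trials: pd.DataFrame
    block_sums: pd.DataFrame

    def to_csv(self, directory, prefix: str = "trace") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(directory / f"{prefix}_trials.csv", index=False)
        self.block_sums.to_csv(directory / f"{prefix}_block_sums.csv", index=False)


def block_reference(
    block_trials: list[TrialCovariance], cfg: EngineConfig
) -> tuple[float, float]:
    """Static (classDistinct, classStability) of a completed block.

    For the weighted-average variant the dispersions are the subset
    dispersions ``Phi*`` (disjoint subsets); the other variants use the
    plain dispersion.
    """
    by_class: dict[int, list[np.ndarray]] = {}
    for t in block_trials:
        by_class.setdefault(t.label, []).append(t.matrix)
    if len(by_class) != 2:
        raise ValueError("block must contain trials from two classes")
    states = {}
    for label, mats in by_class.items():
        stack = np.stack(mats)
        mean, disp = intraclass_dispersion(stack, cfg.geometry)
        if cfg.variant == "weighted_average":
            disp = subset_dispersion(
                stack, cfg.subset, allow_overlap_tail=False, config=cfg.geometry
            )
        states[label] = ClassState(label, mean, disp, n_trials=len(mats))
    labels = sorted(states)
    cd = class_distinct_from_states(states[labels[0]], states[labels[1]])
    cs = overall_class_stability(
        class_stability(states[labels[0]].dispersion),
        class_stability(states[labels[1]].dispersion),
    )
    return cd, cs


def run_session(
    trials: list[TrialCovariance], cfg: EngineConfig
) -> ReinforcementTrace:
    """Run one engine over a multi-block session of trial covariances.

    ``trials`` must be in the chronological order they were performed,
    with ``block`` indices grouping them into completed blocks.  Block 1
    only warms the engine up (there is no previous-block reference);
    every trial of blocks 2..N emits one reinforcement signal per metric.
    """
    blocks = sorted({t.block for t in trials})
    if len(blocks) < 2:
        raise ValueError("session must contain at least two blocks")
    by_block = {b: [t for t in trials if t.block == b] for b in blocks}

    engine = make_engine(cfg)
    for t in by_block[blocks[0]]:
        engine.seed(t)

    rows = []
    for prev_b, b in zip(blocks[:-1], blocks[1:]):
        ref_cd, ref_cs = block_reference(by_block[prev_b], cfg)
        if isinstance(engine, WeightedEngine):
            prev: dict[int, list[np.ndarray]] = {}
            for t in by_block[prev_b]:
                prev.setdefault(t.label, []).append(t.matrix)
            engine.start_block(prev)
        for t in by_block[b]:
            cd, cs = engine.update(t)
            for metric, post, ref in (
                ("classDistinct", cd, ref_cd),
                ("classStability", cs, ref_cs),
            ):
                rows.append(
                    {
                        "variant": cfg.variant,
                        "metric": metric,
                        "block": b,
                        "trial": t.index,
                        "label": t.label,
                        "post_value": post,
                        "reference": ref,
                        "signal": reinforcement_signal(post, ref),
                    }
                )
    trials_df = pd.DataFrame(rows)
    sums = (
        trials_df.groupby(["variant", "metric", "block"], as_index=False)["signal"]
        .sum()
        .rename(columns={"signal": "sum"})
    )
    return ReinforcementTrace(trials=trials_df, block_sums=sums)
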