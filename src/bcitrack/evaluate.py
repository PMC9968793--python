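"""Evaluation battery: do trial-wise reinforcement sums track block-wise change?

Ground truth for a block transition ``k-1 -> k`` is the change in a
block-wise metric (classDistinct, classStability or RWCA) between the two
blocks; the predictor is the per-block sum of a method's trial-wise
reinforcement signals.  Agreement is quantified by

* Spearman rank correlation (simulated corpora) or repeated-measures
  correlation (multi-subject data),
* bootstrap confidence intervals for differences between correlation
  coefficients (Bonferroni-adjusted level),
* ROC / AUC with the sign of the block-wise change as the label and the
  reinforcement sum as the score, methods compared by DeLong's paired test,
* sign-agreement cross-tabulations at the natural threshold of zero,
  methods compared by exact McNemar tests,
* Holm step-down adjustment across each family of pairwise p-values.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pingouin as pg
import scipy.stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.contingency_tables import mcnemar
from statsmodels.stats.multitest import multipletests

from .classifier import classifier_reinforcement, rwca
from .metrics import TrialCovariance, class_distinct, class_stability, intraclass_dispersion, overall_class_stability
from .preprocess import session_covariances
from .session import Session
from .trialwise import EngineConfig, run_session

logger = logging.getLogger("bcitrack")

__all__ = [
    "spearman",
    "rm_corr",
    "bootstrap_corr_diff",
    "roc_auc",
    "delong_test",
    "sign_agreement_table",
    "mcnemar_exact",
    "holm_adjust",
    "block_summaries",
    "session_records",
    "corpus_records",
    "full_report",
]

METRIC_FAMILIES = ("classDistinct", "classStability")


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def spearman(deltas, sums) -> tuple[float, float]:
    """Spearman rank correlation (ties mid-ranked) between block-wise
    changes and reinforcement sums."""
    deltas = np.asarray(deltas, float)
    if np.all(deltas == deltas[0]) or np.all(np.asarray(sums) == np.asarray(sums)[0]):
        raise ValueError("constant input has no rank correlation")
    r, p = scipy.stats.spearmanr(deltas, sums)
    return float(r), float(p)


def rm_corr(df: pd.DataFrame, subject: str = "subject", x: str = "delta", y: str = "sum"):
    """Repeated-measures correlation controlling for between-subject variance.

    Subjects contributing a single record are dropped (logged).  Returns
    the pingouin result row (r, dof, pval, CI95%).
    """
    counts = df[subject].value_counts()
    singletons = counts[counts < 2].index
    if len(singletons):
        logger.info("rm_corr: dropping %d single-record subjects", len(singletons))
        df = df[~df[subject].isin(singletons)]
    if df[subject].nunique() < 2:
        raise ValueError("need at least 2 subjects with >= 2 records each")
    return pg.rm_corr(data=df, x=x, y=y, subject=subject)


def bootstrap_corr_diff(
    records: pd.DataFrame,
    method_a: str,
    method_b: str,
    metric: str,
    n_boot: int = 1000,
    family_size: int = 1,
    unit: str = "session_id",
    rng: np.random.Generator | None = None,
) -> dict:
    """Percentile bootstrap CI for ``r_a - r_b`` (Spearman).

    Resamples whole sessions (or subjects) with replacement, preserving
    the pairing of the two methods on each transition.  The interval is
    at the Bonferroni-adjusted level ``1 - 0.05 / family_size``;
    significance means the interval excludes zero.
    """
    if n_boot < 100:
        import warnings

        warnings.warn("n_boot < 100 gives unstable intervals", stacklevel=2)
    rng = rng or np.random.default_rng(0)
    sub = records[records["metric"] == metric]
    piv = sub.pivot_table(
        index=[unit, "block"], columns="method", values=["delta", "sum"]
    )
    da = piv[("delta", method_a)].to_numpy()
    sa = piv[("sum", method_a)].to_numpy()
    sb = piv[("sum", method_b)].to_numpy()
    units = piv.index.get_level_values(0).to_numpy()
    uniq = np.unique(units)
    groups = {u: np.flatnonzero(units == u) for u in uniq}
    obs = scipy.stats.spearmanr(da, sa)[0] - scipy.stats.spearmanr(da, sb)[0]
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        chosen = rng.choice(uniq, size=len(uniq), replace=True)
        idx = np.concatenate([groups[u] for u in chosen])
        diffs[i] = (
            scipy.stats.spearmanr(da[idx], sa[idx])[0]
            - scipy.stats.spearmanr(da[idx], sb[idx])[0]
        )
    alpha = 0.05 / family_size
    lo, hi = np.percentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return {
        "observed": float(obs),
        "ci": (float(lo), float(hi)),
        "level": 1 - alpha,
        "significant": bool(lo > 0 or hi < 0),
    }


def roc_auc(deltas, sums) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical ROC of predicting ``sign(delta)`` from the sums.

    Returns ``(fpr, tpr, auc)``; the AUC equals the probability that a
    positive-transition sum exceeds a negative-transition one, ties
    counted one half.
    """
    y = (np.asarray(deltas, float) > 0).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("ground truth contains a single class")
    sums = np.asarray(sums, float)
    fpr, tpr, _ = roc_curve(y, sums)
    return fpr, tpr, float(roc_auc_score(y, sums))


def _midrank(x: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(x, method="average")


def delong_test(y_true, scores_a, scores_b) -> tuple[float, tuple[float, float]]:
    """DeLong's paired test for the difference of two correlated AUCs.

    Uses the structural-components (midrank) formulation.  Returns the
    two-sided p-value and the two AUC estimates.  Identical score
    vectors give p = 1.
    """
    y = np.asarray(y_true).astype(bool)
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("need both positive and negative ground truth")
    aucs, v10, v01 = [], [], []
    for s in (np.asarray(scores_a, float), np.asarray(scores_b, float)):
        x, yneg = s[pos], s[neg]
        allr = _midrank(np.concatenate([x, yneg]))
        rx, ry = _midrank(x), _midrank(yneg)
        auc = (allr[:m].sum() - m * (m + 1) / 2) / (m * n)
        v10.append((allr[:m] - rx) / n)
        v01.append(1.0 - (allr[m:] - ry) / m)
        aucs.append(auc)
    v10 = np.vstack(v10)
    v01 = np.vstack(v01)
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var = s10 / m + s01 / n
    l = np.array([1.0, -1.0])
    denom = float(l @ var @ l)
    diff = aucs[0] - aucs[1]
    if denom <= 0:
        p = 1.0 if np.isclose(diff, 0) else 0.0
    else:
        z = diff / np.sqrt(denom)
        p = float(2 * scipy.stats.norm.sf(abs(z)))
    return p, (float(aucs[0]), float(aucs[1]))


def sign_agreement_table(deltas, sums) -> np.ndarray:
    """2x2 cross-tabulation of ``sign(delta)`` (rows: +, -) against
    ``sign(sum)`` (columns: +, -).  Zeros must be excluded beforehand."""
    deltas = np.asarray(deltas, float)
    sums = np.asarray(sums, float)
    if np.any(deltas == 0) or np.any(sums == 0):
        raise ValueError("exclude zero deltas/sums before tabulating")
    dp, sp = deltas > 0, sums > 0
    return np.array(
        [
            [int(np.sum(dp & sp)), int(np.sum(dp & ~sp))],
            [int(np.sum(~dp & sp)), int(np.sum(~dp & ~sp))],
        ]
    )


def mcnemar_exact(correct_a, correct_b) -> float:
    """Exact McNemar test on paired correctness indicators.

    ``b`` counts transitions where only method A agreed in sign, ``c``
    where only method B did; the p-value is the two-sided exact binomial
    test on the discordant pairs.  No discordant pairs gives p = 1.
    """
    a = np.asarray(correct_a, bool)
    b_arr = np.asarray(correct_b, bool)
    if a.shape != b_arr.shape:
        raise ValueError("paired indicators must have equal length")
    b = int(np.sum(a & ~b_arr))
    c = int(np.sum(~a & b_arr))
    if b + c == 0:
        return 1.0
    table = [[0, b], [c, 0]]
    return float(mcnemar(table, exact=True).pvalue)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# corpus orchestration
# ---------------------------------------------------------------------------

def block_summaries(
    covs: list[TrialCovariance],
    session: Session | None = None,
    include_rwca: bool = False,
    epoch_duration: float = 2.0,
) -> pd.DataFrame:
    """Static per-block metrics and block-to-block deltas.

    ``covs`` is the covariance pipeline output for the whole session.
    RWCA (optional, slow: one leave-one-out refit per trial) needs the
    raw session for its preprocessed epochs.
    """
    from .preprocess import FilterSpec, bandpass, epoch_center

    blocks = sorted({c.block for c in covs})
    rows = []
    for b in blocks:
        by_class: dict[int, list[np.ndarray]] = {}
        for c in covs:
            if c.block == b:
                by_class.setdefault(c.label, []).append(c.matrix)
        labels = sorted(by_class)
        if len(labels) != 2:
            raise ValueError(f"block {b} lacks one of the two classes")
        states = {
            lab: intraclass_dispersion(np.stack(by_class[lab])) for lab in labels
        }
        cd = class_distinct(by_class[labels[0]], by_class[labels[1]])
        stab = [class_stability(states[lab][1]) for lab in labels]
        row = {
            "block": b,
            "classDistinct": cd,
            "classStability_c1": stab[0],
            "classStability_c2": stab[1],
            "classStability": overall_class_stability(*stab),
        }
        if include_rwca:
            if session is None:
                raise ValueError("RWCA needs the raw session")
            mask = session.blocks == b
            epochs = epoch_center(
                bandpass(session.trials[mask], session.fs, FilterSpec()),
                session.fs, epoch_duration,
            )
            row["rwca"] = rwca(epochs, session.labels[mask])
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("block").reset_index(drop=True)
    for col in df.columns.drop("block"):
        df[f"delta_{col}"] = df[col].diff()
    return df


DEFAULT_VARIANTS = ("running", "sliding_window", "weighted_average")


def session_records(
    session: Session,
    variants: tuple[str, ...] = DEFAULT_VARIANTS,
    include_classifier: bool = True,
    include_rwca: bool = False,
    alpha1: float = 0.9,
    alpha2: float = 0.9,
    queue_length: int = 20,
) -> pd.DataFrame:
    """Paired (block-wise delta, reinforcement sum) records for one session.

    One row per (block transition, method, metric family).  Metric-based
    methods are paired with the delta of their own metric family; the
    classifier's sums are evaluated against both families.
    """
    covs = session_covariances(session)
    summ = block_summaries(covs, session, include_rwca=include_rwca)
    deltas = summ.set_index("block")
    rows = []

    def add(method: str, metric: str, block: int, total: float) -> None:
        rows.append(
            {
                "session_id": session.session_id,
                "subject": session.meta.get("subject", session.session_id),
                "method": method,
                "metric": metric,
                "block": block,
                "delta": float(deltas.loc[block, f"delta_{metric}"]),
                "sum": float(total),
            }
        )

    for variant in variants:
        cfg = EngineConfig(
            variant=variant, alpha1=alpha1, alpha2=alpha2, queue_length=queue_length
        )
        trace = run_session(covs, cfg)
        for _, r in trace.block_sums.iterrows():
            add(variant, r["metric"], int(r["block"]), r["sum"])
    if include_classifier:
        _, sums = classifier_reinforcement(session)
        for _, r in sums.iterrows():
            for metric in METRIC_FAMILIES:
                add("classifier", metric, int(r["block"]), r["sum"])
    return pd.DataFrame(rows)


def corpus_records(sessions, progress: bool = False, **kwargs) -> pd.DataFrame:
    """Concatenated :func:`session_records` over a corpus."""
    frames = []
    for i, sess in enumerate(sessions):
        frames.append(session_records(sess, **kwargs))
        if progress and (i + 1) % 10 == 0:
            logger.info("evaluated %d/%d sessions", i + 1, len(sessions))
    return pd.concat(frames, ignore_index=True)


def full_report(
    records: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    out_dir=None,
) -> dict:
    """All evaluation statistics for a corpus of paired records.

    Per metric family and method: Spearman correlation, AUC, the 2x2
    sign-agreement table (zero deltas/sums excluded and counted) and the
    diagonal agreement proportion.  Per method pair: DeLong p, exact
    McNemar p (both Holm-adjusted within their family) and the
    Bonferroni-level bootstrap CI for the Spearman difference.  The
    returned dict is JSON-serialisable; ``out_dir`` additionally gets
    ``report.json`` and per-table CSVs.
    """
    rng = np.random.default_rng(seed)
    report: dict = {"config": {"n_boot": n_boot, "seed": seed}, "metrics": {}}
    for metric in sorted(records["metric"].unique()):
        sub = records[records["metric"] == metric]
        methods = sorted(sub["method"].unique())
        piv = sub.pivot_table(
            index=["session_id", "block"], columns="method", values="sum"
        )
        delta = sub.pivot_table(
            index=["session_id", "block"], columns="method", values="delta"
        )[methods[0]]
        entry: dict = {"methods": {}, "pairwise": {}}
        nonzero = delta.to_numpy() != 0
        correctness = {}
        for m in methods:
            s = piv[m].to_numpy()
            r, p = spearman(delta.to_numpy(), s)
            _, _, auc = roc_auc(delta.to_numpy(), s)
            keep = nonzero & (s != 0)
            table = sign_agreement_table(delta.to_numpy()[keep], s[keep])
            correctness[m] = (
                np.sign(delta.to_numpy()) == np.sign(s)
            ) & nonzero & (s != 0)
            entry["methods"][m] = {
                "spearman_r": r,
                "spearman_p": p,
                "auc": auc,
                "sign_table": table.tolist(),
                "agreement": float(np.trace(table) / table.sum()),
                "n_records": int(len(s)),
                "n_zero_excluded": int(len(s) - keep.sum()),
            }
        pairs = [
            (a, b) for i, a in enumerate(methods) for b in methods[i + 1 :]
        ]
        delong_ps, mcnemar_ps = [], []
        for a, b in pairs:
            y = delta.to_numpy() > 0
            dp, _ = delong_test(y, piv[a].to_numpy(), piv[b].to_numpy())
            mp = mcnemar_exact(correctness[a], correctness[b])
            boot = bootstrap_corr_diff(
                sub, a, b, metric, n_boot=n_boot, family_size=len(pairs), rng=rng
            )
            delong_ps.append(dp)
            mcnemar_ps.append(mp)
            entry["pairwise"][f"{a}_vs_{b}"] = {
                "delong_p": dp,
                "mcnemar_p": mp,
                "spearman_diff": boot,
            }
        for key, adj in (
            ("delong_p_holm", holm_adjust(delong_ps)),
            ("mcnemar_p_holm", holm_adjust(mcnemar_ps)),
        ):
            for (a, b), val in zip(pairs, adj):
                entry["pairwise"][f"{a}_vs_{b}"][key] = float(val)
        report["metrics"][metric] = entry
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as f:
            json.dump(report, f, indent=2)
        records.to_csv(out_dir / "records.csv", index=False)
    return report
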