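"""Evaluation statistics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from bcitrack.evaluate import (
    bootstrap_corr_diff,
    delong_test,
    full_report,
    holm_adjust,
    mcnemar_exact,
    rm_corr,
    roc_auc,
    sign_agreement_table,
    spearman,
)


class TestSpearman:
    def test_monotone_and_reversed(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman(x, -np.exp(x))[0] == pytest.approx(-1.0)

    def test_matches_rank_formula(self, rng):
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        # brute force: Pearson correlation of the mid-ranked values
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y)[0] == pytest.approx(oracle, rel=1e-10)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(5), np.arange(5))


class TestRmCorr:
    def test_common_positive_slope_distinct_intercepts(self):
        rows = []
        for s, intercept in enumerate((0.0, 5.0, -3.0)):
            for x in np.linspace(0, 1, 6):
                rows.append({"subject": f"s{s}", "delta": x, "sum": intercept + 2 * x})
        res = rm_corr(pd.DataFrame(rows))
        assert float(res["r"].iloc[0]) == pytest.approx(1.0, abs=1e-6)

    def test_matches_within_subject_centering_oracle(self, rng):
        rows = []
        for s in range(4):
            for _ in range(6):
                rows.append(
                    {
                        "subject": f"s{s}",
                        "delta": rng.standard_normal() + 3 * s,
                        "sum": rng.standard_normal() - 2 * s,
                    }
                )
        df = pd.DataFrame(rows)
        res = rm_corr(df)
        centred = df.copy()
        for col in ("delta", "sum"):
            centred[col] -= centred.groupby("subject")[col].transform("mean")
        oracle = np.corrcoef(centred["delta"], centred["sum"])[0, 1]
        assert float(res["r"].iloc[0]) == pytest.approx(oracle, abs=1e-8)

    def test_zero_slope_noise_near_zero(self, rng):
        rows = [
            {"subject": f"s{s}", "delta": rng.standard_normal(),
             "sum": rng.standard_normal()}
            for s in range(5)
            for _ in range(30)
        ]
        res = rm_corr(pd.DataFrame(rows))
        assert abs(float(res["r"].iloc[0])) < 0.2

    def test_single_record_subject_dropped(self, rng):
        rows = [
            {"subject": "a", "delta": 1.0, "sum": 1.0},
            {"subject": "a", "delta": 2.0, "sum": 2.0},
            {"subject": "b", "delta": 0.0, "sum": 5.0},  # singleton
            {"subject": "c", "delta": 1.0, "sum": 0.0},
            {"subject": "c", "delta": 3.0, "sum": 2.0},
            {"subject": "d", "delta": 0.0, "sum": 4.0},
            {"subject": "d", "delta": 2.0, "sum": 6.0},
        ]
        res = rm_corr(pd.DataFrame(rows))
        assert float(res["r"].iloc[0]) == pytest.approx(1.0, abs=1e-6)


def _paired_records(rng, n=40, effect=0.9):
    """Two methods scored on shared transitions; method_a informative."""
    delta = rng.standard_normal(n)
    rows = []
    for i in range(n):
        sid = f"sess{i}"
        rows.append(
            {"session_id": sid, "block": 2, "method": "a", "metric": "m",
             "delta": delta[i],
             "sum": effect * delta[i] + (1 - effect) * rng.standard_normal()}
        )
        rows.append(
            {"session_id": sid, "block": 2, "method": "b", "metric": "m",
             "delta": delta[i], "sum": rng.standard_normal()}
        )
    return pd.DataFrame(rows)


class TestBootstrap:
    def test_method_vs_itself_contains_zero(self, rng):
        rec = _paired_records(rng)
        rec2 = rec.copy()
        both = pd.concat(
            [rec, rec2.assign(method=rec2["method"].map({"a": "a2", "b": "b2"}))]
        )
        out = bootstrap_corr_diff(both, "a", "a2", "m", n_boot=200, rng=rng)
        lo, hi = out["ci"]
        assert lo <= 0 <= hi

    def test_reproducible_with_fixed_seed(self, rng):
        rec = _paired_records(rng)
        o1 = bootstrap_corr_diff(rec, "a", "b", "m", n_boot=200,
                                 rng=np.random.default_rng(5))
        o2 = bootstrap_corr_diff(rec, "a", "b", "m", n_boot=200,
                                 rng=np.random.default_rng(5))
        assert o1["ci"] == o2["ci"]

    def test_large_effect_excludes_zero(self, rng):
        rec = _paired_records(rng, n=120, effect=0.95)
        out = bootstrap_corr_diff(rec, "a", "b", "m", n_boot=300, rng=rng)
        assert out["significant"]

    def test_small_n_boot_warns(self, rng):
        rec = _paired_records(rng, n=10)
        with pytest.warns(UserWarning, match="n_boot"):
            bootstrap_corr_diff(rec, "a", "b", "m", n_boot=50, rng=rng)


class TestRocAuc:
    def test_perfect_separation(self):
        deltas = np.array([1, 1, 1, -1, -1, -1.0])
        sums = np.array([3, 2, 1, -1, -2, -3.0])
        assert roc_auc(deltas, sums)[2] == 1.0

    def test_matches_pairwise_oracle(self, rng):
        deltas = rng.standard_normal(6)
        sums = rng.standard_normal(6)
        pos = sums[deltas > 0]
        neg = sums[deltas <= 0]
        wins = sum(
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
        )
        oracle = wins / (len(pos) * len(neg))
        assert roc_auc(deltas, sums)[2] == pytest.approx(oracle)

    def test_uninformative_scores_near_half(self, rng):
        deltas = rng.standard_normal(400)
        sums = rng.standard_normal(400)
        assert abs(roc_auc(deltas, sums)[2] - 0.5) < 0.1

    def test_one_class_truth_raises(self):
        with pytest.raises(ValueError, match="single class"):
            roc_auc(np.ones(5), np.arange(5))


class TestDeLong:
    def test_method_vs_itself_p_one(self, rng):
        y = np.array([1, 1, 1, 0, 0, 0])
        s = rng.standard_normal(6)
        p, (a1, a2) = delong_test(y, s, s)
        assert p == 1.0 and a1 == a2

    def test_large_auc_gap_significant(self, rng):
        y = np.r_[np.ones(200), np.zeros(200)]
        good = np.r_[rng.normal(2, 1, 200), rng.normal(0, 1, 200)]
        bad = rng.standard_normal(400)
        p, (a1, a2) = delong_test(y, good, bad)
        assert a1 - a2 > 0.3
        assert p < 1e-3

    def test_matches_structural_component_brute_force(self, rng):
        # independent oracle: psi-kernel double loop instead of midranks
        y = rng.integers(0, 2, 10).astype(bool)
        y[:2] = [True, False]  # both classes present
        sa, sb = rng.standard_normal(10), rng.standard_normal(10)

        def psi(x, yv):
            return 1.0 if x > yv else (0.5 if x == yv else 0.0)

        def components(s):
            pos, neg = s[y], s[~y]
            m, n = len(pos), len(neg)
            v10 = np.array([np.mean([psi(x, q) for q in neg]) for x in pos])
            v01 = np.array([np.mean([psi(x, q) for x in pos]) for q in neg])
            return v10, v01, np.mean(v10)

        va10, va01, auca = components(sa)
        vb10, vb01, aucb = components(sb)
        s10 = np.cov(np.vstack([va10, vb10]))
        s01 = np.cov(np.vstack([va01, vb01]))
        m, n = int(y.sum()), int((~y).sum())
        var = (s10 / m + s01 / n)
        z = (auca - aucb) / np.sqrt(np.array([1, -1]) @ var @ np.array([1, -1]))
        from scipy.stats import norm

        oracle_p = 2 * norm.sf(abs(z))
        p, (a1, a2) = delong_test(y, sa, sb)
        assert a1 == pytest.approx(auca) and a2 == pytest.approx(aucb)
        assert p == pytest.approx(oracle_p, rel=1e-8)


class TestSignTable:
    def test_all_agree_off_diagonal_zero(self):
        deltas = np.array([1, 2, -1, -2.0])
        table = sign_agreement_table(deltas, deltas * 3)
        assert table[0, 1] == 0 and table[1, 0] == 0

    def test_manual_tabulation(self):
        deltas = np.array([1, 1, 1, 1, -1, -1, -1, -1.0])
        sums = np.array([1, 1, -1, -1, 1, -1, -1, -1.0])
        table = sign_agreement_table(deltas, sums)
        assert table.tolist() == [[2, 2], [1, 3]]

    def test_predictor_sign_swap_swaps_columns(self, rng):
        deltas = rng.standard_normal(20)
        sums = rng.standard_normal(20)
        t1 = sign_agreement_table(deltas, sums)
        t2 = sign_agreement_table(deltas, -sums)
        assert np.array_equal(t2, t1[:, ::-1])

    def test_zeros_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            sign_agreement_table([0.0, 1.0], [1.0, 1.0])


class TestMcNemar:
    def test_no_discordance_p_one(self):
        a = np.array([True, True, False])
        assert mcnemar_exact(a, a) == 1.0

    def test_binomial_closed_form(self):
        # 10 discordant pairs all favouring method a: p = 2 * 0.5^10
        a = np.array([True] * 10 + [True] * 5)
        b = np.array([False] * 10 + [True] * 5)
        assert mcnemar_exact(a, b) == pytest.approx(2 * 0.5**10, rel=1e-10)

    def test_balanced_discordance_p_one(self):
        a = np.array([True] * 5 + [False] * 5)
        b = np.array([False] * 5 + [True] * 5)
        assert mcnemar_exact(a, b) == pytest.approx(1.0)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_down_hand_example(self):
        # sorted (0.01, 0.03, 0.04): 0.01*3 = 0.03, 0.03*2 = 0.06,
        # 0.04*1 = 0.04 then monotonicity pushes it up to 0.06
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    def test_equal_ps_scale_by_count(self):
        adj = holm_adjust([0.02, 0.02, 0.02, 0.02])
        assert np.allclose(adj, np.minimum(1.0, 4 * 0.02))

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=8)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestFullReport:
    def _records(self, rng):
        return _paired_records(rng, n=30).assign(metric="classDistinct")

    def test_keys_and_internal_consistency(self, rng):
        rec = self._records(rng)
        rep = full_report(rec, n_boot=100, seed=1)
        entry = rep["metrics"]["classDistinct"]
        assert set(entry["methods"]) == {"a", "b"}
        ma = entry["methods"]["a"]
        assert sum(sum(r) for r in ma["sign_table"]) + ma["n_zero_excluded"] == ma[
            "n_records"
        ]
        assert "a_vs_b" in entry["pairwise"]

    def test_deterministic_given_seed(self, rng):
        rec = self._records(rng)
        r1 = full_report(rec, n_boot=100, seed=2)
        r2 = full_report(rec, n_boot=100, seed=2)
        assert r1 == r2

    def test_statistics_match_operation_level_recomputation(self, rng):
        rec = self._records(rng)
        rep = full_report(rec, n_boot=100, seed=3)
        sub = rec[rec["method"] == "a"]
        r, _ = spearman(sub["delta"], sub["sum"])
        assert rep["metrics"]["classDistinct"]["methods"]["a"][
            "spearman_r"
        ] == pytest.approx(r)
        _, _, auc = roc_auc(sub["delta"].to_numpy(), sub["sum"].to_numpy())
        assert rep["metrics"]["classDistinct"]["methods"]["a"]["auc"] == pytest.approx(auc)

    def test_report_written_to_disk(self, rng, tmp_path):
        full_report(self._records(rng), n_boot=100, seed=1, out_dir=tmp_path)
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "records.csv").exists()
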