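import numpy as np
import pandas as pd
import pytest

from tbal.evaluate import (auprc, auroc, bootstrap_ci, confusion_metrics,
                           metric_report, subgroup_report, temporal_curve)


def auroc_oracle(scores, labels):
    """Brute-force pair counting with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def auprc_oracle(scores, labels):
    """Threshold sweep over unique scores: AP = sum (R_i - R_{i-1}) P_i."""
    thresholds = np.unique(scores)[::-1]
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for thr in thresholds:
        pred = scores >= thr
        tp = int((pred & (labels == 1)).sum())
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestAUROC:
    def test_pair_enumeration_example(self):
        assert auroc(np.array([0.9, 0.2, 0.8]), np.array([1, 1, 0])) == 0.5

    def test_perfect_separation(self):
        assert auroc(np.array([0.9, 0.8, 0.2]), np.array([1, 1, 0])) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auroc(np.full(6, 0.4), np.array([1, 0, 1, 0, 1, 0])) == 0.5

    def test_single_class_undefined(self):
        assert np.isnan(auroc(np.array([0.1, 0.9]), np.array([1, 1])))

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(5, 80)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 2)   # induce ties
            assert auroc(s, y) == pytest.approx(auroc_oracle(s, y),
                                                abs=1e-12)


class TestAUPRC:
    def test_hand_swept_two_points(self):
        assert auprc(np.array([0.2, 0.9]), np.array([1, 0])) == 0.5

    def test_perfect_ranking(self):
        assert auprc(np.array([0.9, 0.8, 0.1]), np.array([1, 1, 0])) == 1.0

    def test_no_positives_undefined(self):
        assert np.isnan(auprc(np.array([0.5]), np.array([0])))

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(1)
        n, pi = 20000, 0.15
        y = (rng.random(n) < pi).astype(int)
        s = rng.random(n)
        assert auprc(s, y) == pytest.approx(pi, abs=0.02)

    def test_matches_threshold_sweep_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = rng.integers(5, 80)
            y = rng.integers(0, 2, n)
            if y.sum() == 0:
                continue
            s = np.round(rng.random(n), 2)
            assert auprc(s, y) == pytest.approx(auprc_oracle(s, y),
                                                abs=1e-12)


class TestConfusion:
    def test_perfect_separation_all_ones(self):
        out = confusion_metrics(np.array([0.9, 0.8, 0.2, 0.1]),
                                np.array([1, 1, 0, 0]), 0.5)
        assert out["accuracy"] == 1.0 and out["f1"] == 1.0

    def test_undefined_precision_flagged_not_zero(self):
        out = confusion_metrics(np.array([0.1, 0.2]), np.array([1, 0]), 0.5)
        assert np.isnan(out["precision"])
        assert out["recall"] == 0.0
        assert "precision" in out["undefined"]

    def test_formula_plugin(self):
        # TP=3, FP=1, FN=1, TN=0
        scores = np.array([0.9, 0.9, 0.9, 0.9, 0.1])
        labels = np.array([1, 1, 1, 0, 1])
        out = confusion_metrics(scores, labels, 0.5)
        assert out["precision"] == 0.75
        assert out["recall"] == 0.75
        assert out["f1"] == pytest.approx(0.75)

    def test_matches_direct_counting(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = rng.integers(4, 60)
            y = rng.integers(0, 2, n)
            s = rng.random(n)
            out = confusion_metrics(s, y, 0.5)
            pred = (s >= 0.5).astype(int)
            assert out["tp"] == int(((pred == 1) & (y == 1)).sum())
            assert out["accuracy"] == pytest.approx((pred == y).mean())


class TestBootstrap:
    def test_single_group_zero_width(self):
        s = np.array([0.9, 0.1, 0.8, 0.3])
        y = np.array([1, 0, 1, 0])
        lo, hi, _ = bootstrap_ci(s, y, ["g"] * 4, auroc, n_boot=50, seed=0)
        assert lo == hi == auroc(s, y)

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(4)
        for trial in range(40):
            n = 40
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = rng.random(n) + 0.3 * y
            lo, hi, _ = bootstrap_ci(s, y, np.arange(n), auroc, n_boot=200,
                                     seed=trial)
            point = auroc(s, y)
            assert lo <= point <= hi

    def test_seeded_ci_identical(self):
        rng = np.random.default_rng(5)
        s, y = rng.random(30), rng.integers(0, 2, 30)
        g = np.arange(30) // 3
        a = bootstrap_ci(s, y, g, auroc, n_boot=100, seed=7)
        b = bootstrap_ci(s, y, g, auroc, n_boot=100, seed=7)
        assert a == b

    def test_single_class_replicates_dropped_and_counted(self):
        s = np.array([0.9, 0.1])
        y = np.array([1, 0])
        _, _, dropped = bootstrap_ci(s, y, ["a", "b"], auroc, n_boot=100,
                                     seed=0)
        assert dropped > 0     # replicates drawing one group twice


class TestTemporalCurve:
    def _preds(self):
        rows = []
        rng = np.random.default_rng(6)
        for trig in (4.0, 8.0, 12.0):
            for i in range(40):
                y = int(i < 6)
                sep = {4.0: 0.1, 8.0: 0.6, 12.0: 3.0}[trig]
                rows.append({"stay_id": f"s{i}", "trigger_h": trig,
                             "label": y,
                             "risk": 1 / (1 + np.exp(-(sep * y +
                                                       rng.normal())))})
        return pd.DataFrame(rows)

    def test_late_triggers_more_separable(self):
        curve = temporal_curve(self._preds(), n_boot=0)
        a = curve.set_index("trigger_h")["auroc"]
        assert a[4.0] < a[12.0]
        assert a[12.0] > 0.95

    def test_single_class_stratum_flagged(self):
        df = self._preds()
        df.loc[df["trigger_h"] == 8.0, "label"] = 0
        curve = temporal_curve(df, n_boot=0)
        row = curve[curve["trigger_h"] == 8.0].iloc[0]
        assert not row["defined"] and np.isnan(row["auroc"])

    def test_strata_partition_pooled_count(self):
        df = self._preds()
        curve = temporal_curve(df, n_boot=0)
        assert curve["n"].sum() == len(df)


class TestSubgroups:
    def _preds_meta(self):
        rng = np.random.default_rng(7)
        n = 120
        stays = pd.DataFrame({
            "stay_id": [f"s{i}" for i in range(n)],
            "patient_id": [f"p{i}" for i in range(n)],
            "icu_los_h": 48.0,
            "death_time_h": np.nan,
            "age_years": rng.integers(30, 81, n),
            "sex": rng.choice(["female", "male"], n),
            "race": rng.choice(["white", "black"], n),
        })
        y = rng.integers(0, 2, n)
        preds = pd.DataFrame({"stay_id": stays["stay_id"], "label": y,
                              "risk": rng.random(n) + 0.4 * y,
                              "trigger_h": 12.0})
        return preds, stays

    def test_counts_sum_to_cohort(self):
        preds, stays = self._preds_meta()
        rep = subgroup_report(preds, stays, n_boot=0)
        age = rep[rep["factor"] == "age"]
        assert age["n"].sum() == len(preds)
        sex = rep[rep["factor"] == "sex"]
        assert sex["n"].sum() == len(preds)

    def test_age_sixty_five_in_upper_stratum(self):
        preds, stays = self._preds_meta()
        stays["age_years"] = 65
        rep = subgroup_report(preds, stays, n_boot=0)
        age = rep[rep["factor"] == "age"].set_index("level")
        assert age.loc[">=65", "n"] == len(preds)
        assert age.loc["<65", "note"] == "empty stratum omitted"

    def test_exchangeable_strata_have_overlapping_cis(self):
        preds, stays = self._preds_meta()
        rep = subgroup_report(preds, stays, n_boot=200, seed=0)
        sex = rep[rep["factor"] == "sex"].set_index("level")
        lo = sex["auroc_lo"]
        hi = sex["auroc_hi"]
        levels = list(sex.index)
        assert lo[levels[0]] <= hi[levels[1]]
        assert lo[levels[1]] <= hi[levels[0]]


class TestMetricReport:
    def test_ci_brackets_point_and_counts(self):
        rng = np.random.default_rng(8)
        n = 80
        y = rng.integers(0, 2, n)
        s = rng.random(n) + 0.5 * y
        rep = metric_report(s, y, np.arange(n) // 2, n_boot=100, seed=0)
        lo, hi = rep.ci["auroc"]
        assert lo <= rep.auroc <= hi
        assert rep.n_pos + rep.n_neg == n
        frame = rep.to_frame()
        assert set(frame["metric"]) == {"auroc", "auprc", "accuracy",
                                        "recall", "precision", "f1"}
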