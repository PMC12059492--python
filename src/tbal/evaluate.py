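"""Discrimination metrics, cluster-bootstrap CIs, temporal / subgroup /
cross-cohort analyses.

AUROC is the Mann-Whitney concordance probability (ties credited 1/2);
AUPRC is the average-precision step sum.  Confidence intervals use a
**cluster bootstrap**: whole stays are resampled with replacement, because
the timepoints of one stay are strongly dependent — resampling individual
timepoints would understate the variance.  For static tasks (one example
per stay) this degenerates to the ordinary case bootstrap.

Thresholded metrics (accuracy, recall, precision, F1) use a configurable
decision threshold, 0.5 by default.  Degenerate strata (single class, empty
denominator) are flagged as undefined rather than silently reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC; NaN when only one class is present."""
    y = np.asarray(labels).astype(int)
    if y.min() == y.max():
        return float("nan")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average-precision AUPRC; NaN when no positives are present."""
    y = np.asarray(labels).astype(int)
    if y.sum() == 0:
        return float("nan")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def confusion_metrics(scores: np.ndarray, labels: np.ndarray,
                      threshold: float = 0.5) -> dict:
    """Accuracy/recall/precision/F1 at ``score >= threshold``.

    Undefined ratios (zero denominator) are reported as NaN and listed under
    the ``"undefined"`` key.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    undefined = []
    accuracy = (tp + tn) / max(len(y), 1)
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    if not (tp + fn):
        undefined.append("recall")
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    if not (tp + fp):
        undefined.append("precision")
    if np.isnan(recall) or np.isnan(precision) or (precision + recall) == 0:
        f1 = float("nan")
        undefined.append("f1")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "recall": recall, "precision": precision,
            "f1": f1, "tp": tp, "tn": tn, "fp": fp, "fn": fn,
            "threshold": threshold, "undefined": undefined}


# ---------------------------------------------------------------------------
# cluster bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(scores: np.ndarray, labels: np.ndarray,
                 group_ids: Sequence, metric_fn: Callable,
                 n_boot: int = 1000, seed: int = 0
                 ) -> tuple[float, float, int]:
    """95% CI by resampling groups (stays) with replacement.

    Replicates where the metric is undefined (single class) are dropped;
    their count is returned as the third element.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    groups = np.asarray(group_ids)
    uniq, inv = np.unique(groups, return_inverse=True)
    members = [np.flatnonzero(inv == g) for g in range(len(uniq))]
    rng = np.random.default_rng(seed)
    stats = []
    dropped = 0
    for _ in range(n_boot):
        pick = rng.integers(0, len(uniq), size=len(uniq))
        idx = np.concatenate([members[g] for g in pick])
        val = metric_fn(scores[idx], labels[idx])
        if np.isnan(val):
            dropped += 1
            continue
        stats.append(val)
    if not stats:
        return float("nan"), float("nan"), dropped
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi), dropped


@dataclass
class MetricReport:
    """Point estimates with cluster-bootstrap CIs for one example set."""

    auroc: float
    auprc: float
    accuracy: float
    recall: float
    precision: float
    f1: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_pos: int = 0
    n_neg: int = 0
    threshold: float = 0.5

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in ("auroc", "auprc", "accuracy", "recall", "precision", "f1"):
            lo, hi = self.ci.get(m, (float("nan"), float("nan")))
            rows.append({"metric": m, "value": getattr(self, m),
                         "ci_lower": lo, "ci_upper": hi})
        return pd.DataFrame(rows)


def metric_report(scores, labels, group_ids, threshold: float = 0.5,
                  n_boot: int = 1000, seed: int = 0,
                  ci_metrics: Sequence[str] = ("auroc", "auprc")
                  ) -> MetricReport:
    """Full metric panel with bootstrap CIs for the requested metrics."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    conf = confusion_metrics(scores, labels, threshold)
    report = MetricReport(
        auroc=auroc(scores, labels), auprc=auprc(scores, labels),
        accuracy=conf["accuracy"], recall=conf["recall"],
        precision=conf["precision"], f1=conf["f1"],
        n_pos=int(labels.sum()), n_neg=int((1 - labels).sum()),
        threshold=threshold,
    )
    fns = {"auroc": auroc, "auprc": auprc,
           "accuracy": lambda s, y: confusion_metrics(s, y, threshold)[
               "accuracy"],
           "f1": lambda s, y: confusion_metrics(s, y, threshold)["f1"],
           "recall": lambda s, y: confusion_metrics(s, y, threshold)[
               "recall"],
           "precision": lambda s, y: confusion_metrics(s, y, threshold)[
               "precision"]}
    if n_boot:
        for i, m in enumerate(ci_metrics):
            lo, hi, _ = bootstrap_ci(scores, labels, group_ids, fns[m],
                                     n_boot=n_boot, seed=seed + i)
            report.ci[m] = (lo, hi)
    return report


# ---------------------------------------------------------------------------
# temporal and subgroup analyses
# ---------------------------------------------------------------------------

def temporal_curve(predictions: pd.DataFrame, stride_h: float = 4.0,
                   n_boot: int = 200, seed: int = 0) -> pd.DataFrame:
    """Per-trigger-time metrics for dynamic predictions.

    ``predictions`` needs columns stay_id, trigger_h, risk, label.  Only
    triggers at multiples of ``stride_h`` enter the curve.  Strata with a
    single class are flagged undefined instead of being dropped.
    """
    df = predictions.copy()
    on_mark = np.isclose(np.mod(df["trigger_h"].to_numpy(float), stride_h),
                         0.0)
    df = df[on_mark]
    rows = []
    for trig, grp in df.groupby("trigger_h", sort=True):
        y = grp["label"].to_numpy(int)
        s = grp["risk"].to_numpy(float)
        defined = 0 < y.sum() < y.size
        row = {"trigger_h": float(trig), "n": len(grp),
               "n_pos": int(y.sum()), "defined": bool(defined),
               "auroc": auroc(s, y), "auprc": auprc(s, y)}
        if defined and n_boot:
            lo, hi, _ = bootstrap_ci(s, y, grp["stay_id"].to_numpy(), auroc,
                                     n_boot=n_boot, seed=seed)
            row["auroc_lo"], row["auroc_hi"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)


def subgroup_report(predictions: pd.DataFrame, stays: pd.DataFrame,
                    age_cut: int = 65, n_boot: int = 200,
                    seed: int = 0) -> pd.DataFrame:
    """Metrics per demographic stratum (age < cut / >= cut, sex, race).

    ``predictions`` needs stay_id, risk, label; demographic columns come
    from the stays table.  Empty strata are omitted with a note row.
    """
    meta = stays.set_index(stays["stay_id"].astype(str))
    df = predictions.copy()
    df["stay_id"] = df["stay_id"].astype(str)
    df["age"] = meta["age_years"].reindex(df["stay_id"]).to_numpy()
    df["sex"] = meta["sex"].reindex(df["stay_id"]).to_numpy()
    df["race"] = meta["race"].reindex(df["stay_id"]).to_numpy()
    strata: list[tuple[str, str, pd.DataFrame]] = [
        ("age", f"<{age_cut}", df[df["age"] < age_cut]),
        ("age", f">={age_cut}", df[df["age"] >= age_cut]),
    ]
    for level, grp in df.groupby("sex", sort=True):
        strata.append(("sex", str(level), grp))
    for level, grp in df.groupby("race", sort=True):
        strata.append(("race", str(level), grp))
    rows = []
    for factor, level, grp in strata:
        if grp.empty:
            rows.append({"factor": factor, "level": level, "n": 0,
                         "note": "empty stratum omitted"})
            continue
        y = grp["label"].to_numpy(int)
        s = grp["risk"].to_numpy(float)
        row = {"factor": factor, "level": level, "n": len(grp),
               "n_pos": int(y.sum()), "auroc": auroc(s, y),
               "auprc": auprc(s, y), "note": ""}
        if 0 < y.sum() < y.size and n_boot:
            lo, hi, _ = bootstrap_ci(s, y, grp["stay_id"].to_numpy(), auroc,
                                     n_boot=n_boot, seed=seed)
            row["auroc_lo"], row["auroc_hi"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-cohort transfer
# ---------------------------------------------------------------------------

def cross_cohort(model, stats, cohort_b, task, common_vars: Sequence[str],
                 stride_h: float = 4.0, n_boot: int = 200,
                 seed: int = 0) -> MetricReport:
    """Evaluate a common-variable model trained on cohort A against cohort B.

    The model must have been trained on features derived from
    ``common_vars`` only (a model trained on a wider set cannot score a
    narrower one), and cohort A's normalization statistics are applied to
    cohort B's events — exactly the deployment situation the transfer
    experiment emulates.
    """
    from tbal.data_model import restrict_variables
    from tbal.model import predict_risks
    from tbal.preprocess import feature_layout, preprocess_cohort
    from tbal.tasks import make_dynamic_labels, make_static_labels

    if not list(common_vars):
        raise ValueError("common variable set is empty")
    restricted = restrict_variables(cohort_b, common_vars)
    expected_names, _ = feature_layout(restricted.dictionary)
    if list(model.feature_names) != expected_names:
        raise ValueError(
            "model features do not match the common-variable layout; train "
            "the transfer model on the restricted dictionary")
    prep = preprocess_cohort(restricted, stats=stats)
    if task.kind == "dynamic":
        labels = make_dynamic_labels(restricted, task, prep.grids())
        on_mark = np.isclose(
            np.mod(labels["trigger_h"].to_numpy(float), stride_h), 0.0)
        labels = labels[on_mark].reset_index(drop=True)
    else:
        labels = make_static_labels(restricted, task)
    risks = predict_risks(model, prep.encoded, labels)
    ok = np.isfinite(risks)
    return metric_report(risks[ok], labels["label"].to_numpy(int)[ok],
                         labels["stay_id"].to_numpy()[ok],
                         n_boot=n_boot, seed=seed)
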