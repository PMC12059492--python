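"""Integrated-gradients attribution for sequence risk predictions.

For a model output F and an input prefix x, integrated gradients attribute
the difference F(x) - F(x') to individual input entries by integrating the
gradient along the straight path from a baseline x' to x.  The integral is
approximated with an m-term right-Riemann sum:

    IG_i = (x_i - x'_i) * (1/m) * sum_{k=1..m} dF(x' + (k/m)(x - x'))/dx_i

The default baseline is the all-zeros tensor, which is meaningful here
because continuous channels are z-scored and categorical channels one-hot
encoded; an all-"missing" categorical baseline is available as an
alternative for sensitivity analysis.  The completeness axiom
(sum IG = F(x) - F(x')) is tracked per map as ``completeness_gap`` and
shrinks as m grows.

Attribution is computed per trigger on exactly the prefix the model saw, so
it inherits the model's causality guarantee.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from tbal import _nn
from tbal.model import TBALModel
from tbal.preprocess import EncodedStay

#: value-and-gradient oracle: X (B, T, F) -> (F(X) (B,), dF/dX (B, T, F))
ValueGradFn = Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]


@dataclass
class AttributionMap:
    """Per-timepoint, per-feature attribution for one prediction."""

    stay_id: str
    trigger_h: float
    IG: np.ndarray                 # (T, F) on the encoded-input scale
    completeness_gap: float        # |sum IG - (F(x) - F(x'))|
    m_steps: int
    fx: float                      # model output at the input
    fx_baseline: float             # model output at the baseline


def integrated_gradients_fn(value_grad_fn: ValueGradFn, x: np.ndarray,
                            baseline: np.ndarray | None = None,
                            m_steps: int = 50) -> tuple[np.ndarray, float,
                                                        float, float]:
    """Core right-Riemann IG for any differentiable scalar-output function.

    Returns ``(IG, completeness_gap, fx, fx_baseline)``.
    """
    x = np.asarray(x, dtype=float)
    if baseline is None:
        baseline = np.zeros_like(x)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != x.shape:
        raise ValueError("baseline and input shapes differ")
    if m_steps < 1:
        raise ValueError("m_steps must be >= 1")
    ks = (np.arange(1, m_steps + 1) / m_steps)      # right-Riemann nodes
    path = baseline[None] + ks[:, None, None] * (x - baseline)[None]
    values, grads = value_grad_fn(path)
    if not np.isfinite(grads).all():
        bad = int(np.flatnonzero(
            ~np.isfinite(grads).reshape(m_steps, -1).all(axis=1))[0])
        raise FloatingPointError(
            f"non-finite gradient at path step {bad + 1}/{m_steps}")
    avg_grad = grads.mean(axis=0)
    IG = (x - baseline) * avg_grad
    f_ends, _ = value_grad_fn(np.stack([baseline, x]))
    fx_baseline, fx = float(f_ends[0]), float(f_ends[1])
    gap = abs(float(IG.sum()) - (fx - fx_baseline))
    return IG, gap, fx, fx_baseline


def _model_value_grad(model: TBALModel, tau: np.ndarray) -> ValueGradFn:
    """Probability output and its input gradient for a batch of path points."""
    def fn(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        B, T, _ = X.shape
        lengths = np.full(B, T)
        taus = np.broadcast_to(tau, (B, T))
        prob, _, cache = _nn.forward(model.params, model.config, X, lengths,
                                     tau=taus)
        dlogit = prob * (1.0 - prob)        # d prob / d logit
        grads = _nn.backward(model.params, model.config, cache, dlogit)
        return prob, grads["_input"]
    return fn


def missing_baseline(encoded: EncodedStay, T: int) -> np.ndarray:
    """All-zeros baseline with every categorical 'missing' level set to 1."""
    base = np.zeros((T, encoded.F))
    for j, name in enumerate(encoded.feature_names):
        if name.endswith("=missing"):
            base[:, j] = 1.0
    return base


def integrated_gradients(model: TBALModel, encoded: EncodedStay,
                         trigger_h: float, baseline: np.ndarray | str | None
                         = None, m_steps: int = 50) -> AttributionMap:
    """Attribution map for one (stay, trigger) prediction.

    ``baseline`` may be an array, ``None`` (all zeros), or the string
    ``"missing"`` for the all-missing-category categorical baseline.
    """
    from tbal.model import apply_context_window
    grid = np.asarray(encoded.grid_h, dtype=float)
    pos = int(np.searchsorted(grid, trigger_h, side="right"))
    if pos == 0:
        raise ValueError(f"trigger {trigger_h} precedes the stay grid")
    x, tau = apply_context_window(encoded.Z[:pos], trigger_h - grid[:pos],
                                  model.config.max_context_h)
    if isinstance(baseline, str):
        if baseline != "missing":
            raise ValueError(f"unknown baseline {baseline!r}")
        baseline = missing_baseline(encoded, pos)
    IG, gap, fx, fx0 = integrated_gradients_fn(
        _model_value_grad(model, tau), x, baseline, m_steps)
    return AttributionMap(stay_id=encoded.stay_id, trigger_h=float(trigger_h),
                          IG=IG, completeness_gap=gap, m_steps=m_steps,
                          fx=fx, fx_baseline=fx0)


# ---------------------------------------------------------------------------
# population ranking and per-stay report
# ---------------------------------------------------------------------------

def rank_features(maps: Sequence[AttributionMap], feature_names: Sequence[str],
                  feature_parent: Sequence[str]) -> pd.DataFrame:
    """Global ranking: mean |IG| per channel, summed into parent variables.

    One-hot levels, mask channels, and interval channels all contribute to
    their parent clinical variable.  Rows are sorted by descending score with
    lexicographic tie-breaks.
    """
    if not maps:
        raise ValueError("no attribution maps given")
    F = len(feature_names)
    total = np.zeros(F)
    count = 0
    for amap in maps:
        if amap.IG.shape[1] != F:
            raise ValueError("attribution maps have mismatched layouts")
        total += np.abs(amap.IG).sum(axis=0)
        count += amap.IG.shape[0]
    channel_score = total / max(count, 1)
    df = pd.DataFrame({"channel": list(feature_names),
                       "parent": list(feature_parent),
                       "score": channel_score})
    ranked = (df.groupby("parent", sort=False)["score"].sum()
              .reset_index().rename(columns={"parent": "variable",
                                             "score": "mean_abs_ig"}))
    ranked = ranked.sort_values(["mean_abs_ig", "variable"],
                                ascending=[False, True],
                                kind="mergesort").reset_index(drop=True)
    return ranked


def stay_report(maps: Sequence[AttributionMap], encoded: EncodedStay,
                top_k: int = 20) -> dict[str, pd.DataFrame]:
    """Time-resolved per-stay report across sorted triggers.

    Returns three aligned tables: the risk trajectory per trigger, the
    top-k variable x trigger attribution matrix (signed IG summed over
    member channels and prefix timesteps), and the top-k variable x grid-time
    normalized-value matrix (z-scored numerics; categorical level index
    scaled to [0, 1]).
    """
    maps = sorted(maps, key=lambda a: a.trigger_h)
    if not maps:
        raise ValueError("no attribution maps given")
    names = encoded.feature_names
    parents = encoded.feature_parent
    ranked = rank_features(maps, names, parents)
    if top_k > len(ranked):
        warnings.warn(f"top_k={top_k} exceeds {len(ranked)} variables; "
                      "clipping", stacklevel=2)
        top_k = len(ranked)
    top_vars = ranked["variable"].head(top_k).tolist()

    risk = pd.DataFrame({
        "trigger_h": [a.trigger_h for a in maps],
        "risk": [a.fx for a in maps],
    })

    parent_arr = np.asarray(parents, dtype=object)
    ig_rows = {}
    for var in top_vars:
        sel = parent_arr == var
        ig_rows[var] = [float(a.IG[:, sel].sum()) for a in maps]
    ig_matrix = pd.DataFrame(ig_rows,
                             index=[a.trigger_h for a in maps]).T
    ig_matrix.index.name = "variable"

    value_rows = {}
    for var in top_vars:
        idx = [j for j, (n, p) in enumerate(zip(names, parents))
               if p == var and not n.startswith(("mask:", "dt:"))]
        block = encoded.Z[:, idx]
        if len(idx) == 1:                      # numeric: the z-scored value
            value_rows[var] = block[:, 0]
        else:                                  # categorical: level index
            value_rows[var] = block.argmax(axis=1) / max(len(idx) - 1, 1)
    value_matrix = pd.DataFrame(value_rows, index=encoded.grid_h).T
    value_matrix.index.name = "variable"

    return {"risk": risk, "ig": ig_matrix, "values": value_matrix}


def attribution_table(maps: Sequence[AttributionMap],
                      encoded: dict[str, EncodedStay]) -> pd.DataFrame:
    """Long-format export: one row per (stay, trigger, grid time, channel)."""
    rows = []
    for amap in maps:
        enc = encoded[amap.stay_id]
        T = amap.IG.shape[0]
        for t in range(T):
            for j, name in enumerate(enc.feature_names):
                rows.append((amap.stay_id, amap.trigger_h,
                             float(enc.grid_h[t]), name,
                             float(amap.IG[t, j])))
    return pd.DataFrame(rows, columns=["stay_id", "trigger_h", "grid_h",
                                       "feature", "ig"])
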