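"""Irregular event streams -> aligned model tensors.

The pipeline for one stay is::

    resample -> drop_empty_bins -> compute_delta -> impute -> encode

* **resample** discretizes the timeline into 1-hour bins anchored at ICU
  admission; bin *t* collects raw observations with time in ``[t-0.5, t+0.5)``
  (bin 0 uses ``[0, 0.5)``) and collapses them with the dictionary's
  aggregation rule.  The binary mask ``M[t, d]`` records whether any raw
  observation fell in bin *t* for variable *d*.
* **drop_empty_bins** removes grid times where no variable was observed;
  surviving grid times keep their original hour values, so the grid may be
  non-uniform afterwards.
* **compute_delta** builds the time-since-last-observation matrix with the
  standard missing-data recurrence: ``delta[0, d] = 0`` and
  ``delta[t, d] = (s_t - s_{t-1}) + (0 if observed at t-1 else delta[t-1, d])``.
* **impute** completes the value matrix: leading gaps carry the stay's
  earliest observation backward; interior numeric gaps are linearly
  interpolated in real time, trailing numeric gaps carry the last observation
  forward; interior and trailing categorical gaps become the explicit
  ``"missing"`` category; variables never observed in a stay take the
  training-set median/mode fallback.  Masks and deltas are never altered.
* **encode** z-scores numerics with training-split statistics, one-hot encodes
  categoricals (including the ``"missing"`` level), and appends one mask
  channel and one scaled interval channel (delta / 24 h) per variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from tbal.data_model import Cohort, VariableSpec

EPS_SD = 1e-6
INTERVAL_SCALE_H = 24.0


class EmptyStayError(ValueError):
    """Every bin of a stay is empty; the stay is unusable."""


@dataclass
class AlignedStay:
    """Hourly-aligned tensors for one stay (values still on the raw scale)."""

    stay_id: str
    variables: list[str]
    grid_h: np.ndarray                 # (T,) strictly increasing hours
    X: pd.DataFrame                    # (T, D) raw values; NaN/None = absent
    M: np.ndarray                      # (T, D) uint8 observation mask
    Delta: np.ndarray | None = None    # (T, D) hours since last observation
    dropped_bins: list[float] = field(default_factory=list)

    @property
    def T(self) -> int:
        return len(self.grid_h)


@dataclass
class EncodedStay:
    """Model-ready input matrix for one stay."""

    stay_id: str
    Z: np.ndarray                      # (T, F) float
    feature_names: list[str]
    feature_parent: list[str]          # parent clinical variable per channel
    grid_h: np.ndarray

    @property
    def T(self) -> int:
        return len(self.grid_h)

    @property
    def F(self) -> int:
        return self.Z.shape[1]


@dataclass
class NormalizationStats:
    """Training-split summaries used for encoding and fallbacks."""

    mean: dict[str, float]
    sd: dict[str, float]
    fallback: dict[str, object]
    interval_scale: float = INTERVAL_SCALE_H

    def save(self, path: str | Path) -> None:
        payload = {
            "mean": {k: float(v) for k, v in self.mean.items()},
            "sd": {k: float(v) for k, v in self.sd.items()},
            "fallback": {k: (float(v) if isinstance(v, (int, float, np.floating))
                             else str(v))
                         for k, v in self.fallback.items()},
            "interval_scale": float(self.interval_scale),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "NormalizationStats":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(
            mean=dict(payload["mean"]),
            sd=dict(payload["sd"]),
            fallback=dict(payload["fallback"]),
            interval_scale=float(payload.get("interval_scale",
                                             INTERVAL_SCALE_H)),
        )


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _mode_recent(values: np.ndarray, times: np.ndarray):
    """Mode with ties broken toward the most recently observed value."""
    counts: dict = {}
    last_seen: dict = {}
    for v, t in zip(values, times):
        counts[v] = counts.get(v, 0) + 1
        last_seen[v] = t
    best = max(counts.items(), key=lambda kv: (kv[1], last_seen[kv[0]]))
    return best[0]


def resample(events: pd.DataFrame, spec_by_var: Mapping[str, VariableSpec],
             los_h: float) -> AlignedStay:
    """Hourly discretization with per-dictionary aggregation (X and M only).

    ``events`` must belong to a single stay.  The grid spans integer hours
    ``0 .. floor(los_h)``; observations landing past the last bin's edge are
    discarded.
    """
    variables = list(spec_by_var)
    T = int(np.floor(los_h)) + 1
    grid = np.arange(T, dtype=float)
    X = pd.DataFrame(np.full((T, len(variables)), np.nan, dtype=object),
                     columns=variables)
    M = np.zeros((T, len(variables)), dtype=np.uint8)

    if len(events):
        stay_ids = events["stay_id"].unique()
        if len(stay_ids) > 1:
            raise ValueError(f"events from multiple stays: {stay_ids[:3]}")
        times = events["time_h"].to_numpy(dtype=float)
        bins = np.floor(times + 0.5).astype(int)   # half-open [t-0.5, t+0.5)
        ok = bins <= T - 1
        ev = events.loc[ok]
        bins = bins[ok]
        for var, grp_idx in ev.groupby("variable", sort=False).indices.items():
            if var not in spec_by_var:
                raise KeyError(f"variable {var!r} has no VariableSpec")
            spec = spec_by_var[var]
            col = variables.index(var)
            vbins = bins[grp_idx]
            vvals = ev["value"].to_numpy()[grp_idx]
            vtimes = ev["time_h"].to_numpy(dtype=float)[grp_idx]
            order = np.argsort(vtimes, kind="mergesort")
            vbins, vvals, vtimes = vbins[order], vvals[order], vtimes[order]
            for b in np.unique(vbins):
                sel = vbins == b
                vals = vvals[sel]
                agg = spec.aggregation
                if agg == "median":
                    out = float(np.median(vals.astype(float)))
                elif agg == "mode":
                    out = _mode_recent(vals, vtimes[sel])
                elif agg == "sum":
                    out = float(np.sum(vals.astype(float)))
                elif agg == "max":
                    out = float(np.max(vals.astype(float)))
                elif agg == "min":
                    out = float(np.min(vals.astype(float)))
                elif agg == "last":
                    out = vals[-1]
                else:  # pragma: no cover - closed set enforced by VariableSpec
                    raise ValueError(agg)
                X.iat[int(b), col] = out
                M[int(b), col] = 1

    return AlignedStay(stay_id=str(events["stay_id"].iloc[0]) if len(events)
                       else "", variables=variables, grid_h=grid, X=X, M=M)


# ---------------------------------------------------------------------------
# empty-bin removal and delta
# ---------------------------------------------------------------------------

def drop_empty_bins(aligned: AlignedStay) -> AlignedStay:
    """Remove grid times where no variable was observed.

    Surviving rows keep their original hour values.  If a Delta matrix is
    already present it is recomputed on the surviving grid.
    """
    keep = aligned.M.any(axis=1)
    if not keep.any():
        raise EmptyStayError(f"stay {aligned.stay_id}: all bins empty")
    dropped = aligned.grid_h[~keep].tolist()
    out = AlignedStay(
        stay_id=aligned.stay_id,
        variables=list(aligned.variables),
        grid_h=aligned.grid_h[keep],
        X=aligned.X.loc[keep].reset_index(drop=True),
        M=aligned.M[keep],
        dropped_bins=aligned.dropped_bins + dropped,
    )
    if aligned.Delta is not None:
        out.Delta = compute_delta(out.M, out.grid_h)
    return out


def compute_delta(M: np.ndarray, grid_h: np.ndarray) -> np.ndarray:
    """Time since the last observation, accumulating across unobserved bins.

    ``delta[0, d] = 0``; for ``t > 0``,
    ``delta[t, d] = (s_t - s_{t-1}) + (0 if M[t-1, d] else delta[t-1, d])``.
    """
    M = np.asarray(M)
    grid_h = np.asarray(grid_h, dtype=float)
    if M.ndim != 2 or len(grid_h) != M.shape[0]:
        raise ValueError("mask and grid shapes disagree")
    if len(grid_h) > 1 and not np.all(np.diff(grid_h) > 0):
        raise ValueError("grid must be strictly increasing")
    T, D = M.shape
    delta = np.zeros((T, D), dtype=float)
    for t in range(1, T):
        gap = grid_h[t] - grid_h[t - 1]
        delta[t] = gap + np.where(M[t - 1] == 1, 0.0, delta[t - 1])
    return delta


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute(aligned: AlignedStay, spec_by_var: Mapping[str, VariableSpec],
           stats: NormalizationStats) -> AlignedStay:
    """Complete the value matrix; masks and deltas are left untouched."""
    X = aligned.X.copy()
    for col, var in enumerate(aligned.variables):
        spec = spec_by_var[var]
        m = aligned.M[:, col].astype(bool)
        if spec.vtype == "numeric":
            X[var] = _impute_numeric(
                X[var].to_numpy(), m, aligned.grid_h, spec, stats, var)
        else:
            X[var] = _impute_categorical(X[var].to_numpy(object), m, spec,
                                         stats, var)
    return AlignedStay(
        stay_id=aligned.stay_id, variables=list(aligned.variables),
        grid_h=aligned.grid_h, X=X, M=aligned.M, Delta=aligned.Delta,
        dropped_bins=list(aligned.dropped_bins),
    )


def _fallback_for(var: str, spec: VariableSpec, stats: NormalizationStats):
    fb = stats.fallback.get(var, spec.fallback)
    if fb is None:
        raise ValueError(
            f"variable {var!r} never observed and no training fallback given")
    return fb


def _impute_numeric(x: np.ndarray, m: np.ndarray, grid_h: np.ndarray,
                    spec: VariableSpec, stats: NormalizationStats,
                    var: str) -> np.ndarray:
    x = x.astype(float)
    obs = np.flatnonzero(m)
    if obs.size == 0:
        return np.full(len(x), float(_fallback_for(var, spec, stats)))
    if spec.imputation == "linear":
        # np.interp extends constantly at both ends: leading gap takes the
        # earliest observation, trailing gap carries the last one forward
        return np.interp(grid_h, grid_h[obs], x[obs].astype(float))
    if spec.imputation == "locf":
        idx = np.searchsorted(obs, np.arange(len(x)), side="right") - 1
        idx = np.clip(idx, 0, obs.size - 1)     # head gap <- first observation
        return x[obs[idx]].astype(float)
    # imputation == "none": unobserved bins take the global fallback
    out = x.copy()
    out[~m] = float(_fallback_for(var, spec, stats))
    return out


def _impute_categorical(x: np.ndarray, m: np.ndarray, spec: VariableSpec,
                        stats: NormalizationStats, var: str) -> np.ndarray:
    out = x.copy()
    obs = np.flatnonzero(m)
    if obs.size == 0:
        out[:] = str(_fallback_for(var, spec, stats))
        return out
    if spec.imputation == "none":
        out[~m] = str(_fallback_for(var, spec, stats))
        return out
    # head gap carries the earliest observation backward; interior and
    # trailing gaps become the explicit "missing" category
    if "missing" not in (spec.categories or ()):
        raise ValueError(
            f"categorical variable {var!r} lacks a 'missing' category")
    first = obs[0]
    out[:first] = out[first]
    missing_after = ~m & (np.arange(len(x)) > first)
    out[missing_after] = "missing"
    return out


# ---------------------------------------------------------------------------
# normalization statistics
# ---------------------------------------------------------------------------

def fit_normalization(training_stays: Iterable[AlignedStay],
                      spec_by_var: Mapping[str, VariableSpec],
                      interval_scale: float = INTERVAL_SCALE_H
                      ) -> NormalizationStats:
    """Per-variable mean/sd and fallbacks from observed entries only.

    Must be called on the training split alone; applying the returned stats
    to validation/test stays is what keeps those splits leakage-free.
    """
    pooled: dict[str, list] = {v: [] for v in spec_by_var}
    for stay in training_stays:
        for col, var in enumerate(stay.variables):
            m = stay.M[:, col].astype(bool)
            if m.any():
                pooled[var].extend(stay.X[var].to_numpy()[m].tolist())

    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    fallback: dict[str, object] = {}
    for var, spec in spec_by_var.items():
        vals = pooled[var]
        if spec.vtype == "numeric":
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0:
                warnings.warn(f"{var}: never observed in training set",
                              stacklevel=2)
                mean[var], sd[var] = 0.0, EPS_SD
                continue
            mean[var] = float(arr.mean())
            s = float(arr.std())
            if arr.size < 2 or s == 0.0:
                warnings.warn(f"{var}: degenerate spread, using epsilon sd",
                              stacklevel=2)
                s = EPS_SD
            sd[var] = s
            fallback[var] = float(np.median(arr))
        else:
            if not vals:
                warnings.warn(f"{var}: never observed in training set",
                              stacklevel=2)
                fallback[var] = "missing"
                continue
            uniq, counts = np.unique(np.asarray(vals, dtype=object),
                                     return_counts=True)
            top = counts.max()
            fallback[var] = str(sorted(uniq[counts == top])[0])
    return NormalizationStats(mean=mean, sd=sd, fallback=fallback,
                              interval_scale=interval_scale)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def feature_layout(spec_by_var: Mapping[str, VariableSpec]
                   ) -> tuple[list[str], list[str]]:
    """Deterministic channel order: numerics, one-hot blocks, masks, deltas."""
    names: list[str] = []
    parents: list[str] = []
    for var, spec in spec_by_var.items():
        if spec.vtype == "numeric":
            names.append(var)
            parents.append(var)
    for var, spec in spec_by_var.items():
        if spec.vtype == "categorical":
            for level in spec.categories:
                names.append(f"{var}={level}")
                parents.append(var)
    for var in spec_by_var:
        names.append(f"mask:{var}")
        parents.append(var)
    for var in spec_by_var:
        names.append(f"dt:{var}")
        parents.append(var)
    return names, parents


def encode(aligned: AlignedStay, stats: NormalizationStats,
           spec_by_var: Mapping[str, VariableSpec]) -> EncodedStay:
    """Z-score numerics, one-hot categoricals, append mask and delta channels."""
    if aligned.Delta is None:
        raise ValueError("compute_delta must run before encode")
    names, parents = feature_layout(spec_by_var)
    T = aligned.T
    cols: list[np.ndarray] = []
    for var, spec in spec_by_var.items():
        if spec.vtype != "numeric":
            continue
        x = aligned.X[var].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"{var}: unimputed values reach encode")
        cols.append((x - stats.mean[var]) / stats.sd[var])
    for var, spec in spec_by_var.items():
        if spec.vtype != "categorical":
            continue
        labels = aligned.X[var].to_numpy(object)
        level_idx = {c: i for i, c in enumerate(spec.categories)}
        onehot = np.zeros((T, len(spec.categories)))
        for t, lab in enumerate(labels):
            j = level_idx.get(lab)
            if j is None:
                warnings.warn(
                    f"{var}: unseen category {lab!r} mapped to 'missing'",
                    stacklevel=2)
                j = level_idx["missing"]
            onehot[t, j] = 1.0
        cols.extend(onehot.T)
    col_order = list(aligned.variables)
    var_pos = {v: i for i, v in enumerate(col_order)}
    for var in spec_by_var:
        cols.append(aligned.M[:, var_pos[var]].astype(float))
    for var in spec_by_var:
        cols.append(aligned.Delta[:, var_pos[var]] / stats.interval_scale)
    Z = np.column_stack(cols)
    return EncodedStay(stay_id=aligned.stay_id, Z=Z, feature_names=names,
                       feature_parent=parents, grid_h=aligned.grid_h.copy())


# ---------------------------------------------------------------------------
# whole-cohort driver
# ---------------------------------------------------------------------------

@dataclass
class PreprocessedCohort:
    encoded: dict[str, EncodedStay]
    stats: NormalizationStats
    skipped: list[str] = field(default_factory=list)

    def grids(self) -> dict[str, np.ndarray]:
        return {sid: enc.grid_h for sid, enc in self.encoded.items()}


def preprocess_stay(events: pd.DataFrame,
                    spec_by_var: Mapping[str, VariableSpec], los_h: float,
                    stats: NormalizationStats) -> EncodedStay:
    """Run the full per-stay pipeline; raises EmptyStayError when unusable."""
    aligned = resample(events, spec_by_var, los_h)
    aligned = drop_empty_bins(aligned)
    aligned.Delta = compute_delta(aligned.M, aligned.grid_h)
    aligned = impute(aligned, spec_by_var, stats)
    return encode(aligned, stats, spec_by_var)


def preprocess_cohort(cohort: Cohort, stats: NormalizationStats | None = None,
                      train_stay_ids: Sequence[str] | None = None
                      ) -> PreprocessedCohort:
    """Preprocess every stay, fitting stats on the training subset if needed.

    When ``stats`` is None, ``train_stay_ids`` selects the stays whose
    observed values define the normalization statistics and fallbacks.
    """
    spec_by_var = cohort.dictionary
    aligned_by_stay: dict[str, AlignedStay] = {}
    skipped: list[str] = []
    events_by_stay = dict(iter(cohort.events.groupby("stay_id", sort=False)))
    for _, row in cohort.stays.iterrows():
        sid = str(row.stay_id)
        ev = events_by_stay.get(sid)
        if ev is None or ev.empty:
            skipped.append(sid)
            continue
        try:
            aligned = drop_empty_bins(
                resample(ev, spec_by_var, float(row.icu_los_h)))
        except EmptyStayError:
            skipped.append(sid)
            continue
        aligned_by_stay[sid] = aligned

    if stats is None:
        if train_stay_ids is None:
            train_stay_ids = list(aligned_by_stay)
        train = [aligned_by_stay[s] for s in train_stay_ids
                 if s in aligned_by_stay]
        stats = fit_normalization(train, spec_by_var)

    encoded: dict[str, EncodedStay] = {}
    for sid, aligned in aligned_by_stay.items():
        aligned.Delta = compute_delta(aligned.M, aligned.grid_h)
        filled = impute(aligned, spec_by_var, stats)
        encoded[sid] = encode(filled, stats, spec_by_var)
    return PreprocessedCohort(encoded=encoded, stats=stats, skipped=skipped)
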