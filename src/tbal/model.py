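"""The TBAL network and its LSTM baseline.

TBAL (time-aware bidirectional attention LSTM) encodes an input prefix with
a bidirectional LSTM, scores every prefix timestep with an additive attention
that sees the elapsed time to the prediction point,

    e_t = v . tanh(W_h h_t + b + w_tau * g(tau_t)),    g(tau) = log(1 + tau/24),

forms the context as the attention-weighted sum of encoder states, and maps
it through a sigmoid head to a risk probability.  With
``bidirectional=False, attention=False`` the same code path is the baseline
unidirectional LSTM classifying from its final hidden state.

Dynamic prediction re-encodes each prefix: at trigger *t* the model sees
exactly the grid rows at or before *t*, so mutating any later row cannot
change the prediction (enforced causality; a single bidirectional pass over
the whole stay would leak future observations into earlier outputs).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from tbal import _nn
from tbal.preprocess import EncodedStay, NormalizationStats


@dataclass(frozen=True)
class TBALConfig:
    """Architecture hyperparameters; fully determines the parameter count.

    ``hidden_size`` defaults to 32, a desk-scale setting that trains in
    minutes on one CPU; 512 is the full-scale choice for large cohorts.
    """

    input_dim: int
    hidden_size: int = 32
    num_layers: int = 1
    attention_dim: int = 32
    dropout: float = 0.0
    l2_weight: float = 1e-5
    bidirectional: bool = True
    attention: bool = True
    time_aware: bool = True
    #: context window in hours: the encoder sees only prefix rows within
    #: this horizon of the trigger (None = the whole prefix).  Recent
    #: physiology dominates short-horizon mortality risk, and the window
    #: bounds the cost of re-encoding prefixes in dynamic prediction.
    max_context_h: float | None = 72.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")

    @classmethod
    def lstm_baseline(cls, input_dim: int, **kw) -> "TBALConfig":
        kw.setdefault("bidirectional", False)
        kw.setdefault("attention", False)
        kw.setdefault("time_aware", False)
        return cls(input_dim=input_dim, **kw)


def apply_context_window(Z: np.ndarray, tau: np.ndarray,
                         max_context_h: float | None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Drop prefix rows farther than the context window from the trigger."""
    if max_context_h is None:
        return Z, tau
    keep = tau <= max_context_h + 1e-9
    if not keep.any():
        keep[-1] = True
    return Z[keep], tau[keep]


@dataclass
class ModelOutput:
    """Risk probability for one (stay, trigger) plus attention weights."""

    risk: float
    attention_weights: np.ndarray | None = None


@dataclass
class TBALModel:
    """A parameterized network instance (architecture + weights)."""

    config: TBALConfig
    params: dict[str, np.ndarray] = field(default_factory=dict)
    feature_names: list[str] = field(default_factory=list)
    feature_parent: list[str] = field(default_factory=list)
    stats: NormalizationStats | None = None

    @classmethod
    def initialize(cls, config: TBALConfig,
                   feature_names: Sequence[str] = (),
                   feature_parent: Sequence[str] = (),
                   stats: NormalizationStats | None = None) -> "TBALModel":
        rng = np.random.default_rng(config.seed)
        params = _nn.init_params(config, rng)
        return cls(config=config, params=params,
                   feature_names=list(feature_names),
                   feature_parent=list(feature_parent), stats=stats)

    # -- single-prefix API ---------------------------------------------------

    def forward(self, Z_prefix: np.ndarray,
                trigger_h: float | None = None,
                grid_h: np.ndarray | None = None) -> ModelOutput:
        """Score one prefix (rows up to and including the trigger time).

        ``tau_t = trigger_h - grid_h[t]`` feeds the time-aware attention;
        when either is omitted, tau falls back to steps-to-end in hours.
        """
        Z_prefix = np.asarray(Z_prefix, dtype=float)
        if Z_prefix.ndim != 2 or Z_prefix.shape[0] < 1:
            raise ValueError("prefix must be a (T, F) matrix with T >= 1")
        if not np.isfinite(Z_prefix).all():
            raise ValueError("non-finite values in input; imputation contract "
                             "violated")
        T = Z_prefix.shape[0]
        if grid_h is None:
            grid_h = np.arange(T, dtype=float)
        if trigger_h is None:
            trigger_h = float(grid_h[-1])
        tau = trigger_h - np.asarray(grid_h, dtype=float)
        Z_prefix, tau = apply_context_window(Z_prefix, tau,
                                             self.config.max_context_h)
        T = Z_prefix.shape[0]
        prob, alpha, _ = _nn.forward(self.params, self.config,
                                     Z_prefix[None, :, :], np.array([T]),
                                     tau=tau[None, :])
        return ModelOutput(
            risk=float(prob[0]),
            attention_weights=None if alpha is None else alpha[0].copy(),
        )

    def forward_dynamic(self, encoded: EncodedStay,
                        triggers: Sequence[float]) -> list[ModelOutput]:
        """Score each trigger using only the grid rows at or before it."""
        grid = np.asarray(encoded.grid_h, dtype=float)
        outputs = []
        for trig in triggers:
            pos = np.searchsorted(grid, trig, side="right")
            if pos == 0 or not np.isclose(grid[pos - 1], trig):
                raise ValueError(f"trigger {trig} not on the stay grid")
            outputs.append(self.forward(encoded.Z[:pos], trigger_h=float(trig),
                                        grid_h=grid[:pos]))
        return outputs

    # -- batched scoring -----------------------------------------------------

    def predict_prefixes(self, prefixes: Sequence[tuple[np.ndarray, np.ndarray]],
                         batch_size: int = 256) -> np.ndarray:
        """Risks for many (Z_prefix, tau) pairs, padded and batched by length."""
        prefixes = [apply_context_window(z, t, self.config.max_context_h)
                    for z, t in prefixes]
        n = len(prefixes)
        risks = np.empty(n)
        order = np.argsort([p[0].shape[0] for p in prefixes], kind="mergesort")
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            lens = np.array([prefixes[i][0].shape[0] for i in idx])
            T_max = int(lens.max())
            F = prefixes[idx[0]][0].shape[1]
            Z = np.zeros((len(idx), T_max, F))
            tau = np.zeros((len(idx), T_max))
            for row, i in enumerate(idx):
                zp, tp = prefixes[i]
                Z[row, :lens[row]] = zp
                tau[row, :lens[row]] = tp
            prob, _, _ = _nn.forward(self.params, self.config, Z, lens,
                                     tau=tau)
            risks[idx] = prob
        return risks

    # -- bookkeeping ---------------------------------------------------------

    def count_parameters(self) -> dict[str, int]:
        """Exact trainable-parameter count, decomposed per submodule."""
        return _nn.parameter_breakdown(self.params)

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def save(self, path: str | Path) -> None:
        """Self-describing checkpoint: config + weights + stats + features."""
        meta = {
            "format": "tbal-checkpoint-1",
            "config": asdict(self.config),
            "feature_names": self.feature_names,
            "feature_parent": self.feature_parent,
            "stats": None if self.stats is None else {
                "mean": {k: float(v) for k, v in self.stats.mean.items()},
                "sd": {k: float(v) for k, v in self.stats.sd.items()},
                "fallback": {k: (v if isinstance(v, str) else float(v))
                             for k, v in self.stats.fallback.items()},
                "interval_scale": self.stats.interval_scale,
            },
        }
        arrays = {f"param/{k}": v for k, v in self.params.items()}
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TBALModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta_json"]).decode("utf-8"))
            params = {k[len("param/"):]: data[k] for k in data.files
                      if k.startswith("param/")}
        stats = None
        if meta["stats"] is not None:
            s = meta["stats"]
            stats = NormalizationStats(
                mean=s["mean"], sd=s["sd"], fallback=s["fallback"],
                interval_scale=s["interval_scale"])
        return cls(config=TBALConfig(**meta["config"]), params=params,
                   feature_names=meta["feature_names"],
                   feature_parent=meta["feature_parent"], stats=stats)


def predict_risks(model: TBALModel, encoded: dict[str, EncodedStay],
                  labels, batch_size: int = 256) -> np.ndarray:
    """Risk per row of a labels table (columns stay_id, trigger_h).

    The prefix for a trigger consists of every surviving grid row at or
    before the trigger time; rows whose stay is missing from ``encoded`` or
    whose prefix would be empty get NaN.
    """
    prefixes = []
    rows = []
    for i, (sid, trig) in enumerate(zip(labels["stay_id"].astype(str),
                                        labels["trigger_h"].astype(float))):
        enc = encoded.get(sid)
        if enc is None:
            continue
        grid = enc.grid_h
        pos = int(np.searchsorted(grid, trig, side="right"))
        if pos == 0:
            continue
        tau = trig - grid[:pos]
        prefixes.append((enc.Z[:pos], tau))
        rows.append(i)
    risks = np.full(len(labels), np.nan)
    if prefixes:
        risks[np.array(rows)] = model.predict_prefixes(prefixes,
                                                       batch_size=batch_size)
    return risks
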