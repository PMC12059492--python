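"""Minimal NumPy recurrent-network engine with exact backpropagation.

Implements everything the TBAL architecture needs — batched (optionally
bidirectional, optionally stacked) LSTM layers, additive attention with a
time-aware term, a sigmoid classifier head, and an Adam optimizer with
decoupled weight decay — as pure functions over a flat ``{name: ndarray}``
parameter dictionary.  The backward pass returns gradients for every
parameter *and* for the input tensor, which is what integrated gradients
needs.

Batches are right-padded; ``lengths`` gives each sequence's true length.
Padded steps carry the previous hidden/cell state forward unchanged, so the
state at the last padded position always equals the state at the true final
step, and attention masks padded positions out of the softmax.

Everything is deterministic given the RNG used at initialization.
"""

from __future__ import annotations

import numpy as np

GATES = 4  # i, f, g, o


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def g_time(tau: np.ndarray, scale_h: float = 24.0) -> np.ndarray:
    """Log-compressed elapsed-time-to-trigger term used by the attention."""
    return np.log1p(np.maximum(tau, 0.0) / scale_h)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_params(cfg, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Initialize all trainable parameters for a config.

    ``cfg`` needs: input_dim, hidden_size, num_layers, bidirectional,
    attention, time_aware, attention_dim.
    """
    H = cfg.hidden_size
    k = 1.0 / np.sqrt(H)
    params: dict[str, np.ndarray] = {}
    dirs = ("f", "b") if cfg.bidirectional else ("f",)
    in_dim = cfg.input_dim
    for layer in range(cfg.num_layers):
        for d in dirs:
            p = f"lstm{layer}{d}"
            params[f"{p}.Wx"] = rng.uniform(-k, k, size=(in_dim, GATES * H))
            params[f"{p}.Wh"] = rng.uniform(-k, k, size=(H, GATES * H))
            b = rng.uniform(-k, k, size=GATES * H)
            b[H:2 * H] += 1.0          # forget-gate bias
            params[f"{p}.b"] = b
        in_dim = H * len(dirs)
    enc_dim = H * len(dirs)
    if cfg.attention:
        A = cfg.attention_dim
        ka = 1.0 / np.sqrt(A)
        params["att.Wa"] = rng.uniform(-ka, ka, size=(enc_dim, A))
        params["att.ba"] = np.zeros(A)
        params["att.wt"] = rng.uniform(-ka, ka, size=A)
        params["att.v"] = rng.uniform(-ka, ka, size=A)
    params["head.w"] = rng.uniform(-k, k, size=enc_dim)
    params["head.b"] = np.zeros(1)
    return params


def parameter_breakdown(params: dict[str, np.ndarray]) -> dict[str, int]:
    """Trainable-parameter count per submodule plus the total."""
    out: dict[str, int] = {}
    for name, arr in params.items():
        group = name.split(".")[0]
        out[group] = out.get(group, 0) + int(arr.size)
    out["total"] = int(sum(arr.size for arr in params.values()))
    return out


# ---------------------------------------------------------------------------
# LSTM layer
# ---------------------------------------------------------------------------

def _lstm_forward(Z, alive, Wx, Wh, b):
    """Run one LSTM direction over a padded batch.

    Z: (B, T, F); alive: (B, T) float {0,1}.  Returns H_seq (B, T, H) and a
    cache for the backward pass.  Padded steps carry state unchanged.
    """
    B, T, _ = Z.shape
    H = Wh.shape[0]
    XW = Z @ Wx                                     # (B, T, 4H)
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    H_seq = np.empty((B, T, H))
    cache_i = np.empty((B, T, H)); cache_f = np.empty((B, T, H))
    cache_g = np.empty((B, T, H)); cache_o = np.empty((B, T, H))
    cache_tc = np.empty((B, T, H))
    cache_cprev = np.empty((B, T, H)); cache_hprev = np.empty((B, T, H))
    for t in range(T):
        m = alive[:, t][:, None]
        a = XW[:, t] + h @ Wh + b
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H:2 * H])
        g = np.tanh(a[:, 2 * H:3 * H])
        o = _sigmoid(a[:, 3 * H:])
        c_raw = f * c + i * g
        tc = np.tanh(c_raw)
        h_raw = o * tc
        cache_i[:, t] = i; cache_f[:, t] = f
        cache_g[:, t] = g; cache_o[:, t] = o
        cache_tc[:, t] = tc
        cache_cprev[:, t] = c; cache_hprev[:, t] = h
        h = m * h_raw + (1.0 - m) * h
        c = m * c_raw + (1.0 - m) * c
        H_seq[:, t] = h
    cache = (Z, alive, Wx, Wh, cache_i, cache_f, cache_g, cache_o,
             cache_tc, cache_cprev, cache_hprev)
    return H_seq, cache


def _lstm_backward(dH_seq, cache):
    """Exact BPTT through one masked LSTM direction."""
    (Z, alive, Wx, Wh, ci, cf, cg, co, ctc, ccprev, chprev) = cache
    B, T, H = dH_seq.shape
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(Wx.shape[1])
    dZ = np.zeros_like(Z)
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        m = alive[:, t][:, None]
        dh = dH_seq[:, t] + dh_next
        dh_raw = dh * m
        i, f, g, o = ci[:, t], cf[:, t], cg[:, t], co[:, t]
        tc = ctc[:, t]
        do = dh_raw * tc
        dc_raw = dh_raw * o * (1.0 - tc * tc) + dc_next * m
        di = dc_raw * g
        df = dc_raw * ccprev[:, t]
        dg = dc_raw * i
        da = np.concatenate([
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            dg * (1.0 - g * g),
            do * o * (1.0 - o),
        ], axis=1)
        x_t = Z[:, t]
        dWx += x_t.T @ da
        dWh += chprev[:, t].T @ da
        db += da.sum(axis=0)
        dZ[:, t] = da @ Wx.T
        dh_next = da @ Wh.T + dh * (1.0 - m)
        dc_next = dc_raw * f + dc_next * (1.0 - m)
    return dZ, dWx, dWh, db


def _reverse_within(Z: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence inside its true length; padding stays in place."""
    B, T = Z.shape[:2]
    idx = np.arange(T)[None, :].repeat(B, axis=0)
    L = lengths[:, None]
    inside = idx < L
    rev = np.where(inside, L - 1 - idx, idx)
    return Z[np.arange(B)[:, None], rev]


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------

def forward(params, cfg, Z, lengths, tau=None, drop_mask=None):
    """Forward pass over a padded batch of prefixes.

    Parameters
    ----------
    Z : (B, T, F) float — encoded inputs, right-padded with zeros.
    lengths : (B,) int — true prefix lengths (>= 1).
    tau : (B, T) float, optional — hours from each step to the trigger;
        required when ``cfg.attention and cfg.time_aware``.

    Returns ``(prob, alpha, cache)`` with prob (B,), alpha (B, T) attention
    weights (None without attention).
    """
    B, T, _ = Z.shape
    lengths = np.asarray(lengths, dtype=int)
    alive = (np.arange(T)[None, :] < lengths[:, None]).astype(float)
    dirs = ("f", "b") if cfg.bidirectional else ("f",)
    layer_caches = []
    X = Z
    for layer in range(cfg.num_layers):
        outs = []
        dir_caches = []
        for d in dirs:
            p = f"lstm{layer}{d}"
            Xd = _reverse_within(X, lengths) if d == "b" else X
            H_seq, cache = _lstm_forward(Xd, alive, params[f"{p}.Wx"],
                                         params[f"{p}.Wh"], params[f"{p}.b"])
            if d == "b":
                H_seq = _reverse_within(H_seq, lengths)
            outs.append(H_seq)
            dir_caches.append(cache)
        X = np.concatenate(outs, axis=2) if len(outs) > 1 else outs[0]
        layer_caches.append(dir_caches)
    Henc = X                                        # (B, T, Dh)

    if cfg.attention:
        gt = g_time(tau) if (cfg.time_aware and tau is not None) else None
        pre = Henc @ params["att.Wa"] + params["att.ba"]
        if gt is not None:
            pre = pre + gt[:, :, None] * params["att.wt"]
        u = np.tanh(pre)
        e = u @ params["att.v"]
        e = np.where(alive > 0, e, -np.inf)
        e_max = e.max(axis=1, keepdims=True)
        ex = np.exp(e - e_max)
        alpha = ex / ex.sum(axis=1, keepdims=True)
        context = np.einsum("bt,btd->bd", alpha, Henc)
        att_cache = (u, alpha, gt)
    else:
        alpha = None
        Hdim = cfg.hidden_size
        last = Henc[np.arange(B), lengths - 1]
        if cfg.bidirectional:
            context = np.concatenate([last[:, :Hdim], Henc[:, 0, Hdim:]],
                                     axis=1)
        else:
            context = last
        att_cache = None

    if drop_mask is not None:            # inverted dropout on the context
        context = context * drop_mask
    logit = context @ params["head.w"] + params["head.b"][0]
    prob = _sigmoid(logit)
    cache = (Z, lengths, alive, layer_caches, Henc, att_cache, context,
             drop_mask)
    return prob, alpha, cache


def backward(params, cfg, cache, dlogit):
    """Backward pass; returns gradients for all parameters and the input.

    ``dlogit`` is the gradient of the scalar objective with respect to each
    example's pre-sigmoid output.  The returned dict maps parameter names to
    gradients and ``"_input"`` to dZ of shape (B, T, F).
    """
    Z, lengths, alive, layer_caches, Henc, att_cache, context, drop_mask = cache
    B, T, _ = Z.shape
    grads: dict[str, np.ndarray] = {}
    grads["head.w"] = context.T @ dlogit
    grads["head.b"] = np.array([dlogit.sum()])
    dcontext = dlogit[:, None] * params["head.w"][None, :]
    if drop_mask is not None:
        dcontext = dcontext * drop_mask

    dHenc = np.zeros_like(Henc)
    if cfg.attention:
        u, alpha, gt = att_cache
        v = params["att.v"]
        dalpha = np.einsum("bd,btd->bt", dcontext, Henc)
        dHenc += alpha[:, :, None] * dcontext[:, None, :]
        s = (alpha * dalpha).sum(axis=1, keepdims=True)
        de = alpha * (dalpha - s)
        du = de[:, :, None] * v[None, None, :]
        grads["att.v"] = np.einsum("btA,bt->A", u, de)
        dpre = du * (1.0 - u * u)
        grads["att.Wa"] = np.einsum("btd,btA->dA", Henc, dpre)
        grads["att.ba"] = dpre.sum(axis=(0, 1))
        if gt is not None:
            grads["att.wt"] = np.einsum("bt,btA->A", gt, dpre)
        elif "att.wt" in params:
            grads["att.wt"] = np.zeros_like(params["att.wt"])
        dHenc += dpre @ params["att.Wa"].T
    else:
        Hdim = cfg.hidden_size
        if cfg.bidirectional:
            dHenc[np.arange(B), lengths - 1, :Hdim] += dcontext[:, :Hdim]
            dHenc[:, 0, Hdim:] += dcontext[:, Hdim:]
        else:
            dHenc[np.arange(B), lengths - 1] += dcontext

    dirs = ("f", "b") if cfg.bidirectional else ("f",)
    H = cfg.hidden_size
    dX_upper = dHenc
    for layer in range(cfg.num_layers - 1, -1, -1):
        dX_lower = None
        for di, d in enumerate(dirs):
            p = f"lstm{layer}{d}"
            dH_dir = dX_upper[:, :, di * H:(di + 1) * H]
            if d == "b":
                dH_dir = _reverse_within(dH_dir, lengths)
            dZ_dir, dWx, dWh, db = _lstm_backward(dH_dir, layer_caches[layer][di])
            if d == "b":
                dZ_dir = _reverse_within(dZ_dir, lengths)
            grads[f"{p}.Wx"] = dWx
            grads[f"{p}.Wh"] = dWh
            grads[f"{p}.b"] = db
            dX_lower = dZ_dir if dX_lower is None else dX_lower + dZ_dir
        dX_upper = dX_lower
    grads["_input"] = dX_upper
    return grads


# ---------------------------------------------------------------------------
# Adam with decoupled weight decay
# ---------------------------------------------------------------------------

class Adam:
    """Adam optimizer; L2 acts as decoupled weight decay on non-bias tensors."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    @staticmethod
    def _decays(name: str) -> bool:
        return not (name.endswith(".b") or name.endswith(".ba"))

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in params.items():
            g = grads.get(k)
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            upd = mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and self._decays(k):
                upd = upd + self.weight_decay * p
            params[k] = p - self.lr * upd
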