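"""The SA-GRU network: stacked GRU layers with squeeze-and-excitation attention.

Architecture (default configuration)::

    input (B, 8, 2)  ->  GRU(32)  ->  SE  ->  GRU(32)  ->  SE
                     ->  last hidden state (B, 32)
                     ->  FC1(128, ReLU) -> FC2(32, ReLU) -> FC3(1)

The GRU cell uses reset gate r, update gate z and candidate state h'::

    r  = sigmoid(W_r x + U_r h_prev + b_r)
    z  = sigmoid(W_z x + U_z h_prev + b_z)
    h' = tanh(W_h x + U_h (r * h_prev) + b_h)
    h  = z * h_prev + (1 - z) * h'

``literal_eq3=True`` drops the recurrent candidate matrix U_h, applying the
reset-gated hidden state additively (a degenerate but sometimes-printed
variant); the standard form with U_h is the default.

The squeeze-and-excitation (SE) block pools the GRU feature sequence along
one axis (squeeze), pushes the pooled descriptor through a two-layer
bottleneck with ReLU then sigmoid (excite), and rescales the features by
the resulting weights in (0, 1)::

    Z = mean over the pooled axis of K
    S = sigmoid(W2 @ relu(W1 @ Z))
    K' = S * K      (broadcast along the pooled axis)

With ``se_axis="channels"`` the 32 hidden channels each get a weight
(squeeze over the 8 time steps); with ``se_axis="steps"`` the 8 time steps
each get a weight (squeeze over channels), which is the view used for
per-time-point attention summaries.

Everything is NumPy; gradients are analytic (see :func:`sagru_backward`)
and are exercised by finite-difference checks in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def relu(x):
    return np.maximum(x, 0.0)


# ---------------------------------------------------------------------------
# configuration and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SAGRUConfig:
    """Hyperparameters of the network.

    ``num_gru_layers``/``use_se`` select the ablation variants: (1, False)
    is the plain GRU, (2, False) the stacked GRU, (2, True) the full SA-GRU.
    """

    input_dim: int = 2
    hidden: int = 32
    num_gru_layers: int = 2
    use_se: bool = True
    se_reduction: int = 4
    se_axis: str = "channels"  # or "steps"
    fc_sizes: tuple[int, ...] = (128, 32, 1)
    fc_input: str = "last"  # or "flatten"
    window_len: int = 8
    literal_eq3: bool = False
    use_bias: bool = True

    def __post_init__(self):
        if self.se_axis not in ("channels", "steps"):
            raise ValueError(f"unknown se_axis {self.se_axis!r}")
        if self.fc_input not in ("last", "flatten"):
            raise ValueError(f"unknown fc_input {self.fc_input!r}")
        if self.num_gru_layers not in (1, 2):
            raise ValueError("num_gru_layers must be 1 or 2")
        if self.use_se:
            c = self.hidden if self.se_axis == "channels" else self.window_len
            if c % self.se_reduction != 0:
                raise ValueError(
                    f"se_reduction {self.se_reduction} does not divide the "
                    f"attended dimension {c}"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fc_sizes"] = list(self.fc_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SAGRUConfig":
        d = dict(d)
        d["fc_sizes"] = tuple(d["fc_sizes"])
        return cls(**d)


@dataclass
class GRULayerParams:
    """Weights of one GRU layer (see module docstring for the equations)."""

    W_r: np.ndarray
    W_z: np.ndarray
    W_h: np.ndarray
    U_r: np.ndarray
    U_z: np.ndarray
    U_h: Optional[np.ndarray]  # None under literal_eq3
    b_r: np.ndarray
    b_z: np.ndarray
    b_h: np.ndarray


@dataclass
class SEBlockParams:
    """Bottleneck weights of one squeeze-and-excitation block (no biases)."""

    W1: np.ndarray  # (C, C // reduction)
    W2: np.ndarray  # (C // reduction, C)
    axis: str = "channels"


#: Parameters are kept as a flat name -> array dict so the optimizer and the
#: checkpoint format can treat them uniformly. Structured views are built on
#: demand by :func:`gru_params` / :func:`se_params`.
ParamDict = dict


def gru_params(params: ParamDict, layer: int, config: SAGRUConfig) -> GRULayerParams:
    p = f"gru{layer}."
    return GRULayerParams(
        W_r=params[p + "W_r"], W_z=params[p + "W_z"], W_h=params[p + "W_h"],
        U_r=params[p + "U_r"], U_z=params[p + "U_z"],
        U_h=None if config.literal_eq3 else params[p + "U_h"],
        b_r=params[p + "b_r"], b_z=params[p + "b_z"], b_h=params[p + "b_h"],
    )


def se_params(params: ParamDict, block: int, config: SAGRUConfig) -> SEBlockParams:
    p = f"se{block}."
    return SEBlockParams(W1=params[p + "W1"], W2=params[p + "W2"], axis=config.se_axis)


def init_params(config: SAGRUConfig, rng: np.random.Generator) -> ParamDict:
    """Initialize all weights uniformly in +-1/sqrt(hidden), biases at zero."""
    s = 1.0 / np.sqrt(config.hidden)
    u = lambda *shape: rng.uniform(-s, s, size=shape)
    params: ParamDict = {}

    d_in = config.input_dim
    for layer in range(1, config.num_gru_layers + 1):
        h = config.hidden
        p = f"gru{layer}."
        for g in ("r", "z", "h"):
            params[p + f"W_{g}"] = u(d_in, h)
            params[p + f"b_{g}"] = np.zeros(h)
        params[p + "U_r"] = u(h, h)
        params[p + "U_z"] = u(h, h)
        if not config.literal_eq3:
            params[p + "U_h"] = u(h, h)
        d_in = h

    if config.use_se:
        c = config.hidden if config.se_axis == "channels" else config.window_len
        b = c // config.se_reduction
        for block in range(1, config.num_gru_layers + 1):
            params[f"se{block}.W1"] = u(c, b)
            params[f"se{block}.W2"] = u(b, c)

    f_in = config.hidden if config.fc_input == "last" else config.hidden * config.window_len
    for i, f_out in enumerate(config.fc_sizes, start=1):
        params[f"fc{i}.W"] = u(f_in, f_out)
        params[f"fc{i}.b"] = np.zeros(f_out)
        f_in = f_out

    if not config.use_bias:
        for k in list(params):
            if ".b" in k:
                params[k] = np.zeros_like(params[k])
    return params


def count_parameters(params: ParamDict) -> int:
    return int(sum(v.size for v in params.values()))


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def gru_cell_step(x: np.ndarray, h_prev: np.ndarray, p: GRULayerParams) -> np.ndarray:
    """One GRU step. ``x``: (..., input_dim), ``h_prev``: (..., hidden)."""
    x = np.asarray(x, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    if x.shape[-1] != p.W_r.shape[0] or h_prev.shape[-1] != p.U_r.shape[0]:
        raise ValueError(
            f"shape mismatch: x {x.shape} vs W {p.W_r.shape}, h {h_prev.shape} vs U {p.U_r.shape}"
        )
    r = sigmoid(x @ p.W_r + h_prev @ p.U_r + p.b_r)
    z = sigmoid(x @ p.W_z + h_prev @ p.U_z + p.b_z)
    rh = r * h_prev
    pre = x @ p.W_h + (rh @ p.U_h if p.U_h is not None else rh) + p.b_h
    h_cand = np.tanh(pre)
    return z * h_prev + (1.0 - z) * h_cand


def gru_layer_forward(window: np.ndarray, p: GRULayerParams,
                      h0: Optional[np.ndarray] = None) -> np.ndarray:
    """Run a GRU over a sequence. ``window``: (T, D) or (B, T, D) -> features
    of the same leading shape with D replaced by hidden."""
    window = np.asarray(window, dtype=float)
    squeeze = window.ndim == 2
    X = window[None] if squeeze else window
    B, T, _ = X.shape
    if T == 0:
        raise ValueError("empty sequence")
    H = p.U_r.shape[0]
    h = np.zeros((B, H)) if h0 is None else np.broadcast_to(h0, (B, H)).copy()
    K = np.empty((B, T, H))
    for t in range(T):
        h = gru_cell_step(X[:, t], h, p)
        K[:, t] = h
    return K[0] if squeeze else K


def se_block_apply(K: np.ndarray, p: SEBlockParams) -> tuple[np.ndarray, np.ndarray]:
    """Apply squeeze-and-excitation to features ``K``: (T, C) or (B, T, C).

    Returns ``(reweighted features, attention weights S)``. With
    ``axis="channels"`` S has one weight per channel (squeeze over steps);
    with ``axis="steps"`` one weight per step (squeeze over channels).
    """
    K = np.asarray(K, dtype=float)
    squeeze = K.ndim == 2
    Kb = K[None] if squeeze else K
    if p.axis == "channels":
        Z = Kb.mean(axis=1)  # (B, C)
    else:
        Z = Kb.mean(axis=2)  # (B, T)
    if Z.shape[-1] != p.W1.shape[0]:
        raise ValueError(f"SE weight shape {p.W1.shape} incompatible with descriptor {Z.shape}")
    S = sigmoid(relu(Z @ p.W1) @ p.W2)
    out = Kb * (S[:, None, :] if p.axis == "channels" else S[:, :, None])
    if squeeze:
        return out[0], S[0]
    return out, S


def _fc_head(v: np.ndarray, params: ParamDict, config: SAGRUConfig) -> np.ndarray:
    n = len(config.fc_sizes)
    for i in range(1, n + 1):
        v = v @ params[f"fc{i}.W"] + params[f"fc{i}.b"]
        if i < n:
            v = relu(v)
    return v


def sagru_forward(batch: np.ndarray, params: ParamDict, config: SAGRUConfig) -> np.ndarray:
    """Full forward pass. ``batch``: (B, T, input_dim) -> predictions (B,)
    in normalized glucose space."""
    y, _ = forward_with_cache(batch, params, config)
    return y


def forward_with_cache(batch: np.ndarray, params: ParamDict, config: SAGRUConfig):
    """Forward pass keeping every intermediate needed for backprop."""
    X = np.asarray(batch, dtype=float)
    if X.ndim != 3 or X.shape[2] != config.input_dim:
        raise ValueError(f"expected (B, T, {config.input_dim}) input, got {X.shape}")
    cache = {"X": X, "gru": [], "se": [], "fc": []}

    feat = X
    for layer in range(1, config.num_gru_layers + 1):
        p = gru_params(params, layer, config)
        K, gcache = _gru_forward_cached(feat, p)
        cache["gru"].append(gcache)
        feat = K
        if config.use_se:
            sp = se_params(params, layer, config)
            feat, S, scache = _se_forward_cached(feat, sp)
            cache["se"].append(scache)

    if config.fc_input == "last":
        v = feat[:, -1, :]
    else:
        v = feat.reshape(feat.shape[0], -1)
    cache["head_in"] = feat
    n = len(config.fc_sizes)
    for i in range(1, n + 1):
        pre = v @ params[f"fc{i}.W"] + params[f"fc{i}.b"]
        out = relu(pre) if i < n else pre
        cache["fc"].append({"in": v, "pre": pre})
        v = out
    y = v[:, 0]
    return y, cache


def _gru_forward_cached(X: np.ndarray, p: GRULayerParams):
    B, T, _ = X.shape
    H = p.U_r.shape[0]
    h = np.zeros((B, H))
    K = np.empty((B, T, H))
    steps = []
    for t in range(T):
        x = X[:, t]
        r = sigmoid(x @ p.W_r + h @ p.U_r + p.b_r)
        z = sigmoid(x @ p.W_z + h @ p.U_z + p.b_z)
        rh = r * h
        h_cand = np.tanh(x @ p.W_h + (rh @ p.U_h if p.U_h is not None else rh) + p.b_h)
        h_new = z * h + (1.0 - z) * h_cand
        steps.append({"x": x, "h_prev": h, "r": r, "z": z, "rh": rh, "hc": h_cand})
        K[:, t] = h_new
        h = h_new
    return K, {"steps": steps, "p": p, "X": X}


def _se_forward_cached(K: np.ndarray, p: SEBlockParams):
    if p.axis == "channels":
        Z = K.mean(axis=1)
    else:
        Z = K.mean(axis=2)
    A1 = Z @ p.W1
    Ar = relu(A1)
    S = sigmoid(Ar @ p.W2)
    out = K * (S[:, None, :] if p.axis == "channels" else S[:, :, None])
    return out, S, {"K": K, "Z": Z, "A1": A1, "Ar": Ar, "S": S, "p": p}


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def sagru_backward(dy: np.ndarray, cache: dict, params: ParamDict,
                   config: SAGRUConfig) -> ParamDict:
    """Analytic gradients of a scalar loss L w.r.t. every parameter, given
    dL/dy for the (B,) output. Returns a dict aligned with ``params``."""
    grads: ParamDict = {k: np.zeros_like(v) for k, v in params.items()}

    n = len(config.fc_sizes)
    dv = np.asarray(dy, dtype=float)[:, None]  # (B, 1)
    for i in range(n, 0, -1):
        fc = cache["fc"][i - 1]
        if i < n:
            dv = dv * (fc["pre"] > 0)
        grads[f"fc{i}.W"] += fc["in"].T @ dv
        grads[f"fc{i}.b"] += dv.sum(axis=0)
        dv = dv @ params[f"fc{i}.W"].T

    feat = cache["head_in"]
    if config.fc_input == "last":
        dfeat = np.zeros_like(feat)
        dfeat[:, -1, :] = dv
    else:
        dfeat = dv.reshape(feat.shape)

    for layer in range(config.num_gru_layers, 0, -1):
        if config.use_se:
            scache = cache["se"][layer - 1]
            dfeat, gW1, gW2 = _se_backward(dfeat, scache)
            grads[f"se{layer}.W1"] += gW1
            grads[f"se{layer}.W2"] += gW2
        gcache = cache["gru"][layer - 1]
        dfeat, g = _gru_backward(dfeat, gcache)
        p = f"gru{layer}."
        for name, val in g.items():
            grads[p + name] += val

    if not config.use_bias:
        for k in grads:
            if ".b" in k:
                grads[k][...] = 0.0
    return grads


def _se_backward(dout: np.ndarray, c: dict):
    K, Z, A1, Ar, S, p = c["K"], c["Z"], c["A1"], c["Ar"], c["S"], c["p"]
    if p.axis == "channels":
        pool_axis = 1
        Sb = S[:, None, :]
    else:
        pool_axis = 2
        Sb = S[:, :, None]
    dK = dout * Sb
    dS = (dout * K).sum(axis=pool_axis)
    dU2 = dS * S * (1.0 - S)
    gW2 = Ar.T @ dU2
    dAr = dU2 @ p.W2.T
    dA1 = dAr * (A1 > 0)
    gW1 = Z.T @ dA1
    dZ = dA1 @ p.W1.T
    T = K.shape[pool_axis]
    if p.axis == "channels":
        dK = dK + dZ[:, None, :] / T
    else:
        dK = dK + dZ[:, :, None] / T
    return dK, gW1, gW2


def _gru_backward(dK: np.ndarray, c: dict):
    p: GRULayerParams = c["p"]
    steps = c["steps"]
    T = len(steps)
    X = c["X"]
    dX = np.zeros_like(X)
    g = {
        "W_r": np.zeros_like(p.W_r), "W_z": np.zeros_like(p.W_z), "W_h": np.zeros_like(p.W_h),
        "U_r": np.zeros_like(p.U_r), "U_z": np.zeros_like(p.U_z),
        "b_r": np.zeros_like(p.b_r), "b_z": np.zeros_like(p.b_z), "b_h": np.zeros_like(p.b_h),
    }
    if p.U_h is not None:
        g["U_h"] = np.zeros_like(p.U_h)

    dh = np.zeros((X.shape[0], p.U_r.shape[0]))
    for t in range(T - 1, -1, -1):
        s = steps[t]
        dht = dK[:, t] + dh
        x, h_prev, r, z, rh, hc = s["x"], s["h_prev"], s["r"], s["z"], s["rh"], s["hc"]

        dz = dht * (h_prev - hc)
        dhc = dht * (1.0 - z)
        dh_prev = dht * z

        dpre_h = dhc * (1.0 - hc * hc)
        g["W_h"] += x.T @ dpre_h
        g["b_h"] += dpre_h.sum(axis=0)
        if p.U_h is not None:
            g["U_h"] += rh.T @ dpre_h
            drh = dpre_h @ p.U_h.T
        else:
            drh = dpre_h
        dr = drh * h_prev
        dh_prev = dh_prev + drh * r

        dpre_z = dz * z * (1.0 - z)
        g["W_z"] += x.T @ dpre_z
        g["U_z"] += h_prev.T @ dpre_z
        g["b_z"] += dpre_z.sum(axis=0)
        dh_prev = dh_prev + dpre_z @ p.U_z.T

        dpre_r = dr * r * (1.0 - r)
        g["W_r"] += x.T @ dpre_r
        g["U_r"] += h_prev.T @ dpre_r
        g["b_r"] += dpre_r.sum(axis=0)
        dh_prev = dh_prev + dpre_r @ p.U_r.T

        dX[:, t] = dpre_h @ p.W_h.T + dpre_z @ p.W_z.T + dpre_r @ p.W_r.T
        dh = dh_prev
    return dX, g


# ---------------------------------------------------------------------------
# attention extraction and checkpoints
# ---------------------------------------------------------------------------

@dataclass
class AttentionRecord:
    """Attention weights for a batch, with the inputs they refer to.

    ``weights`` maps SE-block name (``"se1"``, ``"se2"``) to the sigmoid
    attention array: shape (B, channels) for ``se_axis="channels"`` or
    (B, steps) for ``se_axis="steps"``. ``times_hours`` / ``glucose_mgdl``
    carry each window's clock times and raw glucose for summaries relating
    attention to time of day or glycemic level.
    """

    weights: dict
    times_hours: Optional[np.ndarray] = None
    glucose_mgdl: Optional[np.ndarray] = None


def extract_attention(batch: np.ndarray, params: ParamDict, config: SAGRUConfig,
                      times_hours: Optional[np.ndarray] = None,
                      glucose_mgdl: Optional[np.ndarray] = None) -> AttentionRecord:
    """Run the forward pass and collect the SE attention weights per window."""
    if not config.use_se:
        raise ValueError("model has no SE blocks; attention is undefined")
    _, cache = forward_with_cache(np.asarray(batch, dtype=float), params, config)
    weights = {f"se{i + 1}": c["S"].copy() for i, c in enumerate(cache["se"])}
    return AttentionRecord(weights=weights, times_hours=times_hours, glucose_mgdl=glucose_mgdl)


def save_checkpoint(path, params: ParamDict, config: SAGRUConfig) -> None:
    """Save parameters + config as an ``.npz`` map keyed by parameter name.

    The config rides along as a JSON string under ``__config__``; nothing
    in the container requires executing code to load.
    """
    payload = {k.replace(".", "__"): v for k, v in params.items()}
    payload["__config__"] = np.array(json.dumps(config.to_dict()))
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[ParamDict, SAGRUConfig]:
    z = np.load(path, allow_pickle=False)
    config = SAGRUConfig.from_dict(json.loads(str(z["__config__"])))
    params = {
        k.replace("__", "."): z[k]
        for k in z.files
        if k != "__config__"
    }
    return params, config
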