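"""Independent elementwise reference implementation of the network.

Evaluates the GRU gate equations, the squeeze-and-excitation block, and the
fully connected head with explicit Python loops over scalar elements —
no vectorized linear algebra — so it can serve as an oracle for the
vectorized implementation. Deliberately slow and simple.
"""

import math


def _sigmoid(v):
    return 1.0 / (1.0 + math.exp(-v))


def _linear(v, W):
    """v (len D) times W (D x H nested list indexing) -> list of length H."""
    D = len(v)
    H = len(W[0])
    return [sum(float(v[i]) * float(W[i][j]) for i in range(D)) for j in range(H)]


def ref_gru_cell(x, h_prev, p):
    """One GRU step on plain sequences; ``p`` has W_r..U_h, b_r..b_h attrs."""
    H = len(h_prev)
    wr = _linear(x, p.W_r)
    ur = _linear(h_prev, p.U_r)
    wz = _linear(x, p.W_z)
    uz = _linear(h_prev, p.U_z)
    r = [_sigmoid(wr[j] + ur[j] + float(p.b_r[j])) for j in range(H)]
    z = [_sigmoid(wz[j] + uz[j] + float(p.b_z[j])) for j in range(H)]
    rh = [r[j] * float(h_prev[j]) for j in range(H)]
    wh = _linear(x, p.W_h)
    if p.U_h is not None:
        uh = _linear(rh, p.U_h)
    else:
        uh = rh
    hc = [math.tanh(wh[j] + uh[j] + float(p.b_h[j])) for j in range(H)]
    return [z[j] * float(h_prev[j]) + (1.0 - z[j]) * hc[j] for j in range(H)]


def ref_gru_layer(window, p, hidden):
    """window: T x D nested sequence -> K as T x hidden nested list."""
    h = [0.0] * hidden
    K = []
    for x in window:
        h = ref_gru_cell(list(x), h, p)
        K.append(h)
    return K


def ref_se_block(K, W1, W2, axis):
    """K: T x C nested list -> (reweighted K, attention weights)."""
    T = len(K)
    C = len(K[0])
    if axis == "channels":
        Z = [sum(K[t][c] for t in range(T)) / T for c in range(C)]
    else:
        Z = [sum(K[t][c] for c in range(C)) / C for t in range(T)]
    A = [max(0.0, a) for a in _linear(Z, W1)]
    S = [_sigmoid(u) for u in _linear(A, W2)]
    if axis == "channels":
        out = [[K[t][c] * S[c] for c in range(C)] for t in range(T)]
    else:
        out = [[K[t][c] * S[t] for c in range(C)] for t in range(T)]
    return out, S


def ref_forward_one(window, params, config):
    """Full forward pass for a single window (T x input_dim nested list)."""
    feat = [list(map(float, row)) for row in window]
    for layer in range(1, config.num_gru_layers + 1):
        pre = f"gru{layer}."

        class P:
            pass

        p = P()
        for g in ("r", "z", "h"):
            setattr(p, f"W_{g}", params[pre + f"W_{g}"])
            setattr(p, f"b_{g}", params[pre + f"b_{g}"])
        p.U_r = params[pre + "U_r"]
        p.U_z = params[pre + "U_z"]
        p.U_h = params.get(pre + "U_h")
        feat = ref_gru_layer(feat, p, config.hidden)
        if config.use_se:
            feat, _ = ref_se_block(
                feat, params[f"se{layer}.W1"], params[f"se{layer}.W2"], config.se_axis
            )

    if config.fc_input == "last":
        v = list(feat[-1])
    else:
        v = [feat[t][c] for t in range(len(feat)) for c in range(len(feat[0]))]
    n = len(config.fc_sizes)
    for i in range(1, n + 1):
        W = params[f"fc{i}.W"]
        b = params[f"fc{i}.b"]
        v = [a + float(b[j]) for j, a in enumerate(_linear(v, W))]
        if i < n:
            v = [max(0.0, a) for a in v]
    return v[0]
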