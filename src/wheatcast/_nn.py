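"""NumPy neural-network engine for the sequence regressors.

Implements forward and backward passes for the layers the yield models
need — 1-D convolution over time ('same' padding, features as channels),
temporal max pooling, a batched LSTM layer usable in either direction,
and dense layers — plus an Adam optimizer.  Everything is written against
plain ndarrays with explicit caches so gradients can be verified against
finite differences.

Weight convention for the LSTM follows the gate equations: each gate
matrix has shape (H, H + F_in) and acts on the concatenation
[h_{t-1}, x_t]; gates use the logistic sigmoid, the candidate state and
cell output use tanh.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sigmoid",
    "glorot",
    "init_lstm_params",
    "lstm_layer_forward",
    "SequenceRegressorNet",
    "Adam",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


# ---------------------------------------------------------------------------
# LSTM layer


def init_lstm_params(rng: np.random.Generator, n_in: int, hidden: int, prefix: str) -> dict:
    p = {}
    for gate in ("f", "i", "g", "o"):
        p[f"{prefix}W{gate}"] = glorot(rng, hidden + n_in, hidden, (hidden, hidden + n_in))
        p[f"{prefix}b{gate}"] = np.zeros(hidden)
    # forget-gate bias starts at 1 so early training does not flush the cell
    p[f"{prefix}bf"] = np.ones(hidden)
    return p


def _lstm_step(z, c_prev, Wf, Wi, Wg, Wo, bf, bi, bg, bo):
    f = sigmoid(z @ Wf.T + bf)
    i = sigmoid(z @ Wi.T + bi)
    g = np.tanh(z @ Wg.T + bg)
    o = sigmoid(z @ Wo.T + bo)
    c = f * c_prev + i * g
    hc = np.tanh(c)
    h = o * hc
    return f, i, g, o, c, hc, h


def lstm_layer_forward(X: np.ndarray, params: dict, prefix: str, reverse: bool = False):
    """Run a batched LSTM over X (N, T, F_in).

    Returns (H_seq (N, T, H), cache).  With ``reverse=True`` the layer
    consumes the sequence back-to-front and its output is re-reversed so
    row t of H_seq aligns with time t.
    """
    N, T, _ = X.shape
    Wf, Wi = params[f"{prefix}Wf"], params[f"{prefix}Wi"]
    Wg, Wo = params[f"{prefix}Wg"], params[f"{prefix}Wo"]
    bf, bi = params[f"{prefix}bf"], params[f"{prefix}bi"]
    bg, bo = params[f"{prefix}bg"], params[f"{prefix}bo"]
    H = Wf.shape[0]

    order = range(T - 1, -1, -1) if reverse else range(T)
    h = np.zeros((N, H))
    c = np.zeros((N, H))
    steps = []
    H_seq = np.empty((N, T, H))
    for t in order:
        z = np.concatenate([h, X[:, t, :]], axis=1)
        f, i, g, o, c_new, hc, h_new = _lstm_step(z, c, Wf, Wi, Wg, Wo, bf, bi, bg, bo)
        steps.append((t, z, c, f, i, g, o, c_new, hc))
        h, c = h_new, c_new
        H_seq[:, t, :] = h
    cache = {"steps": steps, "prefix": prefix, "H": H, "n_in": X.shape[2], "reverse": reverse}
    return H_seq, cache


def lstm_layer_backward(dH_seq: np.ndarray, cache: dict) -> tuple[np.ndarray, dict]:
    """Backprop through time.  dH_seq matches the layer output alignment."""
    prefix, H = cache["prefix"], cache["H"]
    steps = cache["steps"]
    n_in = cache["n_in"]
    N, T, _ = dH_seq.shape

    grads = {
        f"{prefix}W{g}": np.zeros((H, H + n_in)) for g in ("f", "i", "g", "o")
    }
    for g in ("f", "i", "g", "o"):
        grads[f"{prefix}b{g}"] = np.zeros(H)
    dX = np.zeros((N, T, n_in))

    # walk the recorded steps in reverse processing order
    dh_next = np.zeros((N, H))
    dc_next = np.zeros((N, H))
    for t, z, c_prev, f, i, g, o, c_new, hc in reversed(steps):
        dh = dH_seq[:, t, :] + dh_next
        do = dh * hc
        dc = dc_next + dh * o * (1.0 - hc * hc)
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        dc_next = dc * f

        da_f = df * f * (1.0 - f)
        da_i = di * i * (1.0 - i)
        da_g = dg * (1.0 - g * g)
        da_o = do * o * (1.0 - o)

        grads[f"{prefix}Wf"] += da_f.T @ z
        grads[f"{prefix}Wi"] += da_i.T @ z
        grads[f"{prefix}Wg"] += da_g.T @ z
        grads[f"{prefix}Wo"] += da_o.T @ z
        grads[f"{prefix}bf"] += da_f.sum(axis=0)
        grads[f"{prefix}bi"] += da_i.sum(axis=0)
        grads[f"{prefix}bg"] += da_g.sum(axis=0)
        grads[f"{prefix}bo"] += da_o.sum(axis=0)

        dz = (
            da_f @ _P(cache, "Wf")
            + da_i @ _P(cache, "Wi")
            + da_g @ _P(cache, "Wg")
            + da_o @ _P(cache, "Wo")
        )
        dh_next = dz[:, :H]
        dX[:, t, :] = dz[:, H:]
    return dX, grads


def _P(cache: dict, name: str) -> np.ndarray:
    return cache["params_ref"][cache["prefix"] + name]


# ---------------------------------------------------------------------------
# full network


class SequenceRegressorNet:
    """CNN-BiLSTM (or plain LSTM) scalar regressor on (N, T, F) tensors.

    ``front_end='conv_bilstm'``: 1-D conv over time (ReLU, 'same' length)
    -> max pool along time -> BiLSTM -> the 2H concatenation of each
    direction's final state -> dense1 (ReLU) -> dense2 (ReLU) -> linear
    scalar.

    ``front_end='lstm'``: one unidirectional LSTM on the raw sequence ->
    last hidden state -> the same dense head.
    """

    def __init__(
        self,
        n_features: int,
        conv_filters: int = 32,
        conv_kernel: int = 3,
        pool_size: int = 2,
        hidden: int = 32,
        dense1: int = 32,
        dense2: int = 16,
        front_end: str = "conv_bilstm",
    ):
        if front_end not in ("conv_bilstm", "lstm"):
            raise ValueError(f"unknown front_end {front_end!r}")
        self.n_features = n_features
        self.conv_filters = conv_filters
        self.conv_kernel = conv_kernel
        self.pool_size = pool_size
        self.hidden = hidden
        self.dense1 = dense1
        self.dense2 = dense2
        self.front_end = front_end

    @property
    def head_in(self) -> int:
        return 2 * self.hidden if self.front_end == "conv_bilstm" else self.hidden

    def init_params(self, rng: np.random.Generator) -> dict:
        p = {}
        if self.front_end == "conv_bilstm":
            kf = self.conv_kernel * self.n_features
            p["Wc"] = glorot(rng, kf, self.conv_filters, (kf, self.conv_filters))
            p["bc"] = np.zeros(self.conv_filters)
            p.update(init_lstm_params(rng, self.conv_filters, self.hidden, "fw_"))
            p.update(init_lstm_params(rng, self.conv_filters, self.hidden, "bw_"))
        else:
            p.update(init_lstm_params(rng, self.n_features, self.hidden, "fw_"))
        p["W1"] = glorot(rng, self.head_in, self.dense1, (self.head_in, self.dense1))
        p["b1"] = np.zeros(self.dense1)
        p["W2"] = glorot(rng, self.dense1, self.dense2, (self.dense1, self.dense2))
        p["b2"] = np.zeros(self.dense2)
        p["W3"] = glorot(rng, self.dense2, 1, (self.dense2, 1))
        p["b3"] = np.zeros(1)
        return p

    # -- conv / pool helpers

    def _conv_patches(self, X: np.ndarray) -> np.ndarray:
        """im2col for 'same' 1-D convolution along the time axis."""
        N, T, F = X.shape
        K = self.conv_kernel
        pad_l = (K - 1) // 2
        pad_r = K - 1 - pad_l
        Xp = np.pad(X, ((0, 0), (pad_l, pad_r), (0, 0)))
        cols = [Xp[:, k : k + T, :] for k in range(K)]
        return np.concatenate(cols, axis=2)  # (N, T, K*F)

    def _conv_patches_backward(self, dP: np.ndarray, T: int) -> np.ndarray:
        N = dP.shape[0]
        K, F = self.conv_kernel, self.n_features
        pad_l = (K - 1) // 2
        pad_r = K - 1 - pad_l
        dXp = np.zeros((N, T + K - 1, F))
        for k in range(K):
            dXp[:, k : k + T, :] += dP[:, :, k * F : (k + 1) * F]
        return dXp[:, pad_l : pad_l + T, :]

    # -- forward / backward

    def forward(self, X: np.ndarray, params: dict) -> tuple[np.ndarray, dict]:
        """Return (predictions (N,), cache)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != self.n_features:
            raise ValueError(f"expected (N, T, {self.n_features}); got {X.shape}")
        cache: dict = {"X_shape": X.shape}

        if self.front_end == "conv_bilstm":
            N, T, _ = X.shape
            patches = self._conv_patches(X)
            pre = patches @ params["Wc"] + params["bc"]
            act = np.maximum(pre, 0.0)
            p = self.pool_size
            T2 = T // p
            if T2 < 1:
                raise ValueError(f"sequence of length {T} too short for pool size {p}")
            blocks = act[:, : T2 * p, :].reshape(N, T2, p, self.conv_filters)
            arg = blocks.argmax(axis=2)
            pooled = np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :]
            cache.update(patches=patches, pre=pre, arg=arg, T2=T2)

            fw, fw_cache = lstm_layer_forward(pooled, params, "fw_", reverse=False)
            bw, bw_cache = lstm_layer_forward(pooled, params, "bw_", reverse=True)
            fw_cache["params_ref"] = params
            bw_cache["params_ref"] = params
            # final state of each direction: forward at t=T-1, backward at t=0
            # (the backward layer's output is re-reversed, so its row 0 is the
            # state that has consumed the whole sequence)
            last = np.concatenate([fw[:, -1, :], bw[:, 0, :]], axis=1)
            cache.update(fw_cache=fw_cache, bw_cache=bw_cache, pooled_T=T2)
        else:
            fw, fw_cache = lstm_layer_forward(X, params, "fw_", reverse=False)
            fw_cache["params_ref"] = params
            last = fw[:, -1, :]
            cache.update(fw_cache=fw_cache)

        a1 = np.maximum(last @ params["W1"] + params["b1"], 0.0)
        a2 = np.maximum(a1 @ params["W2"] + params["b2"], 0.0)
        yhat = (a2 @ params["W3"] + params["b3"])[:, 0]
        cache.update(last=last, a1=a1, a2=a2, params_ref=params)
        return yhat, cache

    def backward(self, dyhat: np.ndarray, cache: dict) -> dict:
        """Gradients of a scalar loss w.r.t. all parameters."""
        params = cache["params_ref"]
        last, a1, a2 = cache["last"], cache["a1"], cache["a2"]
        dy = np.asarray(dyhat, dtype=float)[:, None]

        grads = {"W3": a2.T @ dy, "b3": dy.sum(axis=0)}
        da2 = (dy @ params["W3"].T) * (a2 > 0)
        grads["W2"] = a1.T @ da2
        grads["b2"] = da2.sum(axis=0)
        da1 = (da2 @ params["W2"].T) * (a1 > 0)
        grads["W1"] = last.T @ da1
        grads["b1"] = da1.sum(axis=0)
        dlast = da1 @ params["W1"].T

        if self.front_end == "conv_bilstm":
            N, T, _ = cache["X_shape"]
            T2 = cache["T2"]
            H = self.hidden
            dfw = np.zeros((N, T2, H))
            dbw = np.zeros((N, T2, H))
            dfw[:, -1, :] = dlast[:, :H]
            dbw[:, 0, :] = dlast[:, H:]
            dpool_f, g_f = lstm_layer_backward(dfw, cache["fw_cache"])
            dpool_b, g_b = lstm_layer_backward(dbw, cache["bw_cache"])
            grads.update(g_f)
            grads.update(g_b)
            dpooled = dpool_f + dpool_b

            p = self.pool_size
            dblocks = np.zeros((N, T2, p, self.conv_filters))
            np.put_along_axis(dblocks, cache["arg"][:, :, None, :], dpooled[:, :, None, :], axis=2)
            dact = np.zeros((N, T, self.conv_filters))
            dact[:, : T2 * p, :] = dblocks.reshape(N, T2 * p, self.conv_filters)
            dpre = dact * (cache["pre"] > 0)
            patches = cache["patches"]
            grads["Wc"] = np.einsum("ntk,ntc->kc", patches, dpre)
            grads["bc"] = dpre.sum(axis=(0, 1))
        else:
            N, T, _ = cache["X_shape"]
            dH = np.zeros((N, T, self.hidden))
            dH[:, -1, :] = dlast
            _, g_f = lstm_layer_backward(dH, cache["fw_cache"])
            grads.update(g_f)
        return grads

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray, params: dict):
        """Mean-squared-error loss and its parameter gradients."""
        yhat, cache = self.forward(X, params)
        resid = yhat - y
        loss = float(np.mean(resid**2))
        grads = self.backward(2.0 * resid / len(y), cache)
        return loss, grads


class Adam:
    """Adam optimizer over a parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
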