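"""Numpy neural-network building blocks with reverse-mode gradients.

Each layer owns ``params`` and ``grads`` dicts of identically shaped
arrays; ``forward`` caches what ``backward`` needs. Inputs are processed
one sequence at a time (a spectrogram of shape (N, bins)); minibatching
is done by gradient accumulation across clips, which keeps every softmax
normalization over real frames only.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def tanh(x: np.ndarray) -> np.ndarray:
    return np.tanh(x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def softmax(x: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    z = x - np.max(x, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def glorot(rng: np.random.Generator, *shape: int) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base: a named bag of parameters and matching gradients."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grads(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)


class Conv2DTanh(Layer):
    """2-D convolution over (time, frequency) with same padding, stride 1,
    tanh activation. Input (N, F, C_in) -> output (N, F, C_out).

    Kernel (1, 4) scans frequency within a frame; (4, 4) spans both axes.
    """

    def __init__(
        self, c_in: int, c_out: int, kernel: tuple[int, int], rng: np.random.Generator
    ) -> None:
        super().__init__()
        kt, kf = kernel
        self.kernel = (kt, kf)
        fan_in = c_in * kt * kf
        limit = np.sqrt(6.0 / (fan_in + c_out))
        self.params["W"] = rng.uniform(-limit, limit, size=(c_out, c_in, kt, kf))
        self.params["b"] = np.zeros(c_out)
        self.zero_grads()

    @staticmethod
    def _pad(k: int) -> tuple[int, int]:
        lo = (k - 1) // 2
        return lo, k - 1 - lo

    def forward(self, x: np.ndarray) -> np.ndarray:
        kt, kf = self.kernel
        if x.shape[0] < 1 or x.shape[1] < 1:
            raise ValueError("empty input to convolution")
        pt, pf = self._pad(kt), self._pad(kf)
        xp = np.pad(x, (pt, pf, (0, 0)))
        win = sliding_window_view(xp, (kt, kf), axis=(0, 1))  # (N, F, C, kt, kf)
        z = np.einsum("nfcij,ocij->nfo", win, self.params["W"]) + self.params["b"]
        a = np.tanh(z)
        self._cache = (win, a)
        return a

    def backward(self, da: np.ndarray) -> np.ndarray:
        kt, kf = self.kernel
        win, a = self._cache
        dz = da * (1.0 - a * a)
        self.grads["W"] += np.einsum("nfcij,nfo->ocij", win, dz)
        self.grads["b"] += dz.sum(axis=(0, 1))
        # full correlation of dz with the flipped kernel gives d(x padded)
        dzp = np.pad(dz, ((kt - 1, kt - 1), (kf - 1, kf - 1), (0, 0)))
        dwin = sliding_window_view(dzp, (kt, kf), axis=(0, 1))
        w_flip = self.params["W"][:, :, ::-1, ::-1]
        dxp = np.einsum("mgoij,ocij->mgc", dwin, w_flip)
        pt, pf = self._pad(kt), self._pad(kf)
        n, f = a.shape[0], a.shape[1]
        return dxp[pt[0] : pt[0] + n, pf[0] : pf[0] + f, :]


class LSTM(Layer):
    """Single LSTM layer over a sequence. Input (N, D) -> outputs (N, H).

    Gate order in the packed weight matrices is (input, forget, cell,
    output); the forget-gate bias starts at 1.
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.d_in, self.d_hidden = d_in, d_hidden
        self.params["Wx"] = glorot(rng, d_in, 4 * d_hidden)
        self.params["Wh"] = glorot(rng, d_hidden, 4 * d_hidden)
        b = np.zeros(4 * d_hidden)
        b[d_hidden : 2 * d_hidden] = 1.0
        self.params["b"] = b
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, hdim = x.shape[0], self.d_hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        pre = x @ Wx + b  # input contribution for all steps at once
        h = np.zeros((n, hdim))
        c = np.zeros((n, hdim))
        gates = np.zeros((n, 4 * hdim))
        h_prev = np.zeros(hdim)
        c_prev = np.zeros(hdim)
        for t in range(n):
            g = pre[t] + h_prev @ Wh
            i = sigmoid(g[:hdim])
            f = sigmoid(g[hdim : 2 * hdim])
            gc = np.tanh(g[2 * hdim : 3 * hdim])
            o = sigmoid(g[3 * hdim :])
            c_t = f * c_prev + i * gc
            h_t = o * np.tanh(c_t)
            gates[t] = np.concatenate([i, f, gc, o])
            c[t], h[t] = c_t, h_t
            h_prev, c_prev = h_t, c_t
        self._cache = (x, h, c, gates)
        return h

    def backward(self, dh_out: np.ndarray) -> np.ndarray:
        x, h, c, gates = self._cache
        n, hdim = x.shape[0], self.d_hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dx = np.zeros_like(x)
        dgates_all = np.zeros((n, 4 * hdim))
        dh_next = np.zeros(hdim)
        dc_next = np.zeros(hdim)
        tanh_c = np.tanh(c)
        for t in range(n - 1, -1, -1):
            i = gates[t, :hdim]
            f = gates[t, hdim : 2 * hdim]
            gc = gates[t, 2 * hdim : 3 * hdim]
            o = gates[t, 3 * hdim :]
            c_prev = c[t - 1] if t > 0 else np.zeros(hdim)
            dh = dh_out[t] + dh_next
            do = dh * tanh_c[t]
            dc = dc_next + dh * o * (1.0 - tanh_c[t] ** 2)
            di, df, dgc = dc * gc, dc * c_prev, dc * i
            dg = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dgc * (1 - gc * gc),
                    do * o * (1 - o),
                ]
            )
            dgates_all[t] = dg
            dh_next = Wh @ dg
            dc_next = dc * f
            dx[t] = Wx @ dg
        self.grads["Wx"] += x.T @ dgates_all
        h_prev = np.vstack([np.zeros(hdim), h[:-1]])
        self.grads["Wh"] += h_prev.T @ dgates_all
        self.grads["b"] += dgates_all.sum(axis=0)
        return dx


class Dense(Layer):
    """Fully connected layer, tanh or linear activation. Input 1-D."""

    def __init__(
        self, d_in: int, d_out: int, rng: np.random.Generator, activation: str = "tanh"
    ) -> None:
        super().__init__()
        if activation not in ("tanh", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.params["W"] = glorot(rng, d_in, d_out)
        self.params["b"] = np.zeros(d_out)
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x @ self.params["W"] + self.params["b"]
        a = np.tanh(z) if self.activation == "tanh" else z
        self._cache = (x, a)
        return a

    def backward(self, da: np.ndarray) -> np.ndarray:
        x, a = self._cache
        dz = da * (1.0 - a * a) if self.activation == "tanh" else da
        self.grads["W"] += np.outer(x, dz)
        self.grads["b"] += dz
        return self.params["W"] @ dz


class TapAttention(Layer):
    """Temporal attentive pooling over conv features and the final
    recurrent state.

    Per frame n with conv feature y(n) and last recurrent output h(N):

    * global attentive vector ``c(n) = [W_c y(n); W_r h(N)]``;
    * global weight ``alpha(n) = softmax_n(u^T tanh(c(n) + b_global))``;
    * scaled feature ``z(n) = alpha(n) y(n)``;
    * local weight ``beta(n) = softmax_n(v^T tanh(W_l z(n) + b_l))``;
    * attentive context ``f_hat = (1/N) sum_n alpha(n) beta(n) y(n)``;
    * dense-head input ``s = [f_hat; W_g h(N)]``.

    Both softmaxes are taken across the N frames of the clip, so each
    weight vector is a distribution over time; their per-frame product is
    the event presence likelihood (EPL).

    The score vectors u and v start at zero, so both attentions open
    exactly uniform and the first parameter updates — not the sign of a
    random draw — decide which frames get emphasized. A random-signed
    start makes the trained attention polarity a coin flip between
    "attend the event" and "attend the background", two configurations
    the classification loss cannot distinguish once training converges.
    """

    def __init__(self, cnn_dim: int, rnn_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.cnn_dim, self.rnn_dim = cnn_dim, rnn_dim
        p = self.params
        p["W_c"] = glorot(rng, cnn_dim, cnn_dim)
        p["W_r"] = glorot(rng, rnn_dim, rnn_dim)
        p["u"] = np.zeros(cnn_dim + rnn_dim)
        p["b_global"] = np.zeros(cnn_dim + rnn_dim)
        p["W_l"] = glorot(rng, cnn_dim, cnn_dim)
        p["b_l"] = np.zeros(cnn_dim)
        p["v"] = np.zeros(cnn_dim)
        p["W_g"] = glorot(rng, rnn_dim, rnn_dim)
        self.zero_grads()

    def forward(self, Y: np.ndarray, hN: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (s, alpha, beta) for conv features Y (N, cnn_dim)."""
        p = self.params
        ct = Y @ p["W_c"].T  # top block of c(n), all frames at once
        cb = p["W_r"] @ hN  # bottom block, shared by every frame
        r = np.tanh(
            np.concatenate([ct, np.broadcast_to(cb, (Y.shape[0], self.rnn_dim))], axis=1)
            + p["b_global"]
        )
        e = r @ p["u"]
        alpha = softmax(e)
        Z = alpha[:, None] * Y
        q = np.tanh(Z @ p["W_l"].T + p["b_l"])
        g = q @ p["v"]
        beta = softmax(g)
        w = alpha * beta
        f_hat = (w[:, None] * Y).sum(axis=0) / Y.shape[0]
        s = np.concatenate([f_hat, p["W_g"] @ hN])
        self._cache = (Y, hN, r, alpha, Z, q, beta)
        return s, alpha, beta

    def backward(self, ds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (dY, dhN) given the gradient of the loss w.r.t. s."""
        p = self.params
        Y, hN, r, alpha, Z, q, beta = self._cache
        n = Y.shape[0]
        df = ds[: self.cnn_dim]
        dsr = ds[self.cnn_dim :]
        self.grads["W_g"] += np.outer(dsr, hN)
        dhN = p["W_g"].T @ dsr

        w = alpha * beta
        dY = (w[:, None] / n) * df[None, :]
        dw = (Y @ df) / n
        dalpha = beta * dw
        dbeta = alpha * dw

        # local softmax
        dg = beta * (dbeta - float(beta @ dbeta))
        self.grads["v"] += q.T @ dg
        dq = np.outer(dg, p["v"])
        dp_loc = dq * (1.0 - q * q)
        self.grads["W_l"] += dp_loc.T @ Z
        self.grads["b_l"] += dp_loc.sum(axis=0)
        dZ = dp_loc @ p["W_l"]
        dalpha += np.einsum("nd,nd->n", dZ, Y)
        dY += alpha[:, None] * dZ

        # global softmax
        de = alpha * (dalpha - float(alpha @ dalpha))
        self.grads["u"] += r.T @ de
        dr = np.outer(de, p["u"])
        dc = dr * (1.0 - r * r)
        self.grads["b_global"] += dc.sum(axis=0)
        dct = dc[:, : self.cnn_dim]
        dcb = dc[:, self.cnn_dim :].sum(axis=0)
        self.grads["W_c"] += dct.T @ Y
        dY += dct @ p["W_c"]
        self.grads["W_r"] += np.outer(dcb, hN)
        dhN += p["W_r"].T @ dcb
        return dY, dhN


class Adam:
    """Adaptive moment estimation over a flat name -> array parameter dict."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def softmax_xent(logits: np.ndarray, target: int) -> tuple[float, np.ndarray, np.ndarray]:
    """Return (loss, probs, dlogits) for one sample."""
    probs = softmax(logits)
    loss = -float(np.log(max(probs[target], 1e-300)))
    dlogits = probs.copy()
    dlogits[target] -= 1.0
    return loss, probs, dlogits
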