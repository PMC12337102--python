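"""Minimal NumPy recurrent networks with exact input gradients.

Implements the three model families used by the decoding pipeline:

* a stacked unidirectional LSTM with a per-timestep linear read-out
  (streaming frame classifier),
* a 1-D temporal convolution followed by stacked GRUs and a linear
  read-out on the final hidden state (window classifier),

together with cross-entropy losses, Adam, and full backward passes.
Backpropagation returns the gradient of the loss with respect to the
*inputs* as well, which the mapping module uses for electrode-contribution
(saliency) analyses.  Everything is float64 and seeded, so training is
bit-reproducible on CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "LSTMLayer",
    "GRULayer",
    "Conv1DLayer",
    "DenseLayer",
    "SequenceNet",
    "WindowNet",
    "Adam",
    "softmax",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan: int) -> np.ndarray:
    k = 1.0 / np.sqrt(fan)
    return rng.uniform(-k, k, size=shape)


class DenseLayer:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = _uniform_init(rng, (in_dim, out_dim), in_dim)
        self.b = np.zeros(out_dim)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        flat_x = x.reshape(-1, x.shape[-1])
        flat_d = dout.reshape(-1, dout.shape[-1])
        self.dW += flat_x.T @ flat_d
        self.db += flat_d.sum(axis=0)
        return dout @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class Conv1DLayer:
    """Temporal convolution over (batch, time, features), valid padding, stride 1."""

    def __init__(self, in_dim: int, out_dim: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.W = _uniform_init(rng, (kernel, in_dim, out_dim), kernel * in_dim)
        self.b = np.zeros(out_dim)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        B, T, D = x.shape
        k = self.kernel
        if T < k:
            raise ValueError(f"input length {T} shorter than kernel {k}")
        # windows: (B, T-k+1, k, D)
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        win = np.moveaxis(win, -1, 2)
        out = np.einsum("btkd,kdh->bth", win, self.W, optimize=True) + self.b
        return np.tanh(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, D = x.shape
        k = self.kernel
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        win = np.moveaxis(win, -1, 2)
        pre = np.einsum("btkd,kdh->bth", win, self.W, optimize=True) + self.b
        dpre = dout * (1.0 - np.tanh(pre) ** 2)
        self.dW += np.einsum("btkd,bth->kdh", win, dpre, optimize=True)
        self.db += dpre.sum(axis=(0, 1))
        dx = np.zeros_like(x)
        dwin = np.einsum("bth,kdh->btkd", dpre, self.W, optimize=True)
        for j in range(k):
            dx[:, j : j + T - k + 1, :] += dwin[:, :, j, :]
        return dx

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class LSTMLayer:
    """Unidirectional LSTM. Gate order: input, forget, cell, output."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.Wx = _uniform_init(rng, (in_dim, 4 * hidden), hidden)
        self.Wh = _uniform_init(rng, (hidden, 4 * hidden), hidden)
        self.b = np.zeros(4 * hidden)
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(
        self,
        x: np.ndarray,
        h0: np.ndarray | None = None,
        c0: np.ndarray | None = None,
    ) -> np.ndarray:
        B, T, D = x.shape
        H = self.hidden
        h = np.zeros((B, H)) if h0 is None else h0
        c = np.zeros((B, H)) if c0 is None else c0
        hs = np.empty((B, T, H))
        gates = np.empty((B, T, 4 * H))
        cs = np.empty((B, T, H))
        c_prevs = np.empty((B, T, H))
        h_prevs = np.empty((B, T, H))
        xw = x @ self.Wx + self.b  # precompute input projections
        for t in range(T):
            z = xw[:, t] + h @ self.Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prevs[:, t] = c
            h_prevs[:, t] = h
            c = f * c + i * g
            h = o * np.tanh(c)
            gates[:, t, :H] = i
            gates[:, t, H : 2 * H] = f
            gates[:, t, 2 * H : 3 * H] = g
            gates[:, t, 3 * H :] = o
            cs[:, t] = c
            hs[:, t] = h
        self._cache = (x, gates, cs, c_prevs, h_prevs)
        self.h_last = h
        self.c_last = c
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        x, gates, cs, c_prevs, h_prevs = self._cache
        B, T, D = x.shape
        H = self.hidden
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        dz_all = np.empty((B, T, 4 * H))
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :H]
            f = gates[:, t, H : 2 * H]
            g = gates[:, t, 2 * H : 3 * H]
            o = gates[:, t, 3 * H :]
            tc = np.tanh(cs[:, t])
            dh = dhs[:, t] + dh_next
            dc = dh * o * (1.0 - tc**2) + dc_next
            dz = np.empty((B, 4 * H))
            dz[:, :H] = dc * g * i * (1.0 - i)
            dz[:, H : 2 * H] = dc * c_prevs[:, t] * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = dc * i * (1.0 - g**2)
            dz[:, 3 * H :] = dh * tc * o * (1.0 - o)
            dz_all[:, t] = dz
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        flat_dz = dz_all.reshape(-1, 4 * H)
        self.dWx += x.reshape(-1, D).T @ flat_dz
        self.dWh += h_prevs.reshape(-1, H).T @ flat_dz
        self.db += flat_dz.sum(axis=0)
        dx[:] = (dz_all @ self.Wx.T)
        return dx

    @property
    def params(self):
        return [self.Wx, self.Wh, self.b]

    @property
    def grads(self):
        return [self.dWx, self.dWh, self.db]


class GRULayer:
    """Unidirectional GRU, reset-before-candidate formulation."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.Wx = _uniform_init(rng, (in_dim, 3 * hidden), hidden)  # r, z, n
        self.Wh = _uniform_init(rng, (hidden, 2 * hidden), hidden)  # r, z
        self.Whn = _uniform_init(rng, (hidden, hidden), hidden)
        self.b = np.zeros(3 * hidden)
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.dWhn = np.zeros_like(self.Whn)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray, h0: np.ndarray | None = None) -> np.ndarray:
        B, T, D = x.shape
        H = self.hidden
        h = np.zeros((B, H)) if h0 is None else h0
        hs = np.empty((B, T, H))
        rs = np.empty((B, T, H))
        zs = np.empty((B, T, H))
        ns = np.empty((B, T, H))
        hns = np.empty((B, T, H))
        h_prevs = np.empty((B, T, H))
        xw = x @ self.Wx + self.b
        for t in range(T):
            rz = xw[:, t, : 2 * H] + h @ self.Wh
            r = _sigmoid(rz[:, :H])
            z = _sigmoid(rz[:, H:])
            hn = h @ self.Whn
            n = np.tanh(xw[:, t, 2 * H :] + r * hn)
            h_prevs[:, t] = h
            h = (1.0 - z) * n + z * h
            rs[:, t], zs[:, t], ns[:, t], hns[:, t] = r, z, n, hn
            hs[:, t] = h
        self._cache = (x, rs, zs, ns, hns, h_prevs)
        self.h_last = h
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        x, rs, zs, ns, hns, h_prevs = self._cache
        B, T, D = x.shape
        H = self.hidden
        dh_next = np.zeros((B, H))
        dxw = np.empty((B, T, 3 * H))
        drz_all = np.empty((B, T, 2 * H))
        dhn_all = np.empty((B, T, H))
        for t in range(T - 1, -1, -1):
            r, z, n, hn = rs[:, t], zs[:, t], ns[:, t], hns[:, t]
            h_prev = h_prevs[:, t]
            dh = dhs[:, t] + dh_next
            dz_gate = dh * (h_prev - n) * z * (1.0 - z)
            dn = dh * (1.0 - z)
            dpre_n = dn * (1.0 - n**2)
            dr = dpre_n * hn
            dhn = dpre_n * r
            dr_pre = dr * r * (1.0 - r)
            drz = np.concatenate([dr_pre, dz_gate], axis=1)
            dxw[:, t, : 2 * H] = drz
            dxw[:, t, 2 * H :] = dpre_n
            drz_all[:, t] = drz
            dhn_all[:, t] = dhn
            dh_next = dh * z + drz @ self.Wh.T + dhn @ self.Whn.T
        flat_dxw = dxw.reshape(-1, 3 * H)
        self.dWx += x.reshape(-1, D).T @ flat_dxw
        self.db += flat_dxw.sum(axis=0)
        flat_hp = h_prevs.reshape(-1, H)
        self.dWh += flat_hp.T @ drz_all.reshape(-1, 2 * H)
        self.dWhn += flat_hp.T @ dhn_all.reshape(-1, H)
        return dxw @ self.Wx.T

    @property
    def params(self):
        return [self.Wx, self.Wh, self.Whn, self.b]

    @property
    def grads(self):
        return [self.dWx, self.dWh, self.dWhn, self.db]


class _Net:
    layers: list

    @property
    def params(self):
        return [p for lay in self.layers for p in lay.params]

    @property
    def grads(self):
        return [g for lay in self.layers for g in lay.grads]

    def zero_grad(self) -> None:
        for g in self.grads:
            g[:] = 0.0


class SequenceNet(_Net):
    """Stacked LSTMs + per-timestep linear head; frame-wise class probabilities.

    Strictly causal: the output at time t depends only on inputs at times <= t.
    """

    def __init__(self, in_dim: int, hidden: int, n_classes: int, n_layers: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.lstms = [
            LSTMLayer(in_dim if i == 0 else hidden, hidden, rng) for i in range(n_layers)
        ]
        self.head = DenseLayer(hidden, n_classes, rng)
        self.layers = [*self.lstms, self.head]
        self.n_classes = n_classes
        self.in_dim = in_dim

    def forward_logits(self, x: np.ndarray, state=None) -> tuple[np.ndarray, list]:
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"feature width {x.shape[-1]} != trained width {self.in_dim}")
        h = x
        new_state = []
        for i, lstm in enumerate(self.lstms):
            if state is None:
                h = lstm.forward(h)
            else:
                h = lstm.forward(h, state[i][0], state[i][1])
            new_state.append((lstm.h_last, lstm.c_last))
        return self.head.forward(h), new_state

    def probabilities(self, x: np.ndarray, state=None) -> np.ndarray:
        logits, _ = self.forward_logits(x, state)
        return softmax(logits)

    def loss_and_backward(self, x: np.ndarray, y: np.ndarray, mask: np.ndarray) -> tuple[float, np.ndarray]:
        """Masked mean cross-entropy over frames; returns (loss, dL/dx)."""
        logits, _ = self.forward_logits(x)
        p = softmax(logits)
        n = max(int(mask.sum()), 1)
        eps = 1e-12
        bidx, tidx = np.indices(y.shape)
        loss = -np.sum(mask * np.log(p[bidx, tidx, y] + eps)) / n
        dlogits = p.copy()
        dlogits[bidx, tidx, y] -= 1.0
        dlogits *= (mask / n)[..., None]
        dh = self.head.backward(dlogits)
        for lstm in reversed(self.lstms):
            dh = lstm.backward(dh)
        return float(loss), dh


class WindowNet(_Net):
    """Conv1D -> stacked GRUs -> linear head on the final hidden state."""

    def __init__(
        self,
        in_dim: int,
        n_classes: int,
        hidden: int = 64,
        conv_width: int = 5,
        conv_channels: int | None = None,
        n_gru_layers: int = 2,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        conv_channels = hidden if conv_channels is None else conv_channels
        self.conv = Conv1DLayer(in_dim, conv_channels, conv_width, rng)
        self.grus = [
            GRULayer(conv_channels if i == 0 else hidden, hidden, rng)
            for i in range(n_gru_layers)
        ]
        self.head = DenseLayer(hidden, n_classes, rng)
        self.layers = [self.conv, *self.grus, self.head]
        self.n_classes = n_classes
        self.in_dim = in_dim

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"feature width {x.shape[-1]} != trained width {self.in_dim}")
        h = self.conv.forward(x)
        for gru in self.grus:
            h = gru.forward(h)
        self._T_gru = h.shape[1]
        return self.head.forward(h[:, -1, :])

    def probabilities(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward_logits(x))

    def loss_and_backward(self, x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        logits = self.forward_logits(x)
        p = softmax(logits)
        B = x.shape[0]
        eps = 1e-12
        loss = -np.mean(np.log(p[np.arange(B), y] + eps))
        dlogits = p.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        dh_last = self.head.backward(dlogits)
        dh = np.zeros((B, self._T_gru, self.grus[-1].hidden))
        dh[:, -1, :] = dh_last
        for gru in reversed(self.grus):
            dh = gru.backward(dh)
        return float(loss), self.conv.backward(dh)

    def input_gradient(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """dL/dx of the cross-entropy loss at the true labels (saliency)."""
        self.zero_grad()
        _, dx = self.loss_and_backward(x, y)
        self.zero_grad()
        return dx


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def fit_window_net(
    net: WindowNet,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 30,
    lr: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    patience: int = 5,
    weight_decay: float = 0.0,
) -> list[float]:
    """Adam minibatch training; optional early stopping on validation loss."""
    rng = np.random.default_rng(seed)
    opt = Adam(net.params, lr=lr)
    n = X.shape[0]
    losses = []
    best_val = np.inf
    best_params = None
    wait = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            net.zero_grad()
            loss, _ = net.loss_and_backward(X[idx], y[idx])
            if weight_decay:
                opt.step([g + weight_decay * p for g, p in zip(net.grads, net.params)])
            else:
                opt.step(net.grads)
            ep_loss += loss * len(idx)
        losses.append(ep_loss / n)
        if X_val is not None and len(X_val):
            p = net.probabilities(X_val)
            vloss = -float(np.mean(np.log(p[np.arange(len(y_val)), y_val] + 1e-12)))
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_params = [p_.copy() for p_ in net.params]
                wait = 0
            else:
                wait += 1
                if wait >= patience:
                    break
    if best_params is not None:
        for p_, bp in zip(net.params, best_params):
            p_[:] = bp
    return losses


def fit_sequence_net(
    net: SequenceNet,
    chunks_x: np.ndarray,
    chunks_y: np.ndarray,
    chunks_m: np.ndarray,
    epochs: int = 30,
    lr: float = 1e-3,
    batch_size: int = 8,
    seed: int = 0,
) -> list[float]:
    """Truncated-BPTT training over fixed-length chunks (zero initial state)."""
    rng = np.random.default_rng(seed)
    opt = Adam(net.params, lr=lr)
    n = chunks_x.shape[0]
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            net.zero_grad()
            loss, _ = net.loss_and_backward(chunks_x[idx], chunks_y[idx], chunks_m[idx])
            opt.step(net.grads)
            ep_loss += loss * len(idx)
        losses.append(ep_loss / n)
    return losses
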