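"""Minimal numpy neural networks for one-step-ahead regression.

Both networks are small enough (<= 4 hidden layers, <= 64 units, lag-2
input windows) that explicit forward/backward passes in numpy are fast and
make the training regimes fully controllable: mini-batch order (shuffled or
chronological), node dropout, and — for the recurrent net — recurrent-
connection dropout, all reproducible from a single seed.

Training minimizes mean squared one-step error with Adam (lr 1e-3).
Dropout is the inverted variant: surviving activations are scaled by
1/(1-rate) at train time so inference needs no rescaling.  When the rate is
zero (or dropout is off) no masks are drawn at all, so a zero-rate dropout
run consumes the same random stream as a plain run and is bit-for-bit
identical to it.
"""

from __future__ import annotations

import numpy as np

_ADAM_BETA1 = 0.9
_ADAM_BETA2 = 0.999
_ADAM_EPS = 1e-8


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _glorot(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _Adam:
    """One Adam state per parameter array, updated in place."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - _ADAM_BETA1**self.t
        bc2 = 1.0 - _ADAM_BETA2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= _ADAM_BETA1
            m += (1.0 - _ADAM_BETA1) * g
            v *= _ADAM_BETA2
            v += (1.0 - _ADAM_BETA2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + _ADAM_EPS)


def _batches(n: int, batch_size: int, shuffle: bool, rng: np.random.Generator):
    order = rng.permutation(n) if shuffle else np.arange(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def mlp_forward(window, weights, biases) -> float:
    """Feed-forward pass: ReLU on every hidden layer, linear output unit.

    ``weights``/``biases`` list one entry per layer; the final pair maps to
    the single output neuron.
    """
    a = np.asarray(window, dtype=float)
    for W, b in zip(weights[:-1], biases[:-1]):
        a = _relu(a @ W + b)
    out = a @ weights[-1] + biases[-1]
    return float(out.item()) if out.size == 1 else out


class MLPNet:
    """Fully connected feed-forward regressor (hidden ReLU, linear output)."""

    def __init__(self, lag: int, hidden_layers: int, neurons: int, seed: int):
        rng = np.random.default_rng(seed)
        sizes = [lag] + [neurons] * hidden_layers + [1]
        self.weights = [_glorot(rng, a, b) for a, b in zip(sizes[:-1], sizes[1:])]
        self.biases = [np.zeros(b) for b in sizes[1:]]
        self._rng = rng

    @property
    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def predict(self, X: np.ndarray) -> np.ndarray:
        a = np.atleast_2d(np.asarray(X, dtype=float))
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = _relu(a @ W + b)
        return (a @ self.weights[-1] + self.biases[-1]).ravel()

    def _forward_backward(self, X, y, dropout_rate):
        n_hidden = len(self.weights) - 1
        activations = [X]
        masks = []
        a = X
        for li in range(n_hidden):
            a = _relu(a @ self.weights[li] + self.biases[li])
            if dropout_rate > 0.0:
                mask = (self._rng.random(a.shape) >= dropout_rate) / (1.0 - dropout_rate)
                a = a * mask
                masks.append(mask)
            activations.append(a)
        out = (a @ self.weights[-1] + self.biases[-1]).ravel()
        delta = (2.0 / len(y)) * (out - y)[:, None]

        grads_W = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        grads_W[-1] = activations[-1].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        d = delta @ self.weights[-1].T
        for li in range(n_hidden - 1, -1, -1):
            act = activations[li + 1]
            if dropout_rate > 0.0:
                d = d * masks[li]
            d = d * (act > 0)
            grads_W[li] = activations[li].T @ d
            grads_b[li] = d.sum(axis=0)
            if li:
                d = d @ self.weights[li].T
        return grads_W + grads_b

    def fit(self, X, y, *, epochs, batch_size, shuffle, dropout_rate=0.0) -> "MLPNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        opt = _Adam(self.parameters)
        for _ in range(epochs):
            for idx in _batches(len(y), batch_size, shuffle, self._rng):
                opt.step(self._forward_backward(X[idx], y[idx], dropout_rate))
        return self


class LSTMNet:
    """Stacked LSTM regressor over length-``lag`` scalar sequences.

    Standard memory-cell gating with sigmoid input/forget/output gates and
    ReLU as the cell-input and cell-output activation; a single linear unit
    reads the last hidden state.  Gate weight layout along the last axis is
    [input, forget, cell, output].  Node dropout masks each recurrent
    layer's output sequence; recurrent dropout masks the previous hidden
    state on the recurrent path.  Either mask is drawn once per batch and
    shared across time steps.
    """

    def __init__(self, lag: int, hidden_layers: int, neurons: int, seed: int):
        rng = np.random.default_rng(seed)
        self.lag = lag
        self.hidden = neurons
        self.W, self.U, self.b = [], [], []
        in_dim = 1
        for _ in range(hidden_layers):
            self.W.append(_glorot(rng, in_dim, 4 * neurons))
            self.U.append(_glorot(rng, neurons, 4 * neurons))
            bias = np.zeros(4 * neurons)
            bias[neurons : 2 * neurons] = 1.0  # forget-gate bias init
            self.b.append(bias)
            in_dim = neurons
        self.w_out = _glorot(rng, neurons, 1)
        self.b_out = np.zeros(1)
        self._rng = rng

    @property
    def parameters(self) -> list[np.ndarray]:
        return [*self.W, *self.U, *self.b, self.w_out, self.b_out]

    def _layer_forward(self, x_seq, li, rec_mask=None, cache=None):
        """Run layer ``li`` over the (B, T, D) sequence; returns (B, T, H)."""
        B, T, _ = x_seq.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        out = np.empty((B, T, H))
        for t in range(T):
            h_rec = h * rec_mask if rec_mask is not None else h
            z = x_seq[:, t, :] @ self.W[li] + h_rec @ self.U[li] + self.b[li]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = _relu(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            a = _relu(c)
            h = o * a
            out[:, t, :] = h
            if cache is not None:
                cache.append((x_seq[:, t, :], h_rec, i, f, g, o, c_prev, c, a, z))
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        seq = np.atleast_2d(np.asarray(X, dtype=float))[:, :, None]
        for li in range(len(self.W)):
            seq = self._layer_forward(seq, li)
        return (seq[:, -1, :] @ self.w_out + self.b_out).ravel()

    def _forward_backward(self, X, y, dropout_rate, dropout_mode):
        B = len(y)
        H = self.hidden
        n_layers = len(self.W)
        keep = 1.0 - dropout_rate

        seq = X[:, :, None]
        caches, inputs, out_masks, rec_masks = [], [], [], []
        for li in range(n_layers):
            rec_mask = None
            if dropout_mode == "recurrent" and dropout_rate > 0.0:
                rec_mask = (self._rng.random((B, H)) >= dropout_rate) / keep
            cache: list = []
            inputs.append(seq)
            out = self._layer_forward(seq, li, rec_mask, cache)
            caches.append(cache)
            rec_masks.append(rec_mask)
            if dropout_mode == "node" and dropout_rate > 0.0:
                mask = (self._rng.random((B, H)) >= dropout_rate) / keep
                out = out * mask[:, None, :]
                out_masks.append(mask)
            else:
                out_masks.append(None)
            seq = out

        pred = (seq[:, -1, :] @ self.w_out + self.b_out).ravel()
        delta = (2.0 / B) * (pred - y)[:, None]

        gW = [np.zeros_like(w) for w in self.W]
        gU = [np.zeros_like(u) for u in self.U]
        gb = [np.zeros_like(b) for b in self.b]
        g_wout = seq[:, -1, :].T @ delta
        g_bout = delta.sum(axis=0)

        T = X.shape[1]
        # gradient w.r.t. each layer's (masked) output sequence
        d_out = np.zeros((B, T, H))
        d_out[:, -1, :] = delta @ self.w_out.T
        for li in range(n_layers - 1, -1, -1):
            if out_masks[li] is not None:
                d_out = d_out * out_masks[li][:, None, :]
            cache = caches[li]
            rec_mask = rec_masks[li]
            d_x_seq = np.zeros_like(inputs[li])
            dh_carry = np.zeros((B, H))
            dc_carry = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                x_t, h_rec, i, f, g, o, c_prev, c, a, z = cache[t]
                dh = d_out[:, t, :] + dh_carry
                do = dh * a
                dc = dh * o * (c > 0) + dc_carry
                di = dc * g
                dg = dc * i
                df = dc * c_prev
                dc_carry = dc * f
                dz = np.concatenate(
                    [
                        di * i * (1.0 - i),
                        df * f * (1.0 - f),
                        dg * (z[:, 2 * H : 3 * H] > 0),
                        do * o * (1.0 - o),
                    ],
                    axis=1,
                )
                gW[li] += x_t.T @ dz
                gU[li] += h_rec.T @ dz
                gb[li] += dz.sum(axis=0)
                d_x_seq[:, t, :] = dz @ self.W[li].T
                dh_carry = dz @ self.U[li].T
                if rec_mask is not None:
                    dh_carry = dh_carry * rec_mask
            d_out = d_x_seq
        return [*gW, *gU, *gb, g_wout, g_bout]

    def fit(self, X, y, *, epochs, batch_size, shuffle, dropout_rate=0.0,
            dropout_mode="none") -> "LSTMNet":
        if dropout_mode not in ("none", "node", "recurrent"):
            raise ValueError(f"unknown dropout_mode {dropout_mode!r}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        opt = _Adam(self.parameters)
        for _ in range(epochs):
            for idx in _batches(len(y), batch_size, shuffle, self._rng):
                opt.step(self._forward_backward(X[idx], y[idx], dropout_rate, dropout_mode))
        return self
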