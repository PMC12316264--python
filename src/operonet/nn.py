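"""A compact numpy implementation of the CNN-LSTM-attention classifier.

The network maps one gene-pair tensor ``(150, 6, 3)`` — positions x sample
rows x region channels — to a 2-class softmax:

* ``Conv2D`` with 64 filters and kernel ``(5, 6)``, valid padding.  The
  kernel spans the full sample-row axis, so the output is ``(146, 1, 64)``:
  a sequence of 146 local pattern activations (5,824 parameters).
* reshape to ``(146, 64)`` and an ``LSTM`` with 64 units returning the full
  hidden sequence (33,024 parameters), which integrates the coverage signal
  along the transcript.
* additive self-attention pooling the 146 hidden states into a flat
  1024-length context (16 heads of 64, see :class:`CnnLstmNet`).
* dropout, then a dense layer with 2 softmax outputs (2,050 parameters)
  trained with categorical cross-entropy.

Gradients are computed analytically (backprop through time for the LSTM)
and optimised with Adam.  All randomness flows through explicitly passed
``numpy.random.Generator`` objects, so training is reproducible bit-for-bit
from a seed.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_EPS = 1e-12


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Adam:
    """Adam optimiser over a dict of parameter arrays."""

    def __init__(self, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(params[key])
                self.v[key] = np.zeros_like(params[key])
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1 ** self.t)
            vhat = self.v[key] / (1 - b2 ** self.t)
            params[key] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                params[key].dtype
            )


class CnnLstmNet:
    """CNN-LSTM network with additive self-attention, in plain numpy.

    The attention block is a shared tanh projection of each hidden state to
    ``attention_dim`` features followed by ``attention_heads`` independent
    score vectors.  Each head softmax-weights the 146 hidden states and
    pools them into a 64-length context; the concatenated heads give the
    flat context of length ``attention_heads * lstm_units`` (1024 with the
    defaults) consumed by the dense layer.  Attention weights are exposed
    with shape ``(heads, 146)`` per instance for inspection.
    """

    GATE_ORDER = "ifgo"  # column blocks of the LSTM weight matrices

    def __init__(
        self,
        input_length: int = 150,
        input_rows: int = 6,
        input_channels: int = 3,
        kernel_size: tuple[int, int] = (5, 6),
        filters: int = 64,
        lstm_units: int = 64,
        attention_heads: int = 16,
        attention_dim: int = 16,
        n_classes: int = 2,
        dropout_rate: float = 0.3,
        seed: int = 0,
        dtype=np.float32,
    ):
        if kernel_size[1] != input_rows:
            raise AssertionError(
                "Conv2D kernel width must span the sample-row axis "
                f"({kernel_size[1]} != {input_rows}); output width would not be 1"
            )
        self.input_length = input_length
        self.input_rows = input_rows
        self.input_channels = input_channels
        self.kernel_size = kernel_size
        self.filters = filters
        self.lstm_units = lstm_units
        self.attention_heads = attention_heads
        self.attention_dim = attention_dim
        self.n_classes = n_classes
        self.dropout_rate = dropout_rate
        self.dtype = dtype
        self.seq_length = input_length - kernel_size[0] + 1
        self.context_dim = attention_heads * lstm_units

        kh, kw = kernel_size
        C, F, U, d, H = input_channels, filters, lstm_units, attention_dim, attention_heads
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {
            "conv_W": _glorot(rng, (kh * kw * C, F), dtype),
            "conv_b": np.zeros(F, dtype=dtype),
            "lstm_Wx": _glorot(rng, (F, 4 * U), dtype),
            "lstm_Wh": _glorot(rng, (U, 4 * U), dtype),
            "lstm_b": np.zeros(4 * U, dtype=dtype),
            "att_W": _glorot(rng, (U, d), dtype),
            "att_b": np.zeros(d, dtype=dtype),
            "att_V": _glorot(rng, (d, H), dtype),
            "dense_W": _glorot(rng, (H * U, n_classes), dtype),
            "dense_b": np.zeros(n_classes, dtype=dtype),
        }
        # forget-gate bias starts at 1 to ease early gradient flow
        self.params["lstm_b"][U:2 * U] = 1.0
        self._cache: Optional[dict] = None

    # ---------------------------------------------------------------- shapes
    def layer_param_counts(self) -> dict[str, int]:
        p = self.params
        return {
            "conv": p["conv_W"].size + p["conv_b"].size,
            "lstm": p["lstm_Wx"].size + p["lstm_Wh"].size + p["lstm_b"].size,
            "attention": p["att_W"].size + p["att_b"].size + p["att_V"].size,
            "dense": p["dense_W"].size + p["dense_b"].size,
        }

    def conv_output_shape(self) -> tuple[int, int, int]:
        return (self.seq_length, self.input_rows - self.kernel_size[1] + 1,
                self.filters)

    # --------------------------------------------------------------- forward
    def _conv_windows(self, x: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel_size
        # (N, L', 1, C, kh, kw) -> (N, L', kh, kw, C) -> (N, L', kh*kw*C)
        win = sliding_window_view(x, (kh, kw), axis=(1, 2))[:, :, 0]
        win = np.ascontiguousarray(win.transpose(0, 1, 3, 4, 2))
        return win.reshape(x.shape[0], self.seq_length, kh * kw * self.input_channels)

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> np.ndarray:
        """Run the network; returns softmax probabilities (N, 2).

        With ``training=True`` (requires ``rng``) dropout is active and the
        intermediate activations are cached for :meth:`backward`.
        """
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        expected = (self.input_length, self.input_rows, self.input_channels)
        if x.shape[1:] != expected:
            raise ValueError(f"input shape {x.shape[1:]} != {expected}")
        p = self.params
        N, T, U = x.shape[0], self.seq_length, self.lstm_units

        xw = self._conv_windows(x)
        zc = xw @ p["conv_W"] + p["conv_b"]
        a = np.maximum(zc, 0.0)

        # LSTM (gate order i, f, g, o)
        zx = a @ p["lstm_Wx"] + p["lstm_b"]  # (N, T, 4U)
        Hs = np.zeros((T, N, U), dtype=self.dtype)
        Ig = np.zeros((T, N, U), dtype=self.dtype)
        Fg = np.zeros((T, N, U), dtype=self.dtype)
        Gg = np.zeros((T, N, U), dtype=self.dtype)
        Og = np.zeros((T, N, U), dtype=self.dtype)
        Cs = np.zeros((T, N, U), dtype=self.dtype)
        tanhC = np.zeros((T, N, U), dtype=self.dtype)
        h = np.zeros((N, U), dtype=self.dtype)
        c = np.zeros((N, U), dtype=self.dtype)
        Wh = p["lstm_Wh"]
        for t in range(T):
            z = zx[:, t] + h @ Wh
            i = _sigmoid(z[:, :U])
            f = _sigmoid(z[:, U:2 * U])
            g = np.tanh(z[:, 2 * U:3 * U])
            o = _sigmoid(z[:, 3 * U:])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            Ig[t], Fg[t], Gg[t], Og[t], Cs[t], tanhC[t], Hs[t] = i, f, g, o, c, tc, h
        Hseq = Hs.transpose(1, 0, 2)  # (N, T, U)

        # additive self-attention
        e = np.tanh(Hseq @ p["att_W"] + p["att_b"])  # (N, T, d)
        scores = e @ p["att_V"]  # (N, T, heads)
        alpha = softmax(scores, axis=1)
        ctx = np.einsum("nth,ntu->nhu", alpha, Hseq)  # (N, heads, U)
        ctx_flat = ctx.reshape(N, self.context_dim)

        if training:
            if rng is None:
                raise ValueError("training forward pass needs an rng for dropout")
            keep = 1.0 - self.dropout_rate
            mask = (rng.random(ctx_flat.shape) < keep).astype(self.dtype) / keep
            ctx_drop = ctx_flat * mask
        else:
            mask = None
            ctx_drop = ctx_flat

        logits = ctx_drop @ p["dense_W"] + p["dense_b"]
        probs = softmax(logits, axis=1)

        if training:
            self._cache = {
                "xw": xw, "zc": zc, "a": a,
                "Ig": Ig, "Fg": Fg, "Gg": Gg, "Og": Og, "Cs": Cs,
                "tanhC": tanhC, "Hs": Hs, "Hseq": Hseq,
                "e": e, "alpha": alpha, "mask": mask,
                "ctx_drop": ctx_drop, "probs": probs,
            }
        return probs

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """Attention weight maps, shape (N, heads, seq_length)."""
        self.forward(x, training=True, rng=np.random.default_rng(0))
        alpha = self._cache["alpha"]  # type: ignore[index]
        self._cache = None
        return alpha.transpose(0, 2, 1)

    # -------------------------------------------------------------- backward
    def backward(self, y_onehot: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean categorical cross-entropy wrt all parameters."""
        if self._cache is None:
            raise RuntimeError("backward() requires a prior training forward()")
        cache, p = self._cache, self.params
        N = y_onehot.shape[0]
        T, U = self.seq_length, self.lstm_units
        grads: dict[str, np.ndarray] = {}

        dlogits = (cache["probs"] - y_onehot.astype(self.dtype)) / N
        grads["dense_W"] = cache["ctx_drop"].T @ dlogits
        grads["dense_b"] = dlogits.sum(axis=0)
        dctx = dlogits @ p["dense_W"].T
        if cache["mask"] is not None:
            dctx = dctx * cache["mask"]
        dC = dctx.reshape(N, self.attention_heads, U)

        Hseq, alpha, e = cache["Hseq"], cache["alpha"], cache["e"]
        dalpha = np.einsum("nhu,ntu->nth", dC, Hseq)
        dH = np.einsum("nth,nhu->ntu", alpha, dC)
        ds = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        grads["att_V"] = np.einsum("ntd,nth->dh", e, ds)
        de = np.einsum("nth,dh->ntd", ds, p["att_V"])
        dpre = de * (1.0 - e * e)
        grads["att_W"] = np.einsum("ntu,ntd->ud", Hseq, dpre)
        grads["att_b"] = dpre.sum(axis=(0, 1))
        dH = dH + dpre @ p["att_W"].T  # (N, T, U)

        # BPTT
        Ig, Fg, Gg, Og = cache["Ig"], cache["Fg"], cache["Gg"], cache["Og"]
        Cs, tanhC, Hs, a = cache["Cs"], cache["tanhC"], cache["Hs"], cache["a"]
        Wh, Wx = p["lstm_Wh"], p["lstm_Wx"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(p["lstm_b"])
        dA = np.zeros_like(a)
        dh_next = np.zeros((N, U), dtype=self.dtype)
        dc_next = np.zeros((N, U), dtype=self.dtype)
        dHt = dH.transpose(1, 0, 2)
        for t in range(T - 1, -1, -1):
            dh = dHt[t] + dh_next
            do = dh * tanhC[t]
            dc = dh * Og[t] * (1.0 - tanhC[t] ** 2) + dc_next
            di = dc * Gg[t]
            dg = dc * Ig[t]
            c_prev = Cs[t - 1] if t > 0 else np.zeros_like(dc)
            df = dc * c_prev
            dc_next = dc * Fg[t]
            dz = np.concatenate(
                [
                    di * Ig[t] * (1.0 - Ig[t]),
                    df * Fg[t] * (1.0 - Fg[t]),
                    dg * (1.0 - Gg[t] ** 2),
                    do * Og[t] * (1.0 - Og[t]),
                ],
                axis=1,
            )
            h_prev = Hs[t - 1] if t > 0 else np.zeros((N, U), dtype=self.dtype)
            dWx += a[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh_next = dz @ Wh.T
            dA[:, t] = dz @ Wx.T
        grads["lstm_Wx"], grads["lstm_Wh"], grads["lstm_b"] = dWx, dWh, db

        dZc = dA * (cache["zc"] > 0)
        grads["conv_W"] = cache["xw"].reshape(-1, p["conv_W"].shape[0]).T @ \
            dZc.reshape(-1, self.filters)
        grads["conv_b"] = dZc.sum(axis=(0, 1))
        self._cache = None
        return grads

    # -------------------------------------------------------------- training
    def loss(self, probs: np.ndarray, y_onehot: np.ndarray) -> float:
        return float(-np.mean(np.sum(y_onehot * np.log(probs + _EPS), axis=1)))

    def train_step(self, x: np.ndarray, y_onehot: np.ndarray,
                   optimizer: Adam, rng: np.random.Generator) -> float:
        probs = self.forward(x, training=True, rng=rng)
        loss = self.loss(probs, y_onehot)
        grads = self.backward(y_onehot)
        optimizer.step(self.params, grads)
        return loss

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        out = [
            self.forward(x[i:i + batch_size])
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0)

    # ------------------------------------------------------------- weight io
    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for key, value in weights.items():
            if key not in self.params:
                raise KeyError(f"unknown parameter {key!r}")
            if self.params[key].shape != value.shape:
                raise ValueError(
                    f"parameter {key!r}: shape {value.shape} != "
                    f"{self.params[key].shape}"
                )
            self.params[key] = value.astype(self.dtype).copy()
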