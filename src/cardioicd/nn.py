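"""Minimal numpy implementation of the bidirectional-GRU classifier.

One classifier = trainable embedding (initialized from pretrained word
vectors) -> bidirectional GRU (final hidden state per direction,
concatenated) -> dense rectified-linear layer -> 2-unit softmax head
("assign" / "not assign").  Dropout is applied to the embedded inputs and
to the dense-layer input; recurrent dropout masks the hidden state inside
the GRU recurrence, with masks shared across timesteps (variational
style).  Padding index 0 is masked: padded steps carry the hidden state
through unchanged, so probabilities are invariant to trailing padding.

Gradients are computed by hand with backpropagation through time, and
parameters are updated with Adam.  Everything is seeded through a
``numpy.random.Generator`` so training is bit-reproducible on a fixed
BLAS backend.

GRU recurrence (update gate ``z``, reset gate ``r``, candidate ``c``)::

    z_t = sigmoid(x_t Wz + (h_{t-1} * rdrop) Uz + bz)
    r_t = sigmoid(x_t Wr + (h_{t-1} * rdrop) Ur + br)
    c_t = tanh(x_t Wc + (r_t * h_{t-1} * rdrop) Uc + bc)
    h_t = z_t * h_{t-1} + (1 - z_t) * c_t
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["BGRUClassifier", "NetConfig"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class NetConfig:
    """Architecture/optimization settings of one binary classifier."""

    embedding_dim: int = 300
    hidden_units: int = 100
    dense_units: int = 128
    dropout: float = 0.2
    recurrent_dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 30
    patience: int = 3
    trainable_embedding: bool = True


class _GRUDirection:
    """One direction of the bidirectional GRU (weights + BPTT)."""

    def __init__(self, rng: np.random.Generator, dim_in: int, hidden: int):
        self.H = hidden
        self.W = _glorot(rng, dim_in, 3 * hidden)  # input -> [z, r, c]
        self.Uzr = _glorot(rng, hidden, 2 * hidden)  # recurrent -> [z, r]
        self.Uc = _glorot(rng, hidden, hidden)  # recurrent -> candidate
        self.b = np.zeros(3 * hidden)
        # bias the update gate towards carrying state (long memory), the
        # GRU analogue of LSTM forget-bias-1 initialization
        self.b[:hidden] = 1.0

    def params(self, prefix: str) -> dict[str, np.ndarray]:
        return {
            f"{prefix}.W": self.W,
            f"{prefix}.Uzr": self.Uzr,
            f"{prefix}.Uc": self.Uc,
            f"{prefix}.b": self.b,
        }

    def forward(self, x: np.ndarray, mask: np.ndarray, rmask: np.ndarray):
        """x: (B,T,D) already input-dropped; mask: (B,T); rmask: (B,H)."""
        B, T, _ = x.shape
        H = self.H
        pre = x.reshape(B * T, -1) @ self.W
        pre = (pre + self.b).reshape(B, T, 3 * H)
        h = np.zeros((B, H))
        cache = []
        for t in range(T):
            m = mask[:, t, None]
            hm = h * rmask
            g = hm @ self.Uzr
            z = _sigmoid(pre[:, t, :H] + g[:, :H])
            r = _sigmoid(pre[:, t, H : 2 * H] + g[:, H:])
            c = np.tanh(pre[:, t, 2 * H :] + (r * hm) @ self.Uc)
            h_new = z * h + (1.0 - z) * c
            cache.append((h, hm, z, r, c))
            h = m * h_new + (1.0 - m) * h
        return h, (x, mask, rmask, cache)

    def backward(self, dh: np.ndarray, ctx):
        x, mask, rmask, cache = ctx
        B, T, D = x.shape
        H = self.H
        dW = np.zeros_like(self.W)
        dUzr = np.zeros_like(self.Uzr)
        dUc = np.zeros_like(self.Uc)
        dpre = np.zeros((B, T, 3 * H))
        for t in range(T - 1, -1, -1):
            h_prev, hm, z, r, c = cache[t]
            m = mask[:, t, None]
            dh_new = dh * m
            dh_prev = dh * (1.0 - m)
            dz = dh_new * (h_prev - c)
            dc = dh_new * (1.0 - z)
            dh_prev = dh_prev + dh_new * z
            dc_pre = dc * (1.0 - c * c)
            dUc += (r * hm).T @ dc_pre
            drhm = dc_pre @ self.Uc.T
            dr = drhm * hm
            dhm = drhm * r
            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            dg = np.concatenate([dz_pre, dr_pre], axis=1)
            dUzr += hm.T @ dg
            dhm = dhm + dg @ self.Uzr.T
            dh_prev = dh_prev + dhm * rmask
            dpre[:, t, :H] = dz_pre
            dpre[:, t, H : 2 * H] = dr_pre
            dpre[:, t, 2 * H :] = dc_pre
            dh = dh_prev
        flat = dpre.reshape(B * T, 3 * H)
        dW[...] = x.reshape(B * T, D).T @ flat
        db = flat.sum(axis=0)
        dx = (flat @ self.W.T).reshape(B, T, D)
        grads = {"W": dW, "Uzr": dUzr, "Uc": dUc, "b": db}
        return dx, grads


class BGRUClassifier:
    """Binary classifier over padded token-index sequences."""

    def __init__(
        self,
        vocab_size: int,
        config: NetConfig,
        embedding_matrix: Optional[np.ndarray] = None,
        seed: int = 0,
    ):
        self.config = config
        self.vocab_size = vocab_size
        rng = np.random.default_rng(seed)
        D, H = config.embedding_dim, config.hidden_units
        if embedding_matrix is not None:
            if embedding_matrix.shape != (vocab_size, D):
                raise ValueError(
                    f"embedding matrix shape {embedding_matrix.shape} does not match "
                    f"(vocab_size, embedding_dim) = {(vocab_size, D)}"
                )
            self.E = embedding_matrix.astype(np.float64).copy()
        else:
            self.E = rng.normal(0.0, 0.1, size=(vocab_size, D))
        self.E[0, :] = 0.0  # padding row
        self.fw = _GRUDirection(rng, D, H)
        self.bw = _GRUDirection(rng, D, H)
        self.W1 = _glorot(rng, 2 * H, config.dense_units)
        self.b1 = np.zeros(config.dense_units)
        self.W2 = _glorot(rng, config.dense_units, 2)
        self.b2 = np.zeros(2)
        self._adam: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # ------------------------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        params = {"E": self.E, "W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}
        params.update(self.fw.params("fw"))
        params.update(self.bw.params("bw"))
        return params

    def architecture(self) -> list[str]:
        """Layer-by-layer description of the network."""
        c = self.config
        return [
            f"embedding({self.vocab_size} x {c.embedding_dim}, trainable={c.trainable_embedding}, padding masked)",
            f"bidirectional_gru({c.hidden_units} units/direction, dropout={c.dropout}, "
            f"recurrent_dropout={c.recurrent_dropout})",
            f"concatenate(2 x {c.hidden_units})",
            f"dense({c.dense_units}, relu, dropout={c.dropout})",
            "dense(2, softmax)",
        ]

    # ------------------------------------------------------------------
    def _forward(self, idx: np.ndarray, training: bool, rng: Optional[np.random.Generator]):
        c = self.config
        B, T = idx.shape
        mask = (idx != 0).astype(np.float64)
        x = self.E[idx]  # (B,T,D)
        if training and c.dropout > 0:
            keep = 1.0 - c.dropout
            dmask = (rng.random((B, x.shape[2])) < keep) / keep
            x = x * dmask[:, None, :]
        else:
            dmask = None
        if training and c.recurrent_dropout > 0:
            keep = 1.0 - c.recurrent_dropout
            rmask_f = (rng.random((B, c.hidden_units)) < keep) / keep
            rmask_b = (rng.random((B, c.hidden_units)) < keep) / keep
        else:
            rmask_f = np.ones((B, c.hidden_units))
            rmask_b = np.ones((B, c.hidden_units))
        h_f, ctx_f = self.fw.forward(x, mask, rmask_f)
        h_b, ctx_b = self.bw.forward(x[:, ::-1, :], mask[:, ::-1], rmask_b)
        hcat = np.concatenate([h_f, h_b], axis=1)
        if training and c.dropout > 0:
            keep = 1.0 - c.dropout
            hmask = (rng.random(hcat.shape) < keep) / keep
            hdrop = hcat * hmask
        else:
            hmask = None
            hdrop = hcat
        a1_pre = hdrop @ self.W1 + self.b1
        a1 = np.maximum(a1_pre, 0.0)
        logits = a1 @ self.W2 + self.b2
        probs = _softmax(logits)
        ctx = (idx, dmask, ctx_f, ctx_b, hcat, hmask, hdrop, a1_pre, a1, probs)
        return probs, ctx

    def _backward(self, y: np.ndarray, ctx):
        idx, dmask, ctx_f, ctx_b, hcat, hmask, hdrop, a1_pre, a1, probs = ctx
        B = idx.shape[0]
        H = self.config.hidden_units
        onehot = np.zeros_like(probs)
        onehot[np.arange(B), y] = 1.0
        dlogits = (probs - onehot) / B
        grads: dict[str, np.ndarray] = {}
        grads["W2"] = a1.T @ dlogits
        grads["b2"] = dlogits.sum(axis=0)
        da1 = dlogits @ self.W2.T
        da1_pre = da1 * (a1_pre > 0)
        grads["W1"] = hdrop.T @ da1_pre
        grads["b1"] = da1_pre.sum(axis=0)
        dhdrop = da1_pre @ self.W1.T
        dhcat = dhdrop * hmask if hmask is not None else dhdrop
        dx_f, g_f = self.fw.backward(dhcat[:, :H], ctx_f)
        dx_b_rev, g_b = self.bw.backward(dhcat[:, H:], ctx_b)
        dx = dx_f + dx_b_rev[:, ::-1, :]
        if dmask is not None:
            dx = dx * dmask[:, None, :]
        for k, v in g_f.items():
            grads[f"fw.{k}"] = v
        for k, v in g_b.items():
            grads[f"bw.{k}"] = v
        if self.config.trainable_embedding:
            dE = np.zeros_like(self.E)
            np.add.at(dE, idx.ravel(), dx.reshape(-1, self.E.shape[1]))
            dE[0, :] = 0.0
            grads["E"] = dE
        return grads

    def loss_and_grads(self, idx: np.ndarray, y: np.ndarray, rng=None, training=True):
        probs, ctx = self._forward(idx, training=training, rng=rng)
        B = idx.shape[0]
        loss = -np.mean(np.log(probs[np.arange(B), y] + 1e-12))
        grads = self._backward(y, ctx)
        return loss, grads

    # ------------------------------------------------------------------
    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        lr = self.config.learning_rate
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        params = self.parameters()
        for name, g in grads.items():
            p = params[name]
            if name not in self._adam:
                self._adam[name] = (np.zeros_like(p), np.zeros_like(p))
            m, v = self._adam[name]
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
        self.E[0, :] = 0.0

    @staticmethod
    def _trim(idx: np.ndarray) -> np.ndarray:
        """Drop all-padding trailing columns to shorten BPTT."""
        lengths = (idx != 0).sum(axis=1)
        t = int(lengths.max()) if len(lengths) else 1
        return idx[:, : max(t, 1)]

    def fit(
        self,
        idx: np.ndarray,
        y: np.ndarray,
        val_idx: Optional[np.ndarray] = None,
        val_y: Optional[np.ndarray] = None,
        seed: int = 0,
    ) -> list[dict]:
        """Train with Adam and (if validation data given) early stopping.

        Returns the per-epoch history of training loss and validation loss.
        Restores the best-validation-loss parameters when early stopping
        triggers.
        """
        c = self.config
        rng = np.random.default_rng(seed)
        n = idx.shape[0]
        history: list[dict] = []
        best_val = np.inf
        best_state: Optional[dict[str, np.ndarray]] = None
        bad_epochs = 0
        for epoch in range(c.max_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, c.batch_size):
                batch = order[start : start + c.batch_size]
                xb = self._trim(idx[batch])
                loss, grads = self.loss_and_grads(xb, y[batch], rng=rng)
                self._adam_step(grads)
                losses.append(loss)
            record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if val_idx is not None and len(val_idx):
                vp = self.predict_proba(val_idx)
                vy = val_y
                val_loss = float(
                    -np.mean(np.log(np.where(vy == 1, vp, 1.0 - vp) + 1e-12))
                )
                record["val_loss"] = val_loss
                if val_loss < best_val - 1e-5:
                    best_val = val_loss
                    best_state = {k: v.copy() for k, v in self.parameters().items()}
                    bad_epochs = 0
                else:
                    bad_epochs += 1
            history.append(record)
            if val_idx is not None and bad_epochs >= c.patience:
                break
        if best_state is not None:
            for k, v in self.parameters().items():
                v[...] = best_state[k]
        return history

    def predict_proba(self, idx: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Probability of the positive ("assign") class, shape (n,)."""
        out = []
        for start in range(0, idx.shape[0], batch_size):
            xb = self._trim(idx[start : start + batch_size])
            probs, _ = self._forward(xb, training=False, rng=None)
            out.append(probs[:, 1])
        return np.concatenate(out) if out else np.zeros(0)

    # ------------------------------------------------------------------
    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.parameters().items():
            v[...] = state[k]
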