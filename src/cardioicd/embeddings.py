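"""Skip-gram word-embedding pretraining with negative sampling.

Word vectors are trained on the tokenized training letters and used to
initialize the classifier's embedding layer.  Defaults follow the
pipeline's embedding settings: 300-dimensional vectors, a symmetric
context window of five, and a vocabulary that discards words appearing
only once.  The implementation is a plain numpy skip-gram with
negative sampling (unigram^0.75 noise distribution), mini-batched and
fully seeded, which is ample for corpus sizes where every token is in
memory.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .preprocess import PAD_INDEX, UNK_INDEX, Vocabulary

__all__ = ["pretrain_embeddings"]


def _build_pairs(
    sequences: Iterable[Sequence[int]], window: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    centers: list[int] = []
    contexts: list[int] = []
    for seq in sequences:
        arr = [i for i in seq if i != PAD_INDEX]
        n = len(arr)
        for pos, center in enumerate(arr):
            # dynamic window, as in classic skip-gram training
            w = int(rng.integers(1, window + 1))
            for off in range(-w, w + 1):
                j = pos + off
                if off == 0 or j < 0 or j >= n:
                    continue
                centers.append(center)
                contexts.append(arr[j])
    return np.asarray(centers, dtype=np.int64), np.asarray(contexts, dtype=np.int64)


def pretrain_embeddings(
    token_sequences: Iterable[Sequence[str]],
    vocab: Vocabulary,
    dim: int = 300,
    window: int = 5,
    negatives: int = 5,
    epochs: int = 1,
    learning_rate: float = 0.025,
    batch_size: int = 4096,
    seed: int = 0,
) -> np.ndarray:
    """Train skip-gram vectors and return a (vocab_size, dim) matrix.

    Row 0 (padding) is all-zero.  Deterministic given the seed.  Raises
    when the vocabulary holds nothing beyond the special tokens.
    """
    if vocab.size <= 2:
        raise ValueError("nothing to embed: vocabulary contains only special tokens")
    rng = np.random.default_rng(seed)
    encoded = [[vocab.index(t) for t in seq] for seq in token_sequences]

    counts = np.zeros(vocab.size)
    for seq in encoded:
        for i in seq:
            counts[i] += 1
    counts[PAD_INDEX] = 0.0
    noise = counts**0.75
    total = noise.sum()
    if total <= 0:
        raise ValueError("nothing to embed: no tokens observed")
    noise /= total

    centers, contexts = _build_pairs(encoded, window, rng)
    n_pairs = len(centers)
    if n_pairs == 0:
        raise ValueError("nothing to embed: no co-occurrence pairs")

    W_in = (rng.random((vocab.size, dim)) - 0.5) / dim
    W_out = np.zeros((vocab.size, dim))

    for epoch in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            sel = order[start : start + batch_size]
            b = len(sel)
            lr = learning_rate * (1.0 - (epoch * n_pairs + start) / (epochs * n_pairs))
            lr = max(lr, learning_rate * 0.05)
            c_idx = centers[sel]
            pos_idx = contexts[sel]
            neg_idx = rng.choice(vocab.size, size=(b, negatives), p=noise)
            vin = W_in[c_idx]  # (b, d)
            targets = np.concatenate([pos_idx[:, None], neg_idx], axis=1)  # (b, 1+k)
            vout = W_out[targets]  # (b, 1+k, d)
            score = np.einsum("bd,bkd->bk", vin, vout)
            sig = 1.0 / (1.0 + np.exp(-np.clip(score, -30, 30)))
            label = np.zeros_like(sig)
            label[:, 0] = 1.0
            err = sig - label  # (b, 1+k)
            g_in = np.einsum("bk,bkd->bd", err, vout)
            g_out = err[:, :, None] * vin[:, None, :]
            np.add.at(W_in, c_idx, -lr * g_in)
            np.add.at(W_out, targets.ravel(), -lr * g_out.reshape(-1, dim))

    # post-process: remove the common mean component (which dominates
    # small-corpus skip-gram solutions and washes out token identity) and
    # normalise rows to a fixed scale suited to the classifier's input
    observed = np.flatnonzero(counts > 0)
    if len(observed):
        W_in[observed] -= W_in[observed].mean(axis=0)
        norms = np.linalg.norm(W_in[observed], axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        W_in[observed] = W_in[observed] / norms * 0.5

    W_in[PAD_INDEX, :] = 0.0
    # unknown token may never occur in training text; keep a small vector
    if counts[UNK_INDEX] == 0:
        W_in[UNK_INDEX, :] = 0.0
    return W_in
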