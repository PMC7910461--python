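"""Per-code binary classifiers under the binary-relevance strategy.

Multilabel ICD-10 coding is decomposed into one independent binary
classifier per retained code ("binary relevance"): each model sees the
identical 80% training split with the binary target *code assigned /
not assigned*, so adding or retraining one code never disturbs another.
Every classifier is a small bidirectional GRU over the shared pretrained
word embeddings (see :mod:`cardioicd.nn`).

Defaults follow the reference configuration: 300-dimensional embeddings
(window 5, singletons discarded), 100 GRU units per direction, dropout
and recurrent dropout 0.2, a 128-unit rectified-linear dense layer and a
2-way softmax output.  A down-scaled profile (32/16/16) is provided for
fast runs on a single CPU; it changes capacity, not behaviour.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .corpus import Corpus, Letter
from .embeddings import pretrain_embeddings
from .nn import BGRUClassifier, NetConfig
from .preprocess import Vocabulary, encode

__all__ = [
    "ModelConfig",
    "SplitConfig",
    "TrainedLabelModel",
    "PredictionMatrix",
    "pretrain",
    "build_classifier",
    "train_binary_relevance",
    "predict_proba",
    "crossvalidate",
    "encode_letters",
    "split_corpus",
]


@dataclass
class ModelConfig:
    embedding_dim: int = 300
    embedding_window: int = 5
    rnn_hidden_units: int = 100
    dropout_rate: float = 0.2
    recurrent_dropout_rate: float = 0.2
    dense_units: int = 128
    max_epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    patience: int = 5
    max_len: int = 1500
    trainable_embedding: bool = True
    embedding_epochs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.dropout_rate, self.recurrent_dropout_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("dropout rates must be in [0, 1)")
        for units in (self.embedding_dim, self.rnn_hidden_units, self.dense_units):
            if units <= 0:
                raise ValueError("layer sizes must be positive")

    def net_config(self) -> NetConfig:
        return NetConfig(
            embedding_dim=self.embedding_dim,
            hidden_units=self.rnn_hidden_units,
            dense_units=self.dense_units,
            dropout=self.dropout_rate,
            recurrent_dropout=self.recurrent_dropout_rate,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            trainable_embedding=self.trainable_embedding,
        )

    @classmethod
    def test_profile(cls, **overrides) -> "ModelConfig":
        """Down-scaled profile for single-CPU runs (32/16/16 units)."""
        base = cls(
            embedding_dim=32,
            rnn_hidden_units=16,
            dense_units=16,
            batch_size=32,
            learning_rate=1e-2,
            max_epochs=30,
            patience=6,
            max_len=200,
        )
        return replace(base, **overrides)


@dataclass
class SplitConfig:
    train_fraction: float = 0.80
    test_fraction: float = 0.20
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train_fraction + self.test_fraction - 1.0) > 1e-9:
            raise ValueError("train_fraction and test_fraction must sum to 1")
        if self.n_folds < 2:
            raise ValueError("cross-validation requires >= 2 folds")


def split_corpus(corpus: Corpus, split: SplitConfig) -> tuple[list[int], list[int]]:
    """Random 80/20 split; returns (train_indices, test_indices)."""
    rng = np.random.default_rng(split.seed)
    order = rng.permutation(len(corpus))
    n_train = int(round(split.train_fraction * len(corpus)))
    return sorted(order[:n_train].tolist()), sorted(order[n_train:].tolist())


def encode_letters(
    letters: Sequence[Letter],
    vocab: Vocabulary,
    mode: str = "full",
    use_covariates: bool = False,
    max_len: int = 1500,
) -> np.ndarray:
    """Encode letters into an (n, max_len) int index matrix."""
    rows = [
        encode(l, vocab, mode=mode, use_covariates=use_covariates, max_len=max_len).indices
        for l in letters
    ]
    return np.asarray(rows, dtype=np.int64)


def pretrain(
    token_sequences: Sequence[Sequence[str]], vocab: Vocabulary, config: ModelConfig
) -> np.ndarray:
    """Pretrain skip-gram embeddings for the classifier's first layer."""
    return pretrain_embeddings(
        token_sequences,
        vocab,
        dim=config.embedding_dim,
        window=config.embedding_window,
        epochs=config.embedding_epochs,
        seed=config.seed,
    )


def build_classifier(
    vocab_size: int,
    embedding_matrix: Optional[np.ndarray],
    config: ModelConfig,
    seed: Optional[int] = None,
) -> BGRUClassifier:
    return BGRUClassifier(
        vocab_size,
        config.net_config(),
        embedding_matrix=embedding_matrix,
        seed=config.seed if seed is None else seed,
    )


@dataclass
class TrainedLabelModel:
    """One trained binary classifier bound to a code and a vocabulary."""

    code: str
    classifier: BGRUClassifier
    vocab_fingerprint: str
    training_history: list[dict] = field(default_factory=list)
    config: Optional[ModelConfig] = None

    def predict(self, encoded: np.ndarray, vocab_fingerprint: Optional[str] = None) -> np.ndarray:
        if vocab_fingerprint is not None and vocab_fingerprint != self.vocab_fingerprint:
            raise ValueError(
                f"vocabulary fingerprint mismatch for code {self.code}: "
                f"{vocab_fingerprint} != {self.vocab_fingerprint}"
            )
        return self.classifier.predict_proba(encoded)

    # -- persistence -----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.classifier.parameters())
        meta = {
            "code": self.code,
            "vocab_fingerprint": self.vocab_fingerprint,
            "config": asdict(self.config) if self.config else None,
            "training_history": self.training_history,
            "vocab_size": self.classifier.vocab_size,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedLabelModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        config = ModelConfig(**meta["config"]) if meta["config"] else ModelConfig()
        clf = BGRUClassifier(meta["vocab_size"], config.net_config(), seed=0)
        with np.load(directory / "weights.npz") as data:
            clf.set_state({k: data[k] for k in data.files})
        return cls(
            code=meta["code"],
            classifier=clf,
            vocab_fingerprint=meta["vocab_fingerprint"],
            training_history=meta["training_history"],
            config=config,
        )


@dataclass
class PredictionMatrix:
    """Letters x codes matrix of positive-class probabilities."""

    probabilities: np.ndarray  # (n_letters, n_codes)
    codes: list[str]  # sorted
    letter_ids: list[str]  # input order

    def __post_init__(self) -> None:
        p = self.probabilities
        if p.ndim != 2 or p.shape != (len(self.letter_ids), len(self.codes)):
            raise ValueError("probability matrix shape does not match ids/codes")


def _binary_targets(letters: Sequence[Letter], code: str) -> np.ndarray:
    return np.asarray([1 if code in l.codes else 0 for l in letters], dtype=np.int64)


def train_binary_relevance(
    corpus: Corpus,
    codes: Sequence[str],
    vocab: Vocabulary,
    config: ModelConfig,
    encoded: Optional[np.ndarray] = None,
    embedding_matrix: Optional[np.ndarray] = None,
    mode: str = "full",
    use_covariates: bool = False,
    val_fraction: float = 0.2,
) -> dict[str, TrainedLabelModel]:
    """Train one classifier per code on the same training letters.

    ``corpus`` here is the TRAINING split.  A fraction of it is held out
    per code for early stopping.  All randomness derives from
    ``config.seed``; per-code seeds are offset so classifiers are
    independent yet reproducible.
    """
    letters = list(corpus)
    if encoded is None:
        encoded = encode_letters(
            letters, vocab, mode=mode, use_covariates=use_covariates, max_len=config.max_len
        )
    fingerprint = vocab.fingerprint()
    models: dict[str, TrainedLabelModel] = {}
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(letters))
    n_val = int(round(val_fraction * len(letters)))
    val_sel, train_sel = order[:n_val], order[n_val:]
    for code in sorted(codes):
        y = _binary_targets(letters, code)
        if y[train_sel].sum() == 0:
            raise ValueError(f"code {code} has no positive letters in the training split")
        # per-code seed derived from the code itself, so models are
        # independent: retraining one code never changes another
        code_seed = (config.seed + zlib.crc32(code.encode())) % (2**31)
        clf = build_classifier(vocab.size, embedding_matrix, config, seed=code_seed)
        history = clf.fit(
            encoded[train_sel],
            y[train_sel],
            val_idx=encoded[val_sel] if n_val else None,
            val_y=y[val_sel] if n_val else None,
            seed=code_seed + 1,
        )
        models[code] = TrainedLabelModel(
            code=code,
            classifier=clf,
            vocab_fingerprint=fingerprint,
            training_history=history,
            config=config,
        )
    return models


def predict_proba(
    models: dict[str, TrainedLabelModel],
    encoded: np.ndarray,
    letter_ids: Sequence[str],
    vocab_fingerprint: Optional[str] = None,
) -> PredictionMatrix:
    """Predict the assign-probability for every letter and code.

    Codes are sorted; rows follow the input letter order.
    """
    codes = sorted(models)
    cols = [models[c].predict(encoded, vocab_fingerprint=vocab_fingerprint) for c in codes]
    probs = np.column_stack(cols) if cols else np.zeros((len(letter_ids), 0))
    return PredictionMatrix(probabilities=probs, codes=codes, letter_ids=list(letter_ids))


def crossvalidate(
    corpus: Corpus,
    code: str,
    vocab: Vocabulary,
    split: SplitConfig,
    config: ModelConfig,
    encoded: Optional[np.ndarray] = None,
    embedding_matrix: Optional[np.ndarray] = None,
    mode: str = "full",
    use_covariates: bool = False,
) -> list[dict]:
    """K-fold cross-validation of one code's classifier on the training split.

    Folds partition the letters; each record carries the fold's validation
    loss and F1 plus the stopping epoch, supporting epoch/hyperparameter
    selection.  Folds without a positive letter are skipped with a warning.
    """
    letters = list(corpus)
    if encoded is None:
        encoded = encode_letters(
            letters, vocab, mode=mode, use_covariates=use_covariates, max_len=config.max_len
        )
    y = _binary_targets(letters, code)
    rng = np.random.default_rng(split.seed)
    order = rng.permutation(len(letters))
    folds = np.array_split(order, split.n_folds)
    records: list[dict] = []
    for k, fold in enumerate(folds):
        train_sel = np.concatenate([f for j, f in enumerate(folds) if j != k])
        if y[train_sel].sum() == 0 or y[fold].sum() == 0:
            warnings.warn(f"fold {k} for code {code} has no positive letters; skipped")
            records.append({"fold": k, "skipped": True})
            continue
        clf = build_classifier(vocab.size, embedding_matrix, config, seed=config.seed + k)
        history = clf.fit(
            encoded[train_sel], y[train_sel], encoded[fold], y[fold], seed=config.seed + k
        )
        probs = clf.predict_proba(encoded[fold])
        pred = (probs > 0.5).astype(int)
        tp = int(((pred == 1) & (y[fold] == 1)).sum())
        fp = int(((pred == 1) & (y[fold] == 0)).sum())
        fn = int(((pred == 0) & (y[fold] == 1)).sum())
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
        val_loss = history[-1].get("val_loss", float("nan"))
        records.append(
            {
                "fold": k,
                "skipped": False,
                "n_val": int(len(fold)),
                "val_loss": val_loss,
                "f1": f1,
                "stopping_epoch": len(history),
            }
        )
    return records
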