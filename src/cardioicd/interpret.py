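"""Word coefficients: which tokens drive a code's predicted probability.

Two extraction methods are provided:

``surrogate_linear`` (default)
    Fit a ridge-regularized linear surrogate on binary token-presence
    vectors against the classifier's predicted probabilities and report
    the surrogate's weights.  Cheap and global; the surrogate's fit
    quality bounds how literally its weights describe the network.

``occlusion``
    For each token, remove all its occurrences from the letters that
    contain it and measure the mean drop in predicted log-odds (the
    log-odds scale keeps redundant cues visible even when the probability
    itself is saturated).  Model-faithful by construction but requires
    one prediction pass per token.

Coefficients are computed on the training split, to describe what the
model learned.  Positive coefficients mark tokens that increase the
probability of assigning the code (synonyms, medication names); negation
cues come out negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .corpus import Letter
from .model import TrainedLabelModel, encode_letters
from .preprocess import PAD_INDEX, UNK_INDEX, Vocabulary, extract_summary, normalize_tokenize

__all__ = ["WordCoefficientTable", "word_coefficients", "top_words"]

METHODS = ("surrogate_linear", "occlusion")


def _logit(p: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    p = np.clip(p, eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


@dataclass
class WordCoefficientTable:
    code: str
    #: (token, coefficient, support) sorted by descending coefficient
    entries: list[tuple[str, float, int]]
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["token", "coefficient", "support"])

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _letter_tokens(letters: Sequence[Letter], mode: str) -> list[list[str]]:
    texts = [
        l.text if mode == "full" else extract_summary(l.text) for l in letters
    ]
    return [normalize_tokenize(t) for t in texts]


def word_coefficients(
    model: TrainedLabelModel,
    letters: Sequence[Letter],
    vocab: Vocabulary,
    method: str = "surrogate_linear",
    mode: str = "full",
    use_covariates: bool = False,
    max_len: int = 1500,
    ridge_alpha: float = 1.0,
    max_letters_per_token: int = 50,
    seed: int = 0,
) -> WordCoefficientTable:
    """Compute per-token coefficients for one trained code classifier.

    Tokens absent from every letter are excluded.  Deterministic given
    the seed (the seed only matters for occlusion's letter subsampling).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    token_lists = _letter_tokens(letters, mode)
    encoded = encode_letters(
        letters, vocab, mode=mode, use_covariates=use_covariates, max_len=max_len
    )
    probs = model.predict(encoded)

    specials = {PAD_INDEX, UNK_INDEX}
    candidates = [t for t, i in vocab.token_to_index.items() if i not in specials]
    containing: dict[str, list[int]] = {}
    for li, toks in enumerate(token_lists):
        for t in set(toks):
            if t in vocab.token_to_index and vocab.token_to_index[t] not in specials:
                containing.setdefault(t, []).append(li)
    candidates = [t for t in candidates if t in containing]

    if method == "surrogate_linear":
        col = {t: j for j, t in enumerate(candidates)}
        X = np.zeros((len(letters), len(candidates)))
        for t, rows in containing.items():
            X[rows, col[t]] = 1.0
        reg = Ridge(alpha=ridge_alpha)
        reg.fit(X, probs)
        coefs = {t: float(reg.coef_[j]) for t, j in col.items()}
    else:  # occlusion
        rng = np.random.default_rng(seed)
        coefs = {}
        for t in candidates:
            rows = containing[t]
            if len(rows) > max_letters_per_token:
                rows = sorted(rng.choice(rows, size=max_letters_per_token, replace=False))
            occluded_tokens = [
                [tok for tok in token_lists[r] if tok != t] for r in rows
            ]
            occ_letters = [
                Letter(
                    id=f"occ{j}",
                    text=" ".join(toks),
                    codes=set(),
                    age=letters[r].age,
                    sex=letters[r].sex,
                )
                for j, (r, toks) in enumerate(zip(rows, occluded_tokens))
            ]
            occ_encoded = encode_letters(
                occ_letters, vocab, mode="full", use_covariates=use_covariates, max_len=max_len
            )
            occ_probs = model.predict(occ_encoded)
            # log-odds scale: saturated probabilities (p near 0 or 1) would
            # otherwise hide the evidence carried by redundant cues
            base = _logit(probs[np.asarray(rows)])
            coefs[t] = float(np.mean(base - _logit(occ_probs)))

    entries = sorted(
        ((t, coefs[t], len(containing[t])) for t in candidates),
        key=lambda e: (-e[1], e[0]),
    )
    return WordCoefficientTable(code=model.code, entries=entries, method=method)


def surrogate_faithfulness(
    model: TrainedLabelModel,
    letters: Sequence[Letter],
    vocab: Vocabulary,
    mode: str = "full",
    max_len: int = 1500,
    ridge_alpha: float = 1.0,
) -> float:
    """Pearson correlation between surrogate and classifier probabilities."""
    token_lists = _letter_tokens(letters, mode)
    encoded = encode_letters(letters, vocab, mode=mode, max_len=max_len)
    probs = model.predict(encoded)
    specials = {PAD_INDEX, UNK_INDEX}
    candidates = sorted(
        {t for toks in token_lists for t in toks if vocab.index(t) not in specials}
    )
    col = {t: j for j, t in enumerate(candidates)}
    X = np.zeros((len(letters), len(candidates)))
    for li, toks in enumerate(token_lists):
        for t in set(toks):
            if t in col:
                X[li, col[t]] = 1.0
    reg = Ridge(alpha=ridge_alpha)
    reg.fit(X, probs)
    fitted = reg.predict(X)
    if np.std(fitted) == 0 or np.std(probs) == 0:
        return float("nan")
    return float(np.corrcoef(fitted, probs)[0, 1])


def top_words(table: WordCoefficientTable, k: int, sign: str = "positive") -> list[str]:
    """The k most extreme positive or negative tokens; fewer if unavailable."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if sign == "positive":
        pos = [t for t, c, _ in table.entries if c > 0]
        return pos[:k]
    if sign == "negative":
        neg = sorted(
            ((t, c) for t, c, _ in table.entries if c < 0), key=lambda e: e[1]
        )
        return [t for t, _ in neg[:k]]
    raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")
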