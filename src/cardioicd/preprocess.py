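"""Text normalization, vocabulary building, encoding and label filtering.

Normalization follows the pipeline's preprocessing contract: lowercase
everything, trim whitespace, and drop standalone number tokens.  Digits
embedded in alphanumeric tokens (``i48``, ``dmii``) are kept — those are
exactly the cues the classifiers need.  De-identification placeholders
such as ``<datum-1>`` are kept as single atomic tokens.

The vocabulary is built from the *training* split only and discards
tokens that appear only once (``min_count=2`` by default).  Index 0 is
reserved for padding and index 1 for unknown tokens; remaining indices
are assigned by descending training frequency with alphabetical
tie-breaks, so encoding is fully deterministic.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .corpus import Corpus, Letter, rollup_code

__all__ = [
    "PAD_INDEX",
    "UNK_INDEX",
    "Vocabulary",
    "EncodedLetter",
    "LabelFilterConfig",
    "normalize_tokenize",
    "extract_summary",
    "build_vocabulary",
    "encode",
    "filter_labels",
    "age_token",
    "sex_token",
]

PAD_INDEX = 0
UNK_INDEX = 1
PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"

# a placeholder token like <datum-1>, or a run of word chars with optional
# internal hyphens ("non-stemi" stays one token)
_TOKEN_RE = re.compile(r"<[a-z]+-\d+>|\w+(?:-\w+)*")
_NUMBER_RE = re.compile(r"^[\d.,/-]+$")

DEFAULT_SUMMARY_HEADERS = ("conclusie", "conclusie en beleid", "samenvatting")


def normalize_tokenize(text: str) -> list[str]:
    """Lowercase, tokenize, and drop standalone number tokens."""
    tokens = _TOKEN_RE.findall(text.lower())
    return [t for t in tokens if not _NUMBER_RE.match(t)]


def extract_summary(
    text: str, header_lexicon: Sequence[str] = DEFAULT_SUMMARY_HEADERS
) -> str:
    """Return the summary paragraph: first matched header to the next header.

    Header matching is case-insensitive; at equal start positions the
    longest header wins (so ``conclusie en beleid`` beats ``conclusie``).
    Returns the empty string when no header is found.
    """
    lowered = text.lower()
    headers = sorted(header_lexicon, key=len, reverse=True)

    def find_from(pos: int):
        best = None
        for h in headers:
            i = lowered.find(h.lower(), pos)
            if i < 0:
                continue
            if best is None or i < best[0] or (i == best[0] and len(h) > best[1]):
                best = (i, len(h))
        return best

    first = find_from(0)
    if first is None:
        return ""
    start = first[0] + first[1]
    nxt = find_from(start)
    end = nxt[0] if nxt is not None else len(text)
    return text[start:end].strip()


@dataclass
class Vocabulary:
    token_to_index: dict[str, int]
    min_count: int = 2

    def __len__(self) -> int:
        return len(self.token_to_index)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    def index(self, token: str) -> int:
        return self.token_to_index.get(token, UNK_INDEX)

    @property
    def size(self) -> int:
        return len(self.token_to_index)

    def fingerprint(self) -> str:
        """Stable hash binding trained models to the vocabulary they used."""
        digest = hashlib.sha256()
        for token, idx in sorted(self.token_to_index.items()):
            digest.update(f"{token}\t{idx}\n".encode())
        return digest.hexdigest()[:16]


def build_vocabulary(
    training_token_sequences: Iterable[Sequence[str]], min_count: int = 2
) -> Vocabulary:
    """Build a vocabulary from training text, discarding rare tokens.

    Tokens with frequency below ``min_count`` are excluded (the default
    discards words appearing only once).  Indices start at 2 (0 = padding,
    1 = unknown) and are assigned by descending frequency, alphabetical
    within ties.
    """
    freq: dict[str, int] = {}
    for seq in training_token_sequences:
        for token in seq:
            freq[token] = freq.get(token, 0) + 1
    kept = [(t, c) for t, c in freq.items() if c >= min_count]
    kept.sort(key=lambda tc: (-tc[1], tc[0]))
    token_to_index = {PAD_TOKEN: PAD_INDEX, UNK_TOKEN: UNK_INDEX}
    for i, (token, _) in enumerate(kept):
        token_to_index[token] = i + 2
    return Vocabulary(token_to_index=token_to_index, min_count=min_count)


@dataclass
class EncodedLetter:
    indices: list[int]
    covariate_tokens: list[str] = field(default_factory=list)


def age_token(age: int) -> str:
    """Discretize age into a decade-bucket pseudo-token (68 -> ``age_60``)."""
    return f"age_{(age // 10) * 10}"


def sex_token(sex: str) -> str:
    return "sex_f" if sex == "female" else "sex_m"


def covariate_tokens(letter: Letter) -> list[str]:
    tokens: list[str] = []
    if letter.age is not None:
        tokens.append(age_token(letter.age))
    if letter.sex is not None:
        tokens.append(sex_token(letter.sex))
    return tokens


def encode(
    letter: Letter,
    vocab: Vocabulary,
    mode: str = "full",
    use_covariates: bool = False,
    max_len: int = 1500,
    header_lexicon: Sequence[str] = DEFAULT_SUMMARY_HEADERS,
) -> EncodedLetter:
    """Encode one letter as a padded index sequence.

    ``mode='summary'`` encodes only the extracted summary paragraph.
    With ``use_covariates`` the age-decade and sex pseudo-tokens are
    prepended to the token sequence.  The sequence is truncated or
    zero-padded (at the end) to exactly ``max_len`` indices.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if mode not in ("full", "summary"):
        raise ValueError(f"unknown encoding mode: {mode!r}")
    text = letter.text if mode == "full" else extract_summary(letter.text, header_lexicon)
    tokens = normalize_tokenize(text)
    cov = covariate_tokens(letter) if use_covariates else []
    tokens = cov + tokens
    indices = [vocab.index(t) for t in tokens[:max_len]]
    indices.extend([PAD_INDEX] * (max_len - len(indices)))
    return EncodedLetter(indices=indices, covariate_tokens=cov)


@dataclass
class LabelFilterConfig:
    min_letters_per_code: int = 50
    min_fourchar_appearances: int = 100

    def __post_init__(self) -> None:
        if self.min_letters_per_code < 1 or self.min_fourchar_appearances < 1:
            raise ValueError("label-filter thresholds must be >= 1")


def filter_labels(
    corpus: Corpus,
    config: LabelFilterConfig,
    level: str = "three_char",
    validation_corpus: Optional[Corpus] = None,
) -> list[str]:
    """Apply the label-frequency filters and return the retained codes.

    ``three_char``: roll all codes up to three characters and keep those
    appearing in at least ``min_letters_per_code`` letters.  ``four_char``:
    keep dotted codes appearing at least ``min_fourchar_appearances`` times
    in BOTH the given corpus and the validation corpus.
    """
    if level == "three_char":
        counts: dict[str, int] = {}
        for letter in corpus:
            for code in {rollup_code(c) for c in letter.codes}:
                counts[code] = counts.get(code, 0) + 1
        return sorted(c for c, n in counts.items() if n >= config.min_letters_per_code)
    if level == "four_char":
        if validation_corpus is None:
            raise ValueError("four_char filtering requires a validation corpus")

        def dotted_counts(c: Corpus) -> dict[str, int]:
            counts: dict[str, int] = {}
            for letter in c:
                for code in letter.codes:
                    if "." in code:
                        counts[code] = counts.get(code, 0) + 1
            return counts

        train_counts = dotted_counts(corpus)
        val_counts = dotted_counts(validation_corpus)
        return sorted(
            code
            for code, n in train_counts.items()
            if n >= config.min_fourchar_appearances
            and val_counts.get(code, 0) >= config.min_fourchar_appearances
        )
    raise ValueError(f"unknown filtering level: {level!r}")
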