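"""Reading, writing and validating discharge-letter corpora.

A corpus is a JSON-Lines file, one letter per line, UTF-8::

    {"id": "L0001", "text": "...", "summary": null, "age": 68,
     "sex": "female", "codes": ["I48", "I21.4"]}

``summary``, ``age`` and ``sex`` are optional.  ICD-10 codes are stored
uppercase, as one letter, two digits, and optionally a dot plus one or two
more digits (``I48``, ``I48.1``).  Codes are normalised to uppercase on
read.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "Letter",
    "Corpus",
    "CorpusStats",
    "CorpusFormatError",
    "is_valid_code",
    "validate_code",
    "rollup_code",
    "read_corpus",
    "write_corpus",
]

#: one uppercase letter, two digits, optionally "." and 1-2 more digits
CODE_RE = re.compile(r"^[A-Z][0-9]{2}(?:\.[0-9]{1,2})?$")

VALID_SEX = ("female", "male")


class CorpusFormatError(ValueError):
    """Raised when a corpus file or record violates the format contract."""


def is_valid_code(code: str) -> bool:
    return bool(CODE_RE.match(code))


def validate_code(code: str) -> str:
    """Normalise a code to uppercase and check its shape.

    Raises :class:`CorpusFormatError` naming the offending code.
    """
    if not isinstance(code, str):
        raise CorpusFormatError(f"ICD-10 code must be a string, got {code!r}")
    norm = code.strip().upper()
    if not CODE_RE.match(norm):
        raise CorpusFormatError(f"invalid ICD-10 code: {code!r}")
    return norm


def rollup_code(code: str) -> str:
    """Truncate an ICD-10 code to its three-character (rolled-up) form.

    ``I48.1`` becomes ``I48``; three-character input is returned unchanged
    (idempotent).
    """
    return validate_code(code)[:3]


@dataclass
class Letter:
    """One discharge letter with its gold ICD-10 code set."""

    id: str
    text: str
    codes: set[str] = field(default_factory=set)
    summary: Optional[str] = None
    age: Optional[int] = None
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise CorpusFormatError("letter id must be non-empty")
        if self.sex is not None and self.sex not in VALID_SEX:
            raise CorpusFormatError(
                f"letter {self.id!r}: sex must be one of {VALID_SEX}, got {self.sex!r}"
            )
        if self.age is not None and (not isinstance(self.age, int) or self.age < 0):
            raise CorpusFormatError(f"letter {self.id!r}: age must be a non-negative integer")
        self.codes = {validate_code(c) for c in self.codes}


@dataclass(frozen=True)
class CorpusStats:
    n_letters: int
    label_cardinality: float
    label_counts: dict[str, int]


def _compute_stats(letters: list[Letter]) -> CorpusStats:
    counts: dict[str, int] = {}
    total = 0
    for letter in letters:
        total += len(letter.codes)
        for code in letter.codes:
            counts[code] = counts.get(code, 0) + 1
    n = len(letters)
    # empty corpus: cardinality defined as 0
    cardinality = total / n if n else 0.0
    return CorpusStats(n_letters=n, label_cardinality=cardinality, label_counts=counts)


@dataclass
class Corpus:
    """An ordered collection of letters plus derived label statistics."""

    letters: list[Letter]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for letter in self.letters:
            if letter.id in seen:
                raise CorpusFormatError(f"duplicate letter id: {letter.id!r}")
            seen.add(letter.id)

    @property
    def stats(self) -> CorpusStats:
        return _compute_stats(self.letters)

    def __len__(self) -> int:
        return len(self.letters)

    def __iter__(self):
        return iter(self.letters)

    def subset(self, indices: Iterable[int]) -> "Corpus":
        return Corpus([self.letters[i] for i in indices])

    def codes(self) -> set[str]:
        out: set[str] = set()
        for letter in self.letters:
            out |= letter.codes
        return out


def _letter_from_record(record: dict, lineno: int) -> Letter:
    for fieldname in ("id", "text", "codes"):
        if fieldname not in record:
            raise CorpusFormatError(f"line {lineno}: missing required field {fieldname!r}")
    if not isinstance(record["codes"], list):
        raise CorpusFormatError(f"line {lineno}: field 'codes' must be a list")
    try:
        return Letter(
            id=str(record["id"]),
            text=record["text"],
            codes=set(record["codes"]),
            summary=record.get("summary"),
            age=record.get("age"),
            sex=record.get("sex"),
        )
    except CorpusFormatError as exc:
        raise CorpusFormatError(f"line {lineno}: {exc}") from exc


def read_corpus(path: str | Path) -> Corpus:
    """Read a JSONL corpus file, validating every record.

    Input order is preserved.  Malformed records raise
    :class:`CorpusFormatError` naming the line number and field.
    """
    path = Path(path)
    letters: list[Letter] = []
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON ({exc})") from exc
            if not isinstance(record, dict):
                raise CorpusFormatError(f"line {lineno}: record must be a JSON object")
            letters.append(_letter_from_record(record, lineno))
    return Corpus(letters)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as JSONL; ``read_corpus`` round-trips it exactly."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for letter in corpus.letters:
            record = {
                "id": letter.id,
                "text": letter.text,
                "codes": sorted(letter.codes),
            }
            if letter.summary is not None:
                record["summary"] = letter.summary
            if letter.age is not None:
                record["age"] = letter.age
            if letter.sex is not None:
                record["sex"] = letter.sex
            handle.write(json.dumps(record, ensure_ascii=False) + "\n")
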