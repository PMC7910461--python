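"""Rule-based pseudonymization of discharge letters.

Replaces protected health information (PHI) with numbered category
placeholders of the exact surface form ``<CATEGORY-n>``:

* dates (``12-03-2018``, ``12/03/2018``, ``12 maart 2018``) -> ``<DATUM-n>``
* ages (an integer followed by ``jarige`` or ``jaar oude``) -> ``<LEEFTIJD-n>``
* names from a lexicon (case-insensitive) -> ``<PERSOON-n>``
* institutions from a lexicon -> ``<INSTELLING-n>``

Placeholders are numbered per category in order of first appearance, and
repeated identical originals reuse their ordinal.  Matching is
longest-match-wins, left to right, without overlaps; text outside the
replaced spans is byte-identical to the input.  Because ``<`` and ``>``
never occur inside a PHI pattern, de-identification is idempotent:
running it on its own output changes nothing.

This is a deliberately minimal rule set sufficient for the pipeline
contract — it is not a certified de-identifier.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .corpus import Corpus
from .wordlists import DUTCH_MONTHS

__all__ = ["DeidResult", "Replacement", "deidentify", "deid_evaluate", "DeidReport"]

_MONTH_ALT = "|".join(DUTCH_MONTHS)

# numeric dates dd-mm-yyyy / dd/mm/yyyy, and "12 maart 2018"
_DATE_RE = re.compile(
    r"(?<![\w<>])(?:\d{1,2}[-/]\d{1,2}[-/]\d{4}|\d{1,2} (?:%s) \d{4})(?![\w>])" % _MONTH_ALT
)
# the age number in "68 jarige" / "68 jaar oude"; the unit words are kept
_AGE_RE = re.compile(r"(?<![\w<>.-])(\d{1,3})(?= jarige\b| jaar oude\b)")

_PLACEHOLDER_RE = re.compile(r"<(?:DATUM|PERSOON|LEEFTIJD|INSTELLING)-\d+>")


@dataclass(frozen=True)
class Replacement:
    category: str
    ordinal: int
    start: int  # 0-based, half-open span in the ORIGINAL text
    end: int
    original: str


@dataclass
class DeidResult:
    text: str
    replacements: list[Replacement] = field(default_factory=list)


def _lexicon_pattern(lexicon: Iterable[str]) -> Optional[re.Pattern]:
    entries = sorted({e for e in lexicon if e}, key=len, reverse=True)
    if not entries:
        return None
    alts = "|".join(re.escape(e) for e in entries)
    return re.compile(r"(?<![\w<>])(?:%s)(?![\w>])" % alts, flags=re.IGNORECASE)


def deidentify(
    text: str,
    name_lexicon: Iterable[str] = (),
    institution_lexicon: Iterable[str] = (),
) -> DeidResult:
    """Pseudonymize one text; see module docstring for the rule set."""
    if not text:
        return DeidResult(text="", replacements=[])

    candidates: list[tuple[int, int, str, str]] = []  # (start, end, category, original)

    # never touch anything inside an existing placeholder
    protected = [m.span() for m in _PLACEHOLDER_RE.finditer(text)]

    def is_protected(start: int, end: int) -> bool:
        return any(start < pe and ps < end for ps, pe in protected)

    for m in _DATE_RE.finditer(text):
        candidates.append((m.start(), m.end(), "DATUM", m.group(0)))
    for m in _AGE_RE.finditer(text):
        candidates.append((m.start(1), m.end(1), "LEEFTIJD", m.group(1)))
    pat = _lexicon_pattern(name_lexicon)
    if pat:
        for m in pat.finditer(text):
            candidates.append((m.start(), m.end(), "PERSOON", m.group(0)))
    pat = _lexicon_pattern(institution_lexicon)
    if pat:
        for m in pat.finditer(text):
            candidates.append((m.start(), m.end(), "INSTELLING", m.group(0)))

    # longest-match-wins, left to right, no overlaps
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0])))
    chosen: list[tuple[int, int, str, str]] = []
    last_end = 0
    for start, end, category, original in candidates:
        if start < last_end or is_protected(start, end):
            continue
        chosen.append((start, end, category, original))
        last_end = end

    ordinals: dict[str, dict[str, int]] = {}
    replacements: list[Replacement] = []
    out: list[str] = []
    cursor = 0
    for start, end, category, original in chosen:
        per_cat = ordinals.setdefault(category, {})
        key = original.lower()
        if key not in per_cat:
            per_cat[key] = len(per_cat) + 1
        ordinal = per_cat[key]
        out.append(text[cursor:start])
        out.append(f"<{category}-{ordinal}>")
        cursor = end
        replacements.append(
            Replacement(category=category, ordinal=ordinal, start=start, end=end, original=original)
        )
    out.append(text[cursor:])
    return DeidResult(text="".join(out), replacements=replacements)


@dataclass
class DeidReport:
    """Per-category recall/precision of de-identification on planted PHI."""

    recall: dict[str, float]
    precision: dict[str, float]
    n_gold: dict[str, int]
    n_predicted: dict[str, int]
    #: categories where precision had zero predictions (reported as 1.0)
    zero_prediction_flags: list[str]


def deid_evaluate(
    corpus_with_phi: Corpus,
    gold_spans: dict[str, list[tuple[int, int, str]]],
    results: dict[str, DeidResult],
) -> DeidReport:
    """Score de-identification against gold PHI spans.

    A gold span counts as found iff it is fully covered by a replacement of
    the same category; a replacement counts as correct iff it covers at
    least one gold span of its category.  Precision with zero predictions
    is reported as 1.0 and flagged.
    """
    categories = ("DATUM", "PERSOON", "LEEFTIJD", "INSTELLING")
    found = {c: 0 for c in categories}
    gold_n = {c: 0 for c in categories}
    correct_pred = {c: 0 for c in categories}
    pred_n = {c: 0 for c in categories}

    for letter in corpus_with_phi:
        if letter.id not in results:
            raise KeyError(f"no de-identification result for letter {letter.id!r}")
        spans = gold_spans.get(letter.id, [])
        reps = results[letter.id].replacements
        for start, end, category in spans:
            gold_n[category] += 1
            if any(
                r.category == category and r.start <= start and r.end >= end for r in reps
            ):
                found[category] += 1
        for r in reps:
            pred_n[r.category] += 1
            if any(
                c == r.category and r.start <= s and r.end >= e for s, e, c in spans
            ):
                correct_pred[r.category] += 1

    recall = {c: (found[c] / gold_n[c]) if gold_n[c] else 1.0 for c in categories}
    flags = [c for c in categories if pred_n[c] == 0]
    precision = {
        c: (correct_pred[c] / pred_n[c]) if pred_n[c] else 1.0 for c in categories
    }
    return DeidReport(
        recall=recall,
        precision=precision,
        n_gold=gold_n,
        n_predicted=pred_n,
        zero_prediction_flags=flags,
    )
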