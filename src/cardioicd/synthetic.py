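"""Synthetic Dutch-style discharge-letter generator.

The real coding corpus is private, so every downstream stage is exercised
on generated letters that reproduce the statistical structure the pipeline
relies on:

* named sections (``Reden van opname``, body, ``Conclusie en beleid``);
* a multilabel gold code set per letter with a configurable mean
  cardinality (defaults emulate a cardiology department: ten codes,
  about 4.7 codes per letter);
* per-code trigger vocabulary (synonyms and medication names) planted in
  the text wherever the code is assigned — risk-factor codes plant their
  cues only in the letter body, mirroring how risk factors are rarely
  restated in the summary paragraph;
* negated mentions (``geen`` + trigger) for some codes that are *not*
  assigned, so classifiers must use context, not mere token presence;
* age/sex covariates (median age 68, 36% female by default);
* planted PHI (dates, names, ages, institutions) with exact gold spans,
  providing ground truth for the de-identification stage.

Letter text is template-based token soup rather than grammatical Dutch:
the classifiers are lexical, so token co-occurrence structure is what
matters, and a transparent generator keeps every planted signal auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus import Corpus, Letter, validate_code
from .wordlists import (
    DEFAULT_BODY_ONLY,
    DEFAULT_TRIGGERS,
    DUTCH_MONTHS,
    FAKE_INSTITUTIONS,
    FAKE_NAMES,
    FILLER_TOKENS,
    NEGATION_TERMS,
)

__all__ = [
    "CodeProfile",
    "GeneratorConfig",
    "SyntheticCorpus",
    "default_profiles",
    "generate",
    "generate_corpus",
    "plant_phi",
    "shifted_filler",
    "SECTION_HEADERS",
]

PHI_CATEGORIES = ("DATUM", "PERSOON", "LEEFTIJD", "INSTELLING")

SECTION_HEADERS = (
    "Reden van opname",
    "Anamnese",
    "Conclusie en beleid",
    "Samenvatting",
)


@dataclass
class CodeProfile:
    """Lexical profile of one ICD-10 code in the generator."""

    code: str
    trigger_terms: Sequence[str]
    prevalence: float = 0.4
    body_only: bool = False
    confusable_terms: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.code = validate_code(self.code)
        if not self.trigger_terms:
            raise ValueError(f"profile {self.code}: trigger_terms must be non-empty")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"profile {self.code}: prevalence must be in (0,1)")


@dataclass
class GeneratorConfig:
    n_letters: int = 1000
    profiles: list[CodeProfile] = field(default_factory=lambda: default_profiles())
    target_cardinality: float = 4.7
    negation_terms: Sequence[str] = NEGATION_TERMS
    cooccurrence: Optional[dict[tuple[str, str], float]] = None
    phi_density: float = 2.0
    age_median: int = 68
    age_iqr: tuple[int, int] = (58, 77)
    female_fraction: float = 0.36
    label_noise: float = 0.0
    negation_rate: float = 0.35
    body_tokens: tuple[int, int] = (40, 70)
    summary_tokens: tuple[int, int] = (12, 20)
    filler_tokens: Sequence[str] = FILLER_TOKENS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_letters <= 0:
            raise ValueError("n_letters must be positive")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0,1]")
        if self.target_cardinality > len(self.profiles):
            raise ValueError(
                "target_cardinality exceeds the number of code profiles: "
                f"{self.target_cardinality} > {len(self.profiles)}"
            )
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be in [0,1]")


@dataclass
class SyntheticCorpus:
    """A generated corpus plus the gold PHI spans planted in it."""

    corpus: Corpus
    #: letter id -> list of (start, end, category), 0-based half-open
    phi_spans: dict[str, list[tuple[int, int, str]]]


def default_profiles(prevalence: float = 0.47) -> list[CodeProfile]:
    """Ten cardiology codes with trigger vocabularies; risk factors body-only."""
    return [
        CodeProfile(
            code=code,
            trigger_terms=terms,
            prevalence=prevalence,
            body_only=code in DEFAULT_BODY_ONLY,
        )
        for code, terms in DEFAULT_TRIGGERS.items()
    ]


def shifted_filler(fraction: float, seed: int = 0) -> tuple[str, ...]:
    """Filler vocabulary with a fraction of tokens swapped for unseen ones.

    Emulates a temporal validation corpus written by different clinicians:
    trigger structure is unchanged but part of the background vocabulary is
    new to the trained models.
    """
    rng = np.random.default_rng(seed)
    tokens = list(FILLER_TOKENS)
    n_swap = int(round(fraction * len(tokens)))
    for i in rng.choice(len(tokens), size=n_swap, replace=False):
        tokens[i] = "w" + tokens[i]
    return tuple(tokens)


# ---------------------------------------------------------------------------
# PHI planting


def _phi_surface(category: str, rng: np.random.Generator, age: Optional[int] = None):
    """Return (tokens, span_token_range) for one PHI snippet.

    ``span_token_range`` is (first, last_exclusive) into ``tokens``: for
    LEEFTIJD the gold span covers only the number, not the trailing
    "jarige"/"jaar oude".
    """
    if category == "DATUM":
        d, m, y = rng.integers(1, 29), rng.integers(1, 13), rng.integers(2013, 2020)
        if rng.random() < 0.5:
            return [f"{d:02d}-{m:02d}-{y}"], (0, 1)
        return [str(d), DUTCH_MONTHS[m - 1], str(y)], (0, 3)
    if category == "PERSOON":
        return [FAKE_NAMES[rng.integers(len(FAKE_NAMES))]], (0, 1)
    if category == "LEEFTIJD":
        years = int(age) if age is not None else int(rng.integers(40, 90))
        if rng.random() < 0.5:
            return [str(years), "jarige"], (0, 1)
        return [str(years), "jaar", "oude"], (0, 1)
    if category == "INSTELLING":
        inst = FAKE_INSTITUTIONS[rng.integers(len(FAKE_INSTITUTIONS))]
        toks = inst.split()
        return toks, (0, len(toks))
    raise ValueError(f"unknown PHI category: {category}")


def _assemble(lines: list[list], phi_markers: bool = True):
    """Join token lines into text, resolving PHI marker tuples to spans.

    Tokens are joined with single spaces, lines with newlines.  A PHI
    marker is a tuple ``(tokens, (first, last), category)``.
    """
    parts: list[str] = []
    spans: list[tuple[int, int, str]] = []
    offset = 0
    for li, line in enumerate(lines):
        if li > 0:
            parts.append("\n")
            offset += 1
        for ti, tok in enumerate(line):
            if ti > 0:
                parts.append(" ")
                offset += 1
            if isinstance(tok, tuple):
                toks, (first, last), category = tok
                start = None
                for j, sub in enumerate(toks):
                    if j > 0:
                        parts.append(" ")
                        offset += 1
                    if j == first:
                        start = offset
                    parts.append(sub)
                    offset += len(sub)
                    if j == last - 1:
                        spans.append((start, offset, category))
            else:
                parts.append(tok)
                offset += len(tok)
    return "".join(parts), spans


def plant_phi(
    letter_text: str,
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    age: Optional[int] = None,
):
    """Insert surface-form PHI into text and return exact gold spans.

    The number of insertions is Poisson(``phi_density``); categories are
    drawn uniformly from DATUM, PERSOON, LEEFTIJD and INSTELLING.  PHI is
    never inserted into a section-header line, and spans never overlap.
    Returns ``(text_with_phi, [(start, end, category), ...])`` with
    0-based half-open character spans.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if not letter_text:
        return letter_text, []
    lines: list[list] = [line.split() for line in letter_text.split("\n")]
    header_set = {h.lower() for h in SECTION_HEADERS}
    candidates = [
        i
        for i, line in enumerate(lines)
        if line and " ".join(line).lower() not in header_set
    ]
    n_phi = int(rng.poisson(config.phi_density)) if config.phi_density > 0 else 0
    if not candidates:
        n_phi = 0
    for _ in range(n_phi):
        category = PHI_CATEGORIES[rng.integers(len(PHI_CATEGORIES))]
        toks, span_range = _phi_surface(category, rng, age=age)
        li = candidates[rng.integers(len(candidates))]
        pos = int(rng.integers(len(lines[li]) + 1))
        lines[li].insert(pos, (toks, span_range, category))
    return _assemble(lines)


# ---------------------------------------------------------------------------
# letter generation


def _sample_codes(config: GeneratorConfig, rng: np.random.Generator) -> set[str]:
    profiles = config.profiles
    total = sum(p.prevalence for p in profiles)
    scale = config.target_cardinality / total
    probs = [min(p.prevalence * scale, 0.99) for p in profiles]
    assigned = {p.code for p, q in zip(profiles, probs) if rng.random() < q}
    if config.cooccurrence:
        for (a, b), boost in config.cooccurrence.items():
            if a in assigned and b not in assigned and rng.random() < boost:
                assigned.add(b)
    return assigned


def _sample_age(config: GeneratorConfig, rng: np.random.Generator) -> int:
    lo, hi = config.age_iqr
    sigma = (hi - lo) / 1.349  # IQR of a normal is 1.349 sigma
    age = int(round(rng.normal(config.age_median, sigma)))
    return int(min(max(age, 18), 99))


def _pick_negation(terms: Sequence[str], rng: np.random.Generator) -> str:
    """Sample a negation cue, biased towards the first (most common) term."""
    if len(terms) == 1:
        return terms[0]
    if rng.random() < 0.55:
        return terms[0]
    return terms[1 + rng.integers(len(terms) - 1)]


def _fill(n: int, config: GeneratorConfig, rng: np.random.Generator) -> list[str]:
    vocab = config.filler_tokens
    return [vocab[i] for i in rng.integers(len(vocab), size=n)]


def _insert_tokens(line: list[str], tokens: list[str], rng: np.random.Generator) -> None:
    pos = int(rng.integers(len(line) + 1))
    line[pos:pos] = tokens


def _generate_letter(
    idx: int, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[Letter, list[tuple[int, int, str]]]:
    age = _sample_age(config, rng)
    sex = "female" if rng.random() < config.female_fraction else "male"
    true_codes = _sample_codes(config, rng)
    by_code = {p.code: p for p in config.profiles}

    body_n = int(rng.integers(config.body_tokens[0], config.body_tokens[1] + 1))
    summary_n = int(rng.integers(config.summary_tokens[0], config.summary_tokens[1] + 1))
    body = _fill(body_n, config, rng)
    summary = ["bovengenoemde", "patient"] + _fill(summary_n, config, rng)

    for code in sorted(true_codes):
        profile = by_code[code]
        terms = list(profile.trigger_terms)
        pick = lambda: terms[rng.integers(len(terms))]  # noqa: E731
        if profile.body_only:
            _insert_tokens(body, [pick()], rng)
            _insert_tokens(body, [pick()], rng)
        else:
            _insert_tokens(body, [pick()], rng)
            _insert_tokens(summary, [pick()], rng)
        if profile.confusable_terms and rng.random() < 0.5:
            terms_c = list(profile.confusable_terms)
            _insert_tokens(body, [terms_c[rng.integers(len(terms_c))]], rng)

    # negated mention of a code that is NOT assigned: mirrors the placement
    # of a genuine assignment (same trigger count, same sections) so the
    # negation word is the only discriminating feature
    if rng.random() < config.negation_rate:
        absent = [p for p in config.profiles if p.code not in true_codes]
        if absent:
            profile = absent[rng.integers(len(absent))]
            terms = list(profile.trigger_terms)
            neg = _pick_negation(config.negation_terms, rng)
            first = [neg, terms[rng.integers(len(terms))]]
            second = [neg, terms[rng.integers(len(terms))]]
            if profile.body_only:
                _insert_tokens(body, first, rng)
                _insert_tokens(body, second, rng)
            else:
                _insert_tokens(body, first, rng)
                _insert_tokens(summary, second, rng)

    text = "\n".join(
        [
            "Reden van opname",
            " ".join(body),
            "Conclusie en beleid",
            " ".join(summary),
        ]
    )
    text, spans = plant_phi(text, config, rng=rng, age=age)

    gold = set(true_codes)
    if config.label_noise > 0 and rng.random() < config.label_noise:
        # one coder error per affected letter: flip a random code
        all_codes = [p.code for p in config.profiles]
        flip = all_codes[rng.integers(len(all_codes))]
        gold ^= {flip}

    letter = Letter(
        id=f"L{idx:05d}",
        text=text,
        codes=gold,
        age=age,
        sex=sex,
    )
    return letter, spans


def generate(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate a corpus with gold PHI spans; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    letters: list[Letter] = []
    phi: dict[str, list[tuple[int, int, str]]] = {}
    for i in range(config.n_letters):
        letter, spans = _generate_letter(i, config, rng)
        letters.append(letter)
        phi[letter.id] = spans
    return SyntheticCorpus(corpus=Corpus(letters), phi_spans=phi)


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Generate letters only (PHI gold spans discarded)."""
    return generate(config).corpus


def permute_labels(corpus: Corpus, seed: int = 0) -> Corpus:
    """Shuffle gold code sets across letters (permutation null control).

    Text is untouched, so any residual classifier skill on a permuted
    corpus reflects chance structure, not lexical signal.
    """
    rng = np.random.default_rng(seed)
    code_sets = [set(l.codes) for l in corpus]
    order = rng.permutation(len(code_sets))
    letters = [
        Letter(
            id=l.id,
            text=l.text,
            codes=code_sets[order[i]],
            summary=l.summary,
            age=l.age,
            sex=l.sex,
        )
        for i, l in enumerate(corpus)
    ]
    return Corpus(letters)


def write_phi_sidecar(phi_spans: dict[str, list[tuple[int, int, str]]], path) -> None:
    import json

    with open(path, "w", encoding="utf-8") as handle:
        for letter_id, spans in phi_spans.items():
            rec = {"letter_id": letter_id, "spans": [list(s) for s in spans]}
            handle.write(json.dumps(rec) + "\n")


def read_phi_sidecar(path) -> dict[str, list[tuple[int, int, str]]]:
    import json

    out: dict[str, list[tuple[int, int, str]]] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if line.strip():
                rec = json.loads(line)
                out[rec["letter_id"]] = [tuple(s) for s in rec["spans"]]
    return out
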