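"""Tokenization, summary extraction, vocabulary, encoding, label filters."""

import pytest

from cardioicd.corpus import Corpus, Letter
from cardioicd.preprocess import (
    PAD_INDEX,
    UNK_INDEX,
    LabelFilterConfig,
    build_vocabulary,
    encode,
    extract_summary,
    filter_labels,
    normalize_tokenize,
)


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("STEMI  inferior 3", ["stemi", "inferior"]),
            ("<DATUM-1>", ["<datum-1>"]),
            ("", []),
            ("pijn, op de borst.", ["pijn", "op", "de", "borst"]),
            ("non-stemi en dmii", ["non-stemi", "en", "dmii"]),
            ("12-03-2018 en 500 mg", ["en", "mg"]),
        ],
    )
    def test_examples(self, text, expected):
        assert normalize_tokenize(text) == expected


class TestExtractSummary:
    LETTER = (
        "Reden van opname\nSTEMI inferior\n"
        "Conclusie en beleid\nBovengenoemde <LEEFTIJD-1> jarige man werd gepresenteerd\n"
        "Samenvatting\nHoofddiagnose STEMI"
    )

    def test_first_header_to_next_header(self):
        summary = extract_summary(self.LETTER)
        assert summary.startswith("Bovengenoemde")
        assert "Hoofddiagnose" not in summary

    def test_no_header_gives_empty(self):
        assert extract_summary("alleen lichaamstekst zonder koppen") == ""

    def test_longest_header_wins_at_same_position(self):
        # "conclusie en beleid" must match as one header, not bare "conclusie"
        text = "Conclusie en beleid\nde tekst"
        assert extract_summary(text) == "de tekst"


class TestVocabulary:
    def test_singletons_discarded(self):
        seqs = [["stemi"] * 5, ["zeldzaamwoord"]]
        vocab = build_vocabulary(seqs, min_count=2)
        assert "stemi" in vocab and "zeldzaamwoord" not in vocab

    def test_all_singletons_gives_specials_only(self):
        vocab = build_vocabulary([["a"], ["b"]], min_count=2)
        assert vocab.size == 2

    def test_tie_break_alphabetical(self):
        vocab = build_vocabulary([["b", "a"], ["a", "b"], ["c"] * 5])
        # c most frequent -> 2; a and b tie at 2 -> alphabetical
        assert vocab.token_to_index["c"] == 2
        assert vocab.token_to_index["a"] == 3
        assert vocab.token_to_index["b"] == 4

    def test_fingerprint_changes_with_content(self):
        v1 = build_vocabulary([["a", "a", "b", "b"]])
        v2 = build_vocabulary([["a", "a", "c", "c"]])
        assert v1.fingerprint() != v2.fingerprint()


class TestEncode:
    @pytest.fixture()
    def vocab(self):
        return build_vocabulary(
            [["stemi", "stemi", "pijn", "pijn", "age_60", "age_60", "sex_f", "sex_f"]]
        )

    def test_covariates_prepended(self, vocab):
        letter = Letter(id="a", text="stemi pijn", age=68, sex="female", codes=set())
        enc = encode(letter, vocab, use_covariates=True, max_len=6)
        assert enc.indices[0] == vocab.index("age_60")
        assert enc.indices[1] == vocab.index("sex_f")
        assert enc.indices[2] == vocab.index("stemi")

    def test_oov_maps_to_unknown(self, vocab):
        letter = Letter(id="a", text="onbekendwoord", codes=set())
        assert encode(letter, vocab, max_len=3).indices[0] == UNK_INDEX

    def test_truncation_and_padding(self, vocab):
        letter = Letter(id="a", text="stemi " * 10, codes=set())
        assert len(encode(letter, vocab, max_len=4).indices) == 4
        short = encode(Letter(id="b", text="stemi", codes=set()), vocab, max_len=4)
        assert short.indices[1:] == [PAD_INDEX] * 3

    def test_bad_max_len(self, vocab):
        with pytest.raises(ValueError):
            encode(Letter(id="a", text="x", codes=set()), vocab, max_len=0)


def _corpus_with_counts(count_by_code):
    letters = []
    i = 0
    for code, n in count_by_code.items():
        for _ in range(n):
            letters.append(Letter(id=f"l{i}", text="t", codes={code}))
            i += 1
    return Corpus(letters)


class TestFilterLabels:
    def test_threshold_boundary(self):
        corpus = _corpus_with_counts({"I48": 49, "I21": 50})
        retained = filter_labels(corpus, LabelFilterConfig(), level="three_char")
        assert retained == ["I21"]

    def test_rollup_aggregates_dotted_codes(self):
        corpus = _corpus_with_counts({"I48.0": 30, "I48.1": 25})
        retained = filter_labels(corpus, LabelFilterConfig(), level="three_char")
        assert retained == ["I48"]

    def test_four_char_requires_both_sets(self):
        train = _corpus_with_counts({"I48.1": 120, "I25.1": 130})
        val = _corpus_with_counts({"I48.1": 90, "I25.1": 100})
        retained = filter_labels(
            train, LabelFilterConfig(), level="four_char", validation_corpus=val
        )
        assert retained == ["I25.1"]

    def test_monotone_in_threshold(self):
        corpus = _corpus_with_counts({"I48": 49, "I21": 60, "I10": 80})
        lo = filter_labels(corpus, LabelFilterConfig(min_letters_per_code=40), "three_char")
        hi = filter_labels(corpus, LabelFilterConfig(min_letters_per_code=70), "three_char")
        assert set(hi) <= set(lo)
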