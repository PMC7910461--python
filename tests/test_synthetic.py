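"""Synthetic-letter generator: cardinality, determinism, planted structure."""

import numpy as np
import pytest

from cardioicd.corpus import write_corpus
from cardioicd.preprocess import extract_summary, normalize_tokenize
from cardioicd.synthetic import (
    CodeProfile,
    GeneratorConfig,
    default_profiles,
    generate,
    generate_corpus,
    permute_labels,
    plant_phi,
)


class TestCardinalityAndPrevalence:
    def test_cardinality_close_to_target(self):
        config = GeneratorConfig(
            n_letters=1000, profiles=default_profiles()[:8], target_cardinality=3.0, seed=7
        )
        corpus = generate_corpus(config)
        assert 2.7 <= corpus.stats.label_cardinality <= 3.3

    def test_impossible_cardinality_rejected(self):
        with pytest.raises(ValueError, match="cardinality"):
            GeneratorConfig(profiles=default_profiles()[:3], target_cardinality=4.0)

    def test_label_prevalence_tracks_profiles(self):
        profiles = [
            CodeProfile("I48", ("af",), prevalence=0.8),
            CodeProfile("I21", ("stemi",), prevalence=0.2),
        ]
        config = GeneratorConfig(
            n_letters=1500, profiles=profiles, target_cardinality=1.0, seed=5
        )
        counts = generate_corpus(config).stats.label_counts
        # scaled prevalences 0.8 and 0.2; binomial 3-sigma bands at n=1500
        assert abs(counts.get("I48", 0) / 1500 - 0.8) < 0.04
        assert abs(counts.get("I21", 0) / 1500 - 0.2) < 0.04


class TestPlantedSignal:
    def test_assigned_codes_have_triggers_in_text(self, small_synthetic):
        profiles = {p.code: p for p in default_profiles()[:4]}
        for letter in list(small_synthetic.corpus)[:100]:
            tokens = set(normalize_tokenize(letter.text))
            for code in letter.codes:
                assert tokens & set(profiles[code].trigger_terms), (letter.id, code)

    def test_body_only_codes_keep_summary_clean(self):
        config = GeneratorConfig(
            n_letters=300,
            profiles=default_profiles()[:4],
            target_cardinality=2.0,
            negation_rate=0.0,
            seed=9,
        )
        profiles = {p.code: p for p in config.profiles}
        for letter in generate_corpus(config):
            summary_tokens = set(normalize_tokenize(extract_summary(letter.text)))
            for code in letter.codes:
                if profiles[code].body_only:
                    assert not summary_tokens & set(profiles[code].trigger_terms)

    def test_sections_present(self, small_synthetic):
        letter = small_synthetic.corpus.letters[0]
        assert "Reden van opname" in letter.text
        assert "Conclusie en beleid" in letter.text


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        config = GeneratorConfig(n_letters=50, profiles=default_profiles()[:4],
                                 target_cardinality=2.0, seed=13)
        a, b = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_corpus(generate_corpus(config), a)
        write_corpus(generate_corpus(config), b)
        assert a.read_bytes() == b.read_bytes()

    def test_phi_spans_deterministic(self):
        config = GeneratorConfig(n_letters=30, profiles=default_profiles()[:4],
                                 target_cardinality=2.0, seed=13)
        assert generate(config).phi_spans == generate(config).phi_spans


class TestPlantPhi:
    def test_zero_density_no_change(self):
        config = GeneratorConfig(profiles=default_profiles()[:4], target_cardinality=2.0,
                                 phi_density=0.0, seed=1)
        text = "Reden van opname\npatient werd opgenomen"
        out, spans = plant_phi(text, config)
        assert out == text and spans == []

    def test_mean_density(self):
        config = GeneratorConfig(n_letters=1000, profiles=default_profiles()[:4],
                                 target_cardinality=2.0, phi_density=2.0, seed=3)
        total = sum(len(s) for s in generate(config).phi_spans.values())
        assert 1.8 <= total / 1000 <= 2.2

    def test_spans_cover_surface_exactly_and_never_overlap(self, small_synthetic):
        headers = {"reden van opname", "conclusie en beleid"}
        for letter in list(small_synthetic.corpus)[:200]:
            spans = sorted(small_synthetic.phi_spans[letter.id])
            for (s1, e1, _), (s2, e2, _) in zip(spans, spans[1:]):
                assert e1 <= s2, "overlapping spans"
            for start, end, category in spans:
                surface = letter.text[start:end]
                assert surface.strip() == surface and surface
                assert surface.lower() not in headers


class TestPermuteLabels:
    def test_preserves_text_and_multiset_of_codesets(self, small_synthetic):
        corpus = small_synthetic.corpus
        shuffled = permute_labels(corpus, seed=4)
        assert [l.text for l in corpus] == [l.text for l in shuffled]
        orig = sorted(tuple(sorted(l.codes)) for l in corpus)
        perm = sorted(tuple(sorted(l.codes)) for l in shuffled)
        assert orig == perm
        assert any(a.codes != b.codes for a, b in zip(corpus, shuffled))
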