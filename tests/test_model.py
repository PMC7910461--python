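"""Binary-relevance training: separability, independence, persistence."""

import numpy as np
import pytest

from cardioicd.corpus import Corpus, Letter
from cardioicd.model import (
    ModelConfig,
    SplitConfig,
    TrainedLabelModel,
    crossvalidate,
    encode_letters,
    predict_proba,
    split_corpus,
    train_binary_relevance,
)
from cardioicd.preprocess import build_vocabulary, normalize_tokenize


def _separable_corpus(n=160, seed=0):
    """Two codes, each with one always-present unique trigger token."""
    rng = np.random.default_rng(seed)
    filler = [f"w{i}" for i in range(20)]
    letters = []
    for i in range(n):
        toks = list(rng.choice(filler, size=12))
        codes = set()
        if rng.random() < 0.5:
            toks.insert(rng.integers(len(toks)), "stemi")
            toks.insert(rng.integers(len(toks)), "stemi")
            codes.add("I21")
        if rng.random() < 0.5:
            toks.insert(rng.integers(len(toks)), "pacemaker")
            toks.insert(rng.integers(len(toks)), "pacemaker")
            codes.add("Z95")
        letters.append(Letter(id=f"l{i}", text=" ".join(toks), codes=codes))
    return Corpus(letters)


@pytest.fixture(scope="module")
def separable_setup():
    corpus = _separable_corpus()
    vocab = build_vocabulary([normalize_tokenize(l.text) for l in corpus])
    config = ModelConfig.test_profile(max_len=40, seed=3)
    encoded = encode_letters(list(corpus), vocab, max_len=40)
    models = train_binary_relevance(corpus, ["I21", "Z95"], vocab, config, encoded=encoded)
    return corpus, vocab, config, encoded, models


class TestSeparableTraining:
    def test_perfect_f1_on_separable_fixture(self, separable_setup):
        corpus, vocab, config, encoded, models = separable_setup
        y = {c: np.array([1 if c in l.codes else 0 for l in corpus]) for c in models}
        for code, model in models.items():
            pred = (model.predict(encoded) > 0.5).astype(int)
            tp = ((pred == 1) & (y[code] == 1)).sum()
            fp = ((pred == 1) & (y[code] == 0)).sum()
            fn = ((pred == 0) & (y[code] == 1)).sum()
            assert 2 * tp / (2 * tp + fp + fn) == 1.0

    def test_probabilities_in_unit_interval(self, separable_setup):
        _, _, _, encoded, models = separable_setup
        pm = predict_proba(models, encoded, [f"l{i}" for i in range(encoded.shape[0])])
        assert np.all((pm.probabilities >= 0) & (pm.probabilities <= 1))
        assert pm.codes == ["I21", "Z95"]

    def test_fingerprint_mismatch_rejected(self, separable_setup):
        _, _, _, encoded, models = separable_setup
        with pytest.raises(ValueError, match="fingerprint"):
            models["I21"].predict(encoded[:2], vocab_fingerprint="deadbeef")

    def test_zero_positive_code_rejected(self, separable_setup):
        corpus, vocab, config, encoded, _ = separable_setup
        with pytest.raises(ValueError, match="I99"):
            train_binary_relevance(corpus, ["I99"], vocab, config, encoded=encoded)


class TestIndependenceAndDeterminism:
    def test_binary_relevance_independence(self, separable_setup):
        """Training an extra code leaves the other code's model unchanged."""
        corpus, vocab, config, encoded, models = separable_setup
        solo = train_binary_relevance(corpus, ["Z95"], vocab, config, encoded=encoded)
        p_joint = models["Z95"].predict(encoded)
        p_solo = solo["Z95"].predict(encoded)
        np.testing.assert_array_equal(p_joint, p_solo)

    def test_same_seed_identical_predictions(self, separable_setup):
        corpus, vocab, config, encoded, models = separable_setup
        again = train_binary_relevance(corpus, ["I21"], vocab, config, encoded=encoded)
        np.testing.assert_array_equal(
            models["I21"].predict(encoded), again["I21"].predict(encoded)
        )


class TestSplitAndCrossvalidation:
    def test_split_fractions(self):
        corpus = _separable_corpus(n=100)
        train, test = split_corpus(corpus, SplitConfig(seed=1))
        assert len(train) == 80 and len(test) == 20
        assert sorted(train + test) == list(range(100))

    def test_invalid_fold_count_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            SplitConfig(n_folds=1)

    def test_fold_partition_sizes(self, separable_setup):
        corpus, vocab, config, encoded, _ = separable_setup
        fast = ModelConfig.test_profile(max_len=40, max_epochs=4, seed=3)
        records = crossvalidate(
            corpus, "I21", vocab, SplitConfig(n_folds=5, seed=2), fast, encoded=encoded
        )
        sizes = [r["n_val"] for r in records if not r.get("skipped")]
        assert sum(sizes) == len(corpus)
        assert max(sizes) - min(sizes) <= 1


class TestPersistence:
    def test_save_load_reproduces_probabilities(self, separable_setup, tmp_path):
        _, _, _, encoded, models = separable_setup
        models["I21"].save(tmp_path / "I21")
        loaded = TrainedLabelModel.load(tmp_path / "I21")
        assert loaded.code == "I21"
        assert loaded.vocab_fingerprint == models["I21"].vocab_fingerprint
        np.testing.assert_array_equal(
            loaded.predict(encoded), models["I21"].predict(encoded)
        )
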