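"""Confusion metrics and Cohen's kappa against independent oracles."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from cardioicd.evaluation import (
    ConfusionCounts,
    MetricsReport,
    bootstrap_kappa_ci,
    cohens_kappa,
    confusion,
    metrics_from_confusion,
)


class TestConfusion:
    def test_identity_matrices(self):
        gold = np.array([[1, 0], [0, 1]])
        c = confusion(gold, gold, scope="pooled")
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_cell_by_cell_example(self):
        gold = np.array([[1, 0], [0, 1]])
        pred = np.array([[1, 1], [0, 0]])
        c = confusion(gold, pred, scope="pooled")
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_empty_matrices(self):
        c = confusion(np.zeros((0, 3)), np.zeros((0, 3)), scope="pooled")
        assert c.total == 0

    def test_pooled_equals_sum_of_per_code(self):
        rng = np.random.default_rng(2)
        gold = rng.integers(0, 2, size=(40, 6))
        pred = rng.integers(0, 2, size=(40, 6))
        per = confusion(gold, pred, scope="per_code")
        pooled = confusion(gold, pred, scope="pooled")
        assert pooled.tp == sum(c.tp for c in per)
        assert pooled.fn == sum(c.fn for c in per)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            confusion(np.zeros((2, 2)), np.zeros((2, 3)))


class TestMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (ConfusionCounts(1, 0, 0, 0), {"sensitivity": 1.0, "ppv": 1.0, "f1": 1.0}),
            (ConfusionCounts(0, 0, 5, 3), {"sensitivity": 0.0, "f1": 0.0}),
            (ConfusionCounts(3, 1, 0, 1), {"ppv": 0.75, "sensitivity": 0.75, "f1": 0.75}),
        ],
    )
    def test_worked_examples(self, counts, expected):
        m = metrics_from_confusion(counts)
        for key, value in expected.items():
            assert m[key] == pytest.approx(value)

    def test_zero_denominator_flagged_not_zero(self):
        m = metrics_from_confusion(ConfusionCounts(0, 0, 4, 0))
        assert m["sensitivity"] is None and m["ppv"] is None
        assert {"sensitivity", "ppv", "f1"} <= set(m["undefined"])

    def test_f1_equals_harmonic_mean_on_random_counts(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            c = ConfusionCounts(*rng.integers(0, 50, size=4))
            m = metrics_from_confusion(c)
            if m["ppv"] is not None and m["sensitivity"] is not None and m["f1"] is not None:
                if m["ppv"] + m["sensitivity"] > 0:
                    harmonic = 2 * m["ppv"] * m["sensitivity"] / (m["ppv"] + m["sensitivity"])
                    assert m["f1"] == pytest.approx(harmonic)

    def test_report_frame_has_pooled_row(self):
        gold = np.array([[1, 0], [0, 1]])
        report = MetricsReport.from_matrices(gold, gold, ["I48", "I21"])
        frame = report.to_frame()
        assert set(frame["code"]) == {"I48", "I21", "__pooled__"}


class TestKappa:
    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, size=200)
        b = rng.integers(0, 2, size=200)
        assert cohens_kappa(a, a) == 1.0
        assert cohens_kappa(a, b) == pytest.approx(cohens_kappa(b, a))

    def test_hand_evaluated_table(self):
        # agreement table [[20,5],[10,65]]: p_o=0.85, p_e=0.60, kappa=0.625
        a = [1] * 25 + [0] * 75
        b = [1] * 20 + [0] * 5 + [1] * 10 + [0] * 65
        assert cohens_kappa(a, b) == pytest.approx(0.625)

    def test_chance_level_agreement_is_zero(self):
        a = [1, 1, 0, 0]
        b = [1, 0, 1, 0]
        assert cohens_kappa(a, b) == pytest.approx(0.0)

    def test_matches_sklearn_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a = rng.integers(0, 2, size=80)
            b = np.where(rng.random(80) < 0.3, 1 - a, a)
            if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
                continue
            assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa([1, 0], [1])


class TestBootstrapCI:
    def test_identical_coders_degenerate_ci(self):
        a = np.tile([1, 0, 1, 0, 0], 20)
        groups = np.repeat(np.arange(20), 5)
        result = bootstrap_kappa_ci(a, a, groups, n_boot=200, seed=1)
        assert result.kappa == 1.0
        assert result.ci_low == result.ci_high == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, size=300)
        b = np.where(rng.random(300) < 0.2, 1 - a, a)
        groups = np.repeat(np.arange(50), 6)
        r1 = bootstrap_kappa_ci(a, b, groups, n_boot=200, seed=9)
        r2 = bootstrap_kappa_ci(a, b, groups, n_boot=200, seed=9)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_ci_brackets_kappa_and_orders(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 2, size=500)
        b = np.where(rng.random(500) < 0.15, 1 - a, a)
        groups = np.repeat(np.arange(100), 5)
        r = bootstrap_kappa_ci(a, b, groups, n_boot=300, seed=2)
        assert r.ci_low <= r.kappa <= r.ci_high

    def test_coverage_of_analytic_kappa(self):
        """CI covers the closed-form kappa of the generating process.

        Coders disagree independently with rate 0.1 on balanced items:
        p_o = 0.9; marginals 0.5/0.5 give p_e = 0.5, so kappa = 0.8.
        """
        covered = 0
        reps = 60
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            a = rng.integers(0, 2, size=100 * 10)
            b = np.where(rng.random(1000) < 0.1, 1 - a, a)
            groups = np.repeat(np.arange(100), 10)
            r = bootstrap_kappa_ci(a, b, groups, n_boot=200, seed=rep)
            if r.ci_low <= 0.8 <= r.ci_high:
                covered += 1
        assert covered / reps >= 0.9

    def test_too_few_letters_rejected(self):
        with pytest.raises(ValueError, match="letters"):
            bootstrap_kappa_ci([1, 0], [1, 0], ["a", "a"], n_boot=200)
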