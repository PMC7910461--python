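"""End-to-end experiment runner for the coding pipeline.

Four input configurations are supported, mirroring how a coding pipeline
is typically ablated:

* ``I_summary_only`` — classify from the summary paragraph only;
* ``II_full_text`` — classify from the entire letter;
* ``III_full_plus_demographics`` — full text plus age/sex pseudo-tokens;
* ``IV_multilabel`` — experiment III's models combined into a multilabel
  code-set prediction via the cardinality-matched global threshold,
  scored per code and pooled (micro).

A run executes de-identification -> preprocessing (label filtering,
vocabulary, encoding) -> embedding pretraining -> per-code training ->
prediction -> decision -> evaluation -> interpretation, writing metrics
(CSV/JSON), predictions (JSONL), per-code coefficient tables (CSV), the
threshold calibration record and a config snapshot to the output
directory.  A validation corpus, when given, is scored with the SAME
trained models, vocabulary and threshold — nothing is refit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .corpus import Corpus, Letter, read_corpus, rollup_code
from .decision import ThresholdCalibration, apply_threshold, calibrate_threshold
from .deid import deidentify
from .evaluation import MetricsReport
from .interpret import WordCoefficientTable, word_coefficients
from .model import (
    ModelConfig,
    PredictionMatrix,
    SplitConfig,
    TrainedLabelModel,
    encode_letters,
    predict_proba,
    pretrain,
    split_corpus,
    train_binary_relevance,
)
from .preprocess import (
    LabelFilterConfig,
    Vocabulary,
    build_vocabulary,
    extract_summary,
    filter_labels,
    normalize_tokenize,
)
from .synthetic import GeneratorConfig, generate_corpus
from .wordlists import FAKE_INSTITUTIONS, FAKE_NAMES

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "make_report"]

EXPERIMENTS = (
    "I_summary_only",
    "II_full_text",
    "III_full_plus_demographics",
    "IV_multilabel",
)

logger = logging.getLogger("cardioicd")


@dataclass
class ExperimentConfig:
    experiment: str = "II_full_text"
    corpus_path: Optional[str] = None
    validation_corpus_path: Optional[str] = None
    output_dir: Optional[str] = None
    split: SplitConfig = field(default_factory=SplitConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    label_filter: LabelFilterConfig = field(default_factory=LabelFilterConfig)
    generator: Optional[GeneratorConfig] = None
    apply_deid: bool = True
    min_count: int = 2
    interpret_method: str = "surrogate_linear"
    compute_coefficients: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}")

    @property
    def mode(self) -> str:
        return "summary" if self.experiment == "I_summary_only" else "full"

    @property
    def use_covariates(self) -> bool:
        # experiment III implies covariates; IV is the multilabel view of III
        return self.experiment in ("III_full_plus_demographics", "IV_multilabel")


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    codes: list[str]
    metrics: MetricsReport
    predictions: PredictionMatrix
    models: dict[str, TrainedLabelModel]
    vocab: Vocabulary
    calibration: Optional[ThresholdCalibration] = None
    coefficient_tables: dict[str, WordCoefficientTable] = field(default_factory=dict)
    validation_metrics: Optional[MetricsReport] = None
    training_cardinality: Optional[float] = None
    test_letter_ids: list[str] = field(default_factory=list)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise errors naming the stage."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def _rolled_letters(corpus: Corpus) -> Corpus:
    letters = [
        Letter(
            id=l.id,
            text=l.text,
            codes={rollup_code(c) for c in l.codes},
            summary=l.summary,
            age=l.age,
            sex=l.sex,
        )
        for l in corpus
    ]
    return Corpus(letters)


def _deid_corpus(corpus: Corpus) -> Corpus:
    letters = [
        Letter(
            id=l.id,
            text=deidentify(l.text, FAKE_NAMES, FAKE_INSTITUTIONS).text,
            codes=set(l.codes),
            summary=l.summary,
            age=l.age,
            sex=l.sex,
        )
        for l in corpus
    ]
    return Corpus(letters)


def _gold_matrix(letters, codes: list[str]) -> np.ndarray:
    return np.asarray(
        [[1 if c in l.codes else 0 for c in codes] for l in letters], dtype=np.int64
    )


def _cardinality_over(letters, codes: list[str]) -> float:
    code_set = set(codes)
    if not letters:
        return 0.0
    return float(np.mean([len(l.codes & code_set) for l in letters]))


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run one experiment end to end; see module docstring for stages."""
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        logging.basicConfig(level=logging.INFO)

    with _stage("load"):
        if config.corpus_path:
            corpus = read_corpus(config.corpus_path)
        elif config.generator is not None:
            corpus = generate_corpus(config.generator)
        else:
            raise ValueError("either corpus_path or generator must be configured")
        validation = (
            read_corpus(config.validation_corpus_path)
            if config.validation_corpus_path
            else None
        )

    with _stage("deid"):
        if config.apply_deid:
            corpus = _deid_corpus(corpus)
            if validation is not None:
                validation = _deid_corpus(validation)

    with _stage("preprocess"):
        corpus = _rolled_letters(corpus)
        if validation is not None:
            validation = _rolled_letters(validation)
        train_idx, test_idx = split_corpus(corpus, config.split)
        train_letters = [corpus.letters[i] for i in train_idx]
        test_letters = [corpus.letters[i] for i in test_idx]
        codes = filter_labels(
            Corpus(train_letters), config.label_filter, level="three_char"
        )
        if not codes:
            raise ValueError("no codes retained after label filtering")
        mode = config.mode
        train_texts = [
            l.text if mode == "full" else extract_summary(l.text) for l in train_letters
        ]
        vocab = build_vocabulary(
            (normalize_tokenize(t) for t in train_texts), min_count=config.min_count
        )

    with _stage("embeddings"):
        sequences = [normalize_tokenize(t) for t in train_texts]
        embedding_matrix = pretrain(sequences, vocab, config.model)

    with _stage("train"):
        train_encoded = encode_letters(
            train_letters,
            vocab,
            mode=mode,
            use_covariates=config.use_covariates,
            max_len=config.model.max_len,
        )
        models = train_binary_relevance(
            Corpus(train_letters),
            codes,
            vocab,
            config.model,
            encoded=train_encoded,
            embedding_matrix=embedding_matrix,
            mode=mode,
            use_covariates=config.use_covariates,
        )

    with _stage("predict"):
        test_encoded = encode_letters(
            test_letters,
            vocab,
            mode=mode,
            use_covariates=config.use_covariates,
            max_len=config.model.max_len,
        )
        predictions = predict_proba(
            models, test_encoded, [l.id for l in test_letters], vocab.fingerprint()
        )

    calibration = None
    training_cardinality = None
    with _stage("decide"):
        gold = _gold_matrix(test_letters, codes)
        if config.experiment == "IV_multilabel":
            training_cardinality = _cardinality_over(train_letters, codes)
            calibration = calibrate_threshold(predictions, training_cardinality)
            binary = apply_threshold(predictions, calibration)
        else:
            binary = (predictions.probabilities > 0.5).astype(np.int64)

    with _stage("evaluate"):
        metrics = MetricsReport.from_matrices(gold, binary, codes)

    coefficient_tables: dict[str, WordCoefficientTable] = {}
    if config.compute_coefficients:
        with _stage("interpret"):
            for code in codes:
                coefficient_tables[code] = word_coefficients(
                    models[code],
                    train_letters,
                    vocab,
                    method=config.interpret_method,
                    mode=mode,
                    use_covariates=config.use_covariates,
                    max_len=config.model.max_len,
                    seed=config.seed,
                )

    validation_metrics = None
    if validation is not None:
        with _stage("validate"):
            val_letters = list(validation)
            val_encoded = encode_letters(
                val_letters,
                vocab,
                mode=mode,
                use_covariates=config.use_covariates,
                max_len=config.model.max_len,
            )
            val_pred = predict_proba(
                models, val_encoded, [l.id for l in val_letters], vocab.fingerprint()
            )
            val_gold = _gold_matrix(val_letters, codes)
            if calibration is not None:
                val_binary = apply_threshold(val_pred, calibration)
            else:
                val_binary = (val_pred.probabilities > 0.5).astype(np.int64)
            validation_metrics = MetricsReport.from_matrices(val_gold, val_binary, codes)

    result = ExperimentResult(
        config=config,
        codes=codes,
        metrics=metrics,
        predictions=predictions,
        models=models,
        vocab=vocab,
        calibration=calibration,
        coefficient_tables=coefficient_tables,
        validation_metrics=validation_metrics,
        training_cardinality=training_cardinality,
        test_letter_ids=[l.id for l in test_letters],
    )
    if out:
        with _stage("write"):
            _write_artifacts(result, out, binary)
    return result


def _write_artifacts(result: ExperimentResult, out: Path, binary: np.ndarray) -> None:
    result.metrics.save(out / "metrics.csv", out / "metrics.json")
    if result.validation_metrics is not None:
        result.validation_metrics.save(
            out / "validation_metrics.csv", out / "validation_metrics.json"
        )
    with (out / "predictions.jsonl").open("w") as handle:
        for i, letter_id in enumerate(result.predictions.letter_ids):
            predicted = [
                result.codes[j] for j in range(len(result.codes)) if binary[i, j]
            ]
            record = {
                "letter_id": letter_id,
                "predicted_codes": predicted,
                "probabilities": {
                    c: round(float(p), 6)
                    for c, p in zip(result.codes, result.predictions.probabilities[i])
                },
            }
            handle.write(json.dumps(record) + "\n")
    if result.calibration is not None:
        (out / "calibration.json").write_text(json.dumps(asdict(result.calibration), indent=2))
    if result.coefficient_tables:
        coef_dir = out / "coefficients"
        coef_dir.mkdir(exist_ok=True)
        for code, table in result.coefficient_tables.items():
            table.save(coef_dir / f"{code}.csv")
    snapshot = {
        "experiment": result.config.experiment,
        "seed": result.config.seed,
        "codes": result.codes,
        "model": asdict(result.config.model),
        "split": asdict(result.config.split),
        "label_filter": asdict(result.config.label_filter),
        "vocab_size": result.vocab.size,
        "vocab_fingerprint": result.vocab.fingerprint(),
        "training_cardinality": result.training_cardinality,
    }
    (out / "config.json").write_text(json.dumps(snapshot, indent=2))


def make_report(output_dir: str | Path) -> str:
    """Render a run's artifacts as one markdown summary; idempotent."""
    out = Path(output_dir)
    required = ["metrics.csv", "config.json"]
    missing = [f for f in required if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing artifacts in {out}: {missing}")
    import pandas as pd

    config = json.loads((out / "config.json").read_text())
    metrics = pd.read_csv(out / "metrics.csv")
    lines = [
        f"# Experiment {config['experiment']}",
        "",
        f"- seed: {config['seed']}",
        f"- retained codes: {', '.join(config['codes'])}",
        f"- vocabulary size: {config['vocab_size']}",
        "",
        "## Per-code metrics",
        "",
    ]
    per_code = metrics[metrics["code"] != "__pooled__"]
    lines += ["```", per_code.to_string(index=False), "```"]
    pooled = metrics[metrics["code"] == "__pooled__"]
    if config["experiment"] == "IV_multilabel" and not pooled.empty:
        lines += [
            "",
            "## Multilabel (pooled, micro)",
            "",
            "```",
            pooled.to_string(index=False),
            "```",
        ]
        if (out / "calibration.json").exists():
            cal = json.loads((out / "calibration.json").read_text())
            lines += [
                "",
                f"Calibrated threshold: {cal['threshold']:.4f} "
                f"(training cardinality {cal['training_cardinality']:.3f}, "
                f"achieved {cal['achieved_cardinality']:.3f})",
            ]
    coef_dir = out / "coefficients"
    if coef_dir.exists():
        lines += ["", "## Top word coefficients", ""]
        for path in sorted(coef_dir.glob("*.csv")):
            table = pd.read_csv(path)
            top_pos = table.head(10)["token"].tolist()
            top_neg = table[table["coefficient"] < 0].tail(10)["token"].tolist()
            lines.append(f"- **{path.stem}** positive: {', '.join(top_pos)}")
            if top_neg:
                lines.append(f"  negative: {', '.join(top_neg)}")
    report = "\n".join(lines) + "\n"
    (out / "report.md").write_text(report)
    return report
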