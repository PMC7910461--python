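"""Cardinality-matched multilabel decision rule.

Per-code probabilities become a multilabel code-set prediction through a
single GLOBAL probability threshold, chosen so that the number of labels
assigned on the evaluation set matches the label cardinality observed in
the training set: with ``n`` letters and training cardinality ``c``, the
``k = round(c * n)`` most probable (letter, code) cells are predicted
positive.  Every cell strictly above the threshold counts as a positive.
When tied probabilities straddle the cut the closest achievable count
*below* the target is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PredictionMatrix

__all__ = ["ThresholdCalibration", "calibrate_threshold", "apply_threshold"]


@dataclass(frozen=True)
class ThresholdCalibration:
    threshold: float
    training_cardinality: float
    achieved_cardinality: float
    n_predicted: int


def calibrate_threshold(
    predictions: PredictionMatrix, training_cardinality: float
) -> ThresholdCalibration:
    """Choose the global threshold matching the training label cardinality.

    Sorts all probability cells and cuts at the k-th largest, with
    ``k = round(training_cardinality * n_letters)``.  Raises when the
    requested cardinality exceeds the number of available cells.
    """
    probs = predictions.probabilities
    if probs.size == 0:
        raise ValueError("cannot calibrate on an empty prediction matrix")
    if training_cardinality < 0:
        raise ValueError("training_cardinality must be >= 0")
    n_letters = probs.shape[0]
    k = int(round(training_cardinality * n_letters))
    if k > probs.size:
        raise ValueError(
            f"cardinality unachievable: need {k} positives but only {probs.size} cells"
        )
    flat = np.sort(probs.ravel())[::-1]
    if k == 0:
        threshold = 1.0
    elif k < probs.size:
        # the (k+1)-th largest value: everything strictly above it is the
        # top k, unless ties straddle the cut, in which case the count
        # strictly above drops to the closest achievable value below k
        threshold = float(flat[k])
    else:
        threshold = max(float(np.nextafter(flat[-1], -1.0)), 0.0)
    n_predicted = int((probs > threshold).sum())
    return ThresholdCalibration(
        threshold=threshold,
        training_cardinality=float(training_cardinality),
        achieved_cardinality=n_predicted / n_letters,
        n_predicted=n_predicted,
    )


def apply_threshold(
    predictions: PredictionMatrix, calibration: ThresholdCalibration
) -> np.ndarray:
    """Binary letters x codes matrix: 1 iff probability > threshold (strict)."""
    return (predictions.probabilities > calibration.threshold).astype(np.int64)
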