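"""Confusion accounting, classification metrics and coder agreement.

Per-code metrics treat each code's column of the letters x codes decision
matrices as an independent binary problem; the pooled ("multilabel")
variant counts over all (letter, code) cells (micro-averaging).  Metrics
with a zero denominator are reported as ``None`` and flagged, never
silently as 0, so averages run over defined codes only.

Coder agreement uses Cohen's kappa pooled over (letter, code) items —
each letter contributes one binary decision per retained code — with a
cluster bootstrap over letters for the 95% confidence interval.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "AgreementResult",
    "confusion",
    "metrics_from_confusion",
    "cohens_kappa",
    "bootstrap_kappa_ci",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _check_shapes(gold: np.ndarray, predicted: np.ndarray) -> None:
    gold = np.asarray(gold)
    predicted = np.asarray(predicted)
    if gold.shape != predicted.shape:
        raise ValueError(f"shape mismatch: gold {gold.shape} vs predicted {predicted.shape}")


def _count(gold: np.ndarray, predicted: np.ndarray) -> ConfusionCounts:
    gold = np.asarray(gold).astype(bool)
    predicted = np.asarray(predicted).astype(bool)
    return ConfusionCounts(
        tp=int((gold & predicted).sum()),
        fp=int((~gold & predicted).sum()),
        tn=int((~gold & ~predicted).sum()),
        fn=int((gold & ~predicted).sum()),
    )


def confusion(
    gold: np.ndarray, predicted: np.ndarray, scope: str = "pooled"
) -> ConfusionCounts | list[ConfusionCounts]:
    """Confusion counts per code column or pooled over all cells."""
    _check_shapes(gold, predicted)
    gold = np.atleast_2d(np.asarray(gold))
    predicted = np.atleast_2d(np.asarray(predicted))
    if scope == "pooled":
        return _count(gold, predicted)
    if scope == "per_code":
        return [_count(gold[:, j], predicted[:, j]) for j in range(gold.shape[1])]
    raise ValueError(f"unknown scope: {scope!r}")


def metrics_from_confusion(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity, PPV, NPV and F1 from one confusion table.

    F1 is computed as ``2tp / (2tp + fp + fn)``, algebraically the
    harmonic mean of PPV and sensitivity.  Undefined metrics (zero
    denominator) are ``None``, with their names listed under
    ``"undefined"``.
    """
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> Optional[float]:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    sens = ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = ratio(c.tn, c.tn + c.fp, "specificity")
    ppv = ratio(c.tp, c.tp + c.fp, "ppv")
    npv = ratio(c.tn, c.tn + c.fn, "npv")
    f1 = ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "f1": f1,
        "undefined": undefined,
    }


@dataclass
class MetricsReport:
    """Per-code and pooled (micro) decision metrics with their counts."""

    per_code: dict[str, dict] = field(default_factory=dict)
    per_code_counts: dict[str, ConfusionCounts] = field(default_factory=dict)
    pooled: Optional[dict] = None
    pooled_counts: Optional[ConfusionCounts] = None

    @classmethod
    def from_matrices(
        cls, gold: np.ndarray, predicted: np.ndarray, codes: Sequence[str]
    ) -> "MetricsReport":
        _check_shapes(gold, predicted)
        per_counts = confusion(gold, predicted, scope="per_code")
        report = cls()
        for code, counts in zip(codes, per_counts):
            report.per_code_counts[code] = counts
            report.per_code[code] = metrics_from_confusion(counts)
        report.pooled_counts = confusion(gold, predicted, scope="pooled")
        report.pooled = metrics_from_confusion(report.pooled_counts)
        return report

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for code, m in self.per_code.items():
            c = self.per_code_counts[code]
            rows.append(
                {
                    "code": code,
                    "tp": c.tp,
                    "fp": c.fp,
                    "tn": c.tn,
                    "fn": c.fn,
                    **{k: m[k] for k in ("sensitivity", "specificity", "ppv", "npv", "f1")},
                }
            )
        if self.pooled is not None:
            c = self.pooled_counts
            rows.append(
                {
                    "code": "__pooled__",
                    "tp": c.tp,
                    "fp": c.fp,
                    "tn": c.tn,
                    "fn": c.fn,
                    **{
                        k: self.pooled[k]
                        for k in ("sensitivity", "specificity", "ppv", "npv", "f1")
                    },
                }
            )
        return pd.DataFrame(rows)

    def save(self, csv_path: str | Path, json_path: Optional[str | Path] = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            payload = {
                "per_code": self.per_code,
                "pooled": self.pooled,
            }
            Path(json_path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# agreement


def cohens_kappa(coder_a: Sequence[int], coder_b: Sequence[int]) -> float:
    """Cohen's kappa for paired binary decisions.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with observed agreement ``p_o``
    and chance agreement ``p_e`` from the coders' marginals.  When
    ``p_e == 1`` (both coders constant): 1.0 if they agree perfectly,
    NaN otherwise.
    """
    a = np.asarray(coder_a)
    b = np.asarray(coder_b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    n = a.size
    if n == 0:
        raise ValueError("cannot compute kappa on empty sequences")
    p_o = float((a == b).mean())
    pa1, pb1 = float((a == 1).mean()), float((b == 1).mean())
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if math.isclose(p_e, 1.0):
        return 1.0 if math.isclose(p_o, 1.0) else float("nan")
    return (p_o - p_e) / (1 - p_e)


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    ci_low: float
    ci_high: float
    n_items: int


def bootstrap_kappa_ci(
    coder_a: Sequence[int],
    coder_b: Sequence[int],
    grouping: Sequence,
    n_boot: int = 1000,
    seed: int = 0,
) -> AgreementResult:
    """Percentile 95% CI for kappa via cluster bootstrap over letters.

    Items sharing a ``grouping`` value (letter id) are resampled together,
    respecting the dependence between the per-code decisions of one
    letter.  Deterministic given the seed.
    """
    import warnings

    a = np.asarray(coder_a)
    b = np.asarray(coder_b)
    groups = np.asarray(grouping)
    if not (a.shape == b.shape == groups.shape):
        raise ValueError("coder_a, coder_b and grouping must have equal length")
    unique = pd.unique(groups)
    if len(unique) < 2:
        raise ValueError("cluster bootstrap requires at least 2 letters")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; confidence interval will be noisy")
    index = {g: np.flatnonzero(groups == g) for g in unique}
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for i in range(n_boot):
        chosen = rng.choice(len(unique), size=len(unique), replace=True)
        sel = np.concatenate([index[unique[j]] for j in chosen])
        stats[i] = cohens_kappa(a[sel], b[sel])
    stats = stats[~np.isnan(stats)]
    low, high = np.percentile(stats, [2.5, 97.5]) if len(stats) else (np.nan, np.nan)
    return AgreementResult(
        kappa=cohens_kappa(a, b),
        ci_low=float(low),
        ci_high=float(high),
        n_items=int(a.size),
    )
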