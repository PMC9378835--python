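"""Triage evaluation: four-way confusion plus the shared-task style scores.

Seven indicators, following the conventions of the triage shared task the
four-label scheme comes from:

  * all_f1 / all_acc — unweighted macro-F1 over the four categories and
    plain four-way accuracy;
  * non_green_f1 — macro-F1 restricted to {amber, red, crisis};
  * flagged_f1 / flagged_acc — binary collapse with positive class
    {amber, red, crisis} vs green: positive-class F1 and binary accuracy;
  * urgent_f1 / urgent_acc — binary collapse with positive class
    {red, crisis} vs {green, amber}.

Precision or recall with a 0/0 numerator is scored 0 (never-predicted
convention), so a degenerate system that never outputs red/crisis gets
urgent_f1 = 0 rather than an error.  Whether the "accuracy" of a binary
collapse means binary accuracy or positive-class recall is genuinely open;
binary accuracy is used here and documented as an interpretation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from lexcnn.preprocess import CATEGORIES

LABEL_INDEX = {c: i for i, c in enumerate(CATEGORIES)}
FLAGGED = frozenset({"amber", "red", "crisis"})
URGENT = frozenset({"red", "crisis"})


class MetricsError(ValueError):
    pass


@dataclass
class EvalReport:
    non_green_f1: float
    flagged_f1: float
    flagged_acc: float
    urgent_f1: float
    urgent_acc: float
    all_f1: float
    all_acc: float
    confusion: np.ndarray  # 4x4 counts, rows gold, cols pred, CATEGORIES order

    def to_dict(self) -> dict:
        return {
            "non_green_f1": self.non_green_f1,
            "flagged_f1": self.flagged_f1,
            "flagged_acc": self.flagged_acc,
            "urgent_f1": self.urgent_f1,
            "urgent_acc": self.urgent_acc,
            "all_f1": self.all_f1,
            "all_acc": self.all_acc,
            "confusion": {
                g: {p: int(self.confusion[i, j])
                    for j, p in enumerate(CATEGORIES)}
                for i, g in enumerate(CATEGORIES)
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    def pretty(self) -> str:
        lines = ["%-14s %s" % ("", "  ".join("%7s" % c for c in CATEGORIES))]
        for i, g in enumerate(CATEGORIES):
            lines.append("%-14s %s" % (
                f"gold {g}", "  ".join("%7d" % v for v in self.confusion[i])))
        lines.append("")
        for name in ("non_green_f1", "flagged_f1", "flagged_acc", "urgent_f1",
                     "urgent_acc", "all_f1", "all_acc"):
            lines.append("%-14s %.4f" % (name, getattr(self, name)))
        return "\n".join(lines)


def _check(gold: Sequence[str], pred: Sequence[str]) -> None:
    if len(gold) != len(pred) or len(gold) == 0:
        raise MetricsError(
            f"gold and pred must have equal nonzero length "
            f"({len(gold)} vs {len(pred)})")
    for lab in list(gold) + list(pred):
        if lab not in LABEL_INDEX:
            raise MetricsError(f"unknown label {lab!r}")


def confusion(gold: Sequence[str], pred: Sequence[str]) -> np.ndarray:
    """4x4 count matrix; entry (g, p) counts gold-g posts predicted p."""
    _check(gold, pred)
    mat = np.zeros((4, 4), dtype=int)
    for g, p in zip(gold, pred):
        mat[LABEL_INDEX[g], LABEL_INDEX[p]] += 1
    return mat


def _f1(tp: int, fp: int, fn: int) -> float:
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    rec = tp / (tp + fn) if tp + fn > 0 else 0.0
    return 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0


def _binary_scores(gold, pred, positive: frozenset) -> tuple[float, float]:
    g = np.array([lab in positive for lab in gold])
    p = np.array([lab in positive for lab in pred])
    tp = int((g & p).sum())
    fp = int((~g & p).sum())
    fn = int((g & ~p).sum())
    return _f1(tp, fp, fn), float((g == p).mean())


def evaluate(gold: Sequence[str], pred: Sequence[str]) -> EvalReport:
    """Full triage score report for a labeled prediction set."""
    mat = confusion(gold, pred)
    per_class = {}
    for c, i in LABEL_INDEX.items():
        tp = int(mat[i, i])
        fp = int(mat[:, i].sum()) - tp
        fn = int(mat[i, :].sum()) - tp
        per_class[c] = _f1(tp, fp, fn)
    all_f1 = float(np.mean([per_class[c] for c in CATEGORIES]))
    non_green_f1 = float(np.mean([per_class[c] for c in ("amber", "red", "crisis")]))
    all_acc = float(np.trace(mat) / mat.sum())
    flagged_f1, flagged_acc = _binary_scores(gold, pred, FLAGGED)
    urgent_f1, urgent_acc = _binary_scores(gold, pred, URGENT)
    return EvalReport(non_green_f1, flagged_f1, flagged_acc,
                      urgent_f1, urgent_acc, all_f1, all_acc, mat)
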