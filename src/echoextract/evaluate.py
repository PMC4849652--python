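"""Scoring of extraction output against gold annotations.

Counts are kept at report x element granularity: a true negative is a cell
with neither an expected gold value nor an extracted value.  A predicted
value is a true positive iff the cell holds an expected gold value matching
within tolerance (absolute, after unit canonicalization, for numbers; exact
token for categories); unmatched predictions are false positives, unmatched
expected gold values false negatives.  Cells with several values use greedy
nearest-value multiset pairing.  The micro-average pools counts over
elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .simulate import GoldAnnotation
from .summarize import ElementSummary

DEFAULT_TOLERANCE = 1e-6


@dataclass
class Counts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "Counts") -> "Counts":
        return Counts(self.tp + other.tp, self.fp + other.fp,
                      self.fn + other.fn, self.tn + other.tn)

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    @property
    def precision(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def recall(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return f1_score(p, r)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision (positive predictive value) and recall
    (sensitivity)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class EvalResult:
    per_element: dict[str, Counts] = field(default_factory=dict)

    @property
    def overall(self) -> Counts:
        total = Counts()
        for c in self.per_element.values():
            total = total + c
        return total

    def frame(self) -> pd.DataFrame:
        rows = []
        for eid in sorted(self.per_element) + ["__overall__"]:
            c = self.overall if eid == "__overall__" else self.per_element[eid]
            rows.append({"element_id": "overall" if eid == "__overall__" else eid,
                         "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
                         "precision": c.precision, "recall": c.recall,
                         "f1": c.f1, "specificity": c.specificity,
                         "npv": c.npv})
        return pd.DataFrame(rows)


def _match_cell(preds: list, expected: list, tol: float) -> tuple[int, int, int]:
    """Greedy nearest-value multiset pairing inside one report x element cell."""
    remaining = list(preds)
    tp = 0
    for g in expected:
        best_i, best_d = -1, None
        for i, p in enumerate(remaining):
            if isinstance(g, (int, float)) and isinstance(p, (int, float)):
                d = abs(float(p) - float(g))
                if d <= tol and (best_d is None or d < best_d):
                    best_i, best_d = i, d
            elif isinstance(g, str) and isinstance(p, str) and p == g:
                best_i, best_d = i, 0.0
                break
        if best_i >= 0:
            remaining.pop(best_i)
            tp += 1
    fn = len(expected) - tp
    fp = len(remaining)
    return tp, fp, fn


def score(predicted: list[ElementSummary], gold: list[GoldAnnotation],
          tolerance: float = DEFAULT_TOLERANCE,
          *, against_all_planted: bool = False) -> EvalResult:
    """Score extraction summaries against gold annotations.

    ``against_all_planted`` widens the expectation set to every planted value
    regardless of corruption (the denominator for absolute recall under
    noise); by default only gold records the extraction contract says should
    survive (extractable and kept) are expected.

    Raises ValueError when the gold refers to report ids absent from the
    prediction table (orphans are listed).
    """
    pred_cells: dict[tuple[str, str], list] = {}
    report_ids: set[str] = set()
    elements: set[str] = set()
    for s in predicted:
        report_ids.add(s.report_id)
        elements.add(s.element_id)
        if s.n_values:
            pred_cells[(s.report_id, s.element_id)] = list(s.values)

    orphans = sorted({g.report_id for g in gold} - report_ids)
    if orphans:
        raise ValueError(
            f"gold refers to {len(orphans)} report ids absent from predictions: "
            + ", ".join(orphans[:10]))

    gold_cells: dict[tuple[str, str], list] = {}
    for g in gold:
        elements.add(g.element_id)
        if against_all_planted or (g.expected_extractable and g.expected_kept):
            gold_cells.setdefault((g.report_id, g.element_id), []).append(g.value)

    result = EvalResult()
    for eid in elements:
        result.per_element[eid] = Counts()
    for rid in report_ids:
        for eid in elements:
            cell = (rid, eid)
            preds = pred_cells.get(cell, [])
            expected = gold_cells.get(cell, [])
            c = result.per_element[eid]
            if not preds and not expected:
                c.tn += 1
                continue
            tp, fp, fn = _match_cell(preds, expected, tolerance)
            c.tp += tp
            c.fp += fp
            c.fn += fn
    return result
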