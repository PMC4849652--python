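"""Post-processing and structured output.

Ranges collapse to their mean ("25 to 30 mmHg" -> 27.5 mmHg); each
report x element cell yields one summary row carrying the source sentence
segments, the ordered list of surviving values, and the count/min/max/last
statistics.  "Last" is positional (document order by character offset of the
value's source span): because report section order changed over archive eras,
no single mention position is privileged — all of min/max/last/full-list are
emitted and the consumer chooses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .filters import CanonicalValue
from .registry import Registry

#: within-report spread beyond which a quantitative summary is marked as
#: clinically significantly variable (warn-only; nothing is removed)
VARIABILITY_WARN = 0.20

TABLE_COLUMNS = ("report_id", "element_id", "n_values", "values",
                 "value_min", "value_max", "value_last", "unit",
                 "sentence_segments", "high_variability")


def collapse_range(value: CanonicalValue) -> float:
    """Mean of a range value's canonical-unit bounds."""
    if value.kind != "range":
        raise ValueError("collapse_range expects a range-kind value")
    if value.value_low is None or value.value_low > value.value_high:
        raise ValueError(f"malformed range bounds on {value!r}")
    return (value.value_low + value.value_high) / 2.0


@dataclass(frozen=True)
class ElementSummary:
    report_id: str
    element_id: str
    sentence_segments: tuple[str, ...]
    values: tuple          # floats (canonical unit) or vocab tokens, doc order
    unit: str
    high_variability: bool = False

    @property
    def n_values(self) -> int:
        return len(self.values)

    @property
    def value_min(self):
        nums = [v for v in self.values if isinstance(v, float)]
        return min(nums) if nums else None

    @property
    def value_max(self):
        nums = [v for v in self.values if isinstance(v, float)]
        return max(nums) if nums else None

    @property
    def value_last(self):
        return self.values[-1] if self.values else None


def summarize(report_id: str, element_id: str,
              surviving: list[CanonicalValue]) -> ElementSummary:
    """Summary row for one report x element from its kept values.

    Values are ordered by the character offset of their source span (document
    order); ranges are collapsed to midpoints.  Zero surviving values yield an
    explicit empty summary.
    """
    ordered = sorted(surviving, key=lambda cv: (cv.span_start, cv.span_end))
    values: list = []
    segments: list[str] = []
    unit = ""
    for cv in ordered:
        if cv.kind == "range":
            values.append(collapse_range(cv))
        elif cv.kind == "number":
            values.append(float(cv.value))
        elif cv.kind == "category":
            values.append(str(cv.value))
        else:
            continue
        segments.append(cv.source_span)
        unit = unit or cv.unit
    nums = [v for v in values if isinstance(v, float)]
    high_var = False
    if len(nums) >= 2:
        mean = sum(nums) / len(nums)
        if mean != 0 and (max(nums) - min(nums)) / abs(mean) > VARIABILITY_WARN:
            high_var = True
    return ElementSummary(
        report_id=report_id, element_id=element_id,
        sentence_segments=tuple(segments), values=tuple(values),
        unit=unit, high_variability=high_var,
    )


def summaries_frame(summaries: list[ElementSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "report_id": s.report_id,
            "element_id": s.element_id,
            "n_values": s.n_values,
            "values": json.dumps(list(s.values)),
            "value_min": s.value_min,
            "value_max": s.value_max,
            "value_last": s.value_last if s.value_last is not None else None,
            "unit": s.unit,
            "sentence_segments": json.dumps(list(s.sentence_segments)),
            "high_variability": s.high_variability,
        })
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def write_table(summaries: list[ElementSummary], destination: str | Path) -> Path:
    """One TSV row per report x element; value lists are JSON-encoded so the
    table is delimiter-safe and round-trips losslessly."""
    destination = Path(destination)
    summaries_frame(summaries).to_csv(destination, sep="\t", index=False)
    return destination


def read_table(source: str | Path) -> pd.DataFrame:
    """Read back a summary TSV, decoding the JSON list columns."""
    df = pd.read_csv(source, sep="\t", dtype={"report_id": str, "element_id": str},
                     keep_default_na=False, na_values=[""])
    df["values"] = df["values"].map(json.loads)
    df["sentence_segments"] = df["sentence_segments"].map(json.loads)
    return df


def value_histogram(summaries: list[ElementSummary], element_id: str,
                    bin_edges) -> np.ndarray:
    """Per-bin counts of reports whose summarized value (the last surviving
    value) falls in each half-open bin [edge_i, edge_{i+1})."""
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be a strictly increasing 1-d sequence")
    vals = [s.value_last for s in summaries
            if s.element_id == element_id and isinstance(s.value_last, float)]
    counts = np.zeros(len(edges) - 1, dtype=int)
    for v in vals:
        idx = np.searchsorted(edges, v, side="right") - 1
        if 0 <= idx < len(counts) and v < edges[-1]:
            counts[idx] += 1
    return counts
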