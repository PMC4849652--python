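"""End-to-end orchestration: normalize -> segment -> extract -> co-reference
-> filter -> summarize.

Reports are processed one at a time (streaming); only the extracted value
table is held across the corpus for the corpus-global IQR outlier pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from . import extract as ex
from .filters import (CanonicalValue, MissingnessRow, canonicalize_unit,
                      check_physiologic, iqr_outlier_filter, missingness)
from .normalize import RawReport, normalize, segment_and_classify
from .registry import Registry
from .summarize import ElementSummary, summarize

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    window_before: int = ex.WINDOW_BEFORE
    window_after: int = ex.WINDOW_AFTER
    coref_enabled: bool = True
    physiologic_enabled: bool = True
    iqr_k: float | None = 1.5          # None disables the corpus IQR pass


@dataclass
class PipelineResult:
    summaries: list[ElementSummary]
    values: list[CanonicalValue]       # every extracted value, flagged or not
    missingness: list[MissingnessRow]
    report_ids: list[str]

    @property
    def flagged(self) -> list[CanonicalValue]:
        return [cv for cv in self.values if cv.flags]

    def kept_values(self) -> list[CanonicalValue]:
        return [cv for cv in self.values if cv.kept]

    def flags_frame(self) -> pd.DataFrame:
        rows = []
        for cv in self.flagged:
            for f in cv.flags:
                rows.append({
                    "report_id": cv.report_id, "element_id": cv.element_id,
                    "source_span": cv.source_span,
                    "unit_as_written": cv.unit_as_written,
                    "flag": f.code, "detail": f.detail,
                })
        return pd.DataFrame(rows, columns=["report_id", "element_id",
                                           "source_span", "unit_as_written",
                                           "flag", "detail"])

    def missingness_frame(self) -> pd.DataFrame:
        rows = [{
            "element_id": r.element_id,
            "n_reports_total": r.n_reports_total,
            "n_reports_without_mention": r.n_reports_without_mention,
            "fraction_missing": r.fraction_missing,
        } for r in self.missingness]
        return pd.DataFrame(rows, columns=["element_id", "n_reports_total",
                                           "n_reports_without_mention",
                                           "fraction_missing"])


def build_patterns(registry: Registry, config: RunConfig) -> dict[str, ex.PatternSpec]:
    return {e.element_id: ex.build_pattern(e, config.window_before,
                                           config.window_after)
            for e in registry}


def extract_report(report: RawReport, registry: Registry,
                   patterns: dict[str, ex.PatternSpec],
                   config: RunConfig) -> tuple[list[CanonicalValue], set[str]]:
    """Extract, co-reference and per-report filter one report.

    Returns the canonicalized values (flagged and unflagged) plus the set of
    element_ids mentioned anywhere in the report (the missingness signal).
    """
    text = normalize(report.text)
    sentences = segment_and_classify(text, report.report_id)

    mentions: list[ex.SpanMatch] = []
    for element_id, pattern in patterns.items():
        mentions.extend(ex.find_mentions(text, sentences, pattern,
                                         report.report_id))
    mentions = ex.prune_contained_mentions(mentions)
    mentioned_elements = {m.element_id for m in mentions}

    parsed: list[ex.ParsedValue] = []
    for m in mentions:
        parsed.extend(ex.parse_values(m, registry.get(m.element_id), text))

    if config.coref_enabled:
        claimed = [(m.mention_start, m.mention_end) for m in mentions]
        coref_values = ex.resolve_coreference(
            text, sentences, claimed, registry, report.report_id,
            config.window_before, config.window_after)
        parsed.extend(coref_values)
        mentioned_elements |= {pv.element_id for pv in coref_values}

    # a value claimed by both a direct synonym and a co-reference path (or by
    # two overlapping synonyms) counts once; the direct path wins
    parsed.sort(key=lambda pv: (pv.element_id, pv.span_start, pv.span_end,
                                pv.via_coreference))
    deduped: list[ex.ParsedValue] = []
    seen: set[tuple] = set()
    for pv in parsed:
        key = (pv.element_id, pv.kind, pv.span_start, pv.span_end)
        if key in seen:
            continue
        seen.add(key)
        deduped.append(pv)

    canon = [canonicalize_unit(pv, registry.get(pv.element_id))
             for pv in deduped]
    check_physiologic(canon, registry, enabled=config.physiologic_enabled)
    return canon, mentioned_elements


def run_pipeline(corpus: Iterable[RawReport] | Sequence[RawReport],
                 registry: Registry,
                 config: RunConfig | None = None) -> PipelineResult:
    """Run the full extraction pipeline over a corpus.

    Deterministic: identical corpus + config produce identical results.
    """
    config = config or RunConfig()
    patterns = build_patterns(registry, config)

    all_values: list[CanonicalValue] = []
    mentioned: dict[str, set[str]] = {}
    report_ids: list[str] = []
    for report in corpus:
        report_ids.append(report.report_id)
        values, elements = extract_report(report, registry, patterns, config)
        all_values.extend(values)
        for eid in elements:
            mentioned.setdefault(eid, set()).add(report.report_id)

    if config.iqr_k is not None:
        by_element: dict[str, list[CanonicalValue]] = {}
        for cv in all_values:
            by_element.setdefault(cv.element_id, []).append(cv)
        for values in by_element.values():
            iqr_outlier_filter(values, k=config.iqr_k)

    # duplicate-substitution annotation: a removed value whose element has a
    # surviving mention in the same report is represented by that survivor
    surviving_cells = {(cv.report_id, cv.element_id)
                       for cv in all_values if cv.kept}
    for cv in all_values:
        if cv.flags and (cv.report_id, cv.element_id) in surviving_cells:
            cv.flags[-1] = type(cv.flags[-1])(
                cv.flags[-1].code,
                (cv.flags[-1].detail + "; surviving duplicate retained").strip("; "))

    kept: dict[tuple[str, str], list[CanonicalValue]] = {}
    for cv in all_values:
        if cv.kept:
            kept.setdefault((cv.report_id, cv.element_id), []).append(cv)

    summaries = [summarize(rid, e.element_id, kept.get((rid, e.element_id), []))
                 for rid in report_ids for e in registry]

    missing = missingness(report_ids, registry, mentioned)
    return PipelineResult(summaries=summaries, values=all_values,
                          missingness=missing, report_ids=report_ids)
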