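"""Windowed rule-based extraction of element/value relationships.

Each element gets one pattern template: an alternation over its synonyms
(case-insensitive, flexible internal whitespace) with a 30-character window
before and a 100-character window after the mention — value candidates are
searched inside that window.  The same template serves every element; only
the synonym alternation differs.

Cross-sentence attribution ("A bioprosthetic valve is seen in the aortic
position. ... The mean gradient is 16 mmHg") goes through a deterministic
look-ahead co-reference heuristic: a sentence that establishes a valve entity
donates its identity to generic measurement phrases ("peak velocity",
"mean gradient") in the same or the next two sentences.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from . import units
from .normalize import Sentence
from .registry import ElementSpec, Registry

log = logging.getLogger(__name__)

WINDOW_BEFORE = 30
WINDOW_AFTER = 100

#: extra distance charged to a value candidate left of the mention;
#: label-then-value layouts dominate real reports
LEFT_PENALTY = 20

_NUM = r"\d+(?:\.\d+)?"
_UNIT = units.unit_pattern()

DEID_RE = re.compile(r"\[\*\*.*?\*\*\]")
MISSING_RE = re.compile(r"\?{2,}")
_RANGE_RE = re.compile(
    rf"(?<![\w.])({_NUM})\s*(?:–|—|-|to\s)\s*({_NUM})(?:\s*({_UNIT}))?(?![\w/])",
    re.IGNORECASE,
)
_NUM_RE = re.compile(rf"(?<![\w.])({_NUM})(?:\s*({_UNIT}))?(?![\w/])", re.IGNORECASE)
_ARROW = "-->"


@dataclass(frozen=True)
class PatternSpec:
    element_id: str
    synonym_re: re.Pattern
    window_before: int = WINDOW_BEFORE
    window_after: int = WINDOW_AFTER


@dataclass(frozen=True)
class SpanMatch:
    element_id: str
    report_id: str
    sentence_index: int
    window_text: str
    window_start: int
    window_end: int
    mention_start: int
    mention_end: int
    sent_start: int
    sent_end: int


@dataclass(frozen=True)
class ParsedValue:
    element_id: str
    report_id: str
    sentence_index: int
    kind: str                    # number | range | category | missing_marker
    number: float | None = None
    range_low: float | None = None
    range_high: float | None = None
    category: str | None = None
    unit_as_written: str = ""
    source_span: str = ""
    span_start: int = -1
    span_end: int = -1
    via_coreference: bool = False


def _synonym_alternation(synonyms: tuple[str, ...]) -> re.Pattern:
    alts = []
    for syn in sorted(synonyms, key=len, reverse=True):
        esc = re.escape(syn.strip()).replace(r"\ ", r"\s+")
        alts.append(esc)
    body = "|".join(alts)
    return re.compile(rf"(?<![a-z0-9])(?:{body})(?![a-z0-9])", re.IGNORECASE)


def build_pattern(element: ElementSpec,
                  window_before: int = WINDOW_BEFORE,
                  window_after: int = WINDOW_AFTER) -> PatternSpec:
    """Instantiate the shared window template for one element."""
    if not element.synonyms:
        raise ValueError(f"element {element.element_id!r} has no synonyms")
    return PatternSpec(
        element_id=element.element_id,
        synonym_re=_synonym_alternation(element.synonyms),
        window_before=window_before,
        window_after=window_after,
    )


def find_mentions(report_text: str, sentences: list[Sentence],
                  pattern: PatternSpec, report_id: str = "") -> list[SpanMatch]:
    """All synonym occurrences in a normalized report, windows clipped at the
    text boundaries.  Multiple mentions in different sections all count."""
    out: list[SpanMatch] = []
    for m in pattern.synonym_re.finditer(report_text):
        sent = _sentence_at(sentences, m.start())
        w0 = max(0, m.start() - pattern.window_before)
        w1 = min(len(report_text), m.end() + pattern.window_after)
        out.append(SpanMatch(
            element_id=pattern.element_id,
            report_id=report_id or (sent.report_id if sent else ""),
            sentence_index=sent.index if sent else -1,
            window_text=report_text[w0:w1],
            window_start=w0,
            window_end=w1,
            mention_start=m.start(),
            mention_end=m.end(),
            sent_start=sent.char_start if sent else 0,
            sent_end=sent.char_end if sent else len(report_text),
        ))
    return out


def _sentence_at(sentences: list[Sentence], pos: int) -> Sentence | None:
    for s in sentences:
        if s.char_start <= pos < s.char_end:
            return s
    return None


@dataclass
class _Candidate:
    kind: str
    start: int
    end: int
    number: float | None = None
    range_low: float | None = None
    range_high: float | None = None
    category: str | None = None
    unit: str = ""


def _mask(text: str, spans: list[tuple[int, int]]) -> str:
    chars = list(text)
    for a, b in spans:
        for i in range(a, b):
            chars[i] = "#"
    return "".join(chars)


def _arrow_adjacent(text: str, start: int, end: int) -> bool:
    before = text[max(0, start - 4):start]
    after = text[end:end + 4]
    return _ARROW in before or ">" in before.strip()[-1:] or _ARROW in after.strip()[:3]


_NEGATION_RE = re.compile(r"\bno\s+(?:significant\s+|evidence\s+of\s+)?$", re.IGNORECASE)


def _numeric_candidates(text: str, lo: int, hi: int) -> tuple[list[_Candidate], list[_Candidate]]:
    """Numeric/range candidates and missing-marker candidates in text[lo:hi].

    Numbers inside de-identification placeholders or abutting ``-->`` arrows
    are rejected (they are documented failure modes, not values).
    """
    region = text[lo:hi]
    markers: list[_Candidate] = []
    masked_spans: list[tuple[int, int]] = []
    for m in DEID_RE.finditer(region):
        markers.append(_Candidate("missing_marker", lo + m.start(), lo + m.end()))
        masked_spans.append((m.start(), m.end()))
    for m in MISSING_RE.finditer(region):
        markers.append(_Candidate("missing_marker", lo + m.start(), lo + m.end()))
    work = _mask(region, masked_spans)

    cands: list[_Candidate] = []
    range_spans: list[tuple[int, int]] = []
    for m in _RANGE_RE.finditer(work):
        low, high = float(m.group(1)), float(m.group(2))
        if low > high:
            continue  # "12-02" style artifacts are not ranges
        if _arrow_adjacent(work, m.start(), m.end()):
            continue
        range_spans.append((m.start(), m.end()))
        cands.append(_Candidate("range", lo + m.start(), lo + m.end(),
                                range_low=low, range_high=high,
                                unit=(m.group(3) or "")))
    work = _mask(work, range_spans)
    for m in _NUM_RE.finditer(work):
        if _arrow_adjacent(work, m.start(), m.end()):
            continue
        cands.append(_Candidate("number", lo + m.start(), lo + m.end(),
                                number=float(m.group(1)), unit=(m.group(2) or "")))
    return cands, markers


def _vocab_candidates(text: str, lo: int, hi: int, vocab: tuple[str, ...]) -> list[_Candidate]:
    region = text[lo:hi]
    alts = "|".join(re.escape(v) for v in sorted(vocab, key=len, reverse=True))
    tok_re = re.compile(rf"(?<![a-z0-9-])(?:{alts})(?![a-z0-9-])", re.IGNORECASE)
    out: list[_Candidate] = []
    for m in tok_re.finditer(region):
        if _NEGATION_RE.search(region[:m.start()]) and m.group(0).lower() != "no":
            continue  # negated finding; positive extraction suppressed
        out.append(_Candidate("category", lo + m.start(), lo + m.end(),
                              category=m.group(0).lower()))
    return out


_LABEL_TAIL = re.compile(r"\s{0,3}[^\s:=]{0,10}\s{0,3}[:=]")


def _pick(cands: list[_Candidate], match: SpanMatch, text: str) -> _Candidate | None:
    """Nearest candidate to the mention; rightward preferred.  A mention in
    label position (followed by ':'/'=') only accepts rightward values."""
    label_pos = bool(_LABEL_TAIL.match(text[match.mention_end:match.mention_end + 16]))
    best: tuple[float, int] | None = None
    chosen: _Candidate | None = None
    for c in cands:
        if c.end > match.mention_start and c.start < match.mention_end:
            continue  # overlaps the mention itself
        if c.start >= match.mention_end:
            key = (float(c.start - match.mention_end), 0)
        else:
            if label_pos:
                continue
            key = (float(match.mention_start - c.end + LEFT_PENALTY), 1)
        if best is None or key < best:
            best, chosen = key, c
    return chosen


def parse_values(match: SpanMatch, element: ElementSpec, report_text: str,
                 *, via_coreference: bool = False) -> list[ParsedValue]:
    """Parse the value (number, range, categorical token, or missing marker)
    nearest to a mention, inside its window.

    Candidates outside the mention's sentence are ignored — attribution
    across sentence boundaries is the job of co-reference resolution.
    Returns [] when the window holds neither a parsable value nor a missing
    marker (a non-extraction, not an error).
    """
    lo = max(match.window_start, match.sent_start)
    hi = min(match.window_end, match.sent_end)
    if lo >= hi:
        return []

    if element.value_kind == "qualitative":
        cands = _vocab_candidates(report_text, lo, hi, element.categorical_vocab)
        markers: list[_Candidate] = []
    else:
        cands, markers = _numeric_candidates(report_text, lo, hi)

    chosen = _pick(cands, match, report_text)
    if chosen is None:
        marker = _pick(markers, match, report_text)
        if marker is not None:
            return [ParsedValue(
                element_id=element.element_id, report_id=match.report_id,
                sentence_index=match.sentence_index, kind="missing_marker",
                source_span=report_text[marker.start:marker.end],
                span_start=marker.start, span_end=marker.end,
                via_coreference=via_coreference,
            )]
        return []

    common = dict(
        element_id=element.element_id, report_id=match.report_id,
        sentence_index=match.sentence_index,
        unit_as_written=chosen.unit,
        source_span=report_text[chosen.start:chosen.end],
        span_start=chosen.start, span_end=chosen.end,
        via_coreference=via_coreference,
    )
    if chosen.kind == "number":
        return [ParsedValue(kind="number", number=chosen.number, **common)]
    if chosen.kind == "range":
        return [ParsedValue(kind="range", range_low=chosen.range_low,
                            range_high=chosen.range_high, **common)]
    return [ParsedValue(kind="category", category=chosen.category, **common)]


# --------------------------------------------------------------------------
# co-reference resolution

#: generic measurement phrases that need an antecedent valve entity
GENERIC_RE = re.compile(r"(?<![a-z])(peak|mean)\s+(velocity|gradient)(?![a-z])",
                        re.IGNORECASE)

_VALVE_PREFIX = {"aortic": "av", "mitral": "mv", "tricuspid": "tv",
                 "pulmonic": "pv", "pulmonary": "pv"}

ENTITY_RE = re.compile(
    r"\b(?:valve|prosthesis|bioprosthesis)\b[^.\n]{0,60}?"
    r"\bin\s+the\s+(aortic|mitral|tricuspid|pulmonic|pulmonary)\s+position"
    r"|\b(aortic|mitral|tricuspid|pulmonic|pulmonary)"
    r"\s+(?:bioprosthetic\s+valve|bioprosthesis|prosthesis|valve)",
    re.IGNORECASE,
)

#: how many sentences an established entity reaches forward
COREF_HORIZON = 2


@dataclass(frozen=True)
class _Entity:
    sentence_index: int
    position: int
    prefix: str


def find_entities(report_text: str, sentences: list[Sentence]) -> list[_Entity]:
    """Valve/chamber entities established per sentence, in document order."""
    out: list[_Entity] = []
    for s in sentences:
        for m in ENTITY_RE.finditer(report_text[s.char_start:s.char_end]):
            word = (m.group(1) or m.group(2)).lower()
            out.append(_Entity(s.index, s.char_start + m.start(), _VALVE_PREFIX[word]))
    return out


def resolve_coreference(report_text: str, sentences: list[Sentence],
                        claimed_spans: list[tuple[int, int]],
                        registry: Registry, report_id: str = "",
                        window_before: int = WINDOW_BEFORE,
                        window_after: int = WINDOW_AFTER) -> list[ParsedValue]:
    """Attribute generic measurement phrases to the nearest preceding valve
    entity within the look-ahead horizon (the entity's own sentence plus the
    next two).  Generic phrases already covered by a specific synonym match
    are skipped; generic phrases with no antecedent are dropped and logged.
    """
    entities = find_entities(report_text, sentences)
    values: list[ParsedValue] = []
    for s in sentences:
        for m in GENERIC_RE.finditer(report_text[s.char_start:s.char_end]):
            g0, g1 = s.char_start + m.start(), s.char_start + m.end()
            if any(a <= g0 and g1 <= b for a, b in claimed_spans):
                continue
            antecedent = None
            for e in entities:
                if e.sentence_index > s.index or s.index - e.sentence_index > COREF_HORIZON:
                    continue
                if e.sentence_index == s.index and e.position >= g0:
                    continue
                if (antecedent is None
                        or (e.sentence_index, e.position)
                        > (antecedent.sentence_index, antecedent.position)):
                    antecedent = e
            if antecedent is None:
                log.debug("generic %r at %d has no antecedent entity; dropped",
                          m.group(0), g0)
                continue
            suffix = f"{m.group(1).lower()}_{m.group(2).lower()}"
            element_id = f"{antecedent.prefix}_{suffix}"
            if element_id not in registry:
                continue
            element = registry.get(element_id)
            pseudo = SpanMatch(
                element_id=element_id, report_id=report_id or s.report_id,
                sentence_index=s.index,
                window_text=report_text[max(0, g0 - window_before):g1 + window_after],
                window_start=max(0, g0 - window_before),
                window_end=min(len(report_text), g1 + window_after),
                mention_start=g0, mention_end=g1,
                sent_start=s.char_start, sent_end=s.char_end,
            )
            values.extend(parse_values(pseudo, element, report_text,
                                       via_coreference=True))
    return values


def prune_contained_mentions(mentions: list[SpanMatch]) -> list[SpanMatch]:
    """Drop a mention whose span is strictly contained in another mention's
    span ("la volume" inside "la volume index"): the longer, more specific
    synonym wins."""
    kept: list[SpanMatch] = []
    for m in mentions:
        contained = any(
            (o is not m)
            and o.mention_start <= m.mention_start
            and m.mention_end <= o.mention_end
            and (o.mention_end - o.mention_start) > (m.mention_end - m.mention_start)
            for o in mentions
        )
        if not contained:
            kept.append(m)
    return kept
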