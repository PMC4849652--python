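"""Report pre-processing: whitespace/ellipsis cleanup, sentence
segmentation and structure-style classification.

EHR exports of echocardiography reports are littered with spurious runs of
``.`` characters that split tokens mid-sentence ("Peak.. velocity across the
aortic valve = 5.0 m/s").  The normalizer deletes those runs when they sit in
non-terminal context and converts them to a real sentence boundary when they
are followed by whitespace plus a capital letter, so that both noisy
structured measurement lines and multi-sentence prose segment correctly.

Offsets are 0-based half-open against the normalized text.  Newlines are
preserved (collapsed to one) because line breaks separate report sections and
structured measurement lines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from . import units

STRUCTURE_CLASSES = ("structured", "semi_structured", "unstructured")

#: section headers seen at line starts; recorded per sentence, never used for
#: positional priority (section order changed over time in real archives)
SECTION_HEADERS = ("report text", "procedure components",
                   "measurement and calculations", "conclusion", "summary")


@dataclass(frozen=True)
class RawReport:
    report_id: str
    text: str
    patient_id: str = ""
    report_type: str = "unknown"   # transthoracic|transesophageal|stress|doppler|unknown


@dataclass(frozen=True)
class Sentence:
    report_id: str
    index: int
    text: str
    char_start: int
    char_end: int
    structure_class: str = ""
    section: str = ""


_DOT_RUN = re.compile(r"(?:\.{2,}|…+\.*)")


def normalize(text: str) -> str:
    """Collapse whitespace runs and strip ellipsis noise.

    A run of >=2 dots (or a unicode ellipsis) followed by whitespace and a
    capital letter terminates a sentence and becomes ``. ``; any other run is
    export noise and is deleted (replaced by a single space so the flanking
    tokens rejoin).  Single periods — decimal points, sentence-terminal
    periods, unit abbreviations — are untouched.  Idempotent.
    """
    if not text:
        return ""

    def _dots(m: re.Match) -> str:
        tail = text[m.end():]
        nxt = re.match(r"\s+([A-Za-z/%]+)", tail)
        if nxt and re.match(r"\s+[A-Z]", tail):
            # "28 mm.. Hg": a dot-run splitting a two-token unit is noise,
            # not a sentence boundary
            prev = re.search(r"([A-Za-z/%]+)$", text[:m.start()])
            if prev and units.lookup(f"{prev.group(1)} {nxt.group(1)}"):
                return " "
            return ". "
        return " "

    out = _DOT_RUN.sub(_dots, text)
    out = re.sub(r"[ \t]*\n[ \t\n]*", "\n", out)   # newline = section/line break
    out = re.sub(r"[ \t]+", " ", out)
    # a space left where a dot-run preceded a single period ("x .. ." etc.)
    out = re.sub(r" +\.", " .", out)
    return out.strip()


_BOUNDARY = re.compile(r"(?<=[.?!])\s+(?=[A-Z])")


def segment(text: str, report_id: str = "") -> list[Sentence]:
    """Split normalized text into ordered, non-overlapping sentences.

    Boundaries are newlines (section / measurement-line breaks) and a
    ``.``/``?``/``!`` followed by whitespace and a capital letter.  Decimal
    points and mid-line unit abbreviations never trigger a split, so a
    colon-delimited measurement line stays one sentence.
    """
    sentences: list[Sentence] = []
    section = ""
    pos = 0
    for line in text.split("\n"):
        line_start = pos
        pos += len(line) + 1
        stripped = line.strip()
        if not stripped:
            continue
        head = stripped.rstrip(":").lower()
        if head in SECTION_HEADERS:
            section = head
            continue
        cursor = 0
        for part in _BOUNDARY.split(line):
            start = line.find(part, cursor)
            cursor = start + len(part)
            core = part.strip()
            if not core:
                continue
            s0 = line_start + start + (len(part) - len(part.lstrip()))
            sentences.append(Sentence(
                report_id=report_id,
                index=len(sentences),
                text=core,
                char_start=s0,
                char_end=s0 + len(core),
                section=section,
            ))
    return sentences


_LABEL_VALUE = re.compile(r"[:=]\s*\d")


def classify_structure(sentence: Sentence | str) -> str:
    """Assign exactly one structure class to a sentence.

    * ``structured`` — two or more ``LABEL: value`` groups on one line;
    * ``semi_structured`` — a single ``phrase = value`` / ``phrase: value``
      assignment;
    * ``unstructured`` — prose.
    """
    text = sentence.text if isinstance(sentence, Sentence) else sentence
    n_groups = len(_LABEL_VALUE.findall(text))
    if n_groups >= 2:
        return "structured"
    if n_groups == 1:
        return "semi_structured"
    return "unstructured"


def segment_and_classify(text: str, report_id: str = "") -> list[Sentence]:
    """Segment normalized text and attach a structure class per sentence."""
    return [replace(s, structure_class=classify_structure(s))
            for s in segment(text, report_id)]


def select_reports(corpus, element, registry) -> set[str]:
    """Report ids whose normalized text mentions any synonym of ``element``.

    A report is selected at most once per element regardless of how many
    times (or in how many sections) the element is mentioned.
    """
    from .extract import build_pattern  # local import to avoid a cycle

    pattern = build_pattern(element)
    selected: set[str] = set()
    for report in corpus:
        if pattern.synonym_re.search(normalize(report.text)):
            selected.add(report.report_id)
    return selected
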