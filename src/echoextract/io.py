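"""Corpus input: a directory of plain-text reports (filename stem is the
report id) or a single delimited file with report_id / patient_id /
report_type / text columns."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .normalize import RawReport

REPORT_TYPES = ("transthoracic", "transesophageal", "stress", "doppler", "unknown")


def read_corpus(source: str | Path) -> list[RawReport]:
    """Load reports from a directory of ``.txt`` files or a TSV/CSV corpus
    file (columns: report_id, text; optional patient_id, report_type)."""
    source = Path(source)
    if source.is_dir():
        reports = []
        for path in sorted(source.glob("*.txt")):
            reports.append(RawReport(report_id=path.stem,
                                     text=path.read_text()))
        return reports
    sep = "\t" if source.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    if "report_id" not in df.columns or "text" not in df.columns:
        raise ValueError(f"corpus file {source} needs report_id and text columns")
    reports = []
    for row in df.itertuples(index=False):
        rtype = getattr(row, "report_type", "unknown") or "unknown"
        reports.append(RawReport(
            report_id=str(row.report_id),
            text=str(row.text),
            patient_id=str(getattr(row, "patient_id", "") or ""),
            report_type=rtype if rtype in REPORT_TYPES else "unknown",
        ))
    return reports


def write_corpus(reports: list[RawReport], directory: str | Path) -> Path:
    """Write one ``<report_id>.txt`` per report."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for r in reports:
        (directory / f"{r.report_id}.txt").write_text(r.text)
    return directory
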