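"""Range collapsing, per-cell summaries, table round-trip, histogram."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echoextract import (RawReport, RunConfig, collapse_range, load_registry,
                         read_table, run_pipeline, summarize, value_histogram,
                         write_table)
from echoextract.filters import CanonicalValue
from echoextract.summarize import ElementSummary


def _num(element_id, value, start, report_id="r"):
    return CanonicalValue(element_id=element_id, report_id=report_id,
                          sentence_index=0, kind="number", value=float(value),
                          unit="mmHg", source_span=str(value),
                          span_start=start, span_end=start + 4)


def _range(low, high):
    return CanonicalValue(element_id="av_mean_gradient", report_id="r",
                          sentence_index=0, kind="range",
                          value=(low + high) / 2, value_low=float(low),
                          value_high=float(high), unit="mmHg",
                          source_span=f"{low}-{high}", span_start=0, span_end=5)


@pytest.mark.parametrize("low, high, expected", [
    (25.0, 30.0, 27.5),
    (5.0, 5.0, 5.0),
    (1.0, 1.4, 1.2),
])
def test_collapse_range(low, high, expected):
    assert collapse_range(_range(low, high)) == pytest.approx(expected)


def test_collapse_range_rejects_non_range():
    with pytest.raises(ValueError):
        collapse_range(_num("x", 1.0, 0))


@given(st.floats(min_value=0.1, max_value=500), st.floats(min_value=0, max_value=50))
@settings(max_examples=200, deadline=None)
def test_collapse_range_midpoint_bounds(low, width):
    mid = collapse_range(_range(low, low + width))
    assert low <= mid <= low + width


def test_summarize_statistics_and_document_order():
    s = summarize("r", "av_mean_gradient",
                  [_num("av_mean_gradient", 2.0, 10),
                   _num("av_mean_gradient", 1.6, 50)])
    assert s.n_values == 2
    assert s.values == (2.0, 1.6)
    assert (s.value_min, s.value_max, s.value_last) == (1.6, 2.0, 1.6)
    assert s.high_variability  # (2.0-1.6)/1.8 > 20%


def test_summarize_single_and_empty():
    one = summarize("r", "av_peak_velocity", [_num("av_peak_velocity", 1.9, 0)])
    assert (one.n_values, one.value_min, one.value_max, one.value_last) == \
        (1, 1.9, 1.9, 1.9)
    empty = summarize("r", "av_peak_velocity", [])
    assert empty.n_values == 0
    assert empty.value_min is None and empty.value_last is None


def test_write_table_row_count_and_roundtrip(tmp_path, registry):
    corpus = [RawReport("r1", "The aortic valve area is 1.1 cm2.\n"
                              "There is moderate aortic regurgitation.")]
    result = run_pipeline(corpus, registry, RunConfig(iqr_k=None))
    assert len(result.summaries) == 80  # 1 report x 80 elements

    path = write_table(result.summaries, tmp_path / "summary.tsv")
    df = read_table(path)
    assert len(df) == 80
    by_id = {row.element_id: row for row in df.itertuples(index=False)}
    assert by_id["aortic_valve_area"].values == [1.1]
    assert by_id["aortic_regurgitation"].values == ["moderate"]
    # every summary field survives the round trip
    for s in result.summaries:
        row = df[(df.report_id == s.report_id) &
                 (df.element_id == s.element_id)].iloc[0]
        assert tuple(row["values"]) == s.values
        assert row["n_values"] == s.n_values


def test_write_table_is_deterministic(tmp_path, registry):
    corpus = [RawReport("r1", "LVEF: 55 %\nTAPSE: 2.0 cm")]
    p1 = write_table(run_pipeline(corpus, registry).summaries, tmp_path / "a.tsv")
    p2 = write_table(run_pipeline(corpus, registry).summaries, tmp_path / "b.tsv")
    assert p1.read_bytes() == p2.read_bytes()


def test_empty_corpus_header_only(tmp_path, registry):
    result = run_pipeline([], registry)
    path = write_table(result.summaries, tmp_path / "empty.tsv")
    lines = path.read_text().splitlines()
    assert len(lines) == 1 and lines[0].startswith("report_id\t")


def test_value_histogram():
    summaries = [ElementSummary("r%d" % i, "av_mean_gradient", (), (float(v),),
                                "mmHg") for i, v in enumerate([1, 2, 3])]
    counts = value_histogram(summaries, "av_mean_gradient", [0, 2, 4])
    assert counts.tolist() == [1, 2]
    assert value_histogram([], "av_mean_gradient", [0, 2, 4]).tolist() == [0, 0]
    with pytest.raises(ValueError):
        value_histogram(summaries, "av_mean_gradient", [4, 2, 0])


def test_provenance_spans_in_segments(registry):
    corpus = [RawReport("r1", "The aortic valve area is 1.1 cm2.")]
    result = run_pipeline(corpus, registry)
    s = [x for x in result.summaries if x.element_id == "aortic_valve_area"][0]
    assert len(s.sentence_segments) == s.n_values
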