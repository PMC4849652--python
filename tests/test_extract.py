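"""Pattern building, mention finding, value parsing, co-reference."""

import pytest

from echoextract import (RawReport, build_pattern, find_mentions, load_registry,
                         normalize, parse_values, resolve_coreference,
                         segment_and_classify)
from echoextract.extract import prune_contained_mentions
from echoextract.pipeline import RunConfig, build_patterns, extract_report

from conftest import COREF_PASSAGE, UNSTRUCTURED_LINE


def _mentions(registry, element_id, text):
    norm = normalize(text)
    sentences = segment_and_classify(norm, "r")
    pattern = build_pattern(registry.get(element_id))
    return norm, sentences, find_mentions(norm, sentences, pattern, "r")


def test_build_pattern_window_defaults(registry):
    p = build_pattern(registry.get("aortic_valve_area"))
    assert (p.window_before, p.window_after) == (30, 100)
    assert p.synonym_re.search(" AVA ")
    assert p.synonym_re.search("aortic  valve   area")
    assert not p.synonym_re.search("lava flow")  # word-bounded


def test_build_pattern_rejects_empty_synonyms(registry):
    from dataclasses import replace
    bare = replace(registry.get("aortic_valve_area"), synonyms=())
    with pytest.raises(ValueError):
        build_pattern(bare)


def test_find_mentions_counts_each_occurrence(registry):
    text = ("Measurement and calculations\nAVA: 0.9 cm2\n"
            "Conclusion\nThe aortic valve area is 0.9 cm2.")
    _, _, mentions = _mentions(registry, "aortic_valve_area", text)
    assert len(mentions) == 2
    assert all(m.window_text for m in mentions)


def test_find_mentions_none(registry):
    _, _, mentions = _mentions(registry, "aortic_valve_area",
                               "The mitral valve is unremarkable.")
    assert mentions == []


@pytest.mark.parametrize("text, element_id, expected", [
    # range with unit
    ("the mean gradient across the aortic valve is 25–30 mmhg.",
     "av_mean_gradient", ("range", 25.0, 30.0, "mmhg")),
    # plain number with unit
    ("AO V2 MAX: 335 cm/sec", "av_peak_velocity", ("number", 335.0, None, "cm/sec")),
    # number without unit
    ("AV peak velocity ..2.54", "av_peak_velocity", ("number", 2.54, None, "")),
    # written range with 'to'
    ("mv mean gradient of 4 to 6 mmhg", "mv_mean_gradient",
     ("range", 4.0, 6.0, "mmhg")),
])
def test_parse_numeric_values(registry, text, element_id, expected):
    norm, sentences, mentions = _mentions(registry, element_id, text)
    values = parse_values(mentions[0], registry.get(element_id), norm)
    assert len(values) == 1
    v = values[0]
    kind, a, b, unit = expected
    assert v.kind == kind
    if kind == "number":
        assert v.number == a
    else:
        assert (v.range_low, v.range_high) == (a, b)
    assert v.unit_as_written.lower() == unit
    assert v.source_span in norm  # provenance always recoverable


def test_parse_categorical_value(registry):
    text = "…moderate-severe aortic regurgitation is present."
    norm, sentences, mentions = _mentions(registry, "aortic_regurgitation", text)
    values = parse_values(mentions[0], registry.get("aortic_regurgitation"), norm)
    assert [v.category for v in values] == ["moderate-severe"]
    assert values[0].category in registry.get("aortic_regurgitation").categorical_vocab


def test_negated_categorical_suppressed(registry):
    text = "There is no severe aortic regurgitation."
    norm, _, mentions = _mentions(registry, "aortic_regurgitation", text)
    assert parse_values(mentions[0], registry.get("aortic_regurgitation"), norm) == []


def test_missing_marker(registry):
    text = "Pressure half time…??"
    norm, _, mentions = _mentions(registry, "mv_pressure_half_time", text)
    values = parse_values(mentions[0], registry.get("mv_pressure_half_time"), norm)
    assert [v.kind for v in values] == ["missing_marker"]


def test_arrow_adjacent_numbers_rejected(registry):
    text = "AV peak velocity increased from 1.6 m/s--> 2.0 m/s"
    norm, _, mentions = _mentions(registry, "av_peak_velocity", text)
    assert parse_values(mentions[0], registry.get("av_peak_velocity"), norm) == []


def test_label_position_ignores_left_value(registry):
    # 0.57 belongs to the E/A label, not to the MVA label two chars right of it
    text = "MV E/A: 0.57 MVA(P1/2T): 1.4 cm"
    norm, _, mentions = _mentions(registry, "mitral_valve_area", text)
    values = parse_values(mentions[0], registry.get("mitral_valve_area"), norm)
    assert values[0].number == 1.4


def test_window_does_not_cross_sentences(registry):
    # value in the following sentence is not claimed by the direct pattern
    text = "The av peak velocity is normal. The gradient is 40 mmHg."
    norm, _, mentions = _mentions(registry, "av_peak_velocity", text)
    assert parse_values(mentions[0], registry.get("av_peak_velocity"), norm) == []


def test_coreference_passage(registry):
    norm = normalize(COREF_PASSAGE)
    sentences = segment_and_classify(norm, "r")
    values = resolve_coreference(norm, sentences, [], registry, "r")
    got = {(v.element_id, v.number) for v in values}
    assert ("av_peak_velocity", 1.9) in got
    assert ("av_mean_gradient", 16.0) in got
    assert ("av_peak_gradient", 27.0) in got
    assert all(v.via_coreference for v in values)


def test_coreference_requires_antecedent(registry):
    norm = normalize("The mean gradient is 10 mmHg.")
    sentences = segment_and_classify(norm, "r")
    assert resolve_coreference(norm, sentences, [], registry, "r") == []


def test_coreference_horizon_is_two_sentences(registry):
    text = ("A bioprosthetic valve is seen in the mitral position. "
            "It is well seated. The leaflets move well. "
            "The mean gradient is 5 mmHg.")
    norm = normalize(text)
    sentences = segment_and_classify(norm, "r")
    assert resolve_coreference(norm, sentences, [], registry, "r") == []


def test_coreference_nearest_entity_wins(registry):
    text = ("A bioprosthetic valve is seen in the mitral position. "
            "A second prosthesis is seen in the aortic position. "
            "The mean gradient is 9 mmHg.")
    norm = normalize(text)
    sentences = segment_and_classify(norm, "r")
    values = resolve_coreference(norm, sentences, [], registry, "r")
    assert [(v.element_id, v.number) for v in values] == [("av_mean_gradient", 9.0)]


def test_coreference_never_crosses_reports(registry):
    entity_report = RawReport("r1", "A bioprosthetic valve is seen in the "
                                    "aortic position.")
    orphan_report = RawReport("r2", "The mean gradient is 12 mmHg.")
    config = RunConfig()
    patterns = build_patterns(registry, config)
    _, _ = extract_report(entity_report, registry, patterns, config)
    values, _ = extract_report(orphan_report, registry, patterns, config)
    assert [cv for cv in values if cv.element_id == "av_mean_gradient"] == []


def test_prune_contained_mentions(registry):
    text = "The la volume index is 34 ml/m2."
    norm = normalize(text)
    sentences = segment_and_classify(norm, "r")
    mentions = []
    for eid in ("la_volume", "la_volume_index"):
        mentions.extend(find_mentions(norm, sentences,
                                      build_pattern(registry.get(eid)), "r"))
    kept = prune_contained_mentions(mentions)
    assert [m.element_id for m in kept] == ["la_volume_index"]


def test_unstructured_example_yields_both_elements(pipeline_one):
    result = pipeline_one(UNSTRUCTURED_LINE)
    got = {(s.element_id, s.values) for s in result.summaries if s.n_values}
    assert ("av_peak_velocity", (3.4,)) in got
    assert ("av_mean_gradient", (28.0,)) in got
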