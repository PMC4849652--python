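"""Unit canonicalization, physiologic constraints, IQR fences, missingness."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echoextract import (RawReport, RunConfig, canonicalize_unit,
                         check_physiologic, iqr_outlier_filter, load_registry,
                         missingness, run_pipeline)
from echoextract.extract import ParsedValue
from echoextract.filters import CanonicalValue, FilterFlag, tukey_quartiles


def _pv(element_id, number=None, unit="", kind="number", **kw):
    return ParsedValue(element_id=element_id, report_id="r", sentence_index=0,
                       kind=kind, number=number, unit_as_written=unit,
                       source_span=f"{number} {unit}".strip(), **kw)


@pytest.mark.parametrize("element_id, number, unit, expected_value, expected_flags", [
    ("av_peak_velocity", 335.0, "cm/sec", 3.35, []),           # forced conversion
    ("av_peak_velocity", 2.54, "", 2.54, ["no_unit"]),         # typing error: no unit
    ("mv_mean_gradient", 21.54, "cm/s", None, ["wrong_unit"]), # incompatible unit
    ("septal_thickness", 1.2, "m", 120.0, ["out_of_plausible_range"]),
    ("av_mean_gradient", 16.0, "mm Hg", 16.0, []),             # spelling variant
    ("mv_pressure_half_time", 90.0, "msec", 90.0, []),
    ("aortic_valve_area", 0.53, "am2", None, ["wrong_unit"]),  # unknown unit, no crash
    ("dimensionless_index", 0.19, "", 0.19, []),               # dimensionless
    ("dimensionless_index", 0.19, "mmhg", None, ["wrong_unit"]),
])
def test_canonicalize_unit(registry, element_id, number, unit,
                           expected_value, expected_flags):
    cv = canonicalize_unit(_pv(element_id, number, unit),
                           registry.get(element_id))
    assert [f.code for f in cv.flags] == expected_flags
    if expected_value is not None:
        assert cv.magnitude == pytest.approx(expected_value)
    assert cv.kept == (not expected_flags)


def test_canonicalize_range(registry):
    pv = ParsedValue(element_id="av_mean_gradient", report_id="r",
                     sentence_index=0, kind="range", range_low=25.0,
                     range_high=30.0, unit_as_written="mmhg",
                     source_span="25-30 mmhg")
    cv = canonicalize_unit(pv, registry.get("av_mean_gradient"))
    assert (cv.value_low, cv.value_high) == (25.0, 30.0)
    assert cv.magnitude == 27.5


def test_unknown_flag_code_rejected():
    with pytest.raises(ValueError):
        FilterFlag("made_up_code")


def _canon(registry, element_id, value):
    return canonicalize_unit(
        _pv(element_id, value, registry.get(element_id).canonical_unit),
        registry.get(element_id))


def test_physiologic_violation_flags_both_members(registry):
    values = [_canon(registry, "lveds", 6.0), _canon(registry, "lvedd", 4.5)]
    check_physiologic(values, registry)
    assert all(any(f.code == "physiologic_inconsistent" for f in cv.flags)
               for cv in values)
    assert not any(cv.kept for cv in values)


def test_physiologic_consistent_pair_unflagged(registry):
    values = [_canon(registry, "av_mean_gradient", 16.0),
              _canon(registry, "av_peak_gradient", 27.0)]
    check_physiologic(values, registry)
    assert all(cv.kept for cv in values)


def test_physiologic_single_member_vacuous(registry):
    values = [_canon(registry, "lveds", 6.0)]
    check_physiologic(values, registry)
    assert values[0].kept


def test_physiologic_velocity_gradient_uses_m_per_s(registry):
    # LVOT velocity is canonically cm/s; 100 cm/s = 1 m/s < 4 mmHg holds
    values = [_canon(registry, "lvot_peak_velocity", 100.0),
              _canon(registry, "lvot_peak_gradient", 4.0)]
    check_physiologic(values, registry)
    assert all(cv.kept for cv in values)


def test_physiologic_switch_off(registry):
    values = [_canon(registry, "lveds", 6.0), _canon(registry, "lvedd", 4.5)]
    check_physiologic(values, registry, enabled=False)
    assert all(cv.kept for cv in values)


def test_iqr_flags_misentered_meter_value(registry):
    vals = [_canon(registry, "septal_thickness", v)
            for v in (0.9, 1.0, 1.1, 1.2, 1.0, 0.95, 120.0)]
    iqr_outlier_filter(vals)
    flagged = [cv for cv in vals
               if any(f.code == "iqr_outlier" for f in cv.flags)]
    assert [cv.magnitude for cv in flagged] == [120.0]


def test_iqr_identical_values_unflagged(registry):
    vals = [_canon(registry, "septal_thickness", 1.0) for _ in range(10)]
    iqr_outlier_filter(vals)
    assert all(cv.kept for cv in vals)


def test_iqr_small_sample_noop(registry):
    vals = [_canon(registry, "septal_thickness", v) for v in (0.5, 3.0, 0.6)]
    iqr_outlier_filter(vals)
    assert all(cv.kept for cv in vals)


def test_iqr_planted_sigma_outlier(registry):
    import numpy as np
    rng = np.random.default_rng(7)
    sample = list(1.0 + 0.05 * rng.standard_normal(200))
    sample.append(1.0 + 10 * 0.05 * 10)  # ~100 sigma away
    vals = [_canon(registry, "septal_thickness", round(v, 3)) for v in sample]
    iqr_outlier_filter(vals)
    flagged = [cv.magnitude for cv in vals
               if any(f.code == "iqr_outlier" for f in cv.flags)]
    assert vals[-1].magnitude in flagged


@given(st.lists(st.floats(min_value=0.5, max_value=3.0), min_size=4, max_size=40),
       st.randoms(use_true_random=False))
@settings(max_examples=100, deadline=None)
def test_iqr_permutation_invariant(registry, sample, rnd):
    def flags_for(order):
        vals = [_canon(registry, "septal_thickness", v) for v in order]
        iqr_outlier_filter(vals)
        return sorted((cv.magnitude, len(cv.flags) > 0) for cv in vals)

    shuffled = list(sample)
    rnd.shuffle(shuffled)
    assert flags_for(sample) == flags_for(shuffled)


def test_tukey_quartiles_median_of_halves():
    assert tukey_quartiles([1, 2, 3, 4]) == (1.5, 3.5)
    assert tukey_quartiles([1, 2, 3, 4, 5]) == (1.5, 4.5)  # median excluded


def test_missingness_fractions(registry):
    corpus = [RawReport(f"r{i}", "The aortic valve area is 1.0 cm2."
                        if i < 8 else "Unremarkable study.")
              for i in range(10)]
    result = run_pipeline(corpus, registry, RunConfig(iqr_k=None))
    by_id = {m.element_id: m for m in result.missingness}
    assert by_id["aortic_valve_area"].fraction_missing == pytest.approx(0.2)
    assert by_id["mitral_valve_area"].fraction_missing == 1.0
    for m in result.missingness:
        assert 0.0 <= m.fraction_missing <= 1.0
        assert m.n_reports_without_mention <= m.n_reports_total


def test_flags_never_change_magnitude(registry):
    # the only rescaling anywhere is the documented unit conversion
    cv = _canon(registry, "septal_thickness", 120.0)
    before = cv.magnitude
    iqr_outlier_filter([cv] * 4)
    check_physiologic([cv], registry)
    assert cv.magnitude == before
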