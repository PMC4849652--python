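"""Shared fixtures: the shipped registry and the worked-example report
snippets exercised throughout the suite."""

from __future__ import annotations

import pytest

from echoextract import RawReport, RunConfig, load_registry, run_pipeline

# worked-example sentences in the three report styles
STRUCTURED_LINE = "MV E/A: ..0.57….MVA(P1/2T):..1.4 cm….AO V2 MAX:..335 cm/sec…."
SEMI_STRUCTURED_LINE = "Peak.. velocity across the aortic valve = 5.0 m/s"
UNSTRUCTURED_LINE = ("The forward flow across the aortic valve is ..increased "
                     "at 3.4 m/s with a mean gradient of 28 mm.. Hg")

# three-sentence bioprosthetic-valve co-reference passage
COREF_PASSAGE = (
    "A bioprosthetic valve is seen in the aortic position, which is well "
    "seated. The…peak velocity across this valve is 1.9 m/second. "
    "The mean gradient is 16 mmHg ..and peak gradient is 27 mmHg."
)

RANGE_SENTENCE = "The mean gradient across the aortic valve is 25–30 mmhg."
CATEGORICAL_SENTENCE = "…moderate-severe aortic regurgitation is present."

# documented non-extraction rows: (text, element whose value must not survive)
CORRUPTION_ROWS = [
    ("The ..velocity across the AV bioprosthesis has increased.. "
     "from 1.6 m/s--> 2.0 m/s", "av_peak_velocity"),
    ("A bioprosthetic valve ..is present in the aortic position. "
     "Maximum ..gradient of 24 mm Hg, mean 13 mm Hg", "av_mean_gradient"),
    ("The .. forward flow across the bopprosthetic valve is 3.7 m/s "
     "with a mean .. gradient of 30 mm Hg", "av_peak_velocity"),
    ("across the aortic valve is increased with a mean gradient of "
     "[**12–02**] mmhg", "av_mean_gradient"),
    ("ava 0.53 am2. (ava index is 0.3 cm2/m2) dimensionless index "
     "(tvi ratio) = 0.19", "aortic_valve_area"),
    ("there is a well seated, ..well functioning stentless porcine aortic "
     "valve. There.. is no significant stenosis or regurgitation of the "
     "..prosthesis", "aortic_stenosis"),
]


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def pipeline_one():
    """Run the full pipeline on a single one-report corpus."""

    def _run(text: str, report_id: str = "r0", **config_kwargs):
        from echoextract import run_pipeline
        config = RunConfig(**config_kwargs)
        reg = load_registry()
        return run_pipeline([RawReport(report_id, text)], reg, config)

    return _run


def kept_values(result, element_id: str):
    """Surviving values for one element across a pipeline result."""
    return [v for s in result.summaries if s.element_id == element_id
            for v in s.values]
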