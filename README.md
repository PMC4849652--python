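# echoextract

Rule-based extraction of structured cardiovascular data from
echocardiography report text.

Echocardiography reports bury research-grade measurements — valve gradients
and velocities, chamber dimensions, ejection fractions, qualitative severity
grades — in a mixture of colon-delimited measurement lines, `phrase = value`
assignments, and narrative prose, further corrupted by EHR-export artifacts
(spurious `.` runs, inconsistent units, typing errors, de-identification
placeholders). `echoextract` turns such reports into one tidy row per
report × element for 80 targeted data elements (59 quantitative, 21
qualitative, across seven anatomic categories), for researchers assembling
cohorts or surveilling valve function from report archives.

The pipeline:

1. **normalize** — collapse whitespace, strip ellipsis noise, preserve real
   sentence boundaries;
2. **segment & classify** — sentence segmentation robust to measurement
   lines; structured / semi-structured / unstructured labels;
3. **extract** — per-element synonym alternations with a 30-character
   window before and 100 after each mention
   (`.{30}(\sava\s|aortic\s*valve\s*area|\sav\sarea).{100}` style); numeric,
   range, and categorical value parsing with negation and artifact guards;
4. **co-reference** — a deterministic 2-sentence look-ahead attributes
   generic measurements ("The mean gradient is 16 mmHg") to the valve
   entity established earlier ("A bioprosthetic valve … in the aortic
   position");
5. **filter** — unit canonicalization (cm/s → m/s, mm → cm, …), wrong/missing
   unit flags, physiologic constraints (LVEDs < LVEDd, peak velocity < peak
   gradient, mean gradient < peak gradient), Tukey IQR outlier fences
   (k = 1.5) per element across the corpus;
6. **summarize** — ranges collapse to midpoints ("25–30 mmHg" → 27.5);
   per-cell count/min/max/last plus source sentence segments, written as TSV.

A seeded synthetic-report generator with exact gold annotations and a
precision/recall/F1 evaluator make every stage testable without access to
protected clinical text. See `docs/methods.md` for the full method
description.

## Worked example

```python
from echoextract import RawReport, load_registry, run_pipeline

registry = load_registry()          # shipped 80-element schema
report = RawReport("r1",
    "A bioprosthetic valve is seen in the aortic position, which is well "
    "seated. The…peak velocity across this valve is 1.9 m/second. "
    "The mean gradient is 16 mmHg ..and peak gradient is 27 mmHg.")

result = run_pipeline([report], registry)
for s in result.summaries:
    if s.n_values:
        print(s.element_id, s.values, s.unit)
```

prints

```
av_peak_velocity (1.9,) m/s
av_peak_gradient (27.0,) mmHg
av_mean_gradient (16.0,) mmHg
```

— the peak velocity, although stated only as "across this valve", is
attributed to the aortic valve via the co-reference look-ahead (its
extraction record carries `via_coreference=True`), and each value is in the
element's canonical unit.

The same pipeline is scriptable from the shell:

```bash
echoextract simulate --seed 1 --n-reports 100 --out sim/
echoextract extract  --corpus sim/reports --out run/
echoextract evaluate --pred run/summary.tsv --gold sim/gold.jsonl
echoextract missingness --corpus sim/reports
```

`extract` writes `summary.tsv` (one row per report × element with the
JSON-encoded value list, min/max/last, and provenance spans), `flags.tsv`
(one row per flagged value with its reason), and `missingness.tsv` (per
element, the fraction of reports never mentioning it).

## Layout

| path | contents |
| --- | --- |
| `src/echoextract/registry.py` | element schema, validation, synonym resolution |
| `src/echoextract/data/elements.yaml` | the shipped 80-element config |
| `src/echoextract/normalize.py` | text cleanup, segmentation, structure classes |
| `src/echoextract/extract.py` | windowed patterns, value parsing, co-reference |
| `src/echoextract/filters.py` | units, physiologic constraints, IQR, missingness |
| `src/echoextract/summarize.py` | range collapsing, summary table, histogram |
| `src/echoextract/simulate.py` | seeded synthetic corpus + gold annotations |
| `src/echoextract/evaluate.py` | precision/recall/F1/specificity/NPV scoring |
| `src/echoextract/cli.py` | `echoextract` command-line interface |
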