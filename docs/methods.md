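# Methods

## Problem and approach

Echocardiography reports catalogue dozens of measurements of cardiac
structure and hemodynamics — valve gradients and velocities, chamber
dimensions, ejection fractions, qualitative severity grades — but mix three
textual styles in one document: colon-delimited measurement lines
(`AO V2 MAX: 335 cm/sec`), single `phrase = value unit` assignments, and
narrative prose. EHR exports additionally corrupt the text with spurious
runs of `.` characters, inconsistent unit spellings, typing errors, and
de-identification placeholders.

`echoextract` is a *targeted* rule-based extractor: it knows exactly which 80
data elements it is looking for (59 quantitative, 21 qualitative, organized
in seven anatomic categories) and matches each against a synonym lexicon
rather than running generic clinical NLP. This trades coverage of arbitrary
concepts for high precision and recall on the elements that matter for
cardiovascular research cohorts.

## Pipeline stages

1. **Normalization.** Whitespace runs collapse to one space (newlines are
   kept as line/section breaks). A run of two or more dots followed by
   whitespace and a capital letter is a sentence boundary and becomes `. `;
   any other dot run is export noise and is deleted so the flanking tokens
   rejoin (`Peak.. velocity` → `Peak velocity`). One exception: a dot run
   splitting a two-token unit (`28 mm.. Hg`) is always noise, whatever the
   capitalization of the next token. Normalization is idempotent;
   single periods — decimals, unit abbreviations, terminal periods — are
   untouched. De-identification placeholders (`[**…**]`) pass through
   verbatim so the extractor can flag them.

2. **Segmentation and structure classes.** Sentences split at newlines and
   at `.?!` + whitespace + capital. Each sentence is classified:
   *structured* (≥ 2 `LABEL: value` groups), *semi-structured* (exactly one
   `:`/`=` assignment of a number), else *unstructured*. The class is
   informational; extraction treats all classes uniformly, and no section
   position is privileged (archives have reordered sections over time).

3. **Windowed extraction.** Every element compiles one pattern: an
   alternation over its synonyms (case-insensitive, flexible internal
   whitespace, word-bounded) with a **30-character window before and a
   100-character window after** each mention (both config-overridable).
   Within the window the parser recognizes plain numbers with optional
   units, ranges (`25–30`, `4 to 6`; en-dash and hyphen interchangeable),
   categorical vocabulary tokens, and the missing-value markers `??` and
   `[**…**]`. Numbers abutting `-->` arrows or inside placeholders are
   rejected — these are documented failure modes of non-standardized
   reporting, deliberately not "fixed".

   *Candidate selection.* The nearest candidate wins, preferring rightward
   (label-then-value dominates real reports; leftward candidates carry a
   fixed 20-character distance penalty). A mention immediately followed by
   `:` or `=` is in label position and accepts only rightward candidates —
   without this, multi-label structured lines mis-assign the previous
   label's value (`MV E/A: 0.57 MVA(P1/2T): 1.4 cm` would hand the 0.57 to
   the valve-area label under plain nearest-match). Candidates outside the
   mention's sentence are discarded: cross-sentence attribution is
   exclusively the co-reference path, which prevents a window from stealing
   the next line's value. When one mention span contains another
   (`la volume` inside `la volume index`), the longer, more specific
   synonym wins.

   *Negation guard.* A vocabulary token preceded by "no" (optionally
   "no significant", "no evidence of") is suppressed, so negated findings
   do not become positive extractions.

4. **Co-reference look-ahead.** A sentence establishing a valve entity
   ("A bioprosthetic valve is seen in the aortic position", "across the
   mitral valve") donates its identity to *generic* measurement phrases —
   `peak velocity`, `mean velocity`, `peak gradient`, `mean gradient` — in
   the same sentence or the next **two** sentences. The nearest preceding
   entity wins; generic phrases already covered by a specific synonym match
   are skipped; a generic phrase with no antecedent is dropped and logged.
   Values attributed this way carry `via_coreference = true`. This
   deterministic heuristic replaces any learned co-reference component; its
   horizon of two sentences matches how these chains actually appear.

5. **Consistency filtering.** Flags only ever add; no filter alters a
   magnitude except the documented unit rescaling. Flag codes: `no_unit`,
   `wrong_unit`, `physiologic_inconsistent`, `iqr_outlier`,
   `deid_placeholder`, `out_of_plausible_range`. A flagged value is removed
   from the kept set; when a surviving duplicate of the same element exists
   in the same report, the flag detail records that the duplicate stands in
   (no imputation model is attempted).

   * **Units.** Spellings are folded (`m/sec`, `m/second` → `m/s`; `mm Hg`,
     `mmhg` → `mmHg`; `sq. cm` → `cm^2`) and magnitudes rescaled to the
     element's canonical unit (cm/s → m/s ÷ 100, mm → cm ÷ 10, …).
     Dimensionally incompatible or unrecognized units ⇒ `wrong_unit`;
     absent units on unit-bearing elements ⇒ `no_unit`; dimensionless
     elements (E/A ratio, dimensionless index) take bare numbers and flag
     any written unit. Valve areas stay in cm²; body surface area is m².
   * **Physiologic constraints** (per report, on/off switch, default on):
     LVEDs < LVEDd; each valve's peak velocity < its peak gradient; each
     valve's mean gradient < its peak gradient. Velocities are compared in
     m/s against gradients in mmHg — numerically sound for physiologic
     values via the Bernoulli relation (gradient ≈ 4·v²), though
     dimensionally heterodox, hence the switch. A violated pair flags
     *both* members.
   * **IQR outliers** (corpus-global, per element): values outside
     [Q1 − k·IQR, Q3 + k·IQR], k = 1.5 (Tukey), quartiles by the
     median-of-halves rule (middle observation excluded when n is odd).
     Fewer than 4 values: no-op. All-equal values: fences degenerate to the
     point, nothing flagged. The pass runs on the extracted value table
     only, so per-value outcomes are invariant to corpus order.

6. **Summaries.** Ranges collapse to their midpoint ((25+30)/2 = 27.5).
   Each report × element yields one row: source sentence segments, the
   ordered surviving values (document order by character offset), count,
   min, max, and *last*. All four are emitted because no single mention
   position is reliably authoritative; a warn-only `high_variability`
   column marks cells whose numeric spread exceeds 20% of the mean. Output
   is TSV with JSON-encoded list columns (delimiter-safe, diff-able,
   lossless round-trip).

## Synthetic corpus

The generator emulates the phenomena above with exact gold annotations:
three rendering styles in configurable proportions (default 0.4/0.3/0.3),
random synonym choice per mention, ellipsis insertion, co-reference chains
(default rate 0.15 for valve velocity/gradient elements), range renderings
(default 0.08), alternate-but-consistent units (default 0.10), and the
corruption modes: phrase misspellings (single-character substitution in the
longest word, never in numerals), `-->` arrows, placeholders, wrong units,
missing units. Default prevalence is 0.2 per element per report — most
elements are absent from most reports, as in real archives, which also
exercises the missingness accounting. `CALIBRATED_NOISE` bundles
archive-realistic rates (measured flag fraction ≈ 3%, comfortably under the
10% documented for real data).

**Gold semantics.** `expected_extractable` / `expected_kept` are set by the
corruption rule alone (misspelling/arrow/placeholder ⇒ not extractable;
wrong/missing unit ⇒ extractable but not kept), never by running the
extractor — the gold is an independent oracle.

**Value model.** Quantitative values are normals truncated at ±1.75 SD
around clinically typical means (registry defaults, overridable; presets
ship for severe-aortic-stenosis and post-valve-replacement populations).
Constraint-linked quantities are sampled jointly per valve: peak gradient
first, peak velocity via the Bernoulli relation v = √(g/4), mean gradient
as a uniform 0.5–0.7 fraction of peak; LV systolic diameter as a 0.58–0.72
fraction of diastolic. Joint sampling guarantees a clean corpus violates no
physiologic constraint.

**Determinism and coupling.** Every (report, element) cell draws from an
RNG keyed by (seed, report index, element index) in fixed order, so one
seed reproduces the corpus byte-for-byte and raising any corruption rate
corrupts a *superset* of cells — extraction recall is therefore
non-increasing in the corruption rate for each seed, deterministically.

**What the generator does not model:** real report-length and section-order
distributions, inter-element clinical correlation beyond the constraint
groups, institution-specific templates, and free-text commentary. Passing
tests on synthetic corpora therefore demonstrate correctness of the
mechanics (matching, parsing, attribution, filtering, scoring) under the
modeled phenomena — not performance on any particular institution's
archive.

## Evaluation

Counts live at report × element granularity: a cell with neither an
expected gold value nor an extracted value is a true negative. Within a
cell, predictions and expected values are paired greedily by nearest value;
numbers match within an absolute tolerance of 1e-6 after unit
canonicalization (configurable), categories match exactly. Precision
(positive predictive value), recall (sensitivity), F1 (harmonic mean),
specificity and NPV are reported per element and micro-averaged (pooled
counts).

## Numerical and design choices

* Offsets are 0-based half-open against the normalized text.
* The oracle-equivalence check (P = R = 1.0 on a zero-noise 1,000-report
  corpus) runs with the corpus-statistical IQR pass disabled
  (`RunConfig(iqr_k=None)`): Tukey fences have a nonzero false-alarm rate
  on defect-free bounded data (measured ≈ 0.3% here), which is a property
  of the fences, not an extraction error — and rule-based gold cannot
  anticipate a data-dependent corpus statistic. The IQR stage is tested
  separately on planted outliers and on the calibrated-noise corpus.
* The recall-monotonicity property is likewise evaluated at the extraction
  level (IQR off), because fences shift when the corpus changes.
* Problem sizes in the test suite (50–1,000 synthetic reports, 5 seeds for
  the monotonicity sweep) were chosen to make the statistical assertions
  stable while keeping the default suite fast.
* Degenerate inputs: empty reports yield empty summaries; an empty corpus
  yields header-only tables; unknown units never crash (they flag);
  malformed registry configs abort with a diagnostic listing every
  offending element.

## Known limitations

* Synonym lexicons are seeded from the documented variants and are
  config-extensible; coverage of any particular institution's phrasing
  requires lexicon review.
* The co-reference heuristic only handles valve entities and the four
  generic measurement phrases; pronoun chains beyond two sentences, and
  chamber entities, are out of scope.
* Qualitative severity grading conventions vary between institutions; the
  shipped vocabularies follow the common trace→severe ladder.
* "Estimation from other values" for flagged entries is limited to noting a
  surviving duplicate; no imputation is performed.
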