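"""Unit canonicalization, inconsistency flagging and missing-data burden.

Raw extractions carry typing errors (wrong or absent units), systematic
dissimilar-but-consistent units (cm/s vs m/s), physiologically impossible
combinations (a systolic dimension exceeding its diastolic partner), and
corpus-level statistical outliers (a septal thickness entered as ``1.2 m``).
Each defect attaches a labelled flag; flagged values lose their ``kept``
status but are never silently altered — the only magnitude change anywhere is
the documented rescaling to the canonical unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import units
from .extract import ParsedValue
from .registry import ElementSpec, Registry

FLAG_CODES = ("no_unit", "wrong_unit", "physiologic_inconsistent",
              "iqr_outlier", "deid_placeholder", "out_of_plausible_range")

#: flag codes that remove a value from the kept set (all of them — flags are
#: removal-class; the >20%-variability warning lives on the summary instead)
REMOVAL_CODES = frozenset(FLAG_CODES)


@dataclass(frozen=True)
class FilterFlag:
    code: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.code not in FLAG_CODES:
            raise ValueError(f"unknown flag code {self.code!r}")


@dataclass
class CanonicalValue:
    element_id: str
    report_id: str
    sentence_index: int
    kind: str                        # number | range | category | missing_marker
    value: float | str | None        # canonical-unit float or vocab token
    value_low: float | None = None   # canonical-unit range bounds
    value_high: float | None = None
    unit: str = ""                   # canonical unit when numeric and kept
    unit_as_written: str = ""
    source_span: str = ""
    span_start: int = -1
    span_end: int = -1
    via_coreference: bool = False
    flags: list[FilterFlag] = field(default_factory=list)

    @property
    def kept(self) -> bool:
        return not any(f.code in REMOVAL_CODES for f in self.flags)

    @property
    def magnitude(self) -> float | None:
        """Numeric magnitude in canonical units (range midpoint for ranges);
        None for categorical values, markers, and unconverted numbers."""
        if self.kind == "range" and self.value_low is not None:
            return (self.value_low + self.value_high) / 2.0
        if self.kind == "number" and isinstance(self.value, float):
            return self.value
        return None

    def add_flag(self, code: str, detail: str = "") -> None:
        self.flags.append(FilterFlag(code, detail))


def canonicalize_unit(value: ParsedValue, element: ElementSpec) -> CanonicalValue:
    """Normalize unit spelling and rescale the magnitude to the element's
    canonical unit; flag absent or dimensionally incompatible units.

    Never raises on an unknown unit string — that is a ``wrong_unit`` flag.
    """
    cv = CanonicalValue(
        element_id=value.element_id, report_id=value.report_id,
        sentence_index=value.sentence_index, kind=value.kind,
        value=None, unit_as_written=value.unit_as_written,
        source_span=value.source_span, span_start=value.span_start,
        span_end=value.span_end, via_coreference=value.via_coreference,
    )
    if value.kind == "category":
        cv.value = value.category
        return cv
    if value.kind == "missing_marker":
        cv.add_flag("deid_placeholder",
                    f"unspecified-value marker {value.source_span!r}")
        return cv

    raw = value.unit_as_written.strip()
    canonical = element.canonical_unit

    def _assign(factor: float) -> None:
        if value.kind == "range":
            cv.value_low = value.range_low * factor
            cv.value_high = value.range_high * factor
            cv.value = (cv.value_low + cv.value_high) / 2.0
        else:
            cv.value = value.number * factor
        cv.unit = units.canonical_spelling(canonical) if canonical else ""

    if not raw:
        if canonical == "":
            _assign(1.0)  # dimensionless element: bare number is correct
        else:
            _assign(1.0)  # magnitude retained as written, pending estimation
            cv.unit = ""
            cv.add_flag("no_unit", f"expected {canonical!r}, none written")
    else:
        hit = units.lookup(raw)
        if canonical == "":
            cv.add_flag("wrong_unit",
                        f"dimensionless element, unit {raw!r} written")
        elif hit is None:
            cv.add_flag("wrong_unit", f"unrecognized unit {raw!r}")
        elif hit[0] != units.dimension_of(canonical):
            cv.add_flag("wrong_unit",
                        f"{raw!r} incompatible with canonical {canonical!r}")
        else:
            _assign(units.convert(1.0, raw, canonical))

    if (cv.kept and element.plausible_range is not None
            and cv.magnitude is not None):
        low, high = element.plausible_range
        if not (low <= cv.magnitude <= high):
            cv.add_flag("out_of_plausible_range",
                        f"{cv.magnitude:g} outside [{low:g}, {high:g}] {canonical}")
    return cv


# --------------------------------------------------------------------------
# physiologic-consistency constraints (per report)

_VALVES = ("av", "mv", "tv", "pv", "lvot", "rvot")

#: (element that must be smaller, element that must be larger)
PHYSIOLOGIC_CONSTRAINTS: list[tuple[str, str]] = (
    [("lveds", "lvedd")]
    + [(f"{v}_peak_velocity", f"{v}_peak_gradient") for v in _VALVES]
    + [(f"{v}_mean_gradient", f"{v}_peak_gradient") for v in _VALVES]
)


def _comparison_magnitude(cv: CanonicalValue, registry: Registry) -> float | None:
    """Magnitude on the comparison scale: velocities in m/s, everything else
    in its canonical unit (LVOT/RVOT velocities are canonically cm/s)."""
    mag = cv.magnitude
    if mag is None:
        return None
    unit = registry.get(cv.element_id).canonical_unit
    if units.dimension_of(unit) == "velocity":
        return units.convert(mag, unit, "m/s")
    return mag


def check_physiologic(report_values: list[CanonicalValue], registry: Registry,
                      *, enabled: bool = True) -> list[CanonicalValue]:
    """Flag anatomically/physiologically inconsistent pairs within one report.

    Constraints: systolic < diastolic dimension (LVEDs < LVEDd); each valve's
    peak velocity (m/s) < its peak gradient (mmHg); each valve's mean gradient
    < its peak gradient.  A violated constraint flags BOTH members.  Values in
    an unflagged state on only one side of a pair are vacuously consistent.
    """
    if not enabled:
        return report_values
    by_element: dict[str, list[CanonicalValue]] = {}
    for cv in report_values:
        if cv.kept and cv.magnitude is not None:
            by_element.setdefault(cv.element_id, []).append(cv)
    for small_id, large_id in PHYSIOLOGIC_CONSTRAINTS:
        for a in by_element.get(small_id, []):
            for b in by_element.get(large_id, []):
                va = _comparison_magnitude(a, registry)
                vb = _comparison_magnitude(b, registry)
                if va is None or vb is None or va < vb:
                    continue
                detail = (f"{small_id}={va:g} not < {large_id}={vb:g} "
                          f"in report {a.report_id}")
                a.add_flag("physiologic_inconsistent", detail)
                b.add_flag("physiologic_inconsistent", detail)
    return report_values


# --------------------------------------------------------------------------
# corpus-level IQR outlier filtering

def tukey_quartiles(sorted_values: list[float]) -> tuple[float, float]:
    """Q1/Q3 by the median-of-halves rule: split the sorted sample at the
    median (excluding the middle observation when n is odd) and take the
    median of each half."""
    n = len(sorted_values)
    half = n // 2
    lower = sorted_values[:half]
    upper = sorted_values[n - half:]

    def _median(xs: list[float]) -> float:
        m = len(xs)
        mid = m // 2
        if m % 2:
            return xs[mid]
        return (xs[mid - 1] + xs[mid]) / 2.0

    return _median(lower), _median(upper)


def iqr_outlier_filter(element_values: list[CanonicalValue],
                       k: float = 1.5) -> list[CanonicalValue]:
    """Flag values outside the Tukey fences [Q1 - k*IQR, Q3 + k*IQR] computed
    over one element's corpus-wide numeric values.  Fewer than 4 comparable
    values: no-op.  Identical values: IQR = 0, the fences degenerate to the
    common point and nothing is flagged.
    """
    numeric = [cv for cv in element_values
               if cv.magnitude is not None
               and not any(f.code in ("wrong_unit", "no_unit", "deid_placeholder")
                           for f in cv.flags)]
    if len(numeric) < 4:
        return element_values
    mags = sorted(cv.magnitude for cv in numeric)
    q1, q3 = tukey_quartiles(mags)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    for cv in numeric:
        m = cv.magnitude
        if m < lo or m > hi:
            cv.add_flag("iqr_outlier",
                        f"{m:g} outside fences [{lo:g}, {hi:g}] (k={k:g})")
    return element_values


# --------------------------------------------------------------------------
# missing-data burden

@dataclass(frozen=True)
class MissingnessRow:
    element_id: str
    n_reports_total: int
    n_reports_without_mention: int

    @property
    def fraction_missing(self) -> float:
        if self.n_reports_total == 0:
            return 0.0
        return self.n_reports_without_mention / self.n_reports_total


def missingness(report_ids: list[str], registry: Registry,
                mentioned: dict[str, set[str]]) -> list[MissingnessRow]:
    """Per element: how many reports never mention it.

    ``mentioned`` maps element_id -> set of report_ids with >=1 mention
    (an extraction by-product; a mention counts whether or not a value was
    parsed).
    """
    total = len(report_ids)
    ids = set(report_ids)
    rows = []
    for e in registry:
        with_mention = len(mentioned.get(e.element_id, set()) & ids)
        rows.append(MissingnessRow(e.element_id, total, total - with_mention))
    return rows
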