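"""Measurement-unit lexicon, normalization and conversion.

Echocardiography reports spell units inconsistently (``m/sec``, ``m/second``,
``mm Hg``, ``sq. cm`` ...) and sometimes report a measurement in a
dissimilar-but-consistent unit (``cm/sec`` where the canonical unit is
``m/s``).  This module maps every recognized spelling to a *dimension* and a
conversion factor to that dimension's base unit, so values can be rescaled to
each element's canonical unit and dimensionally incompatible units can be
flagged.
"""

from __future__ import annotations

import re

# spelling (normalized) -> (dimension, factor to the dimension base unit)
# Base units: velocity m/s, pressure mmHg, length cm, area cm^2, time ms,
# fraction %, volume ml, volume index ml/m^2, area index cm^2/m^2.
_UNIT_TABLE: dict[str, tuple[str, float]] = {
    # velocity
    "m/s": ("velocity", 1.0),
    "m/sec": ("velocity", 1.0),
    "m/second": ("velocity", 1.0),
    "meters/second": ("velocity", 1.0),
    "cm/s": ("velocity", 0.01),
    "cm/sec": ("velocity", 0.01),
    "cm/second": ("velocity", 0.01),
    "mm/s": ("velocity", 0.001),
    "mm/sec": ("velocity", 0.001),
    # pressure
    "mmhg": ("pressure", 1.0),
    "mm hg": ("pressure", 1.0),
    # length
    "cm": ("length", 1.0),
    "centimeters": ("length", 1.0),
    "mm": ("length", 0.1),
    "m": ("length", 100.0),
    # area
    "cm2": ("area", 1.0),
    "cm^2": ("area", 1.0),
    "sq cm": ("area", 1.0),
    "sq. cm": ("area", 1.0),
    "mm2": ("area", 0.01),
    "mm^2": ("area", 0.01),
    "sq mm": ("area", 0.01),
    "m2": ("area", 10000.0),
    "m^2": ("area", 10000.0),
    "sq m": ("area", 10000.0),
    # time
    "ms": ("time", 1.0),
    "msec": ("time", 1.0),
    "milliseconds": ("time", 1.0),
    "sec": ("time", 1000.0),
    "seconds": ("time", 1000.0),
    # fraction
    "%": ("fraction", 1.0),
    "percent": ("fraction", 1.0),
    # volume
    "ml": ("volume", 1.0),
    "cc": ("volume", 1.0),
    "l": ("volume", 1000.0),
    # indexed quantities
    "ml/m2": ("volume_index", 1.0),
    "ml/m^2": ("volume_index", 1.0),
    "cc/m2": ("volume_index", 1.0),
    "cm2/m2": ("area_index", 1.0),
    "cm^2/m^2": ("area_index", 1.0),
    "cm^2/m2": ("area_index", 1.0),
}

#: canonical display spelling per (dimension, factor) pair
_CANONICAL_SPELLING = {
    ("velocity", 1.0): "m/s",
    ("velocity", 0.01): "cm/s",
    ("velocity", 0.001): "mm/s",
    ("pressure", 1.0): "mmHg",
    ("length", 1.0): "cm",
    ("length", 0.1): "mm",
    ("length", 100.0): "m",
    ("area", 1.0): "cm^2",
    ("area", 0.01): "mm^2",
    ("area", 10000.0): "m^2",
    ("time", 1.0): "ms",
    ("time", 1000.0): "s",
    ("fraction", 1.0): "%",
    ("volume", 1.0): "ml",
    ("volume", 1000.0): "l",
    ("volume_index", 1.0): "ml/m^2",
    ("area_index", 1.0): "cm^2/m^2",
}


def normalize_spelling(unit: str) -> str:
    """Fold a unit spelling to the lexicon key form (lowercase, ``^``/``²``
    folded, internal whitespace collapsed, trailing periods stripped)."""
    u = unit.strip().lower().replace("²", "2").replace("^", "")
    u = re.sub(r"\s+", " ", u).rstrip(".")
    # re-insert '^' for table lookup of exponent forms
    u = re.sub(r"([a-z])2\b", r"\g<1>^2", u)
    if u in _UNIT_TABLE:
        return u
    u2 = u.replace("^", "")
    return u2


def lookup(unit: str) -> tuple[str, float] | None:
    """Return ``(dimension, factor_to_base)`` for a unit spelling, or None."""
    u = normalize_spelling(unit)
    if u in _UNIT_TABLE:
        return _UNIT_TABLE[u]
    return _UNIT_TABLE.get(u.replace("^", ""))


def dimension_of(unit: str) -> str | None:
    """Dimension name for a unit spelling (None if unrecognized or empty)."""
    if not unit:
        return None
    hit = lookup(unit)
    return hit[0] if hit else None


def canonical_spelling(unit: str) -> str:
    hit = lookup(unit)
    if hit is None:
        return unit
    return _CANONICAL_SPELLING.get(hit, unit)


def convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two recognized units of the same dimension.

    Raises ValueError if either unit is unknown or dimensions differ.
    """
    src, dst = lookup(from_unit), lookup(to_unit)
    if src is None or dst is None:
        raise ValueError(f"unknown unit: {from_unit if src is None else to_unit!r}")
    if src[0] != dst[0]:
        raise ValueError(f"incompatible units: {from_unit!r} -> {to_unit!r}")
    return value * src[1] / dst[1]


def known_spellings() -> list[str]:
    """All recognized spellings, longest first (for regex alternation)."""
    return sorted(_UNIT_TABLE, key=len, reverse=True)


def unit_pattern() -> str:
    """Regex alternation matching any recognized unit spelling (plus a
    fallback for unknown unit-shaped tokens such as the mistyped ``am2``)."""
    alts = []
    for s in known_spellings():
        esc = re.escape(s).replace(r"\ ", r"\s+")
        alts.append(esc)
    known = "|".join(alts)
    # unknown-but-unit-shaped: short token containing a digit or slash
    fallback = r"[a-z]{1,4}\d|[a-z]{1,6}/[a-z0-9]{1,6}"
    return rf"(?:{known}|{fallback})"
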