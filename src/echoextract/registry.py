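"""Registry of targeted echocardiographic data elements.

The registry is loaded from a versioned YAML config (the shipped default
lives in ``echoextract/data/elements.yaml``) and validated on load: 80
elements across seven anatomic categories, 59 quantitative and 21
qualitative, with an unambiguous synonym -> element mapping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from . import units

CATEGORIES = (
    "left_ventricle",
    "right_ventricle",
    "aortic_valve",
    "mitral_valve",
    "tricuspid_pulmonic",
    "atria",
    "miscellaneous",
)

EXPECTED_TOTAL = 80
EXPECTED_QUANTITATIVE = 59
EXPECTED_QUALITATIVE = 21


class RegistryError(ValueError):
    """Raised when a registry config fails validation."""


@dataclass(frozen=True)
class ElementSpec:
    """Schema of one targeted data element."""

    element_id: str
    display_name: str
    category: str
    value_kind: str                      # "quantitative" | "qualitative"
    canonical_unit: str = ""             # empty for qualitative / dimensionless
    synonyms: tuple[str, ...] = ()
    categorical_vocab: tuple[str, ...] = ()
    plausible_range: tuple[float, float] | None = None
    accepted_units: tuple[str, ...] = () # spellings convertible to canonical
    typical: tuple[float, float] | None = None  # (mean, sd) for simulation
    origin: str = ""

    @property
    def is_quantitative(self) -> bool:
        return self.value_kind == "quantitative"


@dataclass
class Registry:
    elements: list[ElementSpec]
    version: str = ""
    _by_id: dict[str, ElementSpec] = field(default_factory=dict, repr=False)
    _by_synonym: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {e.element_id: e for e in self.elements}
        self._by_synonym = {}
        for e in self.elements:
            for s in e.synonyms:
                self._by_synonym[_fold(s)] = e.element_id

    def __iter__(self):
        return iter(self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def get(self, element_id: str) -> ElementSpec:
        return self._by_id[element_id]

    def __contains__(self, element_id: str) -> bool:
        return element_id in self._by_id

    @property
    def quantitative(self) -> list[ElementSpec]:
        return [e for e in self.elements if e.is_quantitative]

    @property
    def qualitative(self) -> list[ElementSpec]:
        return [e for e in self.elements if not e.is_quantitative]


def _fold(surface: str) -> str:
    """Case-fold and collapse internal whitespace for synonym comparison."""
    return re.sub(r"\s+", " ", surface.strip().lower())


def _accepted_units_for(canonical: str) -> tuple[str, ...]:
    dim = units.dimension_of(canonical)
    if dim is None:
        return ()
    return tuple(s for s in units.known_spellings() if units.dimension_of(s) == dim)


def _parse_element(raw: dict, errors: list[str]) -> ElementSpec | None:
    eid = raw.get("id", "")
    where = f"element {eid!r}" if eid else f"element entry {raw!r}"
    kind = raw.get("kind")
    if kind not in ("quantitative", "qualitative"):
        errors.append(f"{where}: value_kind must be quantitative|qualitative, got {kind!r}")
        return None
    if raw.get("category") not in CATEGORIES:
        errors.append(f"{where}: unknown category {raw.get('category')!r}")
        return None
    synonyms = tuple(str(s) for s in raw.get("synonyms", ()))
    if not synonyms or any(not s.strip() for s in synonyms):
        errors.append(f"{where}: synonyms must be non-empty after trimming")
        return None
    vocab = tuple(str(v) for v in raw.get("vocab", ()))
    unit = str(raw.get("unit", "") or "")
    rng = raw.get("range")
    if kind == "qualitative":
        if not vocab:
            errors.append(f"{where}: qualitative element needs a categorical vocabulary")
            return None
        if unit:
            errors.append(f"{where}: qualitative element must not carry a unit")
            return None
    else:
        if unit and units.dimension_of(unit) is None:
            errors.append(f"{where}: unrecognized canonical unit {unit!r}")
            return None
        if rng is None:
            errors.append(f"{where}: quantitative element needs a plausible range")
            return None
        low, high = float(rng[0]), float(rng[1])
        if not low < high:
            errors.append(f"{where}: plausible range low must be < high ({low} >= {high})")
            return None
        rng = (low, high)
    typical = raw.get("typical")
    return ElementSpec(
        element_id=str(eid),
        display_name=str(raw.get("name", eid)),
        category=raw["category"],
        value_kind=kind,
        canonical_unit=unit,
        synonyms=synonyms,
        categorical_vocab=vocab,
        plausible_range=tuple(rng) if rng is not None else None,
        accepted_units=_accepted_units_for(unit) if kind == "quantitative" else (),
        typical=tuple(float(x) for x in typical) if typical else None,
        origin=str(raw.get("origin", "")),
    )


def default_config_path() -> Path:
    """Path of the shipped element-schema config."""
    return Path(str(resources.files("echoextract").joinpath("data/elements.yaml")))


def load_registry(source: str | Path | None = None, *, strict_counts: bool = True) -> Registry:
    """Load and validate a registry config.

    Parameters
    ----------
    source:
        YAML config path; the shipped 80-element schema when omitted.
    strict_counts:
        Enforce the 80 = 59 quantitative + 21 qualitative cardinality.
        Disable for reduced custom registries.

    Raises
    ------
    RegistryError
        listing every offending element on any invariant violation.
    """
    path = Path(source) if source is not None else default_config_path()
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise RegistryError(f"malformed registry config {path}: {exc}") from exc
    if not isinstance(doc, dict) or "elements" not in doc:
        raise RegistryError(f"registry config {path} lacks an 'elements' list")

    errors: list[str] = []
    elements: list[ElementSpec] = []
    for raw in doc["elements"]:
        spec = _parse_element(raw, errors)
        if spec is not None:
            elements.append(spec)

    seen_ids: set[str] = set()
    for e in elements:
        if e.element_id in seen_ids:
            errors.append(f"duplicate element_id {e.element_id!r}")
        seen_ids.add(e.element_id)

    syn_owner: dict[str, str] = {}
    for e in elements:
        for s in e.synonyms:
            key = _fold(s)
            other = syn_owner.get(key)
            if other is not None and other != e.element_id:
                errors.append(
                    f"ambiguous synonym {s!r}: maps to both {other!r} and {e.element_id!r}"
                )
            syn_owner[key] = e.element_id

    if strict_counts:
        n_q = sum(1 for e in elements if e.is_quantitative)
        n_c = len(elements) - n_q
        if len(elements) != EXPECTED_TOTAL:
            errors.append(f"registry holds {len(elements)} elements, expected {EXPECTED_TOTAL}")
        if n_q != EXPECTED_QUANTITATIVE or n_c != EXPECTED_QUALITATIVE:
            errors.append(
                f"registry split {n_q} quantitative / {n_c} qualitative, "
                f"expected {EXPECTED_QUANTITATIVE}/{EXPECTED_QUALITATIVE}"
            )

    if errors:
        raise RegistryError(
            "registry validation failed:\n  " + "\n  ".join(errors)
        )
    return Registry(elements=elements, version=str(doc.get("version", "")))


def resolve_term(registry: Registry, surface: str) -> str | None:
    """Map a surface phrase to its owning element_id (case- and
    whitespace-insensitive); None when no synonym matches."""
    return registry._by_synonym.get(_fold(surface))


def registry_counts(registry: Registry) -> dict:
    """Total, per-value_kind and per-category element counts."""
    by_kind: dict[str, int] = {"quantitative": 0, "qualitative": 0}
    by_category: dict[str, int] = {c: 0 for c in CATEGORIES}
    for e in registry:
        by_kind[e.value_kind] += 1
        by_category[e.category] = by_category.get(e.category, 0) + 1
    return {"total": len(registry), "by_kind": by_kind, "by_category": by_category}


def write_registry(registry: Registry, destination: str | Path) -> None:
    """Serialize a registry back to YAML (round-trips through load_registry)."""
    doc = {"version": registry.version, "elements": []}
    for e in registry:
        raw: dict = {
            "id": e.element_id,
            "name": e.display_name,
            "category": e.category,
            "kind": e.value_kind,
            "origin": e.origin,
            "synonyms": list(e.synonyms),
        }
        if e.is_quantitative:
            raw["unit"] = e.canonical_unit
            raw["range"] = list(e.plausible_range)
            if e.typical:
                raw["typical"] = list(e.typical)
        else:
            raw["vocab"] = list(e.categorical_vocab)
        doc["elements"].append(raw)
    Path(destination).write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True))
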