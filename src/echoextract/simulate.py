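"""Seeded synthetic echocardiography report generator with gold annotations.

The generator emulates the report phenomena the extractor must survive:

* three sentence styles — structured label:value lines, semi-structured
  ``phrase = value unit`` assignments, and narrative prose;
* synonym variation (each planted mention picks a random registry synonym);
* EHR-export ellipsis noise (spurious ``..`` runs inside sentences);
* co-reference chains (an entity sentence followed by generic measurement
  phrases: "A bioprosthetic valve is seen in the aortic position. The peak
  velocity across this valve is 1.9 m/second.");
* documented corruption modes: misspelled element phrases, ``-->`` arrows
  around values, de-identification placeholders, wrong units, missing units.

Every planted value carries one gold record; ``expected_extractable`` /
``expected_kept`` are set by the corruption rule, never by running the
extractor.

Determinism and rate coupling
-----------------------------
All randomness for a (report, element) cell is drawn from an RNG keyed by
``(seed, report_index, element_index)`` in a fixed draw order, so the same
seed yields byte-identical corpora, and raising a corruption rate corrupts a
superset of the cells corrupted at a lower rate (which makes recall
provably non-increasing in the corruption rate for a fixed seed).

Value model
-----------
Quantitative values are drawn from normal distributions truncated at
+/-1.75 SD around a clinically typical mean (per-element defaults in the
registry; overridable).  Truncation reflects that a clean report archive
holds values inside reference bands — by construction a zero-noise corpus
contains no physiologic-constraint violations and no Tukey-fence outliers,
which is what makes it a *clean* corpus.  Within each valve, the peak
gradient is sampled first and the peak velocity derived through the
Bernoulli relation (v = sqrt(g/4)), the mean gradient as a 0.5-0.7 fraction
of the peak; LV systolic diameter is a 0.58-0.72 fraction of the diastolic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from . import units
from .normalize import RawReport
from .registry import ElementSpec, Registry

TRUNC_SD = 1.75

STYLES = ("structured", "semi_structured", "unstructured")

#: decimal places used when rendering a value in a given unit spelling
_DECIMALS = {"m/s": 2, "cm/s": 0, "mmhg": 1, "cm": 1, "cm2": 2, "mm2": 0,
             "ms": 0, "%": 0, "ml": 0, "ml/m2": 0, "m2": 2, "": 2}

#: alternate (dissimilar but consistent) unit per canonical unit
_ALT_UNIT = {"m/s": ("cm/sec", 0), "cm/s": ("m/s", 2), "mmHg": ("mm hg", 1),
             "cm": ("mm", 0), "cm^2": ("sq cm", 2), "ms": ("msec", 0),
             "%": ("percent", 0), "ml": ("cc", 0), "ml/m^2": ("cc/m2", 0)}

#: incompatible unit used for the wrong-unit corruption, per dimension
_WRONG_UNIT = {"velocity": "mmhg", "pressure": "cm/s", "length": "m/s",
               "area": "mmhg", "time": "cm", "fraction": "cm",
               "volume": "cm", "volume_index": "cm"}

_VALVE_POSITION = {"av": "aortic", "mv": "mitral", "tv": "tricuspid", "pv": "pulmonic"}
_GENERIC_PHRASE = {"peak_velocity": "peak velocity", "mean_velocity": "mean velocity",
                   "peak_gradient": "peak gradient", "mean_gradient": "mean gradient"}

#: elements renderable as a look-ahead co-reference chain
COREF_ELIGIBLE = {f"{v}_{m}" for v in _VALVE_POSITION for m in _GENERIC_PHRASE}

#: primary-element overrides emulating a severe-aortic-stenosis population
SEVERE_AS_OVERRIDES = {"av_peak_gradient": (75.0, 10.0)}
#: and a post-valve-replacement population
POST_AVR_OVERRIDES = {"av_peak_gradient": (18.0, 4.0)}


@dataclass
class NoiseRates:
    """Per-value probabilities of each corruption / noise op."""
    ellipsis: float = 0.0     # non-destructive export noise
    typo: float = 0.0         # misspelled element phrase -> not extractable
    wrong_unit: float = 0.0   # incompatible unit -> extracted, flagged
    no_unit: float = 0.0      # unit omitted -> extracted, flagged
    deid: float = 0.0         # value replaced by [** ... **] placeholder
    arrow: float = 0.0        # value wrapped in "from x --> y"

    def validate(self) -> None:
        for name, v in vars(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"noise rate {name}={v} outside [0, 1]")


#: modest defaults mirroring a real archive in which the large majority of
#: values are clean
CALIBRATED_NOISE = NoiseRates(ellipsis=0.15, typo=0.02, wrong_unit=0.01,
                              no_unit=0.02, deid=0.01, arrow=0.01)


@dataclass
class SynthConfig:
    seed: int = 0
    n_reports: int = 100
    element_prevalence: float | dict[str, float] = 0.2
    structure_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)
    coref_rate: float = 0.15
    range_rate: float = 0.08      # rendering style, not noise: "25 to 30 mmhg"
    alt_unit_rate: float = 0.10   # consistent non-canonical units ("cm/sec")
    noise: NoiseRates = field(default_factory=NoiseRates)
    value_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        if abs(sum(self.structure_mix) - 1.0) > 1e-9:
            raise ValueError("structure_mix proportions must sum to 1")
        for p in (self.coref_rate, self.range_rate, self.alt_unit_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        prev = self.element_prevalence
        vals = prev.values() if isinstance(prev, dict) else [prev]
        for p in vals:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {p} outside [0, 1]")
        self.noise.validate()

    def prevalence_of(self, element_id: str) -> float:
        if isinstance(self.element_prevalence, dict):
            return self.element_prevalence.get(element_id, 0.0)
        return self.element_prevalence


@dataclass(frozen=True)
class GoldAnnotation:
    report_id: str
    element_id: str
    value: float | str | None     # canonical-unit value (or vocab token)
    unit: str                     # canonical unit
    rendered: str                 # value text as planted, pre-noise
    style: str
    corruptions: tuple[str, ...]
    expected_extractable: bool
    expected_kept: bool
    via_coreference: bool = False


# --------------------------------------------------------------------------
# value sampling

def _tnorm(u: float, mean: float, sd: float) -> float:
    return float(truncnorm.ppf(u, -TRUNC_SD, TRUNC_SD, loc=mean, scale=sd))


_GROUP_INDEX = {"av": 0, "mv": 1, "tv": 2, "pv": 3, "lvot": 4, "rvot": 5, "lv": 6}


def _group_values(registry: Registry, config: SynthConfig,
                  seed: int, report_idx: int) -> dict[str, float]:
    """Physiologically coupled canonical values for constraint-linked
    elements, one draw set per valve group per report."""
    out: dict[str, float] = {}
    for group, gi in _GROUP_INDEX.items():
        rng = np.random.default_rng((seed, report_idx, 9000 + gi))
        u = rng.random(4)
        if group == "lv":
            eid = "lvedd"
            mean, sd = config.value_overrides.get(eid) or registry.get(eid).typical
            lvedd = _tnorm(u[0], mean, sd)
            out["lvedd"] = lvedd
            out["lveds"] = lvedd * (0.58 + 0.14 * u[1])
            continue
        eid = f"{group}_peak_gradient"
        mean, sd = config.value_overrides.get(eid) or registry.get(eid).typical
        gpk = _tnorm(u[0], mean, sd)
        pkv_ms = math.sqrt(gpk / 4.0)
        vel_factor = 100.0 if registry.get(f"{group}_peak_velocity").canonical_unit == "cm/s" else 1.0
        out[f"{group}_peak_gradient"] = gpk
        out[f"{group}_mean_gradient"] = gpk * (0.5 + 0.2 * u[1])
        out[f"{group}_peak_velocity"] = pkv_ms * vel_factor
        out[f"{group}_mean_velocity"] = pkv_ms * (0.6 + 0.1 * u[2]) * vel_factor
    return out


def _sample_value(element: ElementSpec, config: SynthConfig,
                  group_vals: dict[str, float], u: float):
    if element.value_kind == "qualitative":
        vocab = element.categorical_vocab
        return vocab[min(int(u * len(vocab)), len(vocab) - 1)]
    if element.element_id in group_vals:
        return group_vals[element.element_id]
    mean, sd = (config.value_overrides.get(element.element_id)
                or element.typical or
                ((element.plausible_range[0] + element.plausible_range[1]) / 2,
                 (element.plausible_range[1] - element.plausible_range[0]) / 8))
    v = _tnorm(u, mean, sd)
    lo, hi = element.plausible_range
    return min(max(v, lo), hi)


# --------------------------------------------------------------------------
# rendering

def _fmt(v: float, spelling: str) -> str:
    nd = _DECIMALS.get(spelling, 1)
    return f"{v:.{nd}f}"


def _render_spelling(canonical: str) -> str:
    return {"mmHg": "mmhg", "cm^2": "cm2", "mm^2": "mm2", "m^2": "m2",
            "ml/m^2": "ml/m2"}.get(canonical, canonical)


@dataclass
class _Item:
    element_id: str
    style: str
    lines: list[str]          # one or more sentences/lines
    gold: GoldAnnotation
    structured_pair: str = "" # "LABEL: value unit" for structured chunking


def _insert_ellipsis(sentence: str, aux: np.random.Generator) -> str:
    """Insert a spurious dot run between two words where the next word does
    not start with a capital (so the run is pure noise, not a boundary)."""
    words = sentence.split(" ")
    gaps = [i for i in range(1, len(words))
            if words[i][:1].islower() or words[i][:1].isdigit()]
    if not gaps:
        return sentence
    g = gaps[int(aux.integers(0, len(gaps)))]
    run = ".." if aux.integers(0, 2) == 0 else "…"
    return " ".join(words[:g - 1] + [words[g - 1] + run] + words[g:])


def _typo(phrase: str, aux: np.random.Generator) -> str:
    """Single-character substitution inside the longest word of the phrase
    (never inside numerals)."""
    words = phrase.split(" ")
    wi = max(range(len(words)), key=lambda i: len(words[i]))
    word = words[wi]
    alpha = [i for i, ch in enumerate(word) if ch.isalpha()]
    if not alpha:
        return phrase
    ci = alpha[int(aux.integers(0, len(alpha)))]
    sub = "x" if word[ci].lower() != "x" else "q"
    words[wi] = word[:ci] + sub + word[ci + 1:]
    return " ".join(words)


def _capfirst(s: str) -> str:
    return s[:1].upper() + s[1:] if s else s


def _render_element(element: ElementSpec, report_id: str, value,
                    style: str, corruption: str | None, *,
                    as_range: bool, alt_unit: bool, coref: bool,
                    ellipsis: bool, aux: np.random.Generator) -> _Item:
    syn = element.synonyms[int(aux.integers(0, len(element.synonyms)))]
    label = element.synonyms[0].upper()
    canonical = element.canonical_unit
    corruptions: list[str] = []
    expected_extractable = True
    expected_kept = True

    if element.value_kind == "qualitative":
        token = str(value)
        gold_value: float | str | None = token
        if style == "structured":
            pair = f"{label}: {token}"
            lines = []
        elif style == "semi_structured":
            pair = ""
            lines = [f"{_capfirst(syn)}: {token}."]
        else:
            pair = ""
            if set(element.categorical_vocab) == {"present", "absent"}:
                lines = [f"{_capfirst(syn)} is {token}."]
            else:
                lines = [f"There is {token} {syn}."]
        rendered = token
        unit_text = ""
    else:
        spelling = _render_spelling(canonical)
        render_value = float(value)
        if alt_unit and canonical in _ALT_UNIT:
            spelling, nd = _ALT_UNIT[canonical]
            render_value = units.convert(render_value, canonical, spelling)
            num_text = f"{render_value:.{nd}f}"
        else:
            num_text = _fmt(render_value, spelling)
        rendered = num_text
        gold_raw = float(num_text)
        if as_range:
            nd = len(num_text.split(".")[1]) if "." in num_text else 0
            center = float(num_text)
            delta = max(round(0.1 * center, nd), 10.0 ** -nd)
            low, high = round(center - delta, nd), round(center + delta, nd)
            if low > 0 and low < high:
                joiner = str(aux.choice(["-", " to ", "–"]))
                rendered = f"{low:.{nd}f}{joiner}{high:.{nd}f}"
                gold_raw = (float(f"{low:.{nd}f}") + float(f"{high:.{nd}f}")) / 2.0
        gold_value = (units.convert(gold_raw, spelling, canonical)
                      if canonical and spelling else gold_raw)
        unit_text = spelling

        if corruption == "wrong_unit" and canonical:
            dim = units.dimension_of(canonical)
            unit_text = _WRONG_UNIT.get(dim, "mmhg")
            corruptions.append("wrong_unit")
            expected_kept = False
        elif corruption == "no_unit" and canonical:
            unit_text = ""
            corruptions.append("no_unit")
            expected_kept = False

        value_text = f"{rendered} {unit_text}".strip()
        if corruption == "deid":
            value_text = "[**Value (ValuePattern1)**]"
            corruptions.append("deid")
            expected_extractable = expected_kept = False
        elif corruption == "arrow":
            prior = _fmt(0.8 * float(num_text), unit_text or spelling)
            value_text = f"from {prior} {unit_text}--> {rendered} {unit_text}".strip()
            corruptions.append("arrow")
            expected_extractable = expected_kept = False
            style = "unstructured"

        if coref and corruption != "arrow":
            prefix, _, measure = element.element_id.partition("_")
            position = _VALVE_POSITION[prefix]
            phrase = _GENERIC_PHRASE[measure]
            if corruption == "typo":
                phrase = _typo(phrase, aux)
                corruptions.append("typo")
                expected_extractable = expected_kept = False
            lines = [
                f"A bioprosthetic valve is seen in the {position} position, "
                f"which is well seated.",
                f"The {phrase} across this valve is {value_text}.",
            ]
            pair = ""
            style = "unstructured"
        else:
            mention = syn
            if corruption == "typo":
                mention = _typo(mention, aux)
                corruptions.append("typo")
                expected_extractable = expected_kept = False
            if style == "structured" and corruption != "arrow":
                pair = f"{mention.upper()}: {value_text}"
                lines = []
            elif style == "semi_structured":
                pair = ""
                lines = [f"{_capfirst(mention)} = {value_text}."]
            else:
                pair = ""
                lines = [f"The {mention} is {value_text}."]

    if element.value_kind == "qualitative" and corruption in ("typo", "deid"):
        if corruption == "typo":
            corrupted = _typo(syn, aux)
            corruptions.append("typo")
            expected_extractable = expected_kept = False
            if pair:
                pair = f"{corrupted.upper()}: {value}"
            else:
                lines = [line.replace(syn, corrupted) for line in lines]
        else:
            corruptions.append("deid")
            expected_extractable = expected_kept = False
            marker = "[**Finding (FindingPattern1)**]"
            if pair:
                pair = f"{label}: {marker}"
            else:
                lines = [f"{_capfirst(syn)}: {marker}."]
            gold_value = None

    if ellipsis:
        corruptions.append("ellipsis")
        lines = [_insert_ellipsis(line, aux) for line in lines]

    gold = GoldAnnotation(
        report_id=report_id, element_id=element.element_id,
        value=gold_value, unit=canonical if element.is_quantitative else "",
        rendered=rendered, style=style, corruptions=tuple(corruptions),
        expected_extractable=expected_extractable,
        expected_kept=expected_kept and expected_extractable,
        via_coreference=coref,
    )
    return _Item(element.element_id, style, lines, gold, structured_pair=pair)


# --------------------------------------------------------------------------
# corpus generation

def generate(registry: Registry,
             config: SynthConfig) -> tuple[list[RawReport], list[GoldAnnotation]]:
    """Generate a seeded corpus plus its gold annotation list."""
    config.validate()
    seed = config.seed
    reports: list[RawReport] = []
    gold: list[GoldAnnotation] = []
    mix = np.cumsum(config.structure_mix)

    for i in range(config.n_reports):
        report_id = f"synth-{i:05d}"
        group_vals = _group_values(registry, config, seed, i)
        items: list[_Item] = []
        for j, element in enumerate(registry):
            rng = np.random.default_rng((seed, i, j))
            u = rng.random(12)
            aux = np.random.default_rng((seed, i, j, 7))
            if u[0] >= config.prevalence_of(element.element_id):
                continue
            value = _sample_value(element, config, group_vals, u[1])
            style = STYLES[int(np.searchsorted(mix, u[2], side="right"))]
            coref = bool(element.element_id in COREF_ELIGIBLE
                         and u[3] < config.coref_rate)
            as_range = bool(element.is_quantitative and not coref
                            and u[4] < config.range_rate)
            alt_unit = bool(element.is_quantitative and u[5] < config.alt_unit_rate)
            n = config.noise
            if u[10] < n.deid:
                corruption: str | None = "deid"
            elif u[11] < n.arrow and element.is_quantitative:
                corruption = "arrow"
            elif u[7] < n.typo:
                corruption = "typo"
            elif u[8] < n.wrong_unit and element.is_quantitative and element.canonical_unit:
                corruption = "wrong_unit"
            elif u[9] < n.no_unit and element.is_quantitative and element.canonical_unit:
                corruption = "no_unit"
            else:
                corruption = None
            ellipsis = bool(u[6] < n.ellipsis)
            item = _render_element(element, report_id, value, style, corruption,
                                   as_range=as_range, alt_unit=alt_unit,
                                   coref=coref, ellipsis=ellipsis, aux=aux)
            items.append(item)
            gold.append(item.gold)

        lines: list[str] = []
        pairs = [it.structured_pair for it in items if it.structured_pair]
        for k in range(0, len(pairs), 3):
            lines.append("  ".join(pairs[k:k + 3]))
        for it in items:
            lines.extend(it.lines)
        reports.append(RawReport(report_id=report_id, text="\n".join(lines),
                                 report_type="transthoracic"))
    return reports, gold


def write_gold(gold: list[GoldAnnotation], destination: str | Path) -> Path:
    destination = Path(destination)
    with destination.open("w") as fh:
        for g in gold:
            fh.write(json.dumps({
                "report_id": g.report_id, "element_id": g.element_id,
                "value": g.value, "unit": g.unit, "rendered": g.rendered,
                "style": g.style, "corruptions": list(g.corruptions),
                "expected_extractable": g.expected_extractable,
                "expected_kept": g.expected_kept,
                "via_coreference": g.via_coreference,
            }) + "\n")
    return destination


def read_gold(source: str | Path) -> list[GoldAnnotation]:
    out = []
    for line in Path(source).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        out.append(GoldAnnotation(
            report_id=d["report_id"], element_id=d["element_id"],
            value=d["value"], unit=d["unit"], rendered=d["rendered"],
            style=d["style"], corruptions=tuple(d["corruptions"]),
            expected_extractable=d["expected_extractable"],
            expected_kept=d["expected_kept"],
            via_coreference=d.get("via_coreference", False),
        ))
    return out
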