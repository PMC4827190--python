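"""Evidence-to-code rubrics: raw evidence -> integer criterion codes 1-5.

Nine criteria score each candidate technology.  Each criterion has a coding
table mapping evidence (a number, a qualitative level, or "unspecified") to
an integer code where 5 always means "more reason to prioritize" — note the
alternatives-availability table is deliberately inverted (scarce
alternatives score high).  The tables ship as editable JSON
(``data/rubrics.json``) so another agency's bands can be swapped in; band
edges are closed on their printed endpoints, and values falling in a gap
between printed bands resolve to the higher code.

Numeric band lists are ordered condition chains: the first condition
(``lt``/``le``/``gt``/``ge`` against a threshold) that holds fires; an
``else`` code catches the rest, and an ``unspecified`` code (where the
table defines one) is used when the evidence is absent.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, NamedTuple, Sequence

import numpy as np

from .errors import InvalidInputError
from .topsis import DecisionMatrix

__all__ = [
    "CLASS_TREATMENT",
    "CLASS_SCREENING",
    "CLASS_PREVENTION",
    "Coded",
    "Rubrics",
    "EvidenceProfile",
    "CodedDecisionRow",
    "default_rubrics",
    "code_effectiveness",
    "code_safety",
    "code_population_size",
    "code_vulnerable_share",
    "code_alternatives_availability",
    "code_evidence_quality",
    "code_cost_effectiveness",
    "code_budget_impact",
    "code_financial_protection",
    "build_decision_matrix",
]

CLASS_TREATMENT = "treatment"  # treatment / rehabilitation technologies
CLASS_SCREENING = "screening"  # screening / diagnosis technologies
CLASS_PREVENTION = "prevention"

_OPS = {
    "lt": lambda x, t: x < t,
    "le": lambda x, t: x <= t,
    "gt": lambda x, t: x > t,
    "ge": lambda x, t: x >= t,
}


class Coded(NamedTuple):
    """An assigned code plus the band/label that produced it."""

    code: int
    band: str


def _canon_label(label: str) -> str:
    """Lowercase, drop parentheticals, collapse separators.

    Lets the long printed wordings ("Relatively safe (mild and slight side
    effects)") match their canonical short keys.
    """
    s = re.sub(r"\([^)]*\)", " ", str(label)).lower()
    s = re.sub(r"[_\-]+", " ", s)
    return re.sub(r"\s+", " ", s).strip()


def _eval_bands(x: float, bands: Sequence[dict], else_code: int) -> Coded:
    for band in bands:
        if _OPS[band["op"]](x, band["value"]):
            return Coded(int(band["code"]), f"{band['op']} {band['value']}")
    return Coded(int(else_code), "else")


def _match_prefix(label: str, levels: dict[str, int], what: str) -> Coded:
    canon = _canon_label(label)
    for key in sorted(levels, key=len, reverse=True):
        if canon.startswith(key):
            return Coded(int(levels[key]), key)
    raise InvalidInputError(
        f"unrecognized {what} level {label!r}; expected one of {sorted(levels)}"
    )


def _check_percent(x: float, what: str) -> float:
    x = float(x)
    if not np.isfinite(x) or not 0.0 <= x <= 100.0:
        raise InvalidInputError(f"{what} must be a percentage in [0, 100], got {x}")
    return x


@dataclass(frozen=True)
class Rubrics:
    """The full set of coding tables, loaded from a JSON configuration."""

    config: dict[str, Any]

    @classmethod
    def load_default(cls) -> "Rubrics":
        text = resources.files("htaprio").joinpath("data/rubrics.json").read_text()
        return cls(json.loads(text))

    @classmethod
    def from_file(cls, path) -> "Rubrics":
        with open(path) as fh:
            return cls(json.load(fh))

    @property
    def criteria_order(self) -> tuple[str, ...]:
        return tuple(self.config["criteria_order"])

    # --- efficiency / effectiveness (class-specific) -----------------------

    def code_effectiveness(self, technology_class: str, descriptor: Any) -> Coded:
        """Class-specific effectiveness coding.

        treatment: one of the five clinical-benefit labels.
        screening: mapping/tuple with accuracy (%) and a treatable flag.
        prevention: prevention effectiveness in percent.
        """
        cfg = self.config["efficiency_effectiveness"]
        cls_ = _canon_label(technology_class).split()[0]
        if cls_ in ("treatment", "rehabilitation"):
            if not isinstance(descriptor, str):
                raise InvalidInputError(
                    "treatment effectiveness expects a clinical-benefit label, "
                    f"got {descriptor!r}"
                )
            labels = {_canon_label(k): v for k, v in cfg["treatment_labels"].items()}
            canon = _canon_label(descriptor)
            if canon not in labels:
                raise InvalidInputError(
                    f"unrecognized clinical-benefit label {descriptor!r}"
                )
            return Coded(int(labels[canon]), canon)
        if cls_ == "screening":
            if isinstance(descriptor, dict):
                acc, treatable = descriptor.get("accuracy"), descriptor.get("treatable")
            else:
                try:
                    acc, treatable = descriptor
                except (TypeError, ValueError):
                    raise InvalidInputError(
                        "screening effectiveness expects (accuracy %, treatable flag), "
                        f"got {descriptor!r}"
                    ) from None
            if acc is None or treatable is None:
                raise InvalidInputError(
                    "screening effectiveness needs both accuracy and treatable"
                )
            acc = _check_percent(acc, "screening accuracy")
            hi, lo = cfg["screening"]["high_accuracy"], cfg["screening"]["low_accuracy"]
            treatable = bool(treatable)
            if acc > hi:
                return Coded(5 if treatable else 3, f"accuracy > {hi}")
            if acc >= lo:
                return Coded(4 if treatable else 2, f"{lo} <= accuracy <= {hi}")
            # the printed table leaves accuracy < 60 with an untreatable
            # disease unmapped; both low-accuracy cases fall to code 1
            return Coded(1, f"accuracy < {lo}" + ("" if treatable else " (gap: untreatable)"))
        if cls_ == "prevention":
            pct = _check_percent(descriptor, "prevention effectiveness")
            return self._banded("efficiency_effectiveness", pct,
                                cfg["prevention_bands"], cfg["prevention_else"])
        raise InvalidInputError(
            f"unknown technology class {technology_class!r}; expected "
            "treatment/rehabilitation, screening/diagnosis, or prevention"
        )

    def _banded(self, criterion: str, x: float, bands, else_code) -> Coded:
        return _eval_bands(float(x), bands, else_code)

    # --- single-criterion rubrics -----------------------------------------

    def code_safety(self, incidence: float | None = None,
                    level: str | None = None) -> Coded:
        """Adverse-event coding; numeric incidence (%) takes precedence over
        the qualitative label when both are given."""
        cfg = self.config["safety"]
        if incidence is not None:
            x = _check_percent(incidence, "side-effect incidence")
            return _eval_bands(x, cfg["bands"], cfg["else"])
        if level is not None:
            levels = {_canon_label(k): v for k, v in cfg["levels"].items()}
            return _match_prefix(level, levels, "safety")
        raise InvalidInputError("safety evidence is required (no unspecified band)")

    def code_population_size(self, n: float) -> Coded:
        cfg = self.config["population_size"]
        n = float(n)
        if not np.isfinite(n) or n < 0:
            raise InvalidInputError(f"population size must be >= 0, got {n}")
        return _eval_bands(n, cfg["bands"], cfg["else"])

    def code_vulnerable_share(self, share: float | None) -> Coded:
        cfg = self.config["vulnerable_population"]
        if share is None:
            return Coded(int(cfg["unspecified"]), "unspecified")
        x = _check_percent(share, "vulnerable share")
        return _eval_bands(x, cfg["bands"], cfg["else"])

    def code_alternatives_availability(self, level: str) -> Coded:
        levels = {_canon_label(k): v
                  for k, v in self.config["alternatives_availability"]["levels"].items()}
        return _match_prefix(level, levels, "alternatives-availability")

    def code_evidence_quality(self, category: str) -> Coded:
        cats = {_canon_label(k): v
                for k, v in self.config["evidence_quality"]["categories"].items()}
        canon = _canon_label(category)
        if canon not in cats:
            raise InvalidInputError(
                f"unrecognized evidence-quality category {category!r}; "
                f"expected one of {sorted(cats)}"
            )
        return Coded(int(cats[canon]), canon)

    def code_cost_effectiveness(self, icer: float | None = None,
                                gdp_per_capita: float | None = None) -> Coded:
        """Bands on the ICER / GDP-per-capita ratio; unspecified evidence has
        its own code (the table treats missing economic evidence as lowest)."""
        cfg = self.config["cost_effectiveness"]
        if icer is None:
            return Coded(int(cfg["unspecified"]), "unspecified")
        if gdp_per_capita is None or float(gdp_per_capita) <= 0:
            raise InvalidInputError(
                "a positive GDP per capita is required alongside a specified ICER"
            )
        if float(icer) < 0:
            raise InvalidInputError(f"ICER must be >= 0, got {icer}")
        ratio = float(icer) / float(gdp_per_capita)
        coded = _eval_bands(ratio, cfg["bands"], cfg["else"])
        return Coded(coded.code, f"ratio {ratio:.4g}: {coded.band}")

    def code_budget_impact(self, level: str | None) -> Coded:
        cfg = self.config["budget_impact"]
        if level is None:
            return Coded(int(cfg["unspecified"]), "unspecified")
        levels = {_canon_label(k): v for k, v in cfg["levels"].items()}
        return _match_prefix(level, levels, "budget-impact")

    def code_financial_protection(self, prob: float | None) -> Coded:
        cfg = self.config["financial_protection"]
        if prob is None:
            return Coded(int(cfg["unspecified"]), "unspecified")
        x = _check_percent(prob, "financial-protection probability")
        return _eval_bands(x, cfg["bands"], cfg["else"])


_DEFAULT: Rubrics | None = None


def default_rubrics() -> Rubrics:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = Rubrics.load_default()
    return _DEFAULT


# Convenience module-level functions over the shipped configuration.

def code_effectiveness(technology_class: str, descriptor) -> int:
    return default_rubrics().code_effectiveness(technology_class, descriptor).code


def code_safety(incidence: float | None = None, level: str | None = None) -> int:
    return default_rubrics().code_safety(incidence, level).code


def code_population_size(n: float) -> int:
    return default_rubrics().code_population_size(n).code


def code_vulnerable_share(share: float | None) -> int:
    return default_rubrics().code_vulnerable_share(share).code


def code_alternatives_availability(level: str) -> int:
    return default_rubrics().code_alternatives_availability(level).code


def code_evidence_quality(category: str) -> int:
    return default_rubrics().code_evidence_quality(category).code


def code_cost_effectiveness(icer: float | None = None,
                            gdp_per_capita: float | None = None) -> int:
    return default_rubrics().code_cost_effectiveness(icer, gdp_per_capita).code


def code_budget_impact(level: str | None) -> int:
    return default_rubrics().code_budget_impact(level).code


def code_financial_protection(prob: float | None) -> int:
    return default_rubrics().code_financial_protection(prob).code


@dataclass(frozen=True)
class EvidenceProfile:
    """Raw per-criterion evidence for one technology.

    ``effectiveness`` is class-specific: a clinical-benefit label
    (treatment/rehabilitation), an ``{"accuracy": %, "treatable": bool}``
    mapping (screening/diagnosis), or a prevention effectiveness percent.
    ``None`` marks evidence as unspecified where the rubric defines an
    unspecified band; safety has none, so either a numeric incidence or a
    qualitative safety level is mandatory.
    """

    technology_id: str
    technology_class: str
    effectiveness: Any
    target_population: float
    alternatives_availability: str
    evidence_quality: str
    safety_incidence: float | None = None
    safety_level: str | None = None
    vulnerable_share: float | None = None
    icer: float | None = None
    gdp_per_capita: float | None = None
    budget_impact: str | None = None
    financial_protection: float | None = None

    def to_dict(self) -> dict:
        return {
            "technology_id": self.technology_id,
            "technology_class": self.technology_class,
            "effectiveness": self.effectiveness,
            "safety_incidence": self.safety_incidence,
            "safety_level": self.safety_level,
            "target_population": self.target_population,
            "vulnerable_share": self.vulnerable_share,
            "alternatives_availability": self.alternatives_availability,
            "evidence_quality": self.evidence_quality,
            "icer": self.icer,
            "gdp_per_capita": self.gdp_per_capita,
            "budget_impact": self.budget_impact,
            "financial_protection": self.financial_protection,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvidenceProfile":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise InvalidInputError(f"unknown evidence profile field(s) {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class CodedDecisionRow:
    """One technology's codes over the configured criteria, with the band
    that fired for each criterion."""

    technology_id: str
    criteria: tuple[str, ...]
    codes: tuple[int, ...]
    provenance: dict[str, str] = field(compare=False)


def code_profile(profile: EvidenceProfile,
                 rubrics: Rubrics | None = None) -> CodedDecisionRow:
    """Run every rubric on one evidence profile."""
    rb = rubrics or default_rubrics()
    coded: dict[str, Coded] = {
        "efficiency_effectiveness": rb.code_effectiveness(
            profile.technology_class, profile.effectiveness),
        "safety": rb.code_safety(profile.safety_incidence, profile.safety_level),
        "population_size": rb.code_population_size(profile.target_population),
        "vulnerable_population": rb.code_vulnerable_share(profile.vulnerable_share),
        "alternatives_availability": rb.code_alternatives_availability(
            profile.alternatives_availability),
        "cost_effectiveness": rb.code_cost_effectiveness(
            profile.icer, profile.gdp_per_capita),
        "budget_impact": rb.code_budget_impact(profile.budget_impact),
        "financial_protection": rb.code_financial_protection(
            profile.financial_protection),
        "evidence_quality": rb.code_evidence_quality(profile.evidence_quality),
    }
    order = rb.criteria_order
    missing = set(order) - set(coded)
    if missing:
        raise InvalidInputError(f"no rubric implementation for criteria {sorted(missing)}")
    return CodedDecisionRow(
        technology_id=profile.technology_id,
        criteria=order,
        codes=tuple(coded[c].code for c in order),
        provenance={c: coded[c].band for c in order},
    )


def build_decision_matrix(profiles: Sequence[EvidenceProfile],
                          rubrics: Rubrics | None = None) -> DecisionMatrix:
    """Code every profile and assemble the alternatives x criteria matrix.

    An empty profile list yields an empty (0 x 9) matrix.
    """
    rb = rubrics or default_rubrics()
    rows = [code_profile(p, rb) for p in profiles]
    order = rb.criteria_order
    return DecisionMatrix(
        alternatives=tuple(r.technology_id for r in rows),
        criteria=order,
        values=np.array([r.codes for r in rows], dtype=float).reshape(len(rows), len(order)),
    )
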