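"""Characterization stage: deterministic persona construction.

A persona is structured data, not prose: the score table of the records
matching a conjunction of demographic selectors, summarized as a top
attribute, a secondary attribute, and the two lowest-priority
attributes, with a templated name "<Top attribute> Focused <descriptor>".
Persona construction is a pure function of (dataset, rule).

The default rule set encodes the four archetypes of the published
characterization: a retired married female (spiritual well-being
focused), a full-time single male (economic opportunity seeking), a
working single female with lower education (health care focused), and
an unemployed single with lower education (food security focused).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import FrozenSet, List, Mapping, Optional, Tuple, Union

import yaml

from .errors import InsufficientSupportError
from .schema import DEFAULT_SCHEMA, LOW_EDUCATION, DemographicSchema
from .scoring import BWSScoreTable, score_table
from .survey import Dataset, RespondentRecord

__all__ = [
    "PersonaRule",
    "Persona",
    "GalleryResult",
    "build_persona",
    "persona_gallery",
    "default_persona_rules",
    "rules_from_yaml",
]

SelectorValue = Union[str, FrozenSet[str]]


@dataclass(frozen=True)
class PersonaRule:
    """Conjunction of demographic (variable -> allowed categories) pairs."""

    selector: Mapping[str, SelectorValue]
    min_n: int = 10
    descriptor: Optional[str] = None  # None: derive from selector; "": empty

    def __post_init__(self):
        if not self.selector:
            raise ValueError("selector must not be empty")
        norm = {var: (frozenset(val) if not isinstance(val, str) else frozenset([val]))
                for var, val in self.selector.items()}
        object.__setattr__(self, "selector", MappingProxyType(norm))

    def matches(self, record: RespondentRecord) -> bool:
        return all(record.demographic(var) in allowed
                   for var, allowed in self.selector.items())

    def describe(self, schema: DemographicSchema = DEFAULT_SCHEMA) -> str:
        if self.descriptor is not None:
            return self.descriptor
        parts = []
        for var, allowed in self.selector.items():
            labels = sorted(schema[var].label(t) if var in schema else t
                            for t in allowed)
            parts.append("/".join(labels))
        return " ".join(parts)

    def selector_as_lists(self) -> dict:
        return {var: sorted(allowed) for var, allowed in self.selector.items()}


@dataclass(frozen=True)
class Persona:
    name: str
    rule: PersonaRule
    n: int
    top_attribute: str
    secondary_attribute: str
    low_priority_attributes: Tuple[str, str]  # ascending B-W: lowest first
    scores: BWSScoreTable
    tie_flag: bool = False

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "selector": self.rule.selector_as_lists(),
            "n": self.n,
            "top_attribute": self.top_attribute,
            "secondary_attribute": self.secondary_attribute,
            "low_priority_attributes": list(self.low_priority_attributes),
            "tie_flag": self.tie_flag,
            "weights": {r.attribute_id: r.weight for r in self.scores.rows},
            "bw": {r.attribute_id: r.bw for r in self.scores.rows},
        }


@dataclass(frozen=True)
class GalleryResult:
    personas: Tuple[Persona, ...]
    skipped: Tuple[Tuple[PersonaRule, str], ...] = ()


def build_persona(dataset: Dataset, rule: PersonaRule) -> Persona:
    """Score the records matching the rule and summarize them as a persona."""
    matched = [r for r in dataset.records if rule.matches(r)]
    if len(matched) < rule.min_n:
        raise InsufficientSupportError(
            f"selector matched {len(matched)} records, below min_n={rule.min_n}",
            n_matched=len(matched))
    table = score_table(dataset.subset(matched))
    ordered = table.by_rank()
    top, secondary = ordered[0], ordered[1]
    low = (ordered[-1].attribute_id, ordered[-2].attribute_id)
    descriptor = rule.describe(dataset.schema)
    name = f"{top.label} Focused {descriptor}".strip()
    return Persona(name=name, rule=rule, n=len(matched),
                   top_attribute=top.attribute_id,
                   secondary_attribute=secondary.attribute_id,
                   low_priority_attributes=low, scores=table,
                   tie_flag=top.bw == ordered[1].bw)


def persona_gallery(dataset: Dataset, rules) -> GalleryResult:
    """Build one persona per rule; under-supported rules are skipped, not fatal."""
    personas: List[Persona] = []
    skipped = []
    for rule in rules:
        try:
            personas.append(build_persona(dataset, rule))
        except InsufficientSupportError as err:
            skipped.append((rule, f"insufficient support (matched {err.n_matched})"))
    return GalleryResult(tuple(personas), tuple(skipped))


def default_persona_rules(min_n: int = 10) -> Tuple[PersonaRule, ...]:
    """The four published persona selectors."""
    return (
        PersonaRule({"employment": "retired", "relationship": "married_cohab",
                     "gender": "female"}, min_n=min_n, descriptor="Retired Female"),
        PersonaRule({"employment": "full_time", "relationship": "single",
                     "gender": "male"}, min_n=min_n, descriptor="Working Single Male"),
        PersonaRule({"employment": "full_time", "relationship": "single",
                     "gender": "female", "education": LOW_EDUCATION},
                    min_n=min_n, descriptor="Working Single Female"),
        PersonaRule({"employment": "unemployed", "relationship": "single",
                     "education": LOW_EDUCATION},
                    min_n=min_n, descriptor="Unemployed Single"),
    )


def rules_from_yaml(path) -> Tuple[PersonaRule, ...]:
    """Load persona rules from a YAML list of {selector, min_n, descriptor}."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    rules = []
    for item in raw:
        selector = {var: (val if isinstance(val, str) else frozenset(val))
                    for var, val in item["selector"].items()}
        rules.append(PersonaRule(selector, min_n=int(item.get("min_n", 10)),
                                 descriptor=item.get("descriptor", "")))
    return tuple(rules)
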