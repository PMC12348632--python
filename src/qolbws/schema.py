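"""Demographic schema: variables, category order, merge maps.

The sentinel category ``PNR`` ("prefer not to respond" or missing) is a
first-class reporting category — descriptive tables print it as
"PNR or missing" — but it is excluded from segment-level inference.

Merge maps encode reporting-time category folds, e.g. the young-adult
age band is absorbed into adults for segmentation because too few young
adults were interviewed to stand as their own segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Tuple

__all__ = [
    "PNR",
    "PNR_LABEL",
    "Variable",
    "DemographicSchema",
    "DEFAULT_SCHEMA",
    "LOW_EDUCATION",
    "EDUCATED",
]

PNR = "PNR"
PNR_LABEL = "PNR or missing"


@dataclass(frozen=True)
class Variable:
    """One demographic variable with its ordered categories."""

    name: str
    categories: Tuple[Tuple[str, str], ...]  # (token, display label)
    merge_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "merge_map", MappingProxyType(dict(self.merge_map)))

    @property
    def tokens(self) -> Tuple[str, ...]:
        return tuple(t for t, _ in self.categories)

    def label(self, token: str) -> str:
        if token == PNR:
            return PNR_LABEL
        for t, lbl in self.categories:
            if t == token:
                return lbl
        return token  # unknown categories are preserved verbatim

    def merged(self, token: str) -> str:
        return self.merge_map.get(token, token)


@dataclass(frozen=True)
class DemographicSchema:
    variables: Tuple[Variable, ...]

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)


DEFAULT_SCHEMA = DemographicSchema(
    (
        Variable(
            "gender",
            (("female", "Female"), ("male", "Male")),
        ),
        Variable(
            "age_group",
            (
                ("young", "Young Adults (18-24)"),
                ("adults", "Adults (25-54)"),
                ("early_seniors", "Early Seniors (55-64)"),
                ("seniors", "Seniors (65+)"),
            ),
            merge_map={"young": "adults"},
        ),
        Variable(
            "race",
            (
                ("native", "American Indian or Alaska Native"),
                ("black", "Black or African American"),
                ("white", "White"),
            ),
        ),
        Variable(
            "education",
            (
                ("masters_plus", "Master's degree or higher"),
                ("bachelors", "Bachelor's degree"),
                ("associates", "Associate's degree"),
                ("some_college", "Some college but did not complete degree"),
                ("high_school", "High school graduate or GED completed"),
                ("some_high_school", "Some high school"),
            ),
        ),
        Variable(
            "relationship",
            (
                ("married_cohab", "Married and living with spouse"),
                ("married_apart", "Married and not living with spouse"),
                ("single", "Not in a committed relationship (i.e., single)"),
                ("partnered", "Not married but in a committed relationship"),
                ("not_sure", "Not sure"),
            ),
        ),
        Variable(
            "employment",
            (
                ("full_time", "Working full time, 35 h/week or more"),
                ("part_time", "Working part-time, less than 35 h/week"),
                ("retired", "Retired"),
                ("stay_home", "A full-time stay-at-home parent"),
                ("unemployed", "Unemployed"),
                ("disabled", "Disabled, not able to work"),
            ),
        ),
    )
)

# Education groupings used by persona selectors. "Educated" reads as a
# completed four-year degree or more; "low education" as no completed
# degree (associate's holders fall in neither bucket). Overridable in
# persona rule configs.
LOW_EDUCATION = frozenset({"some_college", "high_school", "some_high_school"})
EDUCATED = frozenset({"bachelors", "masters_plus"})
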