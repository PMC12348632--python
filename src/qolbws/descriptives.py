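"""Identification stage: descriptive tables and sampling-design arithmetic.

The published demographic table mixes two denominator conventions:
gender is tabulated over the 208 respondents who answered it, while
every other variable is tabulated over all rows including "PNR or
missing". It also mixes printed precisions (gender and age at two
decimals, the rest at one, zero-padded). ``REPORT_CONVENTIONS`` encodes
both so the printed percentages regenerate without hidden magic.

Sample-size design uses the standard normal-approximation proportion
formula n = ceil(z^2 p(1-p) / e^2); at 95% confidence and a 6% margin it
gives 267, below the 280 completed interviews, and the achieved margin
at the 213 valid responses is ~6.7% — "slightly" above the design
target, as the survey narrative states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import pandas as pd
from scipy.stats import norm

from .errors import SchemaError
from .rounding import round_half_away
from .schema import PNR, PNR_LABEL
from .survey import Dataset

__all__ = [
    "DescriptiveTable",
    "descriptive_table",
    "tabulate",
    "REPORT_CONVENTIONS",
    "identification_report",
    "SampleSizeSpec",
    "required_sample_size",
    "achieved_margin",
]

_PNR_KEYS = {PNR, PNR_LABEL}


@dataclass(frozen=True)
class DescriptiveTable:
    """Category counts and percentages for one demographic variable."""

    variable: str
    rows: Tuple[Tuple[str, int, float], ...]  # (category label, count, percent)
    denominator: int
    denominator_mode: str  # "all_rows" | "nonmissing_only"
    decimals: int = 2

    def percent(self, category: str) -> float:
        for cat, _, pct in self.rows:
            if cat == category:
                return pct
        raise KeyError(category)

    def count(self, category: str) -> int:
        for cat, cnt, _ in self.rows:
            if cat == category:
                return cnt
        raise KeyError(category)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.rows), columns=["Category", "Count", "Percent"])

    def metadata(self) -> dict:
        return {"variable": self.variable, "denominator": self.denominator,
                "denominator_mode": self.denominator_mode, "decimals": self.decimals}


def descriptive_table(variable: str, counts: Mapping[str, int], *,
                      denominator_mode: str = "all_rows", decimals: int = 2,
                      denominator: Optional[int] = None) -> DescriptiveTable:
    """Build a DescriptiveTable from an ordered category -> count mapping.

    Under ``all_rows`` every category (including PNR) is a row and the
    denominator defaults to the sum of all counts; under
    ``nonmissing_only`` PNR rows are dropped from both the table and the
    denominator. An explicit ``denominator`` overrides the default —
    needed to represent published tables whose rows do not exhaust the
    stated denominator.
    """
    if denominator_mode not in ("all_rows", "nonmissing_only"):
        raise ValueError(f"unknown denominator_mode: {denominator_mode!r}")
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    entries = [(cat, cnt) for cat, cnt in counts.items()
               if denominator_mode == "all_rows" or cat not in _PNR_KEYS]
    denom = denominator if denominator is not None else sum(c for _, c in entries)
    if denom < 0 or (denom == 0 and any(c > 0 for _, c in entries)):
        raise ValueError("denominator must be positive")
    rows = tuple((cat, cnt,
                  0.0 if denom == 0 else round_half_away(100.0 * cnt / denom, decimals))
                 for cat, cnt in entries)
    return DescriptiveTable(variable, rows, denom, denominator_mode, decimals)


def tabulate(dataset: Dataset, variable: str,
             denominator_mode: str = "all_rows", decimals: int = 2) -> DescriptiveTable:
    """Tabulate one demographic variable of a dataset.

    Rows cover observed categories in the schema's declared order (with
    unknown categories appended in first-seen order and PNR last).
    """
    if variable not in dataset.schema:
        raise SchemaError(f"unknown demographic variable: {variable!r}")
    var = dataset.schema[variable]
    observed: dict = {}
    for rec in dataset.records:
        token = rec.demographic(variable)
        observed[token] = observed.get(token, 0) + 1
    ordered: dict = {}
    for token in var.tokens:
        if token in observed:
            ordered[var.label(token)] = observed.pop(token)
    pnr = observed.pop(PNR, None)
    for token, cnt in observed.items():  # unknown categories, verbatim
        ordered[token] = cnt
    if pnr is not None:
        ordered[PNR_LABEL] = pnr
    return descriptive_table(variable, ordered,
                             denominator_mode=denominator_mode, decimals=decimals)


# Published-table conventions: (denominator_mode, printed decimals).
REPORT_CONVENTIONS = {
    "gender": ("nonmissing_only", 2),
    "age_group": ("all_rows", 2),
    "race": ("all_rows", 1),
    "education": ("all_rows", 1),
    "relationship": ("all_rows", 1),
    "employment": ("all_rows", 1),
}


def identification_report(dataset: Dataset, conventions=None) -> dict:
    """Descriptive tables for every schema variable under the report preset."""
    conventions = conventions or REPORT_CONVENTIONS
    out = {}
    for name in dataset.schema.names:
        mode, decimals = conventions.get(name, ("all_rows", 2))
        out[name] = tabulate(dataset, name, denominator_mode=mode, decimals=decimals)
    return out


@dataclass(frozen=True)
class SampleSizeSpec:
    """Design inputs for a proportion estimate: p, confidence, margin."""

    p: float = 0.5
    confidence: float = 0.95
    margin: float = 0.06
    z: Optional[float] = None

    def __post_init__(self):
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if not 0 < self.margin < 1:
            raise ValueError("margin must be in (0, 1)")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        if self.z is not None and self.z <= 0:
            raise ValueError("z must be positive")

    def z_value(self) -> float:
        return self.z if self.z is not None else float(norm.ppf((1 + self.confidence) / 2))

    def required_n(self) -> int:
        return required_sample_size(self.p, self.confidence, self.margin, z=self.z)


def required_sample_size(p: float = 0.5, confidence: float = 0.95,
                         margin: float = 0.06, z: Optional[float] = None) -> int:
    """ceil(z^2 p(1-p) / e^2) for an unbounded population."""
    spec = SampleSizeSpec(p=p, confidence=confidence, margin=margin, z=z)
    zv = spec.z_value()
    return int(math.ceil(zv * zv * spec.p * (1 - spec.p) / (spec.margin ** 2)))


def achieved_margin(n: int, p: float = 0.5, confidence: float = 0.95,
                    z: Optional[float] = None) -> float:
    """Half-width z*sqrt(p(1-p)/n) actually attained at sample size n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    zv = z if z is not None else float(norm.ppf((1 + confidence) / 2))
    return zv * math.sqrt(p * (1 - p) / n)
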