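"""Respondent records, delimited-text I/O, and response cleaning.

A raw survey file has one row per respondent: an id column, the best and
worst attribute picks, and one column per demographic variable. Reading
is non-destructive — malformed choices are carried through and flagged
only by :func:`clean`, which removes records under exactly one reason
each (the report is a partition of the removed rows):

1. ``incomplete_choice``   — best or worst missing
2. ``unknown_attribute``   — best or worst not in the attribute set
3. ``contradictory_choice`` — best == worst
4. ``duplicate_respondent`` — repeated id (first occurrence kept)

Demographic ``PNR`` values are never grounds for removal; the published
descriptive table retains its "PNR or missing" rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping, Optional, Tuple

import pandas as pd

from .attributes import DEFAULT_ATTRIBUTES, AttributeSet
from .errors import EmptyAnalysisError, SchemaError
from .schema import DEFAULT_SCHEMA, PNR, DemographicSchema

__all__ = [
    "RespondentRecord",
    "Dataset",
    "CleaningReport",
    "REMOVAL_REASONS",
    "read_responses",
    "write_dataset",
    "clean",
]

REMOVAL_REASONS = (
    "incomplete_choice",
    "unknown_attribute",
    "contradictory_choice",
    "duplicate_respondent",
)


@dataclass(frozen=True)
class RespondentRecord:
    """One survey answer: best pick, worst pick, demographics."""

    respondent_id: str
    best: Optional[str]
    worst: Optional[str]
    demographics: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "demographics", MappingProxyType(dict(self.demographics)))

    def demographic(self, variable: str) -> str:
        return self.demographics.get(variable, PNR)


@dataclass(frozen=True)
class Dataset:
    """An attribute set plus respondent records and their provenance."""

    attributes: AttributeSet
    schema: DemographicSchema
    records: Tuple[RespondentRecord, ...]
    provenance: str = ""

    @property
    def n(self) -> int:
        return len(self.records)

    def subset(self, records) -> "Dataset":
        return replace(self, records=tuple(records))

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"respondent_id": [r.respondent_id for r in self.records],
                "best": [r.best or "" for r in self.records],
                "worst": [r.worst or "" for r in self.records]}
        for name in self.schema.names:
            cols[name] = [r.demographic(name) for r in self.records]
        return pd.DataFrame(cols, dtype=str)


@dataclass(frozen=True)
class CleaningReport:
    n_raw: int
    n_valid: int
    removed_by_reason: Mapping[str, int]

    def __post_init__(self):
        object.__setattr__(self, "removed_by_reason", MappingProxyType(dict(self.removed_by_reason)))
        if self.n_raw != self.n_valid + sum(self.removed_by_reason.values()):
            raise ValueError("cleaning report does not reconcile: "
                             f"{self.n_raw} != {self.n_valid} + removed")
        if self.n_valid < 0 or any(v < 0 for v in self.removed_by_reason.values()):
            raise ValueError("counts must be non-negative")

    def to_dict(self) -> dict:
        return {"n_raw": self.n_raw, "n_valid": self.n_valid,
                "removed_by_reason": dict(self.removed_by_reason)}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_responses(path, schema: DemographicSchema = DEFAULT_SCHEMA,
                   attributes: AttributeSet = DEFAULT_ATTRIBUTES,
                   delimiter: str = ",") -> Dataset:
    """Read a delimited survey file into a Dataset (non-destructively).

    Blank demographic cells become the ``PNR`` sentinel; blank best/worst
    cells become missing. Unknown attribute tokens and demographic
    categories are preserved verbatim for the cleaner / tabulator.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, sep=delimiter)
    required = ["respondent_id", "best", "worst", *schema.names]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        demo = {name: (d[name].strip() or PNR) for name in schema.names}
        records.append(RespondentRecord(
            respondent_id=d["respondent_id"].strip(),
            best=d["best"].strip() or None,
            worst=d["worst"].strip() or None,
            demographics=demo,
        ))
    return Dataset(attributes, schema, tuple(records), provenance=str(path))


def write_dataset(dataset: Dataset, path, delimiter: str = ",") -> None:
    """Write a Dataset as delimited text that round-trips losslessly."""
    dataset.to_dataframe().to_csv(path, index=False, sep=delimiter)


def clean(dataset: Dataset):
    """Apply the response-cleaning rules.

    Returns ``(cleaned_dataset, CleaningReport)``. Idempotent, and the
    report partitions the input: ``n_raw = n_valid + sum(removed)``.
    Raises :class:`EmptyAnalysisError` if nothing survives.
    """
    removed = {reason: 0 for reason in REMOVAL_REASONS}
    seen_ids = set()
    valid = []
    for rec in dataset.records:
        if rec.best is None or rec.worst is None:
            removed["incomplete_choice"] += 1
        elif rec.best not in dataset.attributes or rec.worst not in dataset.attributes:
            removed["unknown_attribute"] += 1
        elif rec.best == rec.worst:
            removed["contradictory_choice"] += 1
        elif rec.respondent_id in seen_ids:
            removed["duplicate_respondent"] += 1
        else:
            seen_ids.add(rec.respondent_id)
            valid.append(rec)
    if not valid:
        raise EmptyAnalysisError("no valid records remain after cleaning")
    report = CleaningReport(n_raw=dataset.n, n_valid=len(valid), removed_by_reason=removed)
    return dataset.subset(valid), report
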