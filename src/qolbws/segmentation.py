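"""Segmentation stage: per-subgroup score tables and chi-square contrasts.

Each non-PNR category of a demographic variable is a segment (after the
schema's merge map folds under-sized bands, e.g. young adults into
adults). Segment preferences are contrasted with a chi-square test of
independence on the segment x best-choice contingency table — best
counts are non-negative integers with fixed margins, unlike B-W scores,
which are not valid chi-square inputs. No continuity correction is
applied; attributes nobody picked are dropped (df adjusts); a flag marks
tables with any expected cell below 5. No multiple-testing correction is
applied across variables by default; a Bonferroni helper is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .errors import DegenerateTableError, EmptySegmentationError, SchemaError
from .schema import PNR
from .scoring import BWSScoreTable, score_table
from .survey import Dataset, RespondentRecord

__all__ = [
    "SegmentProfile",
    "SegmentComparison",
    "segment_scores",
    "compare_segments",
    "significance_label",
    "bonferroni",
]


@dataclass(frozen=True)
class SegmentProfile:
    variable: str
    category: str  # merged category token
    label: str
    n: int
    scores: BWSScoreTable


@dataclass(frozen=True)
class SegmentComparison:
    variable: str
    contingency: pd.DataFrame  # segments x attributes, best-choice counts
    statistic: float
    df: int
    p_value: float
    low_expected_flag: bool


def _split(dataset: Dataset, variable: str) -> Dict[str, List[RespondentRecord]]:
    """Group records by merged non-PNR category, schema order first."""
    if variable not in dataset.schema:
        raise SchemaError(f"unknown demographic variable: {variable!r}")
    var = dataset.schema[variable]
    groups: Dict[str, List[RespondentRecord]] = {}
    declared = [var.merged(t) for t in var.tokens]
    for token in dict.fromkeys(declared):  # deduplicated, in order
        groups[token] = []
    for rec in dataset.records:
        token = var.merged(rec.demographic(variable))
        if token == PNR:
            continue
        groups.setdefault(token, []).append(rec)
    return {t: recs for t, recs in groups.items() if recs}


def segment_scores(dataset: Dataset, variable: str,
                   min_segment_n: int = 10) -> Tuple[SegmentProfile, ...]:
    """One score-table profile per segment with n >= min_segment_n."""
    var = dataset.schema[variable] if variable in dataset.schema else None
    if var is None:
        raise SchemaError(f"unknown demographic variable: {variable!r}")
    groups = _split(dataset, variable)
    profiles = []
    for token, recs in groups.items():
        if len(recs) < min_segment_n:
            continue
        profiles.append(SegmentProfile(
            variable=variable, category=token, label=var.label(token),
            n=len(recs), scores=score_table(dataset.subset(recs))))
    if not profiles:
        raise EmptySegmentationError(
            f"no {variable!r} category reaches the floor of {min_segment_n}")
    return tuple(profiles)


def compare_segments(dataset: Dataset, variable: str,
                     basis: str = "best") -> SegmentComparison:
    """Chi-square independence test of segment membership vs. choice.

    ``basis`` selects the best-choice table (default) or, behind the
    flag, the worst-choice table.
    """
    if basis not in ("best", "worst"):
        raise ValueError("basis must be 'best' or 'worst'")
    groups = _split(dataset, variable)
    if len(groups) < 2:
        raise DegenerateTableError(
            f"{variable!r} has fewer than 2 non-PNR segments")
    attrs = dataset.attributes
    idx = {a: i for i, a in enumerate(attrs.ids)}
    table = np.zeros((len(groups), len(attrs)), dtype=int)
    var = dataset.schema[variable]
    seg_tokens = list(groups)
    for i, token in enumerate(seg_tokens):
        for rec in groups[token]:
            choice = rec.best if basis == "best" else rec.worst
            table[i, idx[choice]] += 1
    keep = table.sum(axis=0) > 0  # drop attributes never chosen
    table = table[:, keep]
    kept_ids = [a for a, k in zip(attrs.ids, keep) if k]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateTableError(
            f"contingency table for {variable!r} is degenerate ({table.shape})")
    stat, p, df, expected = chi2_contingency(table, correction=False)
    contingency = pd.DataFrame(table,
                               index=[var.label(t) for t in seg_tokens],
                               columns=kept_ids)
    return SegmentComparison(variable=variable, contingency=contingency,
                             statistic=float(stat), df=int(df), p_value=float(p),
                             low_expected_flag=bool((expected < 5).any()))


def significance_label(p_value: float) -> str:
    """Map a p-value to the printed significance marker."""
    if not 0 <= p_value <= 1:
        raise ValueError("p-value must be in [0, 1]")
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    if p_value < 0.10:
        return "."
    return ""


def bonferroni(p_values, m=None):
    """Optional Bonferroni adjustment across demographic variables."""
    p_values = list(p_values)
    m = m if m is not None else len(p_values)
    return [min(1.0, p * m) for p in p_values]
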