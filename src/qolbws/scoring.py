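"""Best-worst scaling counting analysis.

For each attribute j over n valid respondents: best count B_j, worst
count W_j, the difference score bw_j = B_j - W_j (summing to zero across
attributes because every respondent contributes one +1 and one -1), the
mean score bw_j / n in [-1, 1], and normalized relative weights

    weight_j = 100 * (bw_j - min_k bw_k) / sum_k (bw_k - min_k bw_k)

so the least-preferred attribute scores exactly 0 and weights sum to
100 (up to rounding). This min-shift share form exactly regenerates the
published weight column from the published B-W column.

The Friedman test runs on the implied within-respondent rank matrix:
best gets rank 1, worst gets rank J, the remaining J-2 attributes share
the tie-averaged mid-rank (J+1)/2. The statistic uses the general
tie-corrected form

    chi2 = (J-1) * sum_j (R_j - n(J+1)/2)^2 / (A - C)

with A the sum of squared ranks and C = n J (J+1)^2 / 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .attributes import AttributeSet
from .errors import EmptyAnalysisError
from .rounding import round_half_away
from .survey import Dataset

__all__ = [
    "BWSCounts",
    "ScoreRow",
    "BWSScoreTable",
    "FriedmanResult",
    "count_choices",
    "bw_scores",
    "mean_bw",
    "normalized_weights",
    "score_table",
    "score_table_from_counts",
    "implied_ranks",
    "rank_matrix",
    "friedman_test",
    "friedman_from_ranks",
]

TABLE_COLUMNS = ["Variables", "Best Frequency", "Worst Frequency", "B-W",
                 "Mean (B-W)", "Normalized Relative Weights (%)"]


@dataclass(frozen=True)
class BWSCounts:
    """Per-attribute best/worst selection counts."""

    attributes: AttributeSet
    best: Tuple[int, ...]
    worst: Tuple[int, ...]

    def __post_init__(self):
        J = len(self.attributes)
        if len(self.best) != J or len(self.worst) != J:
            raise ValueError("count vectors must match the attribute set")
        if any(b < 0 for b in self.best) or any(w < 0 for w in self.worst):
            raise ValueError("counts must be non-negative")
        if sum(self.best) != sum(self.worst):
            raise ValueError("total best and worst counts must both equal n_valid")

    @property
    def n_valid(self) -> int:
        return sum(self.best)


@dataclass(frozen=True)
class ScoreRow:
    attribute_id: str
    label: str
    best: int
    worst: int
    bw: int
    mean_bw: float
    weight: float
    rank: int


@dataclass(frozen=True)
class BWSScoreTable:
    """The published-score-table object: one ScoreRow per attribute."""

    attributes: AttributeSet
    rows: Tuple[ScoreRow, ...]
    n_valid: int

    def row(self, attribute_id: str) -> ScoreRow:
        return self.rows[self.attributes.index(attribute_id)]

    def by_rank(self) -> Tuple[ScoreRow, ...]:
        return tuple(sorted(self.rows, key=lambda r: r.rank))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[r.label, r.best, r.worst, r.bw, r.mean_bw, r.weight] for r in self.rows],
            columns=TABLE_COLUMNS)


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    df: int
    p_value: float
    n: int


def count_choices(dataset: Dataset) -> BWSCounts:
    """Tally best and worst picks per attribute over a cleaned dataset."""
    if dataset.n == 0:
        raise EmptyAnalysisError("cannot count choices of an empty dataset")
    idx = {a: i for i, a in enumerate(dataset.attributes.ids)}
    best = [0] * len(idx)
    worst = [0] * len(idx)
    for rec in dataset.records:
        best[idx[rec.best]] += 1
        worst[idx[rec.worst]] += 1
    return BWSCounts(dataset.attributes, tuple(best), tuple(worst))


def bw_scores(counts: BWSCounts) -> Tuple[int, ...]:
    """bw_j = B_j - W_j."""
    return tuple(b - w for b, w in zip(counts.best, counts.worst))


def mean_bw(bw: int, n_valid: int) -> float:
    """bw / n_valid, half-away rounded to 3 decimals."""
    if n_valid <= 0:
        raise ValueError("n_valid must be positive")
    return round_half_away(bw / n_valid, 3)


def normalized_weights(bw: Sequence[float]) -> Tuple[float, ...]:
    """Min-shift share normalization of B-W scores, in percent (2 dp).

    All-equal input is the degenerate case and returns the uniform
    100/J split.
    """
    J = len(bw)
    if J < 2:
        raise ValueError("need at least 2 attributes")
    lo = min(bw)
    shifted = [b - lo for b in bw]
    total = sum(shifted)
    if total == 0:  # all scores equal
        return tuple(round_half_away(100.0 / J, 2) for _ in bw)
    return tuple(round_half_away(100.0 * s / total, 2) for s in shifted)


def _ranks(counts: BWSCounts) -> Tuple[int, ...]:
    """Rank 1 = highest bw; ties broken by best count desc, then order."""
    bw = bw_scores(counts)
    order = sorted(range(len(bw)), key=lambda j: (-bw[j], -counts.best[j], j))
    rank = [0] * len(bw)
    for pos, j in enumerate(order, start=1):
        rank[j] = pos
    return tuple(rank)


def score_table_from_counts(counts: BWSCounts) -> BWSScoreTable:
    """Compose scores, means, weights, and ranks from marginal counts."""
    n = counts.n_valid
    bw = bw_scores(counts)
    weights = normalized_weights(bw)
    ranks = _ranks(counts)
    rows = tuple(
        ScoreRow(attribute_id=aid, label=lbl, best=counts.best[j], worst=counts.worst[j],
                 bw=bw[j], mean_bw=mean_bw(bw[j], n), weight=weights[j], rank=ranks[j])
        for j, (aid, lbl) in enumerate(counts.attributes)
    )
    return BWSScoreTable(counts.attributes, rows, n)


def score_table(dataset: Dataset) -> BWSScoreTable:
    """The full counting analysis of a cleaned dataset."""
    return score_table_from_counts(count_choices(dataset))


def implied_ranks(best_index: int, worst_index: int, n_attributes: int) -> np.ndarray:
    """Within-respondent ranks implied by a single best/worst pick.

    Best gets 1, worst gets J, the other J-2 attributes share the
    tie-averaged mid-rank (J+1)/2; the ranks sum to J(J+1)/2.
    """
    J = n_attributes
    ranks = np.full(J, (J + 1) / 2.0)
    ranks[best_index] = 1.0
    ranks[worst_index] = float(J)
    return ranks


def rank_matrix(dataset: Dataset) -> np.ndarray:
    """n x J matrix of implied ranks, one row per respondent."""
    J = len(dataset.attributes)
    idx = {a: i for i, a in enumerate(dataset.attributes.ids)}
    return np.vstack([implied_ranks(idx[r.best], idx[r.worst], J)
                      for r in dataset.records])


def friedman_from_ranks(ranks: np.ndarray) -> FriedmanResult:
    """Tie-corrected Friedman chi-square on a given n x J rank matrix."""
    ranks = np.asarray(ranks, dtype=float)
    n, J = ranks.shape
    if J < 3:
        raise ValueError("Friedman test needs at least 3 attributes")
    A = float((ranks ** 2).sum())
    C = n * J * (J + 1) ** 2 / 4.0
    R = ranks.sum(axis=0)
    ss = float(((R - n * (J + 1) / 2.0) ** 2).sum())
    if A == C:  # every row completely tied: no information
        stat = 0.0
    else:
        stat = (J - 1) * ss / (A - C)
    df = J - 1
    return FriedmanResult(statistic=stat, df=df,
                          p_value=float(chi2_dist.sf(stat, df)), n=n)


def friedman_test(dataset: Dataset) -> FriedmanResult:
    """Friedman test over the dataset's implied-rank matrix."""
    if len(dataset.attributes) < 3:
        raise ValueError("Friedman test needs at least 3 attributes")
    if dataset.n == 0:
        raise EmptyAnalysisError("cannot test an empty dataset")
    return friedman_from_ranks(rank_matrix(dataset))
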