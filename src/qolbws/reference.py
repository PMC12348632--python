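"""Published summary tables of the Guilford County QOL survey.

The survey's respondent-level data were never deposited; what is public
are the demographic margins (217 rows, with gender answered by 208) and
the best/worst frequency table over the 213 valid responses. Those
printed numbers are inputs here: they seed the synthetic generator's
marginals and utility targets, and they let the counting analysis be
checked cell-by-cell against the published tables.

Known quirks of the published tables, preserved faithfully:

* the demographic table's denominator is 217 even though the
  relationship categories only sum to 207;
* gender percentages use the 208 non-missing answers;
* the male share prints as 40.39 although 84/208 rounds to 40.38;
* two of the six mean B-W scores (health care 0.207, community assets
  -0.239) are consistent with dividing by ~217, not the stated n=213.
"""

from __future__ import annotations

from .attributes import DEFAULT_ATTRIBUTES
from .descriptives import REPORT_CONVENTIONS, DescriptiveTable, descriptive_table
from .schema import DEFAULT_SCHEMA, PNR, PNR_LABEL
from .scoring import BWSCounts, BWSScoreTable, score_table_from_counts

__all__ = [
    "N_VALID",
    "N_DEMOGRAPHIC",
    "N_GENDER_ANSWERED",
    "N_COMPLETED",
    "BEST_FREQUENCIES",
    "WORST_FREQUENCIES",
    "DEMOGRAPHIC_COUNTS",
    "published_counts",
    "published_score_table",
    "published_descriptives",
    "demographic_marginals",
]

N_COMPLETED = 280     # completed telephone interviews
N_VALID = 213         # valid responses after cleaning
N_DEMOGRAPHIC = 217   # denominator of the demographic table
N_GENDER_ANSWERED = 208

BEST_FREQUENCIES = {"spiritual": 70, "food": 22, "health": 52,
                    "social": 10, "economic": 53, "community": 6}
WORST_FREQUENCIES = {"spiritual": 22, "food": 8, "health": 7,
                     "social": 100, "economic": 18, "community": 58}

# Category counts per variable, schema order, PNR inferred where the
# published table prints only the non-missing rows (gender: 217-208=9).
DEMOGRAPHIC_COUNTS = {
    "gender": {"female": 124, "male": 84, PNR: 9},
    "age_group": {"young": 5, "adults": 114, "early_seniors": 44,
                  "seniors": 43, PNR: 11},
    "race": {"native": 3, "black": 88, "white": 115, PNR: 11},
    "education": {"masters_plus": 59, "bachelors": 76, "associates": 25,
                  "some_college": 26, "high_school": 9,
                  "some_high_school": 1, PNR: 21},
    "relationship": {"married_cohab": 102, "married_apart": 17, "single": 46,
                     "partnered": 11, "not_sure": 3, PNR: 28},
    "employment": {"full_time": 133, "part_time": 7, "retired": 53,
                   "stay_home": 8, "unemployed": 6, "disabled": 1, PNR: 9},
}


def published_counts() -> BWSCounts:
    """The published best/worst frequencies as a BWSCounts object."""
    ids = DEFAULT_ATTRIBUTES.ids
    return BWSCounts(DEFAULT_ATTRIBUTES,
                     tuple(BEST_FREQUENCIES[a] for a in ids),
                     tuple(WORST_FREQUENCIES[a] for a in ids))


def published_score_table() -> BWSScoreTable:
    """Recompute the full published score table from its frequency columns."""
    return score_table_from_counts(published_counts())


def published_descriptives() -> dict:
    """Recompute the published demographic table from its count column.

    Uses the report conventions (gender over the 208 non-missing
    answers at 2 dp; everything else over all 217 rows, age at 2 dp and
    the rest at 1 dp). The 217 denominator is passed explicitly for the
    all-rows variables because the relationship rows do not exhaust it.
    """
    out = {}
    for name, counts in DEMOGRAPHIC_COUNTS.items():
        var = DEFAULT_SCHEMA[name]
        labelled = {(PNR_LABEL if t == PNR else var.label(t)): c
                    for t, c in counts.items()}
        mode, decimals = REPORT_CONVENTIONS[name]
        denominator = None if mode == "nonmissing_only" else N_DEMOGRAPHIC
        out[name] = descriptive_table(name, labelled, denominator_mode=mode,
                                      decimals=decimals, denominator=denominator)
    return out


def demographic_marginals() -> dict:
    """Category probabilities per variable, normalized from the counts.

    Normalization is by each variable's own column sum (217 everywhere
    except relationship, whose published rows sum to 207).
    """
    out = {}
    for name, counts in DEMOGRAPHIC_COUNTS.items():
        total = sum(counts.values())
        out[name] = {t: c / total for t, c in counts.items()}
    return out
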