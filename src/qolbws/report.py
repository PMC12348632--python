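"""Assembled analysis outputs: CSV/JSON tables and a Markdown report.

``analyze`` orchestrates the full pipeline on one input dataset —
clean, identification descriptives, score table + Friedman test,
per-variable segment contrasts, personas — and writes:

    cleaning_report.json, table1.csv, table2.csv,
    segments/<variable>.csv, comparisons.json, personas.json, report.md

The analysis path contains no random draws, so running it twice on the
same input produces byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .descriptives import REPORT_CONVENTIONS, identification_report
from .errors import DegenerateTableError, EmptySegmentationError
from .personas import default_persona_rules, persona_gallery
from .scoring import TABLE_COLUMNS, friedman_test, score_table
from .segmentation import compare_segments, segment_scores, significance_label
from .survey import Dataset, clean, read_responses

__all__ = ["analyze"]


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def analyze(source, outdir, *, min_segment_n: int = 10,
            segmentation_variables: Optional[Sequence[str]] = None,
            persona_rules=None, conventions=None,
            delimiter: str = ",", log=lambda msg: None) -> dict:
    """Run the three-stage pipeline and write its artifacts to ``outdir``.

    ``source`` is a dataset path or an in-memory :class:`Dataset`.
    Returns a summary dict (also the content of the JSON outputs).
    Per-variable segmentation failures are recorded, not fatal.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = source if isinstance(source, Dataset) else read_responses(
        source, delimiter=delimiter)
    log(f"input: {dataset.n} records ({dataset.provenance})")

    cleaned, creport = clean(dataset)
    _write_json(outdir / "cleaning_report.json", creport.to_dict())
    log(f"clean: {creport.n_raw} -> {creport.n_valid} "
        f"(removed {dict(creport.removed_by_reason)})")

    # Identification
    tables = identification_report(cleaned, conventions=conventions or REPORT_CONVENTIONS)
    frames = []
    for name, table in tables.items():
        frame = table.to_dataframe()
        if frame.empty:
            continue
        frame.insert(0, "Variable", name)
        frames.append(frame)
    table1 = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=["Variable", "Category", "Count", "Percent"]))
    table1.to_csv(outdir / "table1.csv", index=False)
    log(f"identification: {len(table1)} category rows")

    # Scores + Friedman
    scores = score_table(cleaned)
    scores.to_dataframe().to_csv(outdir / "table2.csv", index=False)
    fried = friedman_test(cleaned)
    log(f"scores: n_valid={scores.n_valid}, friedman={fried.statistic:.2f}")

    # Segmentation
    seg_vars = list(segmentation_variables
                    if segmentation_variables is not None
                    else cleaned.schema.names)
    (outdir / "segments").mkdir(exist_ok=True)
    comparisons = {}
    seg_skipped = {}
    for name in seg_vars:
        try:
            profiles = segment_scores(cleaned, name, min_segment_n=min_segment_n)
            cmp_ = compare_segments(cleaned, name)
        except (EmptySegmentationError, DegenerateTableError) as err:
            seg_skipped[name] = str(err)
            log(f"segmentation[{name}]: skipped ({err})")
            continue
        frames = []
        for prof in profiles:
            frame = prof.scores.to_dataframe()
            frame.insert(0, "Segment", prof.label)
            frame.insert(1, "Segment n", prof.n)
            frames.append(frame)
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "segments" / f"{name}.csv", index=False)
        comparisons[name] = {
            "statistic": cmp_.statistic, "df": cmp_.df, "p_value": cmp_.p_value,
            "label": significance_label(cmp_.p_value),
            "low_expected_flag": cmp_.low_expected_flag,
            "segments": {prof.label: prof.n for prof in profiles},
        }
        log(f"segmentation[{name}]: chi2={cmp_.statistic:.3f} "
            f"df={cmp_.df} p={cmp_.p_value:.4f}")
    _write_json(outdir / "comparisons.json", {
        "friedman": {"statistic": fried.statistic, "df": fried.df,
                     "p_value": fried.p_value, "n": fried.n},
        "variables": comparisons,
        "skipped": seg_skipped,
    })

    # Characterization
    rules = persona_rules if persona_rules is not None else default_persona_rules()
    gallery = persona_gallery(cleaned, rules)
    _write_json(outdir / "personas.json", {
        "personas": [p.to_dict() for p in gallery.personas],
        "skipped": [{"descriptor": rule.describe(cleaned.schema),
                     "selector": rule.selector_as_lists(), "reason": reason}
                    for rule, reason in gallery.skipped],
    })
    log(f"personas: {len(gallery.personas)} built, {len(gallery.skipped)} skipped")

    _write_markdown(outdir, cleaned, creport, tables, scores, fried,
                    comparisons, seg_skipped, gallery)
    return {
        "n_raw": creport.n_raw, "n_valid": creport.n_valid,
        "friedman": fried.statistic, "comparisons": comparisons,
        "personas": [p.name for p in gallery.personas],
    }


def _md_table(frame: pd.DataFrame) -> str:
    cols = list(frame.columns)
    lines = ["| " + " | ".join(str(c) for c in cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for row in frame.itertuples(index=False):
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines)


def _write_markdown(outdir, cleaned, creport, tables, scores, fried,
                    comparisons, seg_skipped, gallery) -> None:
    parts = ["# Quality-of-life best-worst analysis report", ""]
    parts += ["## Cleaning", "",
              f"{creport.n_raw} raw records, {creport.n_valid} valid; removed: "
              + ", ".join(f"{k}={v}" for k, v in creport.removed_by_reason.items()),
              ""]
    parts += ["## Identification", ""]
    for name, table in tables.items():
        parts += [f"### {name} (denominator {table.denominator}, "
                  f"{table.denominator_mode})", "",
                  _md_table(table.to_dataframe()), ""]
    parts += ["## Best-worst scores", "", _md_table(scores.to_dataframe()), "",
              f"Friedman test statistic: {fried.statistic:.2f} "
              f"(p = {fried.p_value:.2f}); n = {fried.n}.", ""]
    parts += ["## Segmentation", ""]
    for name, cmp_ in comparisons.items():
        parts.append(f"- {name}: Chi-Square {cmp_['statistic']:.3f} "
                     f"(df {cmp_['df']}, p {cmp_['p_value']:.4f}) "
                     f"{cmp_['label']}"
                     + (" [low expected counts]" if cmp_["low_expected_flag"] else ""))
    for name, reason in seg_skipped.items():
        parts.append(f"- {name}: skipped ({reason})")
    parts += ["", "## Personas", ""]
    for p in gallery.personas:
        low = ", ".join(p.low_priority_attributes)
        parts.append(f"- **{p.name}** (n={p.n}): top {p.top_attribute}, "
                     f"secondary {p.secondary_attribute}, lowest priority [{low}]"
                     + (" [tie at top]" if p.tie_flag else ""))
    for rule, reason in gallery.skipped:
        parts.append(f"- skipped {rule.describe(cleaned.schema)}: {reason}")
    (Path(outdir) / "report.md").write_text("\n".join(parts) + "\n", encoding="utf-8")
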