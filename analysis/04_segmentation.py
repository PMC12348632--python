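#!/usr/bin/env python
"""Segmentation stage: subgroup score tables and chi-square contrasts.

For each demographic variable, scores every segment (merged per the
schema, PNR excluded) and tests independence of segment membership and
best-choice with a chi-square contrast, writing the per-variable tables
under results/segments/ and a comparison summary.
"""

import json
from pathlib import Path

import pandas as pd

from qolbws import (DegenerateTableError, EmptySegmentationError, clean,
                    compare_segments, read_responses, segment_scores,
                    significance_label)

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
(OUT / "segments").mkdir(parents=True, exist_ok=True)

dataset = read_responses(OUT / "simulated" / "dataset.csv")
cleaned, _ = clean(dataset)

summary = {}
for variable in cleaned.schema.names:
    try:
        profiles = segment_scores(cleaned, variable, min_segment_n=10)
        cmp_ = compare_segments(cleaned, variable)
    except (EmptySegmentationError, DegenerateTableError) as err:
        print(f"{variable}: skipped ({err})")
        continue
    frames = []
    for prof in profiles:
        frame = prof.scores.to_dataframe()
        frame.insert(0, "Segment", prof.label)
        frame.insert(1, "Segment n", prof.n)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(
        OUT / "segments" / f"{variable}.csv", index=False)
    label = significance_label(cmp_.p_value)
    summary[variable] = {"statistic": cmp_.statistic, "df": cmp_.df,
                         "p_value": cmp_.p_value, "label": label,
                         "low_expected_flag": cmp_.low_expected_flag}
    tops = {p.label: p.scores.by_rank()[0].attribute_id for p in profiles}
    print(f"{variable}: chi2={cmp_.statistic:.3f} df={cmp_.df} "
          f"p={cmp_.p_value:.4f} {label}  segment tops: {tops}")

(OUT / "comparisons.json").write_text(
    json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8")
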