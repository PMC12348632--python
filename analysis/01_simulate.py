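#!/usr/bin/env python
"""Generate the synthetic telephone-survey dataset used by the analysis.

Emulates the field pipeline's scale: 280 completed interviews with
response-error rates chosen so that roughly a quarter are removed by
cleaning, leaving a valid set near the published 213. Writes the raw
dataset, its ground truth, and the generator config under
results/simulated/.
"""

import json
from pathlib import Path

from qolbws import generate, preset_paper_like, write_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 20250731

config = preset_paper_like(n_respondents=280, seed=SEED,
                           incomplete_rate=0.15, contradictory_rate=0.09)
dataset, truth = generate(config)

OUT.mkdir(parents=True, exist_ok=True)
write_dataset(dataset, OUT / "dataset.csv")
(OUT / "ground_truth.json").write_text(
    json.dumps(truth.to_dict(), sort_keys=True) + "\n", encoding="utf-8")
(OUT / "config.json").write_text(
    json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n",
    encoding="utf-8")

counts = truth.corruption_counts()
print(f"simulated {dataset.n} respondents (seed {SEED}, "
      f"config {config.config_hash()[:12]})")
print(f"injected corruption: {counts['incomplete']} incomplete, "
      f"{counts['contradictory']} contradictory "
      f"-> expect ~{dataset.n - sum(counts.values())} valid after cleaning")
print(f"wrote {OUT}/dataset.csv")
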