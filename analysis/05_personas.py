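#!/usr/bin/env python
"""Characterization stage: persona construction.

At the survey's own sample size most persona cells are too thin to
support a stable archetype, so this driver shows both: the gallery on
the cleaned n~213-scale simulated survey (expect skips), and on a
60,000-respondent draw from the same generator where every cell has
hundreds of members and the four published archetypes emerge.
"""

import json
from pathlib import Path

from qolbws import (clean, default_persona_rules, generate, persona_gallery,
                    preset_paper_like, read_responses)

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"

rules = default_persona_rules()

survey = read_responses(OUT / "simulated" / "dataset.csv")
cleaned, _ = clean(survey)
small = persona_gallery(cleaned, rules)
print(f"survey-scale gallery (n={cleaned.n}): "
      f"{len(small.personas)} built, {len(small.skipped)} skipped")
for rule, reason in small.skipped:
    print(f"  skipped {rule.describe(cleaned.schema)}: {reason}")

large, _ = generate(preset_paper_like(n_respondents=60000, seed=5))
gallery = persona_gallery(large, rules)
print(f"\nlarge-sample gallery (n={large.n}):")
for persona in gallery.personas:
    low = ", ".join(persona.low_priority_attributes)
    print(f"  {persona.name} (n={persona.n}): top={persona.top_attribute}, "
          f"secondary={persona.secondary_attribute}, lowest=[{low}]")

(OUT / "personas.json").write_text(json.dumps(
    {"survey_scale": {"personas": [p.to_dict() for p in small.personas],
                      "skipped": [{"descriptor": r.describe(cleaned.schema),
                                   "reason": why} for r, why in small.skipped]},
     "large_sample": {"personas": [p.to_dict() for p in gallery.personas]}},
    indent=2, sort_keys=True) + "\n", encoding="utf-8")
print(f"\nwrote {OUT}/personas.json")
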