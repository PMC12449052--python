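#!/usr/bin/env python
"""Run the strict Wood-Ljungdahl screen on the fixture catalog and score it
against the planted truth; summarize acsB prevalence.

Reads results/data/, writes results/verdicts.tsv and results/prevalence.tsv.
"""
import json
from pathlib import Path

from acetotype.acetogen_screen import screen_genome, summarize_prevalence, verdicts_to_frame
from acetotype.genome_model import load_genome_catalog

DATA = Path("results/data")
catalog = load_genome_catalog(DATA / "catalog.tsv")
truth = json.loads((DATA / "truth.json").read_text())["catalog"]["genomes"]

verdicts = {g.genome_id: screen_genome(g) for g in catalog}
verdicts_to_frame(catalog, verdicts).to_csv("results/verdicts.tsv", sep="\t", index=False)

n_strict = sum(v.is_strict_acetogen for v in verdicts.values())
agree = sum(verdicts[g].is_strict_acetogen == t["planted_strict_acetogen"]
            for g, t in truth.items())
table, summary = summarize_prevalence([(g, verdicts[g.genome_id]) for g in catalog])
table.to_csv("results/prevalence.tsv", sep="\t", index=False)

print(f"{n_strict}/{len(catalog)} genomes pass the six-gene strict screen")
print(f"screen agrees with planted truth for {agree}/{len(truth)} genomes")
print(f"acsB-positive prevalence: {summary['median_pct']:.1f}% "
      f"(single synthetic study)")
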