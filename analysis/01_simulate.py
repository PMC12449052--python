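#!/usr/bin/env python
"""Generate the study fixture: a 200-genome annotation catalog drawn from the
five genotype archetypes (zero dropout) and a two-diet community matrix with
20 genomes planted 8-fold enriched (10 per diet), n=10 animals per group.

Writes results/data/{catalog,abundance,metadata}.tsv and truth.json.
"""
from pathlib import Path

from acetotype.synthetic import CommunityScenario, write_fixture

OUT = Path("results/data")
SEED = 17

truth = write_fixture(OUT, n_genomes=200, dropout_rate=0.0, seed=SEED,
                      scenario=CommunityScenario(n_genomes=200, seed=SEED))
genomes = truth["catalog"]["genomes"]
n_acet = sum(g["planted_strict_acetogen"] for g in genomes.values())
n_enr = sum(len(v) for v in truth["community"]["enriched"].values())
print(f"wrote fixture to {OUT}")
print(f"  200 genomes, {n_acet} planted strict acetogens")
print(f"  community: 200 genomes x 20 samples, {n_enr} planted enriched "
      f"({truth['community']['fold_change']}-fold)")
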