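# acetotype

Genome-resolved identification and metabolic typing of rumen acetogens, with
diet-contrast community statistics and a thermodynamic model of the rumen's
competing H₂ sinks.

## The problem

Rumen fermentation disposes of electrons largely as H₂, which methanogenic
archaea convert to CH₄ — an energy loss and a greenhouse gas. Acetogenic
bacteria offer an alternative sink: the reductive Wood–Ljungdahl (WL)
pathway fixes 2 CO₂ into one acetate using 8 reducing equivalents
([H] = 1 H⁺ + 1 e⁻), the same electron budget methanogens spend per CH₄:

```
fermentation:            C6H12O6 + 2 H2O → 2 CH3COOH + 2 CO2 + 8 [H]
reductive acetogenesis:  2 CO2 + 8 [H]   → CH3COOH + 2 H2O
methanogenesis:          CO2 + 8 [H]     → CH4 + 2 H2O
combined (heterotrophic acetogenesis):  C6H12O6 → 3 CH3COOH
```

`acetotype` implements, over per-genome annotation tables (no sequence data
required):

* **Quality gating** — CheckM-style classes: *high* iff completeness > 90%
  and contamination < 5%; *medium* iff completeness ≥ 50% and
  contamination < 10%; else *fail*.
* **Hydrogenase evidence filtering** — hits kept iff e-value ≤ 1e-50,
  identity > 60%, aligned length > 40 aa, one best target per query.
* **The strict acetogen screen** — a genome is a putative acetogen iff it
  carries all six key WL genes (*acsA*, *acsB*, *fhs*, *fchA*, *metF*,
  *acsE*); formate dehydrogenase is recorded but never required.
* **Trophic-strategy typing** — `hydrogenotrophic_capable` (FDH or the
  fdhF/hydA2/hycB H₂-dependent CO₂-reductase triad, plus an
  electron-bifurcating [FeFe] group A3/A4 hydrogenase),
  `formate_dependent_h2_using` (no FDH, hydrogenases present; formate via
  transporter or pyruvate formate-lyase), or `fermentation_electron_only` —
  alongside CAZyme substrate profiles and glycolysis/PPP/ED completeness.
* **Community statistics** — per-sample community *acsB* fraction, row-wise
  Z-scores (Z = (X − μ)/σ, population σ), two-group Wilcoxon rank-sum
  contrasts with Benjamini–Hochberg FDR, Bray–Curtis dissimilarity, Shannon
  diversity.
* **Thermodynamics** — ΔG = ΔG°′ + RT ln Q for the three reactions above
  with [H] realized as ½ H₂, and the dissolved-H₂ threshold (ΔG = 0) of each
  sink.
* **Synthetic data** — annotation catalogs built from five genotype
  archetypes with completeness-dependent gene dropout, and two-diet
  community matrices with planted enrichment, each with a truth ledger.

## Worked example

The `analysis/` scripts run the whole pipeline on a generated fixture:

```sh
python analysis/01_simulate.py   # 200-genome catalog + 2-diet community
python analysis/02_screen.py
python analysis/03_type.py
python analysis/04_contrast.py
python analysis/05_thermo.py
```

Output (abridged):

```
77/200 genomes pass the six-gene strict screen
screen agrees with planted truth for 200/200 genomes
assigned labels match planted archetypes for 200/200 genomes
diet contrast: 25 genomes called at FDR 0.05; 20/20 planted enrichments
  recovered with the right direction
dissolved-H2 threshold (ΔG=0) at rumen conditions: acetogenesis 380.5 uM
  vs methanogenesis 1.60 uM (ratio 238x)
```

77 of the 200 synthetic genomes were planted as strict acetogens and every
one is recovered at zero gene dropout; all 20 genomes planted 8-fold
enriched in one diet are detected with the correct direction; and the
acetogenesis H₂ threshold sits two orders of magnitude above the
methanogenesis threshold — the thermodynamic reason acetogens cannot win a
direct competition for H₂ and heterotrophic strategies matter.

The same stages are available as a CLI:

```sh
acetotype simulate --seed 17 --n-genomes 75 --outdir fixture
acetotype screen --catalog fixture/catalog.tsv
acetotype type --catalog fixture/catalog.tsv
acetotype contrast --abundance fixture/abundance.tsv --meta fixture/metadata.tsv
acetotype thermo-sweep --h2-min 1e-7 --h2-max 1e-3
acetotype run-all --catalog fixture/catalog.tsv --outdir results/run
```

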