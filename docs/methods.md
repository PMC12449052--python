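# Methods

## Scope and data model

`acetotype` operates downstream of assembly, binning, and annotation: its
inputs are per-genome annotation tables (gene symbols with optional
DIAMOND-style alignment evidence, CAZy family hits, hydrogenase class
labels, CheckM-style completeness/contamination) and genome × sample
relative-abundance matrices. It does not call genes, run HMMER/DIAMOND, or
estimate abundances; those tools' outputs are its inputs. Gene symbols are
normalized case-insensitively to a controlled vocabulary; unknown symbols
are retained with category `other`, so screening is conservative with
respect to annotation noise but cannot rescue mislabeled genes.

## Quality gating and evidence filtering

Quality classes apply the printed inequalities literally: *high* iff
completeness > 90 **and** contamination < 5; *medium* iff completeness ≥ 50
**and** contamination < 10; otherwise *fail*. Exact-boundary genomes
(completeness = 90, contamination = 5 or 10) therefore fall to the weaker
class: with mixed strict/non-strict operators in circulation, literal
application is the only defensible reading, and it is what the tests pin.

Hydrogenase hits survive iff e-value ≤ 1e-50, identity > 60%, and aligned
length > 40 aa (strict where stated). When several hits share a query
identifier, the lowest e-value wins (ties: highest identity, then
lexicographic query id) — a deterministic rendering of "one maximum target
sequence per query". Hits missing evidence fields cannot satisfy the filter
and are dropped with a logged warning rather than imputed. The filter is
idempotent and order-independent.

## The strict screen

A putative acetogen must carry all six of *acsA*, *acsB* (CODH/ACS), *fhs*
(FTHFS), *fchA* (MC/MD), *metF* (MR), and *acsE* (MT). Formate dehydrogenase
(*fdhA*/*fdhF*) is deliberately not required — FDH-lacking acetogens import
formate or generate it via pyruvate formate-lyase — and the accessory genes
tracked in the 15-gene WL inventory (*metV*, *rnfC2*, *hydA2*, *hycB*,
*pfl*) are recorded but never required. Presence is assessed at the genome
level; whether the genes co-locate on one contig is not modeled, since the
input is an annotation table without coordinates. The screen is monotone
under gene addition and invariant to hit multiplicity.

Prevalence summaries (median/range of the acsB-positive percentage) are
computed across groups (studies or host species), not across genomes,
mirroring how multi-study surveys report prevalence.

## Strategy typing

Typing applies three rules in order to each strict acetogen:

1. FDH present (or the fdhF/hydA2/hycB H₂-dependent CO₂-reductase triad)
   **and** ≥ 1 electron-bifurcating hydrogenase ([FeFe] group A3/A4) →
   `hydrogenotrophic_capable`.
2. No FDH **and** any hydrogenase (bifurcating, fermentative group B,
   sensory group C, or unclassified) → `formate_dependent_h2_using`; the
   rationale notes the formate source (transporter *fcoA*/*nirC* or PFL, or
   "formate source unresolved").
3. Otherwise → `fermentation_electron_only`.

The rule order encodes the biological hierarchy (autotrophic capability
dominates, then H₂ use without CO₂ reduction to formate); no explicit
decision tree is fixed by prior literature, so the order is a package
design choice and the full rule trail is emitted in the rationale. Sensory
hydrogenases count toward "any hydrogenase" by default. Mixotrophy is not a
separate label: a hydrogenotrophic genome with glycolysis completeness
≥ 0.8 receives a "mixotrophy-consistent" rationale note only, since no
quantitative mixotrophy criterion exists to type against. FDH without a
bifurcating hydrogenase falls through to rule 3 — the genome can make
formate but has no modeled H₂-electron entry point.

Substrate profiles sum CAZy family hits per class — cellulose (GH3, GH94),
hemicellulose (GH2, GH43), host glycans (GH18, GH36), starch/amylase (GH13,
GH77) — with all other families reported raw. Pathway completeness is the
fraction of a pathway's defined gene set present; the Embden–Meyerhof,
pentose-phosphate, and Entner–Doudoroff definitions follow standard KEGG
module composition and ship as editable YAML (`data/pathways.yaml`) — they
are a convention, not a measured quantity, and no "complete/incomplete"
threshold is imposed: raw fractions are reported.

## Community statistics

Z-scores use the population (divide-by-*n*) standard deviation, matching the
estimator the display convention specifies; zero-variance rows map to
all-zero Z rows with a flag instead of NaNs, keeping downstream heatmaps
renderable while preserving the information. Diet contrasts run a two-sided
Wilcoxon rank-sum test per genome (exact null distribution when the combined
sample size is ≤ 20 with no ties; normal approximation with tie and
continuity correction otherwise) with Benjamini–Hochberg adjustment across
genomes and calls at adjusted p < .05. Bray–Curtis dissimilarity and Shannon
diversity (natural log, on relative abundances) are computed via
scipy; Shannon is the package's alpha-diversity convention. The community
*acsB* fraction is the summed relative abundance of acsB-positive genomes
per sample — a MAG-mass definition; read-mapping gene-abundance estimators
would weight by gene copy and coverage and can differ.

## Thermodynamics

Reactions are signed stoichiometry maps over {glucose, acetate, CO₂, H₂,
CH₄, H₂O, formate, [H]}, where [H] is one proton plus one electron. The
shipped fermentation reaction includes the 2 H₂O reactant
(C₆H₁₂O₆ + 2 H₂O → 2 CH₃COOH + 2 CO₂ + 8 [H]); the common shorthand omits
water and does not balance H and O, and the package enforces elemental
balance (C, H, O) before any electron bookkeeping. The electron balance is
the net [H] coefficient with H₂ counted as 2 [H]: +8 for fermentation, −8
per WL acetate and per CH₄, 0 for the combined glucose → 3 acetate pathway.

ΔG = ΔG°′ + RT ln Q with [H] entering quotients as ½ H₂ (the default
electron-carrier model; NADH/ferredoxin carriers are representable but not
defaulted, since the competition argument is made at the level of H₂), water
at unit activity, and pH folded into ΔG°′. ΔG°′ defaults (kJ/mol, 25 °C,
pH 7) follow classic anaerobe bioenergetics tables (Thauer, Jungermann &
Decker 1977 and descendants): −216 (fermentation), −94.9 (hydrogenotrophic
acetogenesis per acetate), −131 (methanogenesis per CH₄). They ship in
`data/thermo.yaml` together with rumen-like default activities (acetate
60 mM, CO₂ 20 mM, CH₄ 1 mM, T = 312.65 K) and a Henry's-law constant for H₂
(7.8 × 10⁻⁴ mol/L/atm) for headspace↔dissolved conversion. Temperature
correction of ΔG°′ (van 't Hoff) is not applied: 25 °C constants are used at
rumen temperature, as is common practice at this level of argument. Because
the exact constant set behind any particular published curve is rarely
printed, numeric ΔG outputs are treated as provenance-labeled estimates and
validated by properties only: sign and monotonicity in dissolved H₂
(fermentation ΔG strictly rises, the H₂-consuming sinks strictly fall), the
threshold ordering (acetogenesis ≫ methanogenesis; ≈ 380 µM vs ≈ 1.6 µM
under the defaults, a ~240× ratio), antisymmetry under reversal, and
additivity when [H] cancels.

H₂ thresholds solve ΔG = 0 by Brent's method on ln a(H₂) over the bracket
[10⁻¹⁵, 1] M to relative tolerance below 1e-9; ΔG is affine in ln a(H₂), so
the root is unique whenever the net H₂ exponent is nonzero, and the tests
cross-check the solver against the closed-form solution. Glucose
fermentation stays exergonic over the whole physical bracket and correctly
reports "no crossing".

## Synthetic data

The generator plants five genotype archetypes: a full-WL hydrogenotroph
(Terrisporobacter-like: six strict genes, fdhA/fdhF, the triad, A3+A4
bifurcating hydrogenases, Rnf, full glycolysis), an FDH-lacking PFL
heterotroph with an A3 hydrogenase (Lachnospirales-like), an FDH-lacking
hydrogenase-free acetogen with a formate transporter (Oscillospirales-like),
a non-acetogen fermenter (partial WL genes, group B hydrogenase, starch
CAZymes), and a methanogen-like decoy (mcr genes, no acsB) that exercises
screen specificity. Default mixture: 15/15/10/45/15%. Completeness is drawn
U(55, 99.5)% and contamination U(0, 9.5)%, spanning the medium/high quality
boundaries.

Gene dropout emulates MAG incompleteness. The per-gene omission probability
is `1 − (1 − r)^(1 + w·(1 − completeness/100))` with dropout rate `r` and
incompleteness weight `w` (default 1): zero at r = 0, one at r = 1, and
increasing with incompleteness in between. (A purely multiplicative scaling
by (1 − completeness/100) could never reach certainty at r = 1; the
exponential form preserves both limits and the scaling intent.)

Communities draw per-genome baselines LogNormal(0, 2) — a realistically
heavy-tailed rank-abundance curve — and per-sample replicate noise
LogNormal(0, 0.5), i.e. ≈ 50% CV between animals on the same diet, a typical
between-animal spread for rumen MAG abundances. Enriched genomes (default
10% of genomes, split evenly between the two diet groups) are multiplied by
the fold change (default 8) in their favored group before column
renormalization; renormalization makes the data compositional, so planted
enrichment slightly depresses all other genomes in that group, exactly as in
real relative-abundance data. These defaults are the study conditions for
the calibration suite (200 genomes, n = 10 samples/group, 20 true
positives): under them the null FDR call rate stays ≤ 5% and power at the
8-fold enrichment exceeds 90%.

What the generator does **not** emulate: phylogenetic correlation among
genomes, annotation false positives (wrong symbols rather than missing
ones), contamination-induced gene gain, compositional zero-inflation, or
sequencing-depth effects. Passing tests therefore demonstrate correctness of
the screening/typing/statistics logic under planted truth, not robustness to
every failure mode of real MAG catalogs.

## Reproducibility and problem sizes

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`), and generation is byte-identical under a fixed
seed. The shipped analyses and the acceptance script use a 200-genome
catalog, a 16-study × 1000-genome prevalence fixture, 200 null and 100
power community simulations — sizes at which every quantity is stable to
well within the tolerances asserted, while the full pipeline runs in well
under a minute on one CPU.

## Known limitations

* acsA/acsB disambiguation and CAZy consensus are the annotation source's
  responsibility; symbols are taken at face value.
* Genome-level (not contig-level) gene presence.
* MAG-mass acsB fraction rather than read-mapped gene abundance.
* No kinetics or affinity modeling: the thermodynamic module ranks sinks at
  equilibrium boundaries, not rates.
* ΔG°′ constants are table defaults, not fitted to any particular
  measurement; swap the YAML to use your own set.
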