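"""Trophic-strategy typing of strict acetogens from their gene repertoires.

Three strategies partition the strict acetogens:

* ``hydrogenotrophic_capable`` — formate dehydrogenase (or the H2-dependent
  CO2-reductase triad) together with at least one electron-bifurcating
  [FeFe]-hydrogenase: the genome can run the full methyl branch from CO2 with
  electrons from H2.
* ``formate_dependent_h2_using`` — no FDH but hydrogenases present: the
  methyl branch must start from imported or PFL-derived formate, with H2 as
  an electron source.
* ``fermentation_electron_only`` — neither route; electrons come from
  fermentative carbohydrate degradation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import vocab
from .acetogen_screen import ScreenVerdict, WLInventory, build_wl_inventory, screen_strict
from .genome_model import GenomeRecord, classify_quality, filter_hydrogenase_hits

STRATEGY_LABELS = (
    "hydrogenotrophic_capable",
    "formate_dependent_h2_using",
    "fermentation_electron_only",
)

#: glycolysis completeness at or above which a hydrogenotrophic genome is
#: annotated mixotrophy-consistent (annotation only, never a label)
MIXOTROPHY_GLYCOLYSIS_MIN = 0.8


@dataclass(frozen=True)
class SubstrateProfile:
    """CAZyme counts grouped by substrate class, plus raw family counts."""

    cellulose: int
    hemicellulose: int
    host_glycan: int
    starch: int
    raw_family_counts: tuple[tuple[str, int], ...] = field(default_factory=tuple)

    @property
    def amylase_copies(self) -> int:
        return self.starch

    def as_dict(self) -> dict[str, int]:
        return {
            "cazy_cellulose": self.cellulose,
            "cazy_hemicellulose": self.hemicellulose,
            "cazy_host_glycan": self.host_glycan,
            "cazy_starch": self.starch,
            "amylase_copies": self.amylase_copies,
        }


@dataclass(frozen=True)
class HydrogenaseRepertoire:
    electron_bifurcating: int
    fermentative: int
    sensory: int
    unknown: int = 0

    @property
    def any_hydrogenase(self) -> bool:
        """True when any filtered hydrogenase hit exists (unknown classes count)."""
        return (self.electron_bifurcating + self.fermentative + self.sensory + self.unknown) > 0

    def as_dict(self) -> dict[str, int]:
        return {
            "hyd_electron_bifurcating": self.electron_bifurcating,
            "hyd_fermentative": self.fermentative,
            "hyd_sensory": self.sensory,
            "hyd_unknown": self.unknown,
        }


@dataclass(frozen=True)
class EnergySystems:
    pfl: bool
    pta: bool
    ackA: bool
    rnf_complex: bool
    ech_complex: bool
    atp_synthase: bool
    pfor: bool
    pdh: bool
    formate_transporter: bool
    glycolysis_completeness: float
    pentose_phosphate_completeness: float
    entner_doudoroff_completeness: float

    def __post_init__(self) -> None:
        for name in ("glycolysis_completeness", "pentose_phosphate_completeness",
                     "entner_doudoroff_completeness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "pfl": self.pfl,
            "pta": self.pta,
            "ackA": self.ackA,
            "rnf_complex": self.rnf_complex,
            "ech_complex": self.ech_complex,
            "atp_synthase": self.atp_synthase,
            "pfor": self.pfor,
            "pdh": self.pdh,
            "formate_transporter": self.formate_transporter,
            "glycolysis_completeness": self.glycolysis_completeness,
            "pentose_phosphate_completeness": self.pentose_phosphate_completeness,
            "entner_doudoroff_completeness": self.entner_doudoroff_completeness,
        }


@dataclass(frozen=True)
class StrategyLabel:
    label: str
    rationale: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.label not in STRATEGY_LABELS:
            raise ValueError(f"unknown strategy label {self.label!r}")
        if not self.rationale:
            raise ValueError("rationale must record the evaluated rules")


def profile_substrates(genome: GenomeRecord) -> SubstrateProfile:
    """Count CAZy hits per substrate class.

    Classes sum the hits of their member families (cellulose: GH3+GH94,
    hemicellulose: GH2+GH43, host glycans: GH18+GH36, starch: GH13+GH77);
    families outside the eight still appear in the raw counts.
    """
    fam_counts: dict[str, int] = {}
    for h in genome.hits:
        if h.category != "cazyme":
            continue
        fam = vocab.normalize_symbol(h.gene_symbol)
        fam_counts[fam] = fam_counts.get(fam, 0) + 1
    class_totals = {
        cls: sum(fam_counts.get(f, 0) for f in fams)
        for cls, fams in vocab.SUBSTRATE_CLASSES.items()
    }
    return SubstrateProfile(
        cellulose=class_totals["cellulose"],
        hemicellulose=class_totals["hemicellulose"],
        host_glycan=class_totals["host_glycan"],
        starch=class_totals["starch"],
        raw_family_counts=tuple(sorted(fam_counts.items())),
    )


def classify_hydrogenases(genome: GenomeRecord) -> HydrogenaseRepertoire:
    """Tally evidence-filtered hydrogenase hits by functional class.

    FeFe-A3/A4 count as electron-bifurcating, FeFe-B fermentative, FeFe-C
    sensory; any other class token is tallied as unknown and still counts
    toward ``any_hydrogenase``.
    """
    counts = {"electron_bifurcating": 0, "fermentative": 0, "sensory": 0, "unknown": 0}
    for h in filter_hydrogenase_hits(genome.hits):
        if h.category != "hydrogenase":
            continue
        func = vocab.HYDROGENASE_FUNCTION.get(
            vocab.normalize_hydrogenase_class(h.hydrogenase_class or ""), "unknown"
        )
        counts[func] += 1
    return HydrogenaseRepertoire(**counts)


def pathway_completeness(genome: GenomeRecord, pathway_def: Sequence[str]) -> float:
    """Fraction of a pathway's defined genes present in the genome."""
    if not pathway_def:
        raise ValueError("pathway definition is empty")
    defined = {vocab.normalize_symbol(g) for g in pathway_def}
    present = genome.symbols() & defined
    return len(present) / len(defined)


def energy_systems(genome: GenomeRecord) -> EnergySystems:
    """Detect energy-conservation genes and pathway completeness fractions."""
    syms = genome.symbols()
    defs = vocab.pathway_definitions()
    flags = {
        key: any(g in syms for g in members)
        for key, members in vocab.ENERGY_GENES.items()
    }
    return EnergySystems(
        pfl="pfl" in syms,
        pta=flags["pta"],
        ackA=flags["ackA"],
        rnf_complex=flags["rnf_complex"],
        ech_complex=flags["ech_complex"],
        atp_synthase=flags["atp_synthase"],
        pfor=flags["pfor"],
        pdh=flags["pdh"],
        formate_transporter=any(g in syms for g in vocab.FORMATE_TRANSPORTERS),
        glycolysis_completeness=pathway_completeness(genome, defs["glycolysis_em"]),
        pentose_phosphate_completeness=pathway_completeness(genome, defs["pentose_phosphate"]),
        entner_doudoroff_completeness=pathway_completeness(genome, defs["entner_doudoroff"]),
    )


def assign_strategy(
    inv: WLInventory, hyd: HydrogenaseRepertoire, energy: EnergySystems
) -> StrategyLabel:
    """Assign one trophic-strategy label to a strict acetogen.

    Rules fire in order: (1) FDH (or the CO2-reductase triad) with an
    electron-bifurcating hydrogenase makes the genome hydrogenotrophic-
    capable; (2) absent FDH, any hydrogenase marks formate-dependent H2 use,
    with the formate source (transporter or PFL) noted; (3) otherwise the
    genome relies on fermentation-derived electrons. Raises if called on a
    genome failing the strict screen.
    """
    verdict = screen_strict(inv)
    if not verdict.is_strict_acetogen:
        raise ValueError(
            f"strategy typing requires a strict acetogen (missing: {verdict.missing_required})"
        )
    rationale: list[str] = []
    fdh = inv.fdh_present or inv.triad_present
    rationale.append(
        f"rule1 fdh_present={inv.fdh_present} triad_present={inv.triad_present} "
        f"electron_bifurcating={hyd.electron_bifurcating}"
    )
    if fdh and hyd.electron_bifurcating >= 1:
        if energy.glycolysis_completeness >= MIXOTROPHY_GLYCOLYSIS_MIN:
            rationale.append(
                "mixotrophy-consistent: glycolysis completeness "
                f"{energy.glycolysis_completeness:.2f} >= {MIXOTROPHY_GLYCOLYSIS_MIN}"
            )
        return StrategyLabel("hydrogenotrophic_capable", tuple(rationale))
    rationale.append(f"rule2 fdh_absent={not fdh} any_hydrogenase={hyd.any_hydrogenase}")
    if not fdh and hyd.any_hydrogenase:
        if energy.formate_transporter or energy.pfl:
            src = "transporter" if energy.formate_transporter else "pfl"
            rationale.append(f"formate source: {src}")
        else:
            rationale.append("formate source unresolved")
        return StrategyLabel("formate_dependent_h2_using", tuple(rationale))
    rationale.append("rule3 fallback: fermentation-derived electrons")
    return StrategyLabel("fermentation_electron_only", tuple(rationale))


@dataclass(frozen=True)
class AcetogenProfile:
    """Everything the pipeline knows about one genome, post-typing."""

    genome: GenomeRecord
    quality: str
    inventory: WLInventory
    verdict: ScreenVerdict
    substrates: SubstrateProfile
    hydrogenases: HydrogenaseRepertoire
    energy: EnergySystems
    strategy: StrategyLabel | None  # None for non-acetogens


def profile_genome(genome: GenomeRecord) -> AcetogenProfile:
    inv = build_wl_inventory(genome)
    verdict = screen_strict(inv)
    hyd = classify_hydrogenases(genome)
    energy = energy_systems(genome)
    strategy = assign_strategy(inv, hyd, energy) if verdict.is_strict_acetogen else None
    return AcetogenProfile(
        genome=genome,
        quality=classify_quality(genome),
        inventory=inv,
        verdict=verdict,
        substrates=profile_substrates(genome),
        hydrogenases=hyd,
        energy=energy,
        strategy=strategy,
    )


#: fixed column order of the feature matrix
FEATURE_COLUMNS = (
    ["genome_id", "quality_class", "taxonomy", "source",
     "completeness_pct", "contamination_pct",
     "is_acsB_positive", "is_strict_acetogen", "missing_required"]
    + list(vocab.WL_GENES)
    + ["fdh_present", "triad_present"]
    + ["hyd_electron_bifurcating", "hyd_fermentative", "hyd_sensory", "hyd_unknown",
       "any_hydrogenase"]
    + ["cazy_cellulose", "cazy_hemicellulose", "cazy_host_glycan", "cazy_starch",
       "amylase_copies"]
    + ["pfl", "pta", "ackA", "rnf_complex", "ech_complex", "atp_synthase",
       "pfor", "pdh", "formate_transporter",
       "glycolysis_completeness", "pentose_phosphate_completeness",
       "entner_doudoroff_completeness"]
    + ["strategy", "rationale"]
)


def feature_matrix(catalog: Sequence[GenomeRecord],
                   profiles: Mapping[str, AcetogenProfile] | None = None) -> pd.DataFrame:
    """One wide row per genome joining quality, verdicts, repertoires, labels.

    Rows are sorted by genome id so the output is invariant to input order.
    """
    if profiles is None:
        profiles = {g.genome_id: profile_genome(g) for g in catalog}
    rows = []
    for g in sorted(catalog, key=lambda r: r.genome_id):
        p = profiles[g.genome_id]
        row: dict = {
            "genome_id": g.genome_id,
            "quality_class": p.quality,
            "taxonomy": g.taxonomy,
            "source": g.source,
            "completeness_pct": g.completeness_pct,
            "contamination_pct": g.contamination_pct,
            "is_acsB_positive": p.verdict.is_acsB_positive,
            "is_strict_acetogen": p.verdict.is_strict_acetogen,
            "missing_required": ",".join(p.verdict.missing_required),
        }
        row.update(p.inventory.as_dict())
        row.update(p.hydrogenases.as_dict())
        row["any_hydrogenase"] = p.hydrogenases.any_hydrogenase
        row.update(p.substrates.as_dict())
        row.update(p.energy.as_dict())
        row["strategy"] = p.strategy.label if p.strategy else ""
        row["rationale"] = "; ".join(p.strategy.rationale) if p.strategy else ""
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
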