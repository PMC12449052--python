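"""Synthetic annotation catalogs and community matrices with planted truth.

Every generated dataset carries a truth ledger so each pipeline stage can be
scored against known ground truth without any external downloads. The unit
of synthesis is the annotation table — no reads or sequences are simulated.

Genotype archetypes mirror the trophic types seen among rumen acetogens: a
full-WL hydrogenotroph (Terrisporobacter-like), FDH-lacking acetogens with
and without hydrogenases, a non-acetogen fermenter, and a methanogen-like
decoy carrying mcr genes but no acsB (to exercise screen specificity).
Gene dropout emulates MAG incompleteness: less complete genomes lose more
genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import vocab
from .community import CommunityMatrix
from .genome_model import GenomeRecord, catalog_from_frame

_GLYCOLYSIS = tuple(vocab.pathway_definitions()["glycolysis_em"])
_PPP = tuple(vocab.pathway_definitions()["pentose_phosphate"])


@dataclass(frozen=True)
class ArchetypeSpec:
    """A genotype template: genes, hydrogenase classes, CAZy profile, label."""

    name: str
    gene_set: tuple[str, ...]
    hydrogenase_classes: tuple[str, ...] = ()
    cazy_profile: Mapping[str, int] = field(default_factory=dict)
    planted_label: str | None = None
    taxonomy: str = ""

    def __post_init__(self) -> None:
        if self.planted_label is not None:
            missing = set(vocab.STRICT_REQUIRED) - set(self.gene_set)
            if missing:
                raise ValueError(
                    f"{self.name}: labelled archetype missing strict genes {sorted(missing)}"
                )


_STRICT_SIX = vocab.STRICT_REQUIRED

DEFAULT_ARCHETYPES: tuple[ArchetypeSpec, ...] = (
    ArchetypeSpec(
        name="full_wl_hydrogenotroph",
        gene_set=_STRICT_SIX + ("acsC", "acsD", "metV", "rnfC2",
                                "fdhA", "fdhF", "hydA2", "hycB")
        + _GLYCOLYSIS + _PPP
        + ("pta", "ackA", "rnfA", "rnfB", "rnfC", "atpA", "atpD", "por"),
        hydrogenase_classes=("FeFe-A3", "FeFe-A4"),
        cazy_profile={"GH13": 2, "GH3": 1, "GH2": 1},
        planted_label="hydrogenotrophic_capable",
        taxonomy="d__Bacteria;p__Firmicutes_A;c__Clostridia;o__Peptostreptococcales;"
                 "f__Peptostreptococcaceae;g__Terrisporobacter",
    ),
    ArchetypeSpec(
        name="fdh_lacking_pfl_heterotroph",
        gene_set=_STRICT_SIX + ("acsC", "acsD", "pfl")
        + _GLYCOLYSIS + _PPP
        + ("pta", "ackA", "rnfA", "rnfB", "atpA", "por"),
        hydrogenase_classes=("FeFe-A3",),
        cazy_profile={"GH13": 3, "GH77": 1, "GH3": 1},
        planted_label="formate_dependent_h2_using",
        taxonomy="d__Bacteria;p__Firmicutes_A;c__Clostridia;o__Lachnospirales;"
                 "f__Lachnospiraceae;g__Bilifractor",
    ),
    ArchetypeSpec(
        name="fdh_lacking_no_hydrogenase",
        gene_set=_STRICT_SIX + ("acsC", "acsD", "nirC")
        + _GLYCOLYSIS + _PPP
        + ("pta", "ackA", "atpA", "por"),
        cazy_profile={"GH43": 2, "GH2": 1, "GH3": 1},
        planted_label="fermentation_electron_only",
        taxonomy="d__Bacteria;p__Firmicutes_A;c__Clostridia;o__Oscillospirales;"
                 "f__Oscillospiraceae;g__RGIG7114",
    ),
    ArchetypeSpec(
        name="non_acetogen_fermenter",
        gene_set=("fhs", "metF") + _GLYCOLYSIS + ("pta", "ackA", "atpA"),
        hydrogenase_classes=("FeFe-B",),
        cazy_profile={"GH13": 3, "GH43": 1},
        planted_label=None,
        taxonomy="d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;"
                 "f__Prevotellaceae;g__Prevotella",
    ),
    ArchetypeSpec(
        name="methanogen_like_decoy",
        gene_set=("mcrA", "mcrB", "mcrG", "mtrA", "fdhA"),
        cazy_profile={},
        planted_label=None,
        taxonomy="d__Archaea;p__Methanobacteriota;c__Methanobacteria;"
                 "o__Methanobacteriales;f__Methanobacteriaceae;g__Methanobrevibacter",
    ),
)

#: default archetype mixture (proportions sum to 1)
DEFAULT_MIX: tuple[float, ...] = (0.15, 0.15, 0.10, 0.45, 0.15)


def dropout_probability(dropout_rate: float, completeness_pct: float,
                        incompleteness_weight: float = 1.0) -> float:
    """Per-gene omission probability given the genome's completeness.

    ``1 - (1 - rate) ** (1 + w * (1 - completeness/100))``: zero at rate 0,
    one at rate 1, and increasing with incompleteness in between.
    """
    if not 0.0 <= dropout_rate <= 1.0:
        raise ValueError("dropout_rate must be in [0, 1]")
    exponent = 1.0 + incompleteness_weight * (1.0 - completeness_pct / 100.0)
    return 1.0 - (1.0 - dropout_rate) ** exponent


def _hit_row(gid: str, comp: float, cont: float, tax: str, source: str,
             symbol: str, rng: np.random.Generator,
             hyd_class: str | None = None) -> dict:
    category = "hydrogenase" if hyd_class else vocab.default_category(symbol)
    row = {
        "genome_id": gid,
        "completeness_pct": round(comp, 2),
        "contamination_pct": round(cont, 2),
        "taxonomy": tax,
        "source": source,
        "gene_symbol": symbol,
        "category": category,
        "hydrogenase_class": hyd_class,
        "identity_pct": round(float(rng.uniform(65.0, 99.0)), 2),
        "evalue": float(10.0 ** rng.uniform(-120.0, -55.0)),
        "aligned_length_aa": int(rng.integers(120, 600)),
    }
    return row


def generate_catalog(
    n: int,
    dropout_rate: float = 0.0,
    seed: int = 0,
    specs: Sequence[ArchetypeSpec] = DEFAULT_ARCHETYPES,
    mix: Sequence[float] = DEFAULT_MIX,
    source: str = "synthetic_study",
    incompleteness_weight: float = 1.0,
) -> tuple[tuple[GenomeRecord, ...], dict]:
    """Generate ``n`` genomes from the archetype mixture with gene dropout.

    Returns the catalog and a truth ledger recording, per genome, its
    archetype, planted strategy label, dropped genes, and surviving hit
    count. Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(mix) != len(specs) or abs(sum(mix) - 1.0) > 1e-9:
        raise ValueError("mix must match specs and sum to 1")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    ledger: dict = {"seed": seed, "dropout_rate": dropout_rate, "genomes": {}}
    arch_idx = rng.choice(len(specs), size=n, p=list(mix))
    for i in range(n):
        spec = specs[arch_idx[i]]
        gid = f"SYN_{i:04d}"
        comp = float(rng.uniform(55.0, 99.5))
        cont = float(rng.uniform(0.0, 9.5))
        p_drop = dropout_probability(dropout_rate, comp, incompleteness_weight)
        dropped: list[str] = []
        genome_rows: list[dict] = []
        for sym in spec.gene_set:
            if rng.random() < p_drop:
                dropped.append(sym)
                continue
            genome_rows.append(_hit_row(gid, comp, cont, spec.taxonomy, source, sym, rng))
        for cls in spec.hydrogenase_classes:
            if rng.random() < p_drop:
                dropped.append(f"hydA({cls})")
                continue
            genome_rows.append(
                _hit_row(gid, comp, cont, spec.taxonomy, source, "hydA", rng, hyd_class=cls)
            )
        for fam, count in sorted(spec.cazy_profile.items()):
            for _ in range(count):
                if rng.random() < p_drop:
                    dropped.append(fam)
                    continue
                genome_rows.append(
                    _hit_row(gid, comp, cont, spec.taxonomy, source, fam, rng)
                )
        if not genome_rows:  # keep the genome visible even if fully stripped
            genome_rows.append({
                "genome_id": gid, "completeness_pct": round(comp, 2),
                "contamination_pct": round(cont, 2), "taxonomy": spec.taxonomy,
                "source": source, "gene_symbol": "", "category": "",
            })
        rows.extend(genome_rows)
        ledger["genomes"][gid] = {
            "archetype": spec.name,
            "planted_label": spec.planted_label,
            "planted_strict_acetogen": spec.planted_label is not None,
            "planted_acsB": "acsB" in spec.gene_set,
            "dropped_genes": dropped,
            "n_hits": sum(1 for r in genome_rows if r["gene_symbol"]),
        }
    df = pd.DataFrame(rows)
    return catalog_from_frame(df), ledger


@dataclass(frozen=True)
class CommunityScenario:
    """Two-group community design with planted enrichment effects.

    Baseline genome abundances follow LogNormal(baseline_log_mean,
    baseline_log_sd) across genomes; replicate samples scatter around each
    baseline with LogNormal(0, sample_log_sd) noise; enriched genomes are
    multiplied by ``fold_change`` in their favored group before column
    renormalization.
    """

    n_genomes: int = 200
    n_samples_per_group: int = 10
    groups: tuple[str, str] = ("fiber", "starch")
    enriched_fraction: float = 0.1
    fold_change: float = 8.0
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 2.0
    sample_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if not 0.0 <= self.enriched_fraction <= 1.0:
            raise ValueError("enriched_fraction must be in [0, 1]")


def generate_community(scenario: CommunityScenario) -> tuple[CommunityMatrix, dict]:
    """Simulate a relative-abundance matrix under the scenario.

    Enriched genomes are split evenly between the two groups. The truth
    ledger lists the enriched genome ids per group.
    """
    rng = np.random.default_rng(scenario.seed)
    n_g, n_s = scenario.n_genomes, scenario.n_samples_per_group
    genome_ids = [f"G{i:04d}" for i in range(n_g)]
    sample_ids = [f"{grp}_{j:02d}" for grp in scenario.groups for j in range(n_s)]
    group_of = {s: s.rsplit("_", 1)[0] for s in sample_ids}

    n_enriched = int(round(scenario.enriched_fraction * n_g))
    enriched_idx = rng.choice(n_g, size=n_enriched, replace=False)
    half = n_enriched // 2
    enrichment: dict[str, str] = {}
    for k, idx in enumerate(sorted(enriched_idx)):
        enrichment[genome_ids[idx]] = scenario.groups[0] if k < half else scenario.groups[1]

    baseline = rng.lognormal(scenario.baseline_log_mean, scenario.baseline_log_sd, size=n_g)
    noise = rng.lognormal(0.0, scenario.sample_log_sd, size=(n_g, len(sample_ids)))
    X = baseline[:, None] * noise
    for gi, gid in enumerate(genome_ids):
        fav = enrichment.get(gid)
        if fav is None:
            continue
        for sj, sid in enumerate(sample_ids):
            if group_of[sid] == fav:
                X[gi, sj] *= scenario.fold_change
    X = X / X.sum(axis=0, keepdims=True)

    matrix = CommunityMatrix(
        abundance=pd.DataFrame(X, index=genome_ids, columns=sample_ids),
        sample_groups=pd.Series({s: group_of[s] for s in sample_ids}),
        normalization="relative",
    )
    ledger = {
        "seed": scenario.seed,
        "fold_change": scenario.fold_change,
        "enriched": {
            grp: sorted(g for g, fav in enrichment.items() if fav == grp)
            for grp in scenario.groups
        },
    }
    return matrix, ledger


def write_fixture(outdir: str | Path, n_genomes: int = 75, dropout_rate: float = 0.0,
                  seed: int = 0, scenario: CommunityScenario | None = None) -> dict:
    """Write a complete fixture: catalog TSV, community TSVs, truth JSON."""
    from .genome_model import write_genome_catalog
    from .community import write_community

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog, cat_ledger = generate_catalog(n_genomes, dropout_rate, seed)
    write_genome_catalog(catalog, outdir / "catalog.tsv")
    scenario = scenario or CommunityScenario(n_genomes=n_genomes, seed=seed)
    matrix, com_ledger = generate_community(scenario)
    write_community(matrix, outdir / "abundance.tsv", outdir / "metadata.tsv")
    truth = {"catalog": cat_ledger, "community": com_ledger}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return truth
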