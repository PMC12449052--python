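"""The strict Wood-Ljungdahl screen that defines a putative acetogen.

A genome is acsB-positive when it carries the acetyl-CoA synthase catalytic
subunit gene, the classic acetogen marker. The strict screen additionally
requires the other five key WL genes (acsA, fhs, fchA, metF, acsE); formate
dehydrogenase is never required, because FDH-lacking acetogens thrive in
formate-rich gut habitats.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import vocab
from .genome_model import GenomeRecord, filter_hydrogenase_hits


@dataclass(frozen=True)
class WLInventory:
    """Presence flags for the 15 WL-associated genes plus derived flags."""

    present: frozenset[str]  # subset of vocab.WL_GENES

    def __post_init__(self) -> None:
        extra = self.present - set(vocab.WL_GENES)
        if extra:
            raise ValueError(f"non-WL symbols in inventory: {sorted(extra)}")

    def has(self, gene: str) -> bool:
        return gene in self.present

    @property
    def fdh_present(self) -> bool:
        """True when either formate dehydrogenase gene (fdhA/fdhF) is present."""
        return any(g in self.present for g in vocab.FDH_GENES)

    @property
    def triad_present(self) -> bool:
        """fdhF + hydA2 + hycB together: the H2-dependent CO2-reductase triad."""
        return all(g in self.present for g in vocab.H2_CO2_REDUCTASE_TRIAD)

    def as_dict(self) -> dict[str, bool]:
        d = {g: g in self.present for g in vocab.WL_GENES}
        d["fdh_present"] = self.fdh_present
        d["triad_present"] = self.triad_present
        return d


@dataclass(frozen=True)
class ScreenVerdict:
    is_acsB_positive: bool
    is_strict_acetogen: bool
    missing_required: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.is_strict_acetogen and not self.is_acsB_positive:
            raise ValueError("strict acetogen must be acsB-positive")
        if self.is_strict_acetogen != (len(self.missing_required) == 0):
            raise ValueError("is_strict_acetogen must mirror empty missing_required")


def build_wl_inventory(genome: GenomeRecord) -> WLInventory:
    """Flag each WL gene present in the genome after evidence filtering.

    Hydrogenase-category hits only count once they survive the evidence
    filter; presence is insensitive to hit multiplicity.
    """
    surviving = filter_hydrogenase_hits(genome.hits)
    symbols = {vocab.normalize_symbol(h.gene_symbol) for h in surviving}
    return WLInventory(present=frozenset(symbols & set(vocab.WL_GENES)))


def screen_strict(inv: WLInventory) -> ScreenVerdict:
    """Apply the six-gene strict acetogen criterion.

    All of acsA, acsB, fhs, fchA, metF, acsE must be present; FDH genes are
    recorded but never required.
    """
    missing = tuple(g for g in vocab.STRICT_REQUIRED if not inv.has(g))
    return ScreenVerdict(
        is_acsB_positive=inv.has("acsB"),
        is_strict_acetogen=len(missing) == 0,
        missing_required=missing,
    )


def screen_genome(genome: GenomeRecord) -> ScreenVerdict:
    """Convenience: inventory + strict screen in one call."""
    return screen_strict(build_wl_inventory(genome))


def verdicts_to_frame(
    catalog: Sequence[GenomeRecord], verdicts: Mapping[str, ScreenVerdict]
) -> pd.DataFrame:
    rows = [
        {
            "genome_id": g.genome_id,
            "is_acsB_positive": verdicts[g.genome_id].is_acsB_positive,
            "is_strict_acetogen": verdicts[g.genome_id].is_strict_acetogen,
            "missing_required": ",".join(verdicts[g.genome_id].missing_required),
        }
        for g in catalog
    ]
    return pd.DataFrame(rows)


def summarize_prevalence(
    catalog: Iterable[tuple[GenomeRecord, ScreenVerdict]],
    group_by: str = "source",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-group acsB-positive prevalence with an across-group summary.

    Groups are the study (``source``) or host-species labels carried by each
    genome. Returns a per-group table (n_genomes, n_acsB_positive,
    percentage) and the median/min/max percentage across groups — summarised
    over groups, not genomes, matching how survey prevalence is reported.
    """
    if group_by not in ("source", "study", "host_species", "taxonomy"):
        raise ValueError(f"unsupported group_by {group_by!r}")
    attr = "source" if group_by in ("source", "study", "host_species") else "taxonomy"
    counts: dict[str, list[int]] = {}
    for genome, verdict in catalog:
        key = getattr(genome, attr) or "(unlabelled)"
        n_pos = counts.setdefault(key, [0, 0])
        n_pos[0] += 1
        n_pos[1] += int(verdict.is_acsB_positive)
    if not counts:
        raise ValueError("empty catalog: nothing to summarize")
    rows = [
        {
            "group": grp,
            "n_genomes": n,
            "n_acsB_positive": pos,
            "acsB_positive_pct": 100.0 * pos / n,
        }
        for grp, (n, pos) in sorted(counts.items())
    ]
    table = pd.DataFrame(rows)
    pcts = table["acsB_positive_pct"].tolist()
    summary = {
        "median_pct": float(median(pcts)),
        "min_pct": float(min(pcts)),
        "max_pct": float(max(pcts)),
        "n_groups": len(pcts),
    }
    return table, summary
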