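"""Domain types, annotation-table I/O, quality gating, and evidence filtering.

The unit of analysis is the annotated genome (a MAG or SAG): a set of gene
hits with optional alignment evidence, plus CheckM-style completeness and
contamination estimates. Tables arrive as one row per gene hit, tab-separated
or as a JSON array of the same records.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import vocab

logger = logging.getLogger(__name__)

#: thresholds of the hydrogenase evidence filter (DIAMOND-vs-HydDB style)
HYD_EVALUE_MAX = 1e-50
HYD_IDENTITY_MIN = 60.0  # strict: identity must exceed this
HYD_LENGTH_MIN = 40      # strict: aligned length must exceed this

REQUIRED_COLUMNS = (
    "genome_id",
    "completeness_pct",
    "contamination_pct",
    "gene_symbol",
    "category",
)
OPTIONAL_COLUMNS = (
    "taxonomy",
    "source",
    "hydrogenase_class",
    "identity_pct",
    "evalue",
    "aligned_length_aa",
    "query_id",
)


class SchemaError(ValueError):
    """An input table is missing a required column or violates the schema."""


class ConsistencyError(ValueError):
    """Rows for one genome carry conflicting quality metrics."""


@dataclass(frozen=True)
class GeneHit:
    """One annotated gene occurrence with optional alignment evidence.

    Evidence fields are ``None`` when the annotation source supplied none;
    absence is preserved, never imputed.
    """

    gene_symbol: str
    category: str
    hydrogenase_class: str | None = None
    identity_pct: float | None = None
    evalue: float | None = None
    aligned_length_aa: int | None = None
    query_id: str | None = None

    def __post_init__(self) -> None:
        if self.category not in vocab.CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.identity_pct is not None and not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(f"identity_pct {self.identity_pct} outside [0, 100]")
        if self.evalue is not None and self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if self.aligned_length_aa is not None and self.aligned_length_aa < 0:
            raise ValueError("aligned_length_aa must be non-negative")
        if (self.hydrogenase_class is not None) != (self.category == "hydrogenase"):
            raise ValueError(
                "hydrogenase_class must be present iff category == 'hydrogenase' "
                f"(got class={self.hydrogenase_class!r}, category={self.category!r})"
            )

    @property
    def has_evidence(self) -> bool:
        return (
            self.identity_pct is not None
            and self.evalue is not None
            and self.aligned_length_aa is not None
        )


@dataclass(frozen=True)
class GenomeRecord:
    """One genome with quality metrics, taxonomy, and its gene-evidence set."""

    genome_id: str
    completeness_pct: float
    contamination_pct: float
    taxonomy: str = ""
    source: str = ""
    hits: tuple[GeneHit, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness_pct <= 100.0:
            raise ValueError(f"completeness_pct {self.completeness_pct} outside [0, 100]")
        if self.contamination_pct < 0:
            raise ValueError("contamination_pct must be >= 0")

    def symbols(self) -> set[str]:
        """Distinct normalized gene symbols present in this genome."""
        return {vocab.normalize_symbol(h.gene_symbol) for h in self.hits}

    def with_hits(self, hits: Iterable[GeneHit]) -> "GenomeRecord":
        return replace(self, hits=tuple(hits))


def classify_quality(genome: GenomeRecord) -> str:
    """Grade a genome as ``high``, ``medium``, or ``fail``.

    High quality requires completeness strictly above 90% with contamination
    strictly below 5%; medium requires completeness at least 50% with
    contamination strictly below 10%. The inequalities are applied literally,
    so a genome at exactly 90% completeness is medium at best.
    """
    comp, cont = genome.completeness_pct, genome.contamination_pct
    if comp is None or cont is None or math.isnan(comp) or math.isnan(cont):
        raise ValueError(f"{genome.genome_id}: missing quality metric")
    if comp > 90.0 and cont < 5.0:
        return "high"
    if comp >= 50.0 and cont < 10.0:
        return "medium"
    return "fail"


def _hit_passes(hit: GeneHit) -> bool:
    return (
        hit.evalue <= HYD_EVALUE_MAX
        and hit.aligned_length_aa > HYD_LENGTH_MIN
        and hit.identity_pct > HYD_IDENTITY_MIN
    )


def filter_hydrogenase_hits(hits: Sequence[GeneHit]) -> tuple[GeneHit, ...]:
    """Apply the hydrogenase evidence filter; other categories pass through.

    A hydrogenase hit survives iff e-value <= 1e-50, aligned length > 40
    residues, and identity > 60% (all strict where stated). Hits missing any
    evidence field cannot satisfy the filter and are dropped with a warning.
    When several hydrogenase hits share a ``query_id``, only the best is kept
    (lowest e-value, then highest identity, then lexicographic query id) —
    one maximum target sequence per query.
    """
    kept: list[GeneHit] = []
    best_by_query: dict[str, GeneHit] = {}
    for hit in hits:
        if hit.category != "hydrogenase":
            kept.append(hit)
            continue
        if not hit.has_evidence:
            logger.warning(
                "hydrogenase hit %s dropped: missing evidence fields", hit.gene_symbol
            )
            continue
        if not _hit_passes(hit):
            continue
        if hit.query_id is None:
            kept.append(hit)
            continue
        prev = best_by_query.get(hit.query_id)
        if prev is None or (hit.evalue, -hit.identity_pct) < (prev.evalue, -prev.identity_pct):
            best_by_query[hit.query_id] = hit
    kept.extend(best_by_query[q] for q in sorted(best_by_query))
    return tuple(kept)


def _parse_hit(row: dict) -> GeneHit:
    symbol = vocab.normalize_symbol(str(row["gene_symbol"]))
    category = row.get("category")
    if category is None or (isinstance(category, float) and math.isnan(category)) or category == "":
        category = vocab.default_category(symbol)
    category = str(category).strip().lower()
    if category not in vocab.CATEGORIES:
        category = "other"

    def _num(key, cast):
        v = row.get(key)
        if v is None or v == "":
            return None
        if isinstance(v, float) and math.isnan(v):
            return None
        return cast(v)

    hyd_class = row.get("hydrogenase_class")
    if hyd_class is not None and (hyd_class == "" or (isinstance(hyd_class, float) and math.isnan(hyd_class))):
        hyd_class = None
    if category == "hydrogenase":
        hyd_class = vocab.normalize_hydrogenase_class(str(hyd_class)) if hyd_class else "unknown"
    else:
        hyd_class = None

    query_id = row.get("query_id")
    if query_id is not None and (query_id == "" or (isinstance(query_id, float) and math.isnan(query_id))):
        query_id = None

    length = _num("aligned_length_aa", float)
    return GeneHit(
        gene_symbol=symbol,
        category=category,
        hydrogenase_class=hyd_class,
        identity_pct=_num("identity_pct", float),
        evalue=_num("evalue", float),
        aligned_length_aa=int(length) if length is not None else None,
        query_id=str(query_id) if query_id is not None else None,
    )


def load_genome_catalog(path: str | Path, format: str | None = None) -> tuple[GenomeRecord, ...]:
    """Read an annotation table into one :class:`GenomeRecord` per genome.

    Accepts tab-separated text with a header, or a JSON array of row objects
    (``format`` inferred from the suffix when not given). Row order never
    affects the result: genomes are returned sorted by id and hits keep a
    stable sorted order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    if fmt == "json":
        rows = json.loads(path.read_text())
        df = pd.DataFrame(rows)
        if df.empty:
            df = pd.DataFrame(columns=REQUIRED_COLUMNS)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    else:
        raise ValueError(f"unknown format {fmt!r}")

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return catalog_from_frame(df)


def catalog_from_frame(df: pd.DataFrame) -> tuple[GenomeRecord, ...]:
    """Build a catalog from a long-format annotation DataFrame."""
    records: list[GenomeRecord] = []
    for gid, grp in sorted(df.groupby("genome_id", sort=True), key=lambda kv: str(kv[0])):
        comp_vals = grp["completeness_pct"].dropna().unique()
        cont_vals = grp["contamination_pct"].dropna().unique()
        if len(comp_vals) > 1 or len(cont_vals) > 1:
            raise ConsistencyError(
                f"genome {gid}: conflicting quality metrics across rows"
            )
        if len(comp_vals) == 0 or len(cont_vals) == 0:
            raise ConsistencyError(f"genome {gid}: missing quality metrics")
        taxonomy = ""
        if "taxonomy" in grp.columns:
            tax_vals = grp["taxonomy"].dropna().unique()
            taxonomy = str(tax_vals[0]) if len(tax_vals) else ""
        source = ""
        if "source" in grp.columns:
            src_vals = grp["source"].dropna().unique()
            source = str(src_vals[0]) if len(src_vals) else ""
        hits = []
        for _, row in grp.iterrows():
            sym = row.get("gene_symbol")
            if sym is None or (isinstance(sym, float) and math.isnan(sym)) or str(sym) == "":
                continue  # genome row with no gene (e.g. empty genome placeholder)
            hits.append(_parse_hit(row.to_dict()))
        hits.sort(key=lambda h: (h.gene_symbol, h.evalue if h.evalue is not None else math.inf))
        records.append(
            GenomeRecord(
                genome_id=str(gid),
                completeness_pct=float(comp_vals[0]),
                contamination_pct=float(cont_vals[0]),
                taxonomy=taxonomy,
                source=source,
                hits=tuple(hits),
            )
        )
    return tuple(records)


def catalog_to_frame(catalog: Sequence[GenomeRecord], with_quality: bool = True) -> pd.DataFrame:
    """Flatten a catalog back to the long row-per-hit schema."""
    rows = []
    for g in catalog:
        base = {
            "genome_id": g.genome_id,
            "completeness_pct": g.completeness_pct,
            "contamination_pct": g.contamination_pct,
            "taxonomy": g.taxonomy,
            "source": g.source,
        }
        if with_quality:
            base["quality_class"] = classify_quality(g)
        if not g.hits:
            rows.append({**base, "gene_symbol": "", "category": ""})
        for h in g.hits:
            rows.append(
                {
                    **base,
                    "gene_symbol": h.gene_symbol,
                    "category": h.category,
                    "hydrogenase_class": h.hydrogenase_class,
                    "identity_pct": h.identity_pct,
                    "evalue": h.evalue,
                    "aligned_length_aa": h.aligned_length_aa,
                    "query_id": h.query_id,
                }
            )
    return pd.DataFrame(rows)


def write_genome_catalog(catalog: Sequence[GenomeRecord], path: str | Path,
                         format: str | None = None) -> None:
    """Write a catalog as TSV (default) or JSON, round-trippable by load."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    df = catalog_to_frame(catalog, with_quality=(fmt == "tsv"))
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        clean = df.drop(columns=["quality_class"], errors="ignore")
        records = [
            {k: v for k, v in row.items() if v is not None and v == v}
            for row in clean.to_dict(orient="records")
        ]
        path.write_text(json.dumps(records, indent=1))
    else:
        raise ValueError(f"unknown format {fmt!r}")
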