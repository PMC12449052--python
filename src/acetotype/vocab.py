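"""Controlled vocabulary for gene symbols, categories, and functional maps.

Annotation sources disagree on casing (``AcsB``, ``acsb``, ``ACSB``); every
symbol entering the data model is normalized case-insensitively against the
canonical tokens below. Symbols outside the vocabulary are kept verbatim and
fall into category ``other`` unless the input table says otherwise.
"""

from __future__ import annotations

from importlib import resources
from functools import lru_cache

import yaml

# Categories a GeneHit may carry.
CATEGORIES = frozenset(
    {"wl_pathway", "hydrogenase", "cazyme", "transporter", "energy", "glycolysis", "other"}
)

# The 15 genes tracked in the Wood-Ljungdahl genomic inventory: the CODH/ACS
# subunits, methyl-branch enzymes, the dispensable formate dehydrogenases and
# the H2-dependent CO2-reductase triad partners, plus pyruvate formate-lyase.
WL_GENES = (
    "acsA", "acsB", "acsC", "acsD", "acsE",
    "fhs", "fchA", "metF", "metV", "rnfC2",
    "fdhA", "fdhF", "hydA2", "hycB", "pfl",
)

# The six genes whose joint presence defines a strict (putative) acetogen.
# Formate dehydrogenase is deliberately absent: FDH-lacking acetogens are
# common in formate-rich gut habitats.
STRICT_REQUIRED = ("acsA", "acsB", "fhs", "fchA", "metF", "acsE")

FDH_GENES = ("fdhA", "fdhF")
H2_CO2_REDUCTASE_TRIAD = ("fdhF", "hydA2", "hycB")

# CAZy glycoside-hydrolase families grouped by preferred substrate class.
SUBSTRATE_CLASSES: dict[str, tuple[str, ...]] = {
    "cellulose": ("GH3", "GH94"),
    "hemicellulose": ("GH2", "GH43"),
    "host_glycan": ("GH18", "GH36"),
    "starch": ("GH13", "GH77"),
}
AMYLASE_FAMILIES = SUBSTRATE_CLASSES["starch"]

# Hydrogenase structural class -> functional role. [FeFe] group A3/A4 couple
# H2 oxidation to electron bifurcation; group B are fermentative H2 evolvers;
# group C are putative H2 sensors. Classes outside the map count as unknown.
HYDROGENASE_FUNCTION: dict[str, str] = {
    "FeFe-A3": "electron_bifurcating",
    "FeFe-A4": "electron_bifurcating",
    "FeFe-B": "fermentative",
    "FeFe-C": "sensory",
}

ENERGY_GENES = {
    "pta": ("pta",),
    "ackA": ("ackA",),
    "rnf_complex": ("rnfA", "rnfB", "rnfC", "rnfD", "rnfE", "rnfG"),
    "ech_complex": ("echA", "echB", "echC", "echD", "echE", "echF"),
    "atp_synthase": ("atpA", "atpB", "atpD", "atpF"),
    "pfor": ("por", "porA", "porB"),
    "pdh": ("aceE", "aceF", "pdhA", "pdhB"),
}
FORMATE_TRANSPORTERS = ("fcoA", "nirC")

_CANONICAL_BY_CATEGORY: dict[str, str] = {}
for _g in WL_GENES:
    _CANONICAL_BY_CATEGORY[_g] = "wl_pathway"
for _cls in SUBSTRATE_CLASSES.values():
    for _g in _cls:
        _CANONICAL_BY_CATEGORY[_g] = "cazyme"
for _gs in ENERGY_GENES.values():
    for _g in _gs:
        _CANONICAL_BY_CATEGORY[_g] = "energy"
for _g in FORMATE_TRANSPORTERS:
    _CANONICAL_BY_CATEGORY[_g] = "transporter"
# generic hydrogenase catalytic-subunit symbols seen in annotation tables
for _g in ("hydA", "hydB", "hydC", "hyaA", "hyaB", "mbhL"):
    _CANONICAL_BY_CATEGORY.setdefault(_g, "hydrogenase")

_LOWER_TO_CANONICAL = {s.lower(): s for s in _CANONICAL_BY_CATEGORY}
_HYD_CLASS_LOWER = {c.lower(): c for c in HYDROGENASE_FUNCTION}


def normalize_symbol(symbol: str) -> str:
    """Map a symbol to its canonical casing; unknown symbols pass through.

    CAZy-family-shaped tokens (``gh13``) are upper-cased even when the family
    is outside the eight substrate-class members, so raw CAZy reporting stays
    consistent.
    """
    s = symbol.strip()
    canon = _LOWER_TO_CANONICAL.get(s.lower())
    if canon is not None:
        return canon
    low = s.lower()
    if (low.startswith(("gh", "gt", "pl", "ce", "cbm", "aa"))
            and any(ch.isdigit() for ch in low)):
        return s.upper()
    return s


def normalize_hydrogenase_class(token: str) -> str:
    """Canonicalize a hydrogenase class token (``fefe-a3`` -> ``FeFe-A3``)."""
    return _HYD_CLASS_LOWER.get(token.strip().lower(), token.strip())


def default_category(symbol: str) -> str:
    """Category of a canonical symbol, ``other`` if not in the vocabulary."""
    canon = normalize_symbol(symbol)
    if canon in _CANONICAL_BY_CATEGORY:
        return _CANONICAL_BY_CATEGORY[canon]
    if canon.upper().startswith(("GH", "GT", "PL", "CE", "CBM")) and any(
        ch.isdigit() for ch in canon
    ):
        return "cazyme"
    return "other"


@lru_cache(maxsize=None)
def pathway_definitions() -> dict[str, tuple[str, ...]]:
    """Gene sets for fermentative glucose-degradation pathways.

    Shipped as editable YAML (``data/pathways.yaml``); the sets follow the
    standard KEGG module composition for the Embden-Meyerhof, pentose
    phosphate and Entner-Doudoroff routes and are a package convention, not a
    measured quantity.
    """
    text = resources.files("acetotype.data").joinpath("pathways.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: tuple(genes) for name, genes in raw.items()}
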