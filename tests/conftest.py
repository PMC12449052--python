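import pandas as pd
import pytest

from acetotype.genome_model import GeneHit, GenomeRecord


def make_genome(genome_id="G1", genes=(), completeness=95.0, contamination=2.0,
                hyd_classes=(), taxonomy="", source="studyA"):
    """Genome with well-evidenced hits for the given symbols/hydrogenase classes."""
    hits = [
        GeneHit(gene_symbol=g, category=None or _cat(g), identity_pct=85.0,
                evalue=1e-80, aligned_length_aa=300)
        for g in genes
    ]
    hits += [
        GeneHit(gene_symbol="hydA", category="hydrogenase", hydrogenase_class=c,
                identity_pct=85.0, evalue=1e-80, aligned_length_aa=300)
        for c in hyd_classes
    ]
    return GenomeRecord(genome_id=genome_id, completeness_pct=completeness,
                        contamination_pct=contamination, taxonomy=taxonomy,
                        source=source, hits=tuple(hits))


def _cat(symbol):
    from acetotype.vocab import default_category
    return default_category(symbol)


@pytest.fixture
def strict_six():
    return ("acsA", "acsB", "fhs", "fchA", "metF", "acsE")


@pytest.fixture
def small_catalog_tsv(tmp_path):
    """3-row TSV, one genome, genes acsB + fhs."""
    df = pd.DataFrame(
        [
            {"genome_id": "M1", "completeness_pct": 92.0, "contamination_pct": 3.0,
             "taxonomy": "d__Bacteria", "gene_symbol": "acsB", "category": "wl_pathway"},
            {"genome_id": "M1", "completeness_pct": 92.0, "contamination_pct": 3.0,
             "taxonomy": "d__Bacteria", "gene_symbol": "fhs", "category": "wl_pathway"},
        ]
    )
    path = tmp_path / "catalog.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path
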