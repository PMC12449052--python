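"""Quality gating, evidence filtering, and annotation-table round trips."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from acetotype.genome_model import (
    GeneHit,
    GenomeRecord,
    HYD_EVALUE_MAX,
    HYD_IDENTITY_MIN,
    HYD_LENGTH_MIN,
    SchemaError,
    ConsistencyError,
    classify_quality,
    filter_hydrogenase_hits,
    load_genome_catalog,
    write_genome_catalog,
)
from conftest import make_genome


class TestQualityGate:
    @pytest.mark.parametrize(
        "completeness,contamination,expected",
        [
            (95.0, 3.0, "high"),
            (90.0, 4.0, "medium"),   # ">90" is strict: exactly 90 is not high
            (91.0, 5.0, "medium"),   # "<5" is strict: exactly 5 is not high
            (50.0, 9.9, "medium"),   # ">=50" is inclusive
            (49.9, 2.0, "fail"),
            (60.0, 10.0, "fail"),    # "<10" is strict
            (100.0, 0.0, "high"),
            (0.0, 0.0, "fail"),
        ],
    )
    def test_boundary_semantics(self, completeness, contamination, expected):
        g = make_genome(completeness=completeness, contamination=contamination)
        assert classify_quality(g) == expected

    def test_missing_metric_raises(self):
        g = make_genome(completeness=80.0, contamination=float("nan"))
        with pytest.raises(ValueError):
            classify_quality(g)

    @given(
        comp=st.floats(0.0, 100.0, allow_nan=False),
        cont=st.floats(0.0, 50.0, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=200)
    def test_total_function(self, comp, cont):
        """Every in-range pair maps to exactly one of the three classes."""
        cls = classify_quality(make_genome(completeness=comp, contamination=cont))
        assert cls in {"high", "medium", "fail"}
        if cls == "high":  # high region is inside the medium-eligible region
            assert comp >= 50.0 and cont < 10.0


def _hyd(evalue, identity, length, query=None):
    return GeneHit(gene_symbol="hydA", category="hydrogenase",
                   hydrogenase_class="FeFe-A3", identity_pct=identity,
                   evalue=evalue, aligned_length_aa=length, query_id=query)


class TestHydrogenaseFilter:
    @pytest.mark.parametrize(
        "evalue,identity,length,kept",
        [
            (1e-60, 75.0, 100, True),
            (1e-60, 60.0, 100, False),  # identity must strictly exceed 60
            (1e-60, 75.0, 40, False),   # length must strictly exceed 40
            (1e-50, 75.0, 100, True),   # e-value bound is inclusive
            (1e-49, 75.0, 100, False),
        ],
    )
    def test_thresholds(self, evalue, identity, length, kept):
        out = filter_hydrogenase_hits([_hyd(evalue, identity, length)])
        assert (len(out) == 1) is kept

    def test_non_hydrogenase_pass_through(self):
        other = GeneHit(gene_symbol="acsB", category="wl_pathway")
        assert filter_hydrogenase_hits([other]) == (other,)

    def test_missing_evidence_excluded(self):
        incomplete = GeneHit(gene_symbol="hydA", category="hydrogenase",
                             hydrogenase_class="FeFe-B")
        assert filter_hydrogenase_hits([incomplete]) == ()

    def test_one_target_per_query_keeps_best(self):
        hits = [
            _hyd(1e-60, 70.0, 100, query="q1"),
            _hyd(1e-80, 65.0, 100, query="q1"),  # lower e-value wins
            _hyd(1e-70, 90.0, 100, query="q2"),
        ]
        out = filter_hydrogenase_hits(hits)
        assert len(out) == 2
        assert {h.evalue for h in out} == {1e-80, 1e-70}

    @given(
        st.lists(
            st.tuples(
                st.floats(1e-120, 1e-20, allow_nan=False),
                st.floats(0.0, 100.0, allow_nan=False),
                st.integers(0, 500),
            ),
            max_size=200,
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_matches_brute_force_and_is_idempotent(self, rows):
        """Retained set equals the brute-force predicate; filter is idempotent
        and order-independent (no shared query ids)."""
        hits = [_hyd(e, i, l) for e, i, l in rows]
        out = filter_hydrogenase_hits(hits)
        brute = tuple(
            h for h in hits
            if h.evalue <= HYD_EVALUE_MAX
            and h.aligned_length_aa > HYD_LENGTH_MIN
            and h.identity_pct > HYD_IDENTITY_MIN
        )
        assert out == brute
        assert filter_hydrogenase_hits(out) == out
        reversed_out = filter_hydrogenase_hits(list(reversed(hits)))
        assert sorted(h.evalue for h in reversed_out) == sorted(h.evalue for h in out)


class TestCatalogIO:
    def test_parse_small_tsv(self, small_catalog_tsv):
        catalog = load_genome_catalog(small_catalog_tsv)
        assert len(catalog) == 1
        (g,) = catalog
        assert g.genome_id == "M1"
        assert len(g.hits) == 2
        assert g.symbols() == {"acsB", "fhs"}

    def test_header_only_file_yields_empty_catalog(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("genome_id\tcompleteness_pct\tcontamination_pct\tgene_symbol\tcategory\n")
        assert load_genome_catalog(path) == ()

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("genome_id\tcompleteness_pct\tgene_symbol\tcategory\nA\t90\tacsB\twl_pathway\n")
        with pytest.raises(SchemaError, match="contamination_pct"):
            load_genome_catalog(path)

    def test_conflicting_quality_metrics_raise(self, tmp_path):
        path = tmp_path / "conflict.tsv"
        path.write_text(
            "genome_id\tcompleteness_pct\tcontamination_pct\tgene_symbol\tcategory\n"
            "A\t90\t1\tacsB\twl_pathway\nA\t80\t1\tfhs\twl_pathway\n"
        )
        with pytest.raises(ConsistencyError):
            load_genome_catalog(path)

    def test_row_order_does_not_matter(self, tmp_path):
        header = "genome_id\tcompleteness_pct\tcontamination_pct\tgene_symbol\tcategory\n"
        r1 = "A\t90\t1\tacsB\twl_pathway\n"
        r2 = "B\t70\t2\tfhs\twl_pathway\n"
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        p1.write_text(header + r1 + r2)
        p2.write_text(header + r2 + r1)
        assert load_genome_catalog(p1) == load_genome_catalog(p2)

    @pytest.mark.parametrize("fmt,suffix", [("tsv", ".tsv"), ("json", ".json")])
    def test_round_trip(self, tmp_path, fmt, suffix):
        """load -> write -> load reproduces an identical catalog."""
        genome = make_genome(
            genome_id="RT1",
            genes=("acsB", "fhs", "GH13"),
            hyd_classes=("FeFe-A3",),
            taxonomy="d__Bacteria;p__Firmicutes_A",
        )
        p1, p2 = tmp_path / f"c1{suffix}", tmp_path / f"c2{suffix}"
        write_genome_catalog([genome], p1, format=fmt)
        loaded1 = load_genome_catalog(p1, format=fmt)
        write_genome_catalog(loaded1, p2, format=fmt)
        assert load_genome_catalog(p2, format=fmt) == loaded1
        assert loaded1[0].symbols() == genome.symbols()
        assert set(loaded1[0].hits) == set(genome.hits)

    def test_symbol_normalization_is_case_insensitive(self, tmp_path):
        path = tmp_path / "case.tsv"
        path.write_text(
            "genome_id\tcompleteness_pct\tcontamination_pct\tgene_symbol\tcategory\n"
            "A\t90\t1\tACSB\twl_pathway\nA\t90\t1\tgh13\tcazyme\nA\t90\t1\tweirdGene\tother\n"
        )
        (g,) = load_genome_catalog(path)
        assert g.symbols() == {"acsB", "GH13", "weirdGene"}
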