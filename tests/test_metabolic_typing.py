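"""Substrate profiling, hydrogenase repertoires, and strategy assignment."""

import pytest

from acetotype import vocab
from acetotype.acetogen_screen import build_wl_inventory
from acetotype.metabolic_typing import (
    assign_strategy,
    classify_hydrogenases,
    energy_systems,
    feature_matrix,
    pathway_completeness,
    profile_genome,
    profile_substrates,
)
from conftest import make_genome


class TestSubstrateProfile:
    def test_starch_counts_and_amylase(self):
        g = make_genome(genes=("GH13",) * 4 + ("GH77",) * 2)
        p = profile_substrates(g)
        assert p.starch == 6 and p.amylase_copies == 6

    def test_empty(self):
        p = profile_substrates(make_genome(genes=("acsB",)))
        assert (p.cellulose, p.hemicellulose, p.host_glycan, p.starch) == (0, 0, 0, 0)

    def test_hemicellulose_families(self):
        p = profile_substrates(make_genome(genes=("GH2", "GH43", "GH43")))
        assert p.hemicellulose == 3

    def test_outside_families_reported_raw_only(self):
        p = profile_substrates(make_genome(genes=("GH25", "GH13")))
        assert p.host_glycan == 0 and p.starch == 1
        assert dict(p.raw_family_counts)["GH25"] == 1


class TestHydrogenaseRepertoire:
    def test_single_a3(self):
        rep = classify_hydrogenases(make_genome(hyd_classes=("FeFe-A3",)))
        assert rep.electron_bifurcating == 1 and rep.any_hydrogenase

    def test_none(self):
        rep = classify_hydrogenases(make_genome(genes=("acsB",)))
        assert not rep.any_hydrogenase

    def test_mixed_set_matches_brute_force(self):
        classes = ("FeFe-A3", "FeFe-A4", "FeFe-B", "FeFe-B", "FeFe-C",
                   "FeFe-A3", "NiFe-4e", "FeFe-B", "FeFe-C", "FeFe-A4")
        rep = classify_hydrogenases(make_genome(hyd_classes=classes))
        tally = {"electron_bifurcating": 0, "fermentative": 0, "sensory": 0, "unknown": 0}
        for c in classes:
            tally[vocab.HYDROGENASE_FUNCTION.get(c, "unknown")] += 1
        assert rep.electron_bifurcating == tally["electron_bifurcating"]
        assert rep.fermentative == tally["fermentative"]
        assert rep.sensory == tally["sensory"]
        assert rep.unknown == tally["unknown"]
        assert rep.any_hydrogenase  # unknown classes count toward the sum


class TestPathwayCompleteness:
    def test_complete_and_empty(self):
        defs = vocab.pathway_definitions()["glycolysis_em"]
        assert pathway_completeness(make_genome(genes=tuple(defs)), defs) == 1.0
        assert pathway_completeness(make_genome(genes=("acsB",)), defs) == 0.0

    def test_partial_fraction(self):
        defs = vocab.pathway_definitions()["glycolysis_em"]  # 10 genes
        assert pathway_completeness(make_genome(genes=tuple(defs[:7])), defs) == pytest.approx(0.7)

    def test_empty_definition_raises(self):
        with pytest.raises(ValueError):
            pathway_completeness(make_genome(), [])


class TestAssignStrategy:
    def _parts(self, genes, hyd_classes):
        g = make_genome(genes=genes, hyd_classes=hyd_classes)
        return build_wl_inventory(g), classify_hydrogenases(g), energy_systems(g)

    def test_full_wl_with_fdh_and_bifurcating(self, strict_six):
        inv, hyd, en = self._parts(strict_six + ("fdhA", "rnfA", "rnfB"),
                                   ("FeFe-A3", "FeFe-A4"))
        label = assign_strategy(inv, hyd, en)
        assert label.label == "hydrogenotrophic_capable"

    def test_no_fdh_with_hydrogenase_and_pfl(self, strict_six):
        inv, hyd, en = self._parts(strict_six + ("pfl",), ("FeFe-A3",))
        label = assign_strategy(inv, hyd, en)
        assert label.label == "formate_dependent_h2_using"
        assert any("pfl" in r for r in label.rationale)

    def test_no_fdh_no_hydrogenase(self, strict_six):
        inv, hyd, en = self._parts(strict_six, ())
        assert assign_strategy(inv, hyd, en).label == "fermentation_electron_only"

    def test_formate_source_unresolved_noted(self, strict_six):
        inv, hyd, en = self._parts(strict_six, ("FeFe-B",))
        label = assign_strategy(inv, hyd, en)
        assert label.label == "formate_dependent_h2_using"
        assert any("unresolved" in r for r in label.rationale)

    def test_fdh_without_bifurcating_falls_through(self, strict_six):
        inv, hyd, en = self._parts(strict_six + ("fdhA",), ())
        assert assign_strategy(inv, hyd, en).label == "fermentation_electron_only"

    def test_non_acetogen_raises(self):
        inv, hyd, en = self._parts(("acsB", "fhs"), ())
        with pytest.raises(ValueError):
            assign_strategy(inv, hyd, en)

    def test_demotion_when_hydrogenases_removed(self, strict_six):
        """Stripping hydrogenase evidence demotes a hydrogenotroph."""
        genes = strict_six + ("fdhA",)
        inv, hyd, en = self._parts(genes, ("FeFe-A3",))
        assert assign_strategy(inv, hyd, en).label == "hydrogenotrophic_capable"
        inv2, hyd2, en2 = self._parts(genes, ())
        demoted = assign_strategy(inv2, hyd2, en2).label
        assert demoted != "hydrogenotrophic_capable"

    def test_labels_partition_strict_acetogens(self, strict_six):
        """Every gene/hydrogenase combination yields exactly one label."""
        import itertools
        for fdh, hyds in itertools.product(
            [(), ("fdhA",), ("fdhF", "hydA2", "hycB")],
            [(), ("FeFe-A3",), ("FeFe-B",), ("FeFe-C",)],
        ):
            inv, hyd, en = self._parts(strict_six + fdh, hyds)
            label = assign_strategy(inv, hyd, en)
            assert label.label in {"hydrogenotrophic_capable",
                                   "formate_dependent_h2_using",
                                   "fermentation_electron_only"}
            assert label.rationale


class TestFeatureMatrix:
    def test_single_genome_reproduces_components(self, strict_six):
        g = make_genome(genome_id="X", genes=strict_six + ("GH13", "fdhA"),
                        hyd_classes=("FeFe-A3",))
        fm = feature_matrix([g])
        assert len(fm) == 1
        row = fm.iloc[0]
        p = profile_genome(g)
        assert row["strategy"] == p.strategy.label == "hydrogenotrophic_capable"
        assert row["cazy_starch"] == 1
        assert bool(row["fdh_present"])

    def test_shape_and_no_missing_cells(self):
        from acetotype.synthetic import generate_catalog
        catalog, _ = generate_catalog(75, 0.0, seed=3)
        fm = feature_matrix(catalog)
        assert fm.shape[0] == 75
        assert not fm.isna().any().any()

    def test_input_order_invariance(self, strict_six):
        gs = [make_genome(genome_id=f"g{i}", genes=strict_six) for i in range(5)]
        fm1 = feature_matrix(gs)
        fm2 = feature_matrix(list(reversed(gs)))
        assert fm1.equals(fm2)
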