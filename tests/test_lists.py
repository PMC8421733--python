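"""Named-list construction: DE selection, FPKM ranking, projection, variants."""

import numpy as np
import pytest

from chdprio.core import (
    Consequence,
    DEGRecord,
    GeneList,
    HomologMap,
    Inheritance,
    Lineage,
    Namespace,
    VariantRecord,
    human_gene,
    mouse_gene,
)
from chdprio.lists import (
    LIST_PRESETS,
    FPKMRecord,
    ListSpec,
    build_named_list,
    compute_fpkm,
    genes_with_variants,
    lineage_filter_via_homologs,
    project_homologs,
    require_homolog,
    select_degs,
    top_expressed,
)
from chdprio.markers import CellTypeAssignment, lineage_filter


def _deg(sym, total, padj, pvalue=None):
    p = padj / 2 if pvalue is None else pvalue
    return DEGRecord(mouse_gene(sym), total, 1.0, p, padj)


class TestSelectDEGs:
    def test_count_boundary_exclusive_at_five(self):
        recs = [_deg("Ga", 5, 0.01), _deg("Gb", 6, 0.01)]
        assert select_degs(recs).symbols == ["Gb"]

    def test_padj_boundary_inclusive(self):
        recs = [_deg("Ga", 100, 0.05), _deg("Gb", 100, 0.051)]
        assert select_degs(recs).symbols == ["Ga"]

    def test_empty_input(self):
        assert len(select_degs([])) == 0

    def test_all_padj_missing_rejected(self):
        recs = [DEGRecord(mouse_gene("Ga"), 10, 1.0, 0.01, None)]
        with pytest.raises(ValueError, match="adjusted p"):
            select_degs(recs)

    def test_provenance_records_both_filters(self):
        out = select_degs([_deg("Ga", 100, 0.01), _deg("Gb", 3, 0.01)])
        text = "\n".join(out.provenance)
        assert "total_counts > 5" in text and "padj <= 0.05" in text


class TestComputeFPKM:
    def test_closed_form(self):
        recs = compute_fpkm(
            {mouse_gene("Ga"): [10]}, {mouse_gene("Ga"): 2000}, totals=[1e6]
        )
        assert recs[0].mean_fpkm == pytest.approx(5.0)

    def test_zero_count_is_zero(self):
        recs = compute_fpkm({mouse_gene("Ga"): [0, 0]}, {mouse_gene("Ga"): 1000}, totals=[1e6, 2e6])
        assert recs[0].mean_fpkm == 0.0

    def test_doubling_total_halves_fpkm(self):
        counts = {mouse_gene("Ga"): [50]}
        lengths = {mouse_gene("Ga"): 1500}
        one = compute_fpkm(counts, lengths, totals=[1e6])[0].mean_fpkm
        two = compute_fpkm(counts, lengths, totals=[2e6])[0].mean_fpkm
        assert one == pytest.approx(2 * two)

    def test_missing_length_names_gene(self):
        with pytest.raises(ValueError, match="Ga"):
            compute_fpkm({mouse_gene("Ga"): [1]}, {}, totals=[1e6])

    def test_default_totals_are_column_sums(self):
        counts = {mouse_gene("Ga"): [10, 10], mouse_gene("Gb"): [90, 190]}
        recs = compute_fpkm(counts, {mouse_gene("Ga"): 1000, mouse_gene("Gb"): 1000})
        # totals 100 and 200 -> FPKM for Ga: 10/(1*1e-4)=1e5 and 10/(2e-4)=5e4
        assert recs[0].fpkm_per_sample == pytest.approx((1e5, 5e4))


class TestTopExpressed:
    def _rec(self, sym, fpkm):
        return FPKMRecord(mouse_gene(sym), (fpkm,), fpkm)

    def test_top_two(self):
        recs = [self._rec(s, v) for s, v in [("Ga", 1), ("Gb", 9), ("Gc", 5), ("Gd", 3), ("Ge", 2)]]
        assert top_expressed(recs, 2).symbols == ["Gb", "Gc"]

    def test_tie_at_boundary_lexicographic(self):
        recs = [self._rec(s, v) for s, v in [("Gz", 5.0), ("Ga", 5.0), ("Gb", 9.0)]]
        # rank 2 is tied between Ga and Gz: the lexicographically smaller wins
        assert top_expressed(recs, 2).symbols == ["Ga", "Gb"]

    def test_n_equals_all(self):
        recs = [self._rec(s, v) for s, v in [("Ga", 1), ("Gb", 2)]]
        assert set(top_expressed(recs, 2).symbols) == {"Ga", "Gb"}

    def test_n_too_large_rejected(self):
        with pytest.raises(ValueError):
            top_expressed([self._rec("Ga", 1)], 2)


def _map(*pairs):
    return HomologMap(frozenset((mouse_gene(m), human_gene(h)) for m, h in pairs))


class TestProjectHomologs:
    def test_one_to_many_expands(self):
        hmap = _map(("GeneA", "HUMA1"), ("GeneA", "HUMA2"), ("GeneB", "HUMB"))
        gl = GeneList("L", Namespace.MOUSE, frozenset({mouse_gene("GeneA"), mouse_gene("GeneB")}))
        out = project_homologs(gl, hmap, Namespace.HUMAN)
        assert out.symbols == ["HUMA1", "HUMA2", "HUMB"]

    def test_partnerless_gene_dropped_and_counted(self):
        hmap = _map(("GeneA", "HUMA"))
        gl = GeneList("L", Namespace.MOUSE, frozenset({mouse_gene("GeneA"), mouse_gene("GeneX")}))
        out = project_homologs(gl, hmap, Namespace.HUMAN)
        assert out.symbols == ["HUMA"]
        assert "1 without partner dropped" in out.provenance[-1]

    def test_round_trip_superset_only_for_bijections(self):
        rng = np.random.default_rng(0)
        # bijective map: there-and-back returns exactly the start
        bij = _map(*[(f"Gm{i}", f"HS{i}") for i in range(10)])
        gl = GeneList("L", Namespace.MOUSE, frozenset(mouse_gene(f"Gm{i}") for i in range(5)))
        back = project_homologs(project_homologs(gl, bij, "human"), bij, "mouse")
        assert back.genes == gl.genes
        # many-to-one map: the round trip can gain members
        m2o = _map(("Gm0", "HS0"), ("Gm1", "HS0"))
        gl2 = GeneList("L", Namespace.MOUSE, frozenset({mouse_gene("Gm0")}))
        back2 = project_homologs(project_homologs(gl2, m2o, "human"), m2o, "mouse")
        assert back2.genes >= gl2.genes and len(back2) == 2

    def test_empty_map_rejected(self):
        gl = GeneList("L", Namespace.MOUSE, frozenset({mouse_gene("Ga")}))
        with pytest.raises(ValueError, match="empty"):
            project_homologs(gl, HomologMap(frozenset()), "human")

    def test_same_namespace_rejected(self):
        gl = GeneList("L", Namespace.MOUSE, frozenset({mouse_gene("Ga")}))
        with pytest.raises(ValueError):
            project_homologs(gl, _map(("Ga", "GA")), "mouse")


def _variants():
    return [
        VariantRecord("P1", human_gene("A"), Consequence.MISSENSE, Inheritance.DE_NOVO, "TOF"),
        VariantRecord("P2", human_gene("B"), Consequence.LOSS_OF_FUNCTION, Inheritance.INHERITED, "TOF"),
        VariantRecord("P3", human_gene("C"), Consequence.SYNONYMOUS, Inheritance.DE_NOVO, "TOF"),
    ]


class TestGenesWithVariants:
    def test_de_novo_nonsynonymous(self):
        assert genes_with_variants(_variants(), "TOF").symbols == ["A"]

    def test_any_inheritance(self):
        assert genes_with_variants(_variants(), "TOF", inheritance="any").symbols == ["A", "B"]

    def test_keep_synonymous(self):
        out = genes_with_variants(_variants(), "TOF", drop_synonymous=False)
        assert out.symbols == ["A", "C"]

    def test_empty_cohort(self):
        assert len(genes_with_variants([], "TOF")) == 0

    def test_unknown_diagnosis_warns_not_raises(self):
        with pytest.warns(UserWarning, match="SLV"):
            out = genes_with_variants(_variants(), "SLV")
        assert len(out) == 0

    def test_provenance_counts_patients_and_variants(self):
        out = genes_with_variants(_variants(), "TOF")
        assert "3 patients" in out.provenance[0]


class TestBuildNamedList:
    ANNOT = {"c0": Lineage.BLOOD, "c1": Lineage.MYOCARDIAL}

    def _assignment(self):
        return CellTypeAssignment(
            clusters_by_gene={mouse_gene("Gb"): frozenset({"c0"})},  # blood-specific
            annotation=self.ANNOT,
        )

    def _inputs(self):
        degs = [_deg("Ga", 100, 0.01), _deg("Gb", 100, 0.01), _deg("Gc", 100, 0.5), _deg("Gd", 4, 0.01)]
        hmap = _map(("Ga", "GA"), ("Gb", "GB"), ("Gc", "GC"))
        return degs, hmap

    def test_deg_preset_equals_manual_composition(self):
        degs, hmap = self._inputs()
        asg = self._assignment()
        auto = build_named_list(LIST_PRESETS["deg_hh"], degs=degs, homolog_map=hmap, assignment=asg)
        manual = project_homologs(
            lineage_filter(select_degs(degs), asg, "exclude_lineages",
                           {Lineage.BLOOD, Lineage.ECTODERMAL}),
            hmap, "human",
        )
        assert auto.genes == manual.genes
        assert auto.symbols == ["GA"]  # Gb blood-specific, Gc not DE, Gd low counts

    def test_variant_preset_provenance_steps(self):
        variants = [
            VariantRecord("P1", human_gene("GA"), Consequence.MISSENSE, Inheritance.DE_NOVO, "TOF", "jin"),
            VariantRecord("P2", human_gene("GB"), Consequence.MISSENSE, Inheritance.DE_NOVO, "TOF", "jin"),
            VariantRecord("P3", human_gene("ZZ"), Consequence.MISSENSE, Inheritance.DE_NOVO, "TOF", "jin"),
        ]
        _, hmap = self._inputs()
        out = build_named_list(
            LIST_PRESETS["tof_dn_mh"], variants=variants, homolog_map=hmap, assignment=self._assignment()
        )
        # GA kept; GB's only mouse partner is blood-specific; ZZ has no homolog
        assert out.symbols == ["GA"]
        assert len(out.provenance) >= 4

    def test_no_filter_spec_is_identity(self):
        degs, _ = self._inputs()
        out = build_named_list(ListSpec("raw", "deg"), degs=degs)
        assert len(out) == len(degs)

    def test_filters_validated_against_source(self):
        with pytest.raises(ValueError, match="not applicable"):
            ListSpec("bad", "deg", ({"kind": "diagnosis", "value": "TOF"},))

    def test_monotone_filters_never_grow_lists(self):
        degs, hmap = self._inputs()
        sel = select_degs(degs)
        req = require_homolog(sel, hmap)
        assert len(req) <= len(sel)
        fil = lineage_filter(req, self._assignment(), "exclude_lineages", {Lineage.BLOOD})
        assert len(fil) <= len(req)


class TestLineageProjectionCommutes:
    def test_mouse_filter_then_project_matches_human_side_filter(self):
        # for one-to-one maps, filtering on the mouse side then projecting
        # equals projecting then filtering each human gene via its partner
        rng = np.random.default_rng(42)
        for trial in range(20):
            n = 12
            hmap = _map(*[(f"Gm{i}", f"HS{i}") for i in range(n)])
            annotation = {"c0": Lineage.BLOOD, "c1": Lineage.VSMC}
            assigned = {
                mouse_gene(f"Gm{i}"): frozenset(
                    c for c in ("c0", "c1") if rng.random() < 0.4
                )
                for i in range(n)
            }
            asg = CellTypeAssignment(
                clusters_by_gene={g: c for g, c in assigned.items() if c}, annotation=annotation
            )
            members = frozenset(mouse_gene(f"Gm{i}") for i in range(n) if rng.random() < 0.6)
            gl = GeneList("L", Namespace.MOUSE, members)
            route_a = project_homologs(
                lineage_filter(gl, asg, "exclude_lineages", {Lineage.BLOOD}), hmap, "human"
            )
            route_b = lineage_filter_via_homologs(
                project_homologs(gl, hmap, "human"), hmap, asg, "exclude_lineages", {Lineage.BLOOD}
            )
            assert route_a.genes == route_b.genes
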