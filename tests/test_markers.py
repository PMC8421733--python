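"""Selection-marker removal, normalization, marker calling, lineage filters."""

import math

import numpy as np
import pytest
import scipy.sparse as sp

from chdprio.core import CellMatrix, GeneList, Lineage, Namespace, NamespaceError, human_gene, mouse_gene
from chdprio.markers import (
    CellTypeAssignment,
    MarkerParams,
    MarkerRecord,
    assign_gene_celltypes,
    find_cluster_markers,
    lineage_filter,
    log_normalize,
    remove_marked_cells,
)

NEOR = mouse_gene("NeoR")


class TestRemoveMarkedCells:
    def test_positive_cells_removed(self, toy_matrix):
        out = remove_marked_cells(toy_matrix, NEOR)
        assert out.n_cells == 4  # cells 1 and 3 carry NeoR reads
        assert out.cell_ids == ["c0", "c2", "c4", "c5"]
        assert out.n_genes == toy_matrix.n_genes

    def test_idempotent(self, toy_matrix):
        once = remove_marked_cells(toy_matrix, NEOR)
        twice = remove_marked_cells(once, NEOR)
        assert twice.cell_ids == once.cell_ids

    def test_absent_marker_warns_and_returns_identity(self, toy_matrix):
        with pytest.warns(UserWarning, match="not present"):
            out = remove_marked_cells(toy_matrix, mouse_gene("Missing"))
        assert out is toy_matrix

    def test_all_negative_is_identity(self, toy_matrix):
        clean = remove_marked_cells(toy_matrix, NEOR)
        again = remove_marked_cells(clean, NEOR)
        assert again.n_cells == clean.n_cells


class TestLogNormalize:
    def test_zero_counts_stay_zero(self, toy_matrix):
        norm = log_normalize(toy_matrix)
        dense = np.asarray(norm.todense())
        raw = np.asarray(toy_matrix.counts.todense())
        assert (dense[raw == 0] == 0).all()

    def test_closed_form_single_gene_cell(self):
        m = CellMatrix(
            counts=sp.csr_matrix(np.array([[7, 1], [0, 1]])),
            gene_ids=[mouse_gene("Ga"), mouse_gene("Gb")],
            cell_ids=["c0", "c1"],
            cluster_labels=["A", "A"],
            lineage_of_cluster={"A": Lineage.BLOOD},
        )
        norm = np.asarray(log_normalize(m, scale=1e4).todense())
        # cell 0: the single expressed gene holds the full depth
        assert norm[0, 0] == pytest.approx(math.log(10001))

    def test_expm1_column_sums_equal_scale(self, toy_matrix):
        scale = 1e4
        norm = log_normalize(toy_matrix, scale=scale)
        col_sums = np.asarray(norm.copy().expm1().sum(axis=0)).ravel()
        assert col_sums == pytest.approx(np.full(toy_matrix.n_cells, scale))

    def test_zero_total_cell_rejected(self):
        m = CellMatrix(
            counts=sp.csr_matrix(np.array([[1, 0], [2, 0]])),
            gene_ids=[mouse_gene("Ga"), mouse_gene("Gb")],
            cell_ids=["c0", "dead"],
            cluster_labels=["A", "A"],
            lineage_of_cluster={"A": Lineage.BLOOD},
        )
        with pytest.raises(ValueError, match="dead"):
            log_normalize(m)


def _planted_matrix(seed=0, n_in=20, n_out=60):
    """One strong marker (g0) in cluster A, a flat gene, background noise.

    A ballast gene pins every cell's depth to the same total, so normalized
    values of the flat gene really are identical across cells.
    """
    rng = np.random.default_rng(seed)
    g0 = np.concatenate([rng.poisson(6.0, n_in), rng.poisson(0.2, n_out)])
    flat = np.full(n_in + n_out, 2)
    bg1 = rng.poisson(1.0, n_in + n_out)
    bg2 = rng.poisson(1.0, n_in + n_out)
    depth = 40
    ballast = depth - (g0 + flat + bg1 + bg2)
    assert (ballast > 0).all()
    counts = np.vstack([g0, flat, bg1, bg2, ballast])
    labels = ["A"] * n_in + ["B"] * n_out
    m = CellMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=[mouse_gene(s) for s in ["g0", "flat", "bg1", "bg2", "ballast"]],
        cell_ids=[f"c{i}" for i in range(n_in + n_out)],
        cluster_labels=labels,
        lineage_of_cluster={"A": Lineage.VSMC, "B": Lineage.BLOOD},
    )
    return m


class TestFindClusterMarkers:
    def test_planted_marker_statistics(self):
        m = _planted_matrix()
        norm = log_normalize(m)
        records = find_cluster_markers(norm, m.gene_ids, m.cluster_labels, MarkerParams())
        rec = next(r for r in records if r.gene.symbol == "g0" and r.cluster == "A")
        # oracle: presence fractions computed directly from the raw counts
        raw = np.asarray(m.counts.todense())
        labels = np.asarray(m.cluster_labels)
        assert rec.pct_in == pytest.approx((raw[0, labels == "A"] > 0).mean())
        assert rec.pct_out == pytest.approx((raw[0, labels == "B"] > 0).mean())
        assert rec.pct_in > 0.9 and rec.pct_out < 0.4
        assert rec.log_fc > 0.5 and rec.padj < 1e-6

    def test_identical_values_filtered_before_testing(self):
        m = _planted_matrix()
        norm = log_normalize(m)
        records = find_cluster_markers(norm, m.gene_ids, m.cluster_labels, MarkerParams())
        # the flat gene has log_fc ~ 0 in every cluster: below the gate
        assert not any(r.gene.symbol == "flat" for r in records)

    def test_min_pct_gate(self):
        # a gene present in 10% of cells everywhere is never eligible at 0.25
        rng = np.random.default_rng(3)
        rare = (rng.random(80) < 0.10).astype(int) * 5
        other = np.full(80, 1)
        m = CellMatrix(
            counts=sp.csr_matrix(np.vstack([rare, other])),
            gene_ids=[mouse_gene("rare"), mouse_gene("other")],
            cell_ids=[f"c{i}" for i in range(80)],
            cluster_labels=["A"] * 40 + ["B"] * 40,
            lineage_of_cluster={"A": Lineage.VSMC, "B": Lineage.BLOOD},
        )
        records = find_cluster_markers(log_normalize(m), m.gene_ids, m.cluster_labels, MarkerParams())
        assert not any(r.gene.symbol == "rare" for r in records)

    def test_wald_matches_hand_formula(self):
        m = _planted_matrix(seed=5)
        norm = log_normalize(m)
        params = MarkerParams(test="wald_normal")
        records = find_cluster_markers(norm, m.gene_ids, m.cluster_labels, params)
        rec = next(r for r in records if r.gene.symbol == "g0" and r.cluster == "A")
        from scipy.stats import norm as normal

        x = np.asarray(norm.todense())[0]
        labels = np.asarray(m.cluster_labels)
        a, b = x[labels == "A"], x[labels == "B"]
        se = math.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        expect = 2 * normal.sf(abs((a.mean() - b.mean()) / se))
        assert rec.pvalue == pytest.approx(expect, rel=1e-9)

    def test_label_permutation_invariance(self):
        m = _planted_matrix(seed=7)
        norm = log_normalize(m)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.n_cells)
        rec_a = find_cluster_markers(norm, m.gene_ids, m.cluster_labels, MarkerParams())
        labels_p = [m.cluster_labels[i] for i in perm]
        rec_b = find_cluster_markers(norm[:, perm], m.gene_ids, labels_p, MarkerParams())
        key = lambda r: (r.gene.symbol, r.cluster)
        assert sorted(map(key, rec_a)) == sorted(map(key, rec_b))
        for ra, rb in zip(sorted(rec_a, key=key), sorted(rec_b, key=key)):
            assert ra.pvalue == pytest.approx(rb.pvalue, rel=1e-9)

    def test_small_cluster_rejected(self):
        m = _planted_matrix()
        labels = ["A"] * 2 + ["B"] * (m.n_cells - 2)
        with pytest.raises(ValueError, match="A"):
            find_cluster_markers(log_normalize(m), m.gene_ids, labels, MarkerParams())

    def test_single_cluster_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="2 clusters"):
            find_cluster_markers(
                log_normalize(toy_matrix), toy_matrix.gene_ids, ["A"] * 6, MarkerParams()
            )


def _mk_record(sym, cluster, padj, log_fc=1.0):
    return MarkerRecord(mouse_gene(sym), cluster, log_fc, 0.8, 0.1, padj / 2, padj)


class TestAssignment:
    ANNOT = {"A": Lineage.VSMC, "B": Lineage.BLOOD, "C": Lineage.MYOCARDIAL}

    def test_single_cluster_assignment(self):
        asg = assign_gene_celltypes([_mk_record("g", "A", 0.01)], MarkerParams(), self.ANNOT)
        assert asg.clusters_by_gene[mouse_gene("g")] == {"A"}
        assert asg.lineages_of(mouse_gene("g")) == {Lineage.VSMC}

    def test_multi_cluster_assignment_retained(self):
        asg = assign_gene_celltypes(
            [_mk_record("g", "A", 0.01), _mk_record("g", "C", 0.02)], MarkerParams(), self.ANNOT
        )
        assert asg.clusters_by_gene[mouse_gene("g")] == {"A", "C"}

    def test_boundary_padj_inclusive(self):
        asg = assign_gene_celltypes([_mk_record("g", "A", 0.05)], MarkerParams(), self.ANNOT)
        assert asg.is_assigned(mouse_gene("g"))

    def test_negative_fold_change_not_specific(self):
        asg = assign_gene_celltypes([_mk_record("g", "A", 0.01, log_fc=-2.0)], MarkerParams(), self.ANNOT)
        assert not asg.is_assigned(mouse_gene("g"))


class TestLineageFilter:
    ANNOT = {"A": Lineage.BLOOD, "B": Lineage.MYOCARDIAL, "C": Lineage.ECTODERMAL}

    def _asg(self, mapping):
        return CellTypeAssignment(
            clusters_by_gene={mouse_gene(k): frozenset(v) for k, v in mapping.items()},
            annotation=self.ANNOT,
        )

    def _list(self, *symbols):
        return GeneList("L", Namespace.MOUSE, frozenset(mouse_gene(s) for s in symbols))

    def test_blood_only_gene_removed(self):
        asg = self._asg({"g1": {"A"}, "g2": {"B"}})
        out = lineage_filter(self._list("g1", "g2"), asg, "exclude_lineages",
                             {Lineage.BLOOD, Lineage.ECTODERMAL})
        assert out.symbols == ["g2"]

    def test_mixed_lineage_gene_retained(self):
        asg = self._asg({"g1": {"A", "B"}})  # blood AND myocardium
        out = lineage_filter(self._list("g1"), asg, "exclude_lineages",
                             {Lineage.BLOOD, Lineage.ECTODERMAL})
        assert out.symbols == ["g1"]

    def test_unassigned_gene_kept_by_default(self):
        out = lineage_filter(self._list("g9"), self._asg({}), "exclude_lineages", {Lineage.BLOOD})
        assert out.symbols == ["g9"]

    def test_require_mode(self):
        asg = self._asg({"g1": {"A"}, "g2": {"B"}})
        out = lineage_filter(self._list("g1", "g2", "g3"), asg, "require_lineages",
                             {Lineage.MYOCARDIAL}, keep_unassigned=False)
        assert out.symbols == ["g2"]

    def test_never_grows_and_exclude_idempotent(self):
        asg = self._asg({"g1": {"A"}, "g2": {"B"}, "g3": {"C"}})
        start = self._list("g1", "g2", "g3", "g4")
        once = lineage_filter(start, asg, "exclude_lineages", {Lineage.BLOOD, Lineage.ECTODERMAL})
        twice = lineage_filter(once, asg, "exclude_lineages", {Lineage.BLOOD, Lineage.ECTODERMAL})
        assert len(once) <= len(start)
        assert once.genes == twice.genes

    def test_human_list_rejected(self):
        hl = GeneList("h", Namespace.HUMAN, frozenset({human_gene("NOTCH1")}))
        with pytest.raises(NamespaceError):
            lineage_filter(hl, self._asg({}), "exclude_lineages", {Lineage.BLOOD})
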