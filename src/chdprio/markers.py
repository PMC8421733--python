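"""Single-cell lineage-specificity calling.

Stages mirror a standard droplet scRNA-seq marker workflow: remove cells
carrying the genotype-selection marker (a neomycin-resistance cassette marks
heterozygote cells in the source experiment), depth-normalize, call one-vs-
rest cluster markers under joint fold-change / percent-expressed gates, and
map each gene to the cell lineages where it is specifically expressed.  The
resulting assignment drives the lineage exclusion filter: genes specific
only to lineages that do not contribute to the outflow tract (blood,
ectoderm) are dropped from candidate lists.

Two significance tests are available.  ``rank_sum`` is the Wilcoxon rank-sum
(Mann–Whitney) test with normal approximation and tie correction;
``wald_normal`` is a difference of means over a pooled standard error on the
log-normalized values.  Both operate on the same pre-filtered (gene,
cluster) family and feed one joint BH adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp
from scipy import stats as sps

from .core import CellMatrix, GeneList, GeneRef, Lineage, Namespace, NamespaceError
from .stats import bh_adjust

__all__ = [
    "MarkerParams",
    "MarkerRecord",
    "CellTypeAssignment",
    "remove_marked_cells",
    "log_normalize",
    "find_cluster_markers",
    "assign_gene_celltypes",
    "lineage_filter",
]

#: Pseudocount for fold-change ratios of expm1-means, pinning the natural-log
#: convention under which the 0.5 threshold is interpreted.
LOGFC_PSEUDOCOUNT = 1e-9


@dataclass(frozen=True)
class MarkerParams:
    logfc_threshold: float = 0.5
    min_pct: float = 0.25
    padj_cutoff: float = 0.05
    test: Literal["rank_sum", "wald_normal"] = "rank_sum"

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_pct <= 1.0):
            raise ValueError("min_pct must lie in [0, 1]")
        if not (0.0 <= self.padj_cutoff <= 1.0):
            raise ValueError("padj_cutoff must lie in [0, 1]")
        if self.test not in ("rank_sum", "wald_normal"):
            raise ValueError(f"unknown test {self.test!r}")


@dataclass(frozen=True)
class MarkerRecord:
    """Specificity statistics for one (gene, cluster) pair."""

    gene: GeneRef
    cluster: str
    log_fc: float
    pct_in: float
    pct_out: float
    pvalue: float
    padj: float

    def __post_init__(self) -> None:
        for label, v in (("pct_in", self.pct_in), ("pct_out", self.pct_out)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{label} {v} outside [0, 1]")
        if self.padj < self.pvalue - 1e-12:
            raise ValueError(f"padj {self.padj} < pvalue {self.pvalue}")


def remove_marked_cells(m: CellMatrix, marker_gene: GeneRef) -> CellMatrix:
    """Drop every cell with at least one read of the selection marker.

    If the marker gene is absent from the matrix, the input is returned
    unchanged with a warning.  Idempotent: the surviving cells all have zero
    marker counts.
    """
    idx = m.gene_index().get(marker_gene)
    if idx is None:
        warnings.warn(f"selection marker {marker_gene} not present; no cells removed")
        return m
    marker_counts = np.asarray(m.counts[idx].todense()).ravel()
    return m.subset_cells(marker_counts == 0)


def log_normalize(m: CellMatrix, scale: float = 1e4) -> sp.csr_matrix:
    """Per-cell depth normalization: ``ln(1 + scale * count / cell_total)``.

    Zero counts stay exactly zero, so sparsity is preserved.  Cells with zero
    total counts cannot be normalized and raise an error naming them.
    """
    totals = np.asarray(m.counts.sum(axis=0)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [m.cell_ids[i] for i in zero[:5]]
        raise ValueError(f"{zero.size} cell(s) have zero total counts, e.g. {names}")
    norm = m.counts.tocsc(copy=True).astype(float)
    for j in range(norm.shape[1]):
        sl = slice(norm.indptr[j], norm.indptr[j + 1])
        norm.data[sl] = np.log1p(scale * norm.data[sl] / totals[j])
    return norm.tocsr()


def _rank_sum_p(values: np.ndarray, in_mask: np.ndarray) -> float:
    # Wilcoxon rank-sum, two-sided, normal approximation with tie correction
    # and continuity correction (matches scipy's asymptotic Mann-Whitney U).
    res = sps.mannwhitneyu(values[in_mask], values[~in_mask], alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _wald_p(values: np.ndarray, in_mask: np.ndarray) -> float:
    x, y = values[in_mask], values[~in_mask]
    n1, n2 = x.size, y.size
    se = np.sqrt(x.var(ddof=1) / n1 + y.var(ddof=1) / n2)
    if se == 0.0:
        return 1.0
    z = (x.mean() - y.mean()) / se
    return float(2.0 * sps.norm.sf(abs(z)))


def find_cluster_markers(
    norm: sp.csr_matrix,
    gene_ids: Sequence[GeneRef],
    labels: Sequence[str],
    params: MarkerParams = MarkerParams(),
) -> list[MarkerRecord]:
    """One-vs-rest cluster marker statistics for every eligible pair.

    A (gene, cluster) pair is tested only if ``max(pct_in, pct_out) >=
    min_pct`` and ``|log_fc| >= logfc_threshold`` (both inclusive).  The
    fold change is the natural log of the ratio of within/without means of
    ``expm1(normalized)`` plus a small pseudocount.  P-values for all tested
    pairs form one family for BH adjustment; no significance cut is applied
    here — callers decide downstream.
    """
    norm = sp.csr_matrix(norm)
    labels_arr = np.asarray(labels)
    if norm.shape[1] != labels_arr.size:
        raise ValueError("label vector length does not match cell count")
    clusters = sorted(set(labels_arr.tolist()))
    if len(clusters) < 2:
        raise ValueError("marker calling needs at least 2 clusters")
    for c in clusters:
        if int((labels_arr == c).sum()) < 3:
            raise ValueError(f"cluster {c!r} has fewer than 3 cells")

    n_genes, n_cells = norm.shape
    masks = {c: labels_arr == c for c in clusters}
    present = norm.copy()
    present.data = np.ones_like(present.data)
    expm1 = norm.copy()
    expm1.data = np.expm1(expm1.data)

    # per-cluster per-gene presence fractions and expm1 means, vectorized
    pct_in: dict[str, np.ndarray] = {}
    pct_out: dict[str, np.ndarray] = {}
    lfc: dict[str, np.ndarray] = {}
    total_present = np.asarray(present.sum(axis=1)).ravel()
    total_expm1 = np.asarray(expm1.sum(axis=1)).ravel()
    for c in clusters:
        n_in = int(masks[c].sum())
        n_out = n_cells - n_in
        in_present = np.asarray(present[:, masks[c]].sum(axis=1)).ravel()
        in_sum = np.asarray(expm1[:, masks[c]].sum(axis=1)).ravel()
        pct_in[c] = in_present / n_in
        pct_out[c] = (total_present - in_present) / n_out
        mean_in = in_sum / n_in
        mean_out = (total_expm1 - in_sum) / n_out
        lfc[c] = np.log(mean_in + LOGFC_PSEUDOCOUNT) - np.log(mean_out + LOGFC_PSEUDOCOUNT)

    test_fn = _rank_sum_p if params.test == "rank_sum" else _wald_p
    candidates: list[tuple[int, str]] = []
    for c in clusters:
        eligible = (np.maximum(pct_in[c], pct_out[c]) >= params.min_pct) & (
            np.abs(lfc[c]) >= params.logfc_threshold
        )
        candidates.extend((int(g), c) for g in np.flatnonzero(eligible))

    pvals: list[float] = []
    dense_cache: dict[int, np.ndarray] = {}
    for g, c in candidates:
        if g not in dense_cache:
            dense_cache[g] = np.asarray(norm[g].todense()).ravel()
        pvals.append(test_fn(dense_cache[g], masks[c]))
    padj = bh_adjust(pvals) if pvals else np.array([])

    records = [
        MarkerRecord(
            gene=gene_ids[g],
            cluster=c,
            log_fc=float(lfc[c][g]),
            pct_in=float(pct_in[c][g]),
            pct_out=float(pct_out[c][g]),
            pvalue=float(p),
            padj=float(pa),
        )
        for (g, c), p, pa in zip(candidates, pvals, padj)
    ]
    records.sort(key=lambda r: (r.cluster, r.gene.symbol))
    return records


@dataclass(frozen=True)
class CellTypeAssignment:
    """Gene -> clusters of specific expression, with a lineage view."""

    clusters_by_gene: Mapping[GeneRef, frozenset[str]]
    annotation: Mapping[str, Lineage]

    def __post_init__(self) -> None:
        unknown = {c for cs in self.clusters_by_gene.values() for c in cs} - set(self.annotation)
        if unknown:
            raise ValueError(f"assignment references unannotated clusters: {sorted(unknown)}")

    def lineages_of(self, gene: GeneRef) -> frozenset[Lineage]:
        return frozenset(self.annotation[c] for c in self.clusters_by_gene.get(gene, frozenset()))

    def is_assigned(self, gene: GeneRef) -> bool:
        return bool(self.clusters_by_gene.get(gene))


def assign_gene_celltypes(
    markers: Sequence[MarkerRecord],
    params: MarkerParams,
    annotation: Mapping[str, Lineage],
) -> CellTypeAssignment:
    """Assign each gene to every cluster where it is a significant positive
    marker (``padj <= padj_cutoff`` — inclusive — and ``log_fc > 0``).
    Multi-cluster assignment is allowed."""
    clusters_by_gene: dict[GeneRef, set[str]] = {}
    for rec in markers:
        if rec.padj <= params.padj_cutoff and rec.log_fc > 0:
            clusters_by_gene.setdefault(rec.gene, set()).add(rec.cluster)
    return CellTypeAssignment(
        clusters_by_gene={g: frozenset(cs) for g, cs in clusters_by_gene.items()},
        annotation={c: Lineage(v) for c, v in annotation.items()},
    )


def lineage_filter(
    gene_list: GeneList,
    assignment: CellTypeAssignment,
    mode: Literal["exclude_lineages", "require_lineages"],
    lineages: set[Union[Lineage, str]],
    keep_unassigned: bool = True,
) -> GeneList:
    """Filter a mouse gene list by the lineages it is specific to.

    ``exclude_lineages`` drops a gene only when its lineage set is non-empty
    and entirely contained in the excluded lineages — a gene specific to
    blood *and* myocardium survives a blood/ectoderm exclusion.
    ``require_lineages`` keeps genes detected in at least one required
    lineage, plus (by default) genes with no specific assignment at all.
    """
    if gene_list.namespace != Namespace.MOUSE:
        raise NamespaceError(
            f"lineage evidence lives on mouse genes; got list {gene_list.name!r} "
            f"in namespace {gene_list.namespace.value}"
        )
    lineage_set = frozenset(Lineage(l) for l in lineages)
    if mode not in ("exclude_lineages", "require_lineages"):
        raise ValueError(f"unknown mode {mode!r}")

    kept: list[GeneRef] = []
    for gene in gene_list.genes:
        gl = assignment.lineages_of(gene)
        if mode == "exclude_lineages":
            drop = bool(gl) and gl <= lineage_set
            if not drop:
                kept.append(gene)
        else:
            if gl & lineage_set or (not gl and keep_unassigned):
                kept.append(gene)
    verb = "exclude" if mode == "exclude_lineages" else "require"
    desc = f"lineage filter ({verb} {{{', '.join(sorted(l.value for l in lineage_set))}}})"
    return gene_list.with_step(desc, kept)
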