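"""Construction of the named candidate gene lists.

Every list the analysis compares is built here from four evidence sources —
a bulk differential-expression table (mouse), single-cell lineage
specificity (mouse), a mouse<->human homolog map, and patient variant tables
(human) — by composing a small set of filters.  Each filter appends one
provenance line with input/output sizes, so a finished list carries the full
attrition trail of its construction.

Shipped presets (``LIST_PRESETS``) encode the published list definitions:

* ``deg_hh`` — differentially expressed mouse genes (count filter, adjusted
  p <= 0.05), lineage-excluded (blood/ectoderm), projected to human homologs.
* ``tof_dn_mh`` / ``slv_dn_mh`` / ``hlhs_dn_mh`` — human genes with at least
  one de novo non-synonymous variant in the respective diagnosis group,
  restricted to genes with a mouse homolog whose expression is not confined
  to blood/ectoderm.
* ``tof_var_jin_mh`` / ``tof_var_page_mh`` — as above but counting variants
  of any inheritance, per cohort.
* ``hem`` — top genes by mean FPKM in wildtype samples (the highly-expressed
  control), lineage-excluded and projected to human.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Literal, Mapping, Optional, Sequence, Union

import numpy as np

from .core import (
    Consequence,
    DEGRecord,
    GeneList,
    GeneRef,
    HomologMap,
    Inheritance,
    Lineage,
    Namespace,
    VariantRecord,
)
from .markers import CellTypeAssignment, lineage_filter

__all__ = [
    "FPKMRecord",
    "ListSpec",
    "select_degs",
    "compute_fpkm",
    "top_expressed",
    "project_homologs",
    "require_homolog",
    "lineage_filter_via_homologs",
    "genes_with_variants",
    "build_named_list",
    "LIST_PRESETS",
]


@dataclass(frozen=True)
class FPKMRecord:
    """Length- and depth-normalized expression for one mouse gene."""

    gene: GeneRef
    fpkm_per_sample: tuple[float, ...]
    mean_fpkm: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.fpkm_per_sample) or self.mean_fpkm < 0:
            raise ValueError(f"{self.gene}: negative FPKM")
        expect = float(np.mean(self.fpkm_per_sample)) if self.fpkm_per_sample else 0.0
        if abs(expect - self.mean_fpkm) > 1e-9 * max(1.0, expect):
            raise ValueError(f"{self.gene}: mean_fpkm is not the mean of per-sample values")


def select_degs(
    records: Sequence[DEGRecord],
    padj_cutoff: float = 0.05,
    min_total_reads_exclusive: int = 5,
    name: str = "DEG",
) -> GeneList:
    """Select differentially expressed genes from a results table.

    Genes with ``total_counts <= min_total_reads_exclusive`` are excluded
    (strict: a gene with exactly 5 reads is dropped); among the rest, genes
    with ``padj <= padj_cutoff`` (inclusive) are kept.  Genes whose padj is
    missing (as an adjusted-p procedure reports for independently filtered
    genes) are never selected; if every record lacks padj the table cannot be
    thresholded and an error is raised.
    """
    if records and all(r.padj is None for r in records):
        raise ValueError("no record carries an adjusted p-value; cannot apply the padj cutoff")
    counted = [r for r in records if r.total_counts > min_total_reads_exclusive]
    selected = [r.gene for r in counted if r.padj is not None and r.padj <= padj_cutoff]
    start = GeneList(name, Namespace.MOUSE, frozenset(r.gene for r in records),
                     (f"input table: {len(records)} genes",))
    step1 = start.with_step(f"total_counts > {min_total_reads_exclusive}", (r.gene for r in counted))
    return step1.with_step(f"padj <= {padj_cutoff}", selected)


def compute_fpkm(
    counts: Mapping[GeneRef, Sequence[int]],
    lengths_bp: Mapping[GeneRef, int],
    totals: Optional[Sequence[float]] = None,
) -> list[FPKMRecord]:
    """Fragments per kilobase per million mapped fragments, per sample.

    ``fpkm = count / ((length/1000) * (total/1e6))``.  When ``totals`` is not
    given, per-sample totals are the column sums over all supplied genes.
    """
    genes = list(counts)
    missing = [g for g in genes if g not in lengths_bp]
    if missing:
        raise ValueError(f"no length for gene(s): {sorted(g.symbol for g in missing)[:5]}")
    mat = np.asarray([list(counts[g]) for g in genes], dtype=float)
    if totals is None:
        totals_arr = mat.sum(axis=0)
    else:
        totals_arr = np.asarray(totals, dtype=float)
        if totals_arr.size != mat.shape[1]:
            raise ValueError("per-sample totals length does not match sample count")
    if (totals_arr <= 0).any():
        raise ValueError("per-sample totals must be positive")
    lengths = np.asarray([lengths_bp[g] for g in genes], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    fpkm = mat / (lengths[:, None] / 1e3) / (totals_arr[None, :] / 1e6)
    return [
        FPKMRecord(gene=g, fpkm_per_sample=tuple(row), mean_fpkm=float(row.mean()))
        for g, row in zip(genes, fpkm)
    ]


def top_expressed(records: Sequence[FPKMRecord], n: int = 1352, name: str = "HEM") -> GeneList:
    """The top-``n`` genes by mean FPKM (the highly-expressed control list).

    Ties at the rank-``n`` boundary break deterministically by lexicographic
    symbol order (smaller symbol kept).
    """
    if n > len(records):
        raise ValueError(f"requested top {n} of only {len(records)} records")
    ranked = sorted(records, key=lambda r: (-r.mean_fpkm, r.gene.symbol))
    base = GeneList(name, Namespace.MOUSE, frozenset(r.gene for r in records),
                    (f"expression table: {len(records)} genes",))
    return base.with_step(f"top {n} by mean FPKM", (r.gene for r in ranked[:n]))


def project_homologs(gene_list: GeneList, homolog_map: HomologMap, target: Union[Namespace, str]) -> GeneList:
    """Project a gene list across species through the homolog map.

    The output is the union of all partners of all members; members with no
    partner are dropped (and counted in provenance); one-to-many mappings
    expand the set.
    """
    target = Namespace(target)
    if gene_list.namespace == target:
        raise ValueError(f"list {gene_list.name!r} is already in namespace {target.value}")
    if len(homolog_map) == 0:
        raise ValueError("empty homolog map")
    index = homolog_map.partner_index(target)
    projected: set[GeneRef] = set()
    dropped = 0
    for gene in gene_list.genes:
        partners = index.get(gene)
        if partners:
            projected.update(partners)
        else:
            dropped += 1
    line = (
        f"project to {target.value} homologs: {len(gene_list)} -> {len(projected)} "
        f"({dropped} without partner dropped)"
    )
    return GeneList(gene_list.name, target, frozenset(projected), gene_list.provenance + (line,))


def require_homolog(gene_list: GeneList, homolog_map: HomologMap) -> GeneList:
    """Keep only genes that have at least one cross-species partner,
    without changing namespace."""
    if len(homolog_map) == 0:
        raise ValueError("empty homolog map")
    other = Namespace.MOUSE if gene_list.namespace == Namespace.HUMAN else Namespace.HUMAN
    index = homolog_map.partner_index(other)
    kept = [g for g in gene_list.genes if index.get(g)]
    return gene_list.with_step(f"require {other.value} homolog", kept)


def lineage_filter_via_homologs(
    gene_list: GeneList,
    homolog_map: HomologMap,
    assignment: CellTypeAssignment,
    mode: Literal["exclude_lineages", "require_lineages"] = "exclude_lineages",
    lineages: set = frozenset({Lineage.BLOOD, Lineage.ECTODERMAL}),
    keep_unassigned: bool = True,
) -> GeneList:
    """Apply a mouse-side lineage filter to a human gene list.

    Single-cell evidence exists only for mouse genes, so each human gene is
    projected back to its mouse partners and kept when at least one partner
    passes the mouse-side lineage filter.  Human genes with no mouse partner
    are dropped (they carry no expression evidence either way).
    """
    if gene_list.namespace != Namespace.HUMAN:
        raise ValueError("lineage_filter_via_homologs expects a human gene list")
    index = homolog_map.partner_index(Namespace.MOUSE)
    lineage_set = frozenset(Lineage(l) for l in lineages)

    def partner_passes(mouse_ref: GeneRef) -> bool:
        gl = assignment.lineages_of(mouse_ref)
        if mode == "exclude_lineages":
            return not (bool(gl) and gl <= lineage_set)
        return bool(gl & lineage_set) or (not gl and keep_unassigned)

    kept = [g for g in gene_list.genes if any(partner_passes(m) for m in index.get(g, ()))]
    verb = "exclude" if mode == "exclude_lineages" else "require"
    desc = f"mouse-side lineage filter via homologs ({verb} {{{', '.join(sorted(l.value for l in lineage_set))}}})"
    return gene_list.with_step(desc, kept)


def genes_with_variants(
    variants: Sequence[VariantRecord],
    diagnosis: str,
    inheritance: Literal["de_novo_only", "any"] = "de_novo_only",
    drop_synonymous: bool = True,
    cohort: Optional[str] = None,
    name: Optional[str] = None,
) -> GeneList:
    """Genes carrying at least one qualifying variant in a diagnosis group.

    ``de_novo_only`` keeps only variants flagged de novo; ``any`` keeps all
    inheritance states.  Synonymous variants are dropped by default.  An
    unknown diagnosis label yields an empty list with a warning rather than
    an error (cohort extracts legitimately cover disjoint diagnoses).
    """
    if inheritance not in ("de_novo_only", "any"):
        raise ValueError(f"unknown inheritance filter {inheritance!r}")
    pool = [v for v in variants if cohort is None or v.cohort == cohort]
    in_dx = [v for v in pool if v.diagnosis == diagnosis]
    if not in_dx and pool:
        warnings.warn(f"no variants with diagnosis {diagnosis!r}; returning an empty list")
    qualifying = [
        v
        for v in in_dx
        if (inheritance == "any" or v.inheritance == Inheritance.DE_NOVO)
        and not (drop_synonymous and v.consequence == Consequence.SYNONYMOUS)
    ]
    patients = len({v.patient_id for v in in_dx})
    # the size-arrow notation ("a -> b") is reserved for gene-set sizes
    provenance = (
        f"cohort={cohort or 'all'}, diagnosis={diagnosis}: {patients} patients, {len(in_dx)} variants",
        f"inheritance={inheritance}, drop_synonymous={drop_synonymous}: "
        f"{len(qualifying)} of {len(in_dx)} variants qualify",
        f"distinct genes with >=1 qualifying variant: {len({v.gene for v in qualifying})}",
    )
    return GeneList(
        name or f"{diagnosis}-variant-genes",
        Namespace.HUMAN,
        frozenset(v.gene for v in qualifying),
        provenance,
    )


@dataclass(frozen=True)
class ListSpec:
    """A named recipe: an evidence source plus an ordered filter chain.

    Filters are small dicts with a ``kind`` key; supported kinds are
    ``padj`` (cutoff, min_counts), ``diagnosis``/``cohort``/``inheritance``/
    ``exclude_synonymous`` (variant filters applied jointly through
    :func:`genes_with_variants`), ``top_n``, ``lineage`` (mode, lineages),
    ``require_homolog``, and ``project`` (target namespace).
    """

    name: str
    source: Literal["deg", "variants", "expression_rank"]
    filters: tuple[Mapping[str, Any], ...] = ()

    def __post_init__(self) -> None:
        if self.source not in ("deg", "variants", "expression_rank"):
            raise ValueError(f"unknown source {self.source!r}")
        per_source = {
            "deg": {"padj", "lineage", "require_homolog", "project", "top_n"},
            "variants": {"diagnosis", "cohort", "inheritance", "exclude_synonymous",
                         "lineage", "require_homolog", "project"},
            "expression_rank": {"top_n", "lineage", "require_homolog", "project"},
        }
        for f in self.filters:
            if f.get("kind") not in per_source[self.source]:
                raise ValueError(f"filter {f!r} not applicable to source {self.source!r}")


def build_named_list(
    spec: ListSpec,
    *,
    degs: Optional[Sequence[DEGRecord]] = None,
    variants: Optional[Sequence[VariantRecord]] = None,
    fpkm: Optional[Sequence[FPKMRecord]] = None,
    homolog_map: Optional[HomologMap] = None,
    assignment: Optional[CellTypeAssignment] = None,
) -> GeneList:
    """Materialize a ListSpec against the supplied evidence tables.

    Filters run in spec order; each appends a provenance line, so the result
    reproduces the published attrition-trail style of list construction.
    """
    filters = list(spec.filters)

    if spec.source == "variants":
        if variants is None:
            raise ValueError(f"spec {spec.name!r} needs a variant table")
        opts: dict[str, Any] = {"inheritance": "any", "drop_synonymous": False,
                                "diagnosis": None, "cohort": None}
        rest: list[Mapping[str, Any]] = []
        for f in filters:
            if f["kind"] == "diagnosis":
                opts["diagnosis"] = f["value"]
            elif f["kind"] == "cohort":
                opts["cohort"] = f["value"]
            elif f["kind"] == "inheritance":
                opts["inheritance"] = "de_novo_only" if f["value"] == "de_novo" else "any"
            elif f["kind"] == "exclude_synonymous":
                opts["drop_synonymous"] = True
            else:
                rest.append(f)
        if opts["diagnosis"] is None:
            raise ValueError(f"spec {spec.name!r}: variant source requires a diagnosis filter")
        current = genes_with_variants(
            variants, opts["diagnosis"], opts["inheritance"], opts["drop_synonymous"],
            cohort=opts["cohort"], name=spec.name,
        )
        filters = rest
    elif spec.source == "deg":
        if degs is None:
            raise ValueError(f"spec {spec.name!r} needs a DE table")
        padj_filters = [f for f in filters if f["kind"] == "padj"]
        if padj_filters:
            f = padj_filters[0]
            current = select_degs(degs, f.get("cutoff", 0.05), f.get("min_counts", 5), name=spec.name)
        else:
            current = GeneList(spec.name, Namespace.MOUSE, frozenset(r.gene for r in degs),
                               (f"input table: {len(degs)} genes",))
        filters = [f for f in filters if f["kind"] != "padj"]
    else:  # expression_rank
        if fpkm is None:
            raise ValueError(f"spec {spec.name!r} needs an FPKM table")
        top_filters = [f for f in filters if f["kind"] == "top_n"]
        if top_filters:
            current = top_expressed(fpkm, top_filters[0]["n"], name=spec.name)
        else:
            current = GeneList(spec.name, Namespace.MOUSE, frozenset(r.gene for r in fpkm),
                               (f"expression table: {len(fpkm)} genes",))
        filters = [f for f in filters if f["kind"] != "top_n"]

    for f in filters:
        kind = f["kind"]
        if kind == "lineage":
            if assignment is None:
                raise ValueError(f"spec {spec.name!r}: lineage filter needs a cell-type assignment")
            mode = f.get("mode", "exclude_lineages")
            lineages = set(f.get("lineages", {Lineage.BLOOD, Lineage.ECTODERMAL}))
            if current.namespace == Namespace.MOUSE:
                current = lineage_filter(current, assignment, mode, lineages,
                                         keep_unassigned=f.get("keep_unassigned", True))
            else:
                if homolog_map is None:
                    raise ValueError(f"spec {spec.name!r}: human-side lineage filter needs a homolog map")
                current = lineage_filter_via_homologs(
                    current, homolog_map, assignment, mode, lineages,
                    keep_unassigned=f.get("keep_unassigned", True),
                )
        elif kind == "require_homolog":
            if homolog_map is None:
                raise ValueError(f"spec {spec.name!r}: homolog filter needs a homolog map")
            current = require_homolog(current, homolog_map)
        elif kind == "project":
            if homolog_map is None:
                raise ValueError(f"spec {spec.name!r}: projection needs a homolog map")
            current = project_homologs(current, homolog_map, f["target"])
        elif kind == "top_n":
            raise ValueError("top_n applies only to the expression_rank source")
        else:  # pragma: no cover - guarded by ListSpec validation
            raise ValueError(f"unknown filter kind {kind!r}")
    return current


_BLOOD_ECTO = ("blood", "ectodermal")

#: Preset recipes for the published list definitions.  The variant-table
#: diagnosis labels (TOF/SLV/HLHS) and cohort labels (jin/page) must match
#: the supplied cohort extract.
LIST_PRESETS: dict[str, ListSpec] = {
    "deg_hh": ListSpec(
        name="DEG-HH",
        source="deg",
        filters=(
            {"kind": "padj", "cutoff": 0.05, "min_counts": 5},
            {"kind": "lineage", "mode": "exclude_lineages", "lineages": _BLOOD_ECTO},
            {"kind": "project", "target": "human"},
        ),
    ),
    "tof_dn_mh": ListSpec(
        name="TOF-DN-MH",
        source="variants",
        filters=(
            {"kind": "diagnosis", "value": "TOF"},
            {"kind": "cohort", "value": "jin"},
            {"kind": "inheritance", "value": "de_novo"},
            {"kind": "exclude_synonymous"},
            {"kind": "require_homolog"},
            {"kind": "lineage", "mode": "exclude_lineages", "lineages": _BLOOD_ECTO},
        ),
    ),
    "slv_dn_mh": ListSpec(
        name="SLV-DN-MH",
        source="variants",
        filters=(
            {"kind": "diagnosis", "value": "SLV"},
            {"kind": "cohort", "value": "jin"},
            {"kind": "inheritance", "value": "de_novo"},
            {"kind": "exclude_synonymous"},
            {"kind": "require_homolog"},
            {"kind": "lineage", "mode": "exclude_lineages", "lineages": _BLOOD_ECTO},
        ),
    ),
    "hlhs_dn_mh": ListSpec(
        name="HLHS-DN-MH",
        source="variants",
        filters=(
            {"kind": "diagnosis", "value": "HLHS"},
            {"kind": "cohort", "value": "jin"},
            {"kind": "inheritance", "value": "de_novo"},
            {"kind": "exclude_synonymous"},
            {"kind": "require_homolog"},
            {"kind": "lineage", "mode": "exclude_lineages", "lineages": _BLOOD_ECTO},
        ),
    ),
    "tof_var_jin_mh": ListSpec(
        name="TOF-VAR-JIN-MH",
        source="variants",
        filters=(
            {"kind": "diagnosis", "value": "TOF"},
            {"kind": "cohort", "value": "jin"},
            {"kind": "exclude_synonymous"},
            {"kind": "require_homolog"},
        ),
    ),
    "tof_var_page_mh": ListSpec(
        name="TOF-VAR-PAGE-MH",
        source="variants",
        filters=(
            {"kind": "diagnosis", "value": "TOF"},
            {"kind": "cohort", "value": "page"},
            {"kind": "exclude_synonymous"},
            {"kind": "require_homolog"},
        ),
    ),
    "hem": ListSpec(
        name="HEM",
        source="expression_rank",
        filters=(
            {"kind": "top_n", "n": 1352},
            {"kind": "lineage", "mode": "exclude_lineages", "lineages": _BLOOD_ECTO},
            {"kind": "project", "target": "human"},
        ),
    ),
}
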