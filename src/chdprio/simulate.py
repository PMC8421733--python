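"""Synthetic inputs with planted ground truth.

Every table the pipeline consumes can be generated here with known structure:
a differential-expression table with a planted true-DEG set, clustered
negative-binomial single-cell counts with planted lineage markers (including
blood/ectoderm clusters and a selection-marker gene expressed in a known cell
subset), a many-to-many homolog map, and per-patient variant draws with a
configurable enrichment factor on a causal gene set.  The ``TruthBundle``
carries the planted truth so recovery can be measured at every stage.

Randomness discipline: one root seed fans out to per-generator child streams
via ``SeedSequence(seed, spawn_key=(crc32(name),))``, so adding a generator
never perturbs the draws of another, and re-running with the same seed
reproduces byte-identical output files.

Scale: defaults are desk-scale (4,000 mouse genes, 7 clusters x 50 cells,
400 patients) — deliberately far below a real experiment (~24k genes, ~2k
cells) but large enough that recall/false-positive properties of every stage
are measurable in seconds.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import (
    CellMatrix,
    Consequence,
    DEGRecord,
    GeneList,
    GeneRef,
    HomologMap,
    Inheritance,
    Lineage,
    Namespace,
    VariantRecord,
    human_gene,
    mouse_gene,
)
from .stats import bh_adjust

__all__ = [
    "SimConfig",
    "TruthBundle",
    "child_rng",
    "gen_homolog_map",
    "gen_deg_table",
    "gen_sc_counts",
    "gen_variant_cohort",
    "make_truth_bundle",
]

#: Name of the synthetic selection-marker gene (emulating a resistance
#: cassette used to flag heterozygote cells).
SELECTION_MARKER = "NeoR"

_LINEAGE_CYCLE = [
    Lineage.MESENCHYMAL,
    Lineage.VSMC,
    Lineage.ENDOTHELIAL,
    Lineage.MYOCARDIAL,
    Lineage.EPICARDIAL,
    Lineage.BLOOD,
    Lineage.ECTODERMAL,
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    The defaults define the simulated study conditions; see the methods note
    for the rationale behind each value.
    """

    seed: int = 0
    # gene universe / homology
    n_mouse_genes: int = 4000
    p_human_homolog: float = 0.85
    p_one_to_many: float = 0.06
    # bulk DE table
    n_true_degs: int = 300
    deg_beta_a: float = 0.05
    n_samples: int = 6
    low_count_frac: float = 0.02
    # single-cell counts
    n_clusters: int = 7
    cells_per_cluster: int = 50
    markers_per_cluster: int = 10
    nb_mean: float = 0.3
    nb_dispersion: float = 2.0
    marker_fold: float = 8.0
    neor_frac: float = 0.3
    # variant cohort
    n_patients: int = 400
    dnv_rate_per_patient: float = 1.0
    causal_set_size: int = 150
    causal_overlap_with_degs: float = 0.5
    enrichment_factor: float = 1.0
    frac_synonymous: float = 0.3
    frac_inherited: float = 0.5

    def __post_init__(self) -> None:
        for label in ("p_human_homolog", "p_one_to_many", "low_count_frac", "neor_frac",
                      "causal_overlap_with_degs", "frac_synonymous"):
            v = getattr(self, label)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{label} must lie in [0, 1], got {v}")
        if not (0.0 < self.deg_beta_a <= 1.0):
            raise ValueError("deg_beta_a must lie in (0, 1]")
        if not (0.0 <= self.frac_inherited < 1.0):
            raise ValueError("frac_inherited must lie in [0, 1)")
        if self.enrichment_factor < 1.0:
            raise ValueError("enrichment_factor must be >= 1")
        if self.n_true_degs > self.n_mouse_genes:
            raise ValueError("n_true_degs exceeds n_mouse_genes")
        if self.n_clusters * self.markers_per_cluster > self.n_mouse_genes:
            raise ValueError("more planted markers than genes")
        for label in ("nb_mean", "nb_dispersion", "dnv_rate_per_patient"):
            if getattr(self, label) <= 0:
                raise ValueError(f"{label} must be positive")
        if self.marker_fold < 1.0:
            raise ValueError("marker_fold must be >= 1")


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Independent child stream for a named generator under one root seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _mouse_symbols(n: int) -> list[str]:
    return [f"Sim{i:05d}" for i in range(n)]


def gen_homolog_map(cfg: SimConfig) -> HomologMap:
    """Random many-to-many homolog map over the synthetic gene universe.

    Each mouse gene gains a human partner (its upper-cased symbol) with
    probability ``p_human_homolog``; partnered genes gain a second partner
    (suffix ``B``) with probability ``p_one_to_many``.
    """
    rng = child_rng(cfg.seed, "homolog_map")
    pairs: set[tuple[GeneRef, GeneRef]] = set()
    has_partner = rng.random(cfg.n_mouse_genes) < cfg.p_human_homolog
    second = rng.random(cfg.n_mouse_genes) < cfg.p_one_to_many
    for i, sym in enumerate(_mouse_symbols(cfg.n_mouse_genes)):
        if has_partner[i]:
            pairs.add((mouse_gene(sym), human_gene(sym.upper())))
            if second[i]:
                pairs.add((mouse_gene(sym), human_gene(sym.upper() + "B")))
    return HomologMap(frozenset(pairs))


def gen_deg_table(cfg: SimConfig) -> tuple[list[DEGRecord], GeneList]:
    """Differential-expression table with a planted true-DEG set.

    Null genes draw p ~ Uniform(0,1); true DEGs draw p ~ Beta(a, 1) with a
    small shape (default 0.05) concentrating mass near zero.  padj is BH over
    the whole table.  log2 fold changes are N(0,1) for nulls and
    sign * |N(2, 0.5)| for true DEGs.  Total counts are negative-binomial;
    a fraction of *null* genes is forced to <= 5 total reads to exercise the
    low-count exclusion without contaminating the planted truth.
    """
    rng = child_rng(cfg.seed, "deg_table")
    n = cfg.n_mouse_genes
    symbols = _mouse_symbols(n)
    is_true = np.zeros(n, dtype=bool)
    is_true[rng.choice(n, size=cfg.n_true_degs, replace=False)] = True

    pvals = rng.uniform(size=n)
    pvals[is_true] = rng.beta(cfg.deg_beta_a, 1.0, size=cfg.n_true_degs)
    padj = bh_adjust(pvals)

    log2fc = rng.normal(0.0, 1.0, size=n)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_true_degs)
    log2fc[is_true] = signs * np.abs(rng.normal(2.0, 0.5, size=cfg.n_true_degs))

    # bulk totals: NB with mean ~500 reads/gene over all samples
    totals = rng.negative_binomial(2, 2 / (2 + 500.0), size=n).astype(int)
    totals = np.maximum(totals, 6)  # keep unforced genes above the count filter
    null_idx = np.flatnonzero(~is_true)
    n_low = int(round(cfg.low_count_frac * n))
    forced = rng.choice(null_idx, size=min(n_low, null_idx.size), replace=False)
    totals[forced] = rng.integers(0, 6, size=forced.size)

    records = []
    for i in range(n):
        per_sample = rng.multinomial(totals[i], np.full(cfg.n_samples, 1.0 / cfg.n_samples))
        records.append(
            DEGRecord(
                gene=mouse_gene(symbols[i]),
                total_counts=int(totals[i]),
                log2fc=float(log2fc[i]),
                pvalue=float(pvals[i]),
                padj=float(padj[i]),
                per_sample_counts=tuple(int(x) for x in per_sample),
            )
        )
    truth = GeneList(
        "true-DEG", Namespace.MOUSE,
        frozenset(mouse_gene(symbols[i]) for i in np.flatnonzero(is_true)),
        (f"planted true DEGs: {cfg.n_true_degs} of {n}",),
    )
    return records, truth


def gen_sc_counts(cfg: SimConfig) -> tuple[CellMatrix, dict[str, frozenset[GeneRef]]]:
    """Clustered negative-binomial single-cell counts with planted markers.

    Clusters cycle through the seven lineages (mesenchymal, VSMC,
    endothelial, myocardial, epicardial, blood, ectodermal).  Each cluster
    owns ``markers_per_cluster`` planted marker genes whose mean is
    multiplied by ``marker_fold`` in the home cluster.  A selection-marker
    gene is appended with nonzero counts in exactly ``neor_frac`` of cells.
    """
    rng = child_rng(cfg.seed, "sc_counts")
    n_genes, n_cells = cfg.n_mouse_genes, cfg.n_clusters * cfg.cells_per_cluster
    symbols = _mouse_symbols(n_genes)
    clusters = [f"cluster{c}" for c in range(cfg.n_clusters)]
    labels = [clusters[c] for c in range(cfg.n_clusters) for _ in range(cfg.cells_per_cluster)]
    lineage_of = {clusters[c]: _LINEAGE_CYCLE[c % len(_LINEAGE_CYCLE)] for c in range(cfg.n_clusters)}

    marker_idx = rng.choice(n_genes, size=cfg.n_clusters * cfg.markers_per_cluster, replace=False)
    markers_by_cluster = {
        clusters[c]: frozenset(
            mouse_gene(symbols[i])
            for i in marker_idx[c * cfg.markers_per_cluster : (c + 1) * cfg.markers_per_cluster]
        )
        for c in range(cfg.n_clusters)
    }

    mean = np.full((n_genes, n_cells), cfg.nb_mean)
    for c in range(cfg.n_clusters):
        cols = slice(c * cfg.cells_per_cluster, (c + 1) * cfg.cells_per_cluster)
        rows = marker_idx[c * cfg.markers_per_cluster : (c + 1) * cfg.markers_per_cluster]
        mean[np.ix_(rows, range(cols.start, cols.stop))] *= cfg.marker_fold
    r = cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mean)).astype(np.int64)

    # selection marker: positive in exactly round(neor_frac * n_cells) cells
    n_pos = int(round(cfg.neor_frac * n_cells))
    neor_row = np.zeros(n_cells, dtype=np.int64)
    pos = rng.choice(n_cells, size=n_pos, replace=False)
    neor_row[pos] = 1 + rng.poisson(1.0, size=n_pos)
    counts = np.vstack([counts, neor_row])

    return (
        CellMatrix(
            counts=sp.csr_matrix(counts),
            gene_ids=[mouse_gene(s) for s in symbols] + [mouse_gene(SELECTION_MARKER)],
            cell_ids=[f"cell{j:04d}" for j in range(n_cells)],
            cluster_labels=labels,
            lineage_of_cluster=lineage_of,
        ),
        markers_by_cluster,
    )


def gen_variant_cohort(
    cfg: SimConfig,
    human_genes: GeneList,
    causal_set: GeneList,
    diagnosis: str = "TOF",
    cohort: str = "jin",
    n_patients: Optional[int] = None,
    enrichment_factor: Optional[float] = None,
    stream: Optional[str] = None,
) -> list[VariantRecord]:
    """Per-patient variant draws with enrichment on the causal gene set.

    Each patient carries Poisson(``dnv_rate_per_patient``) de novo variants
    plus Poisson-distributed inherited variants tuned so that a fraction
    ``frac_inherited`` of all variants is inherited.  Variant genes are drawn
    from a weight vector in which causal genes carry ``enrichment_factor``
    times the baseline weight; consequences are synonymous with probability
    ``frac_synonymous``, otherwise missense/LoF/other at 60/25/15.
    """
    if not causal_set.genes <= human_genes.genes:
        raise ValueError("causal set must be contained in the human gene universe")
    n_patients = cfg.n_patients if n_patients is None else n_patients
    factor = cfg.enrichment_factor if enrichment_factor is None else factor_check(enrichment_factor)
    rng = child_rng(cfg.seed, stream or f"variants:{cohort}:{diagnosis}")

    genes = sorted(human_genes.genes, key=lambda g: g.symbol)
    weights = np.ones(len(genes))
    causal_mask = np.array([g in causal_set.genes for g in genes])
    weights[causal_mask] *= factor
    weights /= weights.sum()

    inherited_rate = cfg.dnv_rate_per_patient * cfg.frac_inherited / (1.0 - cfg.frac_inherited)
    n_dnv = rng.poisson(cfg.dnv_rate_per_patient, size=n_patients)
    n_inh = rng.poisson(inherited_rate, size=n_patients)
    total = int(n_dnv.sum() + n_inh.sum())
    gene_draws = rng.choice(len(genes), size=total, p=weights)
    syn = rng.random(total) < cfg.frac_synonymous
    nonsyn_pool = [Consequence.MISSENSE, Consequence.LOSS_OF_FUNCTION, Consequence.OTHER_NONSYNONYMOUS]
    nonsyn_idx = rng.choice(3, size=total, p=[0.60, 0.25, 0.15])

    records: list[VariantRecord] = []
    pos = 0
    for p in range(n_patients):
        for inh, count in ((Inheritance.DE_NOVO, n_dnv[p]), (Inheritance.INHERITED, n_inh[p])):
            for _ in range(int(count)):
                records.append(
                    VariantRecord(
                        patient_id=f"{cohort}-{diagnosis}-P{p:04d}",
                        gene=genes[int(gene_draws[pos])],
                        consequence=Consequence.SYNONYMOUS if syn[pos] else nonsyn_pool[int(nonsyn_idx[pos])],
                        inheritance=inh,
                        diagnosis=diagnosis,
                        cohort=cohort,
                    )
                )
                pos += 1
    return records


def factor_check(x: float) -> float:
    if x < 1.0:
        raise ValueError("enrichment_factor must be >= 1")
    return float(x)


@dataclass
class TruthBundle:
    """All synthetic inputs plus the planted ground truth."""

    config: SimConfig
    homolog_map: HomologMap
    deg_records: list[DEGRecord]
    true_deg_set: GeneList
    cell_matrix: CellMatrix
    markers_by_cluster: dict[str, frozenset[GeneRef]]
    human_universe: GeneList
    causal_set: GeneList
    variants: list[VariantRecord]
    gene_lengths: dict[GeneRef, int]


#: Per-diagnosis patient-count multipliers relative to ``n_patients``,
#: mirroring the relative sizes of the emulated cohort extracts
#: (TOF 419 / SLV 245 / HLHS 371 in one cohort; TOF 829 in the second).
_COHORT_PLAN = (
    ("jin", "TOF", 1.0, "enriched"),
    ("jin", "SLV", 245 / 419, "null"),
    ("jin", "HLHS", 371 / 419, "null"),
    ("page", "TOF", 829 / 419, "enriched"),
)


def make_truth_bundle(cfg: SimConfig, out_dir: Optional[Path] = None) -> TruthBundle:
    """Generate a complete, mutually consistent input set (optionally on disk).

    The causal human gene set draws a fraction ``causal_overlap_with_degs``
    of its members from the human homologs of the planted true DEGs and the
    rest from non-DEG human genes.  Variant cohorts follow the emulated study
    design: the TOF groups (both cohorts) carry the configured enrichment on
    the causal set; SLV and HLHS are null cohorts.

    With the same config (same seed) the emitted files are byte-identical.
    """
    homolog = gen_homolog_map(cfg)
    deg_records, true_degs = gen_deg_table(cfg)
    cell_matrix, markers_by_cluster = gen_sc_counts(cfg)

    human_universe = GeneList(
        "human-universe", Namespace.HUMAN, homolog.human_genes(),
        (f"human genes with a mouse homolog: {len(homolog.human_genes())}",),
    )
    mouse_index = homolog.partner_index(Namespace.HUMAN)
    deg_humans = sorted(
        {h for g in true_degs.genes for h in mouse_index.get(g, ())}, key=lambda g: g.symbol
    )
    other_humans = sorted(human_universe.genes - set(deg_humans), key=lambda g: g.symbol)
    rng = child_rng(cfg.seed, "causal_set")
    n_from_degs = min(int(round(cfg.causal_overlap_with_degs * cfg.causal_set_size)), len(deg_humans))
    n_rest = min(cfg.causal_set_size - n_from_degs, len(other_humans))
    picked = [deg_humans[i] for i in rng.choice(len(deg_humans), size=n_from_degs, replace=False)] + [
        other_humans[i] for i in rng.choice(len(other_humans), size=n_rest, replace=False)
    ]
    causal_set = GeneList(
        "causal", Namespace.HUMAN, frozenset(picked),
        (f"planted causal set: {len(picked)} ({n_from_degs} overlapping true-DEG homologs)",),
    )

    variants: list[VariantRecord] = []
    for cohort, dx, mult, kind in _COHORT_PLAN:
        variants.extend(
            gen_variant_cohort(
                cfg, human_universe, causal_set, diagnosis=dx, cohort=cohort,
                n_patients=int(round(mult * cfg.n_patients)),
                enrichment_factor=cfg.enrichment_factor if kind == "enriched" else 1.0,
            )
        )

    rng_len = child_rng(cfg.seed, "gene_lengths")
    gene_lengths = {
        mouse_gene(s): int(v)
        for s, v in zip(_mouse_symbols(cfg.n_mouse_genes),
                        rng_len.integers(500, 5001, size=cfg.n_mouse_genes))
    }

    bundle = TruthBundle(
        config=cfg,
        homolog_map=homolog,
        deg_records=deg_records,
        true_deg_set=true_degs,
        cell_matrix=cell_matrix,
        markers_by_cluster=markers_by_cluster,
        human_universe=human_universe,
        causal_set=causal_set,
        variants=variants,
        gene_lengths=gene_lengths,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: TruthBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config

    rows = []
    for r in bundle.deg_records:
        row = {
            "gene": r.gene.symbol,
            "total_counts": r.total_counts,
            "log2fc": f"{r.log2fc:.6g}",
            "pvalue": f"{r.pvalue:.10g}",
            "padj": f"{r.padj:.10g}",
        }
        for j, c in enumerate(r.per_sample_counts or ()):
            row[f"count_s{j + 1}"] = c
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "deg_table.tsv", sep="\t", index=False)

    with open(out_dir / "homolog_map.tsv", "w") as fh:
        for m, h in sorted(bundle.homolog_map.pairs, key=lambda p: (p[0].symbol, p[1].symbol)):
            fh.write(f"{m.symbol}\t{h.symbol}\n")

    m = bundle.cell_matrix
    scipy.io.mmwrite(str(out_dir / "counts.mtx"), m.counts.tocoo())
    (out_dir / "genes.txt").write_text("".join(g.symbol + "\n" for g in m.gene_ids))
    (out_dir / "cells.txt").write_text("".join(c + "\n" for c in m.cell_ids))
    with open(out_dir / "clusters.tsv", "w") as fh:
        for cell, cl in zip(m.cell_ids, m.cluster_labels):
            fh.write(f"{cell}\t{cl}\n")
    with open(out_dir / "lineages.tsv", "w") as fh:
        for cl in sorted(m.lineage_of_cluster):
            fh.write(f"{cl}\t{m.lineage_of_cluster[cl].value}\n")

    pd.DataFrame(
        [
            {
                "patient_id": v.patient_id,
                "gene": v.gene.symbol,
                "consequence": v.consequence.value,
                "inheritance": v.inheritance.value,
                "diagnosis": v.diagnosis,
                "cohort": v.cohort,
            }
            for v in bundle.variants
        ]
    ).to_csv(out_dir / "variants.tsv", sep="\t", index=False)

    with open(out_dir / "gene_lengths.tsv", "w") as fh:
        fh.write("gene\tlength_bp\n")
        for g in sorted(bundle.gene_lengths, key=lambda g: g.symbol):
            fh.write(f"{g.symbol}\t{bundle.gene_lengths[g]}\n")

    truth = {
        "config": asdict(cfg),
        "true_deg_set": bundle.true_deg_set.symbols,
        "markers_by_cluster": {
            c: sorted(g.symbol for g in gs) for c, gs in sorted(bundle.markers_by_cluster.items())
        },
        "causal_set": bundle.causal_set.symbols,
        "selection_marker": SELECTION_MARKER,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
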