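"""Domain types shared across the prioritization pipeline.

The pipeline moves gene sets between two species, so every gene symbol is
tagged with its namespace (``mouse`` or ``human``).  A mouse ``Notch1`` and a
human ``NOTCH1`` are distinct objects and never compare equal; crossing the
species boundary requires an explicit homolog projection.  Keeping equality
case-sensitive within a namespace is deliberate — silent case-folding hides
real identifier errors.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Namespace",
    "GeneRef",
    "mouse_gene",
    "human_gene",
    "GeneList",
    "HomologMap",
    "DEGRecord",
    "Consequence",
    "Inheritance",
    "VariantRecord",
    "Lineage",
    "CellMatrix",
    "NamespaceError",
    "FormatError",
]


class NamespaceError(ValueError):
    """Raised when mouse and human gene sets are combined without projection."""


class FormatError(ValueError):
    """Raised when an input table violates its documented format contract."""


class Namespace(str, enum.Enum):
    MOUSE = "mouse"
    HUMAN = "human"


@dataclass(frozen=True, slots=True)
class GeneRef:
    """A gene symbol tagged with the species namespace it lives in."""

    namespace: Namespace
    symbol: str

    def __post_init__(self) -> None:
        if not isinstance(self.namespace, Namespace):
            object.__setattr__(self, "namespace", Namespace(self.namespace))
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.namespace.value}:{self.symbol}"


def mouse_gene(symbol: str) -> GeneRef:
    return GeneRef(Namespace.MOUSE, symbol)


def human_gene(symbol: str) -> GeneRef:
    return GeneRef(Namespace.HUMAN, symbol)


@dataclass(frozen=True)
class GeneList:
    """A named set of same-namespace genes with a filter audit trail.

    ``provenance`` accumulates one human-readable line per applied filter
    (with input/output sizes), mirroring the attrition narrative a published
    analysis reports (e.g. "327 -> 270 after lineage exclusion").
    """

    name: str
    namespace: Namespace
    genes: frozenset[GeneRef]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.namespace, Namespace):
            object.__setattr__(self, "namespace", Namespace(self.namespace))
        if not isinstance(self.genes, frozenset):
            object.__setattr__(self, "genes", frozenset(self.genes))
        bad = [g for g in self.genes if g.namespace != self.namespace]
        if bad:
            raise NamespaceError(
                f"gene list {self.name!r} ({self.namespace.value}) contains "
                f"{len(bad)} genes from the other namespace, e.g. {sorted(str(b) for b in bad)[0]}"
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: GeneRef) -> bool:
        return gene in self.genes

    def __iter__(self) -> Iterator[GeneRef]:
        return iter(sorted(self.genes, key=lambda g: g.symbol))

    @property
    def symbols(self) -> list[str]:
        """Member symbols, sorted for deterministic output."""
        return sorted(g.symbol for g in self.genes)

    def with_step(self, description: str, genes: Iterable[GeneRef], name: Optional[str] = None) -> "GeneList":
        """Return a derived list, appending a provenance line with sizes."""
        new = frozenset(genes)
        line = f"{description}: {len(self.genes)} -> {len(new)}"
        return GeneList(name or self.name, self.namespace, new, self.provenance + (line,))

    def intersect(self, other: "GeneList", name: Optional[str] = None) -> "GeneList":
        self._check_namespace(other)
        common = self.genes & other.genes
        return GeneList(
            name or f"{self.name}&{other.name}",
            self.namespace,
            common,
            self.provenance + (f"intersect with {other.name} ({len(other)}): {len(self)} -> {len(common)}",),
        )

    def _check_namespace(self, other: "GeneList") -> None:
        if self.namespace != other.namespace:
            raise NamespaceError(
                f"cannot combine {self.name!r} ({self.namespace.value}) with "
                f"{other.name!r} ({other.namespace.value}) without homolog projection"
            )


@dataclass(frozen=True)
class HomologMap:
    """A many-to-many mouse<->human homolog correspondence."""

    pairs: frozenset[tuple[GeneRef, GeneRef]]

    def __post_init__(self) -> None:
        if not isinstance(self.pairs, frozenset):
            object.__setattr__(self, "pairs", frozenset(self.pairs))
        for m, h in self.pairs:
            if m.namespace != Namespace.MOUSE or h.namespace != Namespace.HUMAN:
                raise NamespaceError(f"homolog pair ({m}, {h}) must be (mouse, human)")

    def __len__(self) -> int:
        return len(self.pairs)

    def human_partners(self, gene: GeneRef) -> frozenset[GeneRef]:
        return frozenset(h for m, h in self.pairs if m == gene)

    def mouse_partners(self, gene: GeneRef) -> frozenset[GeneRef]:
        return frozenset(m for m, h in self.pairs if h == gene)

    def mouse_genes(self) -> frozenset[GeneRef]:
        return frozenset(m for m, _ in self.pairs)

    def human_genes(self) -> frozenset[GeneRef]:
        return frozenset(h for _, h in self.pairs)

    def partner_index(self, target: Namespace) -> dict[GeneRef, set[GeneRef]]:
        """Index from source genes to the set of partners in ``target``."""
        idx: dict[GeneRef, set[GeneRef]] = {}
        for m, h in self.pairs:
            src, dst = (h, m) if target == Namespace.MOUSE else (m, h)
            idx.setdefault(src, set()).add(dst)
        return idx


@dataclass(frozen=True)
class DEGRecord:
    """One row of a differential-expression results table (mouse gene)."""

    gene: GeneRef
    total_counts: int
    log2fc: float
    pvalue: float
    padj: Optional[float] = None
    per_sample_counts: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.gene.namespace != Namespace.MOUSE:
            raise NamespaceError("DEG records describe mouse genes")
        if self.total_counts < 0:
            raise ValueError(f"{self.gene}: negative total_counts")
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"{self.gene}: pvalue {self.pvalue} outside [0, 1]")
        if self.padj is not None:
            if not (0.0 <= self.padj <= 1.0):
                raise ValueError(f"{self.gene}: padj {self.padj} outside [0, 1]")
            # BH adjustment within one family can only raise a p-value.
            if self.padj < self.pvalue - 1e-12:
                raise ValueError(f"{self.gene}: padj {self.padj} < pvalue {self.pvalue}")
        if self.per_sample_counts is not None:
            if any(c < 0 for c in self.per_sample_counts):
                raise ValueError(f"{self.gene}: negative per-sample count")
            if sum(self.per_sample_counts) != self.total_counts:
                raise ValueError(
                    f"{self.gene}: total_counts {self.total_counts} != "
                    f"sum(per_sample_counts) {sum(self.per_sample_counts)}"
                )


class Consequence(str, enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    LOSS_OF_FUNCTION = "loss_of_function"
    OTHER_NONSYNONYMOUS = "other_nonsynonymous"


class Inheritance(str, enum.Enum):
    DE_NOVO = "de_novo"
    INHERITED = "inherited"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class VariantRecord:
    """One patient variant, already collapsed to the gene level."""

    patient_id: str
    gene: GeneRef
    consequence: Consequence
    inheritance: Inheritance
    diagnosis: str
    cohort: str = ""

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.gene.namespace != Namespace.HUMAN:
            raise NamespaceError("variant records describe human genes")


class Lineage(str, enum.Enum):
    MESENCHYMAL = "mesenchymal"
    VSMC = "VSMC"
    ENDOTHELIAL = "endothelial"
    MYOCARDIAL = "myocardial"
    EPICARDIAL = "epicardial"
    BLOOD = "blood"
    ECTODERMAL = "ectodermal"


#: Lineages that contribute to the developing outflow tract; blood and
#: ectoderm do not and are excluded when prioritizing candidates.
OFT_LINEAGES = frozenset(
    {Lineage.MESENCHYMAL, Lineage.VSMC, Lineage.ENDOTHELIAL, Lineage.MYOCARDIAL, Lineage.EPICARDIAL}
)
NON_OFT_LINEAGES = frozenset({Lineage.BLOOD, Lineage.ECTODERMAL})


@dataclass
class CellMatrix:
    """A genes x cells raw count matrix with cluster and lineage annotation."""

    counts: sp.csr_matrix
    gene_ids: list[GeneRef]
    cell_ids: list[str]
    cluster_labels: list[str]
    lineage_of_cluster: dict[str, Lineage]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.counts.eliminate_zeros()
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(f"expected {n_genes} gene ids, found {len(self.gene_ids)}")
        if len(self.cell_ids) != n_cells:
            raise FormatError(f"expected {n_cells} cell ids, found {len(self.cell_ids)}")
        if len(self.cluster_labels) != n_cells:
            raise FormatError(
                f"expected a cluster label for each of {n_cells} cells, found {len(self.cluster_labels)}"
            )
        missing = sorted(set(self.cluster_labels) - set(self.lineage_of_cluster))
        if missing:
            raise FormatError(f"clusters without a lineage annotation: {missing}")
        self.lineage_of_cluster = {c: Lineage(v) for c, v in self.lineage_of_cluster.items()}
        if (self.counts.data < 0).any():
            raise FormatError("count matrix contains negative entries")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self) -> dict[GeneRef, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_cells(self, keep: np.ndarray) -> "CellMatrix":
        """Return a matrix restricted to the cells selected by a boolean mask."""
        keep = np.asarray(keep, dtype=bool)
        return CellMatrix(
            counts=self.counts[:, keep],
            gene_ids=list(self.gene_ids),
            cell_ids=[c for c, k in zip(self.cell_ids, keep) if k],
            cluster_labels=[c for c, k in zip(self.cluster_labels, keep) if k],
            lineage_of_cluster=dict(self.lineage_of_cluster),
        )
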