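"""Exact overlap-enrichment and de novo burden statistics.

The central test asks: given two gene sets of sizes ``m`` and ``k`` drawn
from a population of ``N`` genes, how surprising is an overlap of ``q``
genes?  Under the null that the sets are independent draws, the overlap is
hypergeometric, and the one-sided p-value is the upper tail — equivalent to
a one-tailed Fisher's exact test.  Both tail conventions are implemented:

* ``ge`` — P(X >= q), the probability of "equal or more" overlap;
* ``gt`` — P(X > q), what R's ``phyper(q, m, n, k, lower.tail=FALSE)``
  actually returns.

The two differ by one PMF term, which matters when q sits in the far tail.
All tail sums are exact log-gamma computations in log space; no normal
approximation is used anywhere, since the p-values of interest span roughly
1e-5 to 0.4.

The de novo burden test compares the observed number of de novo variants in
a gene set against the expectation under per-gene mutation rates
(``expected = 2 * n_trios * sum(rates)``, the factor 2 counting both parental
haplotypes), with an exact Poisson upper tail.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.special import gammaln, logsumexp

from .core import GeneList, GeneRef, NamespaceError

__all__ = [
    "Tail",
    "OverlapTestResult",
    "BurdenResult",
    "hypergeom_log_pmf",
    "hypergeom_upper_tail",
    "overlap_enrichment",
    "replication_overlap_test",
    "poisson_burden",
    "bh_adjust",
    "uniform_rates",
    "length_proportional_rates",
]


class Tail(str, enum.Enum):
    GE = "ge"  # P(X >= q): "equal or more" overlap
    GT = "gt"  # P(X > q): strictly more (R phyper upper tail)


def _validate_sizes(m: int, n: int, k: int) -> None:
    if m < 0 or n < 0 or k < 0:
        raise ValueError(f"negative hypergeometric parameter: m={m}, n={n}, k={k}")
    if k > m + n:
        raise ValueError(f"draw size k={k} exceeds population m+n={m + n}")


def _log_choose(n: Union[int, np.ndarray], r: Union[int, np.ndarray]) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(r) + 1) - gammaln(np.asarray(n) - np.asarray(r) + 1)


def hypergeom_log_pmf(x: int, m: int, n: int, k: int) -> float:
    """Natural-log PMF of drawing ``x`` marked items in ``k`` draws.

    The population holds ``m`` marked and ``n`` unmarked items.  Outside the
    support the log-probability is ``-inf``.
    """
    _validate_sizes(m, n, k)
    lo, hi = max(0, k - n), min(m, k)
    if x < lo or x > hi:
        return float("-inf")
    return float(_log_choose(m, x) + _log_choose(n, k - x) - _log_choose(m + n, k))


def hypergeom_upper_tail(q: int, m: int, n: int, k: int, tail: Union[Tail, str] = Tail.GE) -> float:
    """Exact upper-tail hypergeometric probability.

    ``tail='ge'`` returns P(X >= q); ``tail='gt'`` returns P(X > q).  The sum
    runs over the support in log space (log-sum-exp), so values down to the
    smallest representable magnitudes are exact to machine precision.
    """
    tail = Tail(tail)
    _validate_sizes(m, n, k)
    lo, hi = max(0, k - n), min(m, k)
    start = q if tail == Tail.GE else q + 1
    if start <= lo:
        return 1.0
    if start > hi:
        return 0.0
    xs = np.arange(start, hi + 1)
    log_terms = _log_choose(m, xs) + _log_choose(n, k - xs) - _log_choose(m + n, k)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


@dataclass(frozen=True)
class OverlapTestResult:
    """Parameterization and outcome of one hypergeometric overlap test."""

    q: int
    m: int
    n: int
    k: int
    tail: Tail
    p_value: float
    overlap_genes: Optional[GeneList] = None
    group1_name: str = ""
    group2_name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.q <= min(self.m, self.k)):
            raise ValueError(f"overlap q={self.q} outside [0, min(m={self.m}, k={self.k})]")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def N(self) -> int:
        return self.m + self.n


def overlap_enrichment(
    group1: GeneList,
    group2: GeneList,
    population: Union[int, GeneList],
    tail: Union[Tail, str] = Tail.GE,
) -> OverlapTestResult:
    """Test whether two same-namespace gene lists overlap more than chance.

    ``population`` is either the population size N (when only the count of
    eligible genes is known, e.g. "all human genes with a mouse homolog") or
    an explicit population GeneList that must contain both groups.
    """
    if group1.namespace != group2.namespace:
        raise NamespaceError(
            f"overlap between {group1.name!r} ({group1.namespace.value}) and "
            f"{group2.name!r} ({group2.namespace.value}) requires homolog projection first"
        )
    if isinstance(population, GeneList):
        if population.namespace != group1.namespace:
            raise NamespaceError("population namespace differs from the groups")
        for g in (group1, group2):
            if not g.genes <= population.genes:
                extra = sorted(x.symbol for x in g.genes - population.genes)[:5]
                raise ValueError(f"group {g.name!r} not contained in population, e.g. {extra}")
        N = len(population)
    else:
        N = int(population)
    m, k = len(group1), len(group2)
    if m > N or k > N:
        raise ValueError(f"group sizes (m={m}, k={k}) exceed population N={N}")
    common = group1.genes & group2.genes
    q = len(common)
    p = hypergeom_upper_tail(q, m, N - m, k, tail)
    overlap = GeneList(
        name=f"{group1.name}&{group2.name}",
        namespace=group1.namespace,
        genes=frozenset(common),
        provenance=(f"overlap of {group1.name} (m={m}) and {group2.name} (k={k}) in N={N}: q={q}",),
    )
    return OverlapTestResult(
        q=q, m=m, n=N - m, k=k, tail=Tail(tail), p_value=p,
        overlap_genes=overlap, group1_name=group1.name, group2_name=group2.name,
    )


def replication_overlap_test(
    deg_hh: GeneList,
    cohort_a: GeneList,
    cohort_b: GeneList,
    celltype_predicate=None,
    tail: Union[Tail, str] = Tail.GE,
) -> OverlapTestResult:
    """Two-step replication test across two independent patient cohorts.

    Step 1 intersects each cohort's variant gene list with the
    differentially-expressed homolog list (optionally passing each gene
    through a cell-type predicate).  Step 2 asks how surprising the overlap
    of the two step-1 lists is, with the population restricted to the
    differentially-expressed homolog list itself: genes must already be
    dysregulated to enter either side, so the relevant universe is those
    genes, not the whole genome.
    """
    if len(deg_hh) == 0:
        raise ValueError("replication test requires a non-empty expression-evidence list")
    def step1(cohort: GeneList) -> GeneList:
        hit = deg_hh.genes & cohort.genes
        if celltype_predicate is not None:
            hit = frozenset(g for g in hit if celltype_predicate(g))
        return GeneList(
            name=f"{cohort.name}&{deg_hh.name}",
            namespace=deg_hh.namespace,
            genes=frozenset(hit),
            provenance=(f"step 1: {cohort.name} ({len(cohort)}) ∩ {deg_hh.name} ({len(deg_hh)}) = {len(hit)}",),
        )
    return overlap_enrichment(step1(cohort_a), step1(cohort_b), population=len(deg_hh), tail=tail)


@dataclass(frozen=True)
class BurdenResult:
    """Observed vs expected de novo variant count in a gene set."""

    variant_class: str
    observed: int
    expected: float
    p_value: float
    n_trios: int


def poisson_burden(
    observed: int,
    per_gene_rates: Mapping[GeneRef, float],
    n_trios: int,
    variant_class: str = "combined",
) -> BurdenResult:
    """Exact Poisson upper-tail burden test.

    ``per_gene_rates`` holds per-gene, per-haplotype de novo mutation rates
    for the variant class under test; the expected count over the cohort is
    ``2 * n_trios * sum(rates)``.  The p-value is P(X >= observed) under
    Poisson(expected), summed term-by-term in log space.
    """
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    if n_trios <= 0:
        raise ValueError("n_trios must be positive")
    rates = np.asarray(list(per_gene_rates.values()), dtype=float)
    if (rates < 0).any():
        raise ValueError("mutation rates must be non-negative")
    mu = 2.0 * n_trios * float(rates.sum())
    if mu == 0.0:
        if observed > 0:
            warnings.warn("all mutation rates are zero but variants were observed; p = 0")
            return BurdenResult(variant_class, observed, 0.0, 0.0, n_trios)
        return BurdenResult(variant_class, 0, 0.0, 1.0, n_trios)
    if observed == 0:
        return BurdenResult(variant_class, 0, mu, 1.0, n_trios)
    # P(X >= obs) = 1 - sum_{j < obs} pmf(j); for tiny tails sum upward instead.
    log_mu = np.log(mu)
    if observed <= mu:
        js = np.arange(0, observed)
        log_cdf = logsumexp(js * log_mu - mu - gammaln(js + 1))
        p = float(-np.expm1(log_cdf)) if log_cdf < 0 else 0.0
    else:
        width = int(max(50, 20 * np.sqrt(mu) + (observed - mu)))
        js = np.arange(observed, observed + width + 1)
        p = float(np.exp(logsumexp(js * log_mu - mu - gammaln(js + 1))))
    return BurdenResult(variant_class, observed, mu, min(1.0, max(0.0, p)), n_trios)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR)."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests
    return multipletests(arr, method="fdr_bh")[1]


def uniform_rates(genes: Sequence[GeneRef], rate: float = 1e-5) -> dict[GeneRef, float]:
    """Toy per-gene mutation-rate table: one shared rate for every gene."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return {g: rate for g in genes}


def length_proportional_rates(
    lengths_bp: Mapping[GeneRef, int], rate_per_kb: float = 5e-6
) -> dict[GeneRef, float]:
    """Toy rate table proportional to coding length (rate per kilobase)."""
    if rate_per_kb < 0:
        raise ValueError("rate_per_kb must be non-negative")
    return {g: rate_per_kb * (length / 1000.0) for g, length in lengths_bp.items()}
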