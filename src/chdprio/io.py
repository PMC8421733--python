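"""Readers and writers for every table format the pipeline touches.

All tabular formats are plain text (TSV/CSV with ``#`` comment lines, and
MatrixMarket for sparse counts).  Readers validate the documented invariants
up front and raise :class:`~chdprio.core.FormatError` with the offending
column or row index, so malformed inputs fail at the boundary rather than
deep inside the statistics.
"""

from __future__ import annotations

import io as _io
import warnings
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .core import (
    CellMatrix,
    Consequence,
    DEGRecord,
    FormatError,
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

__all__ = [
    "load_deg_table",
    "load_homolog_map",
    "load_variant_table",
    "load_count_matrix",
    "load_consequence_aliases",
    "write_gene_list",
    "read_gene_list",
]

PathLike = Union[str, Path]


def _read_table(path: PathLike, dialect: Optional[str] = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "," if dialect == "csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, comment="#", dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty file")
    return df


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, column: str, path: PathLike, allow_missing: bool = False) -> pd.Series:
    raw = df[column]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw.str.strip() != "")
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(f"{path}: unparseable numeric {raw.iloc[idx]!r} in column {column!r}, row {idx}")
    if not allow_missing and out.isna().any():
        idx = int(np.flatnonzero(out.isna().to_numpy())[0])
        raise FormatError(f"{path}: missing value in required column {column!r}, row {idx}")
    return out


def load_deg_table(path: PathLike, dialect: Optional[str] = None) -> list[DEGRecord]:
    """Load a differential-expression results table into DEGRecords.

    Required columns: ``gene,total_counts,log2fc,pvalue``; ``padj`` is
    optional (missing or blank padj is carried as ``None``).  Any columns
    named ``count_<sample>`` are collected into ``per_sample_counts`` in
    column order.
    """
    df = _read_table(path, dialect)
    _require_columns(df, ["gene", "total_counts", "log2fc", "pvalue"], path)
    totals = _numeric(df, "total_counts", path)
    log2fc = _numeric(df, "log2fc", path)
    pvals = _numeric(df, "pvalue", path)
    padj = _numeric(df, "padj", path, allow_missing=True) if "padj" in df.columns else None
    count_cols = [c for c in df.columns if c.startswith("count_")]
    per_sample = np.column_stack([_numeric(df, c, path) for c in count_cols]) if count_cols else None

    records: list[DEGRecord] = []
    for i in range(len(df)):
        sym = df["gene"].iloc[i]
        if not isinstance(sym, str) or not sym.strip():
            raise FormatError(f"{path}: blank gene symbol at row {i}")
        pa = None
        if padj is not None and not pd.isna(padj.iloc[i]):
            pa = float(padj.iloc[i])
        try:
            records.append(
                DEGRecord(
                    gene=mouse_gene(sym.strip()),
                    total_counts=int(totals.iloc[i]),
                    log2fc=float(log2fc.iloc[i]),
                    pvalue=float(pvals.iloc[i]),
                    padj=pa,
                    per_sample_counts=tuple(int(x) for x in per_sample[i]) if per_sample is not None else None,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: invariant violation at row {i}: {exc}") from exc
    return records


def load_homolog_map(path: PathLike) -> HomologMap:
    """Load a two-column TSV ``mouse_symbol<TAB>human_symbol`` homolog map.

    Duplicate rows collapse (set semantics); one-to-many and many-to-one
    multiplicities are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    pairs: set[tuple[GeneRef, GeneRef]] = set()
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}: expected 2 tab-separated columns at row {i}, found {len(fields)}")
            m, h = fields[0].strip(), fields[1].strip()
            if not m or not h:
                raise FormatError(f"{path}: blank symbol at row {i}")
            pairs.add((mouse_gene(m), human_gene(h)))
    return HomologMap(frozenset(pairs))


def load_consequence_aliases(path: Optional[PathLike] = None) -> dict[str, Consequence]:
    """Load the consequence alias table (shipped default, or a user file)."""
    if path is None:
        text = resources.files("chdprio").joinpath("data/consequence_aliases.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {str(k).lower(): Consequence(v) for k, v in raw.items()}


def load_variant_table(
    path: PathLike,
    dialect: Optional[str] = None,
    aliases: Optional[dict[str, Consequence]] = None,
) -> list[VariantRecord]:
    """Load a patient-level variant table.

    Required columns ``patient_id,gene,consequence,inheritance,diagnosis``;
    ``cohort`` optional.  Consequence tokens are resolved through the alias
    table (case-insensitive); a token absent from the table is a format
    error.  A blank inheritance field defaults to ``unknown``.
    """
    df = _read_table(path, dialect)
    _require_columns(df, ["patient_id", "gene", "consequence", "inheritance", "diagnosis"], path)
    if aliases is None:
        aliases = load_consequence_aliases()
    records: list[VariantRecord] = []
    for i in range(len(df)):
        token = str(df["consequence"].iloc[i]).strip().lower()
        if token not in aliases:
            raise FormatError(f"{path}: unknown consequence token {token!r} at row {i}")
        inh_raw = df["inheritance"].iloc[i]
        inh_token = "" if pd.isna(inh_raw) else str(inh_raw).strip().lower()
        if not inh_token:
            inh = Inheritance.UNKNOWN
        else:
            try:
                inh = Inheritance(inh_token)
            except ValueError:
                raise FormatError(f"{path}: unknown inheritance token {inh_token!r} at row {i}") from None
        cohort = ""
        if "cohort" in df.columns and not pd.isna(df["cohort"].iloc[i]):
            cohort = str(df["cohort"].iloc[i]).strip()
        try:
            records.append(
                VariantRecord(
                    patient_id=str(df["patient_id"].iloc[i]).strip(),
                    gene=human_gene(str(df["gene"].iloc[i]).strip()),
                    consequence=aliases[token],
                    inheritance=inh,
                    diagnosis=str(df["diagnosis"].iloc[i]).strip(),
                    cohort=cohort,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: invalid record at row {i}: {exc}") from exc
    return records


def _read_lines(path: PathLike) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]


def load_count_matrix(
    mtx_path: PathLike,
    genes_path: PathLike,
    cells_path: PathLike,
    clusters_path: PathLike,
    lineages_path: PathLike,
) -> CellMatrix:
    """Assemble a CellMatrix from a MatrixMarket triplet plus annotations.

    ``clusters_path``: 2-column TSV cell_id<TAB>cluster, covering every cell.
    ``lineages_path``: 2-column TSV cluster<TAB>lineage.
    """
    counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    genes = [mouse_gene(s) for s in _read_lines(genes_path)]
    cells = _read_lines(cells_path)
    if counts.shape[0] != len(genes):
        raise FormatError(f"{mtx_path}: expected {len(genes)} gene rows, found {counts.shape[0]}")
    if counts.shape[1] != len(cells):
        raise FormatError(f"{mtx_path}: expected {len(cells)} cell columns, found {counts.shape[1]}")
    cluster_of: dict[str, str] = {}
    for i, line in enumerate(_read_lines(clusters_path)):
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{clusters_path}: expected 2 columns at row {i}")
        cluster_of[fields[0].strip()] = fields[1].strip()
    missing = [c for c in cells if c not in cluster_of]
    if missing:
        raise FormatError(f"{clusters_path}: no cluster label for cell(s) {missing[:5]}")
    lineage_of: dict[str, Lineage] = {}
    for i, line in enumerate(_read_lines(lineages_path)):
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{lineages_path}: expected 2 columns at row {i}")
        try:
            lineage_of[fields[0].strip()] = Lineage(fields[1].strip())
        except ValueError:
            raise FormatError(f"{lineages_path}: unknown lineage {fields[1]!r} at row {i}") from None
    return CellMatrix(
        counts=counts,
        gene_ids=genes,
        cell_ids=cells,
        cluster_labels=[cluster_of[c] for c in cells],
        lineage_of_cluster=lineage_of,
    )


def write_gene_list(gene_list: GeneList, path: PathLike) -> None:
    """Write one symbol per line with a ``#`` header carrying provenance."""
    with open(path, "w") as fh:
        fh.write(f"# name: {gene_list.name}\n")
        fh.write(f"# namespace: {gene_list.namespace.value}\n")
        for line in gene_list.provenance:
            fh.write(f"# provenance: {line}\n")
        for symbol in gene_list.symbols:
            fh.write(symbol + "\n")


def read_gene_list(path: PathLike) -> GeneList:
    """Read a gene-list file written by :func:`write_gene_list`."""
    name, namespace, provenance, symbols = Path(path).stem, None, [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("name:"):
                    name = body[5:].strip()
                elif body.startswith("namespace:"):
                    namespace = Namespace(body[10:].strip())
                elif body.startswith("provenance:"):
                    provenance.append(body[11:].strip())
            elif line.strip():
                symbols.append(line.strip())
    if namespace is None:
        raise FormatError(f"{path}: missing '# namespace:' header")
    return GeneList(
        name=name,
        namespace=namespace,
        genes=frozenset(GeneRef(namespace, s) for s in symbols),
        provenance=tuple(provenance),
    )
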