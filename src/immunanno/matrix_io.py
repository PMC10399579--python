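"""Reading and writing single-cell count matrices and annotation tables.

The in-memory container is :class:`ExpressionMatrix`: genes x cells,
non-negative finite values, unique cell barcodes.  Input is accepted either
as a Matrix Market triplet (matrix + features + barcodes, the common 10x
export layout) or as a dense CSV/TSV table.  No filtering, correction or
normalization is applied at read time: the downstream enrichment statistic
is rank-based, so monotone per-cell transforms do not change labels.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, InputError

Matrix = Union[np.ndarray, sp.spmatrix]
CollapsePolicy = Literal["sum", "max", "first"]


def _open_text(path: Union[str, Path]) -> io.TextIOBase:
    """Open a possibly gzip-compressed text file."""
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


@dataclass
class ExpressionMatrix:
    """A genes x cells expression/count matrix.

    Parameters
    ----------
    gene_ids
        Row labels (gene symbols).  May contain duplicates until
        :func:`collapse_duplicate_genes` is applied; the file readers apply
        it automatically.
    cell_barcodes
        Column labels; must be pairwise distinct.
    counts
        ``(n_genes, n_cells)`` array or scipy sparse matrix of non-negative
        finite values.  Values need not be integers: normalized input is
        accepted because the scoring statistic only uses within-cell ranks.
    """

    gene_ids: list = field(default_factory=list)
    cell_barcodes: list = field(default_factory=list)
    counts: Matrix = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_barcodes = [str(b) for b in self.cell_barcodes]
        if sp.issparse(self.counts):
            self.counts = self.counts.tocsr()
        else:
            self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_barcodes)):
            raise InputError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_barcodes)} cells"
            )
        data = self.counts.data if sp.issparse(self.counts) else self.counts
        if data.size and (not np.all(np.isfinite(data)) or data.min() < 0):
            raise InputError("count values must be finite and non-negative")
        if len(set(self.cell_barcodes)) != len(self.cell_barcodes):
            dups = _duplicates(self.cell_barcodes)
            raise InputError(f"duplicate cell barcodes: {sorted(dups)[:5]}")

    # -- basic protocol -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_barcodes)

    @property
    def shape(self) -> tuple:
        return (self.n_genes, self.n_cells)

    def dense(self) -> np.ndarray:
        """Dense genes x cells float array."""
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return self.counts

    def cells_by_genes(self) -> np.ndarray:
        """Dense cells x genes array (the sklearn orientation)."""
        return self.dense().T

    def subset_cells(self, index: Sequence) -> "ExpressionMatrix":
        """New matrix restricted to the given cell positions or barcodes."""
        index = list(index)
        if index and isinstance(index[0], str):
            pos = {b: i for i, b in enumerate(self.cell_barcodes)}
            missing = [b for b in index if b not in pos]
            if missing:
                raise InputError(f"unknown barcodes: {missing[:5]}")
            index = [pos[b] for b in index]
        idx = np.asarray(index, dtype=int)
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            cell_barcodes=[self.cell_barcodes[i] for i in idx],
            counts=self.counts[:, idx],
        )

    def __repr__(self) -> str:
        kind = "sparse" if sp.issparse(self.counts) else "dense"
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_cells} cells, {kind})"


def _duplicates(items: Sequence) -> set:
    seen: set = set()
    dup: set = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _read_lines(path: Union[str, Path]) -> list:
    with _open_text(path) as fh:
        return [line.rstrip("\n").rstrip("\r") for line in fh if line.strip()]


def read_mtx_triplet(
    matrix_path: Union[str, Path],
    features_path: Union[str, Path],
    barcodes_path: Union[str, Path],
    *,
    symbol_column: int = None,
    collapse_policy: CollapsePolicy = "sum",
) -> ExpressionMatrix:
    """Read a Matrix Market triplet (matrix.mtx + features + barcodes).

    The features file may be a single column of gene symbols or a TSV whose
    second column holds the symbol (10x dialect); ``symbol_column``
    overrides the automatic choice.  Duplicate gene symbols are collapsed
    with ``collapse_policy`` ("sum" by default, conserving total counts).
    """
    try:
        counts = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises ValueError on malformed headers
        raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}") from exc
    counts = sp.csr_matrix(counts)

    feature_rows = [line.split("\t") for line in _read_lines(features_path)]
    if symbol_column is None:
        symbol_column = 1 if feature_rows and len(feature_rows[0]) >= 2 else 0
    try:
        gene_ids = [row[symbol_column] for row in feature_rows]
    except IndexError:
        raise FormatError(
            f"features file has no column {symbol_column}"
        ) from None
    barcodes = _read_lines(barcodes_path)

    if counts.shape != (len(gene_ids), len(barcodes)):
        raise FormatError(
            f"matrix is {counts.shape[0]} x {counts.shape[1]} but features/"
            f"barcodes files list {len(gene_ids)} genes and {len(barcodes)} cells"
        )
    m = ExpressionMatrix(gene_ids=gene_ids, cell_barcodes=barcodes, counts=counts)
    return collapse_duplicate_genes(m, collapse_policy)


def read_dense_table(
    path: Union[str, Path],
    genes_in: Literal["rows", "columns"] = "rows",
    *,
    delimiter: str = None,
    collapse_policy: CollapsePolicy = "sum",
) -> ExpressionMatrix:
    """Read a dense CSV/TSV table with a header row and a label column.

    ``genes_in`` states the orientation of the file; the returned matrix is
    always genes x cells.
    """
    if genes_in not in ("rows", "columns"):
        raise InputError(f"genes_in must be 'rows' or 'columns', got {genes_in!r}")
    path = Path(path)
    if delimiter is None:
        name = path.name[:-3] if path.name.endswith(".gz") else path.name
        delimiter = "\t" if name.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.empty:
        raise InputError(f"empty table: {path}")
    # locate non-numeric cells before coercion so the error names coordinates
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any() or numeric.isna().to_numpy().any():
        r, c = np.argwhere((numeric.isna()).to_numpy())[0]
        raise InputError(
            f"non-numeric value {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path}"
        )
    if genes_in == "columns":
        numeric = numeric.T
    m = ExpressionMatrix(
        gene_ids=list(numeric.index),
        cell_barcodes=list(numeric.columns),
        counts=numeric.to_numpy(dtype=float),
    )
    return collapse_duplicate_genes(m, collapse_policy)


def collapse_duplicate_genes(
    m: ExpressionMatrix, policy: CollapsePolicy = "sum"
) -> ExpressionMatrix:
    """Merge rows sharing a gene symbol (per-cell sum / max / first row).

    Output row order is first-occurrence order; returns the input object
    unchanged when all symbols are already distinct.
    """
    if policy not in ("sum", "max", "first"):
        raise InputError(f"unknown collapse policy {policy!r}")
    if len(set(m.gene_ids)) == len(m.gene_ids):
        return m
    order: dict = {}
    for i, g in enumerate(m.gene_ids):
        order.setdefault(g, []).append(i)
    genes = list(order)
    if policy == "first":
        rows = [idx[0] for idx in order.values()]
        counts = m.counts[rows, :]
    else:
        dense = m.dense()
        agg = np.empty((len(genes), m.n_cells))
        for j, idx in enumerate(order.values()):
            block = dense[idx, :]
            agg[j] = block.sum(axis=0) if policy == "sum" else block.max(axis=0)
        counts = sp.csr_matrix(agg) if sp.issparse(m.counts) else agg
    return ExpressionMatrix(gene_ids=genes, cell_barcodes=list(m.cell_barcodes), counts=counts)


# ---------------------------------------------------------------------------
# annotation result tables

ANNOTATION_COLUMNS = [
    "barcode",
    "prescreen_label",
    "layer1_label",
    "layer1_score",
    "layer2_label",
    "layer2_score",
    "layer3_label",
    "layer3_score",
]


def write_annotation_csv(result, path: Union[str, Path]) -> None:
    """Write per-cell annotation results as CSV (one row per cell).

    Columns: barcode, prescreen_label, then label/score pairs for layers
    1-3.  Layers the cell never reached are left empty.  Row order follows
    the input barcode order and the label fields round-trip exactly.
    """
    df = result.to_frame() if hasattr(result, "to_frame") else pd.DataFrame(result)
    if df.empty:
        raise InputError("refusing to write an empty annotation table")
    out = df.reindex(columns=ANNOTATION_COLUMNS)
    out.to_csv(path, index=False, float_format="%.10g")


def read_annotation_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read an annotation CSV back into a DataFrame (labels as strings)."""
    df = pd.read_csv(path, dtype={c: "string" for c in ANNOTATION_COLUMNS if c.endswith(("barcode", "label"))})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation CSV {path} lacks columns {missing}")
    for col in df.columns:
        if col.endswith("label") or col == "barcode":
            df[col] = df[col].astype(object).where(df[col].notna(), None)
    return df
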