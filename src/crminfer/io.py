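"""Tabular input/output and the expression transform the model assumes.

Two tab-separated formats are supported:

* binding TSV — header ``gene\\t<TF1>\\t<TF2>...``, body rows of 0/1
  indicators marking whether a TF binds a regulatory region associated
  with the gene;
* expression TSV — header ``gene\\t<sample1>...``, body of non-negative
  expression values (TPM or normalized intensities).

Genes are rows, TFs/samples are columns, everywhere. Before inference the
expression matrix is log-transformed and mean-centered per gene, so that a
gene's baseline expression is (approximately) removed and only variation
relative to baseline remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BindingTable",
    "ExpressionTable",
    "LogExpression",
    "load_binding_table",
    "save_binding_table",
    "load_expression_table",
    "save_expression_table",
    "align_genes",
    "log_transform_normalize",
]


class FormatError(ValueError):
    """A file violates the expected tabular format."""


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class BindingTable:
    """Observed binary TF–gene binding events (genes × TFs)."""

    gene_ids: list[str]
    tf_ids: list[str]
    values: np.ndarray  # N×T, entries in {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("binding matrix must be 2-dimensional")
        n, t = self.values.shape
        if n != len(self.gene_ids) or t != len(self.tf_ids):
            raise ValueError("binding matrix shape does not match id lists")
        if n < 1 or t < 1:
            raise ValueError("need at least one gene and one TF")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.tf_ids, "TF")
        if not np.isin(self.values, (0, 1)).all():
            raise FormatError("binding matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BindingTable):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.tf_ids == other.tf_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class ExpressionTable:
    """Non-negative expression values (genes × samples)."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # N×M, >= 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n, m = self.values.shape
        if n != len(self.gene_ids) or m != len(self.sample_ids):
            raise ValueError("expression matrix shape does not match id lists")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.values).all():
            raise FormatError("expression values must be finite numbers")
        if (self.values < 0).any():
            bad = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionTable):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.values, other.values)
        )


@dataclass
class LogExpression:
    """Log-transformed, per-gene mean-centered expression (matrix Y)."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # N×M, each row has mean 0
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        row_means = self.values.mean(axis=1)
        if np.abs(row_means).max(initial=0.0) > 1e-9:
            raise ValueError("log-expression rows must be mean-centered")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _read_tsv(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "column")  # pandas would silently mangle dupes
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def load_binding_table(path) -> BindingTable:
    """Read a binding TSV (header = TF names, first column = gene ids)."""
    df = _read_tsv(path)
    raw = df.to_numpy()
    values = np.zeros(raw.shape, dtype=np.int8)
    for (i, j), cell in np.ndenumerate(raw):
        if cell not in ("0", "1"):
            raise FormatError(
                f"non-binary binding value {cell!r} at gene {df.index[i]!r}, "
                f"TF {df.columns[j]!r}"
            )
        values[i, j] = int(cell)
    return BindingTable(list(df.index), list(df.columns), values)


def save_binding_table(table: BindingTable, path) -> None:
    df = pd.DataFrame(table.values, index=table.gene_ids, columns=table.tf_ids)
    df.to_csv(path, sep="\t", index_label="gene")


def load_expression_table(path) -> ExpressionTable:
    """Read an expression TSV (header = sample ids, first column = gene ids)."""
    df = _read_tsv(path)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression value: {exc}") from exc
    return ExpressionTable(list(df.index), list(df.columns), values)


def save_expression_table(table: ExpressionTable, path) -> None:
    df = pd.DataFrame(
        table.values, index=table.gene_ids, columns=table.sample_ids
    )
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def align_genes(
    binding: BindingTable, expr: ExpressionTable
) -> tuple[BindingTable, ExpressionTable]:
    """Restrict both tables to their shared genes, in binding-table order."""
    expr_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    shared = [g for g in binding.gene_ids if g in expr_pos]
    if not shared:
        raise ValueError("binding and expression tables share no gene ids")
    b_pos = {g: i for i, g in enumerate(binding.gene_ids)}
    b_idx = [b_pos[g] for g in shared]
    e_idx = [expr_pos[g] for g in shared]
    return (
        BindingTable(shared, list(binding.tf_ids), binding.values[b_idx]),
        ExpressionTable(shared, list(expr.sample_ids), expr.values[e_idx]),
    )


def log_transform_normalize(
    expr: ExpressionTable,
    pseudocount: float = 1.0,
    baseline_column: str | None = None,
) -> LogExpression:
    """Natural-log transform and per-gene centering of expression values.

    ``y[n, m] = log(expr[n, m] + pseudocount) - baseline_n`` where the
    baseline is the per-gene mean of the log values (steady-state data) or,
    if ``baseline_column`` names a sample, that sample's log value
    (time-course data referenced to time 0). With a baseline column the
    rows are still re-centered afterwards so the model's zero-mean residual
    assumption holds; the reference shift is absorbed into the centering.

    Parameters
    ----------
    pseudocount:
        Added before the log; must leave all values strictly positive.
        Use 0 only when every expression value is already positive.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    shifted = expr.values + pseudocount
    if (shifted <= 0).any():
        raise ValueError(
            "expression contains zeros; supply a positive pseudocount"
        )
    logged = np.log(shifted)
    if baseline_column is not None:
        if baseline_column not in expr.sample_ids:
            raise ValueError(f"unknown baseline sample {baseline_column!r}")
        j = expr.sample_ids.index(baseline_column)
        logged = logged - logged[:, [j]]
    centered = logged - logged.mean(axis=1, keepdims=True)
    return LogExpression(
        list(expr.gene_ids), list(expr.sample_ids), centered, pseudocount
    )
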