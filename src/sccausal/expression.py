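"""Expression-matrix loading, transforms, gene attributes, filtering and cell sampling.

The substrate of the whole workflow is a dense gene × cell matrix.  Genes are
rows and cells are columns everywhere.  Raw counts (or raw intensities) can be
turned into log2(x+1) values or per-gene z-scores; every downstream stage
records which transform it received.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "FilterSpec",
    "load_expression",
    "transform",
    "compute_gene_attributes",
    "filter_genes",
    "sample_cells",
    "write_gene_attributes",
]

_TRANSFORMS = ("raw", "log2", "zscore")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclasses.dataclass(frozen=True)
class ExpressionMatrix:
    """Dense gene × cell expression matrix with a transform tag.

    Parameters
    ----------
    values
        2-D float array, rows = genes, columns = cells.
    gene_ids, cell_ids
        Unique ordered identifiers matching the matrix axes.
    transform
        One of ``raw``, ``log2``, ``zscore``.  Raw matrices must be
        non-negative.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]
    transform: str = "raw"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"shape {values.shape} does not match {len(self.gene_ids)} genes "
                f"x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.transform not in _TRANSFORMS:
            raise ValidationError(f"unknown transform tag {self.transform!r}")
        if self.transform == "raw" and values.size and values.min() < 0:
            raise ValidationError("raw expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.cell_ids))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: k for k, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(self.values[rows], tuple(genes), self.cell_ids, self.transform)


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id {i!r}")
        seen.add(i)


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """Conjunction of gene-filtering conditions (all strict inequalities).

    The packaged defaults — mean expression > 0.1, expressed in > 50 % of
    cells, |log2 fold change| > 0.3 — are the thresholds used to pick highly
    and differentially expressed genes ahead of feature selection.
    """

    min_mean_expr: float | None = None
    min_pct_cells: float | None = None
    min_variance: float | None = None
    min_abs_log_fc: float | None = None
    tf_only: bool = False

    def __post_init__(self) -> None:
        thresholds = (self.min_mean_expr, self.min_pct_cells, self.min_variance, self.min_abs_log_fc)
        if all(t is None for t in thresholds) and not self.tf_only:
            raise ValidationError("FilterSpec must set at least one condition")
        for t in thresholds:
            if t is not None and not np.isfinite(t):
                raise ValidationError("filter thresholds must be finite")

    @classmethod
    def default(cls) -> "FilterSpec":
        return cls(min_mean_expr=0.1, min_pct_cells=0.5, min_abs_log_fc=0.3)


def load_expression(
    path: str | Path,
    format: str | None = None,
    *,
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
    transform: str = "raw",
) -> ExpressionMatrix:
    """Load a gene × cell matrix from CSV/TSV or matrix-market triplets.

    CSV/TSV files carry cell ids in the header row and gene ids in the first
    column.  ``mtx-triplet`` requires companion one-column text files of gene
    ids and cell barcodes (defaulting to ``genes.tsv`` / ``barcodes.tsv``
    next to the matrix file).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx-triplet"}.get(path.suffix.lower())
        if format is None:
            raise ValidationError(f"cannot infer format from suffix {path.suffix!r}")
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except pd.errors.ParserError as exc:  # keep the offending line visible
            raise ValidationError(f"malformed {format} file {path}: {exc}") from exc
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r} in {path}")
        return ExpressionMatrix(
            df.to_numpy(dtype=float), tuple(map(str, df.index)), tuple(map(str, df.columns)), transform
        )
    if format == "mtx-triplet":
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        barcodes_path = Path(barcodes_path) if barcodes_path else path.parent / "barcodes.tsv"
        for p in (genes_path, barcodes_path):
            if not p.exists():
                raise FileNotFoundError(p)
        try:
            mat = scipy.io.mmread(str(path))
        except ValueError as exc:
            raise ValidationError(f"malformed matrix-market file {path}: {exc}") from exc
        genes = [ln.split("\t")[0].strip() for ln in genes_path.read_text().splitlines() if ln.strip()]
        cells = [ln.split("\t")[0].strip() for ln in barcodes_path.read_text().splitlines() if ln.strip()]
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        if dense.shape != (len(genes), len(cells)):
            raise ValidationError(
                f"matrix shape {dense.shape} does not match {len(genes)} genes x {len(cells)} barcodes"
            )
        return ExpressionMatrix(dense, tuple(genes), tuple(cells), transform)
    raise ValidationError(f"unknown format {format!r}")


def transform(m: ExpressionMatrix, mode: str) -> ExpressionMatrix:
    """Apply ``log2`` (x ↦ log2(x+1), raw input only) or per-gene ``zscore``.

    Constant genes z-score to all zeros; the sample standard deviation
    (ddof=1) is used otherwise.
    """
    if mode == "log2":
        if m.transform != "raw":
            raise ValidationError(f"log2 transform requires raw data, got {m.transform!r}")
        return ExpressionMatrix(np.log2(m.values + 1.0), m.gene_ids, m.cell_ids, "log2")
    if mode == "zscore":
        vals = m.values
        mean = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=1, keepdims=True) if m.n_cells > 1 else np.zeros_like(mean)
        centered = vals - mean
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
        return ExpressionMatrix(z, m.gene_ids, m.cell_ids, "zscore")
    raise ValidationError(f"unknown transform mode {mode!r}")


def compute_gene_attributes(
    case: ExpressionMatrix,
    control: ExpressionMatrix | None = None,
    tf_list: Iterable[str] | None = None,
    pseudo_count: float = 1.0,
) -> pd.DataFrame:
    """Per-gene attribute table: mean, fraction of expressing cells, variance.

    With a control matrix, log2 fold changes are added as
    ``log2((mean_case + c) / (mean_ctrl + c))`` with pseudo-count ``c``
    (default 1), computed on the matrices as given; genes absent from the
    control get NaN.  ``tf_list`` adds a boolean transcription-factor column.
    "Expressed" means strictly positive.
    """
    if case.n_genes == 0 or case.n_cells == 0:
        raise ValidationError("case matrix must be non-empty")
    vals = case.values
    attrs = pd.DataFrame(
        {
            "mean_expr": vals.mean(axis=1),
            "pct_cells": (vals > 0).mean(axis=1),
            "variance": vals.var(axis=1, ddof=1) if case.n_cells > 1 else np.zeros(case.n_genes),
        },
        index=list(case.gene_ids),
    )
    attrs.index.name = "gene"
    if control is not None:
        if control.n_cells == 0:
            raise ValidationError("control matrix has zero cells")
        ctrl_mean = pd.Series(control.values.mean(axis=1), index=list(control.gene_ids))
        lfc = np.full(case.n_genes, np.nan)
        for k, g in enumerate(case.gene_ids):
            if g in ctrl_mean.index:
                lfc[k] = np.log2((attrs["mean_expr"].iloc[k] + pseudo_count) / (ctrl_mean[g] + pseudo_count))
        attrs["log_fc"] = lfc
    if tf_list is not None:
        tfs = set(tf_list)
        attrs["is_tf"] = [g in tfs for g in case.gene_ids]
    return attrs


def filter_genes(
    attrs: pd.DataFrame,
    spec: FilterSpec,
    order_by: str = "mean_expr",
) -> list[str]:
    """Genes passing every set condition, ordered descending by ``order_by``.

    All comparisons are strict; ties in the ordering attribute break
    lexicographically by gene id.
    """
    keep = pd.Series(True, index=attrs.index)
    if spec.min_mean_expr is not None:
        keep &= attrs["mean_expr"] > spec.min_mean_expr
    if spec.min_pct_cells is not None:
        keep &= attrs["pct_cells"] > spec.min_pct_cells
    if spec.min_variance is not None:
        keep &= attrs["variance"] > spec.min_variance
    if spec.min_abs_log_fc is not None:
        if "log_fc" not in attrs.columns:
            raise ValidationError("min_abs_log_fc requires a log_fc column (control matrix)")
        keep &= attrs["log_fc"].abs() > spec.min_abs_log_fc
    if spec.tf_only:
        if "is_tf" not in attrs.columns:
            raise ValidationError("tf_only requires an is_tf column (tf list)")
        keep &= attrs["is_tf"].astype(bool)
    if order_by not in attrs.columns:
        raise ValidationError(f"unknown ordering attribute {order_by!r}")
    kept = attrs.loc[keep].copy()
    kept = kept.sort_index().sort_values(order_by, ascending=False, kind="stable")
    return [str(g) for g in kept.index]


def sample_cells(m: ExpressionMatrix, n: int, mode: str = "random", seed: int = 0) -> ExpressionMatrix:
    """Take ``n`` cells without replacement, either seeded-``random`` or the ``first`` n.

    300 cells (plate-based protocols) and 600 cells (droplet-based) are the
    packaged recommendations for ~50-gene inputs.
    """
    if not 1 <= n <= m.n_cells:
        raise ValidationError(f"cannot sample {n} cells from {m.n_cells}")
    if mode == "first":
        cols = np.arange(n)
    elif mode == "random":
        rng = np.random.default_rng(seed)
        cols = np.sort(rng.choice(m.n_cells, size=n, replace=False))
    else:
        raise ValidationError(f"unknown sampling mode {mode!r}")
    return ExpressionMatrix(
        m.values[:, cols], m.gene_ids, tuple(m.cell_ids[c] for c in cols), m.transform
    )


def write_gene_attributes(attrs: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write the attribute table as TSV (gene, mean_expr, pct_cells, variance, ...)."""
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        attrs.to_csv(fh, sep="\t")
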