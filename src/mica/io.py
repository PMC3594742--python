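"""Reading/writing tabular artifacts and the gene pre-filters.

Expression matrices, association matrices, memberships and partitions are
all plain TSV with a leading label column and a header row; values are
serialized with 12 significant digits so files round-trip numerically.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AssociationMatrix,
    ExpressionMatrix,
    GeneFilterReport,
    MembershipMatrix,
    ModulePartition,
)

_FLOAT_FMT = "%.12g"


def load_expression(
    path, delimiter: str = "\t", genes_in_rows: bool = True
) -> ExpressionMatrix:
    """Load a genes x samples table (or its transpose) from delimited text.

    The first column holds row labels and the first row column labels.
    Duplicate IDs and non-numeric cells raise with the offending
    location named.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if not genes_in_rows:
        df = df.T
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate gene IDs in {path}: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {df.index[r]!r}, sample "
            f"{df.columns[c]!r} in {path}: {df.iat[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    numeric.index = df.index.map(str)
    numeric.columns = df.columns.map(str)
    return ExpressionMatrix.from_frame(numeric)


def write_expression(expr: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    expr.to_frame().to_csv(path, sep=delimiter, float_format=_FLOAT_FMT)


def filter_genes(
    expr: ExpressionMatrix,
    cv_min: float = 0.05,
    use_intensity_filter: bool = True,
) -> tuple[ExpressionMatrix, GeneFilterReport]:
    """Apply the intensity and coefficient-of-variation pre-filters.

    Keeps genes whose mean intensity is strictly above the grand mean of
    per-gene means (when the flag is set), then genes whose CV = sd/mean
    is strictly above ``cv_min``. CV uses the n-1 standard deviation; for
    negative means (log-scale data) |mean| is used with a warning, and
    zero-mean genes are excluded because their CV is undefined.
    """
    if cv_min < 0:
        raise ValueError("cv_min must be nonnegative")
    n_input = expr.n_genes
    means = expr.values.mean(axis=1)

    if use_intensity_filter:
        keep_int = means > means.mean()
    else:
        keep_int = np.ones(n_input, dtype=bool)
    n_after_intensity = int(keep_int.sum())

    sds = expr.values.std(axis=1, ddof=1)
    abs_means = np.abs(means)
    if np.any(means[keep_int] < 0):
        warnings.warn(
            "negative per-gene means encountered; CV computed on |mean|",
            stacklevel=2,
        )
    zero_mean = abs_means == 0
    if np.any(keep_int & zero_mean):
        warnings.warn(
            "genes with zero mean excluded (CV undefined)", stacklevel=2
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(zero_mean, np.nan, sds / abs_means)
    keep = keep_int & ~zero_mean & (cv > cv_min)

    kept_ids = [g for g, k in zip(expr.gene_ids, keep) if k]
    out = ExpressionMatrix(kept_ids, list(expr.sample_ids), expr.values[keep])
    report = GeneFilterReport(n_input, n_after_intensity, len(kept_ids), kept_ids)
    return out, report


def select_top_genes(
    expr: ExpressionMatrix, k: int, by: str = "variance"
) -> ExpressionMatrix:
    """Keep the k most variable (CV) or most highly expressed (mean) genes.

    Complements the threshold filters for datasets where a fixed gene
    count is wanted; input order is preserved among the survivors.
    """
    if by == "variance":
        means = np.abs(expr.values.mean(axis=1))
        sds = expr.values.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(means == 0, -np.inf, sds / means)
    elif by == "expression":
        score = expr.values.mean(axis=1)
    else:
        raise ValueError("by must be 'variance' or 'expression'")
    if k >= expr.n_genes:
        return expr
    order = np.argsort(score, kind="stable")[::-1][:k]
    keep = np.zeros(expr.n_genes, dtype=bool)
    keep[order] = True
    kept = [g for g, kk in zip(expr.gene_ids, keep) if kk]
    return ExpressionMatrix(kept, list(expr.sample_ids), expr.values[keep])


def write_matrix(obj, path) -> None:
    """Serialize an association matrix, membership matrix or partition.

    TSV with row/column labels; values carry 12 significant digits so a
    reload reproduces the object to at least that precision.
    """
    path = Path(path)
    if isinstance(obj, (AssociationMatrix, MembershipMatrix)):
        obj.to_frame().to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    elif isinstance(obj, ModulePartition):
        obj.to_frame().to_csv(path, sep="\t")
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")


def read_association(path, measure_tag: str = "mic") -> AssociationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AssociationMatrix(
        [str(g) for g in df.index], df.to_numpy(dtype=float), measure_tag
    )


def read_membership(path) -> MembershipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    mm = df.to_numpy(dtype=float)
    mm = mm / mm.sum(axis=1, keepdims=True)  # absorb 1e-12 serialization error
    return MembershipMatrix([str(g) for g in df.index], mm)


def read_partition(path) -> ModulePartition:
    df = pd.read_csv(path, sep="\t", index_col=0)
    assignments = []
    n_modules = 0
    for lab in df["module"]:
        if str(lab) == "unplaced":
            assignments.append(frozenset())
        else:
            mods = frozenset(int(tok) for tok in str(lab).split(";"))
            n_modules = max(n_modules, max(mods))
            assignments.append(mods)
    return ModulePartition([str(g) for g in df.index], assignments, n_modules)
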