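"""Expression-matrix container, tabular I/O and the standard normalisations.

The unit of analysis throughout the package is a gene expression profile
(GEP): the vector of log2-scale expression values of all measured genes in
one sample.  Matrices are stored genes x samples, matching the on-disk
layout (first column gene ids, header row sample ids), and one sample
column is what gets fed to a network as a single input vector.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ExpressionIOError",
    "read_matrix",
    "write_matrix",
    "read_annotations",
    "write_annotations",
    "log2_transform",
    "quantile_normalize",
    "minmax_per_gene",
    "top_variance_genes",
]


class ExpressionIOError(ValueError):
    """Malformed expression-matrix or annotation file."""


class ExpressionMatrix:
    """A genes x samples matrix of expression values with unique identifiers.

    Parameters
    ----------
    values : (n_genes, n_samples) array-like of finite floats
    gene_ids : sequence of unique gene identifiers
    sample_ids : sequence of unique sample identifiers
    """

    def __init__(
        self,
        values: np.ndarray,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples array")
        gene_ids = [str(g) for g in gene_ids]
        sample_ids = [str(s) for s in sample_ids]
        if len(gene_ids) != values.shape[0]:
            raise ValueError(
                f"{len(gene_ids)} gene ids for {values.shape[0]} rows"
            )
        if len(sample_ids) != values.shape[1]:
            raise ValueError(
                f"{len(sample_ids)} sample ids for {values.shape[1]} columns"
            )
        if len(set(gene_ids)) != len(gene_ids):
            raise ExpressionIOError("duplicate gene ids")
        if len(set(sample_ids)) != len(sample_ids):
            raise ExpressionIOError("duplicate sample ids")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        self.values = values
        self.gene_ids = list(gene_ids)
        self.sample_ids = list(sample_ids)

    # -- basic protocol ----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        idx = [pos[s] for s in ids]
        return ExpressionMatrix(self.values[:, idx], self.gene_ids, ids)

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(gene_ids)
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in ids if g not in pos]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        idx = [pos[g] for g in ids]
        return ExpressionMatrix(self.values[idx, :], ids, self.sample_ids)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.gene_ids), list(self.sample_ids)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"


# -- I/O -------------------------------------------------------------------

def read_matrix(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample ids, first column = gene ids).

    Raises :class:`ExpressionIOError` on ragged rows or duplicated
    identifiers, naming the offending line.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ExpressionIOError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        if len(set(sample_ids)) != len(sample_ids):
            raise ExpressionIOError(f"{path}: duplicate sample id in header")
        genes: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(sample_ids) + 1:
                raise ExpressionIOError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, "
                    f"got {len(parts)}"
                )
            gid = parts[0]
            if gid in seen:
                raise ExpressionIOError(
                    f"{path}:{lineno}: duplicate gene id {gid!r}"
                )
            seen.add(gid)
            genes.append(gid)
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ExpressionIOError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise ExpressionIOError(f"{path}: no data rows")
    return ExpressionMatrix(np.array(rows, dtype=float), genes, sample_ids)


def write_matrix(m: ExpressionMatrix, path, float_format: str = "%.10g") -> None:
    """Write a matrix as TSV; round-trips through :func:`read_matrix`."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(m.sample_ids) + "\n")
        for gid, row in zip(m.gene_ids, m.values):
            fh.write(gid + "\t" + "\t".join(float_format % v for v in row) + "\n")


def read_annotations(path, header: bool = False) -> pd.Series:
    """Read a two-column sample-id -> type-label TSV into a Series."""
    df = pd.read_csv(
        path, sep="\t", header=0 if header else None, dtype=str
    )
    if df.shape[1] != 2:
        raise ExpressionIOError(
            f"{path}: annotation file must have exactly 2 columns"
        )
    ids = df.iloc[:, 0]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ExpressionIOError(f"{path}: duplicate sample id {dup!r}")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=ids.to_numpy(), name="type")


def write_annotations(ann: pd.Series, path, header: bool = False) -> None:
    ann.to_frame("type").to_csv(
        path, sep="\t", header=header, index_label="sample" if header else None
    )


def check_annotations(m: ExpressionMatrix, ann: pd.Series) -> pd.Series:
    """Validate that every sample in `m` carries exactly one label."""
    missing = [s for s in m.sample_ids if s not in ann.index]
    if missing:
        raise ValueError(f"samples without annotation: {missing[:5]}")
    return ann.loc[m.sample_ids]


# -- transforms ------------------------------------------------------------

def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(value + pseudocount); input must be non-negative."""
    if np.any(m.values < 0):
        raise ValueError("log2_transform requires non-negative values")
    shifted = m.values + pseudocount
    if np.any(shifted <= 0):
        raise ValueError(
            "value + pseudocount must be positive (increase the pseudocount)"
        )
    return ExpressionMatrix(np.log2(shifted), m.gene_ids, m.sample_ids)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column to the common reference distribution.

    The reference is the across-sample mean of per-rank values; within-column
    rank order is preserved.  Ties within a column receive the mean of the
    reference values of their tied ranks (mid-rank convention).  Idempotent.
    """
    if m.n_samples < 2:
        warnings.warn("quantile_normalize on <2 samples is a no-op")
        return m.copy()
    x = m.values
    order = np.argsort(x, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(x, order, axis=0)
    reference = sorted_vals.mean(axis=1)  # per-rank mean across samples
    out = np.empty_like(x)
    n = x.shape[0]
    for j in range(x.shape[1]):
        col = x[:, j]
        # mid-rank assignment of reference values, handling ties
        ranks = np.empty(n)
        ranks[order[:, j]] = np.arange(n)
        out_col = reference[ranks.astype(int)]
        # average reference values over tied groups
        uniq, inv = np.unique(col, return_inverse=True)
        if len(uniq) < n:
            sums = np.bincount(inv, weights=out_col)
            counts = np.bincount(inv)
            out_col = (sums / counts)[inv]
        out[:, j] = out_col
    return ExpressionMatrix(out, m.gene_ids, m.sample_ids)


def minmax_per_gene(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each gene to [0, 1] across samples; constant genes map to 0."""
    lo = m.values.min(axis=1, keepdims=True)
    hi = m.values.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(m.values)
    nonconst = (span > 0).ravel()
    out[nonconst] = (m.values[nonconst] - lo[nonconst]) / span[nonconst]
    return ExpressionMatrix(out, m.gene_ids, m.sample_ids)


def top_variance_genes(m: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """Keep the k genes with largest sample variance (ties: input order).

    Variance uses the unbiased (n-1) denominator.
    """
    if k > m.n_genes:
        raise ValueError(f"k={k} exceeds the {m.n_genes} available genes")
    if k < 1:
        raise ValueError("k must be >= 1")
    var = m.values.var(axis=1, ddof=1) if m.n_samples > 1 else np.zeros(m.n_genes)
    # stable sort on negated variance keeps input order among ties
    idx = np.argsort(-var, kind="stable")[:k]
    idx = np.sort(idx)  # preserve original gene order in the output
    return ExpressionMatrix(
        m.values[idx], [m.gene_ids[i] for i in idx], m.sample_ids
    )
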