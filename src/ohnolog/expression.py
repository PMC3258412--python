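"""Per-gene expression summary statistics from EST library counts.

A gene's expression level in library *i* is the proportion ``L_i`` of that
library's transcripts belonging to the gene.  Three (deliberately
non-independent) summaries describe the profile across libraries:

``T``  total expression, ``sum(L_i)``;
``I``  intensity, the self-weighted mean level ``sum(L_i**2) / sum(L_i)``;
``E``  evenness, ``T / I = sum(L_i)**2 / sum(L_i**2)`` — the inverse Simpson
       index of the profile, interpretable as the effective number of
       libraries in which the gene is expressed (1 = library-specific,
       n_libraries = perfectly even).

Genes with no ESTs anywhere have ``T = 0``, ``I`` set to zero (its limit as
expression vanishes) and ``E`` undefined, encoded as NaN.  Extreme levels
are capped at a fixed fraction of their library (default 1%) before the
summaries are computed, so a handful of very highly expressed genes cannot
dominate downstream regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "library_proportions",
    "truncate_outliers",
    "total_expression",
    "intensity",
    "evenness",
    "summarize_expression",
]

DEFAULT_CAP = 0.01


@dataclass
class ExpressionMatrix:
    """EST counts per gene (rows) across named libraries (columns).

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, index = gene ids, columns = library ids.
    library_sizes : pandas.Series
        Total transcripts per library (the denominator of ``L_i``), indexed
        like ``counts.columns``.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.library_sizes = pd.Series(self.library_sizes)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.library_sizes.isna().any():
            missing = self.library_sizes.index[self.library_sizes.isna()]
            raise ValueError(f"library_sizes missing for libraries: {list(missing)}")
        if (self.library_sizes < 1).any():
            raise ValueError("library sizes must be >= 1")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate library ids")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative EST counts")
        if (vals > self.library_sizes.to_numpy()[None, :]).any():
            raise ValueError("a gene's count exceeds its library size")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def library_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_libraries(self) -> int:
        return self.counts.shape[1]

    def to_tsv(self, counts_path: str | Path, sizes_path: str | Path) -> None:
        """Write counts and a sidecar table of library sizes as TSV."""
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.library_sizes.rename("library_size").to_csv(
            sizes_path, sep="\t", index_label="library_id"
        )

    @classmethod
    def from_tsv(cls, counts_path: str | Path, sizes_path: str | Path) -> "ExpressionMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        sizes = pd.read_csv(sizes_path, sep="\t", index_col="library_id")["library_size"]
        return cls(counts=counts, library_sizes=sizes)


def library_proportions(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene expression levels ``L[g, i] = counts[g, i] / library_sizes[i]``."""
    sizes = matrix.library_sizes.to_numpy(dtype=float)
    if (sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    L = matrix.counts.to_numpy(dtype=float) / sizes[None, :]
    return pd.DataFrame(L, index=matrix.gene_ids, columns=matrix.library_ids)


def truncate_outliers(
    L: pd.DataFrame, cap: float = DEFAULT_CAP
) -> tuple[pd.DataFrame, pd.Series]:
    """Cap expression levels strictly above ``cap`` at ``cap``.

    Returns the capped matrix and a per-gene boolean flag marking genes with
    at least one truncated cell.  Cells exactly at the cap are untouched.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    vals = L.to_numpy(dtype=float)
    over = vals > cap
    capped = np.where(over, cap, vals)
    flags = pd.Series(over.any(axis=1), index=L.index, name="truncated")
    return pd.DataFrame(capped, index=L.index, columns=L.columns), flags


def total_expression(L_gene: np.ndarray) -> float:
    """``T = sum(L_i)``; zero for a gene with no ESTs."""
    return float(np.asarray(L_gene, dtype=float).sum())


def intensity(L_gene: np.ndarray) -> float:
    """``I = sum(L_i**2) / sum(L_i)``, or 0 when the gene has no expression.

    At zero expression the ratio is undefined but tends to zero along any
    path of shrinking levels, hence the convention ``I = 0``.
    """
    L = np.asarray(L_gene, dtype=float)
    T = L.sum()
    if T == 0:
        return 0.0
    p = L / T  # normalized profile: stable even for tiny levels
    return float(T * (p**2).sum())


def evenness(L_gene: np.ndarray) -> float:
    """``E = T / I = sum(L_i)**2 / sum(L_i**2)``; NaN when ``T = 0``.

    E is the inverse Simpson diversity of the normalized profile and lies in
    ``[1, n_libraries]`` whenever defined.
    """
    L = np.asarray(L_gene, dtype=float)
    T = L.sum()
    if T == 0:
        return float("nan")
    p = L / T
    return float(1.0 / (p**2).sum())


def summarize_expression(
    matrix: ExpressionMatrix, cap: float = DEFAULT_CAP
) -> pd.DataFrame:
    """Compute per-gene ``T``, ``I``, ``E`` after proportion-taking and capping.

    Returns a DataFrame indexed by gene id with columns ``T``, ``I``, ``E``
    (NaN where undefined) and the boolean ``truncated`` flag, genes in input
    order.
    """
    L = library_proportions(matrix)
    Lc, flags = truncate_outliers(L, cap=cap)
    vals = Lc.to_numpy()
    T = vals.sum(axis=1)
    safe_T = np.where(T > 0, T, 1.0)
    psq = ((vals / safe_T[:, None]) ** 2).sum(axis=1)  # Simpson index of profile
    I = np.where(T > 0, T * psq, 0.0)
    E = np.where(T > 0, 1.0 / np.where(psq > 0, psq, 1.0), np.nan)
    return pd.DataFrame(
        {"T": T, "I": I, "E": E, "truncated": flags.to_numpy()},
        index=matrix.gene_ids,
    )


def write_summaries(summaries: pd.DataFrame, path: str | Path) -> None:
    """Write T/I/E summaries as TSV with missing E encoded as ``NA``."""
    summaries.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")


def read_summaries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id", na_values=["NA"])
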