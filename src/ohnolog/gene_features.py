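"""Molecular-evolution and gene-structure covariates, and the feature table.

The retention analysis regresses a binary outcome — did both ohnologs of a
whole-genome-duplication pair persist in the tetraploid (1, a "triad") or
was one lost (0, a "dyad") — on ten covariates measured in the diploid
relative:

==================  =====================================================
``T``, ``I``, ``E``  expression summaries (see :mod:`ohnolog.expression`)
``dN``, ``dS``       nonsynonymous / synonymous substitutions per site on
                     the diploid lineage (consumed as inputs)
``dnds_adj``         dN / (dS + 0.02), finite even when dS = 0
``n_exons``          exon count
``protein_length``   protein length, amino acids
``intron_length``    total intron length, nucleotides
``aa_diversity``     Shannon entropy of amino-acid composition, nats
==================  =====================================================

Any covariate may be missing for a given gene (no ESTs, no outgroup
alignment); missingness is encoded as NaN and resolved downstream by
grand-mean imputation, never here.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VARIABLES",
    "adjusted_dnds",
    "aa_shannon_diversity",
    "assemble_features",
]

#: The ten regression covariates, in report order.
VARIABLES = [
    "T",
    "I",
    "E",
    "dN",
    "dS",
    "dnds_adj",
    "n_exons",
    "protein_length",
    "intron_length",
    "aa_diversity",
]

DEFAULT_EPSILON = 0.02

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


def adjusted_dnds(dN, dS, epsilon: float = DEFAULT_EPSILON):
    """Adjusted rate ratio ``dN / (dS + epsilon)``.

    The small positive ``epsilon`` (default 0.02) keeps the ratio defined
    for genes whose synonymous divergence is zero; it is applied uniformly
    to every gene so the statistic remains a single consistent proxy for
    selective constraint.  Accepts scalars or arrays; NaN propagates.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    dN = np.asarray(dN, dtype=float)
    dS = np.asarray(dS, dtype=float)
    if np.nanmin(dN, initial=0.0) < 0 or np.nanmin(dS, initial=0.0) < 0:
        raise ValueError("substitution rates must be non-negative")
    out = dN / (dS + epsilon)
    if out.ndim == 0:
        return float(out)
    return out


def aa_shannon_diversity(protein: str) -> float:
    """Shannon entropy (nats) of a protein's amino-acid composition.

    ``H = -sum_a f_a ln f_a`` over the frequencies of the 20 canonical
    residues; ambiguity codes, stops and gaps are dropped before counting.
    Ranges from 0 (homopolymer) to ln 20 (uniform composition).  Returns
    NaN when nothing remains after filtering.
    """
    counts = Counter(c for c in protein.upper() if c in AA_ALPHABET)
    n = sum(counts.values())
    if n == 0:
        return float("nan")
    return -sum((k / n) * math.log(k / n) for k in counts.values())


def assemble_features(
    expression_summaries: pd.DataFrame,
    evolution: pd.DataFrame,
    structure: pd.DataFrame,
    outcomes: pd.Series,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Join the three per-gene data sources into the 10-variable table.

    Parameters
    ----------
    expression_summaries : DataFrame indexed by gene id with T, I, E.
    evolution : DataFrame indexed by gene id with dN, dS (``dnds_adj`` is
        derived here, never read).
    structure : DataFrame indexed by gene id with n_exons, protein_length,
        intron_length and either ``aa_diversity`` or a ``protein`` sequence
        column from which it is computed.
    outcomes : Series indexed by gene id; 1 = both ohnologs persist, 0 =
        singleton.  Defines the row universe: every gene with an outcome is
        kept, and covariates absent from a source become NaN.

    Returns a DataFrame with columns ``outcome`` + :data:`VARIABLES`.
    """
    for name, frame in (
        ("expression", expression_summaries),
        ("evolution", evolution),
        ("structure", structure),
    ):
        if frame.index.duplicated().any():
            raise ValueError(f"duplicate gene id in {name} table")
    if outcomes.index.duplicated().any():
        raise ValueError("duplicate gene id in outcomes")

    idx = outcomes.index
    out = pd.DataFrame(index=idx)
    out["outcome"] = outcomes.astype(int)

    expr = expression_summaries.reindex(idx)
    for col in ("T", "I", "E"):
        out[col] = expr[col] if col in expr else np.nan

    evol = evolution.reindex(idx)
    out["dN"] = evol["dN"] if "dN" in evol else np.nan
    out["dS"] = evol["dS"] if "dS" in evol else np.nan
    out["dnds_adj"] = adjusted_dnds(out["dN"].to_numpy(), out["dS"].to_numpy(), epsilon)

    struct = structure.reindex(idx)
    for col in ("n_exons", "protein_length", "intron_length"):
        out[col] = struct[col] if col in struct else np.nan
    if "aa_diversity" in struct:
        out["aa_diversity"] = struct["aa_diversity"]
    elif "protein" in struct:
        out["aa_diversity"] = [
            aa_shannon_diversity(p) if isinstance(p, str) else np.nan
            for p in struct["protein"]
        ]
    else:
        out["aa_diversity"] = np.nan

    all_missing = out[VARIABLES].isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} gene(s) have an outcome but no observed "
            "covariates; retained with all values missing",
            stacklevel=2,
        )
    return out


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id", na_values=["NA"])
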