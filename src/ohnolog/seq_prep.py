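"""Sequence preprocessing: longest-ORF calling and alignment-length filtering.

EST-derived consensus sequences have unknown strand and often lack their 5'
end, so the coding region is predicted as the longest open reading frame over
all six frames, where an ORF is a maximal stop-free run of codons (a start
codon is not required by default, but can be).  Pairwise/triple alignments
feeding dN/dS estimation are filtered to an ungapped overlap of at least 201
nucleotides, and indel-containing columns can be masked out.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "OrfCall",
    "longest_orf",
    "orf_table",
    "filter_alignment_length",
    "gap_free_column_mask",
    "mask_indel_columns",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

DEFAULT_MIN_OVERLAP = 201


@dataclass(frozen=True)
class OrfCall:
    """A called open reading frame, in input-strand coordinates.

    ``start``/``end`` are 0-based half-open on the sequence as given, even
    for minus-strand calls; ``frame`` is the frame offset on the scanned
    strand (the reverse complement for strand ``-``); ``length_nt`` is a
    multiple of 3 (trailing partial codons are never included).
    """

    sequence_id: str
    start: int
    end: int
    strand: str
    frame: int
    length_nt: int

    def __post_init__(self) -> None:
        assert self.end - self.start == self.length_nt
        assert self.length_nt >= 3 and self.length_nt % 3 == 0


def _frame_runs(seq: str, frame: int, require_start: bool) -> Iterable[tuple[int, int]]:
    """Yield (start, end) of maximal stop-free codon runs in one frame.

    Coordinates are on `seq`. Codons containing N (or any non-ACGT symbol)
    never match a stop or start pattern.
    """
    n = len(seq)
    run_start = None
    pos = frame
    while pos + 3 <= n:
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            if run_start is not None:
                yield run_start, pos
                run_start = None
        elif run_start is None:
            if not require_start or codon == START_CODON:
                run_start = pos
        pos += 3
    if run_start is not None and pos > run_start:
        yield run_start, pos


def longest_orf(
    seq: str, sequence_id: str = "", require_start: bool = False
) -> OrfCall | None:
    """Longest ORF over all three frames on both strands.

    An ORF is a maximal run of codons containing no stop codon; with
    ``require_start=True`` the run instead begins at the first ATG after a
    stop.  Ties break deterministically: plus strand before minus, then
    smaller start coordinate, then lower frame.  Returns None if no ORF of
    at least one codon exists.
    """
    seq = str(seq).upper().replace("U", "T")
    if len(seq) < 3:
        return None
    rc = str(Seq(seq).reverse_complement())
    best: OrfCall | None = None
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            for run_start, run_end in _frame_runs(s, frame, require_start):
                length = run_end - run_start
                if length < 3:
                    continue
                if strand == "+":
                    start, end = run_start, run_end
                else:
                    start, end = len(seq) - run_end, len(seq) - run_start
                cand = OrfCall(sequence_id, start, end, strand, frame, length)
                if best is None or _orf_better(cand, best):
                    best = cand
    return best


def _orf_better(a: OrfCall, b: OrfCall) -> bool:
    key = lambda o: (-o.length_nt, o.strand != "+", o.start, o.frame)
    return key(a) < key(b)


def orf_table(
    fasta_path: str | Path, require_start: bool = False
) -> pd.DataFrame:
    """Call the longest ORF for every record of a FASTA file.

    Records with no callable ORF get NA coordinates.
    """
    rows = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        call = longest_orf(str(rec.seq), rec.id, require_start=require_start)
        if call is None:
            rows.append(
                {"sequence_id": rec.id, "start": pd.NA, "end": pd.NA,
                 "strand": pd.NA, "frame": pd.NA, "length_nt": pd.NA}
            )
        else:
            rows.append(
                {"sequence_id": call.sequence_id, "start": call.start,
                 "end": call.end, "strand": call.strand, "frame": call.frame,
                 "length_nt": call.length_nt}
            )
    return pd.DataFrame(rows)


def filter_alignment_length(
    alignments: pd.DataFrame | Sequence, min_overlap_nt: int = DEFAULT_MIN_OVERLAP
) -> pd.DataFrame:
    """Keep alignments whose ungapped overlap is at least ``min_overlap_nt``.

    ``alignments`` is a DataFrame (or records coercible to one) with a
    numeric ``overlap_nt`` column.  "Shorter than the threshold" is read
    strictly, so an overlap exactly at the threshold is retained.
    """
    df = pd.DataFrame(alignments)
    if len(df) == 0:
        return df
    if "overlap_nt" not in df.columns:
        raise ValueError("alignments need an 'overlap_nt' column")
    if (df["overlap_nt"] < 0).any():
        raise ValueError("negative overlap length")
    return df[df["overlap_nt"] >= min_overlap_nt].reset_index(drop=True)


def gap_free_column_mask(rows: Sequence[str]) -> np.ndarray:
    """Boolean mask of alignment columns containing no gap in any sequence."""
    if not rows:
        return np.zeros(0, dtype=bool)
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    arr = np.array([list(r) for r in rows])
    return ~np.isin(arr, ["-", "."]).any(axis=0)


def mask_indel_columns(rows: Sequence[str], codon_truncate: bool = True) -> list[str]:
    """Remove gap-containing columns; optionally trim to a codon multiple.

    Trimming drops trailing columns so the masked length is a multiple of 3,
    keeping the result usable for codon-based rate estimation.
    """
    mask = gap_free_column_mask(rows)
    kept = [np.array(list(r))[mask] for r in rows]
    n = mask.sum()
    if codon_truncate:
        n -= n % 3
    return ["".join(k[: int(n)]) for k in kept]
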