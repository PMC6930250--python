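"""Raw reads -> filtered, normalized count matrix of unique sequences.

The processing chain mirrors standard small-RNA-seq practice: 3' adapter
removal, size selection to the 15-27 nt window, collapsing to unique
sequences with per-library occurrence counts, removal of low-abundance
sequences, and depth normalization by DESeq-style median-of-ratios size
factors.  Reads containing ambiguous bases are discarded at read-in with a
logged count; adapter matching is exact (no mismatches), consistent with an
analysis that retains only perfectly aligning sequences.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

MIN_LEN = 15
MAX_LEN = 27


def trim_adapter(read: str, adapter: str, min_overlap: int = 6) -> str:
    """Strip the 3' adapter from a read.

    Returns the prefix preceding the leftmost position where a prefix of
    ``adapter`` of length >= ``min_overlap`` matches the read through its
    end (or the full adapter matches internally); the read is returned
    unchanged when no such occurrence exists.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    n, m = len(read), len(adapter)
    for i in range(n - min_overlap + 1):
        k = min(m, n - i)
        if read[i:i + k] == adapter[:k]:
            return read[:i]
    return read


def size_select(seqs: list[str], min_len: int = MIN_LEN,
                max_len: int = MAX_LEN) -> list[str]:
    """Retain sequences with min_len <= length <= max_len (inclusive)."""
    if min_len <= 0 or min_len > max_len:
        raise ValueError("require 0 < min_len <= max_len")
    return [s for s in seqs if min_len <= len(s) <= max_len]


def read_library(path: str | Path, fmt: str | None = None) -> list[str]:
    """Load reads from FASTQ/FASTA, dropping any containing non-ACGT bases."""
    path = Path(path)
    if fmt is None:
        fmt = "fasta" if path.suffix.lower() in (".fa", ".fasta") else "fastq"
    seqs, dropped = [], 0
    valid = set("ACGT")
    for rec in SeqIO.parse(str(path), fmt):
        s = str(rec.seq).upper()
        if set(s) <= valid:
            seqs.append(s)
        else:
            dropped += 1
    if dropped:
        log.warning("%s: dropped %d reads with ambiguous bases", path.name, dropped)
    return seqs


@dataclass
class CountMatrix:
    """Unique sequences x libraries, with optional size factors.

    ``raw`` is indexed by sequence with one column per library.  Size
    factors are positive per-library scalars; ``normalized`` divides each
    column by its factor (identity when all factors are 1).
    """

    raw: pd.DataFrame
    size_factors: pd.Series | None = None

    @property
    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("size factors not computed; call normalize()")
        return self.raw.div(self.size_factors, axis=1)


def collapse(libraries: dict[str, list[str]]) -> CountMatrix:
    """Count occurrences of each distinct sequence per library."""
    cols = {lib: Counter(seqs) for lib, seqs in libraries.items()}
    raw = pd.DataFrame(cols).fillna(0).astype(int)
    raw.index.name = "sequence"
    raw = raw[list(libraries)]  # preserve library order
    return CountMatrix(raw=raw.sort_index())


def filter_low_abundance(matrix: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Keep sequences whose total raw count across libraries is >= min_total."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = matrix.raw.sum(axis=1) >= min_total
    return CountMatrix(raw=matrix.raw.loc[keep], size_factors=matrix.size_factors)


def size_factors(raw: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq convention).

    For each library, the factor is the median over rows positive in every
    library of that row's count divided by its geometric mean across
    libraries.  If no row is positive everywhere, falls back to column-total
    scaling (each library's total over the geometric mean of totals) with a
    warning.
    """
    counts = raw.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if all_pos.any():
        sub = counts[all_pos]
        log_geo = np.log(sub).mean(axis=1)
        ratios = np.log(sub) - log_geo[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    else:
        log.warning("no sequence positive in all libraries; "
                    "falling back to column-total size factors")
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("a library has zero retained reads")
        factors = totals / np.exp(np.log(totals).mean())
    return pd.Series(factors, index=raw.columns, name="size_factor")


def normalize(matrix: CountMatrix) -> CountMatrix:
    """Attach median-of-ratios size factors to the matrix."""
    return CountMatrix(raw=matrix.raw, size_factors=size_factors(matrix.raw))


def preprocess_libraries(fastq_by_library: dict[str, str | Path], adapter: str,
                         min_overlap: int = 6, min_len: int = MIN_LEN,
                         max_len: int = MAX_LEN) -> CountMatrix:
    """trim -> size-select -> collapse, for a set of library files."""
    processed = {}
    for lib, path in fastq_by_library.items():
        reads = read_library(path)
        trimmed = [trim_adapter(r, adapter, min_overlap) for r in reads]
        processed[lib] = size_select(trimmed, min_len, max_len)
    return collapse(processed)
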