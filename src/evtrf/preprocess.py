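"""Adapter trimming, quality/size filtering, and read collapsing.

Small-RNA libraries sequence short inserts followed by the 3' sequencing
adapter.  Preprocessing trims the adapter, drops low-quality reads, size
selects 15-50 nt inserts (the gel size-selection window of the library
prep), and collapses identical reads cohort-wide into counted unique
fragment sequences ("fragment IDs") — the unit of all downstream analysis.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

PHRED_OFFSET = 33


@dataclass
class FragmentTable:
    """Unique fragment sequences x samples, raw counts.

    ``counts`` is an integer DataFrame indexed by fragment sequence with one
    column per sample; column sums equal the retained read count of each
    sample by construction.
    """

    counts: pd.DataFrame

    @property
    def fragments(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "fragment"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FragmentTable":
        counts = pd.read_csv(path, sep="\t", index_col="fragment")
        return cls(counts.astype(np.int64))


def trim_adapter(
    seq: str,
    adapter: str,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
) -> int:
    """Locate the 3' adapter and return the cut position (insert length).

    Searches every alignment of the adapter against the read: internal
    full-adapter matches and suffix-of-read/prefix-of-adapter overlaps of at
    least ``min_overlap`` nt, accepting matches with
    ``errors / overlap <= max_error_rate``.  The best match minimises the
    error rate, ties broken by longest overlap then leftmost position.
    Returns ``len(seq)`` when no acceptable match exists (read untrimmed);
    an empty adapter disables trimming (identity).
    """
    if not adapter:
        return len(seq)
    n, alen = len(seq), len(adapter)

    # Exact-match fast paths cover the overwhelming majority of real reads.
    pos = seq.find(adapter)
    if pos >= 0:
        return pos
    max_suffix = min(alen - 1, n)
    for ov in range(max_suffix, min_overlap - 1, -1):
        if seq.endswith(adapter[:ov]):
            return n - ov

    best: tuple[float, int, int] | None = None  # (error_rate, -overlap, start)
    for i in range(0, n - min_overlap + 1):
        ov = min(alen, n - i)
        if ov < min_overlap:
            continue
        window = seq[i : i + ov]
        errs = sum(a != b for a, b in zip(window, adapter))
        rate = errs / ov
        if rate <= max_error_rate:
            key = (rate, -ov, i)
            if best is None or key < best:
                best = key
    return best[2] if best is not None else n


def quality_filter(
    seq: str,
    qualities: Sequence[int] | str,
    min_mean_q: float = 20.0,
    max_n: int = 0,
) -> bool:
    """Return True if the read passes the mean-quality and N-content filter."""
    if isinstance(qualities, str):
        quals = np.frombuffer(qualities.encode(), dtype=np.uint8).astype(np.int32)
        quals = quals - PHRED_OFFSET
    else:
        quals = np.asarray(qualities, dtype=np.int32)
    if len(quals) != len(seq):
        raise ValueError(
            f"quality string length {len(quals)} != sequence length {len(seq)}"
        )
    if len(seq) == 0:
        return False
    if seq.count("N") > max_n:
        return False
    return float(quals.mean()) >= min_mean_q


def size_select(seq: str, min_len: int = 15, max_len: int = 50) -> bool:
    """Keep reads whose insert length lies in [min_len, max_len], inclusive —
    the 15-50 bp gel size-selection window."""
    return min_len <= len(seq) <= max_len


def preprocess_reads(
    reads: Iterable[tuple[str, str]],
    adapter: str = "",
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
    min_mean_q: float = 20.0,
    max_n: int = 0,
    min_len: int = 15,
    max_len: int = 50,
) -> list[str]:
    """Trim + filter an iterable of (sequence, quality-string) pairs.

    Returns the retained insert sequences in input order.
    """
    kept: list[str] = []
    for seq, qual in reads:
        cut = trim_adapter(seq, adapter, min_overlap, max_error_rate)
        insert, iqual = seq[:cut], qual[:cut]
        if not insert:
            continue
        if not quality_filter(insert, iqual, min_mean_q, max_n):
            continue
        if not size_select(insert, min_len, max_len):
            continue
        kept.append(insert)
    return kept


def read_fastq(path: str | Path) -> Iterable[tuple[str, str]]:
    """Yield (sequence, quality-string) pairs from a FASTQ file."""
    with open(path) as fh:
        for _title, seq, qual in FastqGeneralIterator(fh):
            yield seq.upper(), qual


def preprocess_fastq(path: str | Path, **kwargs) -> list[str]:
    """Run :func:`preprocess_reads` over a FASTQ file."""
    return preprocess_reads(read_fastq(path), **kwargs)


def collapse(reads_by_sample: Mapping[str, Iterable[str]]) -> FragmentTable:
    """Collapse identical reads into one cohort-wide fragment x sample table.

    Every distinct read sequence across all samples becomes one fragment ID;
    ``counts[f, s]`` is the multiplicity of fragment ``f`` among sample
    ``s``'s retained reads, so column sums conserve per-sample read counts.
    """
    if not reads_by_sample:
        raise ValueError("collapse requires at least one sample")
    counters = {s: Counter(reads) for s, reads in reads_by_sample.items()}
    counts = pd.DataFrame(counters).fillna(0).astype(np.int64)
    counts = counts.sort_index()
    counts = counts[list(reads_by_sample)]
    return FragmentTable(counts)


def length_histogram(table: FragmentTable, sample: str) -> pd.Series:
    """Read-count-weighted fragment-length histogram for one sample.

    The histogram is indexed over the full observed fragment-length range
    (zeros filled in) and sums to the sample's retained read count.  EV-like
    libraries peak at 30-34 nt (5'-tRNA halves); tissue libraries show a
    22 nt miRNA peak.
    """
    if sample not in table.counts.columns:
        raise KeyError(f"unknown sample {sample!r}")
    lengths = table.fragments.str.len()
    hist = table.counts[sample].groupby(lengths).sum()
    if len(hist) == 0:
        return pd.Series(dtype=np.int64)
    full = pd.RangeIndex(int(lengths.min()), int(lengths.max()) + 1)
    hist = hist.reindex(full, fill_value=0)
    hist.index.name = "length"
    return hist


def modal_length(table: FragmentTable, sample: str) -> int:
    """Most abundant insert length (by read count) in a sample."""
    hist = length_histogram(table, sample)
    if hist.sum() == 0:
        raise ValueError(f"sample {sample!r} has no retained reads")
    return int(hist.idxmax())
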