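"""Fragment-to-reference mapping, class assignment, tRF typing, coverage.

Fragments are mapped against the five reference databases on the forward
strand allowing up to 2 mismatches (substitutions only; indel variants are
handled by a separate post-hoc step).  Classes are probed in a fixed
priority order and the first class with any hit wins, so every mapped
fragment carries exactly one class.  tRNA hits are typed as 5', 3' or
internal fragments by their position on the reference, and read-weighted
coverage along the (relative) tRNA body summarises where fragments sit —
EV libraries are expected to pile up on the 5' half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import FragmentTable
from .refdb import RNA_CLASSES, ReferenceRecord, ReferenceSet

logger = logging.getLogger(__name__)

TRF_TYPES = ("five_prime", "three_prime", "internal")


@dataclass(frozen=True)
class Hit:
    """One alignment of a fragment to a reference window [start, start+len)."""

    ref_id: str
    start: int
    mismatches: int
    rna_class: str


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def match_hamming(
    fragment: str, reference: ReferenceRecord | str, max_mm: int = 2,
    ref_id: str = "?", rna_class: str = "tRNA",
) -> list[Hit]:
    """All forward-strand windows of ``reference`` within ``max_mm``
    substitutions of ``fragment``.

    Returns an empty list when the fragment is longer than the reference or
    no window qualifies.
    """
    if isinstance(reference, ReferenceRecord):
        ref_seq, ref_id, rna_class = reference.sequence, reference.ref_id, reference.rna_class
    else:
        ref_seq = reference
    m, n = len(fragment), len(ref_seq)
    if m == 0:
        raise ValueError("empty fragment")
    if m > n:
        return []
    frag = _encode(fragment)
    ref = _encode(ref_seq)
    windows = np.lib.stride_tricks.sliding_window_view(ref, m)
    mism = (windows != frag).sum(axis=1)
    starts = np.nonzero(mism <= max_mm)[0]
    return [Hit(ref_id, int(s), int(mism[s]), rna_class) for s in starts]


def classify_trf(
    start: int, fragment_len: int, ref_len: int, end_tol: int = 3
) -> str:
    """Type a tRNA hit as five_prime / three_prime / internal.

    A fragment beginning within ``end_tol`` nt of the tRNA 5' end is a
    5'-tRF; one ending within ``end_tol`` nt of the 3' end (and not already
    5') is a 3'-tRF; anything else is internal.
    """
    if start <= end_tol:
        return "five_prime"
    if ref_len - (start + fragment_len) <= end_tol:
        return "three_prime"
    return "internal"


def _best_hits_for_class(
    fragments: Sequence[str], refset: ReferenceSet, max_mm: int
) -> dict[str, list[Hit]]:
    """Minimal-mismatch hits per fragment within one class (vectorised by
    fragment length across each reference)."""
    by_len: dict[int, list[int]] = {}
    for i, f in enumerate(fragments):
        by_len.setdefault(len(f), []).append(i)

    all_hits: dict[str, list[Hit]] = {f: [] for f in fragments}
    for rec in refset:
        ref = _encode(rec.sequence)
        n = len(ref)
        for m, idxs in by_len.items():
            if m > n or m == 0:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ref, m)
            frag_arr = np.vstack([_encode(fragments[i]) for i in idxs])
            mism = (frag_arr[:, None, :] != windows[None, :, :]).sum(axis=2)
            rows, starts = np.nonzero(mism <= max_mm)
            for r, s in zip(rows, starts):
                f = fragments[idxs[r]]
                all_hits[f].append(
                    Hit(rec.ref_id, int(s), int(mism[r, s]), rec.rna_class)
                )

    best: dict[str, list[Hit]] = {}
    for f, hits in all_hits.items():
        if not hits:
            continue
        mmin = min(h.mismatches for h in hits)
        best[f] = sorted(
            (h for h in hits if h.mismatches == mmin),
            key=lambda h: (h.ref_id, h.start),
        )
    return best


def _fragment_trf_type(hits: list[Hit], fragment_len: int,
                       ref_lengths: Mapping[str, int], end_tol: int) -> str:
    """Fragment-level tRF type from its best hits: 5' wins over 3' over
    internal when multi-hit types disagree."""
    types = {
        classify_trf(h.start, fragment_len, ref_lengths[h.ref_id], end_tol)
        for h in hits
    }
    for t in TRF_TYPES:
        if t in types:
            return t
    raise AssertionError("unreachable")


def assign_classes(
    fragments: Iterable[str],
    databases: Mapping[str, ReferenceSet],
    priority: Sequence[str] = RNA_CLASSES,
    max_mm: int = 2,
    end_tol: int = 3,
) -> pd.DataFrame:
    """Assign one RNA class per fragment by priority-ordered database search.

    Classes are probed in ``priority`` order; the first class producing at
    least one hit claims the fragment, and only minimal-mismatch hits within
    that class are kept (ties all retained).  Fragments hitting nothing are
    labelled ``unmapped``.  Returns a DataFrame indexed by fragment with
    columns ``rna_class``, ``ref_ids`` (comma-joined best hits), ``start``
    and ``mismatches`` (of the first best hit), and ``trf_type`` (tRNA
    fragments only, empty otherwise).
    """
    fragments = list(dict.fromkeys(fragments))
    unknown = [c for c in priority if c not in databases]
    if unknown:
        raise KeyError(f"priority classes missing from databases: {unknown}")

    ref_lengths = {
        rec.ref_id: len(rec.sequence)
        for refset in databases.values()
        for rec in refset
    }

    rows: dict[str, dict] = {}
    remaining = fragments
    for rna_class in priority:
        if not remaining:
            break
        best = _best_hits_for_class(remaining, databases[rna_class], max_mm)
        for f, hits in best.items():
            trf_type = ""
            if rna_class == "tRNA":
                trf_type = _fragment_trf_type(hits, len(f), ref_lengths, end_tol)
            rows[f] = {
                "rna_class": rna_class,
                "ref_ids": ",".join(h.ref_id for h in hits),
                "start": hits[0].start,
                "mismatches": hits[0].mismatches,
                "trf_type": trf_type,
                "n_hits": len(hits),
                "hits": hits,
            }
        remaining = [f for f in remaining if f not in best]
    for f in remaining:
        rows[f] = {
            "rna_class": "unmapped",
            "ref_ids": "",
            "start": -1,
            "mismatches": -1,
            "trf_type": "",
            "n_hits": 0,
            "hits": [],
        }
    out = pd.DataFrame.from_dict(rows, orient="index").loc[fragments]
    out.index.name = "fragment"
    return out


def coverage_profile(
    assignment: pd.DataFrame,
    counts: pd.Series,
    ref_lengths: Mapping[str, int],
    mode: str = "max",
) -> np.ndarray:
    """Read-weighted coverage of tRNA-mapped fragments over 100 relative-
    position bins of the tRNA body.

    Each tRNA-mapped fragment adds its read count (split 1/n_hits across
    multi-hits) to the bins its reference interval covers after rescaling
    [start, start+len) to relative position [0, 100).  ``mode='max'`` scales
    so the deepest bin reads 100% (per-base coverage relative to the peak);
    ``mode='reads'`` reports the percentage of tRNA-mapped read weight
    covering each bin.  Returns a length-100 array of percentages; all-zero
    (with a warning) when no tRNA-mapped reads exist.
    """
    if mode not in ("max", "reads"):
        raise ValueError(f"unknown coverage mode {mode!r}")
    depth = np.zeros(100)
    total_weight = 0.0
    trna = assignment[assignment["rna_class"] == "tRNA"]
    for frag, row in trna.iterrows():
        weight = float(counts.get(frag, 0))
        if weight <= 0:
            continue
        hits: list[Hit] = row["hits"]
        total_weight += weight
        w = weight / len(hits)
        flen = len(frag)
        for h in hits:
            ref_len = ref_lengths[h.ref_id]
            # the hit covers relative span [100*start/L, 100*end/L); add the
            # weight to every bin that span intersects
            b0 = int(np.floor(100 * h.start / ref_len))
            b1 = int(np.ceil(100 * (h.start + flen) / ref_len)) - 1
            depth[b0 : min(b1, 99) + 1] += w
    if total_weight == 0:
        logger.warning("no tRNA-mapped reads; coverage profile is empty")
        return depth
    if mode == "max":
        return 100.0 * depth / depth.max()
    return 100.0 * depth / total_weight


def class_read_fractions(
    assignment: pd.DataFrame, counts: pd.Series
) -> pd.Series:
    """Fraction of reads per RNA class (incl. 'unmapped'), read-weighted."""
    cls = assignment["rna_class"].reindex(counts.index).fillna("unmapped")
    totals = counts.groupby(cls).sum()
    return totals / totals.sum()


def write_annotation_tsv(assignment: pd.DataFrame, path) -> None:
    cols = ["rna_class", "ref_ids", "start", "mismatches", "trf_type", "n_hits"]
    assignment[cols].to_csv(path, sep="\t")
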