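"""Indel-tolerant re-annotation of fragments as 5'-tRF variants.

Abundant differentially expressed fragments frequently fail exact
(substitution-only) database mapping yet differ from a known 5'-tRF by only
1-2 nucleotide insertions or deletions.  This module scores fragments
against an index of exact tRNA 5' prefixes with a banded Levenshtein
distance capped at 2 and reports the best-matching source tRF, the edit
operations, and a status (exact / variant / unresolved).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .refdb import PrefixIndex

#: Sentinel returned when the true distance exceeds the band cap.
ABOVE_MAX = -1


def banded_edit_distance(
    a: str, b: str, max_d: int = 2, substitutions: bool = True
) -> int:
    """Levenshtein distance between ``a`` and ``b`` within a band of
    half-width ``max_d``; :data:`ABOVE_MAX` when the distance exceeds it.

    Unit costs throughout.  With ``substitutions=False`` a mismatch can only
    be resolved by a deletion plus an insertion (substitution cost
    effectively 2), matching a strictly indel-only reading of the variant
    rule.  A length difference beyond ``max_d`` short-circuits.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if max_d < 0:
        raise ValueError("max_d must be non-negative")
    n, m = len(a), len(b)
    if abs(n - m) > max_d:
        return ABOVE_MAX
    big = max_d + 1
    # prev[k] = edit distance for b-prefix j = i - max_d + k at row i.
    width = 2 * max_d + 1
    prev = np.full(width, big, dtype=np.int64)
    # Row 0: D[0][j] = j for j <= max_d.
    for k in range(width):
        j = k - max_d
        if 0 <= j <= m:
            prev[k] = j
    for i in range(1, n + 1):
        cur = np.full(width, big, dtype=np.int64)
        ca = a[i - 1]
        lo = max(0, i - max_d)
        hi = min(m, i + max_d)
        for j in range(lo, hi + 1):
            k = j - i + max_d
            if j == 0:
                cur[k] = i
                continue
            best = big
            # deletion from a (vertical): D[i-1][j] is prev at k+1
            if k + 1 < width:
                best = min(best, prev[k + 1] + 1)
            # insertion into a (horizontal): D[i][j-1] is cur at k-1
            if k - 1 >= 0:
                best = min(best, cur[k - 1] + 1)
            # diagonal
            diag = prev[k]
            if ca == b[j - 1]:
                best = min(best, diag)
            elif substitutions:
                best = min(best, diag + 1)
            cur[k] = min(best, big)
        prev = cur
    d = int(prev[m - n + max_d])
    return d if d <= max_d else ABOVE_MAX


def edit_operations(a: str, b: str, substitutions: bool = True) -> tuple[int, int, int]:
    """Operation breakdown (substitutions, insertions, deletions) of one
    minimal edit path from ``a`` to ``b`` (full DP with traceback; ties
    prefer matches/substitutions, then deletions).

    Insertions/deletions are counted relative to ``a``: an insertion adds a
    base to ``a``, a deletion removes one.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    n, m = len(a), len(b)
    sub_cost = 1 if substitutions else n + m + 1  # effectively forbidden
    D = np.zeros((n + 1, m + 1), dtype=np.int64)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = 0 if a[i - 1] == b[j - 1] else sub_cost
            D[i, j] = min(D[i - 1, j - 1] + cost, D[i - 1, j] + 1, D[i, j - 1] + 1)
    subs = ins = dels = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            cost = 0 if a[i - 1] == b[j - 1] else sub_cost
            if D[i, j] == D[i - 1, j - 1] + cost:
                if cost:
                    subs += 1
                i, j = i - 1, j - 1
                continue
        if i > 0 and D[i, j] == D[i - 1, j] + 1:
            dels += 1
            i -= 1
            continue
        ins += 1
        j -= 1
    return subs, ins, dels


@dataclass
class VariantAnnotation:
    """Resolution of one fragment against the 5'-tRF prefix index."""

    fragment: str
    status: str  # exact | variant | unresolved
    prefix: str | None = None
    sources: tuple[str, ...] = ()
    distance: int | None = None
    substitutions: int = 0
    insertions: int = 0
    deletions: int = 0


def annotate_variants(
    fragments: Iterable[str],
    index: PrefixIndex,
    max_d: int = 2,
    substitutions: bool = True,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Score fragments against all indexed 5'-tRF prefixes and report the
    minimal-distance match within ``max_d`` edits.

    Candidate prefixes are restricted to lengths within ``max_d`` of the
    fragment length (any further length difference already exceeds the cap;
    ``exhaustive=True`` disables the restriction for verification).  Ties at
    the minimal distance prefer the prefix with more source tRNAs, then the
    lexicographically smallest prefix.  Fragments with no prefix within
    ``max_d`` are ``unresolved``.
    """
    if len(index) == 0:
        raise ValueError("prefix index is empty")
    by_len: dict[int, list[str]] = {}
    for prefix in index.entries:
        by_len.setdefault(len(prefix), []).append(prefix)
    for prefixes in by_len.values():
        prefixes.sort()

    rows = []
    for frag in dict.fromkeys(fragments):
        flen = len(frag)
        if exhaustive:
            candidates: Iterable[str] = (
                p for plist in by_len.values() for p in plist
            )
        else:
            candidates = (
                p
                for length in range(flen - max_d, flen + max_d + 1)
                for p in by_len.get(length, [])
            )
        best: tuple[int, int, str] | None = None  # (d, -n_sources, prefix)
        for prefix in candidates:
            d = banded_edit_distance(frag, prefix, max_d, substitutions)
            if d == ABOVE_MAX:
                continue
            key = (d, -len(index.entries[prefix]), prefix)
            if best is None or key < best:
                best = key
                if d == 0:
                    break
        if best is None:
            ann = VariantAnnotation(frag, "unresolved")
        else:
            d, _, prefix = best
            subs, ins, dels = edit_operations(frag, prefix, substitutions)
            ann = VariantAnnotation(
                frag,
                "exact" if d == 0 else "variant",
                prefix,
                tuple(index.entries[prefix]),
                d,
                subs,
                ins,
                dels,
            )
        rows.append(
            {
                "fragment": ann.fragment,
                "status": ann.status,
                "prefix": ann.prefix or "",
                "sources": ",".join(ann.sources),
                "distance": ann.distance if ann.distance is not None else ABOVE_MAX,
                "substitutions": ann.substitutions,
                "insertions": ann.insertions,
                "deletions": ann.deletions,
            }
        )
    cols = ["fragment", "status", "prefix", "sources", "distance",
            "substitutions", "insertions", "deletions"]
    out = pd.DataFrame(rows, columns=cols).set_index("fragment")
    return out
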