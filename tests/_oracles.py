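"""Independent brute-force oracles used to verify the statistical and
mapping primitives.  These deliberately share no code with the package."""

from __future__ import annotations

import itertools

import numpy as np


def mw_u_stat(a, b) -> float:
    """U statistic of group a by direct pairwise comparison."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def mw_exact_p_two_sided(a, b) -> float:
    """Exact two-sided Mann-Whitney p by exhaustive enumeration of all
    C(n_a+n_b, n_a) group labelings of the pooled values (no ties)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    u_obs = mw_u_stat(a, b)
    us = []
    idx = set(range(n))
    for combo in itertools.combinations(range(n), na):
        rest = list(idx - set(combo))
        us.append(mw_u_stat(pooled[list(combo)], pooled[rest]))
    us = np.array(us)
    total = len(us)
    p_le = (us <= u_obs).sum() / total
    p_ge = (us >= u_obs).sum() / total
    return min(1.0, 2 * min(p_le, p_ge))


def wilcoxon_exact_p(diffs, alternative="greater") -> float:
    """Exact signed-rank p by enumeration of all 2^n sign patterns of the
    ranked absolute differences (no zeros, no tied magnitudes)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append((ranks * np.array(signs)).sum())
    ws = np.array(ws)
    if alternative == "greater":
        return float((ws >= w_obs).sum() / len(ws))
    if alternative == "less":
        return float((ws <= w_obs).sum() / len(ws))
    p = 2 * min((ws >= w_obs).mean(), (ws <= w_obs).mean())
    return float(min(1.0, p))


def bh_step_up(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} m p_(j) / j,
    capped at 1, mapped back to input order."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hamming_scan(fragment: str, reference: str, max_mm: int) -> list[tuple[int, int]]:
    """All (start, mismatches) windows by a direct position-by-position scan."""
    out = []
    m = len(fragment)
    for start in range(len(reference) - m + 1):
        mm = sum(x != y for x, y in zip(fragment, reference[start : start + m]))
        if mm <= max_mm:
            out.append((start, mm))
    return out


def levenshtein_full(a: str, b: str) -> int:
    """Full-matrix Levenshtein distance (unit costs)."""
    n, m = len(a), len(b)
    D = np.zeros((n + 1, m + 1), dtype=int)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            D[i, j] = min(D[i - 1, j - 1] + cost, D[i - 1, j] + 1, D[i, j - 1] + 1)
    return int(D[n, m])


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
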