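"""Class-wise RPM normalisation and nonparametric differential expression.

Raw fragment counts are normalised to reads per million *within each RNA
class* (the scaling factor of a fragment is the total reads of its class in
that sample), so class composition differences between compartments do not
distort within-class comparisons.  Differential expression between case
(preeclampsia) and control libraries then applies an abundance filter
(>100 RPM in at least one filter sample), a two-sided Mann-Whitney U test
per fragment, and Benjamini-Hochberg correction across the filtered set.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import FragmentTable

logger = logging.getLogger(__name__)

EXACT_LIMIT = 20  # largest n_a + n_b for which the exact null is used


def rpm_normalize(
    table: FragmentTable, classes: pd.Series | Mapping[str, str]
) -> pd.DataFrame:
    """Reads-per-million within RNA class:
    ``rpm[f, s] = 1e6 * count[f, s] / (total reads of class(f) in s)``.

    Unmapped fragments carry no RPM and are excluded from the result.  When
    a class has zero reads in a sample, its fragments' RPM is missing (NaN)
    for that sample, not zero.  For every sample and class with reads, the
    class RPM column sums to 1e6.
    """
    classes = pd.Series(classes)
    cls = classes.reindex(table.fragments).fillna("unmapped")
    mapped = cls[cls != "unmapped"]
    counts = table.counts.loc[mapped.index].astype(float)
    class_totals = counts.groupby(mapped).transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        rpm = 1e6 * counts / class_totals.where(class_totals > 0)
    return rpm


def abundance_filter(
    rpm: pd.DataFrame, samples: Sequence[str], threshold: float = 100.0
) -> pd.Index:
    """Fragments whose RPM strictly exceeds ``threshold`` in at least one of
    ``samples`` (the study applied >100 RPM over the MLEV samples)."""
    samples = list(samples)
    if not samples:
        raise ValueError("abundance_filter requires a non-empty sample subset")
    sub = rpm[samples]
    keep = (sub > threshold).any(axis=1)
    return rpm.index[keep]


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of group a, p).

    Uses the exact permutation null when the pooled size is at most
    :data:`EXACT_LIMIT` and there are no ties; otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    exact = a.size + b.size <= EXACT_LIMIT and not _has_ties(np.concatenate([a, b]))
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def _mann_whitney_many(
    A: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Mann-Whitney over matrices (fragments x samples per group),
    choosing the exact/asymptotic branch per row as in :func:`mann_whitney_u`."""
    pooled = np.concatenate([A, B], axis=1)
    sorted_pool = np.sort(pooled, axis=1)
    tied = (np.diff(sorted_pool, axis=1) == 0).any(axis=1)
    exact_ok = pooled.shape[1] <= EXACT_LIMIT

    U = np.empty(A.shape[0])
    p = np.empty(A.shape[0])
    rows_exact = np.nonzero(~tied)[0] if exact_ok else np.array([], dtype=int)
    rows_asym = np.nonzero(tied)[0] if exact_ok else np.arange(A.shape[0])
    if rows_exact.size:
        res = stats.mannwhitneyu(
            A[rows_exact], B[rows_exact], alternative="two-sided",
            method="exact", axis=1,
        )
        U[rows_exact] = res.statistic
        p[rows_exact] = res.pvalue
    if rows_asym.size:
        res = stats.mannwhitneyu(
            A[rows_asym], B[rows_asym], alternative="two-sided",
            method="asymptotic", axis=1,
        )
        U[rows_asym] = res.statistic
        p[rows_asym] = res.pvalue
    return U, p


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (W, p).

    Zero differences are dropped; the exact sign-pattern null is used for up
    to 15 retained pairs without tied absolute differences, the normal
    approximation (with correction) otherwise.  ``alternative`` follows
    scipy: 'two-sided', 'greater' (x > y), 'less'.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    exact = d.size <= 15 and not _has_ties(np.abs(d))
    res = stats.wilcoxon(
        d, alternative=alternative, method="exact" if exact else "approx",
        correction=True,
    )
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def differential_expression(
    rpm: pd.DataFrame,
    groups: pd.Series | Mapping[str, str],
    classes: pd.Series | Mapping[str, str] | None = None,
    case: str = "case",
    control: str = "control",
    filter_samples: Sequence[str] | None = None,
    threshold: float = 100.0,
    alpha: float = 0.05,
    eps: float = 1.0,
) -> pd.DataFrame:
    """The full differential-expression procedure on an RPM table.

    Fragments passing the abundance filter (>``threshold`` RPM in at least
    one of ``filter_samples``; default all samples) are tested case vs
    control with a two-sided Mann-Whitney U on their RPM, corrected by
    Benjamini-Hochberg across the filtered set.  Fold change uses group
    medians with pseudocount ``eps`` RPM.  Returns a DataFrame indexed by
    fragment with medians, ``fold_change``, ``U``, ``p``, ``q``,
    ``significant`` (q < ``alpha``) and, when ``classes`` is given,
    ``rna_class``.
    """
    groups = pd.Series(groups)
    case_samples = groups.index[groups == case].tolist()
    control_samples = groups.index[groups == control].tolist()
    if len(case_samples) < 2 or len(control_samples) < 2:
        raise ValueError("need at least 2 samples per group")
    if filter_samples is None:
        filter_samples = case_samples + control_samples
    kept = abundance_filter(rpm, list(filter_samples), threshold)
    cols = ["rna_class", "median_case", "median_control", "fold_change",
            "U", "p", "q", "significant"]
    if len(kept) == 0:
        logger.info("no fragment passed the %.0f RPM abundance filter", threshold)
        out = pd.DataFrame(columns=cols)
        out.index.name = "fragment"
        return out

    A = rpm.loc[kept, case_samples].to_numpy(float)
    B = rpm.loc[kept, control_samples].to_numpy(float)
    # Missing RPM (class absent from a sample) is treated as zero abundance
    # for testing: the class truly contributed no reads in that library.
    A = np.nan_to_num(A, nan=0.0)
    B = np.nan_to_num(B, nan=0.0)

    U, p = _mann_whitney_many(A, B)
    q = benjamini_hochberg(p)
    med_a = np.median(A, axis=1)
    med_b = np.median(B, axis=1)
    fc = (med_a + eps) / (med_b + eps)

    out = pd.DataFrame(
        {
            "median_case": med_a,
            "median_control": med_b,
            "fold_change": fc,
            "U": U,
            "p": p,
            "q": q,
            "significant": q < alpha,
        },
        index=kept,
    )
    if classes is not None:
        out.insert(0, "rna_class", pd.Series(classes).reindex(kept).fillna("unmapped"))
    else:
        out.insert(0, "rna_class", "")
    out.index.name = "fragment"
    return out


def cumulative_share(
    de: pd.DataFrame, rpm: pd.DataFrame, case_samples: Sequence[str], k: int
) -> float:
    """Share of summed case-group normalised counts captured by the top-k
    most abundant differentially expressed fragments.

    Fragments are ranked by their summed case-sample RPM among the
    significant DE set; the denominator is the same sum over all significant
    fragments (the study's "64% of the differentially expressed counts" for
    its top 12).
    """
    sig = de.index[de["significant"]] if "significant" in de else de.index
    if len(sig) == 0:
        raise ValueError("no differentially expressed fragments")
    if not 0 < k <= len(sig):
        raise ValueError(f"k must lie in [1, {len(sig)}]")
    sums = rpm.loc[sig, list(case_samples)].fillna(0.0).sum(axis=1)
    ranked = sums.sort_values(ascending=False)
    return float(ranked.iloc[:k].sum() / ranked.sum())
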