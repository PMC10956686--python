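"""qPCR validation-target selection and Pfaffl relative quantification.

Candidate 5'-tRFs for qPCR validation must be significant, upregulated,
abundant (above a percentile of case-group expression among all
differentially expressed fragments), and of low abundance in background
datasets standing in for contaminating blood-cell EV sources.  Measured Cq
values above 35 cycles are treated as undetectable.  Relative expression
follows the Pfaffl efficiency-corrected ratio

    ratio_s = E_t^(medCq_t,ctrl - Cq_t,s) / E_r^(medCq_r,ctrl - Cq_r,s)

normalised so that the control-group median is 1.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CQ_CUTOFF = 35.0


def censor_cq(cq, cutoff: float = CQ_CUTOFF):
    """Mark Cq values strictly above ``cutoff`` as undetectable (NaN).

    Accepts a scalar or array/Series; Cq exactly at the cutoff is retained.
    """
    arr = pd.Series(cq, dtype=float) if not np.isscalar(cq) else None
    if arr is None:
        return float("nan") if cq > cutoff else float(cq)
    out = arr.where(arr <= cutoff)
    return out.to_numpy() if isinstance(cq, (list, np.ndarray)) else out


def select_targets(
    de: pd.DataFrame,
    background_rpm: pd.DataFrame,
    percentile: float = 90.0,
    bg_threshold: float = 100.0,
) -> pd.DataFrame:
    """Pick qPCR validation candidates from a DE table.

    A fragment is selected iff it is significant, upregulated
    (fold_change > 1), its case-group median RPM reaches the
    ``percentile``-th percentile (linear interpolation) of case medians
    among all DE-significant fragments, and its maximum RPM across the
    background datasets does not exceed ``bg_threshold``.  Fragments absent
    from the background table count as background 0.
    """
    if len(de) == 0:
        raise ValueError("empty differential-expression table")
    sig = de[de["significant"]]
    if len(sig) == 0:
        out = de.iloc[0:0].copy()
        out["background_max"] = pd.Series(dtype=float)
        out["selected"] = pd.Series(dtype=bool)
        return out
    cutoff = float(np.percentile(sig["median_case"].to_numpy(float), percentile))
    bg_max = (
        background_rpm.reindex(sig.index).fillna(0.0).max(axis=1)
        if background_rpm.shape[1]
        else pd.Series(0.0, index=sig.index)
    )
    out = sig.copy()
    out["background_max"] = bg_max
    out["selected"] = (
        (out["fold_change"] > 1.0)
        & (out["median_case"] >= cutoff)
        & (out["background_max"] <= bg_threshold)
    )
    return out


def _sample_cq(records: pd.DataFrame, assay: str, cutoff: float) -> pd.Series:
    """Per-sample median retained Cq for one assay (replicate wells pooled)."""
    sub = records[records["assay"] == assay].copy()
    sub["Cq"] = censor_cq(sub["Cq"], cutoff)
    sub = sub.dropna(subset=["Cq"])
    return sub.groupby("sample_id")["Cq"].median()


def pfaffl_relative_expression(
    records: pd.DataFrame,
    target: str,
    reference: str,
    control_group: str = "control",
    cutoff: float = CQ_CUTOFF,
) -> pd.DataFrame:
    """Efficiency-corrected relative expression per sample.

    ``records`` needs columns sample_id, group, assay, Cq, efficiency.
    Undetectable wells (Cq > ``cutoff``) are excluded; a sample is dropped
    (with a log message) when either assay has no retained well.  The output
    ratio is rescaled so the control-group median equals 1.
    """
    required = {"sample_id", "group", "assay", "Cq", "efficiency"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"qPCR records missing columns {sorted(missing)}")

    eff = records.groupby("assay")["efficiency"].first()
    for assay in (target, reference):
        if assay not in eff.index:
            raise ValueError(f"assay {assay!r} absent from records")
        if not 1.0 < eff[assay] <= 2.0:
            raise ValueError(f"assay {assay!r} efficiency {eff[assay]} outside (1, 2]")

    cq_t = _sample_cq(records, target, cutoff)
    cq_r = _sample_cq(records, reference, cutoff)
    groups = records.drop_duplicates("sample_id").set_index("sample_id")["group"]

    samples = groups.index
    usable = [s for s in samples if s in cq_t.index and s in cq_r.index]
    dropped = [s for s in samples if s not in usable]
    if dropped:
        logger.info("dropping samples with undetectable wells: %s", dropped)

    ctrl = [s for s in usable if groups[s] == control_group]
    if not ctrl:
        raise ValueError("control group entirely undetectable")
    med_t = float(cq_t[ctrl].median())
    med_r = float(cq_r[ctrl].median())

    ratio = (eff[target] ** (med_t - cq_t[usable])) / (
        eff[reference] ** (med_r - cq_r[usable])
    )
    ratio = ratio / float(ratio[ctrl].median())
    out = pd.DataFrame(
        {"group": groups[usable], "relative_expression": ratio}
    )
    out.index.name = "sample_id"
    return out


def exclude_outliers(
    values: Sequence[float], centile: float = 85.0
) -> tuple[np.ndarray, np.ndarray]:
    """Flag values strictly above the group's ``centile``-th percentile
    (linear interpolation between order statistics).

    Returns (retained, excluded).  Requires at least 3 values.  Off by
    default in analyses; enabled explicitly where the suspected-outlier rule
    is wanted.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("outlier exclusion requires at least 3 values")
    cut = np.percentile(arr, centile)
    mask = arr > cut
    return arr[~mask], arr[mask]


def scramble_control(seq: str) -> str:
    """Scramble-control rule for synthetic RNA oligos: U -> A, all else kept.

    Input must be RNA (A/C/G/U); output has the same length and no U.
    """
    bad = set(seq.upper()) - set("ACGU")
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return seq.upper().replace("U", "A")
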