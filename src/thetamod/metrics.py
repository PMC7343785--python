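"""Per-subject derived indices: the within-video percent-change biomarker
and its specificity controls.

The primary index is the fractional change in frontal theta power between
the first and second halves of the *first* presentation of a video,
(P2 - P1)/P1 (the second presentation is contaminated by familiarity).
Controls: the same index for posterior theta (spatial specificity), for
upper alpha (band specificity), and for the count of clean attended
epochs (a behavioral proxy).

``mode`` selects whether P is the natural-log band power (default, the
literal reading of the extraction step) or the linear band power (uV^2).
Percent change is scale-invariant in linear mode only; across the log
transform the identity percent_change(k*a, k*b) = percent_change(a, b)
does not hold, which is why both modes are exposed and the recovery
checks run in both.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("thetamod")

__all__ = [
    "MetricUndefinedError",
    "percent_change",
    "within_video_change",
    "between_repetition_change",
    "attended_proportion_change",
    "baseline_power",
    "feature_table",
]


class MetricUndefinedError(ValueError):
    """Denominator invalid for the percent-change index."""


def percent_change(p1: float, p2: float, require_positive: bool = True) -> float:
    """(p2 - p1)/p1.

    ``require_positive`` enforces p1 > 0 (mandatory for ln-power inputs,
    where a non-positive baseline makes the index meaningless).
    """
    if p1 == 0:
        raise MetricUndefinedError("percent change undefined: baseline is zero")
    if require_positive and p1 < 0:
        raise MetricUndefinedError(f"percent change undefined: baseline {p1} < 0")
    return (p2 - p1) / p1


def _value_col(mode: str) -> str:
    if mode == "ln":
        return "ln_power"
    if mode == "linear":
        return "power"
    raise ValueError(f"mode must be 'ln' or 'linear', got '{mode}'")


def _qc_included(qc: pd.DataFrame, video_id: str, repetition: int) -> bool:
    sel = qc[(qc["video_id"] == video_id) & (qc["repetition"] == repetition)]
    return bool(len(sel)) and bool(sel["include"].all())


def within_video_change(
    frontal: pd.DataFrame,
    qc: pd.DataFrame,
    mode: str = "ln",
    presentation: int = 1,
) -> tuple[float, dict[str, float]]:
    """Half-1 -> half-2 percent change on the first presentation.

    Computed per condition, then collapsed as the unweighted mean of the
    conditions that pass QC — a subject with usable data in only one
    condition is still included (provenance retained in the returned
    per-condition dict).
    """
    col = _value_col(mode)
    per_condition: dict[str, float] = {}
    for cond, grp in frontal[frontal["repetition"] == presentation].groupby("condition"):
        video = grp["video_id"].iloc[0]
        if not _qc_included(qc, video, presentation):
            continue
        halves = grp.set_index("half")[col]
        if 1 not in halves.index or 2 not in halves.index:
            continue
        per_condition[cond] = percent_change(float(halves[1]), float(halves[2]))
    if not per_condition:
        raise MetricUndefinedError("no condition passed QC for the within-video index")
    return float(np.mean(list(per_condition.values()))), per_condition


def between_repetition_change(
    frontal: pd.DataFrame,
    qc: pd.DataFrame,
    condition: str,
    mode: str = "ln",
) -> float:
    """Whole-presentation-1 -> whole-presentation-2 percent change.

    Presentation power is the epoch-weighted mean of its two halves'
    linear power (logged afterwards in ln mode), i.e. the mean over all
    usable epochs of the presentation.
    """
    sub = frontal[frontal["condition"] == condition]
    values = {}
    for rep, grp in sub.groupby("repetition"):
        video = grp["video_id"].iloc[0]
        if not _qc_included(qc, video, int(rep)):
            continue
        w = grp["n_epochs"].to_numpy(float)
        lin = float(np.average(grp["power"].to_numpy(float), weights=w))
        values[int(rep)] = np.log(lin) if mode == "ln" else lin
    if 1 not in values or 2 not in values:
        raise MetricUndefinedError(
            f"condition '{condition}': a presentation is missing or failed QC"
        )
    return percent_change(values[1], values[2])


def attended_proportion_change(qc: pd.DataFrame) -> float:
    """Percent change in clean attended epoch counts, half 1 -> half 2.

    Uses the first presentation of each condition and collapses like the
    theta index (unweighted mean over conditions with a nonzero half-1
    count).
    """
    per_condition = []
    for _, grp in qc[qc["repetition"] == 1].groupby("condition"):
        halves = grp.set_index("half")["n_clean_attended"]
        if 1 not in halves.index or 2 not in halves.index or halves[1] == 0:
            continue
        per_condition.append(percent_change(float(halves[1]), float(halves[2])))
    if not per_condition:
        raise MetricUndefinedError("no condition has a nonzero half-1 attended count")
    return float(np.mean(per_condition))


def baseline_power(frontal: pd.DataFrame, condition: str, mode: str = "ln") -> float:
    """Total frontal theta during the first half of the first video of a
    condition — the covariate partialled out of the repetition analyses."""
    col = _value_col(mode)
    sel = frontal[
        (frontal["condition"] == condition)
        & (frontal["repetition"] == 1)
        & (frontal["half"] == 1)
    ]
    if not len(sel):
        raise MetricUndefinedError(f"no baseline row for condition '{condition}'")
    return float(sel[col].iloc[0])


def feature_table(
    subject_results: list[dict],
) -> pd.DataFrame:
    """Assemble per-subject feature dicts into the analysis table.

    Each entry comes from ``pipeline.subject_features``; subjects whose
    primary index is undefined carry an ``exclusion_reason`` instead and
    are logged, giving a table with at most one row per cohort member.
    """
    rows = [r for r in subject_results if "exclusion_reason" not in r]
    for r in subject_results:
        if "exclusion_reason" in r:
            logger.warning("subject %s excluded: %s", r.get("subject_id"),
                           r["exclusion_reason"])
    return pd.DataFrame(rows)
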