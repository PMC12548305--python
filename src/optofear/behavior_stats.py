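"""Freezing-table statistics for the fear-renewal and contextual designs.

Planned, uncorrected unpaired t-tests at the stimulation timepoints are the
primary comparison (pooled-variance Student t, df = n1 + n2 - 2); the two
control groups (GFP virus, and ChR2 without laser) are pooled only after
verifying that they do not differ at any shared stage. Per-animal extinction
progress is tracked as the mean freezing over the first four CS
presentations of each daily session, with a strict below-60% criterion and a
seven-day cutoff.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import InvalidParameterError

log = logging.getLogger("optofear")

CONTROL_GROUPS = ("control_GFP", "control_nolaser")
POOLED_CONTROL = "pooled_control"


@dataclass(frozen=True)
class StageComparison:
    """One unpaired two-sample comparison at a stage."""

    stage: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t: float
    df: int
    p: float
    p_corrected: float | None = None


@dataclass(frozen=True)
class ExtinctionRecord:
    """Per-animal daily extinction progress (mean freezing over CS 1-4)."""

    animal_id: str
    day_means: tuple
    days_to_criterion: int | None = None
    included: bool = False


def t_to_p(t: float, df: float) -> float:
    """Two-sided p of a t statistic under the central Student t."""
    if df < 1:
        raise InvalidParameterError("df must be >= 1")
    return float(2.0 * stats.t.sf(abs(t), df))


def planned_ttest(values_a, values_b, stage: str = "") -> StageComparison:
    """Pooled-variance (Student) unpaired t-test, df = n1 + n2 - 2."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidParameterError("non-finite values in input")
    df = a.size + b.size - 2
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled_var == 0.0:
        if diff == 0.0:
            t = 0.0
            p = 1.0
        else:
            raise InvalidParameterError(
                "zero pooled variance with unequal means: degenerate input"
            )
    else:
        t = diff / np.sqrt(pooled_var * (1.0 / a.size + 1.0 / b.size))
        p = t_to_p(t, df)
    return StageComparison(
        stage=stage,
        n_a=a.size,
        n_b=b.size,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(stats.sem(a)),
        sem_b=float(stats.sem(b)),
        t=float(t),
        df=df,
        p=float(p),
    )


def stage_means(table: pd.DataFrame, stage_def: dict) -> pd.DataFrame:
    """Per-animal arithmetic means over epoch sets.

    ``stage_def`` maps an output stage label to the raw epoch labels it
    averages (e.g. ``{"CS_1_4": ["CS1", "CS2", "CS3", "CS4"]}``). Animals
    missing any epoch of a stage are excluded from that stage with a
    warning. Returns a (animal_id, group, stage, percent_freezing) frame.
    """
    vocab = set(table["stage"])
    rows = []
    for label, epochs in stage_def.items():
        epochs = list(epochs)
        unknown = set(epochs) - vocab
        if unknown:
            raise InvalidParameterError(
                f"unknown epochs {sorted(unknown)}; table vocabulary: {sorted(vocab)}"
            )
        sub = table[table["stage"].isin(epochs)]
        for (animal, group), g in sub.groupby(["animal_id", "group"], sort=True):
            if set(g["stage"]) != set(epochs):
                log.warning(
                    "animal %s missing epochs %s; excluded from stage %s",
                    animal, sorted(set(epochs) - set(g["stage"])), label,
                )
                continue
            rows.append(
                {
                    "animal_id": animal,
                    "group": group,
                    "stage": label,
                    "percent_freezing": float(g["percent_freezing"].mean()),
                }
            )
    return pd.DataFrame(rows, columns=["animal_id", "group", "stage", "percent_freezing"])


def extinction_filter(records, threshold_pct: float = 60.0, max_days: int = 7):
    """Apply the extinction criterion to per-animal daily CS 1-4 means.

    The criterion day is the first day whose mean is strictly below
    ``threshold_pct``; an animal is included iff that day is at most
    ``max_days``. Accepts ExtinctionRecords or a mapping
    ``{animal_id: day-mean sequence}``.
    """
    if isinstance(records, dict):
        records = [
            ExtinctionRecord(animal_id=k, day_means=tuple(v)) for k, v in records.items()
        ]
    records = list(records)
    if not records:
        raise InvalidParameterError("no extinction records supplied")
    out = []
    for rec in records:
        means = np.asarray(rec.day_means, dtype=float)
        if means.size == 0:
            raise InvalidParameterError(f"animal {rec.animal_id}: no extinction days")
        below = np.nonzero(means < threshold_pct)[0]
        day = int(below[0]) + 1 if below.size else None
        included = day is not None and day <= max_days
        out.append(
            ExtinctionRecord(
                animal_id=rec.animal_id,
                day_means=tuple(means),
                days_to_criterion=day,
                included=included,
            )
        )
    return out


def _stage_values(table: pd.DataFrame, group: str, stage: str) -> np.ndarray:
    sel = (table["group"] == group) & (table["stage"] == stage)
    return table.loc[sel, "percent_freezing"].to_numpy(dtype=float)


def pool_controls_check(table: pd.DataFrame, alpha: float = 0.05):
    """Compare the two control groups stage by stage; pool them if justified.

    Runs a planned t-test between control_GFP and control_nolaser at every
    stage both share. If no stage differs (min p > alpha) the returned table
    has both groups relabelled ``pooled_control``; otherwise the original
    table is returned alongside the per-stage report.
    """
    present = set(table["group"])
    missing = [g for g in CONTROL_GROUPS if g not in present]
    if missing:
        raise InvalidParameterError(f"control group(s) absent: {missing}")
    stages = [
        s
        for s in table["stage"].unique()
        if all(_stage_values(table, g, s).size >= 2 for g in CONTROL_GROUPS)
    ]
    if not stages:
        raise InvalidParameterError("no stage shared by both control groups")
    comparisons = [
        planned_ttest(
            _stage_values(table, CONTROL_GROUPS[0], s),
            _stage_values(table, CONTROL_GROUPS[1], s),
            stage=s,
        )
        for s in stages
    ]
    pooled = all(c.p > alpha for c in comparisons)
    out = table.copy()
    if pooled:
        out.loc[out["group"].isin(CONTROL_GROUPS), "group"] = POOLED_CONTROL
    else:
        log.warning(
            "control groups differ at %s; not pooled",
            [c.stage for c in comparisons if c.p <= alpha],
        )
    return comparisons, out, pooled


def timecourse_compare(
    table: pd.DataFrame,
    stages,
    correction: str = "none",
    group_a: str = "ChR2",
    group_b: str = POOLED_CONTROL,
):
    """Unpaired t-test at each stage between two groups.

    No multiple-comparison correction by default (the planned-comparison
    convention of the source analysis); ``bonferroni`` or ``holm`` adjusted
    p-values are reported alongside the raw ones when requested.
    """
    if correction not in ("none", "bonferroni", "holm"):
        raise InvalidParameterError("correction must be none, bonferroni, or holm")
    vocab = set(table["stage"])
    unknown = set(stages) - vocab
    if unknown:
        raise InvalidParameterError(
            f"unknown stages {sorted(unknown)}; table vocabulary: {sorted(vocab)}"
        )
    comparisons = [
        planned_ttest(
            _stage_values(table, group_a, s), _stage_values(table, group_b, s), stage=s
        )
        for s in stages
    ]
    if correction != "none":
        adj = multipletests([c.p for c in comparisons], method=correction)[1]
        comparisons = [
            StageComparison(**{**c.__dict__, "p_corrected": float(q)})
            for c, q in zip(comparisons, adj)
        ]
    return comparisons


def comparisons_to_frame(comparisons) -> pd.DataFrame:
    """Tabulate StageComparisons for CSV export."""
    return pd.DataFrame([c.__dict__ for c in comparisons])
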