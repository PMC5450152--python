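"""Response-phenotype derivation from the clinical table.

Implements the annualized relapse rate (ARR) endpoints, the extreme
response classes, the relapse-free definition with its 47-day efficacy
window, confirmed EDSS progression, and the NEDA3/NEDA4 composites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pgxsig.datatypes import ClinicalTable, DataError

#: Relapses within this many days of treatment start are excluded from the
#: relapse-free determination (drug not yet at full efficacy).
EARLY_WINDOW_DAYS = 47

#: End of the first treatment year, in days.
ONE_YEAR_DAYS = 365

#: Standard pre-study observation window, in years.
PRE_STUDY_YEARS = 2.0

#: Brain-volume loss at or beyond this percentage breaks NEDA4.
NEDA4_BV_LOSS_PCT = 0.4

HIGH = "high"
HIGHEST = "highest"
LOW = "low"
LOWEST = "lowest"
INTERMEDIATE = "intermediate"

RESPONDER = "responder"
NON_RESPONDER = "non_responder"
EXCLUDED_EARLY_RELAPSE = "excluded_early_relapse"


@dataclass(frozen=True)
class RelapseHistory:
    pre_study_relapses: int
    history_years: float
    on_study_relapse_days: tuple[float, ...]
    exposure_years: float

    def __post_init__(self) -> None:
        if self.pre_study_relapses < 0:
            raise DataError("negative pre-study relapse count")
        if self.history_years < 0:
            raise DataError("negative history years")
        if any(d < 0 for d in self.on_study_relapse_days):
            raise DataError("negative relapse day")
        if self.exposure_years <= 0:
            raise DataError("exposure must be positive")


def compute_arr(relapses: int, years: float) -> float:
    """Annualized relapse rate: relapses per year of observation."""
    if years <= 0:
        raise DataError(f"observation time must be positive, got {years}")
    return relapses / years


def pre_study_arr(relapses: int, history_years: float) -> float:
    """Pre-study ARR over the standard 2-year window.

    With fewer than two years of recorded history the time since first
    symptom is the denominator instead.
    """
    years = history_years if history_years < PRE_STUDY_YEARS else PRE_STUDY_YEARS
    return compute_arr(relapses, years)


def classify_extreme(arr_reduction: float, new_t2: int) -> str:
    """Map ARR reduction and new-T2 count to an extreme response class.

    reduction > 1 -> high; high with no new T2 lesions -> highest.
    reduction <= 0 -> low; low with >= 1 new T2 lesion -> lowest.
    reduction in (0, 1] -> intermediate.
    """
    if not np.isfinite(arr_reduction):
        raise DataError("non-finite ARR reduction")
    if new_t2 < 0:
        raise DataError("negative new-T2 count")
    if arr_reduction > 1:
        return HIGHEST if new_t2 == 0 else HIGH
    if arr_reduction <= 0:
        return LOWEST if new_t2 >= 1 else LOW
    return INTERMEDIATE


def is_high(extreme_class: str) -> bool:
    return extreme_class in (HIGH, HIGHEST)


def is_low(extreme_class: str) -> bool:
    return extreme_class in (LOW, LOWEST)


def relapse_free_label(history: RelapseHistory) -> str:
    """Relapse-free responder status over the first treatment year.

    Any relapse on or before day 47 excludes the subject outright (even if
    later relapses occur); otherwise a relapse in days 48..365 makes the
    subject a non-responder and its absence a responder.
    """
    days = history.on_study_relapse_days
    if any(d <= EARLY_WINDOW_DAYS for d in days):
        return EXCLUDED_EARLY_RELAPSE
    if any(EARLY_WINDOW_DAYS < d <= ONE_YEAR_DAYS for d in days):
        return NON_RESPONDER
    return RESPONDER


def confirmed_progression(
    edss_series: list[tuple[float, float]], baseline_edss: float
) -> bool:
    """Confirmed disability progression from an EDSS visit series.

    Progression is a rise from baseline of >= 1.0 point (baseline EDSS in
    [0, 5]) or >= 0.5 point (baseline above 5), sustained at a visit at
    least 90 days after the qualifying visit.
    """
    if not edss_series:
        return False
    step = 0.5 if baseline_edss > 5.0 else 1.0
    threshold = baseline_edss + step
    series = sorted(edss_series)
    for i, (day_i, score_i) in enumerate(series):
        if score_i < threshold:
            continue
        for day_j, score_j in series[i + 1 :]:
            if day_j - day_i >= 90 and score_j >= threshold:
                return True
    return False


def neda_status(
    relapse_free: bool,
    progression: bool,
    t1_gd_lesions: int | None,
    new_or_enlarging_t2: int | None,
    brain_volume_loss_pct: float | None,
) -> tuple[bool | None, bool | None]:
    """NEDA3/NEDA4 composites at the 12-month landmark.

    NEDA3: no relapse, no confirmed progression, and no MRI activity
    (zero gadolinium-enhancing T1 lesions and zero new/enlarging T2).
    NEDA4 additionally requires brain-volume loss below 0.4%.
    Missing MRI inputs yield ``None`` (undetermined), not ``False``.
    """
    if not relapse_free or progression:
        return False, False
    if t1_gd_lesions is None or new_or_enlarging_t2 is None:
        return None, None
    neda3 = t1_gd_lesions == 0 and new_or_enlarging_t2 == 0
    if not neda3:
        return False, False
    if brain_volume_loss_pct is None:
        return True, None
    return True, brain_volume_loss_pct < NEDA4_BV_LOSS_PCT


def compute_labels(clinical: ClinicalTable) -> pd.DataFrame:
    """Derive every per-subject response label from the clinical table.

    Returns a frame indexed by subject id with: arr_pre, arr_on,
    arr_reduction, extreme_class, relapse_free, time_to_first_relapse (in
    days; censored at follow-up end for relapse-free subjects, flagged),
    censored, progression, neda3, neda4.
    """
    rows = []
    for rec in clinical.df.itertuples(index=False):
        days = tuple(rec.on_study_relapse_days)
        arr_pre = pre_study_arr(rec.pre_study_relapses, rec.history_years)
        arr_on = compute_arr(len(days), rec.exposure_years)
        reduction = arr_pre - arr_on
        extreme = classify_extreme(reduction, int(rec.new_t2_count))
        history = RelapseHistory(
            pre_study_relapses=int(rec.pre_study_relapses),
            history_years=float(rec.history_years),
            on_study_relapse_days=days,
            exposure_years=float(rec.exposure_years),
        )
        rf = relapse_free_label(history)
        if days:
            ttfr, censored = float(min(days)), False
        else:
            ttfr, censored = float(rec.follow_up_days), True
        progression = confirmed_progression(rec.edss_series, float(rec.baseline_edss))
        # NEDA relapse criterion counts every first-year relapse (the
        # 47-day exclusion applies only to the relapse-free endpoint)
        any_relapse = any(d <= ONE_YEAR_DAYS for d in days)
        loss = -float(rec.brain_volume_change_pct)
        neda3, neda4 = neda_status(
            not any_relapse,
            progression,
            int(rec.on_t1_count),
            int(rec.new_t2_count),
            loss,
        )
        rows.append(
            {
                "subject_id": rec.subject_id,
                "arr_pre": arr_pre,
                "arr_on": arr_on,
                "arr_reduction": reduction,
                "extreme_class": extreme,
                "relapse_free": rf,
                "time_to_first_relapse": ttfr,
                "censored": censored,
                "progression": progression,
                "neda3": neda3,
                "neda4": neda4,
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")


def extreme_case_control(labels: pd.DataFrame, highest_only: bool = False) -> pd.Series:
    """Binary case/control vector for association screening.

    Default: cases are high (incl. highest) responders, controls low
    (incl. lowest); intermediates are dropped (NaN).  With
    ``highest_only`` the contrast is highest vs lowest.
    """
    cls = labels["extreme_class"]
    if highest_only:
        y = pd.Series(np.nan, index=labels.index)
        y[cls == HIGHEST] = 1.0
        y[cls == LOWEST] = 0.0
        return y
    y = pd.Series(np.nan, index=labels.index)
    y[cls.isin([HIGH, HIGHEST])] = 1.0
    y[cls.isin([LOW, LOWEST])] = 0.0
    return y


def relapse_free_outcome(labels: pd.DataFrame) -> pd.Series:
    """Binary relapse-free outcome (1 responder, 0 non-responder, NaN excluded)."""
    rf = labels["relapse_free"]
    y = pd.Series(np.nan, index=labels.index)
    y[rf == RESPONDER] = 1.0
    y[rf == NON_RESPONDER] = 0.0
    return y
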