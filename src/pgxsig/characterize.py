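"""Stage IV: quintile binning of predicted probabilities and per-bin
clinical summaries."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from pgxsig.datatypes import ClinicalTable, DataError
from pgxsig.phenotypes import RESPONDER, EXCLUDED_EARLY_RELAPSE

N_BINS = 5


def quintile_bins(probs: pd.Series | np.ndarray) -> pd.Series:
    """Assign subjects to five bins cut at the empirical 20/40/60/80
    percentiles of predicted probability; ties at an edge fall in the lower
    bin.  A fully tied vector collapses into one bin (flagged by warning).
    """
    if isinstance(probs, pd.Series):
        values, index = probs.to_numpy(dtype=float), probs.index
    else:
        values = np.asarray(probs, dtype=float)
        index = pd.RangeIndex(values.size)
    if values.size < N_BINS:
        raise DataError(f"need at least {N_BINS} subjects, got {values.size}")
    edges = np.quantile(values, [0.2, 0.4, 0.6, 0.8], method="inverted_cdf")
    assignment = (values[:, None] > edges[None, :]).sum(axis=1)
    if np.unique(assignment).size == 1:
        warnings.warn("degenerate binning: all probabilities tied", UserWarning)
    return pd.Series(assignment, index=index, name="bin")


def bin_edges_table(probs: pd.Series, assignment: pd.Series) -> pd.DataFrame:
    """Observed (min, max) probability per bin, for axis labeling."""
    df = pd.DataFrame({"prob": probs, "bin": assignment})
    out = df.groupby("bin")["prob"].agg(["min", "max", "count"])
    out.columns = ["prob_min", "prob_max", "n"]
    return out


def _mean_sd(x: pd.Series) -> tuple[float, float]:
    x = x.astype(float)
    return float(x.mean()), float(x.std(ddof=1)) if len(x) > 1 else 0.0


def bin_summaries(
    assignment: pd.Series,
    labels: pd.DataFrame,
    clinical: ClinicalTable,
) -> pd.DataFrame:
    """Per-bin descriptive statistics of baseline and on-treatment measures.

    One row per bin: n; % responders (relapse-free, among subjects not
    excluded for an early relapse); mean/SD of baseline EDSS, T1 count, T2
    volume and pre-study ARR; on-treatment T1 count, T2-volume change and
    on-trial ARR; group-level percent ARR reduction versus pre-study ARR;
    mean time to first relapse (censored subjects at follow-up end); and %
    NEDA3 / % NEDA4.  Empty bins yield rows of NaN, flagged by warning.
    """
    clin = clinical.df.set_index("subject_id")
    joined = clin.join(labels, how="inner")
    if len(joined) != len(assignment):
        raise DataError("assignment does not match labeled subjects")
    joined = joined.assign(bin=assignment.reindex(joined.index))

    rows = []
    for b in range(N_BINS):
        grp = joined[joined["bin"] == b]
        if grp.empty:
            warnings.warn(f"empty bin {b}", UserWarning)
            rows.append({"bin": b, "n": 0})
            continue
        not_excluded = grp[grp["relapse_free"] != EXCLUDED_EARLY_RELAPSE]
        pct_resp = (
            100.0 * (not_excluded["relapse_free"] == RESPONDER).mean()
            if len(not_excluded)
            else np.nan
        )
        relapses = int(grp["on_study_relapse_days"].map(len).sum())
        exposure = float(grp["exposure_years"].sum())
        arr_on_group = relapses / exposure
        pre_relapses = float(grp["pre_study_relapses"].sum())
        pre_years = float(
            grp["history_years"].clip(upper=2.0).replace(0.0, np.nan).sum()
        )
        arr_pre_group = pre_relapses / pre_years if pre_years > 0 else np.nan
        pct_arr_reduction = (
            100.0 * (arr_pre_group - arr_on_group) / arr_pre_group
            if arr_pre_group and np.isfinite(arr_pre_group) and arr_pre_group > 0
            else np.nan
        )
        edss_m, edss_s = _mean_sd(grp["baseline_edss"])
        t1_m, t1_s = _mean_sd(grp["baseline_t1_count"])
        t2_m, t2_s = _mean_sd(grp["baseline_t2_volume"])
        arrpre_m, arrpre_s = _mean_sd(grp["arr_pre"])
        ont1_m, ont1_s = _mean_sd(grp["on_t1_count"])
        t2c_m, t2c_s = _mean_sd(grp["t2_volume_change"])
        rows.append(
            {
                "bin": b,
                "n": int(len(grp)),
                "pct_responders": pct_resp,
                "baseline_edss_mean": edss_m,
                "baseline_edss_sd": edss_s,
                "baseline_t1_mean": t1_m,
                "baseline_t1_sd": t1_s,
                "baseline_t2_volume_mean": t2_m,
                "baseline_t2_volume_sd": t2_s,
                "baseline_arr_mean": arrpre_m,
                "baseline_arr_sd": arrpre_s,
                "on_t1_mean": ont1_m,
                "on_t1_sd": ont1_s,
                "t2_volume_change_mean": t2c_m,
                "t2_volume_change_sd": t2c_s,
                "on_trial_arr": arr_on_group,
                "pct_arr_reduction": pct_arr_reduction,
                "time_to_first_relapse_mean": float(
                    grp["time_to_first_relapse"].mean()
                ),
                "pct_neda3": 100.0 * _bool_rate(grp["neda3"]),
                "pct_neda4": 100.0 * _bool_rate(grp["neda4"]),
            }
        )
    table = pd.DataFrame(rows).set_index("bin")
    if int(table["n"].sum()) != len(joined):
        raise DataError("bin sizes do not reconcile with cohort size")
    return table


def _bool_rate(col: pd.Series) -> float:
    known = col[col.notna()]
    if known.empty:
        return np.nan
    return float(known.astype(bool).mean())
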