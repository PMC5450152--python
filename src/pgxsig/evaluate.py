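"""Stage III: predicted probabilities, ROC/AUC, top-left threshold
classification, group ARR comparison, bootstrap AUC testing and
leave-one-out subset models."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pgxsig.datatypes import (
    ClinicalTable,
    DataError,
    GenotypeMatrix,
    SignatureModel,
    StructuralError,
)
from pgxsig.qc import encode_snp

SIG_POS = "sig+"
SIG_NEG = "sig-"


@dataclass
class ROCSummary:
    """ROC triples ordered by decreasing threshold, with the AUC and the
    top-left operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    top_left_threshold: float
    top_left_sens: float
    top_left_spec: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def predict_probs(model: SignatureModel, genotypes: GenotypeMatrix) -> pd.Series:
    """Per-subject predicted probability under the signature model.

    Missing genotypes propagate to missing probabilities.
    """
    absent = [s for s in model.snp_ids if s not in genotypes.snp_ids]
    if absent:
        raise StructuralError(f"model SNPs absent from genotypes: {absent}")
    lp = np.full(genotypes.n_subjects, model.intercept, dtype=float)
    for snp, coding, beta in zip(model.snp_ids, model.codings, model.coefficients):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coded = encode_snp(genotypes.column(snp), coding)
        lp = lp + beta * coded
    probs = 1.0 / (1.0 + np.exp(-lp))
    return pd.Series(probs, index=list(genotypes.subject_ids), name="prob")


def _clean(probs: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    probs = np.asarray(probs, dtype=float)
    truth = np.asarray(truth, dtype=float)
    ok = ~np.isnan(probs) & ~np.isnan(truth)
    probs, truth = probs[ok], truth[ok]
    if not ((truth == 1).any() and (truth == 0).any()):
        raise DataError("both classes must be present")
    return probs, truth


def roc_auc(probs: np.ndarray, truth: np.ndarray) -> ROCSummary:
    """ROC over the unique predicted probabilities plus trapezoidal AUC.

    The trapezoidal area equals the rank statistic (probability a random
    positive outranks a random negative, ties counted half).  The top-left
    threshold minimizes the Euclidean distance to (sens, spec) = (1, 1);
    ties go to the smallest (most sensitive) threshold.
    """
    probs, truth = _clean(probs, truth)
    n_pos = float((truth == 1).sum())
    n_neg = float((truth == 0).sum())
    order = np.argsort(-probs, kind="stable")
    p_sorted, t_sorted = probs[order], truth[order]
    # cumulative counts at each unique score (classification rule: >= threshold)
    uniq_mask = np.r_[np.diff(p_sorted) != 0, True]
    tp = np.cumsum(t_sorted == 1)[uniq_mask]
    fp = np.cumsum(t_sorted == 0)[uniq_mask]
    thresholds = p_sorted[uniq_mask]
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    # trapezoid over (fpr, tpr) including the (0,0) endpoint
    fpr = np.r_[0.0, fp / n_neg]
    tpr = np.r_[0.0, tp / n_pos]
    auc = float(np.trapezoid(tpr, fpr))
    dist = np.sqrt((1.0 - sens) ** 2 + (1.0 - spec) ** 2)
    best = dist.min()
    # ties -> smallest threshold
    candidates = thresholds[np.isclose(dist, best, rtol=0.0, atol=1e-12)]
    top_left = float(candidates.min())
    at = np.flatnonzero(thresholds == top_left)[0]
    return ROCSummary(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        top_left_threshold=top_left,
        top_left_sens=float(sens[at]),
        top_left_spec=float(spec[at]),
    )


def top_left_threshold(roc: ROCSummary) -> float:
    if roc.thresholds.size == 0:
        raise DataError("empty ROC curve")
    return roc.top_left_threshold


def classify_signature(probs: pd.Series | np.ndarray, threshold: float) -> pd.Series:
    """sig+ when the predicted probability meets or exceeds the threshold."""
    if isinstance(probs, pd.Series):
        values, index = probs.to_numpy(dtype=float), probs.index
    else:
        values = np.asarray(probs, dtype=float)
        index = pd.RangeIndex(values.size)
    labels = np.where(values >= threshold, SIG_POS, SIG_NEG).astype(object)
    labels[np.isnan(values)] = None
    return pd.Series(labels, index=index, name="signature")


@dataclass
class GroupARRSummary:
    relapses_pos: int
    exposure_pos: float
    relapses_neg: int
    exposure_neg: float

    @property
    def arr_pos(self) -> float:
        return self.relapses_pos / self.exposure_pos

    @property
    def arr_neg(self) -> float:
        return self.relapses_neg / self.exposure_neg

    @property
    def percent_change(self) -> float:
        """100 * (ARR_pos - ARR_neg) / ARR_neg; negative favors sig+."""
        if self.arr_neg == 0.0:
            raise DataError("sig- group ARR is zero; percent change undefined")
        return 100.0 * (self.arr_pos - self.arr_neg) / self.arr_neg


def group_arr_change(
    signature: pd.Series, clinical: ClinicalTable
) -> GroupARRSummary:
    """Pooled-relapse / pooled-exposure ARR per signature group.

    Mean group ARR divides the total relapse count in a group by the total
    exposure (in years) of that group.
    """
    df = clinical.df.set_index("subject_id")
    sig = signature.reindex(df.index)
    groups = {}
    for label in (SIG_POS, SIG_NEG):
        members = df[sig == label]
        if members.empty:
            raise DataError(f"empty {label} group")
        relapses = int(members["on_study_relapse_days"].map(len).sum())
        exposure = float(members["exposure_years"].sum())
        if exposure <= 0:
            raise DataError("non-positive exposure")
        groups[label] = (relapses, exposure)
    return GroupARRSummary(
        relapses_pos=groups[SIG_POS][0],
        exposure_pos=groups[SIG_POS][1],
        relapses_neg=groups[SIG_NEG][0],
        exposure_neg=groups[SIG_NEG][1],
    )


def auc_bootstrap_difference(
    cohort_a: tuple[np.ndarray, np.ndarray],
    cohort_b: tuple[np.ndarray, np.ndarray],
    n_boot: int = 2000,
    seed: int = 0,
    max_retries: int = 100,
) -> float:
    """Two-sided bootstrap p for a difference in AUC between two cohorts.

    Subjects are resampled with replacement within each cohort; the p-value
    is twice the smaller tail proportion of the bootstrap distribution of
    AUC_a - AUC_b around zero.
    """
    pa, ta = _clean(*cohort_a)
    pb, tb = _clean(*cohort_b)
    rng = np.random.default_rng(seed)

    def resample(p, t):
        for _ in range(max_retries):
            idx = rng.integers(0, p.size, size=p.size)
            if (t[idx] == 1).any() and (t[idx] == 0).any():
                return p[idx], t[idx]
        raise DataError("could not draw a two-class resample")

    diffs = np.empty(n_boot)
    for i in range(n_boot):
        ra = roc_auc(*resample(pa, ta)).auc
        rb = roc_auc(*resample(pb, tb)).auc
        diffs[i] = ra - rb
    lower = float((diffs <= 0).mean())
    upper = float((diffs >= 0).mean())
    return float(min(1.0, 2.0 * min(lower, upper)))


def subset_model_eval(
    design: pd.DataFrame,
    outcome: np.ndarray,
    codings: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Refit and evaluate every leave-one-out subset of the signature SNPs.

    Returns one row per dropped SNP with the refitted subset's AUC and the
    sensitivity/specificity at its own top-left threshold.
    """
    from pgxsig.bma import refit_final

    snps = list(design.columns)
    if len(snps) < 2:
        raise DataError("need at least two SNPs to form subsets")
    y = np.asarray(outcome, dtype=float)
    rows = []
    for dropped in snps:
        sub = design.drop(columns=[dropped])
        model = refit_final(sub, y, codings=codings)
        lp = model.intercept + sub.to_numpy() @ np.asarray(model.coefficients)
        probs = 1.0 / (1.0 + np.exp(-lp))
        ok = ~np.isnan(probs) & ~np.isnan(y)
        roc = roc_auc(probs[ok], y[ok])
        rows.append(
            {
                "dropped_snp": dropped,
                "n_snps": len(snps) - 1,
                "auc": roc.auc,
                "sensitivity": roc.top_left_sens,
                "specificity": roc.top_left_spec,
                "threshold": roc.top_left_threshold,
            }
        )
    return pd.DataFrame(rows).set_index("dropped_snp")


def performance_report(
    cohorts: dict[str, tuple[pd.Series, np.ndarray]],
    threshold: float,
) -> pd.DataFrame:
    """Per-cohort classification summary at a frozen threshold: n, sig+/-
    counts, specificity, sensitivity and AUC."""
    rows = []
    for cohort, (probs, truth) in cohorts.items():
        p, t = _clean(probs.to_numpy(dtype=float), truth)
        roc = roc_auc(p, t)
        pred_pos = p >= threshold
        tp = float(((t == 1) & pred_pos).sum())
        tn = float(((t == 0) & ~pred_pos).sum())
        rows.append(
            {
                "cohort": cohort,
                "n": int(p.size),
                "sig_pos": int(pred_pos.sum()),
                "sig_neg": int((~pred_pos).sum()),
                "sensitivity": tp / float((t == 1).sum()),
                "specificity": tn / float((t == 0).sum()),
                "auc": roc.auc,
            }
        )
    return pd.DataFrame(rows).set_index("cohort")
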