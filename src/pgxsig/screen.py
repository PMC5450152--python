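"""Stage I: per-SNP logistic association on extreme phenotypes, the staged
selection funnel across two discovery cohorts, and the placebo filter."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from pgxsig.datatypes import ADDITIVE, DataError, GenotypeMatrix
from pgxsig.phenotypes import extreme_case_control
from pgxsig.qc import encode_snp, ld_r2, select_inheritance_model

DEFAULT_PLACEBO_ALPHA = 0.05
#: |beta| beyond this is treated as evidence of complete separation.
_SEPARATION_BETA = 15.0


@dataclass(frozen=True)
class AssociationResult:
    snp_id: str
    cohort_id: str
    coding: str
    beta: float
    odds_ratio: float
    p_value: float
    n_cases: int
    n_controls: int
    separated: bool = False

    def as_dict(self) -> dict:
        return {
            "snp_id": self.snp_id,
            "cohort_id": self.cohort_id,
            "coding": self.coding,
            "beta": self.beta,
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "separated": self.separated,
        }


@dataclass(frozen=True)
class FunnelStep:
    """One step of the selection funnel.

    ``candidate_set`` lists SNP ids, or ``None`` for genome-wide (every SNP
    in the matrix).  ``thresholds`` maps cohort id -> p cutoff; a SNP must
    meet every cohort's cutoff to be selected.
    """

    step_id: int
    thresholds: dict[str, float]
    candidate_set: tuple[str, ...] | None = None
    phenotype: str = "extreme"  # "extreme" | "highest_extreme"

    def __post_init__(self) -> None:
        for cohort, thr in self.thresholds.items():
            if not (0.0 < thr < 1.0):
                raise DataError(f"threshold for {cohort} must be in (0,1), got {thr}")


@dataclass
class FunnelResult:
    selected: list[str]
    provenance: pd.DataFrame  # per (step, snp, cohort) association rows
    per_step: dict[int, list[str]] = field(default_factory=dict)
    codings: dict[str, str] = field(default_factory=dict)


def snp_logistic(
    coded_snp: np.ndarray,
    labels: np.ndarray,
    snp_id: str = "snp",
    cohort_id: str = "cohort",
    coding: str = ADDITIVE,
) -> AssociationResult:
    """Single-SNP maximum-likelihood logistic fit with Wald p-value.

    Under complete separation the Wald statistic degenerates; the result is
    flagged and the p-value falls back to the likelihood-ratio test.
    """
    x = np.asarray(coded_snp, dtype=float)
    y = np.asarray(labels, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    n_cases = int((y == 1).sum())
    n_controls = int((y == 0).sum())
    if n_cases < 1 or n_controls < 1:
        raise DataError("need at least one case and one control")
    if np.std(x) == 0.0:
        raise DataError("degenerate (zero-variance) covariate")

    X = sm.add_constant(x)
    model = sm.Logit(y, X)
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=100)
        except Exception:
            separated = True
            res = model.fit(method="bfgs", disp=0, maxiter=500)
    beta = float(res.params[1])
    p_wald = float(res.pvalues[1])
    if not separated and (abs(beta) > _SEPARATION_BETA or not np.isfinite(p_wald)):
        separated = True
    if separated:
        llf = float(res.llf)
        llnull = float(sm.Logit(y, np.ones_like(y)).fit(disp=0).llf)
        lr = max(0.0, 2.0 * (llf - llnull))
        p_value = float(stats.chi2.sf(lr, 1))
    else:
        p_value = p_wald
    return AssociationResult(
        snp_id=snp_id,
        cohort_id=cohort_id,
        coding=coding,
        beta=beta,
        odds_ratio=float(np.exp(beta)),
        p_value=p_value,
        n_cases=n_cases,
        n_controls=n_controls,
        separated=separated,
    )


def _cohort_assoc(
    genotypes: GenotypeMatrix,
    outcome: pd.Series,
    snp_id: str,
    cohort_id: str,
    coding: str,
) -> AssociationResult | None:
    g = genotypes.column(snp_id)
    y = outcome.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coded = encode_snp(g, coding)
    try:
        return snp_logistic(coded, y, snp_id=snp_id, cohort_id=cohort_id, coding=coding)
    except DataError:
        return None


def run_funnel(
    cohorts: dict[str, tuple[GenotypeMatrix, pd.DataFrame]],
    steps: list[FunnelStep],
    coding_cohort: str | None = None,
    ld_r2_max: float = 0.2,
    codings: dict[str, str] | None = None,
) -> FunnelResult:
    """Staged per-SNP screen across discovery cohorts.

    ``cohorts`` maps cohort id to (genotypes, phenotype labels as returned
    by :func:`pgxsig.phenotypes.compute_labels`).  Each step screens its
    candidate set (minus previously selected SNPs) and selects SNPs meeting
    every cohort's p cutoff; steps with ``highest_extreme`` phenotype
    recompute the case/control contrast as highest vs lowest responders.
    Within a step, SNPs in LD (r^2 >= ``ld_r2_max``) are de-duplicated
    keeping the smallest-p representative.  Inheritance codings are chosen
    per SNP on ``coding_cohort`` (default: first cohort) unless a fixed
    ``codings`` mapping is supplied.
    """
    cohort_ids = list(cohorts)
    if coding_cohort is None:
        coding_cohort = cohort_ids[0]
    selected: list[str] = []
    selected_codings: dict[str, str] = {}
    per_step: dict[int, list[str]] = {}
    provenance_rows: list[dict] = []

    for step in steps:
        geno0 = cohorts[cohort_ids[0]][0]
        candidates = (
            list(step.candidate_set) if step.candidate_set is not None else geno0.snp_ids
        )
        candidates = [s for s in candidates if s not in selected]
        if not candidates:
            warnings.warn(f"step {step.step_id}: empty candidate set, skipped")
            per_step[step.step_id] = []
            continue
        highest = step.phenotype == "highest_extreme"

        outcomes = {
            cid: extreme_case_control(labels, highest_only=highest)
            for cid, (_, labels) in cohorts.items()
        }
        # inheritance coding decided once per SNP on the coding cohort,
        # unless fixed codings were supplied
        step_codings: dict[str, str] = {}
        if codings is not None:
            step_codings = {snp: codings.get(snp, ADDITIVE) for snp in candidates}
        else:
            geno_c, _ = cohorts[coding_cohort]
            y_c = outcomes[coding_cohort].to_numpy(dtype=float)
            for snp in candidates:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    step_codings[snp] = select_inheritance_model(geno_c.column(snp), y_c)

        step_hits: list[tuple[str, float]] = []
        for snp in candidates:
            results = {}
            for cid in cohort_ids:
                geno, _ = cohorts[cid]
                res = _cohort_assoc(geno, outcomes[cid], snp, cid, step_codings[snp])
                if res is not None:
                    provenance_rows.append({"step": step.step_id, **res.as_dict()})
                results[cid] = res
            if any(results[cid] is None for cid in step.thresholds):
                continue
            if all(
                results[cid].p_value < thr for cid, thr in step.thresholds.items()
            ):
                ref_p = results[cohort_ids[0]].p_value
                step_hits.append((snp, ref_p))

        # LD de-duplication: keep the smallest-p representative per LD group
        step_hits.sort(key=lambda t: t[1])
        kept: list[str] = []
        geno_ld = cohorts[cohort_ids[0]][0]
        for snp, _p in step_hits:
            in_ld = False
            for other in kept:
                try:
                    if ld_r2(geno_ld.column(snp), geno_ld.column(other)) >= ld_r2_max:
                        in_ld = True
                        break
                except DataError:
                    continue
            if not in_ld:
                kept.append(snp)
        per_step[step.step_id] = kept
        selected.extend(kept)
        for snp in kept:
            selected_codings[snp] = step_codings[snp]

    provenance = pd.DataFrame(provenance_rows)
    return FunnelResult(
        selected=selected,
        provenance=provenance,
        per_step=per_step,
        codings=selected_codings,
    )


def placebo_filter(
    selected: list[str],
    placebo_genotypes: GenotypeMatrix,
    placebo_labels: pd.DataFrame,
    alpha_prognostic: float = DEFAULT_PLACEBO_ALPHA,
    codings: dict[str, str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop SNPs associated with the extreme phenotype under placebo.

    A SNP with placebo-arm association p < ``alpha_prognostic`` is deemed
    prognostic rather than predictive and removed.
    """
    outcome = extreme_case_control(placebo_labels)
    kept, rows = [], []
    for snp in selected:
        coding = (codings or {}).get(snp, ADDITIVE)
        res = _cohort_assoc(placebo_genotypes, outcome, snp, "placebo", coding)
        p = res.p_value if res is not None else np.nan
        prognostic = bool(p < alpha_prognostic) if np.isfinite(p) else False
        rows.append({"snp_id": snp, "placebo_p": p, "prognostic": prognostic})
        if not prognostic:
            kept.append(snp)
    return kept, pd.DataFrame(rows).set_index("snp_id")
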