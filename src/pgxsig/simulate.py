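"""Synthetic trial cohorts with the statistical structure the pipeline assumes.

Genotypes are drawn under Hardy-Weinberg equilibrium at configurable minor
allele frequencies; binary relapse-free outcomes come from a logistic model
over coded genotypes plus optional baseline covariates; relapse processes,
lesion counts, EDSS trajectories and brain-volume change are drawn from
simple configurable distributions.  A placebo arm zeroes all genotype
effects so the genotype-outcome association is null by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pgxsig.datatypes import (
    ADDITIVE,
    ClinicalTable,
    ConfigError,
    GenotypeMatrix,
    SnpSpec,
    StructuralError,
)
from pgxsig.qc import encode_snp

#: 2-year pre-study observation window used for pre-study relapse history.
PRE_STUDY_YEARS = 2.0

#: Efficacy-onset window: relapses in days 1..47 do not count as failures.
EARLY_WINDOW_DAYS = 47

#: On-study follow-up of the double-blind phase, in days.
FOLLOW_UP_DAYS = 365


@dataclass(frozen=True)
class RelapseModel:
    """Pre-study relapse-rate distribution and on-study rate linkage."""

    pre_arr_mean: float = 0.93       # discovery double-blind cohort moments
    pre_arr_sd: float = 0.45
    nonresponder_rate: float = 1.2   # extra relapses/year beyond the first
    early_relapse_prob: float = 0.0  # chance of a relapse in days 1..47

    def __post_init__(self) -> None:
        if self.pre_arr_mean < 0 or self.pre_arr_sd < 0 or self.nonresponder_rate < 0:
            raise ConfigError("relapse rates must be >= 0")
        if not (0.0 <= self.early_relapse_prob <= 1.0):
            raise ConfigError("early_relapse_prob must be in [0, 1]")


@dataclass(frozen=True)
class LesionModel:
    """Rates for T1 lesion counts and new-T2 counts."""

    baseline_t1_rate: float = 1.8
    baseline_t2_volume_mean: float = 15.0
    baseline_t2_volume_sd: float = 8.0
    new_t2_rate_responder: float = 0.4
    new_t2_rate_nonresponder: float = 2.0
    on_t1_rate_responder: float = 0.5
    on_t1_rate_nonresponder: float = 1.5

    def __post_init__(self) -> None:
        for name in (
            "baseline_t1_rate",
            "new_t2_rate_responder",
            "new_t2_rate_nonresponder",
            "on_t1_rate_responder",
            "on_t1_rate_nonresponder",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass(frozen=True)
class BrainVolumeModel:
    """Percent brain-volume change over the first treatment year."""

    mean: float = -0.35
    sd: float = 0.30


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 200
    snp_specs: tuple[SnpSpec, ...] = ()
    intercept: float = 0.0
    #: log-odds per unit of (baseline EDSS, log(pre-study relapses + 1),
    #: baseline T2 volume, baseline T1 status)
    covariate_effects: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    placebo_flag: bool = False
    relapse_model: RelapseModel = field(default_factory=RelapseModel)
    lesion_model: LesionModel = field(default_factory=LesionModel)
    brain_volume_model: BrainVolumeModel = field(default_factory=BrainVolumeModel)
    edss_mean: float = 2.79
    edss_sd: float = 1.22
    cohort: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        ids = [s.id for s in self.snp_specs]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate SNP ids in snp_specs")


def default_snp_specs(
    n_snps: int = 11,
    maf: float = 0.25,
    coefficients: tuple[float, ...] = (),
    codings: tuple[str, ...] = (),
) -> tuple[SnpSpec, ...]:
    """Neutral default panel: ``n_snps`` independent SNPs at one MAF.

    ``coefficients`` fills log-odds effects for the leading SNPs; the rest
    are null.
    """
    specs = []
    for j in range(n_snps):
        coef = coefficients[j] if j < len(coefficients) else 0.0
        coding = codings[j] if j < len(codings) else ADDITIVE
        specs.append(SnpSpec(id=f"snp{j + 1:02d}", maf=maf, coding=coding, coefficient=coef))
    return tuple(specs)


def _streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    """One child stream per output table, split from the master seed."""
    root = np.random.SeedSequence(config.seed)
    names = ("genotypes", "covariates", "outcomes", "relapses", "lesions", "brain")
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw independent HWE genotypes for every SNP in the config.

    For MAF ``q`` the genotype-class counts (0/1/2 minor-allele copies) are
    multinomial with probabilities ((1-q)^2, 2q(1-q), q^2), then permuted
    across subjects, so marginals are exactly HWE-multinomial.
    """
    if not config.snp_specs:
        raise ConfigError("snp_specs is empty")
    rng = _streams(config)["genotypes"]
    n = config.n_subjects
    data = np.empty((n, len(config.snp_specs)), dtype=float)
    for j, spec in enumerate(config.snp_specs):
        q = spec.maf
        probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        counts = rng.multinomial(n, probs)
        col = np.repeat(np.array([0.0, 1.0, 2.0]), counts)
        data[:, j] = col[rng.permutation(n)]
    snps = pd.DataFrame(
        {
            "ref": "A",
            "alt": "G",
            "coding": [s.coding for s in config.snp_specs],
            "true_coefficient": [s.coefficient for s in config.snp_specs],
            "true_maf": [s.maf for s in config.snp_specs],
        },
        index=pd.Index([s.id for s in config.snp_specs], name="snp_id"),
    )
    subject_ids = [f"{config.cohort}-{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(subject_ids, snps, data)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, size: int
) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def _relapse_days(
    rng: np.random.Generator,
    responder: np.ndarray,
    early: np.ndarray,
    rate: float,
    exposure_years: np.ndarray,
) -> list[list[float]]:
    """Relapse-day lists: responders have no relapse in days 48..365,
    non-responders at least one; optional early relapses in days 1..47."""
    days: list[list[float]] = []
    for i in range(responder.size):
        d: list[float] = []
        if early[i]:
            d.append(float(rng.integers(1, EARLY_WINDOW_DAYS + 1)))
        if not responder[i]:
            extra = rng.poisson(rate * exposure_years[i])
            n_rel = 1 + int(extra)
            d.extend(sorted(rng.integers(EARLY_WINDOW_DAYS + 1, FOLLOW_UP_DAYS + 1, size=n_rel).astype(float)))
        days.append(d)
    return days


def simulate_outcomes(genotypes: GenotypeMatrix, config: SimulationConfig) -> ClinicalTable:
    """Draw the clinical table conditional on simulated genotypes.

    The responder indicator is Bernoulli(logit^-1(intercept + sum of coded
    SNP effects + covariate effects)); the placebo arm zeroes SNP effects.
    """
    n = config.n_subjects
    if genotypes.n_subjects != n:
        raise StructuralError(
            f"genotypes have {genotypes.n_subjects} subjects, config says {n}"
        )
    spec_ids = [s.id for s in config.snp_specs]
    if list(genotypes.snps.index) != spec_ids:
        raise StructuralError("genotype columns do not match snp_specs")

    streams = _streams(config)
    rng_cov = streams["covariates"]
    rng_out = streams["outcomes"]
    rng_rel = streams["relapses"]
    rng_les = streams["lesions"]
    rng_brain = streams["brain"]
    rm, lm, bm = config.relapse_model, config.lesion_model, config.brain_volume_model

    # baseline covariates
    edss = _truncated_normal(rng_cov, config.edss_mean, config.edss_sd, 0.0, 10.0, n)
    edss = np.round(edss * 2.0) / 2.0
    arr_pre = _truncated_normal(rng_cov, rm.pre_arr_mean, rm.pre_arr_sd, 0.0, np.inf, n)
    history_years = np.full(n, PRE_STUDY_YEARS)
    pre_relapses = np.round(arr_pre * PRE_STUDY_YEARS).astype(int)
    t1_count = rng_les.poisson(lm.baseline_t1_rate, size=n)
    t1_status = (t1_count > 0).astype(int)
    t2_volume = _truncated_normal(
        rng_cov, lm.baseline_t2_volume_mean, lm.baseline_t2_volume_sd, 0.0, np.inf, n
    )

    # linear predictor
    lp = np.full(n, config.intercept, dtype=float)
    if not config.placebo_flag:
        for j, spec in enumerate(config.snp_specs):
            lp += spec.coefficient * encode_snp(genotypes.data[:, j], spec.coding)
    ce = config.covariate_effects
    lp += (
        ce[0] * edss
        + ce[1] * np.log(pre_relapses + 1.0)
        + ce[2] * t2_volume
        + ce[3] * t1_status
    )
    prob = 1.0 / (1.0 + np.exp(-lp))
    responder = rng_out.random(n) < prob

    early = rng_rel.random(n) < rm.early_relapse_prob
    exposure = np.full(n, FOLLOW_UP_DAYS / 365.0)
    relapse_days = _relapse_days(rng_rel, responder, early, rm.nonresponder_rate, exposure)

    new_t2 = np.where(
        responder,
        rng_les.poisson(lm.new_t2_rate_responder, size=n),
        rng_les.poisson(lm.new_t2_rate_nonresponder, size=n),
    )
    on_t1 = np.where(
        responder,
        rng_les.poisson(lm.on_t1_rate_responder, size=n),
        rng_les.poisson(lm.on_t1_rate_nonresponder, size=n),
    )
    t2_change = np.where(
        responder, rng_les.normal(-0.5, 1.0, size=n), rng_les.normal(1.0, 1.5, size=n)
    )
    brain_change = rng_brain.normal(bm.mean, bm.sd, size=n)

    # EDSS series: baseline plus visits at 6 and 12 months; a fraction of
    # non-responders progress by the baseline-dependent step.
    series = []
    prog_step = np.where(edss > 5.0, 0.5, 1.0)
    progresses = (~responder) & (rng_out.random(n) < 0.25)
    for i in range(n):
        s = edss[i] + (prog_step[i] if progresses[i] else 0.0)
        series.append([(0.0, float(edss[i])), (180.0, float(s)), (365.0, float(s))])

    df = pd.DataFrame(
        {
            "subject_id": list(genotypes.subject_ids),
            "cohort": config.cohort,
            "arm": "placebo" if config.placebo_flag else "active",
            "pre_study_relapses": pre_relapses,
            "history_years": history_years,
            "on_study_relapse_days": relapse_days,
            "exposure_years": exposure,
            "follow_up_days": float(FOLLOW_UP_DAYS),
            "baseline_edss": edss,
            "edss_series": series,
            "baseline_t1_count": t1_count,
            "baseline_t1_status": t1_status,
            "baseline_t2_volume": t2_volume,
            "new_t2_count": new_t2,
            "on_t1_count": on_t1,
            "t2_volume_change": t2_change,
            "brain_volume_change_pct": brain_change,
        }
    )
    df.attrs["true_responder"] = responder.astype(int)
    return ClinicalTable(df)


def simulate_cohort(config: SimulationConfig) -> tuple[GenotypeMatrix, ClinicalTable]:
    genotypes = simulate_genotypes(config)
    clinical = simulate_outcomes(genotypes, config)
    return genotypes, clinical


def make_fixture_cohort(seed: int) -> tuple[GenotypeMatrix, ClinicalTable]:
    """Deterministic small cohort (200 subjects, 11 SNPs) for unit tests."""
    config = SimulationConfig(
        n_subjects=200,
        snp_specs=default_snp_specs(
            11, maf=0.25, coefficients=(-0.68, -0.52, -0.61, -1.46)
        ),
        intercept=1.5,
        cohort="FIX",
        seed=seed,
    )
    return simulate_cohort(config)
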