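"""Post-call genotype QC: call-rate filtering, an exact Hardy-Weinberg
equilibrium test, inheritance-model encoding and selection, and pairwise LD.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

from pgxsig.datatypes import (
    ADDITIVE,
    CODINGS,
    DOMINANT,
    ConfigError,
    DataError,
    GenotypeMatrix,
    StructuralError,
)

DEFAULT_CALL_RATE_MIN = 0.95
DEFAULT_HWE_ALPHA = 1e-4
DEFAULT_LD_R2_MAX = 0.2


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability does not exceed
    that of the observed table.  Returns a p-value in (0, 1].
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise DataError(f"negative genotype count: {counts}")
    n = sum(counts)
    if n < 1:
        raise DataError("need at least one subject")
    # work with the rarer allele so 2*n_rare_hom + n_het = rare-allele count
    n_rare = 2 * min(n_hom_major, n_hom_minor) + n_het
    if n_rare == 0:
        return 1.0

    # admissible het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hets = hets[(n_rare - hets) % 2 == 0]
    hets = hets[n_rare - hets >= 0]
    hets = hets[(2 * n - n_rare - hets) >= 0]
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    hets = hets[common_hom >= 0]
    rare_hom = rare_hom[common_hom >= 0]
    common_hom = common_hom[common_hom >= 0]

    # log P(het | allele counts) up to a shared constant
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[hets == n_het][0]
    # tolerance guards against ties broken by floating-point noise
    p = probs[probs <= observed * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def encode_snp(genotypes: np.ndarray, coding: str) -> np.ndarray:
    """Code minor-allele counts under an inheritance model.

    additive: 0/1/2 copies of the minor allele.
    dominant: 1 iff two copies of the minor allele, else 0.
    Missing values propagate.  A zero-variance result triggers a warning.
    """
    if coding not in CODINGS:
        raise ConfigError(f"unknown coding {coding!r}")
    g = np.asarray(genotypes, dtype=float)
    if coding == ADDITIVE:
        coded = g.copy()
    else:
        coded = np.where(np.isnan(g), np.nan, (g == 2.0).astype(float))
    finite = coded[~np.isnan(coded)]
    if finite.size and np.nanstd(finite) == 0.0:
        warnings.warn("zero-variance coded genotype column", UserWarning, stacklevel=2)
    return coded


def decode_additive(coded: np.ndarray) -> np.ndarray:
    """Inverse of additive encoding (identity; kept for the round-trip contract)."""
    return np.asarray(coded, dtype=float).copy()


def genotype_counts(genotypes: np.ndarray) -> tuple[int, int, int]:
    g = np.asarray(genotypes, dtype=float)
    g = g[~np.isnan(g)]
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def qc_report(
    matrix: GenotypeMatrix,
    call_rate_min: float = DEFAULT_CALL_RATE_MIN,
    hwe_alpha: float = DEFAULT_HWE_ALPHA,
    reference_arm: list[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP call rate, MAF, HWE p (in the reference arm) and verdict."""
    if matrix.n_snps == 0:
        raise StructuralError("empty genotype matrix")
    ref = matrix if reference_arm is None else matrix.subset(subjects=reference_arm)
    rows = []
    for snp_id in matrix.snp_ids:
        call_rate = float(matrix.call_rate()[snp_id])
        freq = float(matrix.minor_allele_frequency()[snp_id])
        maf = min(freq, 1.0 - freq) if np.isfinite(freq) else np.nan
        counts = genotype_counts(ref.column(snp_id))
        hwe_p = hwe_exact_test(*counts) if sum(counts) >= 1 else np.nan
        keep = call_rate >= call_rate_min and (np.isnan(hwe_p) or hwe_p >= hwe_alpha)
        reason = []
        if call_rate < call_rate_min:
            reason.append("call_rate")
        if not np.isnan(hwe_p) and hwe_p < hwe_alpha:
            reason.append("hwe")
        rows.append(
            {
                "snp_id": snp_id,
                "call_rate": call_rate,
                "maf": maf,
                "hwe_p": hwe_p,
                "verdict": "keep" if keep else "drop",
                "reason": ";".join(reason),
            }
        )
    return pd.DataFrame(rows).set_index("snp_id")


def filter_snps(
    matrix: GenotypeMatrix,
    call_rate_min: float = DEFAULT_CALL_RATE_MIN,
    hwe_alpha: float = DEFAULT_HWE_ALPHA,
    reference_arm: list[str] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Retain SNPs passing the call-rate and HWE filters.

    The HWE test is computed in ``reference_arm`` subjects (the placebo
    arm) when given, otherwise in all subjects.
    """
    report = qc_report(matrix, call_rate_min, hwe_alpha, reference_arm)
    keep = report.index[report["verdict"] == "keep"]
    return matrix.subset(snps=list(keep)), report


def _single_snp_p(coded: np.ndarray, labels: np.ndarray) -> float:
    """Wald p for a single coded SNP in a logistic fit (helper for coding
    selection; the screening module carries the full-featured fit)."""
    from pgxsig.screen import snp_logistic

    res = snp_logistic(coded, labels)
    return res.p_value


def select_inheritance_model(genotypes: np.ndarray, labels: np.ndarray) -> str:
    """Pick the coding (additive vs dominant) with the smaller single-SNP
    association p-value; ties and undetermined cases default to additive."""
    g = np.asarray(genotypes, dtype=float)
    labels = np.asarray(labels, dtype=float)
    ok = ~np.isnan(g) & ~np.isnan(labels)
    g, labels = g[ok], labels[ok]
    p_by_coding = {}
    for coding in CODINGS:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coded = encode_snp(g, coding)
        if np.nanstd(coded) == 0.0:
            continue
        try:
            p_by_coding[coding] = _single_snp_p(coded, labels)
        except Exception:
            continue
    if not p_by_coding:
        warnings.warn("both codings degenerate; defaulting to additive", UserWarning)
        return ADDITIVE
    if len(p_by_coding) == 1:
        return next(iter(p_by_coding))
    if p_by_coding[DOMINANT] < p_by_coding[ADDITIVE]:
        return DOMINANT
    return ADDITIVE


def ld_r2(snp_a: np.ndarray, snp_b: np.ndarray) -> float:
    """Squared correlation of genotype counts over pairwise-complete subjects."""
    a = np.asarray(snp_a, dtype=float)
    b = np.asarray(snp_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        raise DataError("need >= 2 overlapping non-missing subjects")
    a, b = a[ok], b[ok]
    if a.std() == 0.0 or b.std() == 0.0:
        raise DataError("zero-variance genotype column in LD computation")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
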