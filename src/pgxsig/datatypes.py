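"""Core data containers shared across pipeline stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ADDITIVE = "additive"
DOMINANT = "dominant"
CODINGS = (ADDITIVE, DOMINANT)

#: Columns every clinical table must provide.  List-valued columns are
#: serialized as ";"-joined strings in CSV.
CLINICAL_COLUMNS = [
    "subject_id",
    "cohort",
    "arm",                      # "active" | "placebo"
    "pre_study_relapses",       # relapse count in the pre-study window
    "history_years",            # years of recorded clinical history
    "on_study_relapse_days",    # list of day offsets from treatment start
    "exposure_years",           # on-study exposure in years
    "follow_up_days",
    "baseline_edss",
    "edss_series",              # list of (day, score) pairs
    "baseline_t1_count",
    "baseline_t1_status",       # 0/1: any gadolinium-enhancing lesion
    "baseline_t2_volume",
    "new_t2_count",
    "on_t1_count",
    "t2_volume_change",
    "brain_volume_change_pct",  # negative = loss
]


class PgxError(Exception):
    """Base error for this package."""


class ConfigError(PgxError):
    """Invalid configuration value."""


class DataError(PgxError):
    """Invalid data value."""


class StructuralError(PgxError):
    """Mismatched or malformed table structure."""


@dataclass(frozen=True)
class SnpSpec:
    """Generative specification of one simulated SNP."""

    id: str
    maf: float
    coding: str = ADDITIVE
    coefficient: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.maf) or not (0.0 < self.maf <= 0.5):
            raise ConfigError(f"MAF for {self.id} must be in (0, 0.5], got {self.maf}")
        if self.coding not in CODINGS:
            raise ConfigError(f"unknown coding {self.coding!r} for {self.id}")
        if not np.isfinite(self.coefficient):
            raise ConfigError(f"non-finite coefficient for {self.id}")


class GenotypeMatrix:
    """Subjects x SNPs genotype codes with per-SNP metadata.

    Genotypes count copies of the minor allele: values in {0, 1, 2} with
    ``NaN`` for missing calls.
    """

    def __init__(
        self,
        subject_ids: Sequence[str],
        snps: pd.DataFrame,
        data: np.ndarray,
    ) -> None:
        data = np.asarray(data, dtype=float)
        if data.ndim != 2:
            raise StructuralError("genotype data must be 2-D (subjects x snps)")
        if data.shape != (len(subject_ids), len(snps)):
            raise StructuralError(
                f"genotype shape {data.shape} does not match "
                f"{len(subject_ids)} subjects x {len(snps)} snps"
            )
        valid = np.isnan(data) | np.isin(data, (0.0, 1.0, 2.0))
        if not valid.all():
            raise DataError("genotype codes must be 0, 1, 2 or missing")
        for col in ("ref", "alt", "coding"):
            if col not in snps.columns:
                raise StructuralError(f"snp metadata missing column {col!r}")
        self.subject_ids = np.asarray(subject_ids, dtype=object)
        self.snps = snps.copy()
        self.data = data

    # -- basic geometry ------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_snps(self) -> int:
        return self.data.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps.index)

    def column(self, snp_id: str) -> np.ndarray:
        j = self.snps.index.get_loc(snp_id)
        return self.data[:, j]

    # -- per-SNP summaries ---------------------------------------------
    def call_rate(self) -> pd.Series:
        rate = 1.0 - np.isnan(self.data).mean(axis=0)
        return pd.Series(rate, index=self.snps.index, name="call_rate")

    def minor_allele_frequency(self) -> pd.Series:
        """Frequency of the coded (minor) allele among non-missing calls.

        May exceed 0.5 after subsetting; callers that need the folded MAF
        should take ``min(f, 1 - f)``.
        """
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.data, axis=0) / 2.0
        return pd.Series(freq, index=self.snps.index, name="maf")

    # -- subsetting ----------------------------------------------------
    def subset(
        self,
        subjects: Iterable[str] | np.ndarray | None = None,
        snps: Iterable[str] | None = None,
    ) -> "GenotypeMatrix":
        rows = np.arange(self.n_subjects)
        if subjects is not None:
            wanted = list(subjects)
            pos = {s: i for i, s in enumerate(self.subject_ids)}
            rows = np.array([pos[s] for s in wanted], dtype=int)
        meta = self.snps
        cols = np.arange(self.n_snps)
        if snps is not None:
            snps = list(snps)
            cols = np.array([self.snps.index.get_loc(s) for s in snps], dtype=int)
            meta = self.snps.iloc[cols]
        return GenotypeMatrix(self.subject_ids[rows], meta, self.data[np.ix_(rows, cols)])


def _join_days(days: Iterable[float]) -> str:
    return ";".join(f"{d:g}" for d in days)


def _split_days(text: object) -> list[float]:
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return []
    text = str(text).strip()
    if not text:
        return []
    return [float(tok) for tok in text.split(";")]


def _join_series(series: Iterable[tuple[float, float]]) -> str:
    return ";".join(f"{d:g}:{s:g}" for d, s in series)


def _split_series(text: object) -> list[tuple[float, float]]:
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return []
    text = str(text).strip()
    if not text:
        return []
    out = []
    for tok in text.split(";"):
        d, s = tok.split(":")
        out.append((float(d), float(s)))
    return out


class ClinicalTable:
    """Per-subject trial phenotype table (see :data:`CLINICAL_COLUMNS`)."""

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise StructuralError(f"clinical table missing columns: {missing}")
        self.df = df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        if df["subject_id"].duplicated().any():
            raise StructuralError("duplicate subject ids")
        if (df["pre_study_relapses"] < 0).any():
            raise DataError("negative pre-study relapse count")
        if (df["history_years"] < 0).any():
            raise DataError("negative history years")
        if (df["exposure_years"] <= 0).any():
            raise DataError("exposure must be positive")
        for days in df["on_study_relapse_days"]:
            if any(d < 0 for d in days):
                raise DataError("negative relapse day")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.df["subject_id"])

    def to_csv(self, path: str) -> None:
        out = self.df.copy()
        out["on_study_relapse_days"] = out["on_study_relapse_days"].map(_join_days)
        out["edss_series"] = out["edss_series"].map(_join_series)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "ClinicalTable":
        df = pd.read_csv(path, dtype={"subject_id": str})
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise StructuralError(f"clinical CSV missing columns: {missing}")
        df["on_study_relapse_days"] = df["on_study_relapse_days"].map(_split_days)
        df["edss_series"] = df["edss_series"].map(_split_series)
        return cls(df)


@dataclass
class SignatureModel:
    """Final multi-SNP logistic model plus its classification threshold."""

    snp_ids: list[str]
    codings: list[str]
    coefficients: list[float]
    intercept: float
    coef_ci: list[tuple[float, float]] = field(default_factory=list)
    threshold: float | None = None
    separated: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def odds_ratios(self) -> list[float]:
        return [float(np.exp(b)) for b in self.coefficients]

    @property
    def odds_ratio_ci(self) -> list[tuple[float, float]]:
        return [(float(np.exp(lo)), float(np.exp(hi))) for lo, hi in self.coef_ci]

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "snp_ids": self.snp_ids,
            "codings": self.codings,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "coef_ci": [list(ci) for ci in self.coef_ci],
            "odds_ratios": self.odds_ratios,
            "odds_ratio_ci": [list(ci) for ci in self.odds_ratio_ci],
            "threshold": self.threshold,
            "separated": self.separated,
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str) -> "SignatureModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            snp_ids=payload["snp_ids"],
            codings=payload["codings"],
            coefficients=payload["coefficients"],
            intercept=payload["intercept"],
            coef_ci=[tuple(ci) for ci in payload["coef_ci"]],
            threshold=payload["threshold"],
            separated=payload.get("separated", False),
            meta=payload.get("meta", {}),
        )
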