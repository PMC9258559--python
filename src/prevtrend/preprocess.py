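"""Logit-scale transformation and covariate encoding.

Observed prevalences are modelled on the logit scale.  Each record's
known sampling standard error (SSE, proportion scale) is carried to the
logit scale by the first-order delta method, zero (and optionally unit)
prevalences are replaced by a limit-of-detection value 1/(2n), and
missing SSEs are imputed from a design-effect-inflated binomial SE.
Partial age intervals are encoded as fractional-overlap weights over the
six standard partitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    STANDARD_PARTITIONS,
    AgeInterval,
    Income,
    PrevalenceRecord,
    Sex,
)

__all__ = [
    "PreprocessConfig",
    "DesignMatrix",
    "lod_substitute",
    "logit",
    "inverse_logit",
    "logit_se",
    "impute_sse",
    "age_partition_weights",
    "encode_sex",
    "encode_income",
    "build_design",
]

AGE_WEIGHT_COLUMNS = [f"age_w{k}" for k in range(1, 7)]
#: Fixed-effect age columns: partitions 2..6, with 0–5 mo the reference.
AGE_COVARIATE_COLUMNS = AGE_WEIGHT_COLUMNS[1:]


@dataclass(frozen=True)
class PreprocessConfig:
    """Options controlling the record → design-row transformation.

    deff
        Design-effect multiplier used when imputing a missing SSE as
        sqrt(deff · p(1−p)/n); 2 is a conventional value for cluster
        surveys.
    study_start_year, study_end_year
        Calendar window of the analysis; time enters the model as
        ``t = year − study_start_year`` (years).
    lod_symmetric
        Also replace prevalence exactly 1 with 1 − 1/(2n).
    """

    deff: float = 2.0
    study_start_year: int = 1990
    study_end_year: int = 2020
    lod_symmetric: bool = True

    def __post_init__(self) -> None:
        if self.deff < 1:
            raise ValueError("deff must be >= 1")
        if self.study_start_year >= self.study_end_year:
            raise ValueError("study_start_year must precede study_end_year")


def lod_substitute(
    prevalence: float, sample_size: int | None, lod_symmetric: bool = True
) -> float:
    """Replace boundary prevalences with a limit-of-detection value.

    A recorded prevalence of exactly 0 is treated as "below detection"
    and replaced with 1/(2n), n the unweighted sample size; with
    ``lod_symmetric`` a prevalence of exactly 1 becomes 1 − 1/(2n).
    Interior prevalences pass through unchanged.
    """
    if prevalence == 0.0:
        if sample_size is None:
            raise ValueError(
                "prevalence 0 with missing sample size cannot be logit-transformed"
            )
        return 1.0 / (2.0 * sample_size)
    if prevalence == 1.0 and lod_symmetric:
        if sample_size is None:
            raise ValueError(
                "prevalence 1 with missing sample size cannot be logit-transformed"
            )
        return 1.0 - 1.0 / (2.0 * sample_size)
    return prevalence


def logit(p: float) -> float:
    """log(p/(1−p)) for p strictly inside (0, 1)."""
    if not 0.0 < p < 1.0:
        raise ValueError(
            f"logit undefined at p={p}; apply limit-of-detection substitution first"
        )
    return math.log(p / (1.0 - p))


def inverse_logit(x):
    """Numerically stable expit, accepting scalars or arrays."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def logit_se(p: float, sse: float) -> float:
    """Delta-method SE of logit(p̂): sse / (p(1−p))."""
    if sse < 0:
        raise ValueError("sse must be nonnegative")
    if not 0.0 < p < 1.0:
        raise ValueError("logit_se requires p in (0, 1)")
    return sse / (p * (1.0 - p))


def impute_sse(p: float, sample_size: int, deff: float = 2.0) -> float:
    """Design-effect-inflated binomial SE: sqrt(deff · p(1−p)/n)."""
    if sample_size is None or sample_size <= 0:
        raise ValueError("impute_sse requires a positive sample size")
    if deff < 1:
        raise ValueError("deff must be >= 1")
    return math.sqrt(deff * p * (1.0 - p) / sample_size)


def age_partition_weights(age: AgeInterval) -> np.ndarray:
    """Fractional overlap of an age interval with the 6 standard partitions.

    weight_k = overlap(interval, partition_k) / length(interval); the
    six weights sum to 1 for any interval inside [0, 60).
    """
    w = np.array(
        [age.overlap_months(part) for part in STANDARD_PARTITIONS], dtype=float
    )
    return w / age.length


def encode_sex(sex: Sex) -> float:
    """Effect coding: male +0.5, female −0.5, both-sexes 0.

    A combined-sex stratum sits exactly at the mean of the two sexes, so
    no row duplication is needed for both-sex records.
    """
    return {Sex.MALE: 0.5, Sex.FEMALE: -0.5, Sex.BOTH: 0.0}[sex]


def encode_income(income: Income) -> float:
    """Indicator coding: LMIC 1, HIC 0."""
    return 1.0 if income is Income.LMIC else 0.0


@dataclass
class DesignMatrix:
    """Logit-scale outcomes, known SEs and encoded covariates.

    ``table`` has one row per record with columns: country_id,
    source_id, year, t, y (logit prevalence), s (logit-scale SE),
    age_w1..age_w6, sex_code, income_code, lod_applied, sse_imputed.
    """

    table: pd.DataFrame
    config: PreprocessConfig

    @property
    def n_obs(self) -> int:
        return len(self.table)

    @property
    def y(self) -> np.ndarray:
        return self.table["y"].to_numpy()

    @property
    def s(self) -> np.ndarray:
        return self.table["s"].to_numpy()

    @property
    def years(self) -> np.ndarray:
        return self.table["year"].to_numpy(dtype=float)

    @property
    def country_ids(self) -> list[str]:
        return sorted(self.table["country_id"].unique())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _design_row(rec: PrevalenceRecord, config: PreprocessConfig) -> dict:
    p = rec.prevalence
    lod = p in (0.0, 1.0)
    p = lod_substitute(p, rec.sample_size, config.lod_symmetric)
    if not 0.0 < p < 1.0:
        raise ValueError(
            f"record {rec.source_id}/{rec.country_id}: prevalence {rec.prevalence} "
            "not transformable (enable lod_symmetric or fix the record)"
        )
    imputed = rec.sse is None
    if imputed:
        if rec.sample_size is None:
            raise ValueError(
                f"record {rec.source_id}/{rec.country_id}: both sse and sample "
                "size missing; should have been excluded"
            )
        sse = impute_sse(p, rec.sample_size, config.deff)
    else:
        sse = rec.sse
    w = age_partition_weights(rec.age)
    row = {
        "country_id": rec.country_id,
        "source_id": rec.source_id,
        "year": rec.year,
        "t": float(rec.year - config.study_start_year),
        "age_start_m": rec.age.start_month,
        "age_end_m": rec.age.end_month,
        "sex": rec.sex.value,
        "y": logit(p),
        "s": logit_se(p, sse),
        "sex_code": encode_sex(rec.sex),
        "income_code": encode_income(rec.income),
        "prevalence": rec.prevalence,
        "lod_applied": lod,
        "sse_imputed": imputed,
    }
    for name, wk in zip(AGE_WEIGHT_COLUMNS, w):
        row[name] = wk
    return row


def build_design(
    records: list[PrevalenceRecord], config: PreprocessConfig | None = None
) -> DesignMatrix:
    """Transform validated, inclusion-filtered records to a design matrix.

    Per record: limit-of-detection substitution, SSE imputation where
    missing, logit transform of the prevalence, delta-method transfer of
    the SSE to the logit scale, and covariate encoding (six age-partition
    weights, effect-coded sex, LMIC indicator).
    """
    config = config or PreprocessConfig()
    rows = [_design_row(r, config) for r in records]
    cols = [
        "country_id", "source_id", "year", "t", "age_start_m", "age_end_m",
        "sex", "y", "s", *AGE_WEIGHT_COLUMNS, "sex_code", "income_code",
        "prevalence", "lod_applied", "sse_imputed",
    ]
    table = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    for yr in table["year"]:
        if not (config.study_start_year <= yr <= config.study_end_year):
            raise ValueError(
                f"survey year {yr} outside study window "
                f"[{config.study_start_year}, {config.study_end_year}]"
            )
    return DesignMatrix(table=table, config=config)
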