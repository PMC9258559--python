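"""Survey prevalence records: types, CSV I/O, inclusion rules, summaries.

The unit of observation is one prevalence estimate for one country ×
survey × sex stratum × age interval.  Age intervals are stored half-open
in completed months, so the conventional "0–5 mo" age group is ``[0, 6)``
and the complete under-five range is ``[0, 60)``.  The six standard age
partitions used throughout the package are 0–5, 6–11, 12–23, 24–35,
36–47 and 48–59 months.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "STANDARD_PARTITIONS",
    "PARTITION_LABELS",
    "COMPLETE_INTERVAL",
    "CSV_COLUMNS",
    "Sex",
    "Income",
    "Indicator",
    "AgeInterval",
    "PrevalenceRecord",
    "SchemaOptions",
    "ValidationError",
    "read_prevalence_csv",
    "write_prevalence_csv",
    "apply_exclusion_rules",
    "summarize_dataset",
    "age_group_label",
]

#: The six standard age partitions, half-open months.
STANDARD_PARTITIONS: tuple[tuple[int, int], ...] = (
    (0, 6),
    (6, 12),
    (12, 24),
    (24, 36),
    (36, 48),
    (48, 60),
)

PARTITION_LABELS: tuple[str, ...] = (
    "0-5",
    "6-11",
    "12-23",
    "24-35",
    "36-47",
    "48-59",
)

COMPLETE_INTERVAL: tuple[int, int] = (0, 60)

CSV_COLUMNS = [
    "country_id",
    "source_id",
    "year",
    "age_start_m",
    "age_end_m",
    "sex",
    "prevalence",
    "sse",
    "n",
    "income",
    "indicator",
]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    BOTH = "both"


class Income(str, enum.Enum):
    LMIC = "LMIC"
    HIC = "HIC"


class Indicator(str, enum.Enum):
    STUNTING = "stunting"
    OVERWEIGHT = "overweight"


class ValidationError(ValueError):
    """Raised when rows of an input table violate the record contract.

    ``errors`` is a list of ``(row_number, field, message)`` tuples;
    row numbers are 1-based positions in the data section of the file.
    """

    def __init__(self, errors: list[tuple[int, str, str]]):
        self.errors = errors
        lines = "; ".join(f"row {r}: {f}: {m}" for r, f, m in errors[:20])
        extra = "" if len(errors) <= 20 else f" (+{len(errors) - 20} more)"
        super().__init__(f"{len(errors)} invalid row(s): {lines}{extra}")


@dataclass(frozen=True)
class AgeInterval:
    """Half-open age interval in completed months, within [0, 60)."""

    start_month: int
    end_month: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_month < self.end_month <= 60):
            raise ValueError(
                f"invalid age interval [{self.start_month}, {self.end_month}): "
                "require 0 <= start < end <= 60"
            )

    @property
    def length(self) -> int:
        return self.end_month - self.start_month

    def overlap_months(self, other: tuple[int, int]) -> int:
        """Months of overlap with another half-open interval."""
        lo = max(self.start_month, other[0])
        hi = min(self.end_month, other[1])
        return max(0, hi - lo)


@dataclass(frozen=True)
class PrevalenceRecord:
    """One observed prevalence estimate with its stratification and uncertainty."""

    country_id: str
    source_id: str
    year: int
    age: AgeInterval
    sex: Sex
    prevalence: float
    sse: float | None  # sampling SE on the proportion scale, None = missing
    sample_size: int | None  # unweighted n, None = missing
    income: Income
    indicator: Indicator = Indicator.STUNTING

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError(f"prevalence {self.prevalence} outside [0, 1]")
        if self.sse is not None and self.sse < 0:
            raise ValueError(f"sse {self.sse} must be nonnegative")
        if self.sample_size is not None and self.sample_size <= 0:
            raise ValueError(f"sample_size {self.sample_size} must be positive")


@dataclass(frozen=True)
class SchemaOptions:
    """CSV dialect options for :func:`read_prevalence_csv`."""

    delimiter: str = ","
    missing_tokens: tuple[str, ...] = ("", "NA", "NaN", "nan")


def _parse_row(
    row: dict[str, str], rownum: int, opts: SchemaOptions,
    errors: list[tuple[int, str, str]],
) -> PrevalenceRecord | None:
    def missing(tok: str) -> bool:
        return tok.strip() in opts.missing_tokens

    problems_before = len(errors)

    def get_float(name: str, optional: bool = False) -> float | None:
        tok = row.get(name, "")
        if missing(tok):
            if optional:
                return None
            errors.append((rownum, name, "missing required value"))
            return None
        try:
            return float(tok)
        except ValueError:
            errors.append((rownum, name, f"not a number: {tok!r}"))
            return None

    def get_int(name: str, optional: bool = False) -> int | None:
        v = get_float(name, optional)
        if v is None:
            return None
        if v != int(v):
            errors.append((rownum, name, f"not an integer: {v}"))
            return None
        return int(v)

    year = get_int("year")
    a0 = get_int("age_start_m")
    a1 = get_int("age_end_m")
    prev = get_float("prevalence")
    sse = get_float("sse", optional=True)
    n = get_int("n", optional=True)

    sex_tok = row.get("sex", "").strip().lower()
    try:
        sex = Sex(sex_tok)
    except ValueError:
        errors.append((rownum, "sex", f"unknown sex token {row.get('sex')!r}"))
        sex = None
    inc_tok = row.get("income", "").strip().upper()
    try:
        income = Income(inc_tok)
    except ValueError:
        errors.append((rownum, "income", f"unknown income token {row.get('income')!r}"))
        income = None
    ind_tok = row.get("indicator", "").strip().lower() or "stunting"
    try:
        indicator = Indicator(ind_tok)
    except ValueError:
        errors.append((rownum, "indicator", f"unknown indicator {row.get('indicator')!r}"))
        indicator = None

    age = None
    if a0 is not None and a1 is not None:
        try:
            age = AgeInterval(a0, a1)
        except ValueError as e:
            errors.append((rownum, "age_end_m", str(e)))
    if prev is not None and not (0.0 <= prev <= 1.0):
        errors.append((rownum, "prevalence", f"value {prev} outside [0, 1]"))
    if sse is not None and sse < 0:
        errors.append((rownum, "sse", f"value {sse} is negative"))
    if n is not None and n <= 0:
        errors.append((rownum, "n", f"value {n} is not positive"))

    if len(errors) > problems_before:
        return None
    assert year is not None and age is not None and prev is not None
    assert sex is not None and income is not None and indicator is not None
    return PrevalenceRecord(
        country_id=row["country_id"].strip(),
        source_id=row["source_id"].strip(),
        year=year,
        age=age,
        sex=sex,
        prevalence=prev,
        sse=sse,
        sample_size=n,
        income=income,
        indicator=indicator,
    )


def read_prevalence_csv(
    path, schema_options: SchemaOptions | None = None
) -> list[PrevalenceRecord]:
    """Read a flat survey-prevalence table into validated records.

    Raises :class:`ValidationError` listing every bad row/field; raises
    ``OSError`` for unreadable files and ``ValueError`` for a missing or
    malformed header.
    """
    opts = schema_options or SchemaOptions()
    records: list[PrevalenceRecord] = []
    errors: list[tuple[int, str, str]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=opts.delimiter)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, no header row")
        missing_cols = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing_cols:
            raise ValueError(f"{path}: header missing columns {missing_cols}")
        for i, row in enumerate(reader, start=1):
            rec = _parse_row(row, i, opts, errors)
            if rec is not None:
                records.append(rec)
    if errors:
        raise ValidationError(errors)
    return records


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_prevalence_csv(records: Iterable[PrevalenceRecord], path) -> None:
    """Write records in the canonical CSV dialect (lossless round-trip)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.country_id,
                    r.source_id,
                    r.year,
                    r.age.start_month,
                    r.age.end_month,
                    r.sex.value,
                    _fmt(r.prevalence),
                    _fmt(r.sse),
                    _fmt(r.sample_size),
                    r.income.value,
                    r.indicator.value,
                ]
            )


def apply_exclusion_rules(
    records: Sequence[PrevalenceRecord],
) -> tuple[list[PrevalenceRecord], list[tuple[PrevalenceRecord, str]]]:
    """Partition records into (kept, excluded-with-reason).

    A record is excluded only when *both* its sampling standard error and
    its sample size are missing: such a record has no usable uncertainty
    and no way to impute one.  Records missing only the SSE are kept (the
    SSE is imputed downstream from the sample size).
    """
    kept: list[PrevalenceRecord] = []
    excluded: list[tuple[PrevalenceRecord, str]] = []
    for r in records:
        if r.sse is None and r.sample_size is None:
            excluded.append((r, "missing both sse and sample_size"))
        else:
            kept.append(r)
    return kept, excluded


def age_group_label(age: AgeInterval) -> str:
    """Classify an interval as one standard partition, '0-59', or 'other'."""
    key = (age.start_month, age.end_month)
    if key == COMPLETE_INTERVAL:
        return "0-59"
    for part, label in zip(STANDARD_PARTITIONS, PARTITION_LABELS):
        if key == part:
            return label
    return "other"


def summarize_dataset(
    records: Sequence[PrevalenceRecord], strata: str = "sex"
) -> pd.DataFrame:
    """Summary statistics of prevalence by age group × sex or × income.

    Returns a table with one row per (age_group, stratum) cell holding
    n, mean, sd, min and max of prevalence on the proportion scale.  Age
    groups are the six standard partitions, the complete 0–59 interval,
    and 'other' for nonstandard partial intervals.
    """
    if not records:
        raise ValueError("cannot summarize an empty record list")
    if strata not in ("sex", "income"):
        raise ValueError(f"strata must be 'sex' or 'income', got {strata!r}")
    rows = []
    for r in records:
        rows.append(
            {
                "age_group": age_group_label(r.age),
                "stratum": (r.sex if strata == "sex" else r.income).value,
                "prevalence": r.prevalence,
            }
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["age_group", "stratum"])["prevalence"]
        .agg(n="size", mean="mean", sd="std", min="min", max="max")
        .reset_index()
    )
    order = ["0-59", *PARTITION_LABELS, "other"]
    out["age_group"] = pd.Categorical(out["age_group"], categories=order, ordered=True)
    return out.sort_values(["age_group", "stratum"]).reset_index(drop=True)
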