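"""Shared fixtures: tiny deterministic designs and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("prevtrend", deadline=None, derandomize=True)
settings.load_profile("prevtrend")

from prevtrend.data_model import (
    STANDARD_PARTITIONS,
    AgeInterval,
    Income,
    PrevalenceRecord,
    Sex,
)
from prevtrend.model import ModelSpec, _ModelMatrices, fit
from prevtrend.preprocess import build_design
from prevtrend.synthetic import SimConfig, generate

# each standard partition appears in two countries, so the age columns
# cannot reconstruct country (hence income) indicators
_TINY_ALLOC = (
    ("C0", 1995, Income.LMIC, (0, 1, 2, 3)),
    ("C1", 2004, Income.LMIC, (2, 3, 4, 5)),
    ("C2", 2012, Income.HIC, (4, 5, 0, 1)),
)


def make_tiny_records(rng: np.random.Generator) -> list[PrevalenceRecord]:
    """12 records, 3 countries, full-rank fixed-effect design."""
    sexes = (Sex.MALE, Sex.FEMALE, Sex.BOTH)
    for _ in range(50):
        recs = []
        for country, year, income, parts in _TINY_ALLOC:
            for j, pi in enumerate(parts):
                a0, a1 = STANDARD_PARTITIONS[pi]
                recs.append(
                    PrevalenceRecord(
                        country_id=country,
                        source_id=f"{country}-s",
                        year=year,
                        age=AgeInterval(a0, a1),
                        sex=sexes[rng.integers(0, 3)],
                        prevalence=float(rng.uniform(0.05, 0.4)),
                        sse=float(rng.uniform(0.005, 0.03)),
                        sample_size=1000,
                        income=income,
                    )
                )
        design = build_design(recs)
        mm = _ModelMatrices(design, ModelSpec(n_country_splines=1, knot_spacing_years=10.0))
        if np.linalg.matrix_rank(mm.X) == mm.X.shape[1]:
            return recs
    raise RuntimeError("could not draw a full-rank tiny design")


def make_two_country_records(seed: int = 3) -> list[PrevalenceRecord]:
    """Richer 48-row, 2-country dataset for prediction-variance checks."""
    rng = np.random.default_rng(seed)
    recs = []
    for c, inc in (("A", Income.LMIC), ("B", Income.HIC)):
        for yi, yr in enumerate((1994, 2001, 2009, 2016)):
            for j, pi in enumerate((0, 2, 4, 1, 3, 5)):
                a0, a1 = STANDARD_PARTITIONS[pi]
                recs.append(
                    PrevalenceRecord(
                        country_id=c,
                        source_id=f"{c}-{yr}",
                        year=yr,
                        age=AgeInterval(a0, a1),
                        sex=(Sex.MALE, Sex.FEMALE, Sex.BOTH)[(j + yi) % 3],
                        prevalence=float(rng.uniform(0.05, 0.4)),
                        sse=float(rng.uniform(0.005, 0.03)),
                        sample_size=1000,
                        income=inc,
                    )
                )
    return recs


@pytest.fixture(scope="session")
def small_sim():
    """A 12-country synthetic dataset with its truth (sized for speed)."""
    cfg = SimConfig(
        n_countries=12,
        surveys_per_country_mean=3.0,
        p_partition_both=0.7,
        p_partition_sex=0.5,
        p_nonstandard=0.3,
        seed=421,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """REML fit of the generating specification on the small dataset."""
    records, _ = small_sim
    design = build_design(records)
    return fit(design, ModelSpec()), design
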