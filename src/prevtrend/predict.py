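"""Country-year prevalence predictions with confidence and prediction intervals.

Point predictions combine the fixed-effect profile (age weights, sex,
income), the population P-spline trend, and the country's BLUP when the
country contributed data.  Logit-scale variances account for fixed-
effect uncertainty, population-spline uncertainty and the conditional
(or, for data-free countries, prior) variance of the country effects,
with all cross-covariances.  Intervals are built on the logit scale and
mapped endpoint-wise through the inverse logit, which keeps them inside
[0, 1] and preserves their ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import AgeInterval, Sex
from .model import FittedModel
from .preprocess import age_partition_weights, encode_sex, inverse_logit
from .splines import basis_of_dimension, bspline_basis

__all__ = [
    "PredictionRequest",
    "TrendEstimate",
    "Z_95",
    "predict_point",
    "intervals",
    "predict_trends",
]

Z_95 = 1.959964  # standard normal 97.5% quantile


@dataclass(frozen=True)
class PredictionRequest:
    country_id: str
    years: tuple[float, ...]
    age: AgeInterval = AgeInterval(0, 60)
    sex: Sex = Sex.BOTH
    use_blup: bool = True
    income_code: float | None = None  # required only for countries absent from the fit
    extra_variance: float = 0.0  # optional survey sampling variance added to the PI


@dataclass
class TrendEstimate:
    """Per-year estimates on both scales; intervals at the 95% level."""

    country_id: str
    years: np.ndarray
    logit_estimate: np.ndarray
    logit_se_ci: np.ndarray
    sigma2_resid: float
    estimate: np.ndarray = field(init=False)
    ci_low: np.ndarray = field(init=False)
    ci_high: np.ndarray = field(init=False)
    pi_low: np.ndarray = field(init=False)
    pi_high: np.ndarray = field(init=False)
    extra_variance: float = 0.0

    def __post_init__(self) -> None:
        est, lo, hi, plo, phi = intervals(
            self.logit_estimate, self.logit_se_ci, self.sigma2_resid,
            extra_variance=self.extra_variance,
        )
        self.estimate, self.ci_low, self.ci_high = est, lo, hi
        self.pi_low, self.pi_high = plo, phi


def intervals(
    logit_estimate,
    logit_se_ci,
    sigma2_resid: float,
    level: float = 0.95,
    extra_variance: float = 0.0,
):
    """95% CI and PI on the proportion scale.

    CI = expit(est ± z·se); PI widens the SE by the residual variance
    σ²_e (plus any user-supplied survey sampling variance), targeting a
    new observation rather than the latent trend.
    """
    if level != 0.95:
        from scipy.stats import norm

        z = float(norm.ppf(0.5 + level / 2.0))
    else:
        z = Z_95
    est = np.asarray(logit_estimate, dtype=float)
    se = np.asarray(logit_se_ci, dtype=float)
    if np.any(se < 0):
        raise ValueError("standard errors must be nonnegative")
    se_pi = np.sqrt(se**2 + sigma2_resid + extra_variance)
    return (
        inverse_logit(est),
        inverse_logit(est - z * se),
        inverse_logit(est + z * se),
        inverse_logit(est - z * se_pi),
        inverse_logit(est + z * se_pi),
    )


def _fixed_row(fit: FittedModel, u: float, age: AgeInterval, sex: Sex,
               income_code: float) -> np.ndarray:
    w = age_partition_weights(age)
    row = [1.0, u, *w[1:], encode_sex(sex), income_code]
    if fit.spec.include_income_time_interaction:
        row.append(income_code * u)
    return np.asarray(row, dtype=float)


def predict_point(fit: FittedModel, request: PredictionRequest) -> TrendEstimate:
    """Logit-scale point prediction and SE for one country profile.

    For a country present in the fit (and ``use_blup``), the estimate
    conditions on that country's data through its BLUP and the SE uses
    the conditional covariance of the prediction error.  For an unknown
    country the prediction falls back to the population curve for its
    income class, with the full prior country variance added.
    """
    years = np.asarray(request.years, dtype=float)
    start, end = fit.study_start_year, fit.study_end_year
    if np.any(years < start) or np.any(years > end):
        raise ValueError(f"prediction years outside spline domain [{start}, {end}]")
    span = end - start
    u = (years - start) / span

    known = request.country_id in fit.countries
    if known:
        income = fit.income_by_country[request.country_id]
    elif request.income_code is not None:
        income = float(request.income_code)
    else:
        raise ValueError(
            f"country {request.country_id!r} not in fit; supply income_code"
        )
    use_blup = request.use_blup and known
    if request.use_blup and not known:
        warnings.warn(
            f"country {request.country_id!r} has no data; using population-level "
            "prediction with prior country-effect variance",
            stacklevel=2,
        )

    B = bspline_basis(years, fit.pop_knots)
    Zpop = B @ fit.T_pop  # n_years × r
    d = fit.country_dim
    zc_cols = [np.ones(len(years))]
    if fit.q > 0:
        zc_cols.append(basis_of_dimension(years, fit.q, start, end))
    Zc = np.column_stack(zc_cols)  # n_years × d

    r = fit.r_pop
    m = fit.C1.shape[0]
    ests = np.empty(len(years))
    ses = np.empty(len(years))
    blk = fit.country_block(request.country_id) if known else None
    sigma2_a = fit.sigma2_spline
    for j in range(len(years)):
        x = _fixed_row(fit, u[j], request.age, request.sex, income)
        ustar = np.zeros(m)
        ustar[:r] = Zpop[j]
        est = float(x @ fit.beta + Zpop[j] @ fit.gamma_pop)
        prior = sigma2_a * float(Zpop[j] @ Zpop[j])
        if use_blup:
            ustar[blk] = Zc[j]
            est += float(Zc[j] @ fit.blups[request.country_id])
            prior += float(Zc[j] @ fit.G @ Zc[j])
        # Var(f̂ − f) = u*ᵀΣu* − u*ᵀC1u* + dᵀC3d with d = x − C2u*
        var = prior - float(ustar @ fit.C1 @ ustar)
        dvec = x - fit.C2 @ ustar
        var += float(dvec @ fit.C3 @ dvec)
        if not use_blup:
            # data-free country: prior country-effect variance on top
            var += float(Zc[j] @ fit.G @ Zc[j])
        ests[j] = est
        ses[j] = np.sqrt(max(var, 0.0))
    return TrendEstimate(
        country_id=request.country_id,
        years=years,
        logit_estimate=ests,
        logit_se_ci=ses,
        sigma2_resid=fit.sigma2_resid,
        extra_variance=request.extra_variance,
    )


def predict_trends(
    fit: FittedModel,
    countries: list[str] | None = None,
    year_grid: list[float] | None = None,
    age: AgeInterval = AgeInterval(0, 60),
    sex: Sex = Sex.BOTH,
) -> pd.DataFrame:
    """Trend table for many countries over a year grid (default profile:
    complete 0–59 mo interval, sexes combined)."""
    countries = countries if countries is not None else fit.countries
    if year_grid is None:
        year_grid = list(
            np.arange(fit.study_start_year, fit.study_end_year + 1.0)
        )
    rows = []
    for c in countries:
        tr = predict_point(fit, PredictionRequest(country_id=c, years=tuple(year_grid),
                                                  age=age, sex=sex))
        for j, yr in enumerate(tr.years):
            rows.append({
                "country_id": c,
                "year": yr,
                "age_start_m": age.start_month,
                "age_end_m": age.end_month,
                "sex": sex.value,
                "estimate": tr.estimate[j],
                "ci_low": tr.ci_low[j],
                "ci_high": tr.ci_high[j],
                "pi_low": tr.pi_low[j],
                "pi_high": tr.pi_high[j],
            })
    return pd.DataFrame(rows)


def write_predictions_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for c in ("estimate", "ci_low", "ci_high", "pi_low", "pi_high"):
        out[c] = out[c].map(lambda v: f"{v:.6f}")
    out.to_csv(path, index=False)
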