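"""Survey-level k-fold cross-validation and its metric suite.

Surveys (sources), not individual records, are the sampling unit of the
split: every record of a held-out survey is predicted by a model that
never saw any record from that survey, though it may condition on the
country's *other* surveys through the BLUP.  Metrics — coverage of 95%
prediction intervals, average/median bias, MSE, RMSE, MAD — are
computed per fold on the proportion scale and averaged across folds.
Prediction intervals for held-out records include the record's own
sampling variance, since an observed survey estimate carries both
model residual and sampling noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import PrevalenceRecord, age_group_label, PARTITION_LABELS
from .model import ConvergenceError, FittedModel, ModelSpec, fit as fit_model
from .predict import PredictionRequest, predict_point
from .preprocess import PreprocessConfig, build_design

__all__ = [
    "FoldAssignment",
    "CVResult",
    "kfold_split",
    "cv_metrics",
    "cross_validate",
    "errors_by_age_group",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Survey → fold mapping; all records of a survey share one fold."""

    folds: dict[str, int]  # source_id -> fold in 1..k
    k: int
    seed: int

    def fold_of(self, source_id: str) -> int:
        return self.folds[source_id]


def kfold_split(records: list[PrevalenceRecord], k: int, seed: int) -> FoldAssignment:
    """Shuffle the distinct sources with `seed` and deal them round-robin."""
    sources = sorted({r.source_id for r in records})
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(sources) < k:
        raise ValueError(f"k={k} exceeds the {len(sources)} distinct sources")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sources))
    folds = {sources[j]: (pos % k) + 1 for pos, j in enumerate(order)}
    return FoldAssignment(folds=folds, k=k, seed=seed)


def cv_metrics(pred, obs, pi_low, pi_high) -> dict[str, float]:
    """Proportion-scale prediction metrics for one set of held-out records."""
    pred, obs = np.asarray(pred, float), np.asarray(obs, float)
    pi_low, pi_high = np.asarray(pi_low, float), np.asarray(pi_high, float)
    if not (len(pred) == len(obs) == len(pi_low) == len(pi_high)) or len(pred) == 0:
        raise ValueError("metric inputs must be equal-length and nonempty")
    err = pred - obs
    mse = float(np.mean(err**2))
    return {
        "coverage": float(np.mean((pi_low <= obs) & (obs <= pi_high))),
        "average_bias": float(np.mean(err)),
        "median_bias": float(np.median(err)),
        "mse": mse,
        "rmse": float(np.sqrt(mse)),
        "mad": float(np.median(np.abs(err))),
        "n": float(len(err)),
    }


METRIC_KEYS = ["coverage", "average_bias", "median_bias", "mse", "rmse", "mad"]


@dataclass
class AgeGroupReport:
    """Fold-level RMSE/MAD summaries per age group plus a one-way ANOVA."""

    summary: pd.DataFrame  # age_group × metric: mean, sd, ci_low, ci_high, n_folds
    anova: dict[str, dict]  # metric -> {F, p, df_between, df_within} or {"skipped": reason}
    fold_values: pd.DataFrame  # fold × age_group × rmse/mad


@dataclass
class CVResult:
    assignment: FoldAssignment
    fold_metrics: pd.DataFrame  # one row per fold
    pooled: dict[str, float]  # fold-averaged metrics
    errors: pd.DataFrame  # one row per held-out record
    age_groups: AgeGroupReport | None
    failed_folds: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "k": self.assignment.k,
            "seed": self.assignment.seed,
            "pooled": self.pooled,
            "fold_metrics": self.fold_metrics.to_dict("records"),
            "failed_folds": self.failed_folds,
            "anova": self.age_groups.anova if self.age_groups else None,
        }


def _dominant_age_group(rec: PrevalenceRecord) -> str:
    """Partition carrying the record's largest age weight; ties → 'other'."""
    from .preprocess import age_partition_weights

    w = age_partition_weights(rec.age)
    top = np.flatnonzero(w == w.max())
    if len(top) > 1:
        return "other"
    return PARTITION_LABELS[top[0]]


def cross_validate(
    records: list[PrevalenceRecord],
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
    config: PreprocessConfig | None = None,
    include_survey_variance: bool = True,
    new_country_mode: bool = False,
) -> CVResult:
    """Survey-level k-fold cross-validation of one model specification.

    Per fold: refit on the k−1 training folds (REML, per ``spec``),
    predict each held-out record using its own covariate profile and
    the training-data BLUP for its country (unless ``new_country_mode``
    or the country has no training data), and score on the proportion
    scale.  Fold-level metrics are averaged for the pooled report; the
    per-record error table feeds the age-group analysis.
    """
    config = config or PreprocessConfig()
    assignment = kfold_split(records, k, seed)
    err_rows = []
    fold_rows = []
    failed = []
    for fold in range(1, k + 1):
        train = [r for r in records if assignment.fold_of(r.source_id) != fold]
        test = [r for r in records if assignment.fold_of(r.source_id) == fold]
        if not test:
            continue
        try:
            design = build_design(train, config)
            fitted = fit_model(design, spec)
        except (ConvergenceError, ValueError, np.linalg.LinAlgError) as e:
            warnings.warn(f"fold {fold} fit failed and is excluded: {e}", stacklevel=2)
            failed.append(fold)
            continue
        # design rows for the held-out records give their observed y/s
        test_design = build_design(test, config)
        ttab = test_design.table
        preds, obs, plo, phi = [], [], [], []
        for j, rec in enumerate(test):
            s2 = float(ttab["s"].iloc[j]) ** 2 if include_survey_variance else 0.0
            known = rec.country_id in fitted.countries
            req = PredictionRequest(
                country_id=rec.country_id,
                years=(float(rec.year),),
                age=rec.age,
                sex=rec.sex,
                use_blup=not new_country_mode,
                income_code=float(ttab["income_code"].iloc[j]),
                extra_variance=s2,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tr = predict_point(fitted, req)
            obs_p = float(ttab["prevalence"].iloc[j])
            # score against the analysable prevalence (LOD-substituted zeros)
            if ttab["lod_applied"].iloc[j]:
                obs_p = float(np.exp(ttab["y"].iloc[j]) / (1 + np.exp(ttab["y"].iloc[j])))
            preds.append(float(tr.estimate[0]))
            obs.append(obs_p)
            plo.append(float(tr.pi_low[0]))
            phi.append(float(tr.pi_high[0]))
            err_rows.append({
                "source_id": rec.source_id,
                "country_id": rec.country_id,
                "year": rec.year,
                "age_start_m": rec.age.start_month,
                "age_end_m": rec.age.end_month,
                "sex": rec.sex.value,
                "age_group": _dominant_age_group(rec),
                "obs": obs_p,
                "pred": preds[-1],
                "pi_low": plo[-1],
                "pi_high": phi[-1],
                "fold": fold,
                "used_blup": known and not new_country_mode,
            })
        mets = cv_metrics(preds, obs, plo, phi)
        mets["fold"] = fold
        fold_rows.append(mets)
    if not fold_rows:
        raise ConvergenceError("every cross-validation fold failed to fit")
    fold_metrics = pd.DataFrame(fold_rows)
    pooled = {m: float(fold_metrics[m].mean()) for m in METRIC_KEYS}
    pooled["rmse"] = float(np.sqrt(pooled["mse"]))  # keep RMSE² = MSE exact
    errors = pd.DataFrame(err_rows)
    age_report = errors_by_age_group(errors) if len(errors) else None
    return CVResult(
        assignment=assignment,
        fold_metrics=fold_metrics,
        pooled=pooled,
        errors=errors,
        age_groups=age_report,
        failed_folds=failed,
    )


def errors_by_age_group(errors: pd.DataFrame) -> AgeGroupReport:
    """Fold-level RMSE/MAD by age group, with a one-way ANOVA across groups.

    The fold is the replication unit: each (age group, fold) cell yields
    one RMSE and one MAD value; groups are compared by a one-way ANOVA
    F-test over those fold-level values.  Groups observed in fewer than
    two folds are excluded from the ANOVA (with a warning) but still
    summarized.
    """
    need = {"age_group", "fold", "obs", "pred"}
    if not need.issubset(errors.columns):
        raise ValueError(f"errors table needs columns {sorted(need)}")
    df = errors.copy()
    df["err"] = df["pred"] - df["obs"]
    cells = (
        df.groupby(["age_group", "fold"])["err"]
        .agg(rmse=lambda e: float(np.sqrt(np.mean(np.square(e)))),
             mad=lambda e: float(np.median(np.abs(e))))
        .reset_index()
    )
    rows = []
    for (grp,), sub in cells.groupby(["age_group"]):
        for metric in ("rmse", "mad"):
            v = sub[metric].to_numpy()
            mean = float(np.mean(v))
            sd = float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
            if len(v) > 1:
                half = stats.t.ppf(0.975, len(v) - 1) * sd / np.sqrt(len(v))
            else:
                half = float("nan")
            rows.append({
                "age_group": grp, "metric": metric, "mean": mean, "sd": sd,
                "ci_low": mean - half, "ci_high": mean + half, "n_folds": len(v),
            })
    summary = pd.DataFrame(rows)
    anova: dict[str, dict] = {}
    for metric in ("rmse", "mad"):
        groups = []
        dropped = []
        for (grp,), sub in cells.groupby(["age_group"]):
            v = sub[metric].to_numpy()
            if len(v) >= 2:
                groups.append(v)
            else:
                dropped.append(grp)
        if dropped:
            warnings.warn(
                f"age groups {dropped} observed in <2 folds; excluded from ANOVA",
                stacklevel=2,
            )
        if len(groups) < 2:
            anova[metric] = {"skipped": "fewer than two age groups with >=2 folds"}
            continue
        F, p = stats.f_oneway(*groups)
        anova[metric] = {
            "F": float(F),
            "p": float(p),
            "df_between": len(groups) - 1,
            "df_within": int(sum(len(g) for g in groups) - len(groups)),
        }
    return AgeGroupReport(summary=summary, anova=anova, fold_values=cells)
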