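"""Heteroscedastic penalized longitudinal mixed model: fit and selection.

The observation model for logit prevalence y_j of country i is

    y_j = x_jᵀβ + z_pop(t_j)ᵀa + z_c(t_j)ᵀ(u_i, b_i) + ε_j

with fixed effects β (intercept, linear time, five age-partition
contrasts, sex, income), population P-spline deviations a ~ N(0, σ²_a I)
in the mixed-model (difference-penalty) reparameterization, country
random intercept + random B-spline coefficients (u_i, b_i) ~ N(0, G)
with a structured G (compound symmetry / diagonal / unstructured), and
heteroscedastic residuals Var(ε_j) = σ²_e + κ·s_j² where s_j is the
record's known logit-scale sampling SE.

Variance components are estimated by ML or REML on unconstrained
transforms (log variances, bounded-correlation z-transform,
log-Cholesky); fixed effects are profiled out by GLS.  The marginal
covariance V = σ²_a Z_a Z_aᵀ + Σ_i Z_i G Z_iᵀ + diag(σ²_e + κ s²) is
handled through the Woodbury identity, so the cost per likelihood
evaluation is O(n·m²) in the total random-effect dimension m, never
O(n³).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .preprocess import AGE_COVARIATE_COLUMNS, DesignMatrix
from .splines import (
    KnotSequence,
    basis_of_dimension,
    bspline_basis,
    difference_penalty,
    knot_sequence,
    reparameterize,
)

__all__ = [
    "ModelSpec",
    "FittedModel",
    "ConvergenceError",
    "country_cov",
    "marginal_loglik",
    "aicc",
    "fit",
    "select_model",
]

STRUCTURES = ("compound_symmetry", "diagonal", "unstructured")


class ConvergenceError(RuntimeError):
    """Optimizer failed; carries the best state found."""

    def __init__(self, message: str, best_state: dict | None = None):
        super().__init__(message)
        self.best_state = best_state


@dataclass(frozen=True)
class ModelSpec:
    """Everything that defines one candidate model."""

    knot_spacing_years: float = 2.0
    n_country_splines: int = 3  # q; country random dimension is q + 1
    country_cov_structure: str = "compound_symmetry"
    include_income_time_interaction: bool = False
    estimation: str = "REML"
    sse_multiplier: float = 1.0  # κ in Var(ε) = σ²_e + κ·s²
    penalty_order: int = 2

    def __post_init__(self) -> None:
        if self.country_cov_structure not in STRUCTURES:
            raise ValueError(f"unknown covariance structure {self.country_cov_structure!r}")
        if self.n_country_splines < 0:
            raise ValueError("n_country_splines must be >= 0")
        if self.country_cov_structure == "unstructured" and self.n_country_splines + 1 > 6:
            raise ValueError("unstructured G limited to dimension <= 6")
        if self.estimation not in ("REML", "ML"):
            raise ValueError("estimation must be 'REML' or 'ML'")
        if self.sse_multiplier < 0:
            raise ValueError("sse_multiplier must be >= 0")

    @property
    def country_dim(self) -> int:
        return self.n_country_splines + 1

    def n_cov_params(self) -> int:
        """Number of parameters in G for this structure."""
        d = self.country_dim
        if self.country_cov_structure == "compound_symmetry":
            return 1 if d == 1 else 2
        if self.country_cov_structure == "diagonal":
            return d
        return d * (d + 1) // 2


def country_cov(structure: str, q: int, params: Sequence[float]) -> np.ndarray:
    """Build the (q+1)×(q+1) country random-effect covariance.

    compound_symmetry: params (σ², ρ) with ρ ∈ (−1/q, 1) (σ² alone when
    q = 0); diagonal: q+1 variances; unstructured: log-Cholesky vector
    (diagonal entries on the log scale, row-major lower triangle).
    """
    d = q + 1
    params = np.asarray(params, dtype=float)
    if structure == "compound_symmetry":
        if d == 1:
            (sigma2,) = params
            return np.array([[sigma2]])
        sigma2, rho = params
        if not (-1.0 / q < rho < 1.0):
            raise ValueError(f"CS correlation {rho} outside (-1/{q}, 1)")
        return sigma2 * ((1 - rho) * np.eye(d) + rho * np.ones((d, d)))
    if structure == "diagonal":
        if len(params) != d:
            raise ValueError("diagonal structure needs q+1 variances")
        if np.any(params < 0):
            raise ValueError("variances must be nonnegative")
        return np.diag(params)
    if structure == "unstructured":
        if len(params) != d * (d + 1) // 2:
            raise ValueError("unstructured needs d(d+1)/2 log-Cholesky parameters")
        L = np.zeros((d, d))
        pos = 0
        for i in range(d):
            for j in range(i + 1):
                L[i, j] = math.exp(params[pos]) if i == j else params[pos]
                pos += 1
        return L @ L.T
    raise ValueError(f"unknown structure {structure!r}")


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: −2ℓ + 2k + 2k(k+1)/(n − k − 1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _psd_sqrt(G: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root factor L with L Lᵀ = G."""
    w, v = np.linalg.eigh(G)
    if np.any(w < -1e-8 * max(1.0, np.max(np.abs(w)))):
        raise ValueError("covariance matrix is not positive semidefinite")
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


class _ModelMatrices:
    """Design pieces shared by every likelihood evaluation of one fit."""

    def __init__(self, design: DesignMatrix, spec: ModelSpec):
        tab = design.table
        cfg = design.config
        self.design = design
        self.spec = spec
        self.start = float(cfg.study_start_year)
        self.end = float(cfg.study_end_year)
        span = self.end - self.start

        self.y = tab["y"].to_numpy(dtype=float)
        self.s2 = tab["s"].to_numpy(dtype=float) ** 2
        self.n = len(self.y)
        years = tab["year"].to_numpy(dtype=float)
        self.u = (years - self.start) / span

        cols = [np.ones(self.n), self.u]
        names = ["intercept", "t_scaled"]
        for c in AGE_COVARIATE_COLUMNS:
            cols.append(tab[c].to_numpy(dtype=float))
            names.append(c)
        cols.append(tab["sex_code"].to_numpy(dtype=float))
        names.append("sex_code")
        cols.append(tab["income_code"].to_numpy(dtype=float))
        names.append("income_code")
        if spec.include_income_time_interaction:
            cols.append(tab["income_code"].to_numpy(dtype=float) * self.u)
            names.append("income_x_t")
        self.X = np.column_stack(cols)
        self.x_names = names
        self.p = self.X.shape[1]

        # population P-spline random block
        self.pop_knots = knot_sequence(self.start, self.end, spec.knot_spacing_years)
        B = bspline_basis(years, self.pop_knots)
        D = difference_penalty(self.pop_knots.dimension, spec.penalty_order)
        self.reparam = reparameterize(B, D)
        self.Zpop = self.reparam.Z
        self.r = self.Zpop.shape[1]

        # country random block: intercept + q spline columns
        self.countries = sorted(tab["country_id"].unique())
        self.n_countries = len(self.countries)
        cmap = {c: i for i, c in enumerate(self.countries)}
        self.cidx = tab["country_id"].map(cmap).to_numpy(dtype=int)
        q = spec.n_country_splines
        self.d = q + 1
        zc = [np.ones(self.n)]
        if q > 0:
            zc.append(basis_of_dimension(years, q, self.start, self.end))
        self.Zc = np.column_stack(zc)
        self.m = self.r + self.n_countries * self.d
        self.rows_by_country = [np.where(self.cidx == i)[0] for i in range(self.n_countries)]

        self.income_by_country = {
            c: float(tab.loc[tab["country_id"] == c, "income_code"].iloc[0])
            for c in self.countries
        }

    def scaled_U(self, sigma2_a: float, LG: np.ndarray) -> np.ndarray:
        """U·Λ where Var(random effects) = Λ Λᵀ; columns ordered
        [population block | country 0 | country 1 | ...]."""
        Us = np.zeros((self.n, self.m))
        Us[:, : self.r] = math.sqrt(max(sigma2_a, 0.0)) * self.Zpop
        ZcL = self.Zc @ LG
        for i, rows in enumerate(self.rows_by_country):
            if len(rows):
                Us[rows, self.r + i * self.d : self.r + (i + 1) * self.d] = ZcL[rows]
        return Us

    def core(self, sigma2_a: float, sigma2_e: float, G: np.ndarray, reml: bool):
        """Profiled log-likelihood and GLS pieces at given variance components."""
        kappa = self.spec.sse_multiplier
        rvec = sigma2_e + kappa * self.s2
        if np.any(rvec <= 0):
            raise ValueError("residual variances must be strictly positive")
        LG = _psd_sqrt(G)
        Us = self.scaled_U(sigma2_a, LG)
        Rw = 1.0 / rvec
        UsR = Us * Rw[:, None]
        A = Us.T @ UsR
        M = A + np.eye(self.m)
        cM = cho_factor(M, lower=True)
        logdetM = 2.0 * np.sum(np.log(np.diag(cM[0])))
        logdetV = float(np.sum(np.log(rvec)) + logdetM)

        W = np.column_stack([self.y, self.X])
        RwW = W * Rw[:, None]
        Tm = Us.T @ RwW  # m × (p+1)
        Gram = W.T @ RwW - Tm.T @ cho_solve(cM, Tm)
        XtViX = Gram[1:, 1:]
        XtViy = Gram[1:, 0]
        ytViy = Gram[0, 0]
        try:
            cX = cho_factor(XtViX, lower=True)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                f"singular fixed-effect information; columns {self.x_names}"
            ) from e
        beta = cho_solve(cX, XtViy)
        rss = float(ytViy - beta @ XtViy)
        if reml:
            logdetX = 2.0 * np.sum(np.log(np.diag(cX[0])))
            ll = -0.5 * (
                (self.n - self.p) * math.log(2 * math.pi) + logdetV + logdetX + rss
            )
        else:
            ll = -0.5 * (self.n * math.log(2 * math.pi) + logdetV + rss)
        return {
            "ll": float(ll),
            "beta": beta,
            "XtViX": XtViX,
            "cX": cX,
            "cM": cM,
            "A": A,
            "Us": Us,
            "Rw": Rw,
            "rvec": rvec,
            "LG": LG,
        }


def marginal_loglik(
    sigma2_a: float,
    sigma2_e: float,
    G: np.ndarray,
    design: DesignMatrix,
    spec: ModelSpec,
) -> float:
    """Marginal (restricted) Gaussian log-likelihood at given variance components.

    Fixed effects are profiled out by GLS; REML vs ML follows
    ``spec.estimation``.  ``G`` must be positive semidefinite.
    """
    if sigma2_a < 0 or sigma2_e <= 0:
        raise ValueError("need sigma2_a >= 0 and sigma2_e > 0")
    mm = _ModelMatrices(design, spec)
    return mm.core(sigma2_a, sigma2_e, np.asarray(G, dtype=float), spec.estimation == "REML")["ll"]


# ---------------------------------------------------------------------------
# unconstrained parameterization of the variance components


def _rho_bounds(q: int) -> tuple[float, float]:
    return (-1.0 / q if q > 0 else -0.999, 1.0)


def _unpack(psi: np.ndarray, spec: ModelSpec, fix: dict) -> tuple[float, float, np.ndarray, dict]:
    """Map the unconstrained optimizer vector to (σ²_a, σ²_e, G)."""
    d = spec.country_dim
    i = 0
    if "sigma2_a" in fix:
        sigma2_a = float(fix["sigma2_a"])
    else:
        sigma2_a = math.exp(psi[i]); i += 1
    if "sigma2_e" in fix:
        sigma2_e = float(fix["sigma2_e"])
    else:
        sigma2_e = math.exp(psi[i]); i += 1
    gpar: dict[str, Any] = {}
    if "G" in fix:
        G = np.asarray(fix["G"], dtype=float)
    elif spec.country_cov_structure == "compound_symmetry":
        sigma2_c = math.exp(psi[i]); i += 1
        if d == 1:
            G = np.array([[sigma2_c]])
            gpar = {"sigma2": sigma2_c}
        else:
            lo, hi = _rho_bounds(spec.n_country_splines)
            rho = lo + (hi - lo) / (1.0 + math.exp(-psi[i])); i += 1
            G = country_cov("compound_symmetry", spec.n_country_splines, (sigma2_c, rho))
            gpar = {"sigma2": sigma2_c, "rho": rho}
    elif spec.country_cov_structure == "diagonal":
        vs = np.exp(psi[i : i + d]); i += d
        G = np.diag(vs)
        gpar = {"variances": vs.tolist()}
    else:
        npar = d * (d + 1) // 2
        G = country_cov("unstructured", spec.n_country_splines, psi[i : i + npar])
        gpar = {"log_cholesky": list(map(float, psi[i : i + npar]))}
        i += npar
    return sigma2_a, sigma2_e, G, gpar


def _n_free(spec: ModelSpec, fix: dict) -> int:
    n = 0
    if "sigma2_a" not in fix:
        n += 1
    if "sigma2_e" not in fix:
        n += 1
    if "G" not in fix:
        n += spec.n_cov_params()
    return n


def _start_values(mm: _ModelMatrices, spec: ModelSpec, fix: dict) -> np.ndarray:
    """Documented starting point: OLS residual variance split across components."""
    beta0, *_ = np.linalg.lstsq(mm.X, mm.y, rcond=None)
    resid = mm.y - mm.X @ beta0
    v = float(np.var(resid))
    v = max(v, 1e-4)
    psi = []
    if "sigma2_a" not in fix:
        # Z_pop columns are O(1)-to-large; scale the prior variance down
        zscale = float(np.mean(np.sum(mm.Zpop**2, axis=1))) or 1.0
        psi.append(math.log(0.5 * v / zscale))
    if "sigma2_e" not in fix:
        psi.append(math.log(0.5 * v))
    if "G" not in fix:
        if spec.country_cov_structure == "compound_symmetry":
            psi.append(math.log(0.1 * v))
            if spec.country_dim > 1:
                psi.append(0.0)  # mid-range correlation
        elif spec.country_cov_structure == "diagonal":
            psi.extend([math.log(0.1 * v)] * spec.country_dim)
        else:
            d = spec.country_dim
            for i in range(d):
                for j in range(i + 1):
                    psi.append(0.5 * math.log(0.1 * v) if i == j else 0.0)
    return np.array(psi)


# ---------------------------------------------------------------------------
# fitted model


@dataclass
class FittedModel:
    """REML/ML estimates plus everything needed for prediction.

    ``beta``/``cov_beta`` are the GLS fixed effects; ``blups`` maps each
    country to its predicted (intercept, spline) random effects with
    naive conditional covariances; ``gamma_pop`` holds the BLUPs of the
    population P-spline deviation coefficients.  The matrices C1, C2,
    C3 carry the cross-covariances needed for prediction variances:
    C1 = Σ Uᵀ V⁻¹ U Σ, C2 = Xᵀ V⁻¹ U Σ, C3 = (Xᵀ V⁻¹ X)⁻¹.
    """

    spec: ModelSpec
    study_start_year: float
    study_end_year: float
    x_names: list[str]
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_spline: float
    sigma2_resid: float
    G: np.ndarray
    g_params: dict
    pop_knots: KnotSequence
    T_pop: np.ndarray
    gamma_pop: np.ndarray
    countries: list[str]
    income_by_country: dict[str, float]
    blups: dict[str, np.ndarray]
    blup_cond_cov: dict[str, np.ndarray]
    C1: np.ndarray
    C2: np.ndarray
    C3: np.ndarray
    loglik: float
    n_params: int
    n_obs: int
    aicc: float
    convergence: dict

    @property
    def q(self) -> int:
        return self.spec.n_country_splines

    @property
    def country_dim(self) -> int:
        return self.spec.country_dim

    @property
    def r_pop(self) -> int:
        return self.T_pop.shape[1]

    def country_block(self, country_id: str) -> slice:
        i = self.countries.index(country_id)
        d = self.country_dim
        return slice(self.r_pop + i * d, self.r_pop + (i + 1) * d)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "study_start_year": self.study_start_year,
            "study_end_year": self.study_end_year,
            "x_names": self.x_names,
            "beta": self.beta.tolist(),
            "cov_beta": self.cov_beta.tolist(),
            "sigma2_spline": self.sigma2_spline,
            "sigma2_resid": self.sigma2_resid,
            "G": self.G.tolist(),
            "g_params": self.g_params,
            "pop_knots": {
                "start": self.pop_knots.start,
                "end": self.pop_knots.end,
                "spacing": self.pop_knots.spacing,
                "degree": self.pop_knots.degree,
            },
            "T_pop": self.T_pop.tolist(),
            "gamma_pop": self.gamma_pop.tolist(),
            "countries": self.countries,
            "income_by_country": self.income_by_country,
            "blups": {c: v.tolist() for c, v in self.blups.items()},
            "blup_cond_cov": {c: v.tolist() for c, v in self.blup_cond_cov.items()},
            "C1": self.C1.tolist(),
            "C2": self.C2.tolist(),
            "C3": self.C3.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "aicc": self.aicc,
            "convergence": self.convergence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            spec=ModelSpec(**d["spec"]),
            study_start_year=d["study_start_year"],
            study_end_year=d["study_end_year"],
            x_names=list(d["x_names"]),
            beta=np.asarray(d["beta"]),
            cov_beta=np.asarray(d["cov_beta"]),
            sigma2_spline=d["sigma2_spline"],
            sigma2_resid=d["sigma2_resid"],
            G=np.asarray(d["G"]),
            g_params=d["g_params"],
            pop_knots=KnotSequence(**d["pop_knots"]),
            T_pop=np.asarray(d["T_pop"]),
            gamma_pop=np.asarray(d["gamma_pop"]),
            countries=list(d["countries"]),
            income_by_country={k: float(v) for k, v in d["income_by_country"].items()},
            blups={c: np.asarray(v) for c, v in d["blups"].items()},
            blup_cond_cov={c: np.asarray(v) for c, v in d["blup_cond_cov"].items()},
            C1=np.asarray(d["C1"]),
            C2=np.asarray(d["C2"]),
            C3=np.asarray(d["C3"]),
            loglik=d["loglik"],
            n_params=d["n_params"],
            n_obs=d["n_obs"],
            aicc=d["aicc"],
            convergence=d["convergence"],
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _apply_lambda(mat: np.ndarray, mm: _ModelMatrices, sigma2_a: float, LG: np.ndarray,
                  left: bool) -> np.ndarray:
    """Multiply Λ (left) or Λᵀ (right) into an m×k / k×m matrix."""
    out = mat.copy()
    sa = math.sqrt(max(sigma2_a, 0.0))
    r, d = mm.r, mm.d
    if left:
        out[:r] *= sa
        for i in range(mm.n_countries):
            blk = slice(r + i * d, r + (i + 1) * d)
            out[blk] = LG @ out[blk]
    else:
        out[:, :r] *= sa
        for i in range(mm.n_countries):
            blk = slice(r + i * d, r + (i + 1) * d)
            out[:, blk] = out[:, blk] @ LG.T
    return out


def _finalize(mm: _ModelMatrices, spec: ModelSpec, sigma2_a: float, sigma2_e: float,
              G: np.ndarray, gpar: dict, n_free_vc: int, conv: dict) -> FittedModel:
    reml = spec.estimation == "REML"
    core = mm.core(sigma2_a, sigma2_e, G, reml)
    beta, cM, A, Us, Rw = core["beta"], core["cM"], core["A"], core["Us"], core["Rw"]
    LG = core["LG"]

    res = mm.y - mm.X @ beta
    tvec = Us.T @ (res * Rw)
    UsVires = tvec - A @ cho_solve(cM, tvec)
    gamma_s = UsVires  # = Usᵀ V⁻¹ (y − Xβ̂)
    gamma = _apply_lambda(gamma_s[:, None], mm, sigma2_a, LG, left=True).ravel()

    Minv_A = cho_solve(cM, A)
    UsViUs = A - A @ Minv_A
    C1 = _apply_lambda(
        _apply_lambda(UsViUs, mm, sigma2_a, LG, left=True), mm, sigma2_a, LG, left=False
    )
    Tmx = Us.T @ (mm.X * Rw[:, None])  # m × p
    XtViUs = Tmx.T - Tmx.T @ cho_solve(cM, A)
    C2 = _apply_lambda(XtViUs, mm, sigma2_a, LG, left=False)
    C3 = cho_solve(core["cX"], np.eye(mm.p))
    C3 = 0.5 * (C3 + C3.T)

    r, d = mm.r, mm.d
    blups = {}
    cond = {}
    for i, c in enumerate(mm.countries):
        blk = slice(r + i * d, r + (i + 1) * d)
        blups[c] = gamma[blk]
        cond[c] = G - C1[blk, blk]
    k = mm.p + n_free_vc
    ll = core["ll"]
    return FittedModel(
        spec=spec,
        study_start_year=mm.start,
        study_end_year=mm.end,
        x_names=mm.x_names,
        beta=beta,
        cov_beta=C3,
        sigma2_spline=sigma2_a,
        sigma2_resid=sigma2_e,
        G=G,
        g_params=gpar,
        pop_knots=mm.pop_knots,
        T_pop=mm.reparam.T,
        gamma_pop=gamma[:r],
        countries=mm.countries,
        income_by_country=mm.income_by_country,
        blups=blups,
        blup_cond_cov=cond,
        C1=C1,
        C2=C2,
        C3=C3,
        loglik=ll,
        n_params=k,
        n_obs=mm.n,
        aicc=aicc(ll, k, mm.n),
        convergence=conv,
    )


def fit(design: DesignMatrix, spec: ModelSpec, fix: dict | None = None) -> FittedModel:
    """Maximize the (RE)ML likelihood over the variance components.

    ``fix`` optionally freezes components at given values, e.g.
    ``{"sigma2_a": 0.0, "G": np.zeros((d, d))}`` — the remaining ones
    are still estimated.  Fitting is deterministic: a quasi-Newton
    search from documented starting values, with up to three jittered
    restarts (fixed jitter stream) if the first search fails.
    """
    fix = dict(fix or {})
    mm = _ModelMatrices(design, spec)
    if mm.n_countries < 2:
        raise ValueError("need at least 2 countries to fit country random effects")
    if mm.n <= mm.p:
        raise ValueError(f"n_obs={mm.n} must exceed the {mm.p} fixed effects")
    reml = spec.estimation == "REML"
    n_free = _n_free(spec, fix)

    def negll(psi: np.ndarray) -> float:
        try:
            sa, se, G, _ = _unpack(psi, spec, fix)
            return -mm.core(sa, se, G, reml)["ll"]
        except (np.linalg.LinAlgError, ValueError, OverflowError, FloatingPointError):
            return 1e12

    if n_free == 0:
        sa, se, G, gpar = _unpack(np.empty(0), spec, fix)
        conv = {"converged": True, "n_iter": 0, "message": "all components fixed"}
        return _finalize(mm, spec, sa, se, G, gpar, 0, conv)

    psi0 = _start_values(mm, spec, fix)
    rng = np.random.default_rng(12345)  # fixed stream: restarts stay deterministic
    best = None
    attempts = []
    for attempt in range(4):
        start = psi0 if attempt == 0 else psi0 + rng.normal(0.0, 0.5 + 0.5 * attempt, psi0.shape)
        res = optimize.minimize(
            negll, start, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
        )
        ok = np.isfinite(res.fun) and (
            res.success or np.max(np.abs(res.jac)) < 1e-3 * (1.0 + abs(res.fun))
        )
        attempts.append({"success": bool(res.success), "fun": float(res.fun),
                         "message": str(res.message)})
        if best is None or res.fun < best.fun:
            best = res
        if ok:
            best = res
            break
    else:
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError(
                "variance-component optimization failed", {"attempts": attempts}
            )
    sa, se, G, gpar = _unpack(best.x, spec, fix)
    conv = {
        "converged": bool(best.success or np.isfinite(best.fun)),
        "n_iter": int(best.nit),
        "neg_loglik": float(best.fun),
        "grad_max": float(np.max(np.abs(best.jac))),
        "message": str(best.message),
        "attempts": attempts,
    }
    return _finalize(mm, spec, sa, se, G, gpar, n_free, conv)


def select_model(
    design: DesignMatrix, candidates: Sequence[ModelSpec]
) -> tuple[FittedModel, pd.DataFrame]:
    """Fit every candidate with ML, pick minimum AICc, refit with REML.

    AICc is compared on ML fits (REML likelihoods are not comparable
    across fixed-effect structures); ties break toward fewer parameters,
    then wider knot spacing (fewer knots).  Returns the REML refit of
    the winner plus the full comparison table.
    """
    if not candidates:
        raise ValueError("need at least one candidate ModelSpec")
    rows = []
    fits: list[tuple[int, ModelSpec, FittedModel | None, str]] = []
    for i, cand in enumerate(candidates):
        cand_ml = replace(cand, estimation="ML")
        try:
            f = fit(design, cand_ml)
            fits.append((i, cand, f, ""))
            rows.append({
                "candidate": i,
                "structure": cand.country_cov_structure,
                "q": cand.n_country_splines,
                "knot_spacing": cand.knot_spacing_years,
                "k": f.n_params,
                "n": f.n_obs,
                "loglik_ml": f.loglik,
                "aicc": f.aicc,
                "error": "",
            })
        except (ConvergenceError, ValueError, np.linalg.LinAlgError) as e:
            fits.append((i, cand, None, str(e)))
            rows.append({
                "candidate": i,
                "structure": cand.country_cov_structure,
                "q": cand.n_country_splines,
                "knot_spacing": cand.knot_spacing_years,
                "k": None, "n": None, "loglik_ml": None, "aicc": None,
                "error": str(e),
            })
    table = pd.DataFrame(rows)
    ok = [(i, c, f) for i, c, f, err in fits if f is not None]
    if not ok:
        raise ConvergenceError(
            "no candidate model converged", {"table": table.to_dict("records")}
        )
    ok.sort(key=lambda t: (t[2].aicc, t[2].n_params, -t[1].knot_spacing_years, t[0]))
    best_spec = replace(ok[0][1], estimation="REML")
    best_fit = fit(design, best_spec)
    table["selected"] = [i == ok[0][0] for i in range(len(candidates))]
    return best_fit, table
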