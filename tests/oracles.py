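"""Independent dense-matrix oracles used to cross-check the model code.

Everything here is deliberately naive O(n³) linear algebra built from
the model definition alone; none of it shares code with the package's
Woodbury-based implementation.
"""

from __future__ import annotations

import math

import numpy as np

from prevtrend.model import ModelSpec, _ModelMatrices
from prevtrend.preprocess import DesignMatrix


def dense_pieces(design: DesignMatrix, spec: ModelSpec, sigma2_a: float,
                 sigma2_e: float, G: np.ndarray):
    """Assemble X, y, U, Σ, R and V for a design with dense matrices."""
    mm = _ModelMatrices(design, spec)
    r, d, m = mm.r, mm.d, mm.m
    U = np.zeros((mm.n, m))
    U[:, :r] = mm.Zpop
    for i, rows in enumerate(mm.rows_by_country):
        U[rows, r + i * d : r + (i + 1) * d] = mm.Zc[rows]
    Sigma = np.zeros((m, m))
    Sigma[:r, :r] = sigma2_a * np.eye(r)
    for i in range(mm.n_countries):
        blk = slice(r + i * d, r + (i + 1) * d)
        Sigma[blk, blk] = G
    R = np.diag(sigma2_e + spec.sse_multiplier * mm.s2)
    V = R + U @ Sigma @ U.T
    return mm, U, Sigma, R, V


def dense_loglik(design: DesignMatrix, spec: ModelSpec, sigma2_a: float,
                 sigma2_e: float, G: np.ndarray) -> float:
    """Marginal (restricted) log-likelihood via direct n×n inversion."""
    mm, _, _, _, V = dense_pieces(design, spec, sigma2_a, sigma2_e, G)
    X, y, n, p = mm.X, mm.y, mm.n, mm.p
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    resid = y - X @ beta
    quad = float(resid @ Vi @ resid)
    logdetV = float(np.linalg.slogdet(V)[1])
    if spec.estimation == "REML":
        return -0.5 * (
            (n - p) * math.log(2 * math.pi)
            + logdetV
            + float(np.linalg.slogdet(XtViX)[1])
            + quad
        )
    return -0.5 * (n * math.log(2 * math.pi) + logdetV + quad)


def henderson_prediction(design: DesignMatrix, spec: ModelSpec, sigma2_a: float,
                         sigma2_e: float, G: np.ndarray, x_star: np.ndarray,
                         u_star: np.ndarray) -> tuple[float, float]:
    """BLUP point prediction and its error variance via the inverse of
    Henderson's mixed-model-equations coefficient matrix (requires Σ
    positive definite)."""
    mm, U, Sigma, R, V = dense_pieces(design, spec, sigma2_a, sigma2_e, G)
    X, y = mm.X, mm.y
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    gamma = Sigma @ U.T @ Vi @ (y - X @ beta)
    Ri = np.linalg.inv(R)
    C = np.block([
        [X.T @ Ri @ X, X.T @ Ri @ U],
        [U.T @ Ri @ X, U.T @ Ri @ U + np.linalg.inv(Sigma)],
    ])
    Cinv = np.linalg.inv(C)
    v = np.concatenate([x_star, u_star])
    return float(x_star @ beta + u_star @ gamma), float(v @ Cinv @ v)
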