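"""Cubic B-spline bases and the P-spline → mixed-model reparameterization.

A penalized B-spline (P-spline) regression with an order-2 difference
penalty on the coefficients is algebraically identical to a linear mixed
model in which the penalty null space (constant + linear trend) enters
as fixed effects and the penalized deviations enter as i.i.d. random
coefficients with variance σ²_e/λ.  This module builds the basis, the
difference penalty, and that reparameterization, which is how the
population trend's smoothing parameter gets estimated by REML.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "KnotSequence",
    "PSplineReparam",
    "knot_sequence",
    "bspline_basis",
    "basis_of_dimension",
    "difference_penalty",
    "reparameterize",
]


@dataclass(frozen=True)
class KnotSequence:
    """Equally spaced interior knots with clamped (replicated) boundaries."""

    start: float
    end: float
    spacing: float
    degree: int = 3

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("knot spacing must be positive")
        if self.end - self.start < 2 * self.spacing:
            raise ValueError(
                f"domain [{self.start}, {self.end}] too short for spacing "
                f"{self.spacing}: need at least one interior knot"
            )

    @property
    def interior(self) -> np.ndarray:
        # strictly inside (start, end)
        n = int(np.floor((self.end - self.start) / self.spacing - 1e-9))
        ks = self.start + self.spacing * np.arange(1, n + 1)
        return ks[ks < self.end - 1e-9]

    @property
    def dimension(self) -> int:
        return len(self.interior) + self.degree + 1

    @property
    def full_knots(self) -> np.ndarray:
        return np.concatenate(
            [
                np.repeat(self.start, self.degree + 1),
                self.interior,
                np.repeat(self.end, self.degree + 1),
            ]
        )


def knot_sequence(start_year: float, end_year: float, spacing: float) -> KnotSequence:
    """Knots every `spacing` years across [start_year, end_year]."""
    return KnotSequence(start=float(start_year), end=float(end_year), spacing=float(spacing))


def bspline_basis(t_values, knots: KnotSequence) -> np.ndarray:
    """Evaluate the clamped B-spline basis; rows sum to 1.

    Raises if any evaluation point lies outside the knot domain — there
    is no silent extrapolation.
    """
    t = np.asarray(t_values, dtype=float)
    if t.ndim != 1:
        t = np.atleast_1d(t).ravel()
    if np.any(t < knots.start) or np.any(t > knots.end):
        bad = t[(t < knots.start) | (t > knots.end)]
        raise ValueError(
            f"evaluation points {bad} outside basis domain "
            f"[{knots.start}, {knots.end}]"
        )
    B = BSpline.design_matrix(
        t, knots.full_knots, knots.degree, extrapolate=False
    ).toarray()
    assert B.shape == (len(t), knots.dimension)
    return B


def basis_of_dimension(t_values, dim: int, start: float, end: float) -> np.ndarray:
    """A B-spline basis with exactly `dim` columns over [start, end].

    Used for the country-level random spline bases whose size q is a
    model-selection variable: for dim ≥ 4 this is a cubic basis with
    dim − 4 interior knots; for dim ∈ {1, 2, 3} the degree is reduced
    to dim − 1 (constant, linear, quadratic) with no interior knots.
    """
    if dim < 1:
        raise ValueError("basis dimension must be >= 1")
    degree = min(3, dim - 1)
    n_interior = dim - degree - 1
    t = np.atleast_1d(np.asarray(t_values, dtype=float)).ravel()
    if np.any(t < start) or np.any(t > end):
        raise ValueError("evaluation points outside basis domain")
    interior = (
        start + (end - start) * np.arange(1, n_interior + 1) / (n_interior + 1)
        if n_interior > 0
        else np.empty(0)
    )
    full = np.concatenate(
        [np.repeat(float(start), degree + 1), interior, np.repeat(float(end), degree + 1)]
    )
    B = BSpline.design_matrix(t, full, degree, extrapolate=False).toarray()
    assert B.shape == (len(t), dim)
    return B


def difference_penalty(n_coef: int, order: int = 2) -> np.ndarray:
    """Finite-difference penalty factor D of shape (n_coef − order, n_coef).

    The penalty is ‖Dθ‖²; its null space is polynomials of degree
    < order in the coefficient index, so order 2 leaves a straight line
    unpenalized.
    """
    if n_coef <= order:
        raise ValueError(f"need n_coef > order, got {n_coef} <= {order}")
    D = np.eye(n_coef)
    for _ in range(order):
        D = np.diff(D, axis=0)
    return D


@dataclass(frozen=True)
class PSplineReparam:
    """Mixed-model form of a penalized basis.

    X_poly spans the image of the penalty null space (constant + linear
    for order 2); Z is the random-effect basis B·Dᵀ(DDᵀ)⁻¹ whose i.i.d.
    coefficients carry the penalty.  ``N`` and ``T`` map (fixed, random)
    coefficients back to original B-spline coefficients via
    θ = N·δ + T·α.
    """

    X_poly: np.ndarray
    Z: np.ndarray
    N: np.ndarray
    T: np.ndarray

    def to_original_coefficients(self, delta: np.ndarray, alpha: np.ndarray) -> np.ndarray:
        return self.N @ delta + self.T @ alpha


def reparameterize(basis: np.ndarray, D: np.ndarray) -> PSplineReparam:
    """Split a penalized basis into fixed polynomial + random deviation parts.

    With T = Dᵀ(DDᵀ)⁻¹ and N a basis of null(D), any coefficient vector
    is θ = N·δ + T·α with α = Dθ, so ‖Dθ‖² = ‖α‖²: penalized least
    squares on (basis, λ) equals a ridge/mixed-model fit with fixed part
    basis·N and random part basis·T.
    """
    n_coef = basis.shape[1]
    order = n_coef - D.shape[0]
    if D.shape[1] != n_coef:
        raise ValueError("penalty and basis dimensions do not conform")
    DDt = D @ D.T
    if np.linalg.matrix_rank(DDt) < D.shape[0]:
        raise ValueError("penalty factor D is rank deficient")
    T = D.T @ np.linalg.inv(DDt)
    # Polynomial null-space basis in the coefficient index (exact for
    # difference penalties): columns 1, i, i², ...
    idx = np.arange(n_coef, dtype=float)
    N = np.column_stack([idx**p for p in range(order)])
    assert np.allclose(D @ N, 0.0, atol=1e-10)
    return PSplineReparam(X_poly=basis @ N, Z=basis @ T, N=N, T=T)
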