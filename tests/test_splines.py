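"""B-spline bases, difference penalties, and the mixed-model reparameterization."""

import numpy as np
import pytest

from prevtrend.splines import (
    KnotSequence,
    basis_of_dimension,
    bspline_basis,
    difference_penalty,
    knot_sequence,
    reparameterize,
)


def cox_de_boor(x: float, t: np.ndarray, k: int, i: int) -> float:
    """Independent textbook recursion for one B-spline basis function."""
    if k == 0:
        if t[i] <= x < t[i + 1]:
            return 1.0
        # close the last nonempty interval at the right boundary
        if x == t[-1] and t[i] < t[i + 1] and t[i + 1] == t[-1]:
            return 1.0
        return 0.0
    left = 0.0 if t[i + k] == t[i] else (x - t[i]) / (t[i + k] - t[i]) * cox_de_boor(x, t, k - 1, i)
    right = 0.0 if t[i + k + 1] == t[i + 1] else (
        (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * cox_de_boor(x, t, k - 1, i + 1)
    )
    return left + right


class TestKnotSequence:
    def test_two_year_spacing_matches_study_layout(self):
        ks = knot_sequence(1990, 2020, 2)
        np.testing.assert_allclose(ks.interior, np.arange(1992, 2019, 2))
        assert len(ks.interior) == 14
        assert ks.dimension == 18

    def test_four_year_spacing(self):
        ks = knot_sequence(1990, 2020, 4)
        np.testing.assert_allclose(ks.interior, np.arange(1994, 2019, 4))
        assert len(ks.interior) == 7
        assert ks.dimension == 11

    def test_too_wide_spacing_rejected(self):
        with pytest.raises(ValueError):
            knot_sequence(1990, 2020, 30)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            knot_sequence(1990, 2020, 0)


class TestBasisEvaluation:
    def test_partition_of_unity(self):
        ks = knot_sequence(1990, 2020, 2)
        t = np.linspace(1990, 2020, 301)
        B = bspline_basis(t, ks)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(B >= 0)
        assert np.all((B > 0).sum(axis=1) <= 4)

    def test_clamped_boundary(self):
        ks = knot_sequence(1990, 2020, 2)
        B = bspline_basis([1990.0], ks)
        assert B[0, 0] == 1.0
        assert np.all(B[0, 1:] == 0.0)

    def test_agrees_with_independent_recursion(self):
        ks = knot_sequence(1990, 2020, 4)
        t_full = ks.full_knots
        pts = [1991.3, 1997.0, 2004.5, 2013.2, 2019.9]
        B = bspline_basis(pts, ks)
        for row, x in enumerate(pts):
            for i in range(ks.dimension):
                assert B[row, i] == pytest.approx(
                    cox_de_boor(x, t_full, 3, i), abs=1e-12
                )

    def test_no_silent_extrapolation(self):
        ks = knot_sequence(1990, 2020, 2)
        with pytest.raises(ValueError):
            bspline_basis([2021.0], ks)

    def test_shift_invariance(self):
        """Shifting years and knots together leaves the basis unchanged."""
        t = np.linspace(1990, 2020, 40)
        B1 = bspline_basis(t, knot_sequence(1990, 2020, 3))
        B2 = bspline_basis(t + 7, knot_sequence(1997, 2027, 3))
        np.testing.assert_allclose(B1, B2, atol=1e-12)

    @pytest.mark.parametrize("dim", [1, 2, 3, 4, 6])
    def test_reduced_dimension_bases(self, dim):
        B = basis_of_dimension(np.linspace(0, 1, 17), dim, 0.0, 1.0)
        assert B.shape == (17, dim)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)


class TestDifferencePenalty:
    def test_second_difference_rows(self):
        D = difference_penalty(5, 2)
        expected = np.array(
            [[1, -2, 1, 0, 0], [0, 1, -2, 1, 0], [0, 0, 1, -2, 1]], dtype=float
        )
        np.testing.assert_array_equal(D, expected)

    def test_linear_sequence_in_null_space(self):
        D = difference_penalty(5, 2)
        assert np.all(D @ np.array([1.0, 2.0, 3.0, 4.0, 5.0]) == 0.0)

    def test_penalty_rank(self):
        D = difference_penalty(11, 2)
        assert np.linalg.matrix_rank(D.T @ D) == 9

    def test_too_few_coefficients_rejected(self):
        with pytest.raises(ValueError):
            difference_penalty(2, 2)


class TestReparameterization:
    @pytest.fixture()
    def toy(self):
        rng = np.random.default_rng(11)
        t = np.sort(rng.uniform(1990, 2020, 20))
        y = np.sin((t - 1990) / 5.0) + rng.normal(0, 0.2, t.size)
        ks = knot_sequence(1990, 2020, 4)
        B = bspline_basis(t, ks)
        D = difference_penalty(ks.dimension, 2)
        return t, y, B, D

    def test_random_part_rank(self):
        ks = knot_sequence(1990, 2020, 2)
        B = bspline_basis(np.linspace(1990, 2020, 60), ks)
        rep = reparameterize(B, difference_penalty(ks.dimension, 2))
        assert rep.Z.shape[1] == 16
        assert np.linalg.matrix_rank(rep.Z) == 16

    def test_spans_same_column_space(self, toy):
        _, _, B, D = toy
        rep = reparameterize(B, D)
        C = np.column_stack([rep.X_poly, rep.Z])
        assert np.linalg.matrix_rank(C) == np.linalg.matrix_rank(B) == B.shape[1]
        # every original basis column is reproduced by the transform
        proj = C @ np.linalg.lstsq(C, B, rcond=None)[0]
        np.testing.assert_allclose(proj, B, atol=1e-9)

    @pytest.mark.parametrize("lam", [0.1, 1.0, 10.0])
    def test_penalized_fit_equals_mixed_form(self, toy, lam):
        """Direct penalized LS and the ridge on (X_poly, Z) give the same fit."""
        _, y, B, D = toy
        theta = np.linalg.solve(B.T @ B + lam * D.T @ D, B.T @ y)
        fitted_direct = B @ theta
        rep = reparameterize(B, D)
        C = np.column_stack([rep.X_poly, rep.Z])
        P = np.zeros((C.shape[1], C.shape[1]))
        P[rep.X_poly.shape[1]:, rep.X_poly.shape[1]:] = lam * np.eye(rep.Z.shape[1])
        coef = np.linalg.solve(C.T @ C + P, C.T @ y)
        np.testing.assert_allclose(C @ coef, fitted_direct, atol=1e-8)
        # coefficient transform reproduces the same fitted values
        p = rep.X_poly.shape[1]
        theta_back = rep.to_original_coefficients(coef[:p], coef[p:])
        np.testing.assert_allclose(B @ theta_back, fitted_direct, atol=1e-8)

    def test_infinite_penalty_limit_is_straight_line(self, toy):
        t, y, B, D = toy
        rep = reparameterize(B, D)
        lam = 1e12
        C = np.column_stack([rep.X_poly, rep.Z])
        P = np.zeros((C.shape[1], C.shape[1]))
        P[rep.X_poly.shape[1]:, rep.X_poly.shape[1]:] = lam * np.eye(rep.Z.shape[1])
        coef = np.linalg.solve(C.T @ C + P, C.T @ y)
        fitted = C @ coef
        # straight-line LS in the penalty null-space coordinates
        Xl = rep.X_poly
        line = Xl @ np.linalg.lstsq(Xl, y, rcond=None)[0]
        np.testing.assert_allclose(fitted, line, atol=1e-6)

    def test_rank_deficient_penalty_rejected(self, toy):
        _, _, B, D = toy
        D_bad = np.vstack([D, D[0]])[: D.shape[0]]
        D_bad[-1] = D_bad[0]
        with pytest.raises(ValueError):
            reparameterize(B, D_bad)
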