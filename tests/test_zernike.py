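"""Zernike basis evaluation, surface fitting, and cohort coefficient comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from okzone import (
    CornealSurface,
    ZernikeBasis,
    compare_coefficients,
    fit_zernike,
    osa_index,
    reconstruct_surface_heights,
    term_name,
    zernike_radial,
    zernike_term,
)
from okzone.grids import default_polar_grid

from .conftest import sphere_surface


def radial_oracle(n: int, m: int, rho: float) -> float:
    """Independent factorial-sum evaluation with exact integer arithmetic."""
    from fractions import Fraction
    from math import factorial

    m = abs(m)
    total = 0.0
    for k in range((n - m) // 2 + 1):
        c = Fraction((-1) ** k * factorial(n - k),
                     factorial(k) * factorial((n + m) // 2 - k) * factorial((n - m) // 2 - k))
        total += float(c) * rho ** (n - 2 * k)
    return total


class TestBasisEvaluation:
    def test_piston_is_one(self):
        assert zernike_radial(0, 0, 0.37) == pytest.approx(1.0)

    def test_defocus_radial_at_unit_rho(self):
        # R_2^0(1) = 2*1 - 1
        assert zernike_radial(2, 0, 1.0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n,m,rho", [(4, 2, 0.6), (5, 3, 0.31), (5, 1, 0.9), (3, 3, 0.5)])
    def test_radial_matches_independent_oracle(self, n, m, rho):
        assert zernike_radial(n, m, rho) == pytest.approx(radial_oracle(n, m, rho), abs=1e-12)

    def test_invalid_parity_rejected(self):
        with pytest.raises(ValueError):
            zernike_radial(3, 2, 0.5)
        with pytest.raises(ValueError):
            zernike_radial(2, 3, 0.5)

    def test_angular_branches(self):
        assert zernike_term(1, 1, 0.7, 0.0) == pytest.approx(0.7)
        assert zernike_term(1, -1, 0.7, 0.0) == pytest.approx(0.0)
        # rho^2 sin(2 phi) at rho=0.5, phi=45 deg -> 0.25
        assert zernike_term(2, -2, 0.5, np.deg2rad(45)) == pytest.approx(0.25, abs=1e-12)

    def test_osa_ordering_and_names(self):
        b = ZernikeBasis(n_max=5)
        assert b.n_terms == 21
        assert b.terms[0] == (0, 0) and b.terms[-1] == (5, 5)
        assert [osa_index(n, m) for n, m in b.terms] == list(range(21))
        assert term_name(3, -1) == "Vertical coma"
        assert term_name(4, 0) == "Primary spherical aberration"

    def test_discrete_orthogonality_of_all_21_terms(self):
        # dense uniform disc sampling with trapezoid area weights
        b = ZernikeBasis(n_max=5)
        r = np.linspace(0, 1, 201)
        p = np.linspace(0, 2 * np.pi, 361)[:-1]
        rr, pp = np.meshgrid(r, p)
        w = rr.ravel().copy()  # area element weight rho drho dphi
        trap = np.ones_like(rr)
        trap[:, 0] = trap[:, -1] = 0.5
        w *= trap.ravel()
        a = b.design_matrix(rr.ravel(), pp.ravel()) * np.sqrt(w)[:, None]
        gram = a.T @ a
        norm = np.sqrt(np.outer(np.diag(gram), np.diag(gram)))
        off = np.abs(gram / norm) - np.eye(21)
        assert np.max(np.abs(off)) < 1e-3


class TestSurfaceFitting:
    def _surface_from_coeffs(self, grid, coeffs, basis):
        x, y = grid.node_xy()
        rho_g = grid.node_rho()
        rho = np.clip(rho_g / basis.rho_max, 0, 1)
        phi = np.arctan2(y, x)
        z = np.zeros(grid.shape)
        for (n, m), c in zip(basis.terms, coeffs):
            z += c * zernike_term(n, m, rho, phi)
        return CornealSurface(grid, np.where(rho_g <= basis.rho_max, z, np.nan), "OD")

    def test_exact_recovery_of_known_coefficients(self, small_grid):
        basis = ZernikeBasis()
        rng = np.random.default_rng(3)
        true = rng.normal(0, 0.01, basis.n_terms)
        s = self._surface_from_coeffs(small_grid, true, basis)
        fit = fit_zernike(s, basis, seed=0)
        assert np.max(np.abs(fit.coefficients - true)) < 1e-8
        assert fit.rms_error < 1e-8

    def test_constant_surface_is_pure_piston(self, small_grid):
        z = np.full(small_grid.shape, -0.4)
        s = CornealSurface(small_grid, z, "OD")
        fit = fit_zernike(s, seed=1)
        assert fit.coefficient(0, 0) == pytest.approx(-0.4, abs=1e-10)
        assert np.max(np.abs(fit.coefficients[1:])) < 1e-10

    def test_sphere_has_no_asymmetric_terms(self, small_grid):
        # full symmetric sampling (no random split) so that the radial
        # truncation error cannot leak into the asymmetric terms
        s = sphere_surface(7.8, small_grid)
        fit = fit_zernike(s, seed=2, validation_fraction=0.0)
        for (n, m), c in zip(fit.basis.terms, fit.coefficients):
            if m != 0:
                assert abs(c) < 1e-9, (n, m)
        assert fit.coefficient(2, 0) != 0.0  # defocus captures the sag
        # Z = -sag convention makes piston and defocus negative
        assert fit.coefficient(0, 0) < 0
        assert fit.coefficient(2, 0) < 0

    def test_split_sizes_and_points_beyond_rho_max_disregarded(self, small_grid):
        s = sphere_surface(7.8, small_grid)
        fit = fit_zernike(s, seed=0)
        n_inside = int((small_grid.node_rho() <= 5.0).sum())
        assert fit.n_points_fit + fit.n_points_validate == n_inside
        assert fit.n_points_fit == pytest.approx(4 * fit.n_points_validate, rel=0.01)

    def test_seed_determinism_and_split_dependence(self, small_grid):
        p_noisy = sphere_surface(7.8, small_grid)
        rng = np.random.default_rng(7)
        z = p_noisy.heights + rng.normal(0, 0.002, small_grid.shape)
        s = CornealSurface(small_grid, z - z[:, 0:1], "OD")
        f1 = fit_zernike(s, seed=5)
        f2 = fit_zernike(s, seed=5)
        f3 = fit_zernike(s, seed=6)
        assert f1.rms_error == f2.rms_error
        assert np.array_equal(f1.coefficients, f2.coefficients)
        assert f1.rms_error != f3.rms_error  # different split

    def test_fit_idempotence(self, small_grid):
        s = sphere_surface(7.8, small_grid)
        fit = fit_zernike(s, seed=0)
        recon = reconstruct_surface_heights(fit, s)
        s2 = CornealSurface(small_grid, recon, "OD")
        fit2 = fit_zernike(s2, seed=0)
        assert np.max(np.abs(fit2.coefficients - fit.coefficients)) < 1e-10

    def test_too_few_points_rejected(self):
        g = default_polar_grid(n_angles=4, n_radii=8)
        s = CornealSurface(g, np.zeros(g.shape), "OD")
        with pytest.raises(ValueError, match="too few"):
            fit_zernike(s)


class TestCohortComparison:
    def _fit_cohort(self, n, shift_term=None, shift=0.0, seed0=0):
        grid = default_polar_grid(n_angles=40, n_radii=61)
        basis = ZernikeBasis()
        fits = []
        rng = np.random.default_rng(seed0)
        for i in range(n):
            coeffs = np.zeros(basis.n_terms)
            coeffs[0] = -0.9
            coeffs[basis.terms.index((2, 0))] = -0.93
            coeffs += rng.normal(0, 0.001, basis.n_terms)
            if shift_term is not None:
                coeffs[basis.terms.index(shift_term)] += shift
            x, y = grid.node_xy()
            rho = np.clip(grid.node_rho() / basis.rho_max, 0, 1)
            phi = np.arctan2(y, x)
            z = sum(c * zernike_term(n_, m_, rho, phi)
                    for (n_, m_), c in zip(basis.terms, coeffs))
            z = np.where(grid.node_rho() <= 5.0, z, np.nan)
            fits.append(fit_zernike(CornealSurface(grid, z, "OD"), basis, seed=i))
        return fits

    def test_identical_cohorts_show_no_change(self):
        pre = self._fit_cohort(5)
        table = compare_coefficients(pre, list(pre))
        assert np.all(table["p_value"] == 1.0)
        assert not table["significant"].any()

    def test_injected_vertical_coma_shift_is_flagged(self):
        pre = self._fit_cohort(100, seed0=1)
        post = self._fit_cohort(100, shift_term=(3, -1), shift=0.01, seed0=2)
        table = compare_coefficients(pre, post, n_terms=None)
        coma = table[(table.n == 3) & (table.m == -1)].iloc[0]
        assert coma.p_value < 0.05
        untouched = table[~((table.n == 3) & (table.m == -1))]
        assert (~untouched.significant).mean() >= 0.90

    def test_single_eye_cohort_rejected(self):
        pre = self._fit_cohort(2)
        with pytest.raises(ValueError, match="at least 2"):
            compare_coefficients(pre[:1], pre[:1])

    def test_basis_mismatch_rejected(self, small_grid):
        a = fit_zernike(sphere_surface(7.8, small_grid), ZernikeBasis(n_max=4), seed=0)
        b = fit_zernike(sphere_surface(7.8, small_grid), ZernikeBasis(n_max=5), seed=0)
        with pytest.raises(ValueError, match="basis"):
            compare_coefficients([a, a], [b, b])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    n=st.integers(0, 6),
    rho=st.floats(0.0, 1.0),
    phi=st.floats(0.0, 2 * np.pi),
)
def test_zernike_terms_bounded_on_unit_disc(n, rho, phi):
    """Raw Zernike terms never exceed 1 in magnitude for rho in [0, 1]."""
    for m in range(-n, n + 1, 2):
        assert abs(zernike_term(n, m, rho, phi)) <= 1.0 + 1e-12
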