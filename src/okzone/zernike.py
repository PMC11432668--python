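"""Zernike polynomial fitting of corneal height maps.

The basis is the *raw* (unnormalised) Zernike set

    Z_n^m(rho, phi) = R_n^|m|(rho) * cos(m phi)     m >= 0
                    = R_n^|m|(rho) * sin(|m| phi)   m < 0

with the standard radial polynomial

    R_n^m(rho) = sum_k (-1)^k (n-k)! /
                 [ k! ((n+m)/2 - k)! ((n-m)/2 - k)! ] * rho^(n-2k).

No OSA/Noll normalisation constants are applied by default (so coefficients
are in the same mm height units as the surface); a ``normalised`` toggle adds
the sqrt(2(n+1)) / sqrt(n+1) factors for users who want the orthonormal set.

Surfaces are fitted in height space over a disc of radius ``rho_max``
(default 5 mm — the reliable central measurement area; data beyond it are
disregarded).  Following the Pareto principle, a seeded random 80% of the
valid points inside the disc are used for the least-squares fit and the
held-out 20% for the RMS validation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .surface import CornealSurface

__all__ = [
    "ZernikeBasis",
    "ZernikeFitResult",
    "zernike_radial",
    "zernike_term",
    "osa_index",
    "term_name",
    "fit_zernike",
    "reconstruct_surface_heights",
    "compare_coefficients",
]

#: Clinical names of the first 15 raw-elevation terms (OSA order).
_TERM_NAMES = {
    (0, 0): "Piston",
    (1, -1): "Vertical tilt",
    (1, 1): "Horizontal tilt",
    (2, -2): "Oblique astigmatism",
    (2, 0): "Defocus",
    (2, 2): "Vertical astigmatism",
    (3, -3): "Vertical trefoil",
    (3, -1): "Vertical coma",
    (3, 1): "Horizontal coma",
    (3, 3): "Oblique trefoil",
    (4, -4): "Oblique quatrefoil",
    (4, -2): "Oblique secondary astigmatism",
    (4, 0): "Primary spherical aberration",
    (4, 2): "Vertical secondary astigmatism",
    (4, 4): "Vertical quatrefoil",
}


def _check_nm(n: int, m: int) -> None:
    if n < 0 or abs(m) > n or (n - abs(m)) % 2 != 0:
        raise ValueError(f"invalid Zernike indices (n={n}, m={m}): need |m|<=n, n-|m| even")


def zernike_radial(n: int, m: int, rho: np.ndarray | float) -> np.ndarray | float:
    """Radial polynomial R_n^|m|(rho) for 0 <= rho <= 1."""
    _check_nm(n, m)
    m = abs(m)
    rho = np.asarray(rho, dtype=float)
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("rho must lie in [0, 1]")
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = (-1) ** k * factorial(n - k) / (
            factorial(k) * factorial((n + m) // 2 - k) * factorial((n - m) // 2 - k)
        )
        out = out + c * rho ** (n - 2 * k)
    return out if out.shape else float(out)


def zernike_term(
    n: int, m: int, rho: np.ndarray | float, phi: np.ndarray | float, normalised: bool = False
) -> np.ndarray | float:
    """Zernike surface term Z_n^m at (rho, phi), phi in radians."""
    _check_nm(n, m)
    r = zernike_radial(n, abs(m), rho)
    phi = np.asarray(phi, dtype=float)
    if m > 0:
        ang = np.cos(m * phi)
    elif m < 0:
        ang = np.sin(-m * phi)
    else:
        ang = np.ones_like(phi)
    out = r * ang
    if normalised:
        norm = np.sqrt(2.0 * (n + 1)) if m != 0 else np.sqrt(n + 1.0)
        out = out * norm
    return out


def osa_index(n: int, m: int) -> int:
    """OSA/ANSI single-index j = (n(n+2) + m) / 2."""
    _check_nm(n, m)
    return (n * (n + 2) + m) // 2


def term_name(n: int, m: int) -> str:
    return _TERM_NAMES.get((n, m), f"Z{n}^{m}")


@dataclass(frozen=True)
class ZernikeBasis:
    """Zernike basis up to radial order ``n_max`` over a disc of ``rho_max`` mm."""

    n_max: int = 5
    rho_max: float = 5.0
    normalised: bool = False

    def __post_init__(self) -> None:
        if self.n_max < 0:
            raise ValueError("n_max must be non-negative")
        if self.rho_max <= 0:
            raise ValueError("rho_max must be positive")

    @property
    def terms(self) -> list[tuple[int, int]]:
        """(n, m) pairs in OSA order; (n_max+1)(n_max+2)/2 terms (21 for n_max=5)."""
        return [(n, m) for n in range(self.n_max + 1) for m in range(-n, n + 1, 2)]

    @property
    def n_terms(self) -> int:
        return (self.n_max + 1) * (self.n_max + 2) // 2

    def design_matrix(self, rho: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Stack of basis terms evaluated at normalised rho in [0,1], phi in rad."""
        cols = [zernike_term(n, m, rho, phi, self.normalised) for n, m in self.terms]
        return np.column_stack([np.broadcast_to(c, rho.shape).ravel() for c in cols])


@dataclass
class ZernikeFitResult:
    """Raw Zernike coefficients (mm) with held-out RMS validation error."""

    basis: ZernikeBasis
    coefficients: np.ndarray  # mm, one per basis term, OSA order
    rms_error: float  # mm, on the held-out 20%
    n_points_fit: int
    n_points_validate: int
    seed: int
    condition_number: float = np.nan

    def coefficient(self, n: int, m: int) -> float:
        return float(self.coefficients[self.basis.terms.index((n, m))])

    def as_table(self, n_terms: int | None = 15) -> pd.DataFrame:
        """Coefficient table (term_index, n, m, name, coefficient_mm)."""
        rows = []
        terms = self.basis.terms if n_terms is None else self.basis.terms[:n_terms]
        for (n, m), c in zip(terms, self.coefficients):
            rows.append(
                {
                    "term_index": osa_index(n, m),
                    "n": n,
                    "m": m,
                    "name": term_name(n, m),
                    "coefficient_mm": float(c),
                }
            )
        return pd.DataFrame(rows)


def fit_zernike(
    surface: CornealSurface,
    basis: ZernikeBasis | None = None,
    seed: int = 0,
    validation_fraction: float = 0.2,
) -> ZernikeFitResult:
    """Least-squares Zernike fit of a corneal height surface.

    Valid nodes with rho_g <= rho_max are pooled; a seeded random
    ``1 - validation_fraction`` share (80% by default) enters the linear
    least-squares fit and the remainder yields the RMS error

        RMS = sqrt( sum_i (Zfit_i - Zsurf_i)^2 / N ).
    """
    if basis is None:
        basis = ZernikeBasis()
    x, y = surface.node_xy()
    rho_g = surface.node_rho()
    ok = (~surface.mask) & (rho_g <= basis.rho_max)
    n_ok = int(ok.sum())
    if n_ok < 2 * basis.n_terms:
        raise ValueError(
            f"too few valid points inside rho_max ({n_ok} < {2 * basis.n_terms})"
        )
    rho = rho_g[ok] / basis.rho_max
    phi = np.arctan2(y[ok], x[ok])
    z = surface.heights[ok]

    if not (0.0 <= validation_fraction < 1.0):
        raise ValueError("validation_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_ok)
    # validation_fraction = 0 fits on every point (and reports in-sample RMS),
    # preserving the sampling symmetry of the grid
    n_val = int(round(validation_fraction * n_ok)) if validation_fraction > 0 else 0
    n_val = max(1, n_val) if validation_fraction > 0 else 0
    val_idx, fit_idx = perm[:n_val], perm[n_val:]

    a_fit = basis.design_matrix(rho[fit_idx], phi[fit_idx])
    coef, _, rank, sv = np.linalg.lstsq(a_fit, z[fit_idx], rcond=None)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if rank < basis.n_terms:
        raise ValueError(
            f"rank-deficient Zernike design matrix (rank {rank} < {basis.n_terms}, "
            f"condition estimate {cond:.3g})"
        )
    eval_idx = val_idx if n_val > 0 else fit_idx
    a_val = basis.design_matrix(rho[eval_idx], phi[eval_idx])
    resid = a_val @ coef - z[eval_idx]
    rms = float(np.sqrt(np.mean(resid**2)))
    return ZernikeFitResult(
        basis=basis,
        coefficients=coef,
        rms_error=rms,
        n_points_fit=int(fit_idx.size),
        n_points_validate=int(val_idx.size),
        seed=seed,
        condition_number=cond,
    )


def reconstruct_surface_heights(
    fit: ZernikeFitResult, surface: CornealSurface
) -> np.ndarray:
    """Evaluate a fitted Zernike expansion on a surface's nodes (NaN outside rho_max)."""
    x, y = surface.node_xy()
    rho_g = surface.node_rho()
    inside = rho_g <= fit.basis.rho_max
    rho = np.where(inside, rho_g / fit.basis.rho_max, 0.0)
    phi = np.arctan2(y, x)
    a = fit.basis.design_matrix(rho.ravel(), phi.ravel())
    z = (a @ fit.coefficients).reshape(x.shape)
    return np.where(inside, z, np.nan)


def compare_coefficients(
    pre_fits: list[ZernikeFitResult],
    post_fits: list[ZernikeFitResult],
    n_terms: int | None = 15,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term cohort comparison of pre vs post coefficients (two-sample t-test).

    Returns a table with per-term mean/SD for both cohorts, the two-sided
    pooled-variance p-value and a significance flag at ``alpha``.
    """
    if len(pre_fits) < 2 or len(post_fits) < 2:
        raise ValueError("need at least 2 fits per cohort")
    basis = pre_fits[0].basis
    for f in (*pre_fits, *post_fits):
        if f.basis.terms != basis.terms or f.basis.normalised != basis.normalised:
            raise ValueError("all fits must share the same basis")
    pre = np.array([f.coefficients for f in pre_fits])
    post = np.array([f.coefficients for f in post_fits])
    terms = basis.terms if n_terms is None else basis.terms[:n_terms]
    rows = []
    for j, (n, m) in enumerate(terms):
        a, b = pre[:, j], post[:, j]
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0 and np.mean(a) == np.mean(b):
            p = 1.0
        else:
            p = float(ttest_ind(a, b, equal_var=True).pvalue)
        rows.append(
            {
                "term_index": osa_index(n, m),
                "n": n,
                "m": m,
                "name": term_name(n, m),
                "mean_pre": float(np.mean(a)),
                "sd_pre": float(np.std(a, ddof=1)),
                "mean_post": float(np.mean(b)),
                "sd_post": float(np.std(b, ddof=1)),
                "p_value": p,
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)
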