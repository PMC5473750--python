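"""REML variance components and Wald tests for the one-random-effect model.

Model per tested position k::

    y = X b + Xq bq + u + e,   u ~ N(0, A sigma_a^2),  e ~ N(0, I sigma_e^2)

where ``X`` is the covariate design (mating type and LYS2/URA3 auxotrophy
combinations), ``Xq`` the founder-allele membership design at the marker,
and ``A`` the LOCO allele-sharing kinship.  Estimation works in the
eigenbasis of ``A`` (negative eigenvalues truncated at 0): with
``A = U diag(d) U'``, rotating by ``U'`` turns the covariance into
``diag(gamma * d + 1) * sigma_e^2`` with ``gamma = sigma_a^2 / sigma_e^2``,
and the restricted likelihood can be profiled down to a 1-D search in
``log10(gamma)``.

The Wald statistic tests the allele fixed-effect block under sum-to-zero
contrast coding (df = q - 1, chi-square upper tail), with the variance
components treated as known at their REML estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

_LOG10_RATIO_BOUNDS = (-5.0, 5.0)
_GRID_POINTS = 21
_FLAT_TOL = 1e-8
_TINY_P = 5e-324


class SingularDesignError(ValueError):
    """Joint fixed-effect design is rank deficient after contrast coding."""


@dataclass
class VarianceComponents:
    """REML estimates of the polygenic and residual variances."""

    sigma_a2: float
    sigma_e2: float
    h2: float
    reml_loglik: float
    identifiable: bool


@dataclass
class WaldTestResult:
    """Chi-square Wald test of the allele fixed-effect block."""

    statistic: float
    df: int
    p_value: float
    allele_effects: np.ndarray | None = None


def psd_eigh(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a symmetric matrix with eigenvalues clipped at 0.

    Allele-share matrices need not be PSD in finite samples; truncation
    defines the (PSD) covariance actually used by the model.
    """
    d, U = np.linalg.eigh(A)
    return np.clip(d, 0.0, None), U


def _restricted_loglik(ratio: float, d: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> float:
    """Profiled REML log-likelihood at variance ratio ``gamma = sa2/se2``."""
    n, p = Xr.shape
    w = ratio * d + 1.0
    sw = 1.0 / np.sqrt(w)
    Xw = Xr * sw[:, None]
    yw = yr * sw
    G = Xw.T @ Xw
    sign, logdet_g = np.linalg.slogdet(G)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(G, Xw.T @ yw)
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    if rss <= 0:
        return -np.inf
    sigma_e2 = rss / (n - p)
    return -0.5 * (
        (n - p) * np.log(2.0 * np.pi * sigma_e2)
        + float(np.sum(np.log(w)))
        + logdet_g
        + (n - p)
    )


def _sigma_e2_at(ratio: float, d: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> float:
    n, p = Xr.shape
    w = ratio * d + 1.0
    sw = 1.0 / np.sqrt(w)
    Xw = Xr * sw[:, None]
    yw = yr * sw
    beta = np.linalg.lstsq(Xw, yw, rcond=None)[0]
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    return rss / (n - p)


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    A: np.ndarray | None = None,
    *,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarianceComponents:
    """Maximize the restricted likelihood over (sigma_a^2, sigma_e^2).

    ``eig`` may carry a precomputed ``psd_eigh(A)`` to amortize the
    decomposition across markers.  The profile over ``log10(gamma)`` is
    evaluated on a 21-point grid on [-5, 5], then refined with bounded
    scalar minimization to ~1e-6 relative; ties (a flat profile, e.g.
    ``A = I``) are broken toward smaller ``sigma_a^2`` and flagged
    ``identifiable=False``.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    if not np.isfinite(y).all():
        raise ValueError("phenotype vector contains non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("phenotype vector is constant; variance components undefined")
    if X.shape[0] != n:
        raise ValueError("design row count != phenotype length")
    p = np.linalg.matrix_rank(X)
    if p < X.shape[1]:
        raise SingularDesignError("fixed-effect design is rank deficient")
    if n < p + 2:
        raise ValueError("too few observations for REML")

    if eig is None:
        if A is None:
            raise ValueError("either A or its eigendecomposition is required")
        eig = psd_eigh(A)
    d, U = eig
    yr = U.T @ y
    Xr = U.T @ X

    grid = np.linspace(*_LOG10_RATIO_BOUNDS, _GRID_POINTS)
    ll = np.array([_restricted_loglik(10.0 ** g, d, yr, Xr) for g in grid])
    if not np.isfinite(ll).any():
        raise ValueError("restricted likelihood non-finite over the whole grid")
    spread = np.nanmax(ll[np.isfinite(ll)]) - np.nanmin(ll[np.isfinite(ll)])
    if spread < _FLAT_TOL:
        # Profile flat in the ratio (e.g. A = I): only the total variance is
        # identified.  Report it all as residual (the smaller-sigma_a2 tie
        # break) and flag non-identifiability.
        sigma_e2 = _sigma_e2_at(0.0, d, yr, Xr)
        return VarianceComponents(0.0, sigma_e2, 0.0, float(ll[0]), False)

    i = int(np.nanargmax(np.where(np.isfinite(ll), ll, -np.inf)))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda t: -_restricted_loglik(10.0 ** t, d, yr, Xr),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-7},
    )
    best_t, best_ll = float(grid[i]), float(ll[i])
    if np.isfinite(res.fun) and -res.fun >= best_ll:
        best_t, best_ll = float(res.x), float(-res.fun)
    # Tie break toward smaller sigma_a2 at the lower boundary.
    if best_ll - float(ll[0]) < _FLAT_TOL:
        best_t = grid[0]
        best_ll = float(ll[0])
    ratio = 10.0 ** best_t
    sigma_e2 = _sigma_e2_at(ratio, d, yr, Xr)
    sigma_a2 = ratio * sigma_e2
    if best_t <= _LOG10_RATIO_BOUNDS[0]:
        sigma_a2 = 0.0
    h2 = sigma_a2 / (sigma_a2 + sigma_e2)
    if not np.isfinite(best_ll):
        raise ValueError("restricted likelihood non-finite at the optimum")
    return VarianceComponents(sigma_a2, sigma_e2, h2, best_ll, True)


def sum_to_zero_contrasts(q: int, reference: int | None = None) -> np.ndarray:
    """q x (q-1) sum-to-zero contrast matrix.

    Column j carries allele j's deviation; the ``reference`` allele row
    (default: last) is ``-1`` everywhere so deviations sum to zero.  The
    column space (hence the Wald statistic) does not depend on the choice
    of reference.
    """
    if q < 2:
        raise ValueError("contrasts require >= 2 alleles")
    ref = q - 1 if reference is None else reference
    others = [j for j in range(q) if j != ref]
    T = np.zeros((q, q - 1))
    for col, j in enumerate(others):
        T[j, col] = 1.0
        T[ref, col] = -1.0
    return T


def wald_test(
    y: np.ndarray,
    X: np.ndarray,
    Xq: np.ndarray,
    A: np.ndarray | None,
    vc: VarianceComponents,
    *,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    reference: int | None = None,
) -> WaldTestResult:
    """GLS Wald test of the allele block under V = sa2 * A + se2 * I.

    Returns the chi-square statistic on df = q - 1, its upper-tail p-value
    and the per-allele effect deviations (sum-to-zero scale).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    q = Xq.shape[1]
    if q < 2:
        raise SingularDesignError("monomorphic marker: no allele contrast exists")
    T = sum_to_zero_contrasts(q, reference)
    D = np.hstack([X, Xq @ T])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise SingularDesignError("joint covariate + allele design is singular")

    if eig is None:
        if A is None:
            raise ValueError("either A or its eigendecomposition is required")
        eig = psd_eigh(A)
    d, U = eig
    w = vc.sigma_a2 * d + vc.sigma_e2
    if (w <= 0).any():
        raise ValueError("non-positive marginal variances; check variance components")
    sw = 1.0 / np.sqrt(w)
    Dw = (U.T @ D) * sw[:, None]
    yw = (U.T @ y) * sw
    G = Dw.T @ Dw
    b = np.linalg.solve(G, Dw.T @ yw)
    cov = np.linalg.inv(G)
    nq = q - 1
    b_blk = b[-nq:]
    cov_blk = cov[-nq:, -nq:]
    stat = float(b_blk @ np.linalg.solve(cov_blk, b_blk))
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, nq))
    p = max(p, _TINY_P)
    deviations = T @ b_blk
    return WaldTestResult(stat, nq, p, deviations)
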