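"""O'Sullivan penalized splines and their mixed-model reparameterization.

An O'Sullivan spline is a cubic B-spline smoother penalized by the integrated
squared second derivative, Omega[j, k] = \\int B_j''(t) B_k''(t) dt. The
penalty has a two-dimensional null space (constant and linear functions), so
the smoother splits into an unpenalized linear part and a penalized deviation
part. Writing the eigendecomposition Omega = U diag(d) U^T and keeping the
eigenpairs with d > 0, the reparameterized design Z = B U_+ diag(d_+)^{-1/2}
turns the ridge problem

    min ||y - B c||^2 + lam * c^T Omega c

into an ordinary mixed model

    y = X_lin beta + Z u,   u ~ N(0, (1/lam) I),

which is the form the Bayesian GAMM samples. Five interior knots per smoother
are placed at equally spaced quantiles of the observed season-days, so knot
positions vary between species without being sampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .errors import DecompositionError, DegenerateInputError, RangeError

#: relative eigenvalue cutoff separating the penalty null space
NULLSPACE_TOL = 1e-10
#: boundary knots sit this fraction of the data range beyond min/max
BOUNDARY_PAD = 1e-3


def place_knots(x, n_knots: int) -> np.ndarray:
    """Interior knots at equally spaced sample quantiles of distinct x values.

    Quantile levels are k/(n_knots+1), k = 1..n_knots, so five knots split the
    distinct observed days into six equal-probability bins.
    """
    if n_knots < 1:
        raise DegenerateInputError("n_knots must be >= 1")
    xd = np.unique(np.asarray(x, dtype=float))
    if xd.size < max(n_knots + 1, 2):
        raise DegenerateInputError(
            f"need more than {n_knots} distinct values to place {n_knots} knots, got {xd.size}"
        )
    levels = np.arange(1, n_knots + 1) / (n_knots + 1)
    knots = np.quantile(xd, levels)
    if np.any(np.diff(knots) <= 0):
        raise DegenerateInputError("tied quantiles: too few distinct values for the knot count")
    return knots


def _full_knot_vector(knots, boundary, degree):
    lo, hi = map(float, boundary)
    knots = np.asarray(knots, dtype=float)
    if knots.size and (knots[0] <= lo or knots[-1] >= hi):
        raise RangeError("interior knots must lie strictly inside the boundary")
    return np.concatenate([[lo] * (degree + 1), knots, [hi] * (degree + 1)])


def bspline_design(x, knots, boundary, degree: int = 3) -> np.ndarray:
    """Cubic (by default) B-spline design matrix on [lower, upper].

    Rows form a partition of unity; K = #interior knots + degree + 1 columns.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    lo, hi = map(float, boundary)
    if np.any(x < lo) or np.any(x > hi):
        raise RangeError(f"x outside boundary [{lo}, {hi}]")
    t = _full_knot_vector(knots, boundary, degree)
    return BSpline.design_matrix(x, t, degree, extrapolate=False).toarray()


def penalty_matrix(knots, boundary, degree: int = 3) -> np.ndarray:
    """Integrated squared-second-derivative penalty Omega[j,k] = int B_j'' B_k''.

    Computed exactly by Gauss-Legendre quadrature on each inter-knot interval
    (the integrand is piecewise polynomial of degree 2*(degree-2), so a 4-point
    rule is exact for cubics and well beyond).
    """
    t = _full_knot_vector(knots, boundary, degree)
    K = len(t) - degree - 1
    spl = BSpline(t, np.eye(K), degree)
    d2 = spl.derivative(2)
    breaks = np.unique(t)
    # 4-point Gauss-Legendre nodes/weights on [-1, 1]
    nodes, weights = np.polynomial.legendre.leggauss(4)
    omega = np.zeros((K, K))
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (b - a)
        xg = 0.5 * (a + b) + half * nodes
        Bg = d2(xg)  # (4, K)
        omega += half * (Bg * weights[:, None]).T @ Bg
    return 0.5 * (omega + omega.T)


@dataclass
class SplineBasis:
    """O'Sullivan basis in mixed-model form for one smoother.

    ``x_lin`` is the centered linear column and ``Z`` the penalized design for
    the fitted x; ``transform`` maps any raw B-spline design matrix onto the Z
    columns so the smoother can be evaluated on new points.
    """

    knots: np.ndarray
    boundary: tuple[float, float]
    degree: int
    x_mean: float
    x_lin: np.ndarray  # (n,)
    Z: np.ndarray  # (n, q)
    transform: np.ndarray  # (K, q)
    penalty_eigenvalues: np.ndarray  # (q,), all > 0

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def design_at(self, xnew) -> tuple[np.ndarray, np.ndarray]:
        """(centered linear column, Z matrix) evaluated at new points."""
        B = bspline_design(xnew, self.knots, self.boundary, self.degree)
        return np.asarray(xnew, dtype=float) - self.x_mean, B @ self.transform


def mixed_model_rep(B: np.ndarray, omega: np.ndarray, x=None) -> SplineBasis | tuple:
    """Spectral reparameterization of (B, Omega) into fixed-linear + random parts.

    Returns ``(Z, transform, eigenvalues)`` when ``x`` is None; with ``x``
    given, a full :class:`SplineBasis` is assembled (this is what
    :func:`osullivan_basis` uses).
    """
    omega = np.asarray(omega, dtype=float)
    K = omega.shape[0]
    d, U = np.linalg.eigh(omega)
    tol = NULLSPACE_TOL * d.max()
    null = d < tol
    if null.sum() != 2:
        raise DecompositionError(
            f"penalty null space has dimension {int(null.sum())}, expected 2 (constant + linear)"
        )
    d_pos, U_pos = d[~null], U[:, ~null]
    transform = U_pos / np.sqrt(d_pos)
    Z = B @ transform
    if x is None:
        return Z, transform, d_pos
    x = np.asarray(x, dtype=float)
    return SplineBasis(
        knots=None, boundary=None, degree=None,  # filled by osullivan_basis
        x_mean=float(x.mean()), x_lin=x - x.mean(), Z=Z,
        transform=transform, penalty_eigenvalues=d_pos,
    )


def osullivan_basis(x, n_knots: int = 5, degree: int = 3) -> SplineBasis:
    """Build the full O'Sullivan mixed-model basis for observed values x.

    Knots at sample quantiles; boundary knots at min/max extended by a small
    fraction of the range to avoid edge degeneracy.
    """
    x = np.asarray(x, dtype=float)
    knots = place_knots(x, n_knots)
    rng = x.max() - x.min()
    if rng <= 0:
        raise DegenerateInputError("x has zero range")
    boundary = (x.min() - BOUNDARY_PAD * rng, x.max() + BOUNDARY_PAD * rng)
    B = bspline_design(x, knots, boundary, degree)
    omega = penalty_matrix(knots, boundary, degree)
    basis = mixed_model_rep(B, omega, x=x)
    basis.knots = knots
    basis.boundary = boundary
    basis.degree = degree
    return basis
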