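"""Exact Pólya-Gamma PG(1, z) sampling (Devroye alternating-series method).

Bernoulli-logit likelihoods admit the augmentation

    1 / (1 + e^{-eta}) = 2^{-1} e^{eta/2} E_omega[ e^{-omega eta^2 / 2} ],
    omega ~ PG(1, 0),

so conditionally on omega ~ PG(1, eta) the logistic model becomes Gaussian and
every coefficient block of the GAMM has a closed-form Gibbs update. PG(1, z)
is J*(1, z/2)/4 where J* is the tilted Jacobi distribution; J* is sampled by
rejection from a mixture of a truncated exponential (right tail) and a
truncated inverse-Gaussian (left of the truncation point 0.64), with the
alternating-series acceptance test of Devroye. The identity
E[PG(1, z)] = tanh(z/2) / (2 z) provides a closed-form check.

The scalar kernels are numba-compiled and use numba's own thread-local
np.random state; call :func:`seed_pg` before a sequence of draws to make the
stream reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TRUNC = 0.64
_HALFPISQ = 0.5 * math.pi * math.pi


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _a_coef(n, x):
    """n-th term of the alternating series for the J* density at x."""
    npf = n + 0.5
    if x > _TRUNC:
        return math.pi * npf * math.exp(-npf * npf * math.pi * math.pi * 0.5 * x)
    return (
        math.pi
        * npf
        * (2.0 / (math.pi * x)) ** 1.5
        * math.exp(-2.0 * npf * npf / x)
    )


@njit(cache=True)
def _pigauss_cdf(t, z):
    """CDF at t of inverse-Gaussian(mu = 1/z, lambda = 1); z may be 0 (mu -> inf)."""
    st = math.sqrt(t)
    if z <= 0.0:
        return 2.0 * _norm_cdf(-1.0 / st)
    a = _norm_cdf((t * z - 1.0) / st)
    tail = _norm_cdf(-(t * z + 1.0) / st)
    if tail <= 0.0:
        return a
    return a + math.exp(2.0 * z) * tail


@njit(cache=True)
def _trunc_invgauss(z, t):
    """Inverse-Gaussian(1/z, 1) truncated to (0, t); z >= 0."""
    if z * t < 1.0:
        # mean beyond the truncation point: sample 1/chi^2-style proposal,
        # thin by the exp(-z^2 X / 2) tilt
        while True:
            while True:
                e1 = -math.log(np.random.random())
                e2 = -math.log(np.random.random())
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            if np.random.random() <= math.exp(-0.5 * z * z * x):
                return x
    else:
        mu = 1.0 / z
        while True:
            y = np.random.normal()
            y *= y
            muy = mu * y
            x = mu + 0.5 * mu * (muy - math.sqrt(4.0 * muy + muy * muy))
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
            if x < t:
                return x


@njit(cache=True)
def _pg1_draw(zval):
    """One draw from PG(1, zval)."""
    z = 0.5 * abs(zval)
    fz = math.pi * math.pi * 0.125 + 0.5 * z * z
    p = (0.5 * math.pi / fz) * math.exp(-fz * _TRUNC)
    q = 2.0 * math.exp(-z) * _pigauss_cdf(_TRUNC, z)
    ratio = p / (p + q)
    while True:
        if np.random.random() < ratio:
            x = _TRUNC - math.log(np.random.random()) / fz
        else:
            x = _trunc_invgauss(z, _TRUNC)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return 0.25 * x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


@njit(cache=True)
def _pg1_array(z, out):
    for i in range(z.shape[0]):
        out[i] = _pg1_draw(z[i])


@njit(cache=True)
def seed_pg(seed):
    """Seed numba's thread-local random stream used by the PG kernels."""
    np.random.seed(seed)


def pg_draw(z: np.ndarray) -> np.ndarray:
    """Vector of independent PG(1, z_i) draws (call :func:`seed_pg` first)."""
    z = np.ascontiguousarray(np.asarray(z, dtype=np.float64))
    out = np.empty_like(z)
    _pg1_array(z, out)
    return out


def pg_mean(z) -> np.ndarray:
    """Closed-form E[PG(1, z)] = tanh(z/2)/(2z), with the z -> 0 limit 1/4."""
    z = np.asarray(z, dtype=float)
    out = np.full(z.shape, 0.25)
    nz = np.abs(z) > 1e-8
    out[nz] = np.tanh(z[nz] / 2.0) / (2.0 * z[nz])
    return out
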