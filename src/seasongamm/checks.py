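"""Posterior-predictive assessment and model comparison.

The headline fit statistic is a Bayesian p-value: for each retained draw a
replicate response vector is simulated from the fitted Bernoulli
probabilities, the Pearson chi-square discrepancy is computed for replicate
and observed data at that draw's probabilities, and the overall probability
is the fraction of draws in which the replicate discrepancy exceeds the
observed one. A well-specified model calibrates this to ~0.5; values near 0
or 1 signal misfit. Per-observation replicate frequencies are reported
alongside. Model comparison between per-species and shared smoothers uses
DIC (with WAIC as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import expit

from .model import GammSpec, PosteriorDraws


def pearson_chisq(y: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Sum over observations of (y - pi)^2 / (pi (1 - pi)); rows = draws."""
    pi = np.clip(pi, 1e-12, 1 - 1e-12)
    return np.sum((y - pi) ** 2 / (pi * (1.0 - pi)), axis=-1)


@dataclass
class PpcResult:
    """Posterior-predictive check output."""

    overall_probability: float  # P(T(y_rep) > T(y) | data), Pearson discrepancy
    per_observation: np.ndarray  # replicate frequency of a 1, per observation
    discrepancy: str = "pearson_chisq"
    n_draws_used: int = 0


def _fitted_probabilities(draws: PosteriorDraws, spec: GammSpec,
                          max_draws: int | None) -> np.ndarray:
    coef = draws.stacked_coef()
    if max_draws is not None and coef.shape[0] > max_draws:
        idx = np.linspace(0, coef.shape[0] - 1, max_draws).astype(int)
        coef = coef[idx]
    return expit(coef @ spec.X.T)  # (draws, n_obs)


def posterior_predictive_check(draws: PosteriorDraws, spec: GammSpec, seed: int = 0,
                               discrepancy: Callable | None = None,
                               max_draws: int | None = 2000) -> PpcResult:
    """Simulate replicate surveys from the posterior and score the fit.

    ``discrepancy(y, pi)`` is pluggable and defaults to the Pearson
    chi-square. At most ``max_draws`` evenly spaced retained draws are used.
    Reproducible given ``seed``; invariant to observation order.
    """
    discrepancy = discrepancy or pearson_chisq
    pi = _fitted_probabilities(draws, spec, max_draws)
    rng = np.random.default_rng(seed)
    y_rep = rng.random(pi.shape) < pi
    t_rep = discrepancy(y_rep.astype(float), pi)
    t_obs = discrepancy(spec.y[None, :], pi)
    return PpcResult(
        overall_probability=float(np.mean(t_rep > t_obs)),
        per_observation=y_rep.mean(axis=0),
        discrepancy=getattr(discrepancy, "__name__", "custom"),
        n_draws_used=pi.shape[0],
    )


def _bernoulli_deviance(y: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """-2 log-likelihood per draw; pi rows = draws."""
    pi = np.clip(pi, 1e-12, 1 - 1e-12)
    return -2.0 * np.sum(y * np.log(pi) + (1.0 - y) * np.log1p(-pi), axis=-1)


def dic(draws: PosteriorDraws, spec: GammSpec, max_draws: int | None = 2000):
    """Deviance information criterion: DIC = Dbar + pD, pD = Dbar - D(theta_bar).

    Smaller is better; pD is the effective number of parameters. Supports the
    per-species vs shared smoother comparison.
    """
    coef = draws.stacked_coef()
    if max_draws is not None and coef.shape[0] > max_draws:
        idx = np.linspace(0, coef.shape[0] - 1, max_draws).astype(int)
        coef = coef[idx]
    pi = expit(coef @ spec.X.T)
    d_bar = float(np.mean(_bernoulli_deviance(spec.y, pi)))
    pi_at_mean = expit(spec.X @ coef.mean(axis=0))
    d_at_mean = float(_bernoulli_deviance(spec.y, pi_at_mean[None, :])[0])
    p_d = d_bar - d_at_mean
    return d_bar + p_d, p_d


def waic(draws: PosteriorDraws, spec: GammSpec, max_draws: int | None = 2000):
    """WAIC = -2(lppd - p_waic); alternative to DIC."""
    pi = _fitted_probabilities(draws, spec, max_draws)
    pi = np.clip(pi, 1e-12, 1 - 1e-12)
    loglik = spec.y * np.log(pi) + (1.0 - spec.y) * np.log1p(-pi)  # (draws, n)
    lppd = float(np.sum(np.log(np.mean(np.exp(loglik), axis=0))))
    p_waic = float(np.sum(np.var(loglik, axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic), p_waic


@dataclass
class ResidualDiagnostics:
    """Pearson-residual summaries at the posterior mean fit."""

    pearson_residuals: np.ndarray  # per observation
    dispersion: float  # cell-aggregated sum r^2 / (cells - pD); ~1 when calibrated
    trend_magnitude: float  # max |cubic trend of residuals vs day|
    effective_df: float
    n_cells: int = 0


def residual_diagnostics(draws: PosteriorDraws, spec: GammSpec,
                         day: np.ndarray | None = None) -> ResidualDiagnostics:
    """Overdispersion and residual-trend diagnostics.

    Residuals use the posterior-mean fitted probabilities. For the dispersion
    statistic, observations sharing an identical covariate row are pooled
    into binomial cells (a 0/1 response carries no overdispersion signal on
    its own; dependence between replicate observations only shows up at the
    cell level): dispersion = sum of squared cell Pearson residuals divided
    by (number of cells - pD), with pD the DIC effective parameter count.
    The trend statistic is the max absolute value of a cubic polynomial
    fitted to residual-vs-day (zero-ish when the smoothers captured the
    seasonality).
    """
    pi_bar = _fitted_probabilities(draws, spec, 2000).mean(axis=0)
    pi_bar = np.clip(pi_bar, 1e-12, 1 - 1e-12)
    resid = (spec.y - pi_bar) / np.sqrt(pi_bar * (1.0 - pi_bar))
    _, p_d = dic(draws, spec)
    _, cell_of = np.unique(spec.X, axis=0, return_inverse=True)
    n_cells = int(cell_of.max()) + 1
    m = np.bincount(cell_of, minlength=n_cells).astype(float)
    y_cell = np.bincount(cell_of, weights=spec.y, minlength=n_cells)
    # pi_bar is constant within a cell (identical covariates)
    pi_cell = np.bincount(cell_of, weights=pi_bar, minlength=n_cells) / m
    r_cell = (y_cell - m * pi_cell) / np.sqrt(m * pi_cell * (1.0 - pi_cell))
    df = max(n_cells - p_d, 1.0)
    dispersion = float(np.sum(r_cell**2) / df)
    if day is None:
        # reconstruct day from the smoother linear columns (sum of centered
        # per-group columns + group means on each group's rows)
        day = np.zeros(spec.n_obs)
        for name in spec.smoother_names:
            col = spec.X[:, spec.blocks[f"slope_{name}"].start]
            rows = col != 0
            day[rows] = col[rows] + spec.lin_offsets[name]
    coeffs = np.polyfit(day, resid, 3)
    grid = np.linspace(day.min(), day.max(), 200)
    trend = float(np.max(np.abs(np.polyval(coeffs, grid))))
    return ResidualDiagnostics(pearson_residuals=resid, dispersion=dispersion,
                               trend_magnitude=trend, effective_df=float(df),
                               n_cells=n_cells)
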