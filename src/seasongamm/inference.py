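"""Posterior inferential products: smoother curves, fitted probability curves,
pairwise smoother contrasts, and baseline-recoded species contrast tables.

All interval summaries are equal-tailed pointwise percentiles of the retained
draws (2.5% / 97.5%), matching standard Gibbs-sampler summary output. A grid
point is flagged "important" when its 95% credible interval excludes zero.
Population-level curves set the lake and year random intercepts to zero; a
marginalized variant integrates them out by Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ExtrapolationError, ValidationError
from .model import GammSpec, PosteriorDraws
from .survey import SPECIES


@dataclass
class SmootherCurve:
    """Posterior mean and 95% band of a smooth curve on a day grid."""

    species: str
    grid: np.ndarray
    mean: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    draw_matrix: np.ndarray | None = None  # (draws, grid points)
    scale: str = "logit"  # or "probability"


@dataclass
class ContrastCurve:
    """Pointwise posterior difference between two species' seasonal curves."""

    species_pair: tuple[str, str]
    grid: np.ndarray
    mean: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    important: np.ndarray  # bool mask: 95% CrI excludes 0
    includes_species_effect: bool = True
    draw_matrix: np.ndarray | None = None


@dataclass
class ContrastTable:
    """Species contrasts under a chosen baseline, plus random-SD summaries."""

    baseline: str
    rows: pd.DataFrame  # parameter, mean, lower95, upper95, important

    def __getitem__(self, parameter: str) -> pd.Series:
        return self.rows.set_index("parameter").loc[parameter]


def _summarize(draw_matrix: np.ndarray):
    mean = draw_matrix.mean(axis=0)
    lower, upper = np.percentile(draw_matrix, [2.5, 97.5], axis=0)
    return mean, lower, upper


def _smoother_block_for(spec: GammSpec, species: str) -> str:
    if species not in SPECIES:
        raise ValidationError(f"unknown species {species!r}")
    return species if spec.smoother_mode == "per_species" else "shared"


def _check_grid(spec: GammSpec, block: str, grid: np.ndarray):
    lo, hi = spec.day_ranges[block]
    if grid[0] < lo or grid[-1] > hi:
        raise ExtrapolationError(
            f"grid [{grid[0]}, {grid[-1]}] outside fitted day range [{lo}, {hi}] "
            f"for smoother {block!r}; no silent extrapolation"
        )
    if np.any(np.diff(grid) <= 0):
        raise ValidationError("grid must be strictly increasing")


def default_grid(spec: GammSpec, species: str, n: int = 100) -> np.ndarray:
    """100 equally spaced days over the species' observed day range."""
    lo, hi = spec.day_ranges[_smoother_block_for(spec, species)]
    return np.linspace(lo, hi, n)


def _smoother_draws(draws: PosteriorDraws, spec: GammSpec, species: str,
                    grid: np.ndarray) -> np.ndarray:
    """Per-draw evaluation of the centered smoother on the grid: (draws, G)."""
    block = _smoother_block_for(spec, species)
    _check_grid(spec, block, grid)
    basis = spec.bases[block]
    # re-apply the within-group centering used at fit time
    lin, Zg_raw = basis.design_at(grid)
    Zg = Zg_raw - spec.z_offsets[block]
    coef = draws.stacked_coef()
    slope = coef[:, spec.blocks[f"slope_{block}"]]  # (D, 1)
    u = coef[:, spec.blocks[f"u_{block}"]]  # (D, q)
    return slope @ lin[None, :] + u @ Zg.T


def _species_effect_draws(draws: PosteriorDraws, spec: GammSpec, species: str) -> np.ndarray:
    """Per-draw species main effect relative to the model baseline (0 for it)."""
    coef = draws.stacked_coef()
    if species == spec.baseline:
        return np.zeros(coef.shape[0])
    non_base = [s for s in spec.species_order if s != spec.baseline]
    j = spec.blocks["species"].start + non_base.index(species)
    return coef[:, j]


def smoother_curve(draws: PosteriorDraws, spec: GammSpec, species: str,
                   grid: np.ndarray | None = None,
                   keep_draws: bool = False) -> SmootherCurve:
    """Posterior mean and 95% band of the species' centered smoother f_s(Day)."""
    if grid is None:
        grid = default_grid(spec, species)
    grid = np.asarray(grid, dtype=float)
    mat = _smoother_draws(draws, spec, species, grid)
    mean, lo, hi = _summarize(mat)
    return SmootherCurve(species=species, grid=grid, mean=mean, lower95=lo,
                         upper95=hi, draw_matrix=mat if keep_draws else None)


def fitted_probability_curve(draws: PosteriorDraws, spec: GammSpec, species: str,
                             grid: np.ndarray | None = None,
                             marginalize_random: bool = False,
                             n_marginal: int = 64,
                             rng: np.random.Generator | None = None,
                             keep_draws: bool = False) -> SmootherCurve:
    """Population-level infection probability curve for one species.

    Per draw, eta(day) = intercept + species effect + smoother(day) with the
    random intercepts at zero, then the inverse logit is applied draw-by-draw
    (never to the posterior-mean eta). ``marginalize_random=True`` instead
    averages expit(eta + a + b) over Monte-Carlo lake/year effects drawn from
    that iteration's N(0, sigma^2) laws.
    """
    if grid is None:
        grid = default_grid(spec, species)
    grid = np.asarray(grid, dtype=float)
    eta = _smoother_draws(draws, spec, species, grid)
    coef = draws.stacked_coef()
    eta = eta + coef[:, spec.blocks["intercept"].start][:, None]
    eta = eta + _species_effect_draws(draws, spec, species)[:, None]
    if marginalize_random:
        rng = rng or np.random.default_rng(0)
        sd = np.sqrt(draws.sd_lake.reshape(-1) ** 2 + draws.sd_year.reshape(-1) ** 2)
        shocks = rng.standard_normal(n_marginal)
        prob = np.mean(
            [expit(eta + (sd * s)[:, None]) for s in shocks], axis=0
        )
    else:
        prob = expit(eta)
    mean, lo, hi = _summarize(prob)
    return SmootherCurve(species=species, grid=grid, mean=mean, lower95=lo,
                         upper95=hi, draw_matrix=prob if keep_draws else None,
                         scale="probability")


def smoother_contrast(draws: PosteriorDraws, spec: GammSpec,
                      species_a: str, species_b: str,
                      grid: np.ndarray | None = None,
                      include_species_effect: bool = True,
                      keep_draws: bool = False) -> ContrastCurve:
    """Pointwise posterior difference between two species' seasonal curves.

    By default the difference includes both the species main effects and the
    smoother difference (total preference on the logit scale); with
    ``include_species_effect=False`` it is the pure smoother difference.
    """
    if grid is None:
        lo_a, hi_a = spec.day_ranges[_smoother_block_for(spec, species_a)]
        lo_b, hi_b = spec.day_ranges[_smoother_block_for(spec, species_b)]
        grid = np.linspace(max(lo_a, lo_b), min(hi_a, hi_b), 100)
    grid = np.asarray(grid, dtype=float)
    diff = (_smoother_draws(draws, spec, species_a, grid)
            - _smoother_draws(draws, spec, species_b, grid))
    if include_species_effect:
        delta = (_species_effect_draws(draws, spec, species_a)
                 - _species_effect_draws(draws, spec, species_b))
        diff = diff + delta[:, None]
    mean, lo, hi = _summarize(diff)
    mask = (lo > 0) | (hi < 0)
    return ContrastCurve(species_pair=(species_a, species_b), grid=grid,
                         mean=mean, lower95=lo, upper95=hi, important=mask,
                         includes_species_effect=include_species_effect,
                         draw_matrix=diff if keep_draws else None)


def species_contrast_table(draws: PosteriorDraws, spec: GammSpec,
                           baseline: str) -> ContrastTable:
    """Species effects re-expressed against a chosen baseline, by differencing
    draws (no refit), plus the random-intercept SD summaries.

    The intercept row is the linear-predictor level of the baseline species
    (model intercept + its species effect); each species row is that species'
    effect minus the baseline's, flagged when the 95% CrI excludes zero.
    """
    if baseline not in SPECIES:
        raise ValidationError(f"unknown baseline {baseline!r}")
    coef = draws.stacked_coef()
    base_eff = _species_effect_draws(draws, spec, baseline)
    rows = []
    intercept = coef[:, spec.blocks["intercept"].start] + base_eff
    m, lo, hi = _summarize(intercept[:, None])
    rows.append((f"intercept[{baseline}]", m[0], lo[0], hi[0], bool(lo[0] > 0 or hi[0] < 0)))
    for s in spec.species_order:
        if s == baseline:
            continue
        d = _species_effect_draws(draws, spec, s) - base_eff
        m, lo, hi = _summarize(d[:, None])
        rows.append((f"species[{s}]", m[0], lo[0], hi[0], bool(lo[0] > 0 or hi[0] < 0)))
    for label, arr in (("sigma_lake", draws.sd_lake), ("sigma_year", draws.sd_year)):
        m, lo, hi = _summarize(arr.reshape(-1, 1))
        rows.append((label, m[0], lo[0], hi[0], False))
    frame = pd.DataFrame(rows, columns=["parameter", "mean", "lower95", "upper95", "important"])
    return ContrastTable(baseline=baseline, rows=frame)


def occupancy_window(curve: SmootherCurve, threshold: float):
    """First and last grid day whose posterior mean exceeds the threshold.

    Returns ``None`` when the curve never exceeds it. Intended for
    probability-scale curves (e.g. the day span over which a species is used).
    """
    above = np.flatnonzero(curve.mean > threshold)
    if above.size == 0:
        return None
    return float(curve.grid[above[0]]), float(curve.grid[above[-1]])
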