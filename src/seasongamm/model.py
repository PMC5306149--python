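"""Bernoulli GAMM specification and MCMC sampling.

The model for embryo-release presence in mussel i, lake j, year k is

    Bitterling_ijk ~ Bernoulli(pi_ijk)
    logit(pi_ijk)  = beta + Species_ijk + f_s(Day_ijk) + Oxbow_j + Year_k
    Oxbow_j ~ N(0, sigma_Oxbow^2),   Year_k ~ N(0, sigma_Year^2)

with one O'Sullivan spline smoother f_s per host species (five interior knots,
mixed-model form: per-species linear slope in the fixed block plus penalized
deviations u_s ~ N(0, tau_s^2 I)). Priors are diffuse: N(0, prior_sd_fixed^2)
on fixed effects, Uniform(0, prior_sd_upper) on every standard deviation.

Sampling is by Pólya-Gamma data augmentation: given omega_i ~ PG(1, eta_i)
all coefficients are one jointly-Gaussian block (a single Cholesky solve per
sweep), and each variance has a conjugate truncated inverse-gamma update.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammainc, gammaincinv

from .errors import InitializationError, SpecError, ValidationError
from .pg import pg_draw, seed_pg
from .splines import SplineBasis, osullivan_basis
from .survey import SPECIES, SurveyRecord, records_to_frame


@dataclass
class McmcSettings:
    """Chain schedule. Retained draws per chain = iterations // thin."""

    n_chains: int = 3
    burn_in: int = 50_000
    iterations: int = 500_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if min(self.n_chains, self.burn_in, self.iterations, self.thin) <= 0:
            raise ValidationError("all MCMC settings must be positive")
        if self.iterations % self.thin != 0:
            raise ValidationError("thin must divide iterations evenly")

    @property
    def retained_per_chain(self) -> int:
        return self.iterations // self.thin


@dataclass
class GammSpec:
    """Assembled design for the Bernoulli GAMM.

    The stacked coefficient vector is laid out as
    [intercept | species dummies | per-smoother linear slopes |
     per-smoother u blocks | lake intercepts | year intercepts],
    with ``blocks`` mapping each named block to its column slice.
    """

    y: np.ndarray
    X: np.ndarray
    blocks: dict[str, slice]
    baseline: str
    species_order: tuple[str, ...]
    smoother_names: tuple[str, ...]  # one per smoother block ('shared',) or species
    bases: dict[str, SplineBasis]
    z_offsets: dict[str, np.ndarray]  # within-group column means removed from Z
    lin_offsets: dict[str, float]  # group day mean removed from the linear column
    day_ranges: dict[str, tuple[float, float]]
    lake_levels: tuple[int, ...]
    year_levels: tuple[int, ...]
    smoother_mode: str = "per_species"
    n_knots: int = 5
    prior_sd_fixed: float = 100.0
    prior_sd_upper: float = 20.0

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    def coef_names(self) -> list[str]:
        names = [""] * self.n_coef
        for block, sl in self.blocks.items():
            width = sl.stop - sl.start
            if width == 1:
                names[sl.start] = block
            else:
                if block == "lake":
                    labels = [f"lake[{j}]" for j in self.lake_levels]
                elif block == "year":
                    labels = [f"year[{k}]" for k in self.year_levels]
                elif block == "species":
                    labels = [f"species[{s}]" for s in self.species_order if s != self.baseline]
                else:
                    labels = [f"{block}[{i}]" for i in range(width)]
                names[sl.start:sl.stop] = labels
        return names

    def prior_precisions(self, sd_lake, sd_year, sd_smooth) -> np.ndarray:
        """Diagonal prior precision for the stacked coefficient vector."""
        prec = np.empty(self.n_coef)
        fixed = 1.0 / self.prior_sd_fixed**2
        prec[self.blocks["intercept"]] = fixed
        prec[self.blocks["species"]] = fixed
        for name in self.smoother_names:
            prec[self.blocks[f"slope_{name}"]] = fixed
            prec[self.blocks[f"u_{name}"]] = 1.0 / sd_smooth[name] ** 2
        prec[self.blocks["lake"]] = 1.0 / sd_lake**2
        prec[self.blocks["year"]] = 1.0 / sd_year**2
        return prec


def build_spec(
    records: Sequence[SurveyRecord],
    baseline: str = "anatina",
    smoother_mode: str = "per_species",
    n_knots: int = 5,
    prior_sd_fixed: float = 100.0,
    prior_sd_upper: float = 20.0,
) -> GammSpec:
    """Assemble design matrices for (already filtered) survey records.

    Smoother blocks are centered within their group: the linear day column and
    every Z column have their group mean removed, so the species dummies alone
    carry each species' level and the smoothers are identifiable deviations.
    """
    if len(records) == 0:
        raise SpecError("no records")
    if smoother_mode not in ("per_species", "shared"):
        raise SpecError(f"unknown smoother_mode {smoother_mode!r}")
    if baseline not in SPECIES:
        raise SpecError(f"baseline {baseline!r} not a species level")
    frame = records_to_frame(records)
    present = set(frame["species"])
    missing = [s for s in SPECIES if s not in present]
    if missing:
        raise SpecError(f"species absent from data: {missing}")

    n = len(frame)
    y = frame["released"].to_numpy(dtype=float)
    day = frame["day"].to_numpy(dtype=float)

    cols: list[np.ndarray] = [np.ones((n, 1))]
    blocks: dict[str, slice] = {"intercept": slice(0, 1)}
    pos = 1

    non_base = [s for s in SPECIES if s != baseline]
    dummies = np.column_stack([(frame["species"] == s).to_numpy(dtype=float) for s in non_base])
    cols.append(dummies)
    blocks["species"] = slice(pos, pos + len(non_base))
    pos += len(non_base)

    smoother_names = tuple(SPECIES) if smoother_mode == "per_species" else ("shared",)
    group_rows = {
        name: (np.flatnonzero((frame["species"] == name).to_numpy())
               if smoother_mode == "per_species" else np.arange(n))
        for name in smoother_names
    }

    bases, z_offsets, lin_offsets, day_ranges = {}, {}, {}, {}
    slope_cols, u_cols = [], []
    for name in smoother_names:
        rows = group_rows[name]
        xg = day[rows]
        basis = osullivan_basis(xg, n_knots=n_knots)
        bases[name] = basis
        day_ranges[name] = (float(xg.min()), float(xg.max()))
        lin_offsets[name] = basis.x_mean
        z_mean = basis.Z.mean(axis=0)
        z_offsets[name] = z_mean
        lin = np.zeros((n, 1))
        lin[rows, 0] = basis.x_lin
        Z = np.zeros((n, basis.q))
        Z[rows] = basis.Z - z_mean
        slope_cols.append(lin)
        u_cols.append(Z)
    for name, lin in zip(smoother_names, slope_cols):
        cols.append(lin)
        blocks[f"slope_{name}"] = slice(pos, pos + 1)
        pos += 1
    for name, Z in zip(smoother_names, u_cols):
        cols.append(Z)
        blocks[f"u_{name}"] = slice(pos, pos + Z.shape[1])
        pos += Z.shape[1]

    lake_levels = tuple(sorted(set(frame["lake_id"])))
    year_levels = tuple(sorted(set(frame["year"])))
    lake_mat = np.column_stack([(frame["lake_id"] == j).to_numpy(dtype=float) for j in lake_levels])
    year_mat = np.column_stack([(frame["year"] == k).to_numpy(dtype=float) for k in year_levels])
    cols.append(lake_mat)
    blocks["lake"] = slice(pos, pos + len(lake_levels))
    pos += len(lake_levels)
    cols.append(year_mat)
    blocks["year"] = slice(pos, pos + len(year_levels))
    pos += len(year_levels)

    return GammSpec(
        y=y, X=np.hstack(cols), blocks=blocks, baseline=baseline,
        species_order=tuple(SPECIES), smoother_names=smoother_names,
        bases=bases, z_offsets=z_offsets, lin_offsets=lin_offsets,
        day_ranges=day_ranges, lake_levels=lake_levels, year_levels=year_levels,
        smoother_mode=smoother_mode, n_knots=n_knots,
        prior_sd_fixed=prior_sd_fixed, prior_sd_upper=prior_sd_upper,
    )


def log_posterior(params: dict, spec: GammSpec) -> float:
    """Unnormalized log posterior density at a parameter state.

    ``params`` holds ``coef`` (stacked vector), ``sd_lake``, ``sd_year`` and
    ``sd_smooth`` (dict per smoother block). A standard deviation outside
    (0, prior_sd_upper) yields -inf (a rejected state, not an error).
    """
    coef = np.asarray(params["coef"], dtype=float)
    if coef.size != spec.n_coef:
        raise ValidationError(f"coef has size {coef.size}, spec needs {spec.n_coef}")
    sd_lake = float(params["sd_lake"])
    sd_year = float(params["sd_year"])
    sd_smooth = {k: float(v) for k, v in params["sd_smooth"].items()}
    upper = spec.prior_sd_upper
    for sd in [sd_lake, sd_year, *sd_smooth.values()]:
        if not (0.0 < sd < upper):
            return -np.inf

    eta = spec.X @ coef
    # log Bernoulli likelihood: y*eta - log(1 + exp(eta)), computed stably
    loglik = float(np.sum(spec.y * eta) - np.sum(np.logaddexp(0.0, eta)))

    def normal_lp(v, sd):
        v = np.atleast_1d(v)
        return float(-0.5 * np.sum(v**2) / sd**2 - v.size * (0.5 * np.log(2 * np.pi) + np.log(sd)))

    lp = loglik
    lp += normal_lp(coef[spec.blocks["intercept"]], spec.prior_sd_fixed)
    lp += normal_lp(coef[spec.blocks["species"]], spec.prior_sd_fixed)
    for name in spec.smoother_names:
        lp += normal_lp(coef[spec.blocks[f"slope_{name}"]], spec.prior_sd_fixed)
        lp += normal_lp(coef[spec.blocks[f"u_{name}"]], sd_smooth[name])
    lp += normal_lp(coef[spec.blocks["lake"]], sd_lake)
    lp += normal_lp(coef[spec.blocks["year"]], sd_year)
    lp += -np.log(upper) * (2 + len(sd_smooth))  # uniform priors on the SDs
    return lp


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, kept per chain.

    ``coef`` has shape (chains, draws, n_coef); each SD array is
    (chains, draws). ``names`` lists one label per coefficient column;
    SD parameters carry their own labels in ``sd_names``.
    """

    coef: np.ndarray
    sd_lake: np.ndarray
    sd_year: np.ndarray
    sd_smooth: dict[str, np.ndarray]
    names: list[str]
    settings: McmcSettings
    seed: int

    @property
    def n_chains(self) -> int:
        return self.coef.shape[0]

    @property
    def n_draws_per_chain(self) -> int:
        return self.coef.shape[1]

    @property
    def n_draws_total(self) -> int:
        return self.n_chains * self.n_draws_per_chain

    def stacked_coef(self) -> np.ndarray:
        """All chains concatenated: (total draws, n_coef)."""
        return self.coef.reshape(-1, self.coef.shape[-1])

    def sd_names(self) -> list[str]:
        return ["sigma_lake", "sigma_year"] + [f"sigma_smooth[{k}]" for k in self.sd_smooth]

    def parameter_chains(self) -> dict[str, np.ndarray]:
        """Every scalar parameter as a (chains, draws) array, by name."""
        out = {name: self.coef[:, :, i] for i, name in enumerate(self.names)}
        out["sigma_lake"] = self.sd_lake
        out["sigma_year"] = self.sd_year
        for k, v in self.sd_smooth.items():
            out[f"sigma_smooth[{k}]"] = v
        return out


def _sample_sd_truncated(rng, v: np.ndarray, upper: float) -> float:
    """Conjugate update for an SD with a Uniform(0, upper) prior.

    Given v ~ N(0, tau^2 I_q), the conditional of tau^2 is inverse-gamma with
    shape (q-1)/2 and rate ||v||^2/2, truncated to (0, upper^2); sampled by
    inverse-CDF on the precision scale.
    """
    q = v.size
    if q < 2:
        raise SpecError("SD update needs at least 2 effects in the block")
    shape = 0.5 * (q - 1)
    rate = max(0.5 * float(v @ v), 1e-300)
    # precision 1/tau^2 ~ Gamma(shape, rate) truncated to (1/upper^2, inf)
    lo = gammainc(shape, rate / upper**2)
    u = lo + (1.0 - lo) * rng.random()
    u = min(u, 1.0 - 1e-16)
    prec = gammaincinv(shape, u) / rate
    prec = max(prec, 1.0 / upper**2 * (1 + 1e-12))
    return 1.0 / np.sqrt(prec)


def sample_logistic(y: np.ndarray, X: np.ndarray, n_iter: int, seed: int,
                    prior_sd: float = 100.0, burn_in: int = 500) -> np.ndarray:
    """PG-Gibbs draws for a plain Bayesian logistic regression (no random
    effects, no smoothers): the conjugate degenerate case of the GAMM sampler.

    Returns (n_iter, p) coefficient draws. With a diffuse prior and large n
    the posterior mean approaches the logistic-regression MLE.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    seed_pg(int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1)))
    kappa = y - 0.5
    Xt_kappa = X.T @ kappa
    coef = np.zeros(p)
    out = np.empty((n_iter, p))
    for it in range(burn_in + n_iter):
        omega = pg_draw(X @ coef)
        Q = (X.T * omega) @ X
        Q[np.diag_indices_from(Q)] += 1.0 / prior_sd**2
        L = np.linalg.cholesky(Q)
        mean = np.linalg.solve(L.T, np.linalg.solve(L, Xt_kappa))
        coef = mean + np.linalg.solve(L.T, rng.standard_normal(p))
        if it >= burn_in:
            out[it - burn_in] = coef
    return out


def _run_chain(spec: GammSpec, settings: McmcSettings, rng, pg_seed: int,
               prior_only: bool = False):
    X, y = spec.X, spec.y
    n, p = X.shape
    kappa = y - 0.5
    Xt_kappa = X.T @ kappa

    coef = np.zeros(p)
    sd_lake = sd_year = 1.0
    sd_smooth = {name: 1.0 for name in spec.smoother_names}

    state = {"coef": coef, "sd_lake": sd_lake, "sd_year": sd_year, "sd_smooth": sd_smooth}
    for attempt in range(11):
        if np.isfinite(log_posterior(state, spec)):
            break
        if attempt == 10:
            raise InitializationError("no finite starting state after 10 jittered retries")
        state["coef"] = rng.normal(scale=0.1, size=p)
    coef = state["coef"]

    seed_pg(pg_seed)
    keep = settings.retained_per_chain
    out_coef = np.empty((keep, p))
    out_sd_lake = np.empty(keep)
    out_sd_year = np.empty(keep)
    out_sd_smooth = {name: np.empty(keep) for name in spec.smoother_names}

    total = settings.burn_in + settings.iterations
    kept = 0
    for it in range(total):
        prec = spec.prior_precisions(sd_lake, sd_year, sd_smooth)
        if prior_only:
            # likelihood switched off: coefficients are exact prior draws
            # given the current SDs, and the SD updates see those draws
            coef = rng.standard_normal(p) / np.sqrt(prec)
        else:
            eta = X @ coef
            omega = pg_draw(eta)
            Q = (X.T * omega) @ X
            Q[np.diag_indices_from(Q)] += prec
            L = np.linalg.cholesky(Q)
            mean = np.linalg.solve(L.T, np.linalg.solve(L, Xt_kappa))
            coef = mean + np.linalg.solve(L.T, rng.standard_normal(p))

        sd_lake = _sample_sd_truncated(rng, coef[spec.blocks["lake"]], spec.prior_sd_upper)
        sd_year = _sample_sd_truncated(rng, coef[spec.blocks["year"]], spec.prior_sd_upper)
        for name in spec.smoother_names:
            sd_smooth[name] = _sample_sd_truncated(
                rng, coef[spec.blocks[f"u_{name}"]], spec.prior_sd_upper
            )

        post = it - settings.burn_in
        if post >= 0 and (post + 1) % settings.thin == 0:
            out_coef[kept] = coef
            out_sd_lake[kept] = sd_lake
            out_sd_year[kept] = sd_year
            for name in spec.smoother_names:
                out_sd_smooth[name][kept] = sd_smooth[name]
            kept += 1
    return out_coef, out_sd_lake, out_sd_year, out_sd_smooth


def sample_posterior(spec: GammSpec, settings: McmcSettings,
                     prior_only: bool = False) -> PosteriorDraws:
    """Run independent PG-Gibbs chains; burn-in discarded, thinning applied.

    Chains get distinct child streams spawned from ``settings.seed``; two runs
    with identical (spec, settings) produce identical draws. With
    ``prior_only=True`` the likelihood is switched off and the chains sample
    the joint prior (a calibration check for the sampler).
    """
    ss = np.random.SeedSequence(settings.seed)
    children = ss.spawn(settings.n_chains)
    chains = []
    for c, child in enumerate(children):
        rng = np.random.default_rng(child)
        pg_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
        chains.append(_run_chain(spec, settings, rng, pg_seed, prior_only=prior_only))
    coef = np.stack([c[0] for c in chains])
    return PosteriorDraws(
        coef=coef,
        sd_lake=np.stack([c[1] for c in chains]),
        sd_year=np.stack([c[2] for c in chains]),
        sd_smooth={
            name: np.stack([c[3][name] for c in chains]) for name in spec.smoother_names
        },
        names=spec.coef_names(),
        settings=settings,
        seed=settings.seed,
    )
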