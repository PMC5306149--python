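"""Side-validation GLMs fitted by iteratively reweighted least squares.

Three uses in the survey analysis:

* a Poisson GLM of released-embryo counts on dissected-embryo counts, and a
  Bernoulli GLM of release presence on the same covariate (does a 24-h mesh-bag
  release reliably indicate embryos in the gill?);
* per-species binomial GLMs of relative host abundance (number out of total)
  on a lake-by-year covariate, checking that the host community was stable
  across years.

Fits use canonical links (log for Poisson, logit for Bernoulli/binomial) and
report the deviance-ratio generalised R^2 = 1 - D/D0 by default (a
squared-correlation variant is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .errors import ConfigError, GlmError, UndefinedResultError, ValidationError

FAMILIES = ("poisson", "bernoulli", "binomial")

#: convergence: relative deviance change below this, or 50 iterations
IRLS_TOL = 1e-10
IRLS_MAX_ITER = 50


@dataclass
class GlmFit:
    """Maximum-likelihood GLM fit with Wald summaries."""

    family: str
    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    deviance: float
    null_deviance: float
    fitted: np.ndarray
    response: np.ndarray
    n_iter: int
    converged: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.terms,
            "estimate": self.coef,
            "se": self.se,
            "z": self.zvalues,
            "p": self.pvalues,
        })


def _family_funcs(family: str):
    if family == "poisson":
        inv = np.exp
        var = lambda mu, m: mu
        def dev(y, mu, m):
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(y > 0, y * np.log(y / mu), 0.0)
            return 2.0 * np.sum(term - (y - mu))
        return inv, var, dev
    if family in ("bernoulli", "binomial"):
        inv = expit
        var = lambda p, m: p * (1.0 - p)
        def dev(y, p, m):
            # y is the observed proportion, m the trials
            with np.errstate(divide="ignore", invalid="ignore"):
                t1 = np.where(y > 0, y * np.log(y / p), 0.0)
                t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - p)), 0.0)
            return 2.0 * np.sum(m * (t1 + t2))
        return inv, var, dev
    raise ConfigError(f"unknown family {family!r}; choose from {FAMILIES}")


def _irls(y, X, family, trials):
    """Core IRLS loop on proportion scale for binomial, counts for Poisson."""
    inv, var, dev = _family_funcs(family)
    n, p = X.shape
    m = trials if trials is not None else np.ones(n)
    if family == "poisson":
        resp = y
        eta = np.log(y + 0.5)
    else:
        resp = y / m
        eta = np.log((y + 0.5) / (m - y + 0.5))
    beta = np.zeros(p)
    deviance = np.inf
    last = None
    for it in range(1, IRLS_MAX_ITER + 1):
        mu = inv(eta)
        if family == "poisson":
            w = mu
            z = eta + (resp - mu) / mu
            d = dev(resp, mu, m)
        else:
            mu = np.clip(mu, 1e-10, 1 - 1e-10)
            w = m * var(mu, m)
            z = eta + (resp - mu) / var(mu, m)
            d = dev(resp, mu, m)
        xtw = X.T * w
        try:
            beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError as exc:
            raise GlmError(f"singular weighted design at iteration {it}: {exc}",
                           last_fit=last)
        eta = X @ beta_new
        rel = abs(d - deviance) / (abs(d) + 0.1)
        beta, deviance = beta_new, d
        last = (beta, deviance, it)
        if rel < IRLS_TOL:
            mu = inv(eta)
            if family != "poisson":
                mu = np.clip(mu, 1e-10, 1 - 1e-10)
            w = mu if family == "poisson" else m * var(mu, m)
            cov = np.linalg.inv((X.T * w) @ X)
            if np.any(np.abs(beta) > 1e3):
                raise GlmError(
                    "separation suspected: coefficients diverged", last_fit=last
                )
            return beta, np.sqrt(np.diag(cov)), deviance, mu, it, True
    raise GlmError(f"IRLS did not converge in {IRLS_MAX_ITER} iterations",
                   last_fit=last)


def fit_glm(data: pd.DataFrame, response: str, covariates: list[str],
            family: str, trials: str | None = None) -> GlmFit:
    """Fit a GLM of ``response`` on an intercept plus the named covariates.

    For ``family='binomial'``, ``response`` holds success counts and
    ``trials`` names the denominator column; ``bernoulli`` expects 0/1.
    """
    if family not in FAMILIES:
        raise ConfigError(f"unknown family {family!r}; choose from {FAMILIES}")
    for col in [response, *covariates] + ([trials] if trials else []):
        if col not in data.columns:
            raise ConfigError(f"column {col!r} missing from data")
    y = data[response].to_numpy(dtype=float)
    m = data[trials].to_numpy(dtype=float) if trials else None
    if family == "binomial" and trials is None:
        raise ConfigError("binomial family needs a trials column")
    if family in ("bernoulli", "binomial"):
        upper = m if m is not None else 1
        if np.any(y < 0) or np.any(y > upper):
            raise ValidationError("successes must satisfy 0 <= y <= trials")
    if family == "poisson" and (np.any(y < 0) or np.any(y != np.floor(y))):
        raise ValidationError("poisson response must be nonnegative integer")
    X = np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in covariates]
    )
    if covariates:
        for c in covariates:
            if data[c].nunique() < 2:
                raise ValidationError(f"covariate {c!r} has fewer than 2 distinct values")
    beta, se, deviance, mu, it, conv = _irls(y, X, family, m)
    # null model for the deviance ratio
    if X.shape[1] > 1:
        b0, _, null_dev, _, _, _ = _irls(y, np.ones((len(y), 1)), family, m)
    else:
        null_dev = deviance
    z = beta / se
    return GlmFit(
        family=family, terms=["intercept", *covariates], coef=beta, se=se,
        zvalues=z, pvalues=2 * norm.sf(np.abs(z)), deviance=float(deviance),
        null_deviance=float(null_dev), fitted=mu,
        response=(y / m if (family != "poisson" and m is not None) else y),
        n_iter=it, converged=conv,
    )


def generalized_r2(fit: GlmFit, kind: str = "deviance") -> float:
    """Generalised R^2 of a converged fit.

    ``deviance`` (default): 1 - residual deviance / null deviance.
    ``sq_corr``: squared Pearson correlation of response and fitted values.
    """
    if kind == "deviance":
        if fit.null_deviance < 1e-12:
            raise UndefinedResultError("null deviance is zero; R^2 undefined")
        return float(1.0 - fit.deviance / fit.null_deviance)
    if kind == "sq_corr":
        if np.std(fit.response) == 0 or np.std(fit.fitted) == 0:
            raise UndefinedResultError("constant response or fit; R^2 undefined")
        return float(np.corrcoef(fit.response, fit.fitted)[0, 1] ** 2)
    raise ConfigError(f"unknown kind {kind!r}")


def predict_glm(coef, covariate_values, family: str) -> np.ndarray:
    """Inverse-link prediction from fixed coefficients.

    ``coef`` is (intercept, slope, ...); ``covariate_values`` a vector (single
    covariate) or matrix without the intercept column.
    """
    coef = np.asarray(coef, dtype=float)
    vals = np.atleast_1d(np.asarray(covariate_values, dtype=float))
    if vals.ndim == 1:
        vals = vals[:, None]
    eta = coef[0] + vals @ coef[1:]
    if family == "poisson":
        return np.exp(eta)
    if family in ("bernoulli", "binomial"):
        return expit(eta)
    raise ConfigError(f"unknown family {family!r}")


ABUNDANCE_LAKES = (2, 6, 8, 13)


def fit_abundance_models(records: pd.DataFrame, lakes=ABUNDANCE_LAKES,
                         covariate: str = "product") -> dict[str, GlmFit]:
    """Per-species binomial GLMs of relative abundance across lake-years.

    ``records`` needs columns lake, year, species, number, total. The default
    design restricts to the lakes sampled in every year and uses a single
    numeric lake-by-year product covariate (one slope per species, matching a
    one-row-per-species summary); ``covariate='additive'`` uses separate
    numeric lake and year terms instead.
    """
    required = {"lake", "year", "species", "number", "total"}
    missing = required - set(records.columns)
    if missing:
        raise ConfigError(f"missing columns: {sorted(missing)}")
    sub = records[records["lake"].isin(lakes)].copy()
    if sub.groupby(["lake", "year"]).ngroups < 2:
        raise ValidationError("need at least 2 lake-year combinations")
    sub["lake_by_year"] = sub["lake"].astype(float) * sub["year"].astype(float)
    fits = {}
    for species, grp in sub.groupby("species"):
        grp = grp.reset_index(drop=True)
        if covariate == "product":
            fits[species] = fit_glm(grp, "number", ["lake_by_year"],
                                    family="binomial", trials="total")
        elif covariate == "additive":
            fits[species] = fit_glm(grp, "number", ["lake", "year"],
                                    family="binomial", trials="total")
        else:
            raise ConfigError(f"unknown covariate scheme {covariate!r}")
    return fits


def abundance_table(fits: dict[str, GlmFit]) -> pd.DataFrame:
    """Stack per-species GLM summaries into one table (species, parameter,
    estimate, SE, z, p)."""
    frames = []
    for species, fit in sorted(fits.items()):
        frame = fit.summary()
        frame.insert(0, "species", species)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
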