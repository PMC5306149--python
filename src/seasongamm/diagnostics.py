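"""MCMC convergence diagnostics: Gelman-Rubin PSRF, autocorrelation, ESS."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


def gelman_rubin(chains: np.ndarray, split: bool = False) -> float:
    """Classic (non-split) Gelman-Rubin potential scale reduction factor.

    ``chains`` is (n_chains, n_draws). With W the mean within-chain variance
    and B/n the variance of the chain means,

        PSRF = sqrt( (W (n-1)/n + B/n) / W ).

    Constant chains (W = 0) return 1 by convention. ``split=True`` halves each
    chain first (split-R-hat variant).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValidationError("need >= 2 chains of equal length")
    if split:
        half = chains.shape[1] // 2
        chains = np.vstack([chains[:, :half], chains[:, half:2 * half]])
    n = chains.shape[1]
    if n < 10:
        raise ValidationError("chains too short for a PSRF (need >= 10 draws)")
    within = chains.var(axis=1, ddof=1).mean()
    between_over_n = chains.mean(axis=1).var(ddof=1)
    if within == 0.0:
        return 1.0
    vhat = within * (n - 1) / n + between_over_n
    return float(np.sqrt(vhat / within))


def autocorrelation(chain: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation function at lags 0..max_lag (lag 0 = 1).

    A constant chain returns zeros beyond lag 0 by convention.
    """
    chain = np.asarray(chain, dtype=float)
    n = chain.size
    if n <= max_lag:
        raise ValidationError("chain must be longer than max_lag")
    x = chain - chain.mean()
    denom = float(x @ x)
    acf = np.zeros(max_lag + 1)
    acf[0] = 1.0
    if denom == 0.0:
        return acf
    for k in range(1, max_lag + 1):
        acf[k] = float(x[:-k] @ x[k:]) / denom
    return acf


def effective_sample_size(chains: np.ndarray, max_lag: int | None = None) -> float:
    """ESS across chains using Geyer's initial-positive-sequence truncation."""
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    c, n = chains.shape
    if max_lag is None:
        max_lag = min(n - 1, 200)
    acf = np.mean([autocorrelation(ch, max_lag) for ch in chains], axis=0)
    tau = 1.0
    for k in range(1, max_lag, 2):
        pair = acf[k] + (acf[k + 1] if k + 1 <= max_lag else 0.0)
        if pair < 0:
            break
        tau += 2.0 * pair
    return float(c * n / tau)


@dataclass
class ConvergenceReport:
    """Per-parameter PSRF, lag-1..L autocorrelation and effective sample size."""

    psrf: dict[str, float]
    acf: dict[str, np.ndarray]
    ess: dict[str, float]

    @property
    def max_psrf(self) -> float:
        return max(self.psrf.values())

    def worst(self, k: int = 5) -> list[tuple[str, float]]:
        return sorted(self.psrf.items(), key=lambda kv: -kv[1])[:k]


def convergence_report(draws, max_lag: int = 20) -> ConvergenceReport:
    """Diagnostics for every scalar parameter of a :class:`PosteriorDraws`."""
    psrf, acfs, ess = {}, {}, {}
    for name, chains in draws.parameter_chains().items():
        psrf[name] = gelman_rubin(chains)
        acfs[name] = np.mean([autocorrelation(ch, max_lag) for ch in chains], axis=0)
        ess[name] = effective_sample_size(chains)
    return ConvergenceReport(psrf=psrf, acf=acfs, ess=ess)
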