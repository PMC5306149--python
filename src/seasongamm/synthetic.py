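"""Synthetic survey generators with known ground truth.

Three generators cover every input the pipeline needs:

* :func:`generate_survey` draws surveys from a known Bernoulli GAMM (Gaussian
  seasonal bumps per species, species effects, lake/year random intercepts)
  for parameter- and smoother-recovery testing;
* :func:`generate_dissection_pairs` draws (released, dissected) embryo count
  pairs whose release-presence probability follows the printed dissection-GLM
  coefficients logit(pi) = -2.38 + 0.26 * Dissected;
* :func:`build_survey_fixture` deterministically lays out 1889 records whose
  marginal counts match the published survey (monthly totals 501/532/751/105,
  species totals 773/430/371/315, and — after excluding August and lakes 3 and
  11 — species counts 723/385/339/285 with 202/20/233/82 positives).

Default truth parameters reproduce the published survey's marginal
prevalences and its qualitative narrative (infection peaking between days 35
and 45; *U. pictorum* most used, *A. cygnea* least) so recovery tests have
known answers; everything is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import FixtureError, ValidationError
from .survey import SPECIES, SurveyRecord


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth GAMM parameters for survey simulation.

    Smoothers are Gaussian bumps ``height * exp(-(day-peak)^2 / (2 width^2))``
    centered to mean zero over the design days (matching the identifiability
    constraint of the fitted model, whose smoothers are centered deviations).
    """

    intercept: float = -1.4
    species_effects: dict = field(default_factory=lambda: {
        "anatina": 0.0, "cygnea": -2.5, "pictorum": 1.5, "tumidus": -0.1,
    })
    # (peak day, width, height) per species
    smoothers: dict = field(default_factory=lambda: {
        "anatina": (40.0, 11.0, 2.2),
        "cygnea": (37.0, 8.0, 1.9),
        "pictorum": (40.0, 19.0, 2.3),
        "tumidus": (42.0, 11.0, 2.0),
    })
    sd_lake: float = 0.5
    sd_year: float = 0.3
    lakes: tuple = tuple(range(1, 14))
    years: tuple = (1995, 1996, 1997)
    #: 9 sampling days per year; 3 years gives the survey's 27 discrete dates
    days: tuple = (8, 18, 28, 38, 48, 58, 68, 78, 88)
    #: marginal species mix of the survey (anatina, cygnea, pictorum, tumidus)
    species_probs: tuple = (0.41, 0.23, 0.20, 0.16)
    n: int = 2000
    seed: int = 0

    def __post_init__(self):
        if any(w <= 0 for _, w, _ in self.smoothers.values()):
            raise ValidationError("smoother widths must be positive")
        if self.n < 0:
            raise ValidationError("sample size must be nonnegative")
        if abs(sum(self.species_probs) - 1.0) > 1e-9:
            raise ValidationError("species_probs must sum to 1")


def true_smoother(day, species: str, truth: TruthConfig) -> np.ndarray:
    """Centered ground-truth smoother value(s) for a species.

    The raw Gaussian bump minus its unweighted mean over the design days, so
    the truth lives on the same (sum-to-zero over days) scale as the fitted
    smoother deviations.
    """
    peak, width, height = truth.smoothers[species]
    bump = lambda d: height * np.exp(-((np.asarray(d, dtype=float) - peak) ** 2)
                                     / (2.0 * width**2))
    center = float(np.mean(bump(np.asarray(truth.days, dtype=float))))
    return bump(day) - center


def true_linear_predictor(day, species: str, truth: TruthConfig) -> np.ndarray:
    """eta(day) for a species at random effects zero (population level)."""
    return (truth.intercept + truth.species_effects[species]
            + true_smoother(day, species, truth))


def generate_survey(truth: TruthConfig) -> tuple[list[SurveyRecord], dict]:
    """Simulate a survey from the ground-truth GAMM.

    Lake and year intercepts are drawn once from their N(0, sigma^2) laws;
    each record then draws lake, year, day and species independently and its
    release flag from Bernoulli(expit(eta)). Returns (records, truth_record)
    where the truth record bundles the config and the realized random effects
    for recovery assertions. Pure function of the config (seeded).
    """
    rng = np.random.default_rng(truth.seed)
    lake_eff = {j: rng.normal(0.0, truth.sd_lake) for j in truth.lakes}
    year_eff = {k: rng.normal(0.0, truth.sd_year) for k in truth.years}
    lakes = rng.choice(truth.lakes, size=truth.n)
    years = rng.choice(truth.years, size=truth.n)
    days = rng.choice(truth.days, size=truth.n)
    species = rng.choice(SPECIES, size=truth.n, p=truth.species_probs)
    records = []
    for j, k, d, s in zip(lakes, years, days, species):
        eta = (true_linear_predictor(int(d), s, truth)
               + lake_eff[int(j)] + year_eff[int(k)])
        released = int(rng.random() < expit(eta))
        records.append(SurveyRecord(lake_id=int(j), year=int(k), day=int(d),
                                    species=str(s), released=released))
    truth_record = {
        "config": truth,
        "lake_effects": lake_eff,
        "year_effects": year_eff,
    }
    return records, truth_record


@dataclass(frozen=True)
class DissectionPair:
    """Paired 24-h mesh-bag release count and dissection count for one mussel."""

    released: int
    dissected: int

    @property
    def released_any(self) -> int:
        return int(self.released > 0)


def generate_dissection_pairs(
    n: int,
    presence_coef: tuple[float, float] = (-2.38, 0.26),
    count_coef: tuple[float, float] = (1.05, 0.01),
    zero_inflation: float = 0.35,
    mean_burden: float = 6.0,
    seed: int = 0,
) -> list[DissectionPair]:
    """Simulate (released, dissected) pairs for the dissection validation GLMs.

    Dissected counts follow a zero-inflated Poisson burden; release presence
    follows Bernoulli(expit(a + b * dissected)) with the printed-coefficient
    defaults, and the released count given presence is a shifted Poisson with
    mean matched to exp(count intercept + slope * dissected). Released and
    dissected embryos are disjoint counts (released embryos left the gill
    before dissection), so neither bounds the other.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    a, b = presence_coef
    c0, c1 = count_coef
    pairs = []
    for _ in range(n):
        dissected = 0 if rng.random() < zero_inflation else int(rng.poisson(mean_burden))
        if rng.random() < expit(a + b * dissected):
            mu = np.exp(c0 + c1 * dissected)
            released = 1 + int(rng.poisson(max(mu - 1.0, 0.0)))
        else:
            released = 0
        pairs.append(DissectionPair(released=released, dissected=dissected))
    return pairs


# ---------------------------------------------------------------------------
# deterministic survey-shaped fixture
# ---------------------------------------------------------------------------

#: printed marginal counts of the survey
FIXTURE = {
    "grand_total": 1889,
    "month_totals": {"May": 501, "June": 532, "July": 751, "August": 105},
    "species_totals": {"anatina": 773, "cygnea": 430, "pictorum": 371, "tumidus": 315},
    "subset_species_totals": {"anatina": 723, "cygnea": 385, "pictorum": 339, "tumidus": 285},
    "subset_positives": {"anatina": 202, "cygnea": 20, "pictorum": 233, "tumidus": 82},
    "excluded_lakes": (3, 11),
    "excluded_months": ("August",),
    "lake3_july": 19,
    "lake11_july": 33,
}

_MONTH_DAYS = {"May": (8, 18, 28), "June": (38, 48, 58), "July": (68, 78, 88),
               "August": (96, 104)}
_YEARS = (1995, 1996, 1997)


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Apportion ``total`` into integer parts proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        out = np.zeros(len(weights), dtype=int)
        out[0] = total
        return out
    quota = total * weights / weights.sum()
    out = np.floor(quota).astype(int)
    frac_order = np.argsort(-(quota - out))
    for i in range(total - out.sum()):
        out[frac_order[i % len(out)]] += 1
    return out


def build_survey_fixture(seed: int = 0) -> list[SurveyRecord]:
    """Deterministic 1889-record survey matching every printed marginal count.

    Lakes 3 and 11 appear only in July (so the August + lakes-3/11 exclusion
    leaves exactly the printed analysis subset), August records carry no
    releases (none were observed), and subset positives per species match the
    printed counts. Allocation beyond the printed margins — the per-lake,
    per-year and per-day composition — is a documented free choice filled by
    largest-remainder apportionment and round-robin assignment. ``seed`` only
    permutes the final record order; the multiset of records is fixed.
    """
    fx = FIXTURE
    subset_counts = dict(fx["subset_species_totals"])
    excl_counts = {s: fx["species_totals"][s] - subset_counts[s] for s in SPECIES}
    n_excl = sum(excl_counts.values())
    n_lakes_37 = fx["lake3_july"] + fx["lake11_july"]
    if n_excl != n_lakes_37 + fx["month_totals"]["August"]:
        raise FixtureError(
            "excluded species counts do not match August + lakes 3/11 totals"
        )

    subset_lakes = [j for j in range(1, 14) if j not in fx["excluded_lakes"]]
    records: list[SurveyRecord] = []

    def emit(n, lake_pool, month, species, positives=0):
        """Append n records cycling lakes/years/days; first `positives` released."""
        days = _MONTH_DAYS[month]
        for i in range(n):
            records.append(SurveyRecord(
                lake_id=lake_pool[i % len(lake_pool)],
                year=_YEARS[(i // len(lake_pool)) % len(_YEARS)],
                day=days[i % len(days)],
                species=species,
                released=int(i < positives),
            ))

    # --- analysis subset: 11 lakes, May-July, column totals fixed ---
    subset_months = ("May", "June", "July")
    capacity = {
        "May": fx["month_totals"]["May"],
        "June": fx["month_totals"]["June"],
        "July": fx["month_totals"]["July"] - n_lakes_37,
    }
    for s in SPECIES:
        remaining_caps = np.array([capacity[m] for m in subset_months], dtype=float)
        alloc = _largest_remainder(subset_counts[s], remaining_caps)
        # seasonal placement of positives: weight by the truth-like profile
        # (peaked in June) but never exceed the cell count
        pos_alloc = _largest_remainder(
            fx["subset_positives"][s], np.array([1.0, 1.6, 1.0]) * np.maximum(alloc, 1e-9)
        )
        pos_alloc = np.minimum(pos_alloc, alloc)
        short = fx["subset_positives"][s] - pos_alloc.sum()
        for i in np.argsort(-(alloc - pos_alloc)):
            if short <= 0:
                break
            add = min(short, alloc[i] - pos_alloc[i])
            pos_alloc[i] += add
            short -= add
        if short > 0:
            raise FixtureError(f"cannot place positives for {s}: subset too small")
        for m, cell, pos in zip(subset_months, alloc, pos_alloc):
            emit(int(cell), subset_lakes, m, s, positives=int(pos))
            capacity[m] -= int(cell)
    if any(v != 0 for v in capacity.values()):
        raise FixtureError(f"subset month totals not met: residual {capacity}")

    # --- excluded regions: lakes 3/11 in July, then August everywhere else ---
    excl_species = np.array([excl_counts[s] for s in SPECIES])
    lake3 = _largest_remainder(fx["lake3_july"], excl_species)
    lake11 = _largest_remainder(fx["lake11_july"], excl_species - lake3)
    august = excl_species - lake3 - lake11
    if np.any(august < 0) or august.sum() != fx["month_totals"]["August"]:
        raise FixtureError("excluded-region apportionment failed: August margin")
    for s, n3, n11, naug in zip(SPECIES, lake3, lake11, august):
        emit(int(n3), [3], "July", s)
        emit(int(n11), [11], "July", s)
        emit(int(naug), subset_lakes, "August", s)

    if len(records) != fx["grand_total"]:
        raise FixtureError(f"grand total {len(records)} != {fx['grand_total']}")
    order = np.random.default_rng(seed).permutation(len(records))
    return [records[i] for i in order]


def check_fixture(records) -> None:
    """Assert every printed marginal count; raise naming the first violation."""
    from .survey import apply_exclusions, tabulate

    fx = FIXTURE
    if len(records) != fx["grand_total"]:
        raise FixtureError(f"grand total: {len(records)} != {fx['grand_total']}")
    months = tabulate(records, "month").table["count"]
    for m, want in fx["month_totals"].items():
        if int(months.get(m, 0)) != want:
            raise FixtureError(f"month {m}: {months.get(m, 0)} != {want}")
    species = tabulate(records, "species").table["count"]
    for s, want in fx["species_totals"].items():
        if int(species.get(s, 0)) != want:
            raise FixtureError(f"species {s}: {species.get(s, 0)} != {want}")
    sub = apply_exclusions(records, fx["excluded_lakes"], fx["excluded_months"])
    sub_species = tabulate(sub, "species").table["count"]
    for s, want in fx["subset_species_totals"].items():
        if int(sub_species.get(s, 0)) != want:
            raise FixtureError(f"subset species {s}: {sub_species.get(s, 0)} != {want}")
    for s, want in fx["subset_positives"].items():
        got = sum(r.released for r in sub if r.species == s)
        if got != want:
            raise FixtureError(f"subset positives {s}: {got} != {want}")
    for r in records:
        if r.lake_id in fx["excluded_lakes"] and r.month != "July":
            raise FixtureError(f"lake {r.lake_id} record outside July")
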