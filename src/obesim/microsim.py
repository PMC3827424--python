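"""Stage 2: individual-level Monte Carlo simulation of BMI and disease.

Each simulated person carries a persistent uniform BMI rank: every year the
rank is mapped through the current (year, sex, age-group) category
distribution from stage 1, so an individual's BMI standing within their
cohort is consistent over time while the population marginals follow the
projected trends.  A continuous latent BMI is obtained from a per-stratum
log-normal whose two parameters are solved so that P(BMI<25) and P(BMI<30)
equal the projected proportions; percentage BMI-reduction scenarios act on
this continuous scale.

Annual discrete time; hazards become probabilities via 1 - exp(-h); within
a year the event order is BMI update -> disease incidence -> disease death
-> other-cause death.  All random draws come from per-(year, purpose) RNG
streams derived from the run seed and are made for every person slot
whether or not the event can apply, so counterfactual scenarios under the
same seed share identical randomness (common random numbers) and
scenario differences are low-variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .defs import BMI_CUTOFFS, CATEGORIES, SEXES, age_group_index, category_from_bmi
from .epi_inputs import DiseaseDefinition, HazardSchedule

if TYPE_CHECKING:
    from .bmi_projection import ProjectedDistribution
    from .scenarios import Scenario

logger = logging.getLogger(__name__)

_LN25, _LN30 = np.log(BMI_CUTOFFS[0]), np.log(BMI_CUTOFFS[1])
_PCLIP = 1e-9

# RNG purpose codes (per-year streams; see _rng)
_P_INIT, _P_MORT, _P_ENTRANT = 0, 5, 6
_P_INC, _P_FATAL = 10, 100


def _rng(seed: int, year: int, purpose: int) -> np.random.Generator:
    """Deterministic stream for (seed, year, purpose), scenario-independent."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(1, int(year), int(purpose))))


@dataclass
class SimulationConfig:
    """Run-level knobs: cohort size, horizon, seed, scenario reference."""

    n_individuals: int = 100_000
    start_year: int = 2010
    end_year: int = 2030
    seed: int = 0
    scenario_id: int = 0
    entrants: bool = True  # keep the age structure stationary with new 20-year-olds

    def __post_init__(self):
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")
        if self.n_individuals < 1:
            raise ValueError("need at least one simulated individual")


@dataclass
class Person:
    """Read-only view of one simulated individual (testing/introspection)."""

    id: int
    sex: str
    birth_year: int
    bmi_rank: float
    latent_bmi: float
    category: str
    disease_states: dict[str, int]  # disease -> onset year
    alive: bool


class Population:
    """Struct-of-arrays container for the simulated individuals."""

    def __init__(self, sex: np.ndarray, birth_year: np.ndarray, rank: np.ndarray,
                 disease_names: tuple[str, ...]):
        n = len(sex)
        self.sex = np.asarray(sex, dtype=np.int8)          # 0 male, 1 female
        self.birth_year = np.asarray(birth_year, dtype=np.int32)
        self.rank = np.asarray(rank, dtype=np.float64)     # persistent uniform
        self.alive = np.ones(n, dtype=bool)
        self.disease_names = disease_names
        self.onset = np.full((n, len(disease_names)), -1, dtype=np.int32)
        self.latent_bmi = np.zeros(n, dtype=np.float64)
        self.category = np.zeros(n, dtype=np.int8)

    def __len__(self) -> int:
        return len(self.sex)

    def ages(self, year: int) -> np.ndarray:
        return year - self.birth_year

    def append(self, sex, birth_year, rank) -> None:
        k = len(sex)
        self.sex = np.concatenate([self.sex, np.asarray(sex, dtype=np.int8)])
        self.birth_year = np.concatenate([self.birth_year, np.asarray(birth_year, np.int32)])
        self.rank = np.concatenate([self.rank, np.asarray(rank, np.float64)])
        self.alive = np.concatenate([self.alive, np.ones(k, dtype=bool)])
        self.onset = np.vstack([self.onset, np.full((k, self.onset.shape[1]), -1, np.int32)])
        self.latent_bmi = np.concatenate([self.latent_bmi, np.zeros(k)])
        self.category = np.concatenate([self.category, np.zeros(k, dtype=np.int8)])

    def person(self, i: int, year: int | None = None) -> Person:
        states = {d: int(self.onset[i, j]) for j, d in enumerate(self.disease_names)
                  if self.onset[i, j] >= 0}
        return Person(id=i, sex=SEXES[self.sex[i]], birth_year=int(self.birth_year[i]),
                      bmi_rank=float(self.rank[i]), latent_bmi=float(self.latent_bmi[i]),
                      category=CATEGORIES[self.category[i]], disease_states=states,
                      alive=bool(self.alive[i]))


def lognormal_params(p_normal, p_overweight):
    """(mu, sigma) of the latent BMI log-normal matching two category cut-offs.

    Solves P(BMI<25) = p_normal and P(BMI<30) = p_normal + p_overweight in
    closed form; degenerate proportions are clipped away from {0, 1}.
    """
    c1 = np.clip(np.asarray(p_normal, float), _PCLIP, 1 - 2 * _PCLIP)
    c2 = np.clip(c1 + np.asarray(p_overweight, float), c1 + _PCLIP, 1 - _PCLIP)
    z1, z2 = ndtri(c1), ndtri(c2)
    sigma = (_LN30 - _LN25) / (z2 - z1)
    mu = _LN25 - sigma * z1
    return mu, sigma


def assign_bmi(pop: Population, dist: "ProjectedDistribution", year: int,
               scenario: "Scenario | None" = None) -> None:
    """Update latent BMI and category from the year's projected distribution.

    The persistent rank is mapped through the stratum's log-normal quantile;
    an active scenario multiplies the continuous BMI before categorisation.
    The rank itself is never modified.
    """
    ages = pop.ages(year)
    gi = age_group_index(dist.age_groups, np.maximum(ages, dist.age_groups[0][0]))
    mu = np.empty(len(pop))
    sigma = np.empty(len(pop))
    for s, sexname in enumerate(SEXES):
        mask = pop.sex == s
        if not mask.any():
            continue
        strat = dist.stratum_matrix(year, sexname)  # (G, 3)
        mu_g, sg_g = lognormal_params(strat[:, 0], strat[:, 1])
        mu[mask] = mu_g[gi[mask]]
        sigma[mask] = sg_g[gi[mask]]
    # clip to a physically wide range; the cut-offs sit far inside
    bmi = np.exp(np.clip(mu + sigma * ndtri(pop.rank), np.log(5.0), np.log(1000.0)))
    if scenario is not None and scenario.active(year):
        bmi = bmi * scenario.bmi_multiplier
    pop.latent_bmi = bmi
    pop.category = category_from_bmi(bmi)


def _category_hazard(pop: Population, schedules: dict[str, HazardSchedule],
                     year: int) -> np.ndarray:
    """Per-person hazard given each person's current category, sex and age."""
    ages = pop.ages(year)
    out = np.zeros(len(pop))
    for s, sexname in enumerate(SEXES):
        for k, cat in enumerate(CATEGORIES):
            mask = (pop.sex == s) & (pop.category == k)
            if mask.any():
                out[mask] = schedules[cat](sexname, ages[mask])
    return out


def simulate_year(pop: Population, diseases: list["CalibratedDisease"],
                  mortality: HazardSchedule, year: int, seed: int) -> pd.DataFrame:
    """Advance the population one year: incidence, disease death, other death.

    Hazards are converted to one-year probabilities via 1 - exp(-h); draws
    are made for every person slot to keep counterfactual runs aligned.
    Returns the year's event counts (event, disease, count).
    """
    ages = pop.ages(year)
    events = []
    for j, d in enumerate(diseases):
        i_h = _category_hazard(pop, d.incidence_by_category, year)
        u = _rng(seed, year, _P_INC + j).random(len(pop))
        new = pop.alive & (pop.onset[:, j] < 0) & (u < -np.expm1(-i_h))
        pop.onset[new, j] = year
        events.append(dict(event="incidence", disease=d.name, count=int(new.sum())))
    for j, d in enumerate(diseases):
        if not d.fatal:
            continue
        u = _rng(seed, year, _P_FATAL + j).random(len(pop))
        die = pop.alive & (pop.onset[:, j] >= 0) & (u < -np.expm1(-d.case_fatality))
        pop.alive[die] = False
        events.append(dict(event="death", disease=d.name, count=int(die.sum())))
    m = np.zeros(len(pop))
    for s, sexname in enumerate(SEXES):
        mask = pop.sex == s
        m[mask] = mortality(sexname, ages[mask])
    u = _rng(seed, year, _P_MORT).random(len(pop))
    die = pop.alive & (u < -np.expm1(-m))
    pop.alive[die] = False
    events.append(dict(event="death", disease="other", count=int(die.sum())))
    return pd.DataFrame(events).assign(year=year)


@dataclass
class CalibratedDisease:
    """A disease with BMI-category-specific incidence, ready to simulate."""

    name: str
    fatal: bool
    incidence_by_category: dict[str, HazardSchedule]
    case_fatality: float
    annual_unit_cost: float
    rr_by_category: tuple[float, float, float]
    #: age/sex prevalence used to seed the disease stock at the start year
    baseline_prevalence: HazardSchedule | None = None


@dataclass
class AnnualTally:
    """Aggregated outputs of one simulation run.

    `strata` holds raw simulated counts per (year, disease, sex, age group):
    prevalent cases among the alive and cumulative incident cases since the
    start year.  `categories` holds alive headcounts per BMI category and
    stratum.  `totals` carries the per-100,000 series: prevalence against
    the year's alive population, cumulative incidence against the start
    year's population (both at simulation scale); `scale` converts
    simulated heads to real-population heads.
    """

    scenario_id: int
    seed: int
    n_individuals: int
    start_year: int
    end_year: int
    scale: float
    strata: pd.DataFrame
    categories: pd.DataFrame
    totals: pd.DataFrame
    deaths: pd.DataFrame
    person_years: pd.Series
    conservation_ok: bool = True

    def matches(self, other: "AnnualTally") -> bool:
        """Same seed, size and horizon — comparable under common random numbers."""
        return (self.seed == other.seed and self.n_individuals == other.n_individuals
                and self.start_year == other.start_year and self.end_year == other.end_year)


def initial_population(cfg: SimulationConfig, population_df: pd.DataFrame,
                       disease_names: tuple[str, ...], min_age: int = 20
                       ) -> tuple[Population, float, dict[str, int]]:
    """Allocate simulated persons proportional to the real age/sex structure.

    Largest-remainder rounding keeps the total exactly n_individuals.
    Returns (population, heads-per-simulated-person scale, per-sex annual
    entrant counts at the minimum age).
    """
    df = population_df[population_df["age"] >= min_age]
    total = df["count"].sum()
    quota = df["count"].to_numpy(float) / total * cfg.n_individuals
    base = np.floor(quota).astype(int)
    short = cfg.n_individuals - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:short]] += 1
    sexes, births = [], []
    entrant_counts: dict[str, int] = {}
    for (_, row), k in zip(df.iterrows(), base):
        s = SEXES.index(row["sex"])
        sexes.append(np.full(k, s, dtype=np.int8))
        births.append(np.full(k, cfg.start_year - int(row["age"]), dtype=np.int32))
        if int(row["age"]) == min_age:
            entrant_counts[row["sex"]] = entrant_counts.get(row["sex"], 0) + int(k)
    rank = _rng(cfg.seed, cfg.start_year, _P_INIT).random(cfg.n_individuals)
    pop = Population(np.concatenate(sexes), np.concatenate(births), rank, disease_names)
    return pop, total / cfg.n_individuals, entrant_counts


def run_simulation(cfg: SimulationConfig, dist: "ProjectedDistribution",
                   diseases: list[CalibratedDisease], population_df: pd.DataFrame,
                   mortality: HazardSchedule,
                   scenario: "Scenario | None" = None) -> AnnualTally:
    """Run the full annual-step simulation and aggregate the tallies.

    Each year: BMI assignment from the projected distribution (with the
    scenario's multiplier if active), disease and death events, stratified
    tallies, then ageing and — unless disabled — new entrants at the
    minimum age so the age structure stays stationary.  Deterministic
    given (seed, config); scenario 0 reproduces the unadjusted run bit for
    bit under the same seed.
    """
    years = range(cfg.start_year, cfg.end_year + 1)
    for year in (cfg.start_year, cfg.end_year):
        for sexname in SEXES:
            dist.stratum_matrix(year, sexname)  # raises on stratum gaps up front
    names = tuple(d.name for d in diseases)
    pop, scale, entrant_counts = initial_population(cfg, population_df, names)
    # seed the baseline disease stock (onset before the start year, so it
    # counts as prevalent but not as incident-since-start); identical draws
    # across scenarios keep the counterfactuals coupled
    ages0 = pop.ages(cfg.start_year)
    for j, d in enumerate(diseases):
        if d.baseline_prevalence is None:
            continue
        p0 = np.zeros(len(pop))
        for s, sexname in enumerate(SEXES):
            mask = pop.sex == s
            p0[mask] = d.baseline_prevalence(sexname, ages0[mask])
        u = _rng(cfg.seed, cfg.start_year - 1, _P_INC + j).random(len(pop))
        pop.onset[u < p0, j] = cfg.start_year - 1
    G = len(dist.age_groups)
    strata_rows, cat_rows, death_rows, py = [], [], [], {}
    n_initial, n_entered = len(pop), 0
    baseline_alive = None
    for year in years:
        assign_bmi(pop, dist, year, scenario)
        events = simulate_year(pop, diseases, mortality, year, cfg.seed)
        death_rows.append(events[events["event"] == "death"])
        ages = pop.ages(year)
        gi = age_group_index(dist.age_groups, np.maximum(ages, dist.age_groups[0][0]))
        code = pop.sex.astype(int) * G + gi
        alive = pop.alive
        py[year] = int(alive.sum())
        if baseline_alive is None:
            baseline_alive = py[year]
        for j, d in enumerate(diseases):
            has = pop.onset[:, j] >= 0
            prev = np.bincount(code[alive & has], minlength=2 * G)
            # cumulative incidence counts onsets since the start year, whether
            # or not the case has since died; baseline stock is excluded
            cum = np.bincount(code[pop.onset[:, j] >= cfg.start_year], minlength=2 * G)
            for s, sexname in enumerate(SEXES):
                for g, (lo, hi) in enumerate(dist.age_groups):
                    strata_rows.append(dict(
                        year=year, disease=d.name, sex=sexname, age_lo=lo, age_hi=hi,
                        prevalent=int(prev[s * G + g]), cum_incident=int(cum[s * G + g])))
        for k, cat in enumerate(CATEGORIES):
            counts = np.bincount(code[alive & (pop.category == k)], minlength=2 * G)
            for s, sexname in enumerate(SEXES):
                for g, (lo, hi) in enumerate(dist.age_groups):
                    cat_rows.append(dict(year=year, sex=sexname, age_lo=lo, age_hi=hi,
                                         category=cat, count=int(counts[s * G + g])))
        if cfg.entrants and year < cfg.end_year and entrant_counts:
            width = max(entrant_counts.values())
            ranks = _rng(cfg.seed, year, _P_ENTRANT).random(len(SEXES) * width)
            for sexname, k in entrant_counts.items():
                if k <= 0:
                    continue
                s = SEXES.index(sexname)
                pop.append(np.full(k, s, dtype=np.int8),
                           np.full(k, year + 1 - 20, dtype=np.int32),
                           ranks[s * width:s * width + k])
                n_entered += k

    strata = pd.DataFrame(strata_rows)
    categories = pd.DataFrame(cat_rows)
    deaths = pd.concat(death_rows, ignore_index=True)[["year", "disease", "count"]]
    person_years = pd.Series(py, name="alive")
    tot = strata.groupby(["year", "disease"], as_index=False)[["prevalent", "cum_incident"]].sum()
    tot["prevalent_per_100k"] = tot.apply(
        lambda r: r.prevalent / person_years[r.year] * 1e5, axis=1)
    tot["cum_incidence_per_100k"] = tot["cum_incident"] / baseline_alive * 1e5
    conservation = (len(pop) == n_initial + n_entered)
    logger.info("simulation scenario=%s n=%d years=%d-%d: %d persons final, %d deaths",
                cfg.scenario_id if scenario is None else scenario.id, cfg.n_individuals,
                cfg.start_year, cfg.end_year, len(pop), deaths["count"].sum())
    return AnnualTally(
        scenario_id=scenario.id if scenario is not None else cfg.scenario_id,
        seed=cfg.seed, n_individuals=cfg.n_individuals, start_year=cfg.start_year,
        end_year=cfg.end_year, scale=scale, strata=strata, categories=categories,
        totals=tot, deaths=deaths, person_years=person_years,
        conservation_ok=conservation,
    )
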