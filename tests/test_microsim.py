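"""Microsimulation: rank-to-category mapping, event dynamics, convergence."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from obesim import SimulationConfig, assign_bmi, run_simulation, simulate_year
from obesim.epi_inputs import HazardSchedule
from obesim.microsim import CalibratedDisease, Population, initial_population

from conftest import flat_distribution, uniform_population_frame

AGES = np.arange(20, 91)


def make_population(n, rank=None, sex=0, birth_year=1990, diseases=("d",)):
    rng = np.random.default_rng(0)
    ranks = np.full(n, rank) if rank is not None else rng.random(n)
    return Population(np.full(n, sex, dtype=np.int8),
                      np.full(n, birth_year, dtype=np.int32), ranks, tuple(diseases))


def make_disease(name="d", i_by_cat=(0.1, 0.1, 0.1), fatal=False, cf=0.0, cost=1000.0):
    by_cat = {cat: HazardSchedule.constant(v, AGES)
              for cat, v in zip(("normal", "overweight", "obese"), i_by_cat)}
    rr = (1.0, i_by_cat[1] / i_by_cat[0] if i_by_cat[0] else 1.0,
          i_by_cat[2] / i_by_cat[0] if i_by_cat[0] else 1.0)
    return CalibratedDisease(name=name, fatal=fatal, incidence_by_category=by_cat,
                             case_fatality=cf, annual_unit_cost=cost, rr_by_category=rr)


# ---------------------------------------------------------------------------
# BMI assignment
# ---------------------------------------------------------------------------

def test_rank_in_first_interval_maps_to_normal():
    dist = flat_distribution(p=(0.2, 0.4, 0.4))
    pop = make_population(1, rank=0.10)
    assign_bmi(pop, dist, 2010)
    person = pop.person(0)
    assert person.category == "normal"
    assert person.latent_bmi < 25.0


def test_rank_boundaries_respect_cutoffs():
    dist = flat_distribution(p=(0.2, 0.4, 0.4))
    pop = make_population(3)
    pop.rank = np.array([0.19999, 0.21, 0.61])
    assign_bmi(pop, dist, 2010)
    assert list(pop.category) == [0, 1, 2]
    assert pop.latent_bmi[0] < 25 <= pop.latent_bmi[1] < 30 <= pop.latent_bmi[2]


def test_category_transitions_monotone_under_rising_obesity():
    """A fixed rank only ever moves normal -> overweight -> obese over time."""
    years = range(2010, 2031)
    rows = []
    for k, year in enumerate(years):
        p_ob = 0.2 + 0.02 * k
        p_n = max(0.6 - 0.025 * k, 0.05)
        for sex in ("male", "female"):
            rows.append(dict(year=year, sex=sex, age_lo=20, age_hi=89,
                             p_normal=p_n, p_overweight=1 - p_n - p_ob, p_obese=p_ob))
    from obesim import ProjectedDistribution
    dist = ProjectedDistribution(pd.DataFrame(rows))
    pop = make_population(200)
    trajectory = []
    for year in years:
        assign_bmi(pop, dist, year)
        trajectory.append(pop.category.copy())
    traj = np.array(trajectory)
    assert np.all(np.diff(traj, axis=0) >= 0)
    assert (traj[-1] > traj[0]).any()  # some people do cross a cut-off


def test_realized_category_frequencies_match_distribution():
    p = (0.2, 0.4, 0.4)
    dist = flat_distribution(p=p)
    pop = make_population(100_000)
    assign_bmi(pop, dist, 2010)
    for k, pk in enumerate(p):
        freq = (pop.category == k).mean()
        se = np.sqrt(pk * (1 - pk) / len(pop))
        assert abs(freq - pk) < 3 * se


def test_missing_stratum_raises_with_coordinates():
    dist = flat_distribution(p=(0.2, 0.4, 0.4), years=[2010])
    pop = make_population(1)
    with pytest.raises(KeyError, match="2011"):
        assign_bmi(pop, dist, 2011)


# ---------------------------------------------------------------------------
# yearly dynamics
# ---------------------------------------------------------------------------

def test_zero_hazards_leave_population_unchanged():
    pop = make_population(500)
    dist = flat_distribution()
    assign_bmi(pop, dist, 2010)
    before = (pop.alive.copy(), pop.onset.copy())
    simulate_year(pop, [make_disease(i_by_cat=(0, 0, 0))],
                  HazardSchedule.constant(0.0, AGES), 2010, seed=1)
    assert np.array_equal(pop.alive, before[0])
    assert np.array_equal(pop.onset, before[1])


def test_exponential_onset_analytic_limit():
    """RR=1, i=0.1/yr, no deaths: 10-year prevalence ~ 1 - e^-1."""
    cfg = SimulationConfig(n_individuals=50_000, start_year=2010, end_year=2019,
                           seed=3, entrants=False)
    dist = flat_distribution(p=(0.3, 0.4, 0.3), years=range(2010, 2020))
    tally = run_simulation(cfg, dist, [make_disease(i_by_cat=(0.1, 0.1, 0.1))],
                           uniform_population_frame(), HazardSchedule.constant(0.0, AGES))
    final = tally.totals[tally.totals.year == 2019]
    prev = float(final["prevalent_per_100k"].iloc[0]) / 1e5
    expect = 1.0 - np.exp(-1.0)
    se = np.sqrt(expect * (1 - expect) / cfg.n_individuals)
    assert abs(prev - expect) < 3 * se


def test_incidence_ratio_follows_hazard_ratio():
    """Doubling the obese hazard doubles obese incidence counts (+- MC error)."""
    dist = flat_distribution(p=(0.5, 1e-6, 0.5 - 1e-6))
    pop = make_population(120_000)
    assign_bmi(pop, dist, 2010)
    d = make_disease(i_by_cat=(0.05, 0.05, 0.10))
    simulate_year(pop, [d], HazardSchedule.constant(0.0, AGES), 2010, seed=4)
    new = pop.onset[:, 0] >= 0
    n_norm = int((new & (pop.category == 0)).sum())
    n_obese = int((new & (pop.category == 2)).sum())
    p1, p2 = 1 - np.exp(-0.05), 1 - np.exp(-0.10)
    expect_ratio = p2 / p1
    ratio = n_obese / n_norm
    se = ratio * np.sqrt(1 / n_norm + 1 / n_obese)
    assert abs(ratio - expect_ratio) < 3 * se


def test_equal_rates_across_categories_when_rr_is_one():
    """With RR=1 the per-category incidence rates are indistinguishable."""
    dist = flat_distribution(p=(0.34, 0.33, 0.33))
    pop = make_population(100_000)
    assign_bmi(pop, dist, 2010)
    simulate_year(pop, [make_disease(i_by_cat=(0.08, 0.08, 0.08))],
                  HazardSchedule.constant(0.0, AGES), 2010, seed=5)
    new = pop.onset[:, 0] >= 0
    table = np.array([[int((new & (pop.category == k)).sum()),
                       int((~new & (pop.category == k)).sum())] for k in range(3)])
    _, pval, _, _ = stats.chi2_contingency(table)
    assert pval > 0.01


def test_fatal_disease_kills_only_cases():
    pop = make_population(20_000)
    dist = flat_distribution()
    assign_bmi(pop, dist, 2010)
    d = make_disease(i_by_cat=(0.5, 0.5, 0.5), fatal=True, cf=0.4)
    simulate_year(pop, [d], HazardSchedule.constant(0.0, AGES), 2010, seed=6)
    dead = ~pop.alive
    assert dead.sum() > 0
    assert np.all(pop.onset[dead, 0] >= 0)  # only cases can die of the disease


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def test_same_seed_gives_bit_identical_tallies():
    cfg = SimulationConfig(n_individuals=3000, start_year=2010, end_year=2016, seed=9)
    dist = flat_distribution(years=range(2010, 2017))
    args = (dist, [make_disease(i_by_cat=(0.02, 0.03, 0.05), fatal=True, cf=0.1)],
            uniform_population_frame(), HazardSchedule.constant(0.005, AGES))
    a = run_simulation(cfg, *args)
    b = run_simulation(cfg, *args)
    pd.testing.assert_frame_equal(a.totals, b.totals)
    pd.testing.assert_frame_equal(a.strata, b.strata)
    c = run_simulation(SimulationConfig(n_individuals=3000, start_year=2010,
                                        end_year=2016, seed=10), *args)
    assert not a.totals.equals(c.totals)


def test_person_count_conservation_and_monotone_cumulative_incidence(pipeline_bundle):
    for tally in pipeline_bundle.tallies.values():
        assert tally.conservation_ok
        for _, sub in tally.totals.groupby("disease"):
            assert np.all(np.diff(sub.sort_values("year")["cum_incident"]) >= 0)


def test_disease_burden_rises_with_rising_obesity(pipeline_bundle):
    """RR>1 plus a rising obesity trend drives prevalence per 100k upward."""
    ob = pipeline_bundle.obesity_tables[0]
    for disease, sub in ob.groupby("disease"):
        sub = sub.sort_values("year")
        assert sub["prevalent_ob_per_100k"].iloc[-1] > sub["prevalent_ob_per_100k"].iloc[0]


def test_no_person_contracts_twice(pipeline_bundle):
    # cumulative incident counts never exceed the persons ever present
    t = pipeline_bundle.tallies[0]
    n_ever = t.n_individuals + 21 * 4000  # generous bound on entrants
    assert t.totals["cum_incident"].max() <= n_ever


def test_replicate_sd_scales_as_inverse_sqrt_n():
    """Replicate-seed SD of final prevalence per 100k shrinks like 1/sqrt(n)."""
    dist = flat_distribution(years=range(2010, 2016))
    disease = [make_disease(i_by_cat=(0.05, 0.05, 0.05))]
    popframe = uniform_population_frame()
    mort = HazardSchedule.constant(0.0, AGES)

    def final_prev(n, seed):
        cfg = SimulationConfig(n_individuals=n, start_year=2010, end_year=2015,
                               seed=seed, entrants=False)
        t = run_simulation(cfg, dist, disease, popframe, mort)
        return float(t.totals[t.totals.year == 2015]["prevalent_per_100k"].iloc[0])

    seeds = range(20)
    sd_small = np.std([final_prev(1500, s) for s in seeds], ddof=1)
    sd_large = np.std([final_prev(6000, 100 + s) for s in seeds], ddof=1)
    ratio = sd_small / sd_large  # expect ~sqrt(4) = 2
    assert 2 / 1.5 < ratio < 2 * 1.5


def test_initial_population_matches_structure_exactly():
    cfg = SimulationConfig(n_individuals=10_000, start_year=2010, end_year=2011, seed=0)
    frame = uniform_population_frame()
    pop, scale, entrants = initial_population(cfg, frame, ("d",))
    assert len(pop) == 10_000
    assert scale == pytest.approx(frame["count"].sum() / 10_000)
    assert set(entrants) == {"male", "female"}
    # uniform structure: sexes split evenly within rounding
    assert abs((pop.sex == 0).sum() - 5000) <= len(frame) // 2
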