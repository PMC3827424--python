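"""Intervention scenarios, obesity attribution, and cases avoided.

Scenario 0 leaves obesity trends unabated; scenarios 1 and 2 reduce every
individual's continuous BMI by 1% and 5% respectively from the scenario
start year onward.  Because all simulation inputs are total-population
figures, outputs are converted to obesity-related figures through the
Levin population attributable fraction, computed per (disease, sex,
age group, year) from the realized category proportions and the disease's
relative risks.  Cases avoided compare cumulative incidence between runs
that share seed, size and horizon (common random numbers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .defs import CATEGORIES, category_from_bmi
from .microsim import AnnualTally, CalibratedDisease

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Scenario:
    """One BMI-constraint scenario: 0 unabated, 1 = -1% BMI, 2 = -5% BMI."""

    id: int
    bmi_multiplier: float
    start_year: int = 2010

    def __post_init__(self):
        if not (0 < self.bmi_multiplier <= 1):
            raise ValueError("bmi multiplier must be in (0, 1]")
        if self.id == 0 and self.bmi_multiplier != 1.0:
            raise ValueError("scenario 0 is the identity scenario")

    def active(self, year: int) -> bool:
        return year >= self.start_year and self.bmi_multiplier != 1.0


def standard_scenarios(start_year: int = 2010) -> dict[int, Scenario]:
    """The three published scenarios keyed by id."""
    return {
        0: Scenario(0, 1.00, start_year),
        1: Scenario(1, 0.99, start_year),
        2: Scenario(2, 0.95, start_year),
    }


def apply_scenario(latent_bmi: np.ndarray, scenario: Scenario, year: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Adjusted (BMI, category codes) under the scenario at `year`.

    Identity before the scenario start year; afterwards a multiplicative
    shift of the continuous BMI with the category re-derived from the WHO
    cut-offs.  The underlying rank is untouched by construction.
    """
    bmi = np.asarray(latent_bmi, dtype=float)
    if scenario.active(year):
        bmi = bmi * scenario.bmi_multiplier
    return bmi, category_from_bmi(bmi)


def attributable_fraction(p_cat, rr) -> np.ndarray | float:
    """Levin population attributable fraction.

    PAF = (sum_k p_k RR_k - 1) / (sum_k p_k RR_k) with normal weight as the
    reference; zero when every RR is 1, and in [0, 1) whenever RR >= 1.
    Accepts stacked proportion rows (..., 3) against a length-3 RR vector.
    """
    p = np.asarray(p_cat, dtype=float)
    r = np.asarray(rr, dtype=float)
    if np.any(r < 0):
        raise ValueError("relative risks must be >= 0")
    if r[0] != 1.0:
        raise ValueError("reference-category RR must be 1")
    s = p @ r
    paf = (s - 1.0) / s
    return float(paf) if paf.ndim == 0 else paf


def obesity_related(tally: AnnualTally, diseases: list[CalibratedDisease]) -> pd.DataFrame:
    """Convert total-population tallies into obesity-related tallies.

    Applies the PAF per (disease, sex, age group, year), using that year's
    realized alive category proportions in the stratum, then aggregates.
    Returns one row per (year, disease) with obesity-related prevalent and
    cumulative-incident cases per 100,000 (prevalence against the year's
    alive population, cumulative incidence against the start-year
    population) and at whole-population scale.
    """
    cat_wide = tally.categories.pivot_table(
        index=["year", "sex", "age_lo"], columns="category", values="count")[list(CATEGORIES)]
    totals = cat_wide.sum(axis=1)
    props = cat_wide.div(totals.replace(0, np.nan), axis=0).fillna(1.0 / 3)
    rr_map = {d.name: np.asarray(d.rr_by_category) for d in diseases}
    baseline_alive = tally.person_years[tally.start_year]
    rows = []
    for (year, disease), sub in tally.strata.groupby(["year", "disease"]):
        keys = list(zip(sub["year"], sub["sex"], sub["age_lo"]))
        p = props.loc[keys].to_numpy()
        paf = attributable_fraction(p, rr_map[disease])
        prev_ob = float(np.sum(sub["prevalent"].to_numpy() * paf))
        cum_ob = float(np.sum(sub["cum_incident"].to_numpy() * paf))
        rows.append(dict(
            year=year, disease=disease,
            prevalent_ob=prev_ob, cum_incident_ob=cum_ob,
            prevalent_ob_per_100k=prev_ob / tally.person_years[year] * 1e5,
            cum_incidence_ob_per_100k=cum_ob / baseline_alive * 1e5,
            prevalent_ob_population=prev_ob * tally.scale,
            cum_incident_ob_population=cum_ob * tally.scale,
        ))
    return pd.DataFrame(rows)


def cases_avoided(tally_0: AnnualTally, tally_k: AnnualTally,
                  diseases: list[CalibratedDisease] | None = None) -> pd.DataFrame:
    """Cumulative incident cases avoided by scenario k relative to scenario 0.

    Requires both runs to share seed, cohort size and horizon so the
    difference isolates the intervention.  With `diseases` supplied the
    comparison is on obesity-related cases (the reported outputs);
    otherwise on total-population cases.  Also scaled to whole-population
    counts.
    """
    if not tally_0.matches(tally_k):
        raise ValueError("tallies come from incomparable runs (seed/n/years differ)")
    if diseases is not None:
        a = obesity_related(tally_0, diseases)
        b = obesity_related(tally_k, diseases)
        merged = a.merge(b, on=["year", "disease"], suffixes=("_0", "_k"))
        merged["avoided_per_100k"] = (merged["cum_incidence_ob_per_100k_0"]
                                      - merged["cum_incidence_ob_per_100k_k"])
        merged["avoided_population"] = (merged["cum_incident_ob_population_0"]
                                        - merged["cum_incident_ob_population_k"])
    else:
        merged = tally_0.totals.merge(tally_k.totals, on=["year", "disease"],
                                      suffixes=("_0", "_k"))
        merged["avoided_per_100k"] = (merged["cum_incidence_per_100k_0"]
                                      - merged["cum_incidence_per_100k_k"])
        merged["avoided_population"] = (merged["cum_incident_0"]
                                        - merged["cum_incident_k"]) * tally_0.scale
    merged["scenario"] = tally_k.scenario_id
    return merged[["scenario", "year", "disease", "avoided_per_100k", "avoided_population"]]
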