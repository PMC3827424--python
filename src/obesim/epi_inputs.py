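"""Per-disease hazard preparation.

Three conversions feed the microsimulation:

* prevalence -> incidence through the chronic illness-death system
  (remission fixed at zero): S' = -(i+m) S, C' = i S - (m+f) C, with
  prevalence p(a) = C/(S+C).  The forward solver uses the exact matrix
  exponential of the piecewise-constant 2x2 system per age step, so
  constant-hazard cases are reproduced to machine precision; the inverse
  recovers the unique non-negative i(a) matching each observed one-step
  prevalence change (infeasible declines are clamped to i = 0 and logged).
* n-year survival -> constant excess hazard f = -ln(s)/n.
* population incidence + relative risks + baseline category proportions ->
  per-category incidence, preserving the population mixture exactly:
  i_ref = i_pop / sum_k p_k RR_k, i_k = RR_k i_ref.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .defs import CATEGORIES, SEXES, age_group_index

logger = logging.getLogger(__name__)


@dataclass
class HazardSchedule:
    """Hazard (per person-year) by sex and single year of age, closed support."""

    ages: np.ndarray  # consecutive integer ages
    values: dict[str, np.ndarray]  # per sex, aligned to ages

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        for sex, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.ages.shape:
                raise ValueError(f"{sex}: schedule misaligned with ages")
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{sex}: hazards must be finite and >= 0")
            self.values[sex] = v

    @classmethod
    def constant(cls, value: float, ages, sexes=SEXES) -> "HazardSchedule":
        ages = np.asarray(ages, dtype=int)
        return cls(ages, {s: np.full(ages.shape, float(value)) for s in sexes})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_col: str = "hazard") -> "HazardSchedule":
        """Build from long-format (sex, age, value) rows."""
        ages = np.sort(df["age"].unique())
        values = {}
        for sex, sub in df.groupby("sex"):
            values[sex] = sub.set_index("age").loc[ages, value_col].to_numpy(float)
        return cls(ages, values)

    def __call__(self, sex: str, age) -> np.ndarray:
        """Vectorised lookup; ages beyond the support are clamped to its ends."""
        idx = np.clip(np.asarray(age, dtype=int) - self.ages[0], 0, len(self.ages) - 1)
        return self.values[sex][idx]

    def scaled(self, factor: float) -> "HazardSchedule":
        return HazardSchedule(self.ages, {s: v * factor for s, v in self.values.items()})


@dataclass
class DiseaseDefinition:
    """One disease's prepared inputs for the simulation stage."""

    name: str
    fatal: bool
    schedule_kind: str  # "incidence" | "prevalence"
    schedule: HazardSchedule  # incidence hazards, or prevalence proportions
    rr_by_category: tuple[float, float, float]  # (normal=1, overweight, obese)
    case_fatality: float = 0.0  # excess death hazard per person-year
    annual_unit_cost: float = 0.0
    baseline_prevalence: HazardSchedule | None = None  # stock at the start year

    def __post_init__(self):
        if self.rr_by_category[0] != 1.0:
            raise ValueError(f"{self.name}: reference-category RR must be 1")
        if any(r < 0 for r in self.rr_by_category):
            raise ValueError(f"{self.name}: negative relative risk")
        if not self.fatal and self.case_fatality != 0.0:
            raise ValueError(f"{self.name}: non-fatal disease cannot carry case fatality")
        if self.annual_unit_cost < 0:
            raise ValueError(f"{self.name}: negative unit cost")


def _step_matrix(i: float, m: float, f: float, h: float) -> np.ndarray:
    """Exact transition over a step of length h for constant hazards.

    State (S, C) evolves by the lower-triangular system with eigenvalues
    a = -(i+m), b = -(m+f); the off-diagonal term has the usual divided-
    difference form (limit i*h*e^{a h} when a == b).
    """
    a, b = -(i + m), -(m + f)
    ea, eb = math.exp(a * h), math.exp(b * h)
    off = i * h * ea if abs(a - b) < 1e-12 else i * (ea - eb) / (a - b)
    return np.array([[ea, 0.0], [off, eb]])


def illness_death_forward(i: HazardSchedule, f: HazardSchedule, m: HazardSchedule,
                          age_range=None, p0: float = 0.0, steps_per_year: int = 1
                          ) -> HazardSchedule:
    """Project prevalence from incidence through the illness-death system.

    Starts each sex at the youngest age with susceptible fraction 1 - p0 and
    case fraction p0 (default 0), steps annually (or finer) with hazards held
    constant within each year of age, and returns p(a) = C/(S+C).
    """
    ages = np.asarray(age_range, dtype=int) if age_range is not None else i.ages
    h = 1.0 / steps_per_year
    values = {}
    for sex in i.values:
        S, C = 1.0 - p0, p0
        p = np.empty(len(ages))
        p[0] = C / (S + C)
        for k, a in enumerate(ages[:-1]):
            M = _step_matrix(i(sex, a), m(sex, a), f(sex, a), h)
            for _ in range(steps_per_year):
                S, C = M[0, 0] * S, M[1, 0] * S + M[1, 1] * C
            p[k + 1] = C / (S + C)
        values[sex] = p
    return HazardSchedule(ages, values)


def prevalence_to_incidence(p: HazardSchedule, f: HazardSchedule, m: HazardSchedule,
                            p0: float | None = None) -> tuple[HazardSchedule, dict[str, list[int]]]:
    """Invert the illness-death system: observed prevalence -> incidence.

    Age by age, solves for the non-negative i(a) whose one-step forward
    projection reproduces the next observed prevalence; prevalence
    trajectories no non-negative incidence can explain (declines steeper
    than differential mortality allows, remission being zero) are clamped
    to i = 0 and the offending ages reported per sex.

    Returns (incidence schedule, clamped ages per sex).  The starting case
    fraction defaults to the observed prevalence at the youngest age.
    """
    ages = p.ages
    clamped: dict[str, list[int]] = {}
    values = {}
    for sex in p.values:
        pv = p.values[sex]
        if np.any(pv >= 1.0) or np.any(pv < 0.0):
            raise ValueError(f"{sex}: prevalence must lie in [0, 1)")
        start = pv[0] if p0 is None else p0
        S, C = 1.0 - start, start
        iv = np.zeros(len(ages))
        clamped[sex] = []
        for k, a in enumerate(ages[:-1]):
            target = pv[k + 1]
            mf, ff = m(sex, a), f(sex, a)

            def next_prev(i_try, S=S, C=C, mf=mf, ff=ff):
                M = _step_matrix(i_try, mf, ff, 1.0)
                S2, C2 = M[0, 0] * S, M[1, 0] * S + M[1, 1] * C
                return C2 / (S2 + C2)

            if next_prev(0.0) >= target:
                i_a = 0.0
                if next_prev(0.0) > target + 1e-12:
                    clamped[sex].append(int(a))
            else:
                hi = 1.0
                while next_prev(hi) < target and hi < 1e3:
                    hi *= 2.0
                i_a = optimize.brentq(lambda x: next_prev(x) - target, 0.0, hi,
                                      xtol=1e-14, rtol=1e-14)
            iv[k] = i_a
            M = _step_matrix(i_a, mf, ff, 1.0)
            S, C = M[0, 0] * S, M[1, 0] * S + M[1, 1] * C
        iv[-1] = iv[-2] if len(iv) > 1 else 0.0  # no forward constraint at the last age
        values[sex] = iv
        if clamped[sex]:
            logger.info("prevalence_to_incidence %s: clamped i=0 at ages %s",
                        sex, clamped[sex])
    return HazardSchedule(ages, values), clamped


def survival_to_excess_hazard(s: float, horizon_n: float) -> float:
    """Constant excess hazard implied by an n-year survival proportion."""
    if not (0 < s <= 1):
        raise ValueError("survival proportion must be in (0, 1]")
    if horizon_n <= 0:
        raise ValueError("survival horizon must be positive")
    return -math.log(s) / horizon_n


def calibrate_category_incidence(i_pop: HazardSchedule, rr: tuple[float, float, float],
                                 dist, baseline_year: int
                                 ) -> dict[str, HazardSchedule]:
    """Split population incidence into BMI-category-specific hazards.

    Uses the baseline year's category proportions per (sex, age):
    i_ref = i_pop / sum_k p_k RR_k and i_k = RR_k i_ref, so the mixture
    sum_k p_k i_k returns i_pop exactly.
    """
    if any(r < 0 for r in rr):
        raise ValueError("negative relative risk")
    rr = np.asarray(rr, dtype=float)
    out = {cat: {} for cat in CATEGORIES}
    for sex in i_pop.values:
        gi = age_group_index(dist.age_groups, i_pop.ages)
        props = dist.stratum_matrix(baseline_year, sex)[gi]  # (n_ages, 3)
        denom = props @ rr
        if np.any(denom <= 0):
            raise ValueError("sum_k p_k RR_k vanished: calibration undefined")
        i_ref = i_pop.values[sex] / denom
        for k, cat in enumerate(CATEGORIES):
            out[cat][sex] = rr[k] * i_ref
    return {cat: HazardSchedule(i_pop.ages, vals) for cat, vals in out.items()}


def prepare_diseases(disease_table: pd.DataFrame, mortality: HazardSchedule,
                     survival_horizon: float = 5.0) -> list[DiseaseDefinition]:
    """Build DiseaseDefinitions from a raw disease table.

    Prevalence-flagged schedules are converted to incidence through the
    illness-death equations using the disease's own case fatality (from
    n-year survival for fatal diseases, zero otherwise) and all-cause
    mortality; incidence-flagged schedules pass through unchanged.  Every
    disease also carries the age/sex prevalence implied by the illness-death
    system (the observed table where prevalence was the input), used to seed
    the disease stock at the simulation start year.
    """
    out = []
    for name, sub in disease_table.groupby("disease", sort=False):
        meta = sub.iloc[0]
        if meta.annual_unit_cost < 0:
            raise ValueError(f"{name}: negative unit cost")
        fatal = bool(meta.fatal)
        cf = 0.0
        if fatal:
            cf = survival_to_excess_hazard(float(meta.five_year_survival), survival_horizon)
        schedule = HazardSchedule.from_frame(sub, value_col="value")
        kind = str(meta.schedule_kind)
        f_sched = HazardSchedule.constant(cf, schedule.ages)
        if kind == "prevalence":
            baseline = schedule
            schedule, clamped = prevalence_to_incidence(schedule, f_sched, mortality)
            kind = "incidence"
        else:
            baseline = illness_death_forward(schedule, f_sched, mortality)
        out.append(DiseaseDefinition(
            name=name, fatal=fatal, schedule_kind=kind, schedule=schedule,
            rr_by_category=(1.0, float(meta.rr_overweight), float(meta.rr_obese)),
            case_fatality=cf, annual_unit_cost=float(meta.annual_unit_cost),
            baseline_prevalence=baseline,
        ))
    return out
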