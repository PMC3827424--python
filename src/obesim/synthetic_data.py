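"""Synthetic survey series, population structures and disease tables.

Emulates the statistical shape of the national data feeding the two-stage
obesity projection: sparse cross-sectional BMI surveys with multinomial
sampling noise and a rising obesity trend, a population age/sex structure
with Gompertz all-cause mortality, and per-disease epidemiology tables
(incidence or prevalence schedules, relative risks by BMI category,
survival and annual unit costs).

The truth model for the surveys is a three-category multinomial logit in
calendar year with additive age-group offsets, so stage-1 parameter
recovery is well defined: the generator and the fitted model share a
functional form but no code.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .defs import AgeGroup, CATEGORIES, SEXES

# Named RNG streams derived from the single global seed.  Each purpose gets
# an independent stream so e.g. drawing more microsimulation randomness never
# perturbs the synthetic survey.
_STREAM_SURVEY = 0
_STREAM_ENTRANTS = 2


def stream_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent RNG stream `stream` derived from the global `seed`."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))


@dataclass(frozen=True)
class DiseaseSpec:
    """Parameters generating one disease's epidemiology table.

    `level` is per-sex: for an incidence schedule it is the hazard at age 50
    (per person-year) with log-linear age gradient `age_slope`; for a
    prevalence schedule it is the asymptotic proportion of a logistic age
    curve with the given `midpoint` and `width` (years).
    `five_year_survival` applies to fatal diseases only and is converted to
    a constant excess hazard downstream.
    """

    name: str
    fatal: bool
    schedule_kind: str  # "incidence" | "prevalence"
    level: Mapping[str, float]
    age_slope: float = 0.08
    midpoint: float = 60.0
    width: float = 12.0
    rr_overweight: float = 1.0
    rr_obese: float = 1.0
    five_year_survival: float | None = None
    annual_unit_cost: float = 0.0

    def __post_init__(self):
        if self.schedule_kind not in ("incidence", "prevalence"):
            raise ValueError(f"unknown schedule kind {self.schedule_kind!r}")
        if self.rr_overweight < 0 or self.rr_obese < 0:
            raise ValueError(f"{self.name}: relative risks must be >= 0")
        if self.annual_unit_cost < 0:
            raise ValueError(f"{self.name}: negative unit cost")
        if any(v < 0 for v in self.level.values()):
            raise ValueError(f"{self.name}: negative rate level")
        if self.fatal and self.five_year_survival is not None and not (0 < self.five_year_survival <= 1):
            raise ValueError(f"{self.name}: survival must be in (0, 1]")


@dataclass(frozen=True)
class GeneratorSpec:
    """Full specification of a synthetic dataset.

    Logit trends are per sex: intercept and per-year slope of the overweight
    and obese logits relative to the normal-weight reference, centred at
    `ref_year`; `age_offsets_*` shift those logits additively per age group
    (shared across sexes). Mortality is Gompertz: m(a) = m20 * exp(slope*(a-20)).
    """

    seed: int
    survey_years: tuple[int, ...]
    age_groups: tuple[AgeGroup, ...]
    trend: Mapping[str, Mapping[str, float]]  # per sex: intercept_ow, slope_ow, intercept_ob, slope_ob
    ref_year: int
    n_per_cell: int
    population: Mapping[str, tuple[float, ...]]  # per sex, counts aligned to age_groups
    mortality: Mapping[str, tuple[float, float]]  # per sex: (m20, gompertz slope)
    diseases: tuple[DiseaseSpec, ...]
    age_offsets_overweight: tuple[float, ...] = ()
    age_offsets_obese: tuple[float, ...] = ()

    def __post_init__(self):
        if self.n_per_cell < 1:
            raise ValueError("survey sample size per cell must be >= 1")
        for sex, (m20, slope) in self.mortality.items():
            if m20 < 0:
                raise ValueError(f"negative mortality hazard for {sex}")
        for sex, counts in self.population.items():
            if len(counts) != len(self.age_groups):
                raise ValueError("population counts must align with age groups")
        for name in ("age_offsets_overweight", "age_offsets_obese"):
            offs = getattr(self, name)
            if offs and len(offs) != len(self.age_groups):
                raise ValueError(f"{name} must align with age groups")

    @property
    def ages(self) -> np.ndarray:
        """Single-year ages spanned by the age groups."""
        return np.arange(self.age_groups[0][0], self.age_groups[-1][1] + 1)


def true_proportions(spec: GeneratorSpec, years, sex: str) -> pd.DataFrame:
    """Noise-free category proportions implied by the spec's logit trends.

    Returns one row per (year, age group) with columns p_normal,
    p_overweight, p_obese summing to one exactly (softmax construction).
    """
    t = spec.trend[sex]
    off_ow = np.asarray(spec.age_offsets_overweight or np.zeros(len(spec.age_groups)))
    off_ob = np.asarray(spec.age_offsets_obese or np.zeros(len(spec.age_groups)))
    rows = []
    for year in years:
        dy = year - spec.ref_year
        eta_ow = t["intercept_ow"] + t["slope_ow"] * dy + off_ow
        eta_ob = t["intercept_ob"] + t["slope_ob"] * dy + off_ob
        denom = 1.0 + np.exp(eta_ow) + np.exp(eta_ob)
        for g, (lo, hi) in enumerate(spec.age_groups):
            rows.append(
                dict(year=year, sex=sex, age_lo=lo, age_hi=hi,
                     p_normal=1.0 / denom[g],
                     p_overweight=np.exp(eta_ow[g]) / denom[g],
                     p_obese=np.exp(eta_ob[g]) / denom[g])
            )
    return pd.DataFrame(rows)


def generate_survey_series(spec: GeneratorSpec) -> pd.DataFrame:
    """Draw the cross-sectional survey series.

    One row per (year, sex, age group, category) with the observed
    proportion (multinomial counts / n) and the cell sample size, i.e. the
    survey schema stage 1 consumes.
    """
    if len(set(spec.survey_years)) < 2:
        raise ValueError("need >= 2 distinct survey years: a trend is unidentifiable from one")
    rng = stream_rng(spec.seed, _STREAM_SURVEY)
    rows = []
    for sex in SEXES:
        truth = true_proportions(spec, spec.survey_years, sex)
        for _, cell in truth.iterrows():
            p = np.array([cell.p_normal, cell.p_overweight, cell.p_obese])
            counts = rng.multinomial(spec.n_per_cell, p)
            for cat, c in zip(CATEGORIES, counts):
                rows.append(
                    dict(year=int(cell.year), sex=sex, age_lo=int(cell.age_lo),
                         age_hi=int(cell.age_hi), category=cat,
                         proportion=c / spec.n_per_cell, n=spec.n_per_cell)
                )
    return pd.DataFrame(rows)


def generate_population(spec: GeneratorSpec) -> pd.DataFrame:
    """Population counts by sex and single year of age (uniform within groups)."""
    rows = []
    for sex in SEXES:
        for (lo, hi), count in zip(spec.age_groups, spec.population[sex]):
            width = hi - lo + 1
            for a in range(lo, hi + 1):
                rows.append(dict(sex=sex, age=a, count=count / width))
    return pd.DataFrame(rows)


def generate_mortality(spec: GeneratorSpec) -> pd.DataFrame:
    """All-cause mortality hazard (per person-year) by sex and single age."""
    rows = []
    for sex in SEXES:
        m20, slope = spec.mortality[sex]
        for a in spec.ages:
            rows.append(dict(sex=sex, age=int(a), hazard=m20 * np.exp(slope * (a - 20))))
    return pd.DataFrame(rows)


def generate_disease_tables(spec: GeneratorSpec) -> pd.DataFrame:
    """Per-disease epidemiology tables.

    One row per (disease, sex, age) carrying the schedule value plus the
    disease metadata (kind, fatality, RRs, survival, unit cost). Diseases
    with a prevalence schedule are flagged `needs_conversion` — their
    prevalence must be converted to incidence through the illness-death
    equations before simulation.
    """
    if not spec.diseases:
        raise ValueError("disease set is empty")
    rows = []
    for d in spec.diseases:
        for sex in SEXES:
            lvl = d.level[sex]
            for a in spec.ages:
                if d.schedule_kind == "incidence":
                    value = min(lvl * np.exp(d.age_slope * (a - 50)), 0.5)
                else:
                    value = lvl / (1.0 + np.exp(-(a - d.midpoint) / d.width))
                rows.append(
                    dict(disease=d.name, sex=sex, age=int(a), value=value,
                         schedule_kind=d.schedule_kind,
                         needs_conversion=d.schedule_kind == "prevalence",
                         fatal=d.fatal,
                         rr_overweight=d.rr_overweight, rr_obese=d.rr_obese,
                         five_year_survival=d.five_year_survival if d.fatal else np.nan,
                         annual_unit_cost=d.annual_unit_cost)
                )
    return pd.DataFrame(rows)


def write_dataset(spec: GeneratorSpec, outdir: str | Path) -> dict[str, Path]:
    """Write survey/population/mortality/disease CSVs plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("survey", generate_survey_series(spec)),
        ("population", generate_population(spec)),
        ("mortality", generate_mortality(spec)),
        ("diseases", generate_disease_tables(spec)),
    ):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps(_spec_to_jsonable(spec), indent=2))
    paths["manifest"] = manifest
    return paths


def _spec_to_jsonable(spec: GeneratorSpec) -> dict:
    def conv(x):
        if isinstance(x, Mapping):
            return {k: conv(v) for k, v in x.items()}
        if isinstance(x, tuple | list):
            return [conv(v) for v in x]
        if dataclasses.is_dataclass(x):
            return conv(dataclasses.asdict(x))
        return x

    return conv(dataclasses.asdict(spec))


# ---------------------------------------------------------------------------
# Irish-like preset: the study conditions downstream stages are exercised on.
# Survey years mirror the sparse national series (two early surveys, a
# mid-decade one, two recent); trends are set so overweight+obesity rises
# from roughly 60% of adults around 2010 toward the high-80s/mid-80s percent
# range by 2030, with obesity higher in women and overweight higher in men.
# ---------------------------------------------------------------------------

def irish_like_spec(seed: int = 0, n_per_cell: int = 1000) -> GeneratorSpec:
    """Synthetic preset with Irish-style survey sparsity and obesity trends."""
    age_groups = ((20, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 89))
    diseases = (
        DiseaseSpec(
            name="chd_stroke", fatal=True, schedule_kind="incidence",
            level={"male": 0.005, "female": 0.0035}, age_slope=0.085,
            rr_overweight=1.6, rr_obese=2.4,
            five_year_survival=0.70, annual_unit_cost=8000.0,
        ),
        DiseaseSpec(
            name="cancer", fatal=True, schedule_kind="incidence",
            level={"male": 0.003, "female": 0.0032}, age_slope=0.075,
            rr_overweight=1.15, rr_obese=1.5,
            five_year_survival=0.55, annual_unit_cost=10000.0,
        ),
        DiseaseSpec(
            name="hypertension", fatal=False, schedule_kind="prevalence",
            level={"male": 0.65, "female": 0.60}, midpoint=58.0, width=11.0,
            rr_overweight=1.8, rr_obese=3.0, annual_unit_cost=600.0,
        ),
        DiseaseSpec(
            name="type2_diabetes", fatal=False, schedule_kind="prevalence",
            level={"male": 0.16, "female": 0.13}, midpoint=62.0, width=10.0,
            rr_overweight=2.0, rr_obese=4.5, annual_unit_cost=2500.0,
        ),
        DiseaseSpec(
            name="knee_osteoarthritis", fatal=False, schedule_kind="prevalence",
            level={"male": 0.10, "female": 0.14}, midpoint=65.0, width=9.0,
            rr_overweight=1.8, rr_obese=3.5, annual_unit_cost=1200.0,
        ),
    )
    # Irish adult population shape (~3.3M aged 20+), thousands per group.
    pop_male = (330e3, 360e3, 330e3, 270e3, 200e3, 160e3)
    pop_female = (330e3, 370e3, 335e3, 275e3, 205e3, 190e3)
    return GeneratorSpec(
        seed=seed,
        survey_years=(1998, 2001, 2002, 2007, 2011),
        age_groups=age_groups,
        trend={
            "male": dict(intercept_ow=-0.16, slope_ow=0.059,
                         intercept_ob=-0.79, slope_ob=0.090),
            "female": dict(intercept_ow=-0.58, slope_ow=0.048,
                           intercept_ob=-0.84, slope_ob=0.087),
        },
        ref_year=2005,
        n_per_cell=n_per_cell,
        population={"male": pop_male, "female": pop_female},
        mortality={"male": (7.0e-4, 0.091), "female": (4.5e-4, 0.094)},
        diseases=diseases,
        age_offsets_overweight=(-0.35, -0.05, 0.10, 0.20, 0.22, 0.12),
        age_offsets_obese=(-0.45, -0.10, 0.12, 0.25, 0.28, 0.10),
    )
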