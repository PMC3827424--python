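"""Shared fixtures: small generator specs, a projected distribution built by
hand, and one session-scoped full pipeline run reused by the scenario,
costing and acceptance tests (common random numbers across its scenarios)."""

import numpy as np
import pandas as pd
import pytest

from obesim import (PipelineConfig, ProjectedDistribution, irish_like_spec, run_pipeline)
from obesim.synthetic_data import GeneratorSpec


def small_spec(seed: int = 0, *, slope_ob: float = 0.05, slope_ow: float = 0.03,
               n_per_cell: int = 10_000, years=(2000, 2002, 2004, 2006, 2008, 2010)
               ) -> GeneratorSpec:
    """Compact three-age-group spec with known logit slopes."""
    return GeneratorSpec(
        seed=seed,
        survey_years=tuple(years),
        age_groups=((20, 39), (40, 59), (60, 89)),
        trend={
            "male": dict(intercept_ow=0.1, slope_ow=slope_ow,
                         intercept_ob=-0.5, slope_ob=slope_ob),
            "female": dict(intercept_ow=-0.2, slope_ow=slope_ow,
                           intercept_ob=-0.4, slope_ob=slope_ob),
        },
        ref_year=int(np.mean(years)),
        n_per_cell=n_per_cell,
        population={"male": (4e5, 4e5, 3e5), "female": (4e5, 4e5, 3e5)},
        mortality={"male": (6e-4, 0.09), "female": (4e-4, 0.09)},
        diseases=irish_like_spec().diseases,
    )


def flat_distribution(p=(0.2, 0.4, 0.4), years=range(2010, 2031),
                      age_groups=((20, 89),)) -> ProjectedDistribution:
    """Year/age-constant projected distribution with the given triple."""
    rows = []
    for year in years:
        for sex in ("male", "female"):
            for lo, hi in age_groups:
                rows.append(dict(year=year, sex=sex, age_lo=lo, age_hi=hi,
                                 p_normal=p[0], p_overweight=p[1], p_obese=p[2]))
    return ProjectedDistribution(pd.DataFrame(rows))


def uniform_population_frame(n_per_age: float = 100.0, ages=range(20, 90)) -> pd.DataFrame:
    rows = [dict(sex=s, age=a, count=n_per_age) for s in ("male", "female") for a in ages]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def pipeline_bundle():
    """One full desk-scale run of the Irish-like preset, all three scenarios.

    Shared across tests: 50,000 individuals, common random numbers across
    scenarios, no bootstrap bands (tested separately).
    """
    cfg = PipelineConfig(generator=irish_like_spec(seed=7), seed=7,
                         n_individuals=50_000, out_dir="scratch/test_bundle",
                         n_boot=0)
    return run_pipeline(cfg, write=False)
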