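"""Shared vocabulary: BMI categories, WHO cut-offs, sexes, age-group helpers."""

from __future__ import annotations

import numpy as np

#: BMI categories in cut-off order (reference category first).
CATEGORIES: tuple[str, ...] = ("normal", "overweight", "obese")

#: WHO cut-offs in kg/m^2: normal <25, overweight 25-29.99, obese >=30.
BMI_CUTOFFS: tuple[float, float] = (25.0, 30.0)

SEXES: tuple[str, ...] = ("male", "female")

#: Closed age range in whole years, e.g. (20, 29).
AgeGroup = tuple[int, int]


def age_group_index(age_groups: tuple[AgeGroup, ...], ages) -> np.ndarray:
    """Map ages to the index of the containing age group.

    Ages beyond the last group's upper bound are clamped into the last
    group (open-ended old age); ages below the first group raise.
    """
    ages = np.asarray(ages)
    if np.any(ages < age_groups[0][0]):
        raise ValueError(f"age below model support (min {age_groups[0][0]})")
    lows = np.array([lo for lo, _ in age_groups])
    idx = np.searchsorted(lows, ages, side="right") - 1
    return np.clip(idx, 0, len(age_groups) - 1)


def category_from_bmi(bmi) -> np.ndarray:
    """Integer category code (0 normal, 1 overweight, 2 obese) from BMI values."""
    bmi = np.asarray(bmi)
    return (bmi >= BMI_CUTOFFS[0]).astype(np.int8) + (bmi >= BMI_CUTOFFS[1]).astype(np.int8)
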