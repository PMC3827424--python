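"""Direct healthcare cost accounting and indirect-cost extrapolation.

Costing is prevalence-based: each obesity-related prevalent case-year of a
disease accrues that disease's annual unit cost (euro/case/year), reported
in € millions at whole-population scale, undiscounted by default (a
discount-rate knob exists).  Indirect costs — productivity losses not
captured by a healthcare-utilisation model — are extrapolated by scaling
direct costs with a published national direct:indirect ratio (defaults
€399m direct : €729m indirect).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .microsim import AnnualTally
from .scenarios import obesity_related

logger = logging.getLogger(__name__)

#: published national cost split the indirect extrapolation defaults to (€m)
DEFAULT_DIRECT_M = 399.0
DEFAULT_INDIRECT_M = 729.0


@dataclass
class CostTable:
    """Annual direct costs by disease for one scenario.

    `by_disease`: (year, disease, cost_millions); `totals`: (year,
    cost_millions) summed across diseases.  Full precision is retained;
    use `report_table` for 3-significant-figure presentation.
    """

    scenario_id: int
    seed: int
    by_disease: pd.DataFrame
    discount_rate: float = 0.0

    @property
    def totals(self) -> pd.DataFrame:
        return (self.by_disease.groupby("year", as_index=False)["cost_millions"].sum())

    def total_at(self, year: int) -> float:
        t = self.totals
        return float(t.loc[t["year"] == year, "cost_millions"].iloc[0])

    def report_table(self) -> pd.DataFrame:
        """Diseases x years, € millions rounded to 3 significant figures."""
        wide = self.by_disease.pivot(index="disease", columns="year", values="cost_millions")
        wide.loc["total"] = wide.sum(axis=0)
        return wide.map(round_sig)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to `sig` significant figures (report-table style)."""
    if x == 0 or not np.isfinite(x):
        return x
    return float(np.round(x, -int(np.floor(np.log10(abs(x)))) + sig - 1))


def annual_direct_costs(tally: AnnualTally, diseases, *, discount_rate: float = 0.0,
                        base_year: int | None = None) -> CostTable:
    """Annual obesity-related direct costs per disease, € millions.

    cost(disease, year) = obesity-related prevalent cases at whole-population
    scale x annual unit cost.  A non-zero discount rate discounts each year
    back to `base_year` (default: the run's start year).
    """
    unit = {d.name: d.annual_unit_cost for d in diseases}
    tallied = set(tally.strata["disease"].unique())
    missing = tallied - set(unit)
    if missing:
        raise ValueError(f"missing unit cost for disease(s): {sorted(missing)}")
    ob = obesity_related(tally, [d for d in diseases if d.name in tallied])
    base = tally.start_year if base_year is None else base_year
    ob = ob.assign(
        cost_millions=[
            r.prevalent_ob_population * unit[r.disease] / 1e6
            / (1.0 + discount_rate) ** (r.year - base)
            for r in ob.itertuples()
        ])
    return CostTable(scenario_id=tally.scenario_id, seed=tally.seed,
                     by_disease=ob[["year", "disease", "cost_millions"]],
                     discount_rate=discount_rate)


def cost_savings(costs_0: CostTable, costs_k: CostTable) -> pd.DataFrame:
    """Per-year total direct cost difference, scenario 0 minus scenario k."""
    if costs_0.seed != costs_k.seed or costs_0.discount_rate != costs_k.discount_rate:
        raise ValueError("cost tables come from incomparable runs")
    merged = costs_0.totals.merge(costs_k.totals, on="year", suffixes=("_0", "_k"))
    merged["savings_millions"] = merged["cost_millions_0"] - merged["cost_millions_k"]
    merged["scenario"] = costs_k.scenario_id
    return merged[["scenario", "year", "savings_millions"]]


def indirect_from_ratio(direct_millions: float,
                        ratio_numerator: float = DEFAULT_INDIRECT_M,
                        ratio_denominator: float = DEFAULT_DIRECT_M) -> float:
    """Indirect cost estimate from direct costs via a published ratio.

    indirect = direct x (numerator / denominator); with the default Irish
    split €399m direct maps back to €729m indirect exactly.
    """
    if ratio_denominator <= 0:
        raise ValueError("ratio denominator must be positive")
    return direct_millions * ratio_numerator / ratio_denominator
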