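"""End-to-end orchestration: synthesize -> project -> convert -> simulate ->
scenarios -> cost, with CSV artifacts and report rendering.

Everything is exchanged as CSV; a run manifest (JSON) records the seed,
sizes, units and wall time.  Rerunning the same configuration reproduces
every CSV byte for byte — only the manifest timestamp differs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bmi_projection import (CategoryTrendModel, ProjectedDistribution, filter_outliers,
                             fit_category_trends, merge_distributions, project_distribution,
                             projection_confidence_limits)
from .costing import CostTable, annual_direct_costs, cost_savings, indirect_from_ratio
from .defs import CATEGORIES, SEXES
from .epi_inputs import HazardSchedule, calibrate_category_incidence, prepare_diseases
from .microsim import AnnualTally, CalibratedDisease, SimulationConfig, run_simulation
from .scenarios import Scenario, cases_avoided, obesity_related, standard_scenarios
from .synthetic_data import GeneratorSpec, irish_like_spec, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one data source (inputs or generator)."""

    out_dir: str | Path = "obesim_out"
    input_dir: str | Path | None = None      # directory of survey/population/... CSVs
    generator: GeneratorSpec | None = None   # or synthesize them
    seed: int = 0
    n_individuals: int = 100_000
    start_year: int = 2010
    end_year: int = 2030
    scenario_ids: tuple[int, ...] = (0, 1, 2)
    n_boot: int = 500
    filter_outliers: bool = True
    weighted_fit: bool = True
    discount_rate: float = 0.0
    verbosity: str = "INFO"

    def __post_init__(self):
        if (self.input_dir is None) == (self.generator is None):
            raise ValueError("supply exactly one of input_dir or generator")
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if raw.get("generator") == "irish_like":
            raw["generator"] = irish_like_spec(seed=int(raw.get("seed", 0)))
        if "scenario_ids" in raw:
            raw["scenario_ids"] = tuple(raw["scenario_ids"])
        return cls(**raw)


@dataclass
class ReportBundle:
    """All pipeline artifacts, in memory plus their CSV paths."""

    config: PipelineConfig
    models: dict[str, CategoryTrendModel]
    distribution: ProjectedDistribution
    bands: ProjectedDistribution | None
    diseases: list[CalibratedDisease]
    tallies: dict[int, AnnualTally]
    obesity_tables: dict[int, pd.DataFrame]
    avoided: pd.DataFrame | None
    costs: dict[int, CostTable]
    savings: pd.DataFrame | None
    paths: dict[str, Path] = field(default_factory=dict)

    def missing(self) -> list[str]:
        need = ["distribution", "tallies", "obesity_tables", "costs"]
        return [k for k in need if not getattr(self, k)]


def _load_inputs(cfg: PipelineConfig):
    if cfg.generator is not None:
        from .synthetic_data import (generate_disease_tables, generate_mortality,
                                     generate_population, generate_survey_series)
        spec = cfg.generator
        return (generate_survey_series(spec), generate_population(spec),
                generate_mortality(spec), generate_disease_tables(spec))
    d = Path(cfg.input_dir)
    frames = []
    for name in ("survey", "population", "mortality", "diseases"):
        p = d / f"{name}.csv"
        if not p.exists():
            raise FileNotFoundError(f"missing input file {p}")
        frames.append(pd.read_csv(p))
    return tuple(frames)


def run_pipeline(cfg: PipelineConfig, *, write: bool = True,
                 render: bool = False) -> ReportBundle:
    """Execute the full two-stage pipeline under one configuration.

    Order: (1) load or synthesize inputs; (2) outlier filter + per-sex
    categorical trend fit + projection with bootstrap bands; (3) disease
    preparation (prevalence -> incidence, survival -> excess hazard) and
    per-category calibration at the baseline year; (4) one simulation run
    per scenario under common random numbers; (5) obesity attribution,
    cases avoided and cost tables.  All artifacts are written as CSV under
    the output directory together with a JSON manifest.
    """
    t0 = time.time()
    logging.basicConfig(level=getattr(logging, cfg.verbosity, logging.INFO))
    survey, population, mortality_df, disease_df = _load_inputs(cfg)
    logger.info("inputs: %d survey rows, %d diseases", len(survey),
                disease_df["disease"].nunique())

    if cfg.filter_outliers:
        survey, removed = filter_outliers(survey, weighted=cfg.weighted_fit)
        logger.info("outlier filter kept %d rows, removed %d", len(survey), len(removed))

    years = range(cfg.start_year, cfg.end_year + 1)
    models, dists, band_dists = {}, [], []
    for sex in SEXES:
        m = fit_category_trends(survey, sex, weighted=cfg.weighted_fit)
        models[sex] = m
        dists.append(project_distribution(m, years))
        if cfg.n_boot:
            band_dists.append(projection_confidence_limits(
                m, years, n_boot=cfg.n_boot, seed=cfg.seed))
    dist = merge_distributions(*dists)
    bands = merge_distributions(*band_dists) if band_dists else None

    mortality = HazardSchedule.from_frame(mortality_df)
    defs = prepare_diseases(disease_df, mortality)
    diseases = []
    for d in defs:
        by_cat = calibrate_category_incidence(d.schedule, d.rr_by_category, dist,
                                              baseline_year=cfg.start_year)
        diseases.append(CalibratedDisease(
            name=d.name, fatal=d.fatal, incidence_by_category=by_cat,
            case_fatality=d.case_fatality, annual_unit_cost=d.annual_unit_cost,
            rr_by_category=d.rr_by_category,
            baseline_prevalence=d.baseline_prevalence))

    scens = standard_scenarios(cfg.start_year)
    tallies, ob_tables, costs = {}, {}, {}
    for sid in cfg.scenario_ids:
        sim_cfg = SimulationConfig(n_individuals=cfg.n_individuals,
                                   start_year=cfg.start_year, end_year=cfg.end_year,
                                   seed=cfg.seed, scenario_id=sid)
        tallies[sid] = run_simulation(sim_cfg, dist, diseases, population, mortality,
                                      scenario=scens[sid])
        ob_tables[sid] = obesity_related(tallies[sid], diseases)
        costs[sid] = annual_direct_costs(tallies[sid], diseases,
                                         discount_rate=cfg.discount_rate)

    avoided = savings = None
    if 0 in tallies and len(tallies) > 1:
        avoided = pd.concat(
            [cases_avoided(tallies[0], tallies[k], diseases)
             for k in cfg.scenario_ids if k != 0], ignore_index=True)
        savings = pd.concat(
            [cost_savings(costs[0], costs[k]) for k in cfg.scenario_ids if k != 0],
            ignore_index=True)

    bundle = ReportBundle(config=cfg, models=models, distribution=dist, bands=bands,
                          diseases=diseases, tallies=tallies, obesity_tables=ob_tables,
                          avoided=avoided, costs=costs, savings=savings)
    if write:
        _write_bundle(bundle, time.time() - t0)
    if render:
        render_reports(bundle)
    return bundle


def _write_bundle(bundle: ReportBundle, wall_time: float) -> None:
    cfg = bundle.config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def save(name: str, df: pd.DataFrame):
        p = out / name
        df.to_csv(p, index=False, float_format="%.10g")
        bundle.paths[name] = p

    save("projected_bmi.csv", bundle.distribution.table)
    if bundle.bands is not None:
        save("projected_bmi_bands.csv", bundle.bands.table)
    for sid, tally in bundle.tallies.items():
        save(f"tally_scenario{sid}.csv",
             tally.totals[["year", "disease", "prevalent_per_100k",
                           "cum_incidence_per_100k"]])
        save(f"obesity_related_scenario{sid}.csv", bundle.obesity_tables[sid])
        save(f"costs_scenario{sid}.csv", bundle.costs[sid].by_disease)
    if bundle.avoided is not None:
        save("cases_avoided.csv", bundle.avoided)
        save("cost_savings.csv", bundle.savings)

    manifest = dict(
        version=__version__,
        seed=cfg.seed, n_individuals=cfg.n_individuals,
        years=[cfg.start_year, cfg.end_year],
        scenarios=list(cfg.scenario_ids), n_boot=cfg.n_boot,
        wall_time_s=round(wall_time, 2),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        units=dict(proportions="fraction in [0,1]",
                   tallies="cases per 100,000 population",
                   costs="euro millions per year",
                   hazards="per person-year"),
        files=sorted(str(p.name) for p in bundle.paths.values()),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def headline_summary(bundle: ReportBundle) -> str:
    """Plain-text summary of the headline numbers of a run."""
    cfg = bundle.config
    y = cfg.end_year
    lines = [f"Projection horizon {y} (n={cfg.n_individuals:,}, seed={cfg.seed})", ""]
    for sex in SEXES:
        tally0 = bundle.tallies[min(bundle.tallies)]
        cats = tally0.categories
        sub = cats[(cats["year"] == y) & (cats["sex"] == sex)]
        tot = sub["count"].sum()
        ow = sub.loc[sub["category"] != "normal", "count"].sum() / tot
        ob = sub.loc[sub["category"] == "obese", "count"].sum() / tot
        lines.append(f"  {sex}: overweight+obese {100 * ow:.0f}%, obese {100 * ob:.0f}% in {y}")
    lines.append("")
    for sid, ct in bundle.costs.items():
        total = ct.total_at(y)
        lines.append(f"  scenario {sid}: direct costs €{total:,.0f}m in {y} "
                     f"(indirect ≈ €{indirect_from_ratio(total):,.0f}m)")
    if bundle.savings is not None:
        for sid in sorted(set(bundle.savings["scenario"])):
            s = bundle.savings
            v = float(s.loc[(s["scenario"] == sid) & (s["year"] == y), "savings_millions"].iloc[0])
            lines.append(f"  scenario {sid} saves €{v:,.0f}m in {y} vs scenario 0")
    return "\n".join(lines)


def render_reports(bundle: ReportBundle) -> dict[str, Path]:
    """Figures (BMI prevalence, disease burden, cases avoided) + text summary."""
    missing = bundle.missing()
    if missing:
        raise ValueError(f"bundle incomplete, missing: {missing}")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cfg = bundle.config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    y_marks = [y for y in (cfg.start_year, (cfg.start_year + cfg.end_year) // 2, cfg.end_year)]

    # overweight/obesity prevalence by sex and year
    fig, ax = plt.subplots(figsize=(7, 4))
    tally0 = bundle.tallies[min(bundle.tallies)]
    width, xpos = 0.35, np.arange(len(y_marks))
    for off, sex in zip((-width / 2, width / 2), SEXES):
        vals = []
        for y in y_marks:
            sub = tally0.categories[(tally0.categories["year"] == y)
                                    & (tally0.categories["sex"] == sex)]
            vals.append(100 * sub.loc[sub["category"] != "normal", "count"].sum()
                        / sub["count"].sum())
        ax.bar(xpos + off, vals, width, label=sex)
    ax.set_xticks(xpos, [str(y) for y in y_marks])
    ax.set_ylabel("overweight + obese (%)")
    ax.legend()
    fig.tight_layout()
    p = out / "fig_bmi_prevalence.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["fig_bmi_prevalence"] = p

    # obesity-related disease prevalence per 100k over time
    fig, ax = plt.subplots(figsize=(7, 4))
    ob0 = bundle.obesity_tables[min(bundle.obesity_tables)]
    for disease, sub in ob0.groupby("disease"):
        ax.plot(sub["year"], sub["prevalent_ob_per_100k"], label=disease)
    ax.set_ylabel("obesity-related prevalent cases per 100,000")
    ax.set_xlabel("year")
    ax.legend(fontsize=8)
    fig.tight_layout()
    p = out / "fig_disease_prevalence.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["fig_disease_prevalence"] = p

    # cumulative incident cases avoided at the horizon
    fig, ax = plt.subplots(figsize=(7, 4))
    if bundle.avoided is not None and len(bundle.avoided):
        horizon = bundle.avoided[bundle.avoided["year"] == cfg.end_year]
        diseases = sorted(horizon["disease"].unique())
        xpos = np.arange(len(diseases))
        sids = sorted(horizon["scenario"].unique())
        w = 0.8 / max(len(sids), 1)
        for i, sid in enumerate(sids):
            sub = horizon[horizon["scenario"] == sid].set_index("disease")
            ax.bar(xpos + i * w, [sub.loc[d, "avoided_per_100k"] for d in diseases],
                   w, label=f"scenario {sid}")
        ax.set_xticks(xpos + w / 2, diseases, rotation=20, fontsize=8)
        ax.legend()
    ax.set_ylabel("cumulative incident cases avoided per 100,000")
    fig.tight_layout()
    p = out / "fig_cases_avoided.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["fig_cases_avoided"] = p

    summary = headline_summary(bundle)
    p = out / "summary.txt"
    p.write_text(summary + "\n")
    paths["summary"] = p
    bundle.paths.update(paths)
    return paths
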