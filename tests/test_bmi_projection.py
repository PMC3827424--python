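"""Stage-1 regression: likelihood fit, outlier rule, projection, bands."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from obesim import (fit_category_trends, filter_outliers, irish_like_spec,
                    merge_distributions, project_distribution,
                    projection_confidence_limits)
from obesim.bmi_projection import loglik_at
from obesim.synthetic_data import generate_survey_series, true_proportions

from conftest import small_spec


@pytest.fixture(scope="module")
def survey():
    return generate_survey_series(small_spec(seed=11))


@pytest.fixture(scope="module")
def fitted(survey):
    return fit_category_trends(survey, "male")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_recovers_known_slope(fitted):
    truth = 0.05
    assert abs(fitted.slope("obese") - truth) < 4 * fitted.slope_se("obese")
    assert abs(fitted.slope("overweight") - 0.03) < 4 * fitted.slope_se("overweight")


def test_null_trend_yields_zero_slope():
    sv = generate_survey_series(small_spec(seed=5, slope_ob=0.0, slope_ow=0.0))
    m = fit_category_trends(sv, "female")
    assert abs(m.slope("obese")) < 2 * m.slope_se("obese")
    assert abs(m.slope("overweight")) < 2 * m.slope_se("overweight")


def test_fit_matches_brute_force_maximizer_on_small_instance():
    """Independent plain-python likelihood + derivative-free search agree."""
    spec = small_spec(seed=2, years=(2000, 2005, 2010), n_per_cell=500)
    spec = dataclasses.replace(spec, age_groups=spec.age_groups[:2],
                               population={"male": (4e5, 4e5), "female": (4e5, 4e5)},
                               age_offsets_overweight=(), age_offsets_obese=())
    sv = generate_survey_series(spec)
    m = fit_category_trends(sv, "male")

    sub = sv[sv.sex == "male"]
    wide = sub.pivot_table(index=["year", "age_lo"], columns="category",
                           values="proportion")
    cells = [(yr, lo, row["normal"] * 500, row["overweight"] * 500, row["obese"] * 500)
             for (yr, lo), row in wide.iterrows()]
    year0 = float(np.mean([2000, 2005, 2010]))

    def oracle_nll(theta):
        b_ow, b_ob = theta[:3], theta[3:]
        nll = 0.0
        for yr, lo, cn, cow, cob in cells:
            x = (1.0, yr - year0, 1.0 if lo == 40 else 0.0)
            e_ow = math.exp(sum(b * xi for b, xi in zip(b_ow, x)))
            e_ob = math.exp(sum(b * xi for b, xi in zip(b_ob, x)))
            z = 1.0 + e_ow + e_ob
            nll -= (cn * math.log(1.0 / z) + cow * math.log(e_ow / z)
                    + cob * math.log(e_ob / z))
        return nll

    best = min(
        (optimize.minimize(oracle_nll, x0, method="Powell",
                           options=dict(xtol=1e-10, ftol=1e-12, maxiter=20000))
         for x0 in (np.zeros(6), np.full(6, 0.1), np.array([0, 0.05, 0, -0.5, 0.05, 0]))),
        key=lambda r: r.fun)
    assert best.fun == pytest.approx(-m.loglik, abs=1e-4)
    assert np.allclose(best.x.reshape(2, 3), m.beta, atol=1e-3)


def test_mle_beats_truth_parameters_in_likelihood(survey, fitted):
    spec = small_spec(seed=11)
    t = spec.trend["male"]
    # truth in the fitted parameterisation (same centring, no age offsets)
    beta_truth = np.array([
        [t["intercept_ow"], t["slope_ow"], 0.0, 0.0],
        [t["intercept_ob"], t["slope_ob"], 0.0, 0.0],
    ])
    assert loglik_at(fitted, survey) >= loglik_at(fitted, survey, beta_truth)


def test_zero_weight_cells_do_not_change_the_fit(survey, fitted):
    ghost = pd.DataFrame([
        dict(year=2003, sex="male", age_lo=20, age_hi=39, category=c,
             proportion=p, n=0)
        for c, p in (("normal", 0.1), ("overweight", 0.1), ("obese", 0.8))])
    m2 = fit_category_trends(pd.concat([survey, ghost], ignore_index=True), "male")
    assert np.allclose(m2.beta, fitted.beta, atol=1e-8)


def test_separation_raises_with_stratum_named():
    sv = generate_survey_series(small_spec(seed=4))
    sv.loc[(sv.sex == "male") & (sv.category == "obese"), "proportion"] = 0.0
    with pytest.raises(ValueError, match="obese.*male"):
        fit_category_trends(sv, "male")


def test_fit_requires_two_years():
    spec = small_spec(years=(2005, 2006))
    sv = generate_survey_series(spec)
    one_year = sv[sv.year == 2005]
    with pytest.raises(ValueError, match="2 distinct"):
        fit_category_trends(one_year, "male")


# ---------------------------------------------------------------------------
# outlier filter
# ---------------------------------------------------------------------------

def test_outlier_filter_flags_few_cells_under_the_truth_model():
    flagged = total = 0
    for seed in range(5):
        sv = generate_survey_series(small_spec(seed=100 + seed, n_per_cell=5000))
        kept, removed = filter_outliers(sv)
        assert len(kept) + len(removed) == len(sv)
        flagged += len(removed)
        total += len(sv)
    assert 0.0 <= flagged / total < 0.10  # nominal ~5% observation flag rate


def test_outlier_filter_removes_gross_perturbation():
    sv = generate_survey_series(small_spec(seed=6, n_per_cell=5000))
    idx = sv[(sv.sex == "male") & (sv.year == 2004) & (sv.age_lo == 20)
             & (sv.category == "obese")].index[0]
    sv.loc[idx, "proportion"] = 0.99
    kept, removed = filter_outliers(sv)
    assert ((removed.year == 2004) & (removed.age_lo == 20)
            & (removed.sex == "male")).any()


def test_outlier_filter_needs_three_years():
    sv = generate_survey_series(small_spec(years=(2005, 2010)))
    with pytest.raises(ValueError, match="3 survey years"):
        filter_outliers(sv)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def test_projection_reproduces_in_sample_fitted_values(fitted):
    dist = project_distribution(fitted, [2000, 2010])
    gi = np.arange(len(fitted.age_groups))
    for year in (2000, 2010):
        expect = fitted.predict(np.full(len(gi), year), gi)
        got = dist.stratum_matrix(year, "male")
        assert np.allclose(got, expect, atol=1e-12)


def test_projected_triples_sum_to_one(fitted):
    dist = project_distribution(fitted, range(1990, 2041))
    sums = dist.table[["p_normal", "p_overweight", "p_obese"]].sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_positive_slope_gives_monotone_obesity(fitted):
    assert fitted.slope("obese") > 0
    dist = project_distribution(fitted, range(2010, 2031))
    for lo, _ in fitted.age_groups:
        sub = dist.table[dist.table.age_lo == lo].sort_values("year")
        assert np.all(np.diff(sub["p_obese"]) > 0)


def test_backcast_years_flagged(fitted):
    dist = project_distribution(fitted, [1995, 2020])
    assert dist.backcast_years == (1995,)


def test_irish_preset_horizon_in_plausibility_corridor():
    """Overweight+obese at the 2030 horizon lands in the 0.70-0.95 corridor."""
    spec = irish_like_spec(seed=0)
    sv = generate_survey_series(spec)
    for sex in ("male", "female"):
        m = fit_category_trends(sv, sex)
        dist = project_distribution(m, [2030])
        weights = np.array(spec.population[sex])
        over = 1.0 - dist.stratum_matrix(2030, sex)[:, 0]
        pooled = float(np.average(over, weights=weights))
        assert 0.70 < pooled < 0.95


# ---------------------------------------------------------------------------
# bootstrap bands
# ---------------------------------------------------------------------------

def test_bands_contain_point_estimate_and_widen_with_horizon(fitted):
    dist = projection_confidence_limits(fitted, [2010, 2030], n_boot=500, seed=1)
    t = dist.table
    for cat in ("normal", "overweight", "obese"):
        assert (t[f"p_{cat}_lo"] <= t[f"p_{cat}"] + 1e-12).all()
        assert (t[f"p_{cat}_hi"] >= t[f"p_{cat}"] - 1e-12).all()
    w10 = (t[t.year == 2010].p_obese_hi - t[t.year == 2010].p_obese_lo).mean()
    w30 = (t[t.year == 2030].p_obese_hi - t[t.year == 2030].p_obese_lo).mean()
    assert w30 > w10


def test_bands_collapse_as_sampling_noise_vanishes():
    wide = []
    for n in (500, 500_000):
        sv = generate_survey_series(small_spec(seed=8, n_per_cell=n))
        m = fit_category_trends(sv, "male")
        t = projection_confidence_limits(m, [2030], n_boot=400, seed=2).table
        wide.append(float((t.p_obese_hi - t.p_obese_lo).mean()))
    assert wide[1] < wide[0] / 10


def test_band_coverage_near_nominal():
    """95% bands cover the known truth in ~95% of replicates (+-3%)."""
    spec0 = small_spec(seed=0, n_per_cell=2000)
    hits = total = 0
    for rep in range(200):
        spec = dataclasses.replace(spec0, seed=1000 + rep)
        sv = generate_survey_series(spec)
        m = fit_category_trends(sv, "male")
        t = projection_confidence_limits(m, [2020], n_boot=300, seed=rep).table
        truth = true_proportions(spec, [2020], "male")
        merged = t.merge(truth, on=["year", "sex", "age_lo", "age_hi"],
                         suffixes=("", "_true"))
        hits += int(((merged.p_obese_lo <= merged.p_obese_true)
                     & (merged.p_obese_true <= merged.p_obese_hi)).sum())
        total += len(merged)
    assert abs(hits / total - 0.95) < 0.03


def test_low_n_boot_warns_but_runs(fitted, caplog):
    import logging
    with caplog.at_level(logging.WARNING):
        projection_confidence_limits(fitted, [2020], n_boot=100, seed=0)
    assert any("n_boot" in r.message for r in caplog.records)


def test_merged_distribution_serves_both_sexes():
    sv = generate_survey_series(small_spec(seed=9))
    dists = [project_distribution(fit_category_trends(sv, s), [2015])
             for s in ("male", "female")]
    merged = merge_distributions(*dists)
    assert merged.proportions(2015, "male", 25).shape == (3,)
    assert merged.proportions(2015, "female", 70).sum() == pytest.approx(1.0)
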