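"""Stage 1: constrained categorical BMI-trend regression and projection.

Cross-sectional survey proportions (normal / overweight / obese, WHO
cut-offs) are fitted per sex with a multinomial logit that is linear in
calendar year with additive age-group offsets.  The softmax link makes
every fitted or projected triple of proportions sum to one by construction
— the 100% constraint is structural, not imposed afterwards.  Surveys are
weighted by their cell sample sizes (effective multinomial counts); a flag
disables the weighting.  Confidence bands come from a parametric bootstrap
of the coefficient vector, which respects the [0, 1] scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .defs import AgeGroup, CATEGORIES, SEXES, age_group_index

logger = logging.getLogger(__name__)

_SURVEY_COLUMNS = ("year", "sex", "age_lo", "age_hi", "category", "proportion", "n")

#: non-reference categories, in logit order
_NONREF = ("overweight", "obese")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CategoryTrendModel:
    """Fitted multinomial-logit trend for one sex.

    `beta` has shape (2, p): one coefficient row per non-reference category
    (overweight, obese) over columns [intercept, year slope, age-group
    offsets 2..G].  `cov` is the (2p, 2p) inverse observed information of
    the stacked coefficient vector.  Years enter centred at `year0`.
    """

    sex: str
    beta: np.ndarray
    cov: np.ndarray
    year0: float
    age_groups: tuple[AgeGroup, ...]
    param_names: tuple[str, ...]
    loglik: float
    deviance: float
    n_obs: int
    reference: str = "normal"
    weighted: bool = True
    year_min: float = float("nan")
    year_max: float = float("nan")

    @property
    def n_params(self) -> int:
        return self.beta.size

    def slope(self, category: str) -> float:
        """Fitted per-year logit slope of a non-reference category."""
        return float(self.beta[_NONREF.index(category), 1])

    def slope_se(self, category: str) -> float:
        p = self.beta.shape[1]
        j = _NONREF.index(category) * p + 1
        return float(np.sqrt(self.cov[j, j]))

    def _design(self, years, group_idx) -> np.ndarray:
        years = np.asarray(years, dtype=float)
        group_idx = np.asarray(group_idx)
        G = len(self.age_groups)
        X = np.zeros((years.size, self.beta.shape[1]))
        X[:, 0] = 1.0
        X[:, 1] = years - self.year0
        for g in range(1, G):
            X[:, 1 + g] = group_idx == g
        return X

    def predict(self, years, group_idx) -> np.ndarray:
        """Category proportions, shape (n_cells, 3), rows summing to one."""
        X = self._design(years, group_idx)
        return _softmax3(X @ self.beta.T)


@dataclass
class ProjectedDistribution:
    """Projected category proportions per (year, sex, age group).

    `table` columns: year, sex, age_lo, age_hi, p_normal, p_overweight,
    p_obese, plus optional `<cat>_lo` / `<cat>_hi` 95% band columns.
    `backcast_years` flags any requested year before the earliest survey.
    """

    table: pd.DataFrame
    backcast_years: tuple[int, ...] = ()

    def __post_init__(self):
        self._index: dict = {}
        for row in self.table.itertuples(index=False):
            self._index[(int(row.year), row.sex, int(row.age_lo))] = (
                row.p_normal, row.p_overweight, row.p_obese)
        self._age_groups = tuple(sorted(
            {(int(lo), int(hi)) for lo, hi in zip(self.table.age_lo, self.table.age_hi)}))

    @property
    def age_groups(self) -> tuple[AgeGroup, ...]:
        return self._age_groups

    def proportions(self, year: int, sex: str, age) -> np.ndarray:
        """(p_normal, p_overweight, p_obese) for the stratum containing `age`."""
        gi = int(age_group_index(self._age_groups, age))
        key = (int(year), sex, self._age_groups[gi][0])
        try:
            return np.array(self._index[key])
        except KeyError:
            raise KeyError(f"no projected stratum for year={year}, sex={sex}, age={age}") from None

    def stratum_matrix(self, year: int, sex: str) -> np.ndarray:
        """Proportions for all age groups at (year, sex), shape (G, 3)."""
        return np.vstack([self._index[(int(year), sex, lo)] for lo, _ in self._age_groups])


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _softmax3(eta: np.ndarray) -> np.ndarray:
    """Proportions from the two non-reference logits; eta shape (n, 2)."""
    z = np.column_stack([np.zeros(len(eta)), eta])
    z -= z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def _cells_from_survey(obs: pd.DataFrame, sex: str, weighted: bool):
    """Pivot long survey rows into per-cell count matrices for one sex.

    Returns (years, group_idx, counts[n_cells, 3], age_groups).  Counts are
    proportion*n (multinomial weights) or bare proportions when unweighted.
    """
    sub = obs[(obs["sex"] == sex) & (obs["n"] > 0)]  # zero-weight cells carry nothing
    if sub.empty:
        raise ValueError(f"no survey rows for sex={sex!r}")
    age_groups = tuple(sorted({(int(lo), int(hi)) for lo, hi in zip(sub.age_lo, sub.age_hi)}))
    wide = sub.pivot_table(index=["year", "age_lo", "age_hi"], columns="category",
                           values=["proportion", "n"], aggfunc="first")
    years = wide.index.get_level_values("year").to_numpy(float)
    lows = wide.index.get_level_values("age_lo").to_numpy(int)
    group_idx = np.searchsorted([lo for lo, _ in age_groups], lows)
    props = np.column_stack([wide[("proportion", c)].to_numpy(float) for c in CATEGORIES])
    ns = wide[("n", CATEGORIES[0])].to_numpy(float)
    if np.isnan(props).any():
        raise ValueError(f"incomplete category triple in survey data for sex={sex!r}")
    counts = props * ns[:, None] if weighted else props
    return years, group_idx, counts, age_groups


def _nll_grad_hess(theta, X, counts):
    """Multinomial-logit negative log-likelihood with analytic derivatives.

    theta is the stacked (2p,) coefficient vector [beta_ow, beta_ob];
    X is the (n, p) design; counts the (n, 3) category weights.
    """
    n, p = X.shape
    beta = theta.reshape(2, p)
    probs = _softmax3(X @ beta.T)
    N = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(probs), 0.0).sum()
    # gradient wrt eta_k per cell: N*p_k - c_k for non-reference categories
    resid = N[:, None] * probs[:, 1:] - counts[:, 1:]  # (n, 2)
    grad = np.concatenate([X.T @ resid[:, 0], X.T @ resid[:, 1]])
    # Hessian blocks: sum_i N_i (p_j delta_jk - p_j p_k) x_i x_i^T
    H = np.empty((2 * p, 2 * p))
    for j in range(2):
        for k in range(2):
            pj, pk = probs[:, 1 + j], probs[:, 1 + k]
            w = N * (pj * (j == k) - pj * pk)
            H[j * p:(j + 1) * p, k * p:(k + 1) * p] = X.T @ (X * w[:, None])
    return -ll, grad, H


def fit_category_trends(obs: pd.DataFrame, sex: str, *, weighted: bool = True,
                        age_year_interaction: bool = False) -> CategoryTrendModel:
    """Fit the multinomial-logit year trend for one sex.

    Maximises the multinomial log-likelihood of observed counts
    (proportion x n) under logit-linear year + age-group structure.  With
    `age_year_interaction` the year slope varies by age group (extra
    columns); off by default for identifiability on sparse series.
    """
    years_all = obs.loc[obs["sex"] == sex, "year"]
    if years_all.nunique() < 2:
        raise ValueError(f"sex={sex!r}: need >= 2 distinct survey years")
    years, group_idx, counts, age_groups = _cells_from_survey(obs, sex, weighted)
    for k, cat in enumerate(CATEGORIES):
        if counts[:, k].sum() <= 0:
            raise ValueError(f"separation: category {cat!r} absent in all cells for sex={sex!r}")

    year0 = float(np.mean(np.unique(years)))
    G = len(age_groups)
    X = np.zeros((len(years), 2 + (G - 1) + (G - 1 if age_year_interaction else 0)))
    X[:, 0] = 1.0
    X[:, 1] = years - year0
    names = ["intercept", "year"]
    for g in range(1, G):
        X[:, 1 + g] = group_idx == g
        names.append(f"age[{age_groups[g][0]}-{age_groups[g][1]}]")
    if age_year_interaction:
        for g in range(1, G):
            X[:, 1 + (G - 1) + g] = (group_idx == g) * (years - year0)
            names.append(f"year:age[{age_groups[g][0]}-{age_groups[g][1]}]")

    p = X.shape[1]
    res = optimize.minimize(
        lambda th: _nll_grad_hess(th, X, counts)[0],
        x0=np.zeros(2 * p),
        jac=lambda th: _nll_grad_hess(th, X, counts)[1],
        hess=lambda th: _nll_grad_hess(th, X, counts)[2],
        method="trust-ncg",
        options=dict(gtol=1e-8, maxiter=500),
    )
    nll, _, H = _nll_grad_hess(res.x, X, counts)
    cov = np.linalg.pinv(H)
    beta = res.x.reshape(2, p)
    # saturated deviance: counts at their own proportions
    N = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(counts > 0, counts * np.log(counts / N[:, None]), 0.0).sum()
    model = CategoryTrendModel(
        sex=sex, beta=beta, cov=cov, year0=year0, age_groups=age_groups,
        param_names=tuple(names), loglik=-nll, deviance=2 * (sat + nll),
        n_obs=len(years), weighted=weighted,
        year_min=float(years.min()), year_max=float(years.max()),
    )
    logger.info("fit %s: %d cells, deviance %.2f, obese slope %.4f/yr",
                sex, len(years), model.deviance, model.slope("obese"))
    return model


def loglik_at(model: CategoryTrendModel, obs: pd.DataFrame, beta: np.ndarray | None = None) -> float:
    """Log-likelihood of the model's data at `beta` (default: the fit)."""
    years, group_idx, counts, _ = _cells_from_survey(obs, model.sex, model.weighted)
    X = model._design(years, group_idx)
    b = model.beta if beta is None else beta
    nll, _, _ = _nll_grad_hess(b.ravel(), X, counts)
    return -nll


# ---------------------------------------------------------------------------
# outlier filter
# ---------------------------------------------------------------------------

def filter_outliers(obs: pd.DataFrame, *, z: float = 1.959964, weighted: bool = True
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove survey observations outside 95% prediction limits.

    A preliminary trend is fitted per sex; each observation's prediction
    variance combines the fit's coefficient uncertainty (delta method) with
    the cell's binomial sampling variance given its n.  Observations whose
    standardised residual exceeds `z` are removed; the filter is applied
    once (a single filter-refit pass — iterating can empty sparse strata).
    Returns (kept, removed) with kept ∪ removed == obs.
    """
    for sex in obs["sex"].unique():
        if obs.loc[obs["sex"] == sex, "year"].nunique() < 3:
            raise ValueError(f"sex={sex!r}: need >= 3 survey years to identify outliers")

    removed_masks = []
    for sex in obs["sex"].unique():
        model = fit_category_trends(obs, sex, weighted=weighted)
        sub = obs[obs["sex"] == sex]
        gi = age_group_index(model.age_groups, sub["age_lo"].to_numpy())
        X = model._design(sub["year"].to_numpy(float), gi)
        probs = _softmax3(X @ model.beta.T)
        cat_idx = sub["category"].map({c: i for i, c in enumerate(CATEGORIES)}).to_numpy()
        phat = probs[np.arange(len(sub)), cat_idx]
        # delta-method fit variance: grad of p_c wrt stacked coefficients
        p = model.beta.shape[1]
        var_fit = np.empty(len(sub))
        for i in range(len(sub)):
            c = cat_idx[i]
            g = np.concatenate([
                probs[i, c] * ((c == 1) - probs[i, 1]) * X[i],
                probs[i, c] * ((c == 2) - probs[i, 2]) * X[i],
            ])
            var_fit[i] = g @ model.cov @ g
        var_samp = phat * (1 - phat) / sub["n"].to_numpy(float)
        zscore = (sub["proportion"].to_numpy(float) - phat) / np.sqrt(var_fit + var_samp)
        removed_masks.append(pd.Series(np.abs(zscore) > z, index=sub.index))

    removed_mask = pd.concat(removed_masks).reindex(obs.index, fill_value=False)
    removed = obs[removed_mask]
    # drop whole cells containing a flagged observation so kept triples stay complete
    bad_cells = set(map(tuple, removed[["year", "sex", "age_lo"]].itertuples(index=False)))
    cell_key = list(map(tuple, obs[["year", "sex", "age_lo"]].itertuples(index=False)))
    kept = obs[[k not in bad_cells for k in cell_key]]
    removed = obs[[k in bad_cells for k in cell_key]]
    logger.info("outlier filter: flagged %d of %d observations (%d cells removed)",
                int(removed_mask.sum()), len(obs), len(bad_cells))
    for sex in obs["sex"].unique():
        sk = kept[kept["sex"] == sex]
        if sk.empty or sk["year"].nunique() < 2:
            raise ValueError(f"sex={sex!r}: outlier filter removed too much data (degenerate)")
        fit_category_trends(kept, sex, weighted=weighted)  # refit must be well posed
    return kept, removed


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project_distribution(model: CategoryTrendModel, years, age_groups=None
                         ) -> ProjectedDistribution:
    """Evaluate the fitted model at each (year, age group) for its sex."""
    age_groups = tuple(age_groups) if age_groups is not None else model.age_groups
    rows = []
    for year in years:
        gi = np.arange(len(age_groups))
        probs = model.predict(np.full(len(age_groups), year), gi)
        for g, (lo, hi) in enumerate(age_groups):
            rows.append(dict(year=int(year), sex=model.sex, age_lo=lo, age_hi=hi,
                             p_normal=probs[g, 0], p_overweight=probs[g, 1],
                             p_obese=probs[g, 2]))
    backcast = tuple(int(y) for y in years if y < model.year_min)
    if backcast:
        logger.info("projection for %s includes backcast years %s", model.sex, backcast)
    return ProjectedDistribution(pd.DataFrame(rows), backcast_years=backcast)


def merge_distributions(*dists: ProjectedDistribution) -> ProjectedDistribution:
    """Concatenate per-sex projections into a single distribution."""
    table = pd.concat([d.table for d in dists], ignore_index=True)
    back = tuple(sorted({y for d in dists for y in d.backcast_years}))
    return ProjectedDistribution(table, backcast_years=back)


def projection_confidence_limits(model: CategoryTrendModel, years, age_groups=None,
                                 n_boot: int = 1000, seed: int = 0) -> ProjectedDistribution:
    """Parametric-bootstrap 95% bands around the projected proportions.

    Coefficient vectors are drawn from N(beta_hat, cov); each draw is
    re-projected and per-cell 2.5/97.5 percentiles taken.  Bands therefore
    widen with distance from the data centroid.
    """
    if n_boot < 200:
        logger.warning("n_boot=%d < 200: bootstrap bands will be noisy", n_boot)
    age_groups = tuple(age_groups) if age_groups is not None else model.age_groups
    rng = np.random.default_rng(seed)
    p = model.beta.shape[1]
    draws = rng.multivariate_normal(model.beta.ravel(), model.cov, size=n_boot,
                                    method="svd")
    point = project_distribution(model, years, age_groups)
    years_v = point.table["year"].to_numpy(float)
    gi = age_group_index(age_groups, point.table["age_lo"].to_numpy())
    X = model._design(years_v, gi)
    boot = np.empty((n_boot, len(years_v), 3))
    for b in range(n_boot):
        beta_b = draws[b].reshape(2, p)
        boot[b] = _softmax3(X @ beta_b.T)
    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)
    table = point.table.copy()
    for k, cat in enumerate(CATEGORIES):
        table[f"p_{cat}_lo"] = np.minimum(lo[:, k], table[f"p_{cat}"])
        table[f"p_{cat}_hi"] = np.maximum(hi[:, k], table[f"p_{cat}"])
    return ProjectedDistribution(table, backcast_years=point.backcast_years)
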