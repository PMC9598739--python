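"""Discrete-time hazard regression and permutation inference.

Survival is analysed on the person-period expansion: one row per individual
per day at risk, with a binary event indicator that is 1 only on the death
day.  A binomial GLM with a complementary log-log link on these rows is the
grouped-data analogue of a proportional-hazards model and needs no
constant-hazard assumption within intervals.

Enclosure ("box") effects are screened with a likelihood-ratio test between
the fixed-effects hazard model and the same model augmented with box
indicator variables - a fixed-effects stand-in for a random intercept, which
is adequate as a screen (and the screen, not a mixed model, is what this
package provides).

Skewed responses (total reproduction output; jackknife pseudo-values of r)
are tested with null-model permutation tests: the observed statistic is the
likelihood-ratio chi-square between the full linear model and the model
without the term of interest, and its reference distribution is rebuilt by
permuting the residuals of the null fit and adding them back to the null
fitted values (Freedman-Lane scheme).  The reported p-value uses the add-one
estimator (1 + #exceedances) / (1 + B), so it is never exactly zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulate import IndividualRecord

__all__ = [
    "build_design",
    "expand_person_period",
    "HazardFit",
    "fit_cloglog_hazard",
    "lrt_random_screen",
    "PermutationTestResult",
    "permutation_test_fixed_effect",
    "permutation_two_sample",
    "fit_trait_model",
]

HAZARD_TERMS = ("ca", "food", "temp", "interval", "ca:food")


def build_design(data: pd.DataFrame, terms: Sequence[str],
                 add_intercept: bool = True) -> pd.DataFrame:
    """Design matrix from continuous-predictor term strings.

    Each term is a column name or a ':'-joined product of column names
    (e.g. ``"ca:food"``).  All predictors are treated as continuous, matching
    the analysis design; transformations (log Ca etc.) are extra columns
    supplied by the caller.
    """
    cols = {}
    if add_intercept:
        cols["intercept"] = np.ones(len(data))
    for term in terms:
        parts = term.split(":")
        col = np.ones(len(data))
        for p in parts:
            if p not in data.columns:
                raise KeyError(f"term {term!r}: column {p!r} not in data")
            col = col * data[p].to_numpy(dtype=float)
        cols[term] = col
    return pd.DataFrame(cols, index=data.index)


def expand_person_period(records: Sequence[IndividualRecord],
                         horizon: int) -> pd.DataFrame:
    """One row per individual per day at risk.

    The event indicator is 1 on the death day and 0 elsewhere; a censored
    individual contributes ``horizon`` all-zero rows.  Total rows equal the
    total animal-days at risk, sum_i min(death_day_i, horizon).
    """
    ids, cas, foods, temps, boxes, intervals, events = [], [], [], [], [], [], []
    for r in records:
        if r.death_day > horizon:
            raise ValueError(
                f"{r.individual_id}: death_day {r.death_day} > horizon {horizon}")
        n_days = r.death_day if not r.censored else horizon
        for t in range(1, n_days + 1):
            ids.append(r.individual_id)
            cas.append(r.treatment.ca)
            foods.append(r.treatment.food)
            temps.append(r.treatment.temp)
            boxes.append(r.treatment.box_id)
            intervals.append(t)
            events.append(1 if (not r.censored and t == r.death_day) else 0)
    return pd.DataFrame({
        "individual_id": ids, "ca": cas, "food": foods, "temp": temps,
        "box_id": boxes, "interval": intervals, "event": events,
    })


@dataclass(frozen=True)
class HazardFit:
    """Fitted discrete-time cloglog hazard model."""

    terms: tuple[str, ...]          # including "intercept"
    params: pd.Series
    bse: pd.Series
    wald_z: pd.Series
    p_values: pd.Series
    loglik: float
    n_rows: int
    n_events: int
    link: str = "cloglog"
    separation_flag: bool = False

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.params, "se": self.bse,
            "wald_z": self.wald_z, "p": self.p_values,
        })


def fit_cloglog_hazard(table: pd.DataFrame,
                       terms: Sequence[str] = HAZARD_TERMS,
                       extra_columns: Optional[pd.DataFrame] = None
                       ) -> HazardFit:
    """Fit the binomial cloglog GLM for P(death in interval t | alive at t).

    ``terms`` follow :func:`build_design`; callers drop non-significant
    interactions and refit as they see fit.  Quasi-complete separation is
    flagged (huge coefficients / standard errors), not raised: estimates are
    still reported with a warning.
    """
    if table["event"].sum() < 1:
        raise ValueError("no death events in the person-period table")
    X = build_design(table, terms)
    if extra_columns is not None:
        X = pd.concat([X, extra_columns], axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient for terms "
                         f"{tuple(terms)}")
    model = sm.GLM(table["event"].to_numpy(), X,
                   family=sm.families.Binomial(
                       link=sm.families.links.CLogLog()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200)
    separation = bool(np.any(np.abs(res.params) > 50)
                      or np.any(res.bse > 100))
    if separation:
        warnings.warn("possible separation in the hazard fit: some "
                      "coefficients or SEs are extreme", stacklevel=2)
    return HazardFit(
        terms=tuple(X.columns),
        params=res.params,
        bse=res.bse,
        wald_z=res.params / res.bse,
        p_values=pd.Series(res.pvalues, index=res.params.index),
        loglik=float(res.llf),
        n_rows=len(table),
        n_events=int(table["event"].sum()),
        separation_flag=separation,
    )


def lrt_random_screen(table: pd.DataFrame,
                      terms: Sequence[str] = HAZARD_TERMS,
                      grouping: str = "box_id") -> tuple[float, float, int]:
    """Likelihood-ratio screen for an enclosure effect on the hazard.

    Compares the fixed-effects hazard model with the same model augmented
    with group indicator columns (reference level dropped).  Returns
    (chi-square statistic, p-value, df = #groups - 1).
    """
    groups = sorted(table[grouping].astype(str).unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups to screen a group effect")
    base = fit_cloglog_hazard(table, terms)
    dummies = pd.get_dummies(table[grouping].astype(str), prefix=grouping,
                             dtype=float).iloc[:, 1:]
    dummies.index = table.index
    full = fit_cloglog_hazard(table, terms, extra_columns=dummies)
    stat = max(0.0, 2.0 * (full.loglik - base.loglik))
    df = len(groups) - 1
    from scipy import stats as sps
    return stat, float(sps.chi2.sf(stat, df)), df


@dataclass(frozen=True)
class PermutationTestResult:
    """Null-model permutation test for one model term."""

    term: str
    statistic: float        # observed LRT chi-square
    n_permutations: int
    p_perm: float           # (1 + #{stat_b >= stat_obs}) / (1 + B)
    seed: int

    def __post_init__(self) -> None:
        assert 1.0 / (self.n_permutations + 1) <= self.p_perm <= 1.0


def _rss(y: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Residual sums of squares of columns of y on orthonormal basis q."""
    proj = q.T @ y
    return np.einsum("ij,ij->j", y, y) - np.einsum("ij,ij->j", proj, proj)


def permutation_test_fixed_effect(
        data: pd.DataFrame,
        response: str,
        full_terms: Sequence[str],
        term: str,
        n_permutations: int = 3000,
        seed: int = 0) -> PermutationTestResult:
    """Freedman-Lane permutation test of one term in a linear model.

    The observed statistic is the Gaussian LRT chi-square
    ``n * ln(RSS_null / RSS_full)`` between the model with all
    ``full_terms`` and the model with ``term`` removed.  Residuals of the
    null fit are permuted, added back to the null fitted values, and both
    models are refit on each synthetic response.
    """
    if term not in full_terms:
        raise ValueError(f"term {term!r} not among the full-model terms")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    null_terms = [t for t in full_terms if t != term]

    y = data[response].to_numpy(dtype=float)
    n = y.size
    X_full = build_design(data, full_terms).to_numpy()
    X_null = build_design(data, null_terms).to_numpy()
    if np.linalg.matrix_rank(X_full) <= np.linalg.matrix_rank(X_null):
        raise ValueError(
            f"term {term!r} is aliased with the remaining design columns")

    q_full, _ = np.linalg.qr(X_full)
    q_null, _ = np.linalg.qr(X_null)

    rss_full, rss_null = _rss(y[:, None], q_full)[0], _rss(y[:, None], q_null)[0]
    stat_obs = n * math.log(rss_null / rss_full) if rss_full > 0 else math.inf

    fitted_null = q_null @ (q_null.T @ y)
    resid_null = y - fitted_null
    rng = np.random.default_rng(seed)
    perm = np.empty((n, n_permutations))
    for b in range(n_permutations):
        perm[:, b] = resid_null[rng.permutation(n)]
    y_star = fitted_null[:, None] + perm
    rss_f = _rss(y_star, q_full)
    rss_0 = _rss(y_star, q_null)
    with np.errstate(divide="ignore", invalid="ignore"):
        stats_b = n * np.log(rss_0 / rss_f)
    stats_b = np.where(np.isfinite(stats_b), stats_b, np.inf)
    exceed = int(np.sum(stats_b >= stat_obs - 1e-12))
    p = (1 + exceed) / (1 + n_permutations)
    return PermutationTestResult(term=term, statistic=float(stat_obs),
                                 n_permutations=n_permutations,
                                 p_perm=float(p), seed=seed)


def permutation_two_sample(x: Sequence[float], y: Sequence[float],
                           n_permutations: int = 3000,
                           seed: int = 0) -> float:
    """Two-sided permutation test for a difference in means (add-one p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n_x = x.size
    obs = abs(x.mean() - y.mean())
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        rng.shuffle(pooled)
        d = abs(pooled[:n_x].mean() - pooled[n_x:].mean())
        if d >= obs - 1e-12:
            exceed += 1
    return (1 + exceed) / (1 + n_permutations)


def fit_trait_model(data: pd.DataFrame, response: str,
                    terms: Sequence[str]) -> pd.DataFrame:
    """Ordinary least-squares fit of a trait on continuous predictors.

    Returns a per-term frame (estimate, SE, Wald z, p).  Rows with a missing
    response are dropped (e.g. traits defined only for mature females).
    """
    sub = data.dropna(subset=[response])
    X = build_design(sub, terms)
    res = sm.OLS(sub[response].to_numpy(dtype=float), X).fit()
    return pd.DataFrame({
        "estimate": res.params, "se": res.bse,
        "wald_z": res.params / res.bse, "p": res.pvalues,
    })
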