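"""Cohort-level regression of mean paternity distance on population covariates.

The cohort mean paternity distance ``PD_c`` is estimated with a full MCMC
posterior per cohort.  To propagate that uncertainty, the regression (on
mean-centred population size, population sex ratio and year) is refitted by
ordinary least squares to every posterior draw index, giving a distribution
over partial regression coefficients; 95% credible intervals are the
2.5/97.5 percentiles, and an effect is flagged significant when its interval
excludes zero.  Because the intercept is fitted on centred covariates it is
interpretable as predicted PD_c at mean population size, sex ratio and year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

PREDICTORS = ["population_size", "population_sex_ratio", "year"]


class RegressionError(ValueError):
    pass


def prepare_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Validate and mean-centre the cohort covariate table.

    Requires columns cohort_year, population_size, population_sex_ratio.
    Adds `year` (= cohort_year) plus `<name>_c` centred columns.
    """
    need = {"cohort_year", "population_size", "population_sex_ratio"}
    missing = need - set(covariates.columns)
    if missing:
        raise RegressionError(f"covariate table lacks columns {sorted(missing)}")
    cov = covariates.copy()
    if cov["cohort_year"].duplicated().any():
        raise RegressionError("duplicate cohort_year rows in covariates")
    sr = cov["population_sex_ratio"]
    if ((sr < 0) | (sr > 1)).any():
        raise RegressionError("population_sex_ratio must lie in [0, 1]")
    cov["year"] = cov["cohort_year"].astype(float)
    for c in PREDICTORS:
        cov[f"{c}_c"] = cov[c] - cov[c].mean()
    return cov


@dataclass
class RegressionPosterior:
    """Posterior draws and summaries of the cohort-level regression."""

    coef_draws: pd.DataFrame  # one row per posterior draw; intercept + predictors
    summary: pd.DataFrame  # estimate, ci2.5, ci97.5, significant per term
    n_cohorts: int

    @property
    def n_draws(self) -> int:
        return len(self.coef_draws)


def fit_posterior_regression(
    pdc_posteriors: Mapping[int, np.ndarray],
    covariates: pd.DataFrame,
    shuffle_pairing: bool = False,
    seed: int = 0,
) -> RegressionPosterior:
    """OLS of PD_c on centred covariates, applied draw-by-draw.

    ``pdc_posteriors`` maps cohort year to its vector of PD_c draws; all
    vectors must have equal length.  Cohorts present in the covariate table
    but lacking a posterior (e.g. run without the distance predictor) are
    simply excluded.  ``shuffle_pairing`` independently permutes each
    cohort's draws before pairing across cohorts (cohort chains are
    independent, so any pairing is valid; this is a sensitivity probe).
    """
    cov = prepare_covariates(covariates)
    years = [int(y) for y in cov["cohort_year"] if int(y) in pdc_posteriors]
    if len(years) < 4:
        raise RegressionError(f"need >= 4 cohorts with PD_c posteriors, have {len(years)}")
    lengths = {len(np.asarray(pdc_posteriors[y])) for y in years}
    if len(lengths) != 1:
        raise RegressionError(f"unequal PD_c draw counts across cohorts: {sorted(lengths)}")
    cov = cov[cov["cohort_year"].isin(years)].reset_index(drop=True)
    # re-centre on the retained cohorts
    for c in PREDICTORS:
        cov[f"{c}_c"] = cov[c] - cov[c].mean()

    Y = np.stack([np.asarray(pdc_posteriors[int(y)], dtype=float) for y in cov["cohort_year"]])
    if shuffle_pairing:
        rng = np.random.default_rng(seed)
        Y = np.stack([rng.permutation(row) for row in Y])

    X = np.column_stack(
        [np.ones(len(cov))] + [cov[f"{c}_c"].to_numpy() for c in PREDICTORS]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RegressionError("collinear covariates: design matrix is rank-deficient")
    coefs, *_ = np.linalg.lstsq(X, Y, rcond=None)  # (4, n_draws)
    names = ["intercept"] + PREDICTORS
    draws = pd.DataFrame(coefs.T, columns=names)
    lo, hi = np.percentile(coefs, [2.5, 97.5], axis=1)
    summary = pd.DataFrame(
        {
            "term": names,
            "estimate": coefs.mean(axis=1),
            "ci_lower": lo,
            "ci_upper": hi,
        }
    )
    summary["significant"] = (summary["ci_lower"] > 0) | (summary["ci_upper"] < 0)
    return RegressionPosterior(coef_draws=draws, summary=summary, n_cohorts=len(cov))
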