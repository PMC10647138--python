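"""External validation of proposed static cut-offs.

On an independent test cohort a fixed cut-off is judged two ways:

* as a dichotomising classifier (sensitivity/specificity/AUC, exactly as in
  the derivation grid), and
* through covariate-adjusted odds ratios: a maximum-likelihood logistic
  regression of the clustering outcome on the WHtR exposure indicator,
  adjusted for sex and age (continuous completed years), plus survey year
  when cohorts are pooled.  The unexposed group (WHtR below the cut-off)
  is the reference; OR = exp(beta_exposure) with a Wald 95% CI
  exp(beta +/- 1.96 * SE).

Fitting is IRLS (via statsmodels GLM with a binomial family), convergence
tolerance 1e-8, at most 25 iterations.  Complete separation and rank
deficiency raise diagnostics rather than returning unstable estimates.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort, MALE
from .criteria import Criteria
from .cutoffs import CutoffEvaluation, confusion_at, evaluate_cutoff, outcome_mask
from .errors import DegenerateOutcomeError, RankDeficientError, SeparationError, WhtrError
from .references import BPReferenceTable

MAX_ITER = 25
TOL = 1e-8
#: |coefficient| beyond this on a binary exposure signals (quasi-)separation.
_SEPARATION_COEF = 15.0


@dataclasses.dataclass(frozen=True)
class ORResult:
    """Adjusted odds ratio for the exposure term of a logistic model."""

    odds_ratio: float
    ci: tuple[float, float]
    coefficients: pd.DataFrame  # term, estimate, se
    n: int
    converged: bool
    adjustment_terms: tuple[str, ...]


def dichotomize(cohort: Cohort, cutoff: float) -> np.ndarray:
    """Exposure indicator per record: WHtR >= cutoff (boundary exposed)."""
    if not (0.0 < cutoff < 1.0):
        raise WhtrError(f"cutoff must lie in (0, 1); got {cutoff}")
    return cohort.df["whtr"].to_numpy(dtype=float) >= cutoff


def fit_logistic(
    outcome: np.ndarray,
    exposure: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> ORResult:
    """Logistic regression of a binary outcome on a binary exposure.

    ``covariates`` columns enter additively; the returned OR is for the
    exposure with the unexposed group as reference.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if y.shape != x.shape:
        raise WhtrError("outcome and exposure must have the same length")
    if y.sum() == 0 or y.sum() == y.size:
        raise DegenerateOutcomeError("outcome has no positives or no negatives")
    if x.min() == x.max():
        raise DegenerateOutcomeError("exposure is constant; OR undefined")

    names = ["intercept", "exposure"]
    cols = [np.ones_like(y), x]
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name].to_numpy(dtype=float)
            if np.ptp(col) == 0:
                raise RankDeficientError(f"covariate {name!r} is constant")
            cols.append(col)
            names.append(str(name))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientError(f"design matrix rank deficient; columns: {names}")

    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        # separation is detected below and raised as SeparationError
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=MAX_ITER, tol=TOL)
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(bse)) or abs(params[1]) > _SEPARATION_COEF:
        raise SeparationError(
            "logistic fit unstable (infinite SE or runaway exposure coefficient); "
            "data are likely completely separated"
        )
    beta, se = params[1], bse[1]
    coef = pd.DataFrame({"term": names, "estimate": params, "se": bse})
    return ORResult(
        odds_ratio=float(np.exp(beta)),
        ci=(float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
        coefficients=coef,
        n=int(y.size),
        converged=bool(getattr(res, "converged", True)),
        adjustment_terms=tuple(names[2:]),
    )


def _default_covariates(cohort: Cohort, extra: pd.DataFrame | None) -> pd.DataFrame:
    cov = pd.DataFrame(
        {
            "male": (cohort.df["sex"] == MALE).astype(float),
            "age_years": cohort.df["age_years"].astype(float),
        }
    )
    if extra is not None:
        cov = pd.concat([cov, extra.reset_index(drop=True)], axis=1)
    return cov


def validate_proposed(
    test_cohort: Cohort,
    cutoff: float,
    criteria: Criteria,
    k: int = 2,
    bp_ref: BPReferenceTable | None = None,
    extra_covariates: pd.DataFrame | None = None,
) -> tuple[CutoffEvaluation, ORResult]:
    """Classifier metrics and sex/age-adjusted OR for one proposed cut-off.

    The test cohort must be independent of the derivation cohorts; that is
    the caller's responsibility and should be flagged in cohort metadata.
    """
    exposure = dichotomize(test_cohort, cutoff)
    y = outcome_mask(test_cohort, criteria, k, bp_ref)
    counts = confusion_at(test_cohort, exposure, y)
    evaluation = evaluate_cutoff(counts, cutoff=cutoff, kind="static", criteria=criteria, k=k)
    orres = fit_logistic(y, exposure, _default_covariates(test_cohort, extra_covariates))
    return evaluation, orres
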