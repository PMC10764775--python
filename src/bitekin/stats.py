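"""Behavioural and kinematic statistics.

Four analyses back the pipeline's inferential layer:

* a binomial GLM (logistic regression, fitted here by iteratively
  reweighted least squares) of event presence on algal length, with the
  odds = 0.5 crossing ``x* = -beta0 / beta1`` — the algal length at
  which the fitted probability of the behaviour equals one half;
* Gaussian GLM (ordinary least squares) regressions, shared with the
  lever model's agreement tests;
* a two-group mean comparison allowing unequal variances (Welch
  statistic with Satterthwaite degrees of freedom, the inference
  equivalent of a two-variance GLS fit for a two-level factor),
  accompanied by a Brown-Forsythe (median-centred Levene) test of
  homogeneity of variance;
* mean +/- standard error summaries (sd / sqrt(n)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import SeparationError, StatsError
from .lever import RegressionSummary, fit_model_agreement

# IRLS controls: convergence on relative deviance change, with a
# separation guard on the standardized-predictor coefficient scale.
IRLS_TOL = 1e-8
IRLS_MAXITER = 25
SEPARATION_BETA = 50.0


@dataclass(frozen=True)
class BehaviorObservation:
    """One bite's algal length and binary behaviour outcome."""

    algal_length_mm: float
    present: int
    bite_id: str = ""
    event: str = "ventral_expansion"

    def __post_init__(self) -> None:
        if self.algal_length_mm <= 0:
            raise StatsError("algal length must be positive")
        if self.present not in (0, 1):
            raise StatsError("presence must be 0 or 1")


@dataclass
class LogisticFit:
    """Binomial-GLM fit of presence on a single predictor."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    z_intercept: float
    z_slope: float
    p_intercept: float
    p_slope: float
    converged: bool
    n_iter: int
    n: int

    @property
    def crossing(self) -> float:
        """Predictor value where the fitted probability equals 0.5."""
        return odds_crossing(self)


def _as_xy(observations) -> Tuple[np.ndarray, np.ndarray]:
    if len(observations) and isinstance(observations[0], BehaviorObservation):
        x = np.array([o.algal_length_mm for o in observations], float)
        y = np.array([o.present for o in observations], float)
    else:
        arr = np.asarray(observations, float)
        x, y = arr[:, 0], arr[:, 1]
    return x, y


def fit_logistic(observations, min_n: int = 10) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS.

    ``observations`` is a sequence of :class:`BehaviorObservation` or an
    (n, 2) array of (length, presence). Requires at least ``min_n``
    observations with both outcome classes. Raises
    :class:`SeparationError` when the fit diverges (complete or
    quasi-complete separation).
    """
    x, y = _as_xy(observations)
    if len(x) < min_n:
        raise StatsError(f"need at least {min_n} observations, got {len(x)}")
    if len(np.unique(y)) < 2:
        raise SeparationError("single-class response: all outcomes identical")

    # standardize the predictor for the fit; back-transform at the end
    mu_x, sd_x = float(np.mean(x)), float(np.std(x))
    if sd_x == 0:
        raise StatsError("zero variance in predictor")
    xs = (x - mu_x) / sd_x
    X = np.column_stack([np.ones_like(xs), xs])

    beta = np.zeros(2)
    dev_old = np.inf
    converged = False
    it = 0
    for it in range(1, IRLS_MAXITER + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        if np.max(np.abs(beta)) > SEPARATION_BETA:
            raise SeparationError(
                "logistic fit diverged: complete or quasi-complete separation"
            )
        dev = -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        if np.isfinite(dev_old) and abs(dev_old - dev) <= IRLS_TOL * (abs(dev) + 0.1):
            converged = True
            break
        dev_old = dev

    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-10, 1 - 1e-10)
    w = mu * (1.0 - mu)
    cov_s = np.linalg.inv(X.T @ (X * w[:, None]))

    # back-transform to the original predictor scale
    b1 = beta[1] / sd_x
    b0 = beta[0] - beta[1] * mu_x / sd_x
    grad0 = np.array([1.0, -mu_x / sd_x])
    grad1 = np.array([0.0, 1.0 / sd_x])
    se0 = float(np.sqrt(grad0 @ cov_s @ grad0))
    se1 = float(np.sqrt(grad1 @ cov_s @ grad1))

    z0, z1 = b0 / se0, b1 / se1
    return LogisticFit(
        intercept=float(b0),
        slope=float(b1),
        se_intercept=se0,
        se_slope=se1,
        z_intercept=float(z0),
        z_slope=float(z1),
        p_intercept=float(2 * sps.norm.sf(abs(z0))),
        p_slope=float(2 * sps.norm.sf(abs(z1))),
        converged=converged,
        n_iter=it,
        n=len(x),
    )


def odds_crossing(fit: LogisticFit) -> float:
    """Algal length at which the fitted probability equals 0.5."""
    if not fit.converged:
        raise StatsError("crossing undefined for a non-converged fit")
    if fit.slope == 0:
        raise StatsError("crossing undefined: slope is zero")
    return -fit.intercept / fit.slope


def gaussian_regression(x: Sequence[float], y: Sequence[float]) -> RegressionSummary:
    """Gaussian-GLM (OLS) regression of y on x; shared with the lever
    model's agreement test."""
    return fit_model_agreement(x, y)


@dataclass
class TwoGroupComparison:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    levene_w: float
    levene_p: float


def heteroscedastic_compare(
    group_a: Sequence[float], group_b: Sequence[float]
) -> TwoGroupComparison:
    """Two-group mean comparison with group-specific variances.

    Welch's t statistic with Satterthwaite degrees of freedom (the
    two-sample analogue of a GLS fit in which each factor level carries
    its own variance), plus a Brown-Forsythe (median-centred Levene)
    test of variance homogeneity. Each group needs n >= 3.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 3 or len(b) < 3:
        raise StatsError("each group needs at least 3 values")
    va, vb = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    if va == 0 and vb == 0 and np.mean(a) == np.mean(b):
        raise StatsError("t undefined: both groups constant and equal")
    res = sps.ttest_ind(a, b, equal_var=False)
    lev_w, lev_p = sps.levene(a, b, center="median")
    return TwoGroupComparison(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        var_a=va,
        var_b=vb,
        levene_w=float(lev_w),
        levene_p=float(lev_p),
    )


def mean_se(values: Sequence[float]) -> Tuple[float, float]:
    """Arithmetic mean and standard error (sd / sqrt(n)); needs n >= 2."""
    v = np.asarray(values, float)
    if len(v) < 2:
        raise StatsError("mean_se needs at least 2 values")
    return float(np.mean(v)), float(np.std(v, ddof=1) / np.sqrt(len(v)))
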