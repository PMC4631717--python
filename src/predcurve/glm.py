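"""Univariate logistic model of compound activity given the screening score.

The activity probability is modelled as

    logit P(A = 1 | Y = y) = beta0 + beta1 * y

fit by maximum likelihood with iteratively reweighted least squares
(IRLS).  Scoring functions that split actives from decoys perfectly make
the MLE diverge (complete or quasi-complete separation); that case is
detected and reported with capped coefficients instead of failing, since
the corresponding predictiveness curve -- a step function -- is still
perfectly well defined.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from predcurve.dataset import ScreeningDataset

logger = logging.getLogger(__name__)

MAX_ITER = 100
DEVIANCE_TOL = 1e-8
PROB_CLIP = 1e-10
# |linear predictor| beyond which the fit is declared separated; expit(30)
# is within 1e-13 of 1, so pushing further only inflates coefficients
ETA_CAP = 30.0


@dataclass(frozen=True)
class LogisticModel:
    """Fitted intercept/slope of the activity-given-score logistic model.

    ``separation_flag`` marks complete or quasi-complete separation: the
    reported coefficients are then capped at the iteration where the
    linear predictor saturated, not a finite MLE.
    """

    intercept: float
    slope: float
    converged: bool
    separation_flag: bool
    n_iterations: int
    deviance: float

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "converged": self.converged,
            "separation_flag": self.separation_flag,
            "n_iterations": self.n_iterations,
            "deviance": self.deviance,
        }


def _expit(eta: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, PROB_CLIP, 1.0 - PROB_CLIP)
    return float(-2.0 * np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))


def fit_logistic(dataset: ScreeningDataset) -> LogisticModel:
    """Fit logit P(A=1|Y=y) = beta0 + beta1*y by IRLS.

    Convergence is declared when the deviance changes by less than 1e-8
    between iterations (at most 100 iterations).  At a converged,
    non-separated fit the mean fitted probability equals the sample
    prevalence exactly, up to tolerance -- the intercept score equation of
    the MLE -- which makes the predictiveness curve average to p.

    Returns
    -------
    LogisticModel
        With ``separation_flag`` set (and coefficients capped) when the
        score separates actives from inactives.
    """
    y = dataset.labels.astype(float)
    x = dataset.scores
    n = dataset.n
    p = dataset.prevalence

    # centring the score improves IRLS conditioning without changing the fit
    x_mean = x.mean()
    xc = x - x_mean

    if np.ptp(x) == 0.0:
        # no score information: slope 0, intercept = logit(prevalence)
        mu = np.full(n, p)
        return LogisticModel(
            intercept=float(np.log(p / (1.0 - p))),
            slope=0.0,
            converged=True,
            separation_flag=False,
            n_iterations=0,
            deviance=_deviance(y, mu),
        )

    beta = np.array([np.log(p / (1.0 - p)), 0.0])
    X = np.column_stack([np.ones(n), xc])
    dev = _deviance(y, _expit(X @ beta))
    converged = False
    separated = False
    grow_streak = 0
    it = 0

    for it in range(1, MAX_ITER + 1):
        eta = X @ beta
        mu = _expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        dev_new = _deviance(y, _expit(X @ beta_new))

        if np.max(np.abs(X @ beta_new)) > ETA_CAP:
            separated = True
            # cap: rescale the step so the largest linear predictor sits at the cap
            scale = ETA_CAP / np.max(np.abs(X @ beta_new))
            beta = beta_new * scale
            dev = _deviance(y, _expit(X @ beta))
            break

        grow_streak = grow_streak + 1 if np.linalg.norm(beta_new) > 2.0 * max(np.linalg.norm(beta), 1e-12) else 0
        if grow_streak >= 5 and dev_new < DEVIANCE_TOL * n:
            separated = True
            beta = beta_new
            dev = dev_new
            break

        delta = abs(dev - dev_new)
        beta, dev = beta_new, dev_new
        if delta < DEVIANCE_TOL:
            converged = True
            break

    if separated:
        warnings.warn(
            "complete or quasi-complete separation detected; coefficients capped",
            stacklevel=2,
        )
    elif not converged:
        warnings.warn("IRLS did not converge within 100 iterations", stacklevel=2)

    # undo the centring
    intercept = float(beta[0] - beta[1] * x_mean)
    slope = float(beta[1])
    return LogisticModel(
        intercept=intercept,
        slope=slope,
        converged=converged,
        separation_flag=separated,
        n_iterations=it,
        deviance=dev,
    )


def predict_probability(model: LogisticModel, scores) -> np.ndarray:
    """Activity probabilities expit(beta0 + beta1*y), clipped to (0, 1).

    Monotone in the score, increasing when the slope is positive.
    """
    scores = np.asarray(scores, dtype=float)
    eta = model.intercept + model.slope * scores
    return np.clip(_expit(eta), PROB_CLIP, 1.0 - PROB_CLIP)


def resolve_orientation(dataset: ScreeningDataset, model: LogisticModel | None = None) -> ScreeningDataset:
    """Resolve an ``"infer"`` orientation from the fitted slope sign.

    A positive slope means higher scores predict activity.  A zero slope
    carries no direction; ``higher_is_better`` is used so downstream
    rank-based metrics remain defined.  Datasets with an explicit
    orientation are returned unchanged.
    """
    if dataset.orientation != "infer":
        return dataset
    if model is None:
        model = fit_logistic(dataset)
    orientation = "lower_is_better" if model.slope < 0 else "higher_is_better"
    logger.info("inferred score orientation: %s (slope %.4g)", orientation, model.slope)
    return dataset.with_orientation(orientation)
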