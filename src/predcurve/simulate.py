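"""Synthetic DUD-like screening benchmarks with known ground truth.

Datasets follow the composition of the Directory of Useful Decoys: a
small set of actives with a fixed number of decoys per active (36 by
default, giving prevalence 1/37).  Scores are drawn from two Gaussians
with a common standard deviation.  With equal variances the true
activity-given-score model is exactly logistic-linear,

    logit P(A=1 | Y=y) = beta0 + beta1 * y,
    beta1 = (mu_active - mu_decoy) / sigma^2,
    beta0 = logit(p) - (mu_active^2 - mu_decoy^2) / (2 sigma^2),

so the fitted model family contains the truth and recovering the total
gain tests the whole pipeline rather than model misfit.  The true TG and
the closed-form ROC AUC, Phi(|mu_active - mu_decoy| / (sigma sqrt(2))),
serve as oracles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm

from predcurve.dataset import ScreeningDataset


@dataclass(frozen=True)
class BinormalSpec:
    """Parameters of a binormal DUD-like screening dataset.

    Defaults emulate a well-separated DUD-style screen: 50 actives with
    36 decoys each (prevalence 1/37 ~ 0.027, the DUD design ratio) and a
    two-standard-deviation gap between the active and decoy score means,
    which corresponds to a ROC AUC of Phi(sqrt(2)) ~ 0.92.
    """

    n_actives: int = 50
    decoys_per_active: int = 36
    mu_active: float = 2.0
    mu_decoy: float = 0.0
    sigma: float = 1.0
    orientation: str = "higher_is_better"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_actives < 1 or self.decoys_per_active < 1:
            raise ValueError("counts must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.orientation not in ("higher_is_better", "lower_is_better"):
            raise ValueError("orientation must be higher_is_better or lower_is_better")

    @property
    def n_decoys(self) -> int:
        return self.n_actives * self.decoys_per_active

    @property
    def n(self) -> int:
        return self.n_actives + self.n_decoys

    @property
    def prevalence(self) -> float:
        return 1.0 / (1.0 + self.decoys_per_active)

    def true_coefficients(self) -> tuple[float, float]:
        """(intercept, slope) of the exact activity-given-score logistic model."""
        p = self.prevalence
        s2 = self.sigma**2
        slope = (self.mu_active - self.mu_decoy) / s2
        intercept = np.log(p / (1 - p)) - (self.mu_active**2 - self.mu_decoy**2) / (2 * s2)
        return float(intercept), float(slope)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def generate_binormal(spec: BinormalSpec) -> ScreeningDataset:
    """Draw a screening dataset from the binormal spec (reproducible by seed).

    Active scores come from Normal(mu_active, sigma), decoy scores from
    Normal(mu_decoy, sigma); under ``lower_is_better`` orientation both
    means are negated so better compounds score lower, as docking
    energies do.
    """
    rng = np.random.default_rng(spec.seed)
    sign = 1.0 if spec.orientation == "higher_is_better" else -1.0
    active_scores = rng.normal(sign * spec.mu_active, spec.sigma, spec.n_actives)
    decoy_scores = rng.normal(sign * spec.mu_decoy, spec.sigma, spec.n_decoys)
    ids = [f"ACT{i:06d}" for i in range(spec.n_actives)] + [
        f"DEC{i:06d}" for i in range(spec.n_decoys)
    ]
    return ScreeningDataset(
        compound_ids=tuple(ids),
        scores=np.concatenate([active_scores, decoy_scores]),
        labels=np.concatenate(
            [np.ones(spec.n_actives, dtype=int), np.zeros(spec.n_decoys, dtype=int)]
        ),
        orientation=spec.orientation,
    )


def _true_posterior(y: np.ndarray, spec: BinormalSpec) -> np.ndarray:
    p = spec.prevalence
    fa = norm.pdf(y, spec.mu_active, spec.sigma)
    fd = norm.pdf(y, spec.mu_decoy, spec.sigma)
    return p * fa / (p * fa + (1 - p) * fd)


def oracle_true_tg(spec: BinormalSpec) -> float:
    """Population total gain of the binormal model, by adaptive quadrature.

    TG_true = E_Y |P(A=1|Y) - p| / (2 p (1 - p)) over the two-component
    mixture density of Y, to absolute tolerance 1e-8.  0 when the means
    coincide; tends to 1 as the standardized gap grows.  Symmetric under
    negating both means (orientation does not matter).
    """
    p = spec.prevalence
    if spec.mu_active == spec.mu_decoy:
        return 0.0

    def integrand(y: float) -> float:
        fa = norm.pdf(y, spec.mu_active, spec.sigma)
        fd = norm.pdf(y, spec.mu_decoy, spec.sigma)
        mix = p * fa + (1 - p) * fd
        if mix <= 0.0:  # both densities underflowed; contribution is nil
            return 0.0
        post = p * fa / mix
        return abs(post - p) * mix

    # the posterior crosses p where the two densities are equal; splitting
    # there keeps the quadrature sharp.  15 sigma beyond either mean the
    # mixture density is ~1e-49, far below the tolerance
    mid = 0.5 * (spec.mu_active + spec.mu_decoy)
    lo = min(spec.mu_active, spec.mu_decoy) - 15.0 * spec.sigma
    hi = max(spec.mu_active, spec.mu_decoy) + 15.0 * spec.sigma
    left = quad(integrand, lo, mid, epsabs=1e-9, limit=200)[0]
    right = quad(integrand, mid, hi, epsabs=1e-9, limit=200)[0]
    return (left + right) / (2 * p * (1 - p))


def analytic_auc(spec: BinormalSpec) -> float:
    """Closed-form ROC AUC of the equal-variance binormal model."""
    gap = abs(spec.mu_active - spec.mu_decoy)
    return float(norm.cdf(gap / (spec.sigma * np.sqrt(2.0))))
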