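"""Predictiveness curve construction and its summary metrics.

The predictiveness curve plots R(v), the activity probability at the v-th
quantile of the score distribution, against v in (0, 1].  Quantiles are
oriented so that predicted activity is nondecreasing: the top x% of the
ranked dataset corresponds to v in (1 - x/100, 1].  An uninformative
scoring function gives the flat curve R(v) = p (the activity prevalence);
a perfect one gives the step function R(v) = I[(1 - p) < v].

Summary measures:

* total gain        TG     = int_0^1 |R(v) - p| dv / (2 p (1 - p))
* partial total gain pTG(v) = int_v^1 |R(u) - p| du / ((1 - v)(1 - p))

both standardized to [0, 1] (0 = no explanatory power, 1 = perfect).
pTG restricts the measure to the early part of the ranked dataset and its
denominator makes it prevalence-independent, which suits the
early-recognition question of virtual screening.  The two satisfy
pTG(0) = 2 p TG identically.

Empirical curves are piecewise constant with one step per compound
(point i carries the interval ((i-1)/n, i/n]); all integrals here are
exact Riemann sums over that step function, so there is no quadrature
error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from predcurve.dataset import ScreeningDataset
from predcurve.glm import LogisticModel, predict_probability

_MONOTONE_TOL = 1e-12


@dataclass(frozen=True)
class PredictivenessCurve:
    """Risk R(v) sampled at score quantiles v, with prevalence p.

    ``source_scores`` carries the raw score of the compound at each grid
    point (for translating a quantile threshold back to the score scale)
    and ``order`` the index of that compound in the originating dataset;
    both are None for analytically constructed curves.
    """

    prevalence: float
    v: np.ndarray
    risk: np.ndarray
    source_scores: Optional[np.ndarray] = None
    order: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        risk = np.asarray(self.risk, dtype=float)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "risk", risk)
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if v.ndim != 1 or v.shape != risk.shape or v.size < 1:
            raise ValueError("v and risk must be 1-d arrays of equal nonzero length")
        if v[0] <= 0.0 or abs(v[-1] - 1.0) > 1e-12 or np.any(np.diff(v) <= 0):
            raise ValueError("v must be strictly increasing in (0, 1] ending at 1")
        if np.any(risk < -_MONOTONE_TOL) or np.any(risk > 1.0 + _MONOTONE_TOL):
            raise ValueError("risk must lie in [0, 1]")
        if np.any(np.diff(risk) < -_MONOTONE_TOL):
            raise ValueError("risk must be nondecreasing along v")

    @property
    def n(self) -> int:
        return self.v.size

    def interval_widths(self) -> np.ndarray:
        """Mass of each grid point: width of its quantile interval."""
        return np.diff(np.concatenate([[0.0], self.v]))

    def to_dict(self) -> dict:
        out = {"prevalence": self.prevalence, "v": self.v.tolist(), "risk": self.risk.tolist()}
        if self.source_scores is not None:
            out["score"] = self.source_scores.tolist()
        return out


@dataclass(frozen=True)
class ThresholdReport:
    """A selection threshold on all three scales, with its local metrics.

    ``fraction_top`` is the selected dataset fraction in percent;
    ``score_threshold`` the raw score of the worst selected compound;
    ``activity_threshold`` the modelled activity probability there.  PPV
    or NPV are NaN when the corresponding side of the split is empty
    (undefined, not zero).
    """

    v: float
    fraction_top: float
    score_threshold: float
    activity_threshold: float
    pTG: float
    pAUC: float
    EF: float
    TPF: float
    FPF: float
    PPV: float
    NPV: float
    n_actives_selected: int
    n_selected: int

    def to_row(self) -> dict:
        """Report row with the conventional precisions (pTG/pAUC 3 d.p., EF 2 d.p.)."""
        def r(x: float, nd: int):
            return None if x != x else round(x, nd)

        return {
            "fraction_top_pct": r(self.fraction_top, 2),
            "activity_threshold": r(self.activity_threshold, 3),
            "pTG": r(self.pTG, 3),
            "pAUC": r(self.pAUC, 3),
            "EF": r(self.EF, 2),
            "score": r(self.score_threshold, 4),
            "actives": self.n_actives_selected,
            "compounds": self.n_selected,
            "TPF": r(self.TPF, 3),
            "FPF": r(self.FPF, 3),
            "PPV": r(self.PPV, 3),
            "NPV": r(self.NPV, 3),
        }


def build_curve(model: LogisticModel, dataset: ScreeningDataset) -> PredictivenessCurve:
    """Build the empirical predictiveness curve of a fitted model.

    Compounds are sorted ascending by predicted activity probability
    (stable, so ties keep input order); the i-th compound sits at quantile
    v_i = i/n with R(v_i) its predicted probability.  The prevalence is
    the sample prevalence.
    """
    probs = predict_probability(model, dataset.scores)
    order = np.argsort(probs, kind="stable")
    n = dataset.n
    return PredictivenessCurve(
        prevalence=dataset.prevalence,
        v=np.arange(1, n + 1) / n,
        risk=probs[order],
        source_scores=dataset.scores[order],
        order=order,
    )


def flat_curve(prevalence: float, n_points: int = 10_000) -> PredictivenessCurve:
    """The uninformative reference curve R(v) = p on a uniform grid."""
    v = np.arange(1, n_points + 1) / n_points
    return PredictivenessCurve(prevalence=prevalence, v=v, risk=np.full(n_points, prevalence))


def step_curve(prevalence: float, n_points: int = 10_000) -> PredictivenessCurve:
    """The perfect reference curve R(v) = I[(1 - p) < v] on a uniform grid."""
    v = np.arange(1, n_points + 1) / n_points
    risk = (v > 1.0 - prevalence).astype(float)
    return PredictivenessCurve(prevalence=prevalence, v=v, risk=risk)


def total_gain(curve: PredictivenessCurve) -> float:
    """Standardized total gain of the curve.

    TG = int_0^1 |R(v) - p| dv / (2 p (1 - p)), exact over the step
    function; 0 for the flat curve, 1 for the perfect step curve.  The
    arithmetic keeps TG in [0, 1]; no post-hoc truncation is applied.
    """
    p = curve.prevalence
    integral = float(np.sum(curve.interval_widths() * np.abs(curve.risk - p)))
    return integral / (2.0 * p * (1.0 - p))


def partial_total_gain(curve: PredictivenessCurve, v: float) -> float:
    """Partial total gain above quantile v.

    pTG(v) = int_v^1 |R(u) - p| du / ((1 - v)(1 - p)), the exact integral
    of the empirical step function over (v, 1]; a grid interval straddling
    v contributes its fractional overlap.  Satisfies pTG(0) = 2 p TG and
    equals 1 at v = 1 - p for the perfect step curve, for any prevalence.
    """
    if not 0.0 <= v < 1.0:
        raise ValueError(f"v must be in [0, 1), got {v}")
    p = curve.prevalence
    edges = np.concatenate([[0.0], curve.v])
    overlap = np.clip(edges[1:] - np.maximum(edges[:-1], v), 0.0, None)
    integral = float(np.sum(overlap * np.abs(curve.risk - p)))
    return integral / ((1.0 - v) * (1.0 - p))


def ptg_top(curve: PredictivenessCurve, fraction_top: float) -> float:
    """pTG of the top ``fraction_top`` percent of the ranked dataset.

    ``ptg_top(curve, 2)`` is the early-recognition pTG at 2% of the
    dataset, i.e. pTG(0.98).
    """
    if not 0.0 < fraction_top <= 100.0:
        raise ValueError(f"fraction_top must be in (0, 100], got {fraction_top}")
    return partial_total_gain(curve, 1.0 - fraction_top / 100.0)


def enrichment_factor(dataset: ScreeningDataset, fraction_top: float) -> float:
    """Enrichment factor of the top ``fraction_top`` percent by score.

    EF_x% = (Hits_x / N_x) / (Hits_t / N_t) with N_x = ceil(x% * N_t):
    the density of actives in the selected head of the ranking over the
    density in the whole dataset.  Bounded above by 1/p.  Requires a
    resolved score orientation.
    """
    if not 0.0 < fraction_top <= 100.0:
        raise ValueError(f"fraction_top must be in (0, 100], got {fraction_top}")
    from predcurve.glm import resolve_orientation

    dataset = resolve_orientation(dataset)
    n_sel = math.ceil(fraction_top * dataset.n / 100.0)
    oriented = dataset.oriented_scores()
    order = np.argsort(-oriented, kind="stable")
    hits = int(dataset.labels[order[:n_sel]].sum())
    return (hits / n_sel) / dataset.prevalence


def threshold_metrics(
    curve: PredictivenessCurve, dataset: ScreeningDataset, v: float
) -> ThresholdReport:
    """Classification and early-recognition metrics at quantile threshold v.

    Compounds at quantiles above v are "selected".  TPF/FPF/PPV/NPV are
    empirical label counts over the split; EF is the selected-fraction
    enrichment; pTG is the partial total gain above v; pAUC is the
    standardized partial ROC area up to the FPF actually reached by the
    selection (NaN when that FPF is zero).
    """
    if not 0.0 <= v < 1.0:
        raise ValueError(f"v must be in [0, 1), got {v}")
    if curve.order is None:
        raise ValueError("curve must be built from a dataset (missing compound order)")
    from predcurve.roc import partial_auc, roc_curve

    labels_sorted = dataset.labels[curve.order]
    selected = curve.v > v
    n_sel = int(selected.sum())
    n = dataset.n
    n_act = dataset.n_actives
    hits = int(labels_sorted[selected].sum())

    tpf = hits / n_act
    fpf = (n_sel - hits) / (n - n_act)
    ppv = hits / n_sel if n_sel else float("nan")
    n_rej = n - n_sel
    npv = (n_rej - (n_act - hits)) / n_rej if n_rej else float("nan")
    ef = (hits / n_sel) / dataset.prevalence if n_sel else float("nan")
    pauc = partial_auc(roc_curve(dataset), fpf) if fpf > 0 else float("nan")

    boundary = n - n_sel  # first selected grid point in curve order
    score_thr = float(curve.source_scores[boundary]) if curve.source_scores is not None else float("nan")
    return ThresholdReport(
        v=v,
        fraction_top=100.0 * (1.0 - v),
        score_threshold=score_thr,
        activity_threshold=float(curve.risk[boundary]),
        pTG=partial_total_gain(curve, v),
        pAUC=pauc,
        EF=ef,
        TPF=tpf,
        FPF=fpf,
        PPV=ppv,
        NPV=npv,
        n_actives_selected=hits,
        n_selected=n_sel,
    )


def probability_partition(curve: PredictivenessCurve, p_low: float, p_high: float) -> dict:
    """Proportions of compounds with low/equivocal/high activity probability.

    Uses the inverse curve R^-1(q) = smallest v with R(v) >= q: the
    low-probability proportion is R^-1(p_low), the high one
    1 - R^-1(p_high).
    """
    if not 0.0 <= p_low <= p_high <= 1.0:
        raise ValueError("need 0 <= p_low <= p_high <= 1")

    def r_inv(q: float) -> float:
        idx = np.searchsorted(curve.risk, q, side="left")
        if idx >= curve.n:
            return 1.0
        return float(curve.v[idx]) - float(curve.interval_widths()[idx])

    low = r_inv(p_low)
    high = 1.0 - r_inv(p_high)
    return {"low": low, "high": high, "equivocal": 1.0 - low - high}
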