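"""Score-selection threshold candidates from the predictiveness curve.

A steep predictiveness curve shows an inflexion point from which the
curve rises: scores beyond it are strongly associated with activity, so
the corresponding score makes a natural selection threshold for
prospective screening.  ``find_inflexion`` locates such points
automatically as local maxima of the smoothed derivative of R(v); it is a
decision-support heuristic -- threshold choice ultimately belongs to the
investigator, and ``translate_threshold`` supports that manual workflow
by converting a threshold given on any one scale (score, top fraction,
activity probability) into a consistent triple.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from predcurve.curve import PredictivenessCurve
from predcurve.dataset import ScreeningDataset


@dataclass(frozen=True)
class ThresholdCandidate:
    """A selection threshold expressed on all three scales.

    ``v_star`` is the quantile below which compounds are rejected (the
    selection is v > v_star); ``score_star`` and ``probability_star``
    belong to the worst selected compound; ``rise_rate`` is the local
    slope of R at the boundary (NaN for manually translated thresholds
    where no smoothing was applied).
    """

    v_star: float
    fraction_top: float
    score_star: float
    probability_star: float
    rise_rate: float


def _smoothed_derivative(curve: PredictivenessCurve, window: int) -> np.ndarray:
    smooth = (
        pd.Series(curve.risk).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    return np.gradient(smooth, curve.v)


def find_inflexion(
    curve: PredictivenessCurve,
    window: Optional[int] = None,
    *,
    dataset: Optional[ScreeningDataset] = None,
    seed: int = 0,
) -> list[ThresholdCandidate]:
    """Threshold candidates at local maxima of the curve's rise rate.

    The risk is smoothed with a centered moving average (default window
    max(5, n/100) points) and differentiated on the quantile grid;
    candidates are the local maxima of that derivative, ranked by height.

    A noise floor guards against reading thresholds into a quasi-flat
    curve: when ``dataset`` is supplied, the labels are permuted once
    (seeded), the model refit, and any candidate below twice the permuted
    curve's maximum rise rate is discarded -- flat or near-null curves
    then return an empty list, meaning "no defensible threshold".
    Without a dataset only the exactly-flat guard applies.
    """
    n = curve.n
    if n < 10:
        raise ValueError(f"curve needs at least 10 points, got {n}")
    if window is None:
        window = max(5, n // 100)
    deriv = _smoothed_derivative(curve, window)

    floor = 0.0
    if dataset is not None:
        from predcurve.curve import build_curve
        from predcurve.glm import fit_logistic

        import warnings as _warnings

        rng = np.random.default_rng(seed)
        permuted = ScreeningDataset(
            compound_ids=dataset.compound_ids,
            scores=dataset.scores,
            labels=rng.permutation(dataset.labels),
            orientation=dataset.orientation,
        )
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            null_model = fit_logistic(permuted)
        null_deriv = _smoothed_derivative(build_curve(null_model, permuted), window)
        floor = 2.0 * float(np.max(null_deriv))

    # distance=window merges the jittery micro-peaks a moving-average
    # plateau produces into one candidate per rise
    peaks, props = find_peaks(
        deriv, height=max(floor, 1e-12), plateau_size=1, distance=window
    )
    # plateau peaks report their left edge; use the plateau midpoint
    mids = ((props["left_edges"] + props["right_edges"]) // 2).astype(int)
    heights = props["peak_heights"]
    ranked = np.argsort(-heights, kind="stable")

    out = []
    for k in ranked:
        idx = int(mids[k])
        out.append(
            ThresholdCandidate(
                v_star=float(curve.v[idx]) - float(curve.interval_widths()[idx]),
                fraction_top=100.0 * (1.0 - float(curve.v[idx]) + float(curve.interval_widths()[idx])),
                score_star=float(curve.source_scores[idx]) if curve.source_scores is not None else float("nan"),
                probability_star=float(curve.risk[idx]),
                rise_rate=float(heights[k]),
            )
        )
    return out


def _candidate_at(curve: PredictivenessCurve, boundary: int) -> ThresholdCandidate:
    """Candidate whose selection is the grid points at indices >= boundary."""
    n = curve.n
    v_star = float(curve.v[boundary]) - float(curve.interval_widths()[boundary])
    i_lo, i_hi = max(boundary - 1, 0), min(boundary + 1, n - 1)
    rise = float(
        (curve.risk[i_hi] - curve.risk[i_lo]) / (curve.v[i_hi] - curve.v[i_lo])
    ) if i_hi > i_lo else float("nan")
    return ThresholdCandidate(
        v_star=v_star,
        fraction_top=100.0 * (n - boundary) / n,
        score_star=float(curve.source_scores[boundary]) if curve.source_scores is not None else float("nan"),
        probability_star=float(curve.risk[boundary]),
        rise_rate=rise,
    )


def translate_threshold(
    curve: PredictivenessCurve,
    *,
    score: Optional[float] = None,
    fraction_top: Optional[float] = None,
    probability: Optional[float] = None,
) -> ThresholdCandidate:
    """Resolve a threshold given on one scale into a consistent triple.

    Exactly one of ``score``, ``fraction_top`` (percent) or
    ``probability`` must be given.  A top fraction selects
    ceil(x% * n) compounds and reports the boundary compound's score; a
    probability q maps through the inverse curve with the convention
    R^-1(q) = smallest v with R(v) >= q.  The mapping is idempotent:
    re-translating any value of a returned triple returns the same
    triple.
    """
    given = [x is not None for x in (score, fraction_top, probability)]
    if sum(given) != 1:
        raise ValueError("give exactly one of score, fraction_top, probability")
    n = curve.n

    if fraction_top is not None:
        if not 0.0 < fraction_top <= 100.0:
            raise ValueError(f"fraction_top must be in (0, 100], got {fraction_top}")
        n_sel = ceil(fraction_top * n / 100.0)
        return _candidate_at(curve, n - n_sel)

    if probability is not None:
        if not curve.risk[0] <= probability <= curve.risk[-1]:
            raise ValueError(
                f"probability {probability} outside the curve's risk range "
                f"[{curve.risk[0]:.4g}, {curve.risk[-1]:.4g}]"
            )
        boundary = int(np.searchsorted(curve.risk, probability, side="left"))
        return _candidate_at(curve, boundary)

    if curve.source_scores is None:
        raise ValueError("curve carries no source scores; cannot translate a score threshold")
    scores = curve.source_scores
    lo, hi = float(np.min(scores)), float(np.max(scores))
    if not lo <= score <= hi:
        raise ValueError(f"score {score} outside the observed range [{lo:.4g}, {hi:.4g}]")
    # scores are monotone along the curve (up to ties); oriented direction
    # is the direction they run in curve order
    ascending = scores[-1] >= scores[0]
    if ascending:
        n_sel = int(np.sum(scores >= score))
    else:
        n_sel = int(np.sum(scores <= score))
    n_sel = max(n_sel, 1)
    return _candidate_at(curve, n - n_sel)
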