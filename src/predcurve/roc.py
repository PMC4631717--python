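"""Rank-based evaluation: ROC curve, AUC and partial AUC.

The ROC curve sweeps the score threshold over the ranked dataset and
plots the true-positive fraction against the false-positive fraction.
Tied scores are collapsed into a single diagonal step, so the trapezoidal
area equals the Mann-Whitney probability that a random active outscores a
random inactive (ties counted one half).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sklearn.metrics

from predcurve.dataset import ScreeningDataset


@dataclass(frozen=True)
class RocCurve:
    """Ordered (FPF, TPF) vertices, one per distinct score, from (0,0) to (1,1)."""

    fpf: np.ndarray
    tpf: np.ndarray

    def __post_init__(self) -> None:
        fpf = np.asarray(self.fpf, dtype=float)
        tpf = np.asarray(self.tpf, dtype=float)
        object.__setattr__(self, "fpf", fpf)
        object.__setattr__(self, "tpf", tpf)
        if fpf.shape != tpf.shape or fpf.ndim != 1 or fpf.size < 2:
            raise ValueError("fpf and tpf must be equal-length 1-d arrays")
        if fpf[0] != 0.0 or tpf[0] != 0.0 or fpf[-1] != 1.0 or tpf[-1] != 1.0:
            raise ValueError("ROC curve must run from (0,0) to (1,1)")
        if np.any(np.diff(fpf) < 0) or np.any(np.diff(tpf) < 0):
            raise ValueError("ROC coordinates must be nondecreasing")

    def vertices(self) -> np.ndarray:
        return np.column_stack([self.fpf, self.tpf])


def roc_curve(dataset: ScreeningDataset) -> RocCurve:
    """Empirical ROC curve of the oriented scores.

    An ``"infer"`` orientation is resolved first (from the fitted logistic
    slope).  Vertices come from thresholding at each distinct score; tied
    scores produce one diagonal step.
    """
    from predcurve.glm import resolve_orientation

    dataset = resolve_orientation(dataset)
    fpf, tpf, _ = sklearn.metrics.roc_curve(
        dataset.labels, dataset.oriented_scores(), drop_intermediate=False
    )
    # sklearn can emit fpf[0] = tpf[0] = 0 twice when the top score is tied;
    # the constructor only needs the endpoints, which sklearn guarantees
    return RocCurve(fpf=fpf, tpf=tpf)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve.

    Equals the Mann-Whitney statistic P[score(active) > score(inactive)]
    + 0.5 P[tie] because tied scores step diagonally.
    """
    return float(np.trapezoid(curve.tpf, curve.fpf))


def partial_auc(curve: RocCurve, fpf_max: float, normalization: str = "standardized") -> float:
    """Partial area under the ROC curve over FPF in [0, fpf_max].

    The curve is linearly interpolated at the cut.  Normalizations:

    * ``"raw"``          -- the area itself, at most fpf_max;
    * ``"standardized"`` -- raw / fpf_max, so a perfect method scores 1
      (the default, and the convention used in threshold reports);
    * ``"mcclish"``      -- McClish transform mapping the diagonal to 0.5
      and the perfect curve to 1.
    """
    if not 0.0 < fpf_max <= 1.0:
        raise ValueError(f"fpf_max must be in (0, 1], got {fpf_max}")
    keep = curve.fpf <= fpf_max
    x = np.append(curve.fpf[keep], fpf_max)
    y = np.append(curve.tpf[keep], np.interp(fpf_max, curve.fpf, curve.tpf))
    raw = float(np.trapezoid(y, x))
    if normalization == "raw":
        return raw
    if normalization == "standardized":
        return raw / fpf_max
    if normalization == "mcclish":
        min_area = fpf_max**2 / 2.0
        return 0.5 * (1.0 + (raw - min_area) / (fpf_max - min_area))
    raise ValueError(f"unknown normalization {normalization!r}")


def partial_auc_top_fraction(
    dataset: ScreeningDataset, fraction_top: float, normalization: str = "standardized"
) -> float:
    """Partial AUC cut at the FPF reached by selecting the top x% of the dataset.

    Selecting ceil(x% * n) compounds by oriented score attains some
    empirical FPF; the partial area is evaluated up to that FPF.  This is
    the fraction-of-dataset counterpart of an FPF-based cut; the two
    coincide only when the top fraction contains no actives.  Returns NaN
    when the attained FPF is zero (a perfect head of the ranking).
    """
    import math

    from predcurve.glm import resolve_orientation

    if not 0.0 < fraction_top <= 100.0:
        raise ValueError(f"fraction_top must be in (0, 100], got {fraction_top}")
    dataset = resolve_orientation(dataset)
    n_sel = math.ceil(fraction_top * dataset.n / 100.0)
    order = np.argsort(-dataset.oriented_scores(), kind="stable")
    hits = int(dataset.labels[order[:n_sel]].sum())
    fpf_cut = (n_sel - hits) / (dataset.n - dataset.n_actives)
    if fpf_cut == 0.0:
        return float("nan")
    return partial_auc(roc_curve(dataset), fpf_cut, normalization=normalization)
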