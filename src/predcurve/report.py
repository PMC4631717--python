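"""Evaluation reports and paired predictiveness/ROC figures."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from predcurve import __version__
from predcurve.curve import PredictivenessCurve, ThresholdReport
from predcurve.roc import RocCurve

# below this total gain a curve is reported as a quasi null-model: the
# scores carry next to no information about activity even if they rank well
QUASI_NULL_TG = 0.05

THRESHOLD_COLUMNS = [
    "target",
    "fraction_top_pct",
    "activity_threshold",
    "pTG",
    "pAUC",
    "EF",
    "score",
    "actives",
    "compounds",
    "TPF",
    "FPF",
    "PPV",
    "NPV",
]


@dataclass
class EvaluationReport:
    """One method/dataset evaluation: summary, global metrics, threshold rows."""

    target: str
    n_actives: int
    n_compounds: int
    prevalence: float
    tg: float
    roc_auc: float
    orientation: str
    model: dict
    n_dropped: int = 0
    quasi_null: bool = False
    thresholds: list[ThresholdReport] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def summary_row(self) -> dict:
        return {
            "target": self.target,
            "n_actives": self.n_actives,
            "n_compounds": self.n_compounds,
            "prevalence": self.prevalence,
            "TG": self.tg,
            "ROC_AUC": self.roc_auc,
        }

    def to_json(self) -> str:
        payload = {
            "target": self.target,
            "n_actives": self.n_actives,
            "n_compounds": self.n_compounds,
            "n_dropped": self.n_dropped,
            "prevalence": round(self.prevalence, 4),
            "TG": round(self.tg, 3),
            "ROC_AUC": round(self.roc_auc, 3),
            "orientation": self.orientation,
            "quasi_null_model": self.quasi_null,
            "model": self.model,
            "thresholds": [t.to_row() for t in self.thresholds],
            "provenance": {**self.provenance, "tool_version": __version__},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def write_threshold_table(reports: Sequence[tuple[str, ThresholdReport]], path, *, delimiter: str = "\t") -> None:
    """Threshold rows, one per (target, threshold), in the conventional column order."""
    rows = [{"target": t, **r.to_row()} for t, r in reports]
    frame = pd.DataFrame(rows, columns=THRESHOLD_COLUMNS)
    frame.to_csv(path, sep=delimiter, index=False)


def plot_pc_roc(
    entries: Sequence[tuple[str, PredictivenessCurve, RocCurve]],
    path,
    *,
    thresholds: Optional[Sequence[Optional[float]]] = None,
    title: Optional[str] = None,
) -> None:
    """Paired predictiveness + ROC panels, one curve per method.

    Dashed gray reference lines mark the activity prevalence (left panel)
    and random picking (right panel); optional vertical dashed lines mark
    each method's selection threshold quantile.
    """
    fig, (ax_pc, ax_roc) = plt.subplots(1, 2, figsize=(10, 4.2))
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    prevalence = entries[0][1].prevalence

    for k, (label, pc, roc) in enumerate(entries):
        color = colors[k % len(colors)]
        ax_pc.plot(pc.v, pc.risk, color=color, label=label)
        ax_roc.plot(roc.fpf, roc.tpf, color=color, label=label)
        if thresholds is not None and thresholds[k] is not None:
            ax_pc.axvline(thresholds[k], color=color, linestyle="--", linewidth=0.8)

    ax_pc.axhline(prevalence, color="gray", linestyle="--", linewidth=0.8)
    ax_pc.set_xlabel("score quantile v")
    ax_pc.set_ylabel("activity probability R(v)")
    ax_pc.set_title("Predictiveness curve")
    ax_pc.set_xlim(0, 1)
    ax_pc.set_ylim(-0.02, 1.02)
    ax_pc.legend(loc="upper left", fontsize=8)

    ax_roc.plot([0, 1], [0, 1], color="gray", linestyle="--", linewidth=0.8)
    ax_roc.set_xlabel("false positive fraction")
    ax_roc.set_ylabel("true positive fraction")
    ax_roc.set_title("ROC curve")
    ax_roc.set_xlim(0, 1)
    ax_roc.set_ylim(0, 1.02)

    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)
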