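"""Screening datasets: per-compound scores and activity labels.

A screening dataset is the unit of evaluation: one compound collection
scored by one method against one target, with a binary activity label per
compound (1 = active, 0 = inactive/decoy).  Scores are continuous and in
arbitrary units; their orientation (whether higher or lower means "more
active-looking") is carried as metadata and may be left to be inferred
from the fitted activity model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ORIENTATIONS = ("higher_is_better", "lower_is_better", "infer")

_TRUE_LABELS = {"1", "true"}
_FALSE_LABELS = {"0", "false"}


class DatasetFormatError(ValueError):
    """The input table does not have the expected columns or value types."""


class DegenerateDatasetError(ValueError):
    """The dataset has no actives or no inactives; prevalence is degenerate."""


@dataclass(frozen=True)
class ScreeningDataset:
    """Per-compound virtual-screening results for one target/method pair.

    Parameters
    ----------
    compound_ids : sequence of str
        Unique opaque identifiers, one per compound.
    scores : array-like of float
        Continuous screening scores ``Y`` in arbitrary units.
    labels : array-like of {0, 1}
        Binary activity ``A``; 1 marks an active compound, 0 an
        inactive/decoy.
    orientation : str
        ``"higher_is_better"``, ``"lower_is_better"`` or ``"infer"``
        (resolve later from the sign of the fitted logistic slope).
    n_dropped : int
        Rows removed on input because the score was missing/non-finite.
    """

    compound_ids: tuple[str, ...]
    scores: np.ndarray
    labels: np.ndarray
    orientation: str = "infer"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        ids = tuple(str(c) for c in self.compound_ids)
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "compound_ids", ids)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}")
        n = len(ids)
        if not (scores.shape == (n,) and labels.shape == (n,)):
            raise ValueError("compound_ids, scores and labels must have equal length")
        if n < 2:
            raise ValueError(f"need at least 2 compounds, got {n}")
        if len(set(ids)) != n:
            raise ValueError("compound_ids must be unique")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        if labels.sum() == 0 or labels.sum() == n:
            raise DegenerateDatasetError(
                "dataset needs at least one active and one inactive compound"
            )

    @property
    def n(self) -> int:
        return len(self.compound_ids)

    @property
    def n_actives(self) -> int:
        return int(self.labels.sum())

    @property
    def prevalence(self) -> float:
        return self.n_actives / self.n

    def with_orientation(self, orientation: str) -> "ScreeningDataset":
        """Copy of the dataset with the orientation metadata replaced."""
        return replace(self, orientation=orientation)

    def oriented_scores(self) -> np.ndarray:
        """Scores on a higher-means-more-active scale.

        Requires a resolved orientation; use
        :func:`predcurve.glm.resolve_orientation` first when it is
        ``"infer"``.
        """
        if self.orientation == "infer":
            raise ValueError(
                "orientation is 'infer'; resolve it from the fitted model first "
                "(predcurve.glm.resolve_orientation)"
            )
        if self.orientation == "higher_is_better":
            return self.scores
        return -self.scores


@dataclass(frozen=True)
class DatasetSummary:
    """Counts and prevalence of a screening dataset."""

    n_actives: int
    n_compounds: int
    prevalence: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.n_actives < self.n_compounds:
            raise ValueError("need 0 < n_actives < n_compounds")
        object.__setattr__(self, "prevalence", self.n_actives / self.n_compounds)


def summarize(dataset: ScreeningDataset) -> DatasetSummary:
    """Dataset-level counts and activity prevalence p = actives/compounds."""
    return DatasetSummary(n_actives=dataset.n_actives, n_compounds=dataset.n)


def _parse_labels(raw: pd.Series) -> np.ndarray:
    text = raw.astype(str).str.strip().str.lower()
    bad = ~text.isin(_TRUE_LABELS | _FALSE_LABELS)
    if bad.any():
        examples = sorted(text[bad].unique())[:5]
        raise DatasetFormatError(
            f"labels must be 0/1 or true/false; found {examples}"
        )
    return text.isin(_TRUE_LABELS).to_numpy().astype(int)


def read_screening_table(
    path,
    *,
    delimiter: str | None = None,
    id_column: str = "id",
    score_column: str = "score",
    label_column: str = "active",
    orientation: str = "infer",
    impute_worst: bool = False,
) -> ScreeningDataset:
    """Read a delimited per-compound screening table.

    The file must have a header row with (configurable) identifier, score
    and activity-label columns.  Rows whose score is missing or non-finite
    are dropped (the count is logged and kept on the dataset), unless
    ``impute_worst`` is set, in which case they receive the worst observed
    score -- the conservative choice for compounds a method failed to dock.

    Parameters
    ----------
    delimiter : str, optional
        Column separator; sniffed from the file when omitted (commas and
        tabs both work).
    orientation : str
        Score orientation metadata for the returned dataset.

    Raises
    ------
    DatasetFormatError
        Missing columns or unparseable labels.
    DegenerateDatasetError
        No actives or no inactives remain after parsing.
    """
    table = pd.read_csv(path, sep=delimiter, engine="python", dtype=str)
    missing = [c for c in (id_column, score_column, label_column) if c not in table.columns]
    if missing:
        raise DatasetFormatError(
            f"missing column(s) {missing}; found {list(table.columns)} in {path}"
        )

    def _to_float(x) -> float:
        try:
            return float(x)
        except (TypeError, ValueError):
            return float("nan")

    # float() is correctly rounded, so write/read round-trips are exact
    scores = np.array([_to_float(x) for x in table[score_column]], dtype=float)
    labels = _parse_labels(table[label_column])
    ids = table[id_column].astype(str).to_numpy()

    ok = np.isfinite(scores)
    n_bad = int((~ok).sum())
    if n_bad:
        if impute_worst:
            # worst = least active-looking; without resolved orientation the
            # safe pick is the side that ranks last either way is unknown, so
            # impute per declared orientation and refuse under "infer"
            if orientation == "infer":
                raise DatasetFormatError(
                    "impute_worst requires an explicit orientation"
                )
            worst = scores[ok].min() if orientation == "higher_is_better" else scores[ok].max()
            scores = np.where(ok, scores, worst)
            logger.warning("imputed worst score for %d row(s) in %s", n_bad, path)
            n_bad = 0
        else:
            logger.warning("dropped %d row(s) with missing/non-finite score in %s", n_bad, path)
            ids, scores, labels = ids[ok], scores[ok], labels[ok]

    return ScreeningDataset(
        compound_ids=tuple(ids),
        scores=scores,
        labels=labels,
        orientation=orientation,
        n_dropped=n_bad if not impute_worst else 0,
    )


def write_screening_table(
    dataset: ScreeningDataset,
    path,
    *,
    delimiter: str = ",",
    id_column: str = "id",
    score_column: str = "score",
    label_column: str = "active",
) -> None:
    """Write a dataset back to the delimited dialect `read_screening_table` reads.

    Scores are written in full ``repr`` precision so a read/write/read
    round-trip reproduces ids, scores and labels exactly.
    """
    frame = pd.DataFrame(
        {
            id_column: list(dataset.compound_ids),
            score_column: [format(float(s), ".17g") for s in dataset.scores],
            label_column: dataset.labels,
        }
    )
    frame.to_csv(path, sep=delimiter, index=False)


def write_summary_table(rows: Sequence[dict], path, *, delimiter: str = "\t") -> None:
    """Write one summary row per dataset (target, counts, prevalence, TG, ROC AUC).

    Prevalence is reported to 4 decimals, TG and ROC AUC to 3, matching the
    conventional precision of benchmark summary tables.
    """
    frame = pd.DataFrame(rows, columns=["target", "n_actives", "n_compounds", "prevalence", "TG", "ROC_AUC"])
    frame["prevalence"] = frame["prevalence"].map(lambda x: f"{x:.4f}")
    for col in ("TG", "ROC_AUC"):
        frame[col] = frame[col].map(lambda x: "" if pd.isna(x) else f"{x:.3f}")
    frame.to_csv(path, sep=delimiter, index=False)


def load_dud_composition() -> pd.DataFrame:
    """Composition of the DUD release-2 benchmark screens.

    Returns a table with one row per target (the 39 DUD targets with an
    experimental structure) and columns ``target``, ``n_actives``,
    ``n_compounds`` for the target's own actives-plus-decoys set.  Useful
    for prevalence arithmetic and for sizing realistic synthetic
    benchmarks.
    """
    with resources.files("predcurve.data").joinpath("dud_composition.csv").open() as fh:
        return pd.read_csv(fh)
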