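"""Domain containers, delimited-text I/O, and questionnaire scale scoring.

The central container is :class:`QoLPanel`: a subjects x visits matrix of
quality-of-life scores on a fixed visit grid (weeks 0, 2, 4, 6, 8, 12, 16 by
default, the schedule of a 16-week treatment protocol), with NaN marking a
missed assessment, plus a per-subject covariate table.  Zeros are legal
scores; missingness is always NaN, never a sentinel value.

Scale scoring follows the EORTC convention: the mean of the answered items
is mapped linearly onto 0-100, provided at least half the items were
answered (the "half rule"); functional scales are reversed so that 100
always means the best possible standing on functional/global scales and the
worst symptom burden on symptom scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_VISIT_WEEKS: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0)

COVARIATE_COLUMNS = ("sex", "ecog", "age", "arm")


class ValidationError(ValueError):
    """Raised when input data violates a container invariant."""


@dataclass(frozen=True)
class ScaleDefinition:
    """One questionnaire scale: its items, response span, and direction.

    ``item_range`` is the span of the item response scale (6 for the 1-7
    global items, 3 for the 1-4 items).  ``direction`` is ``"functional"``
    (higher raw response = worse, score reversed) or ``"symptom"`` /
    ``"global"`` (score increases with the raw mean).
    """

    item_ids: tuple[str, ...]
    item_range: int
    direction: str = "global"

    def __post_init__(self) -> None:
        if len(self.item_ids) == 0:
            raise ValidationError("scale must contain at least one item")
        if self.item_range < 1:
            raise ValidationError(f"item_range must be >= 1, got {self.item_range}")
        if self.direction not in ("functional", "symptom", "global"):
            raise ValidationError(
                f"direction must be functional/symptom/global, got {self.direction!r}"
            )


def score_scale(item_responses: Mapping[str, float | None], scale: ScaleDefinition) -> float:
    """Score one scale from raw item responses.

    Returns NaN when fewer than half the scale's items were answered.
    Responses must lie in [1, 1 + item_range]; out-of-range responses raise
    :class:`ValidationError` naming the offending item.
    """
    lo, hi = 1.0, 1.0 + scale.item_range
    answered = []
    for item in scale.item_ids:
        v = item_responses.get(item)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        if not lo <= v <= hi:
            raise ValidationError(
                f"response {v!r} for item {item!r} outside declared range [{lo:g}, {hi:g}]"
            )
        answered.append(float(v))
    if 2 * len(answered) < len(scale.item_ids):
        return float("nan")
    rs = sum(answered) / len(answered)
    raw = 100.0 * (rs - 1.0) / scale.item_range
    return 100.0 - raw if scale.direction == "functional" else raw


@dataclass
class QoLPanel:
    """Per-subject longitudinal QoL scores on a fixed visit grid.

    ``scores`` is an (n_subjects, n_visits) float array with NaN for missed
    visits.  ``covariates`` is indexed like ``subject_ids`` and carries the
    baseline covariates (sex, ecog, age, arm) used downstream.
    """

    subject_ids: list[str]
    visit_weeks: np.ndarray
    scores: np.ndarray
    covariates: pd.DataFrame
    validate_range: bool = True

    def __post_init__(self) -> None:
        self.visit_weeks = np.asarray(self.visit_weeks, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        self.subject_ids = [str(s) for s in self.subject_ids]
        n, m = len(self.subject_ids), len(self.visit_weeks)
        if len(set(self.subject_ids)) != n:
            raise ValidationError("subject ids must be unique")
        if self.scores.shape != (n, m):
            raise ValidationError(
                f"scores shape {self.scores.shape} != (subjects, visits) = ({n}, {m})"
            )
        if m == 0 or np.any(np.diff(self.visit_weeks) <= 0):
            raise ValidationError("visit_weeks must be non-empty and strictly increasing")
        obs = ~np.isnan(self.scores)
        if self.validate_range and obs.any():
            vals = self.scores[obs]
            if vals.min() < 0 or vals.max() > 100:
                raise ValidationError("non-missing scores must lie in [0, 100]")
        if np.isnan(self.scores[:, 0]).any():
            bad = [s for s, miss in zip(self.subject_ids, np.isnan(self.scores[:, 0])) if miss]
            raise ValidationError(f"subjects missing a baseline score: {bad[:5]}")
        if not self.covariates.index.equals(pd.Index(self.subject_ids)):
            self.covariates = self.covariates.reindex(self.subject_ids)
            if self.covariates.isna().all(axis=1).any():
                raise ValidationError("covariate table does not cover all subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_visits(self) -> int:
        return len(self.visit_weeks)

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of observed cells."""
        return ~np.isnan(self.scores)

    def subset(self, keep: Sequence[str]) -> "QoLPanel":
        keep = list(keep)
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        idx = [pos[s] for s in keep]
        return QoLPanel(
            keep,
            self.visit_weeks.copy(),
            self.scores[idx].copy(),
            self.covariates.loc[keep].copy(),
            validate_range=self.validate_range,
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format frame of observed rows (subject_id, week, qol, covariates)."""
        rows = []
        for i, sid in enumerate(self.subject_ids):
            for j, w in enumerate(self.visit_weeks):
                y = self.scores[i, j]
                if not np.isnan(y):
                    rows.append({"subject_id": sid, "week": w, "qol": y})
        long = pd.DataFrame(rows)
        cov = self.covariates.reset_index(names="subject_id")
        return long.merge(cov, on="subject_id", how="left")


@dataclass
class SurvivalData:
    """Right-censored follow-up: time in months, event = 1 for observed death."""

    subject_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            raise ValidationError("subject ids must be unique")
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValidationError("time/event length must match subject count")
        if np.any(self.time < 0):
            raise ValidationError("follow-up times must be non-negative")
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError("event indicator must be 0 or 1")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subset(self, keep: Sequence[str]) -> "SurvivalData":
        keep = list(keep)
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        idx = [pos[s] for s in keep]
        cov = None if self.covariates is None else self.covariates.loc[keep].copy()
        return SurvivalData(keep, self.time[idx].copy(), self.event[idx].copy(), cov)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"subject_id": self.subject_ids, "time_months": self.time, "event": self.event}
        ).set_index("subject_id")
        if self.covariates is not None:
            df = df.join(self.covariates)
        return df


DEFAULT_LONG_COLUMNS = {
    "subject_id": "subject_id",
    "week": "week",
    "qol": "qol",
    "sex": "sex",
    "ecog": "ecog",
    "age": "age",
    "arm": "arm",
}

DEFAULT_SURVIVAL_COLUMNS = {
    "subject_id": "subject_id",
    "time_months": "time_months",
    "event": "event",
}


def read_long_table(
    path,
    column_map: Mapping[str, str] | None = None,
    visit_weeks: Sequence[float] = DEFAULT_VISIT_WEEKS,
    sep: str = ",",
) -> tuple[QoLPanel, int]:
    """Read a long-format delimited file and pivot onto the visit grid.

    Returns ``(panel, n_dropped)`` where ``n_dropped`` counts subjects
    excluded for lacking a non-missing baseline (week-0) score.  Weeks not on
    the grid and duplicate (subject, week) rows are errors.
    """
    cmap = dict(DEFAULT_LONG_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep)
    missing_cols = [c for k, c in cmap.items() if k in ("subject_id", "week", "qol") and c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing required columns {missing_cols} in {path}")
    df = df.rename(columns={v: k for k, v in cmap.items()})

    weeks = np.asarray(sorted(visit_weeks), dtype=float)
    df["week"] = pd.to_numeric(df["week"], errors="raise").astype(float)
    off_grid = sorted(set(df["week"]) - set(weeks))
    if off_grid:
        raise ValidationError(f"weeks not on the visit grid {weeks.tolist()}: {off_grid}")
    dup = df.duplicated(subset=["subject_id", "week"])
    if dup.any():
        pairs = df.loc[dup, ["subject_id", "week"]].values.tolist()
        raise ValidationError(f"duplicate (subject, week) rows: {pairs[:5]}")
    df["qol"] = pd.to_numeric(df["qol"], errors="raise")

    wide = df.pivot(index="subject_id", columns="week", values="qol").reindex(columns=weeks)
    cov_cols = [c for c in COVARIATE_COLUMNS if c in df.columns]
    cov = df.groupby("subject_id")[cov_cols].first() if cov_cols else pd.DataFrame(index=wide.index)

    has_baseline = ~wide[weeks[0]].isna()
    n_dropped = int((~has_baseline).sum())
    wide = wide.loc[has_baseline]
    panel = QoLPanel(
        list(wide.index),
        weeks,
        wide.to_numpy(dtype=float),
        cov.loc[wide.index],
    )
    return panel, n_dropped


def read_survival_table(
    path, column_map: Mapping[str, str] | None = None, sep: str = ","
) -> SurvivalData:
    """Read a survival table (subject_id, time_months, event)."""
    cmap = dict(DEFAULT_SURVIVAL_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep)
    missing_cols = [c for c in cmap.values() if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing required columns {missing_cols} in {path}")
    df = df.rename(columns={v: k for k, v in cmap.items()})
    time = pd.to_numeric(df["time_months"], errors="raise").to_numpy(dtype=float)
    event = pd.to_numeric(df["event"], errors="raise").to_numpy()
    if not np.isin(event, (0, 1)).all():
        bad = sorted(set(event) - {0, 1})
        raise ValidationError(f"event indicator must be 0/1, found {bad}")
    extra = [c for c in df.columns if c not in ("subject_id", "time_months", "event")]
    cov = df.set_index("subject_id")[extra] if extra else None
    return SurvivalData(list(df["subject_id"].astype(str)), time, event.astype(int), cov)


def write_long_table(panel: QoLPanel, path, sep: str = ",") -> None:
    """Write a panel back to long format (observed rows only)."""
    panel.to_long().to_csv(path, sep=sep, index=False)


def write_wide_table(panel: QoLPanel, path, sep: str = ",") -> None:
    """One row per subject, one ``week_<w>`` column per visit."""
    cols = {f"week_{w:g}": panel.scores[:, j] for j, w in enumerate(panel.visit_weeks)}
    pd.DataFrame({"subject_id": panel.subject_ids, **cols}).to_csv(path, sep=sep, index=False)


def write_survival_table(surv: SurvivalData, path, sep: str = ",") -> None:
    surv.to_frame().reset_index().to_csv(path, sep=sep, index=False)
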