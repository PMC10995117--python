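"""Scoring of model-reconstruction trials.

A reconstruction trial is an ordered event log: the observer views the target
model (the first event is always a view), places some squares, may re-view
the model any number of times, and the trial ends when all set-size items are
placed.  Scoring derives, per trial:

* **utilization** — items placed per model view, i.e. set size divided by the
  number of views; a variant excludes views after which nothing was placed;
* **correspondence matching** — each placed item is bound to the target item
  nearest to it (Euclidean center distance); if two placements claim the same
  target the trial is flagged as a *collision* and excluded, because error
  attribution is then ambiguous;
* **position error** (Euclidean, degrees of visual angle) and **color error**
  (minimal circular hue difference, radians) per matched placement;
* a 3-SD outlier trim over trial-mean errors within a configurable population.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import SquareItem, TargetModel, circular_distance_deg

logger = logging.getLogger(__name__)

__all__ = [
    "TrialEvent",
    "ReconstructionTrial",
    "MatchedPlacement",
    "MatchResult",
    "TrialScore",
    "position_error",
    "color_error",
    "match_items",
    "compute_utilization",
    "score_trial",
    "score_dataset",
    "exclude_outlier_trials",
    "aggregate_subjects",
    "TRIM_POPULATIONS",
]

TRIM_POPULATIONS = ("subject_x_ss", "subject", "pooled")


@dataclass(frozen=True)
class TrialEvent:
    """One event in a reconstruction trial log.

    ``view`` events carry no coordinates; ``place`` events carry the placed
    square's center and hue.  Timestamps are milliseconds from trial start.
    """

    event_type: str  # "view" | "place"
    t_ms: float
    x_deg: float | None = None
    y_deg: float | None = None
    hue_deg: float | None = None

    def __post_init__(self) -> None:
        if self.event_type not in ("view", "place"):
            raise ValueError(f"unknown event_type {self.event_type!r}")
        if self.event_type == "place" and (
            self.x_deg is None or self.y_deg is None or self.hue_deg is None
        ):
            raise ValueError("place event requires x_deg, y_deg, hue_deg")


@dataclass
class ReconstructionTrial:
    """Ordered view/place event log for one trial plus its target model."""

    model: TargetModel
    events: list[TrialEvent]
    subject_id: int = 0
    trial_id: int = 0

    def __post_init__(self) -> None:
        if not self.events or self.events[0].event_type != "view":
            raise ValueError("trial must start with a view event")
        t = [e.t_ms for e in self.events]
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("event timestamps must be strictly increasing")
        n_placed = sum(e.event_type == "place" for e in self.events)
        if n_placed != self.model.set_size:
            raise ValueError(
                f"trial has {n_placed} placements for set size {self.model.set_size}"
            )

    @property
    def set_size(self) -> int:
        return self.model.set_size

    @property
    def n_views(self) -> int:
        """Number of model views, including the initial display."""
        return sum(e.event_type == "view" for e in self.events)

    @property
    def n_nonempty_views(self) -> int:
        """Views followed by at least one placement before the next view."""
        n = 0
        placed_since_view = False
        for e in self.events:
            if e.event_type == "view":
                if placed_since_view:
                    n += 1
                placed_since_view = False
            else:
                placed_since_view = True
        if placed_since_view:
            n += 1
        return n

    @property
    def placements(self) -> list[SquareItem]:
        return [
            SquareItem(x_deg=e.x_deg, y_deg=e.y_deg, hue_deg=e.hue_deg)
            for e in self.events
            if e.event_type == "place"
        ]

    @property
    def view_time_ms(self) -> float:
        """Total time spent viewing the model: per view event, the interval
        until the next event (the final event is always a placement)."""
        total = 0.0
        for a, b in zip(self.events, self.events[1:]):
            if a.event_type == "view":
                total += b.t_ms - a.t_ms
        return total


@dataclass(frozen=True)
class MatchedPlacement:
    """A placed item bound to its inferred target item, with errors."""

    placed: SquareItem
    target_index: int
    position_error_deg: float
    color_error_rad: float


@dataclass(frozen=True)
class MatchResult:
    matches: tuple[MatchedPlacement, ...]
    collision: bool


@dataclass
class TrialScore:
    """Per-trial scoring output feeding exclusion and aggregation."""

    subject_id: int
    trial_id: int
    set_size: int
    n_views: int
    n_nonempty_views: int
    utilization: float
    utilization_nonempty: float
    mean_position_error_deg: float
    mean_color_error_rad: float
    view_time_ms: float
    collision: bool
    excluded: bool = False
    exclusion_reason: str = "none"  # none | collision | outlier
    matches: tuple[MatchedPlacement, ...] = field(default_factory=tuple)


def position_error(placed: SquareItem, target: SquareItem) -> float:
    """Euclidean distance between square centers, degrees of visual angle."""
    return math.hypot(placed.x_deg - target.x_deg, placed.y_deg - target.y_deg)


def color_error(
    placed_hue_deg: float, target_hue_deg: float, circular: bool = True
) -> float:
    """Absolute hue difference in radians.

    With ``circular`` (the default) this is the minimal wrap-around angular
    distance, in [0, pi].  The non-circular option takes |a - b| on raw
    angles, provided only to reproduce analyses that skipped the wrap.
    """
    if circular:
        return math.radians(circular_distance_deg(placed_hue_deg, target_hue_deg))
    return abs(math.radians(placed_hue_deg) - math.radians(target_hue_deg))


def match_items(
    model: TargetModel,
    placements: list[SquareItem],
    circular_color: bool = True,
) -> MatchResult:
    """Bind each placed item to the nearest target item.

    Each placement is assigned the model item with the smallest Euclidean
    center distance.  If two placements receive the same model item the trial
    cannot be scored unambiguously and is flagged as a collision.  Exact
    distance ties (probability zero under continuous noise) are broken by the
    lowest model-item index and logged.
    """
    if not placements:
        raise ValueError("cannot match an empty placement list")
    if len(placements) > model.set_size:
        raise ValueError("more placements than model items")
    targets = model.positions()
    assigned: list[int] = []
    matches: list[MatchedPlacement] = []
    for placed in placements:
        d = np.hypot(targets[:, 0] - placed.x_deg, targets[:, 1] - placed.y_deg)
        best = int(np.argmin(d))  # argmin takes the lowest index on ties
        if np.sum(d == d[best]) > 1:
            logger.info("distance tie broken by lowest model-item index")
        matches.append(
            MatchedPlacement(
                placed=placed,
                target_index=best,
                position_error_deg=float(d[best]),
                color_error_rad=color_error(
                    placed.hue_deg, model.items[best].hue_deg, circular_color
                ),
            )
        )
        assigned.append(best)
    collision = len(set(assigned)) < len(assigned)
    return MatchResult(matches=tuple(matches), collision=collision)


def compute_utilization(
    trial: ReconstructionTrial, exclude_empty_views: bool = False
) -> float:
    """Items placed per model view: set size / number of counted views.

    With ``exclude_empty_views``, views after which the observer placed
    nothing before re-viewing do not count toward the divisor.  At set size 1
    this variant is identically 1 (the single item is placed after exactly
    one counted view); without it, utilization can fall below 1 when the
    observer re-views the model before placing anything.
    """
    n = trial.n_nonempty_views if exclude_empty_views else trial.n_views
    if n == 0:
        raise ValueError("trial has zero counted views")
    return trial.set_size / n


def score_trial(
    trial: ReconstructionTrial, circular_color: bool = True
) -> TrialScore:
    """Score one complete trial: utilization, matching, per-trial mean errors."""
    result = match_items(trial.model, trial.placements, circular_color)
    if result.collision:
        pos_err = math.nan
        col_err = math.nan
    else:
        pos_err = float(np.mean([m.position_error_deg for m in result.matches]))
        col_err = float(np.mean([m.color_error_rad for m in result.matches]))
    return TrialScore(
        subject_id=trial.subject_id,
        trial_id=trial.trial_id,
        set_size=trial.set_size,
        n_views=trial.n_views,
        n_nonempty_views=trial.n_nonempty_views,
        utilization=compute_utilization(trial, exclude_empty_views=False),
        utilization_nonempty=compute_utilization(trial, exclude_empty_views=True),
        mean_position_error_deg=pos_err,
        mean_color_error_rad=col_err,
        view_time_ms=trial.view_time_ms,
        collision=result.collision,
        excluded=result.collision,
        exclusion_reason="collision" if result.collision else "none",
        matches=result.matches,
    )


_SCORE_COLUMNS = [
    "subject_id",
    "trial_id",
    "set_size",
    "n_views",
    "n_nonempty_views",
    "utilization",
    "utilization_nonempty",
    "mean_position_error_deg",
    "mean_color_error_rad",
    "view_time_ms",
    "collision",
    "excluded",
    "exclusion_reason",
]


def scores_to_frame(scores: list[TrialScore]) -> pd.DataFrame:
    rows = [{c: getattr(s, c) for c in _SCORE_COLUMNS} for s in scores]
    return pd.DataFrame(rows, columns=_SCORE_COLUMNS)


def score_dataset(
    trials: list[ReconstructionTrial],
    circular_color: bool = True,
    threshold_sd: float = 3.0,
    trim_population: str = "subject_x_ss",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score, collision-screen and outlier-trim a full set of trials.

    Returns
    -------
    trial_scores : DataFrame
        One row per trial with utilization, errors and exclusion flags.
    exclusion_report : DataFrame
        Per set size: percent of trials removed by collision and by the 3-SD
        trim (each also averaged over per-subject percentages).
    """
    scores = [score_trial(t, circular_color) for t in trials]
    df = scores_to_frame(scores)
    return exclude_outlier_trials(df, threshold_sd, trim_population)


def exclude_outlier_trials(
    trial_scores: pd.DataFrame,
    threshold_sd: float = 3.0,
    population: str = "subject_x_ss",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the 3-SD error trim on top of collision exclusions.

    Collision-flagged trials are removed first and never enter the mean/SD
    computation.  Within each trimming population (default: one subject at
    one set size) a trial is excluded when its mean position error or mean
    color error exceeds the population mean + ``threshold_sd`` * SD of that
    measure.  Populations with zero error variance trim nothing (a warning is
    logged).  The trim is single-pass: it is not re-run on the filtered set.
    """
    if population not in TRIM_POPULATIONS:
        raise ValueError(
            f"population must be one of {TRIM_POPULATIONS}, got {population!r}"
        )
    df = trial_scores.copy()
    clean = ~df["collision"]

    if population == "subject_x_ss":
        keys = ["subject_id", "set_size"]
    elif population == "subject":
        keys = ["subject_id"]
    else:
        keys = []

    outlier = pd.Series(False, index=df.index)
    groups = [((), df[clean])] if not keys else list(df[clean].groupby(keys))
    for _, grp in groups:
        if len(grp) < 2:
            continue
        mask = pd.Series(False, index=grp.index)
        for col in ("mean_position_error_deg", "mean_color_error_rad"):
            vals = grp[col]
            sd = vals.std(ddof=1)
            if sd == 0 or np.isnan(sd):
                logger.warning(
                    "zero-variance trimming population for %s; nothing trimmed", col
                )
                continue
            mask |= vals > vals.mean() + threshold_sd * sd
        outlier.loc[mask.index[mask]] = True

    df.loc[outlier, "excluded"] = True
    df.loc[outlier, "exclusion_reason"] = "outlier"

    report_rows = []
    for ss, grp in df.groupby("set_size"):
        per_subj = grp.groupby("subject_id").agg(
            n=("trial_id", "size"),
            n_collision=("collision", "sum"),
            n_outlier=("exclusion_reason", lambda s: (s == "outlier").sum()),
        )
        report_rows.append(
            {
                "set_size": ss,
                "n_trials": len(grp),
                "pct_collision": 100.0 * grp["collision"].mean(),
                "pct_outlier": 100.0 * (grp["exclusion_reason"] == "outlier").mean(),
                "mean_subject_pct_collision": float(
                    (100.0 * per_subj["n_collision"] / per_subj["n"]).mean()
                ),
                "mean_subject_pct_outlier": float(
                    (100.0 * per_subj["n_outlier"] / per_subj["n"]).mean()
                ),
                "mean_surviving_per_subject": float(
                    (per_subj["n"] - per_subj["n_collision"] - per_subj["n_outlier"]).mean()
                ),
            }
        )
    report = pd.DataFrame(report_rows)
    return df, report


def aggregate_subjects(trial_scores: pd.DataFrame) -> pd.DataFrame:
    """Per subject x set size aggregates over surviving (non-excluded) trials.

    Subjects with zero surviving trials at a set size get a row of missing
    values (and a logged warning) so downstream complete-case handling is
    explicit rather than silent.
    """
    df = trial_scores
    rows = []
    subjects = sorted(df["subject_id"].unique())
    set_sizes = sorted(df["set_size"].unique())
    for subj in subjects:
        for ss in set_sizes:
            cell = df[(df["subject_id"] == subj) & (df["set_size"] == ss)]
            keep = cell[~cell["excluded"]]
            if keep.empty:
                logger.warning(
                    "subject %s has no surviving trials at set size %s", subj, ss
                )
                rows.append(
                    {
                        "subject_id": subj,
                        "set_size": ss,
                        "mean_utilization": np.nan,
                        "mean_utilization_nonempty": np.nan,
                        "mean_position_error_deg": np.nan,
                        "mean_color_error_rad": np.nan,
                        "mean_view_time_ms": np.nan,
                        "n_trials": 0,
                    }
                )
                continue
            rows.append(
                {
                    "subject_id": subj,
                    "set_size": ss,
                    "mean_utilization": keep["utilization"].mean(),
                    "mean_utilization_nonempty": keep["utilization_nonempty"].mean(),
                    "mean_position_error_deg": keep["mean_position_error_deg"].mean(),
                    "mean_color_error_rad": keep["mean_color_error_rad"].mean(),
                    "mean_view_time_ms": keep["view_time_ms"].mean(),
                    "n_trials": len(keep),
                }
            )
    return pd.DataFrame(rows)
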