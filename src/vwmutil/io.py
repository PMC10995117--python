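"""CSV schemas, validation and dataset round-tripping.

Canonical interchange is CSV.  Three input tables:

* ``reconstruction_events.csv`` — subject_id, trial_id, set_size,
  event_index, event_type (view|place), x_deg, y_deg, hue_deg, t_ms.
  View rows carry no coordinates.
* ``target_models.csv`` — subject_id, trial_id, set_size, item_index,
  x_deg, y_deg, hue_deg (one row per model item).
* ``change_detection.csv`` — subject_id, trial_id, set_size, is_change,
  response (change|same), rt_ms.

``column_map`` renames foreign layouts (e.g. a public deposit of the real
data) onto these schemas without editing the files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import ReconstructionTrial, TrialEvent
from .stimuli import SquareItem, TargetModel

__all__ = [
    "ValidationError",
    "EVENT_COLUMNS",
    "MODEL_COLUMNS",
    "CD_COLUMNS",
    "validate_events",
    "validate_models",
    "validate_change_detection",
    "read_dataset",
    "write_dataset",
    "trials_from_frames",
]

EVENT_COLUMNS = [
    "subject_id", "trial_id", "set_size", "event_index",
    "event_type", "x_deg", "y_deg", "hue_deg", "t_ms",
]
MODEL_COLUMNS = [
    "subject_id", "trial_id", "set_size", "item_index", "x_deg", "y_deg", "hue_deg",
]
CD_COLUMNS = ["subject_id", "trial_id", "set_size", "is_change", "response", "rt_ms"]


class ValidationError(ValueError):
    """Raised when an input table violates its schema; the message lists the
    offending rows (0-based positions within the table)."""


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{table}: missing column(s) {missing}")


def validate_events(df: pd.DataFrame) -> pd.DataFrame:
    """Schema-check a reconstruction event table; returns it unchanged."""
    _require_columns(df, EVENT_COLUMNS, "reconstruction_events")
    bad_type = df.index[~df["event_type"].isin(["view", "place"])].tolist()
    if bad_type:
        vals = df.loc[bad_type, "event_type"].unique().tolist()
        raise ValidationError(
            f"reconstruction_events: unknown event_type {vals} at rows {bad_type[:10]}"
        )
    offenders = []
    for (subj, trial), grp in df.groupby(["subject_id", "trial_id"]):
        idx = grp["event_index"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            offenders.append((subj, trial))
        t = grp.sort_values("event_index")["t_ms"].to_numpy()
        if np.any(np.diff(t) <= 0):
            offenders.append((subj, trial))
    if offenders:
        raise ValidationError(
            "reconstruction_events: non-monotone event_index or t_ms in "
            f"trials {offenders[:10]}"
        )
    place = df[df["event_type"] == "place"]
    bad_place = place.index[place[["x_deg", "y_deg", "hue_deg"]].isna().any(axis=1)]
    if len(bad_place):
        raise ValidationError(
            f"reconstruction_events: place rows missing coordinates at rows "
            f"{bad_place.tolist()[:10]}"
        )
    return df


def validate_models(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, MODEL_COLUMNS, "target_models")
    bad = df.index[df[["x_deg", "y_deg", "hue_deg"]].isna().any(axis=1)].tolist()
    if bad:
        raise ValidationError(f"target_models: missing values at rows {bad[:10]}")
    counts = df.groupby(["subject_id", "trial_id"]).agg(
        n=("item_index", "size"), ss=("set_size", "first")
    )
    mismatched = counts.index[counts["n"] != counts["ss"]].tolist()
    if mismatched:
        raise ValidationError(
            f"target_models: item count != set_size for trials {mismatched[:10]}"
        )
    return df


def validate_change_detection(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, CD_COLUMNS, "change_detection")
    bad = df.index[~df["response"].isin(["change", "same"])].tolist()
    if bad:
        raise ValidationError(f"change_detection: invalid response at rows {bad[:10]}")
    bad_rt = df.index[~(df["rt_ms"] > 0)].tolist()
    if bad_rt:
        raise ValidationError(f"change_detection: non-positive rt_ms at rows {bad_rt[:10]}")
    return df


_VALIDATORS = {
    "reconstruction_events": validate_events,
    "target_models": validate_models,
    "change_detection": validate_change_detection,
}


def read_dataset(
    directory: str | Path,
    column_map: dict[str, dict[str, str]] | None = None,
    require: tuple[str, ...] = ("reconstruction_events", "target_models", "change_detection"),
) -> dict[str, pd.DataFrame]:
    """Read and validate the CSV tables of a dataset directory.

    ``column_map`` maps, per table, source column names to schema names
    (``{"change_detection": {"RT": "rt_ms", ...}}``) so foreign layouts can
    be ingested without rewriting files.
    """
    directory = Path(directory)
    column_map = column_map or {}
    out: dict[str, pd.DataFrame] = {}
    for table in require:
        path = directory / f"{table}.csv"
        if not path.exists():
            raise FileNotFoundError(f"required input {path} not found")
        df = pd.read_csv(path)
        if table in column_map:
            df = df.rename(columns=column_map[table])
        if table == "change_detection" and df["is_change"].dtype != bool:
            df["is_change"] = df["is_change"].astype(bool)
        out[table] = _VALIDATORS[table](df)
    truth = directory / "truth_params.csv"
    if truth.exists():
        out["truth_params"] = pd.read_csv(truth)
    return out


def write_dataset(dataset: dict[str, pd.DataFrame], directory: str | Path) -> None:
    """Write each table of a dataset as ``<name>.csv`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in dataset.items():
        df.to_csv(directory / f"{name}.csv", index=False)


def trials_from_frames(
    events: pd.DataFrame, models: pd.DataFrame
) -> list[ReconstructionTrial]:
    """Assemble :class:`ReconstructionTrial` objects from the two CSV tables."""
    validate_events(events)
    validate_models(models)
    model_groups = {
        key: grp.sort_values("item_index") for key, grp in models.groupby(["subject_id", "trial_id"])
    }
    trials = []
    for key, grp in events.groupby(["subject_id", "trial_id"]):
        if key not in model_groups:
            raise ValidationError(f"events for trial {key} have no target model")
        mg = model_groups[key]
        model = TargetModel(
            items=tuple(
                SquareItem(r.x_deg, r.y_deg, r.hue_deg) for r in mg.itertuples()
            ),
            set_size=int(mg["set_size"].iloc[0]),
        )
        evs = [
            TrialEvent(
                event_type=r.event_type,
                t_ms=float(r.t_ms),
                x_deg=None if r.event_type == "view" else float(r.x_deg),
                y_deg=None if r.event_type == "view" else float(r.y_deg),
                hue_deg=None if r.event_type == "view" else float(r.hue_deg),
            )
            for r in grp.sort_values("event_index").itertuples()
        ]
        trials.append(
            ReconstructionTrial(
                model=model, events=evs, subject_id=key[0], trial_id=key[1]
            )
        )
    return trials
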