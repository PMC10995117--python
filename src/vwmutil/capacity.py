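"""Change-detection scoring: RT trimming and Cowan's K.

The change-detection task briefly (200 ms) shows an array of N in {4, 8}
colored squares; after a 1000 ms retention interval a single probe appears
and the observer judges "same" vs "change".  Capacity is estimated per set
size with Cowan's K = N * (H - FA), where H is the hit rate (responding
"change" on change trials) and FA the false-alarm rate (responding "change"
on no-change trials); the subject's capacity is the mean K over the two set
sizes.  Guessing inflates H and FA equally, so it cancels in H - FA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ChangeDetectionTrial",
    "trim_rt",
    "cowans_k",
    "cowans_k_from_rates",
    "capacity_summary",
]

RESPONSES = ("change", "same")


@dataclass(frozen=True)
class ChangeDetectionTrial:
    set_size: int
    is_change: bool
    response: str  # "change" | "same"
    rt_ms: float

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if self.rt_ms <= 0:
            raise ValueError("rt_ms must be positive")


def trim_rt(
    trials: pd.DataFrame, threshold_sd: float = 3.0, per_subject: bool = True
) -> tuple[pd.DataFrame, pd.Series]:
    """Remove trials whose RT lies outside mean +/- ``threshold_sd`` * SD.

    Trimming pools all change-detection trials of a subject (both set sizes),
    in a single pass — it is not iterated to convergence, so re-running on
    the filtered output may remove further trials.  Zero RT variance trims
    nothing (warning logged).

    Returns the filtered frame and the number of removed trials per subject.
    """
    df = trials.copy()
    keys = ["subject_id"] if per_subject and "subject_id" in df else []

    def _keep(grp: pd.DataFrame) -> pd.Series:
        if len(grp) < 2:
            return pd.Series(True, index=grp.index)
        sd = grp["rt_ms"].std(ddof=1)
        if sd == 0 or np.isnan(sd):
            logger.warning("zero RT variance; no trials trimmed")
            return pd.Series(True, index=grp.index)
        m = grp["rt_ms"].mean()
        return (grp["rt_ms"] - m).abs() <= threshold_sd * sd

    keep = pd.Series(True, index=df.index)
    groups = df.groupby(keys[0]) if keys else [(None, df)]
    for _, grp in groups:
        keep.loc[grp.index] = _keep(grp)
    removed = df[~keep]
    if keys:
        n_removed = removed.groupby("subject_id").size().reindex(
            df["subject_id"].unique(), fill_value=0
        )
    else:
        n_removed = pd.Series({0: len(removed)})
    return df[keep], n_removed


def cowans_k_from_rates(n: int, hit_rate: float, fa_rate: float) -> float:
    """K = N * (H - FA)."""
    return n * (hit_rate - fa_rate)


def cowans_k(trials: pd.DataFrame) -> dict:
    """Hit/false-alarm rates and K per set size for one subject's trials.

    Requires both change and no-change trials at every set size present;
    a missing cell raises with the subject and cell named.  Returns a dict
    with per-set-size ``h``, ``fa``, ``k`` and the across-set-size ``mean_k``.
    """
    subj = trials["subject_id"].iloc[0] if "subject_id" in trials else "?"
    out: dict = {"per_set_size": {}}
    ks = []
    for n, grp in trials.groupby("set_size"):
        change = grp[grp["is_change"]]
        same = grp[~grp["is_change"]]
        if change.empty or same.empty:
            missing = "change" if change.empty else "no-change"
            raise ValueError(
                f"subject {subj}: no {missing} trials at set size {n}"
            )
        h = (change["response"] == "change").mean()
        fa = (same["response"] == "change").mean()
        k = cowans_k_from_rates(int(n), float(h), float(fa))
        out["per_set_size"][int(n)] = {"h": float(h), "fa": float(fa), "k": k}
        ks.append(k)
    out["mean_k"] = float(np.mean(ks))
    return out


def capacity_summary(
    trials: pd.DataFrame,
    rt_threshold_sd: float = 3.0,
    exclude_negative_k: bool = True,
    negative_k_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-subject capacity table from raw change-detection trials.

    RT trimming runs first (per subject, pooled over set sizes); K is then
    computed per set size and averaged.  Subjects whose mean K falls below
    ``negative_k_threshold`` are flagged (``excluded`` column) when
    ``exclude_negative_k`` is on — a negative capacity estimate indicates the
    observer performed below chance and the estimate is uninterpretable.
    """
    trimmed, n_removed = trim_rt(trials, rt_threshold_sd)
    rows = []
    for subj, grp in trimmed.groupby("subject_id"):
        summ = cowans_k(grp)
        row = {"subject_id": subj}
        for n, cell in summ["per_set_size"].items():
            row[f"h_ss{n}"] = cell["h"]
            row[f"fa_ss{n}"] = cell["fa"]
            row[f"k_ss{n}"] = cell["k"]
        row["mean_k"] = summ["mean_k"]
        row["n_trimmed"] = int(n_removed.get(subj, 0))
        row["excluded"] = bool(
            exclude_negative_k and summ["mean_k"] < negative_k_threshold
        )
        rows.append(row)
    return pd.DataFrame(rows)
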