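"""Inferential layer: reliability, within-subject CIs, repeated-measures
ANOVA with paired contrasts, and Bonferroni-corrected correlation matrices.

Everything here consumes the subject-level tables produced by
:mod:`vwmutil.scoring` and :mod:`vwmutil.capacity` (or the trial-level
scores, for split-half reliability) and produces :class:`StatResult`
records that serialize to JSON.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "StatResult",
    "spearman_brown",
    "split_half_reliability",
    "split_half_reliability_k",
    "reliability_table",
    "within_subject_ci",
    "rm_anova",
    "paired_contrast",
    "correlation_matrix",
]


@dataclass
class StatResult:
    """One inferential result (F, t or r) with df, effect size and p-values."""

    name: str
    statistic: str
    value: float
    df: float | None = None
    df2: float | None = None
    eta_sq: float | None = None
    p: float | None = None
    p_adjusted: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "statistic": self.statistic,
            "value": self.value,
            "df": self.df,
            "df2": self.df2,
            "eta_sq": self.eta_sq,
            "p": self.p,
            "p_adjusted": self.p_adjusted,
        }
        d.update(self.extra)
        return d


def spearman_brown(r: float) -> float:
    """Step-up a half-test correlation to full length: 2r / (1 + r)."""
    return 2.0 * r / (1.0 + r)


def _half_means(
    trials: pd.DataFrame, value_col: str, first_n: int | None = None
) -> pd.DataFrame:
    """Per-subject means over odd- vs even-positioned trials.

    Position is 1-based within each subject's (already filtered and
    exclusion-screened) trial sequence, in log order; ``first_n`` keeps only
    the first n trials of the sequence before splitting.
    """
    rows = []
    for subj, grp in trials.groupby("subject_id"):
        vals = grp[value_col].to_numpy()
        if first_n is not None:
            vals = vals[:first_n]
        odd, even = vals[0::2], vals[1::2]  # positions 1,3,.. and 2,4,..
        if len(odd) == 0 or len(even) == 0:
            continue
        rows.append(
            {"subject_id": subj, "odd": float(np.mean(odd)), "even": float(np.mean(even))}
        )
    return pd.DataFrame(rows)


def split_half_reliability(
    trials: pd.DataFrame, value_col: str, first_n: int | None = None
) -> float:
    """Spearman-Brown corrected odd/even split-half reliability.

    ``trials`` holds one subject's measure per row, in sequence order (one
    set size at a time — callers filter).  Per subject, means are taken over
    odd- and even-positioned trials; the halves are correlated (Pearson)
    across subjects and stepped up with Spearman-Brown.  Returns NaN when
    either half has zero variance (reliability undefined).
    """
    halves = _half_means(trials, value_col, first_n)
    if len(halves) < 3:
        raise ValueError("split-half reliability needs at least 3 subjects")
    if halves["odd"].std(ddof=1) == 0 or halves["even"].std(ddof=1) == 0:
        return math.nan
    r = float(np.corrcoef(halves["odd"], halves["even"])[0, 1])
    return spearman_brown(r)


def split_half_reliability_k(cd_trials: pd.DataFrame) -> float:
    """Split-half reliability of Cowan's mean K: per subject, K is computed
    separately on odd- and even-positioned change-detection trials (split
    within each set size x change cell so every half retains both trial
    types), then correlated across subjects and Spearman-Brown corrected."""
    from .capacity import cowans_k

    rows = []
    for subj, grp in cd_trials.groupby("subject_id"):
        halves = {"odd": [], "even": []}
        for _, cell in grp.groupby(["set_size", "is_change"]):
            halves["odd"].append(cell.iloc[0::2])
            halves["even"].append(cell.iloc[1::2])
        ks = {}
        for half, parts in halves.items():
            sub = pd.concat(parts)
            ks[half] = cowans_k(sub)["mean_k"]
        rows.append({"subject_id": subj, "odd": ks["odd"], "even": ks["even"]})
    halves_df = pd.DataFrame(rows)
    if len(halves_df) < 3:
        raise ValueError("split-half reliability needs at least 3 subjects")
    if halves_df["odd"].std(ddof=1) == 0 or halves_df["even"].std(ddof=1) == 0:
        return math.nan
    r = float(np.corrcoef(halves_df["odd"], halves_df["even"])[0, 1])
    return spearman_brown(r)


def reliability_table(
    trial_scores: pd.DataFrame,
    measures: dict[str, str] | None = None,
    first_n: int | None = 15,
) -> pd.DataFrame:
    """Split-half reliabilities per measure x set size, over all surviving
    trials and (optionally) over only the first ``first_n`` trials per set
    size — mirroring the usual check that a shortened task stays reliable."""
    measures = measures or {
        "utilization": "utilization",
        "color_error": "mean_color_error_rad",
        "position_error": "mean_position_error_deg",
    }
    surviving = trial_scores[~trial_scores["excluded"]]
    rows = []
    for ss, grp in surviving.groupby("set_size"):
        for label, col in measures.items():
            row = {
                "set_size": ss,
                "measure": label,
                "r_sb_all": split_half_reliability(grp, col),
            }
            if first_n is not None:
                row[f"r_sb_first{first_n}"] = split_half_reliability(grp, col, first_n)
            rows.append(row)
    return pd.DataFrame(rows)


def within_subject_ci(
    matrix: pd.DataFrame, level: float = 0.95
) -> pd.DataFrame:
    """Within-subject confidence intervals per condition.

    ``matrix`` is wide: one row per subject, one column per condition;
    incomplete rows are dropped (complete cases).  Each cell is Cousineau-
    normalized (cell - subject mean + grand mean), the half-widths use the
    Morey correction sqrt(C / (C - 1)) and a t critical value with n - 1 df.
    Returns per-condition mean, CI half-width and bounds.
    """
    m = matrix.dropna()
    n, c = m.shape
    if c < 2:
        raise ValueError("within-subject CI needs at least 2 conditions")
    if n < 2:
        raise ValueError("within-subject CI needs at least 2 subjects")
    normalized = m.sub(m.mean(axis=1), axis=0) + m.to_numpy().mean()
    morey = math.sqrt(c / (c - 1))
    tcrit = sps.t.ppf(0.5 + level / 2.0, n - 1)
    sem = normalized.std(ddof=1) / math.sqrt(n)
    half = morey * tcrit * sem
    means = m.mean()
    return pd.DataFrame(
        {
            "mean": means,
            "ci_half_width": half,
            "ci_low": means - half,
            "ci_high": means + half,
            "n": n,
        }
    )


def rm_anova(
    matrix: pd.DataFrame, eta_sq: str = "partial", name: str = "rm_anova"
) -> StatResult:
    """One-way repeated-measures ANOVA over a wide subject x condition matrix.

    Complete cases only; df = (C-1, (C-1)(n-1)).  ``eta_sq`` selects partial
    (SS_effect / (SS_effect + SS_error), the default) or classical
    (SS_effect / SS_total) effect size.  A degenerate all-equal matrix (zero
    effect and error SS) is reported as F = 0, p = 1.
    """
    m = matrix.dropna()
    n, c = m.shape
    if n < 3:
        raise ValueError("repeated-measures ANOVA needs at least 3 subjects")
    if c < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 conditions")
    if eta_sq not in ("partial", "classical"):
        raise ValueError("eta_sq must be 'partial' or 'classical'")

    long = m.reset_index(names="subject").melt(
        id_vars="subject", var_name="condition", value_name="y"
    )
    arr = m.to_numpy(dtype=float)
    grand = arr.mean()
    ss_effect = n * float(((arr.mean(axis=0) - grand) ** 2).sum())
    ss_subject = c * float(((arr.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((arr - grand) ** 2).sum())
    ss_error = ss_total - ss_effect - ss_subject
    df1, df2 = c - 1, (c - 1) * (n - 1)

    if ss_effect == 0 and ss_error == 0:
        return StatResult(name, "F", 0.0, df1, df2, 0.0, 1.0)

    aov = pg.rm_anova(data=long, dv="y", within="condition", subject="subject")
    row = aov.iloc[0]
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    f_val, p_val = float(row["F"]), float(row[p_col])
    if eta_sq == "partial":
        es = ss_effect / (ss_effect + ss_error)
    else:
        es = ss_effect / ss_total
    return StatResult(
        name, "F", f_val, float(df1), float(df2), float(es), p_val,
        extra={"eta_sq_type": eta_sq},
    )


def paired_contrast(
    a: pd.Series, b: pd.Series, name: str = "contrast"
) -> StatResult:
    """Paired t-test between two condition vectors (complete cases), with
    eta squared t^2 / (t^2 + df) as effect size."""
    paired = pd.concat([a, b], axis=1).dropna()
    x, y = paired.iloc[:, 0], paired.iloc[:, 1]
    if len(paired) < 2:
        raise ValueError("paired contrast needs at least 2 complete cases")
    t, p = sps.ttest_rel(x, y)
    df = len(paired) - 1
    eta = float(t**2 / (t**2 + df)) if not math.isnan(t) else math.nan
    return StatResult(name, "t", float(t), float(df), None, eta, float(p))


def anova_with_contrasts(
    matrix: pd.DataFrame,
    eta_sq: str = "partial",
    contrast_scheme: str = "ss1_vs_mean",
    name: str = "utilization",
) -> list[StatResult]:
    """Omnibus RM-ANOVA plus the standard contrast pair for a three-set-size
    design: the smallest set size against the larger two (averaged within
    subject, or each separately under ``pairwise`` scheme), then the two
    larger set sizes against each other."""
    if contrast_scheme not in ("ss1_vs_mean", "pairwise"):
        raise ValueError("contrast_scheme must be 'ss1_vs_mean' or 'pairwise'")
    cols = list(matrix.columns)
    results = [rm_anova(matrix, eta_sq, name=f"{name}_anova")]
    if len(cols) == 3:
        c0, c1, c2 = cols
        if contrast_scheme == "ss1_vs_mean":
            rest = matrix[[c1, c2]].mean(axis=1)
            results.append(
                paired_contrast(matrix[c0], rest, name=f"{name}_{c0}_vs_rest")
            )
        else:
            results.append(
                paired_contrast(matrix[c0], matrix[c1], name=f"{name}_{c0}_vs_{c1}")
            )
            results.append(
                paired_contrast(matrix[c0], matrix[c2], name=f"{name}_{c0}_vs_{c2}")
            )
        results.append(
            paired_contrast(matrix[c1], matrix[c2], name=f"{name}_{c1}_vs_{c2}")
        )
    return results


def correlation_matrix(
    subject_table: pd.DataFrame,
    columns: list[str] | None = None,
    reliabilities: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, list[StatResult]]:
    """Pearson correlations between per-subject measures.

    P-values are Bonferroni-adjusted over the number of off-diagonal pairs.
    The returned matrix carries r off the diagonal and, when supplied, the
    split-half reliability of each measure on the diagonal.  Columns with
    zero variance yield missing correlations.
    """
    columns = columns or list(subject_table.columns)
    if len(subject_table.dropna(subset=columns)) < 4:
        raise ValueError("correlation matrix needs at least 4 complete cases")
    tbl = subject_table[columns].dropna()
    pairs = list(combinations(columns, 2))
    m = len(pairs)
    mat = pd.DataFrame(np.nan, index=columns, columns=columns)
    results = []
    for a, b in pairs:
        if tbl[a].std(ddof=1) == 0 or tbl[b].std(ddof=1) == 0:
            r, p = math.nan, math.nan
        else:
            r, p = sps.pearsonr(tbl[a], tbl[b])
        p_adj = min(1.0, p * m) if not math.isnan(p) else math.nan
        mat.loc[a, b] = mat.loc[b, a] = r
        results.append(
            StatResult(
                f"corr_{a}_x_{b}", "r", float(r), float(len(tbl) - 2),
                p=float(p), p_adjusted=float(p_adj),
                extra={"n": int(len(tbl)), "n_comparisons": m},
            )
        )
    if reliabilities:
        for c in columns:
            if c in reliabilities:
                mat.loc[c, c] = reliabilities[c]
    return mat, results
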