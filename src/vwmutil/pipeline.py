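"""End-to-end pipeline: simulate (or ingest) → score → capacity → stats.

Given a :class:`~vwmutil.config.RunConfig`, :func:`run_pipeline` produces
every output table (trial scores, subject summaries, exclusion report,
capacity summary) plus ``stats_report.json`` with the full inferential
layer, deterministically for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import capacity as cap
from . import io as vio
from . import scoring, simulate, stats
from .config import RunConfig
from .stimuli import GeometryConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "simulate_stage", "score_stage", "capacity_stage", "stats_stage"]


def _geometry(config: RunConfig) -> GeometryConfig:
    g = config.geometry
    return GeometryConfig(
        frame_deg=g.frame_deg, square_deg=g.square_deg,
        min_gap_deg=g.min_gap_deg, ppd=g.ppd,
    )


def simulate_stage(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Generate a synthetic cohort according to the config's design."""
    s = config.simulate
    design = simulate.CohortDesign(
        recon_set_sizes=tuple(s.recon_set_sizes),
        trials_per_set_size=s.trials_per_set_size,
        cd_set_sizes=tuple(s.cd_set_sizes),
        cd_trials=s.cd_trials,
    )
    return simulate.simulate_cohort(
        n_subjects=s.n_subjects,
        rng=np.random.default_rng(config.seed),
        design=design,
        param_distributions=s.param_distributions,
        strategy=simulate.StrategyVariant(name=s.strategy),
        geometry=_geometry(config),
    )


def score_stage(
    dataset: dict[str, pd.DataFrame], config: RunConfig
) -> dict[str, pd.DataFrame]:
    """Score reconstruction trials: matching, errors, exclusions, aggregates."""
    trials = vio.trials_from_frames(
        dataset["reconstruction_events"], dataset["target_models"]
    )
    trial_scores, exclusion_report = scoring.score_dataset(
        trials,
        circular_color=config.scoring.circular_color,
        threshold_sd=config.scoring.threshold_sd,
        trim_population=config.scoring.trim_population,
    )
    subject_summary = scoring.aggregate_subjects(trial_scores)
    return {
        "trial_scores": trial_scores,
        "exclusion_report": exclusion_report,
        "subject_summary": subject_summary,
    }


def capacity_stage(
    dataset: dict[str, pd.DataFrame], config: RunConfig
) -> pd.DataFrame:
    c = config.capacity
    return cap.capacity_summary(
        dataset["change_detection"],
        rt_threshold_sd=c.rt_threshold_sd,
        exclude_negative_k=c.exclude_negative_k,
        negative_k_threshold=c.negative_k_threshold,
    )


def _wide(subject_summary: pd.DataFrame, col: str) -> pd.DataFrame:
    w = subject_summary.pivot(index="subject_id", columns="set_size", values=col)
    return w.rename(columns=lambda ss: f"ss{ss}")


def stats_stage(
    scored: dict[str, pd.DataFrame],
    capacity_summary: pd.DataFrame,
    dataset: dict[str, pd.DataFrame],
    config: RunConfig,
) -> dict:
    """The inferential layer: ANOVAs with contrasts, within-subject CIs,
    reliabilities and the capacity/utilization/accuracy correlation matrix
    (largest set size only, where between-subject variation is greatest)."""
    st = config.stats
    summary = scored["subject_summary"]
    trial_scores = scored["trial_scores"]
    results: dict = {}

    measures = {
        "utilization": "mean_utilization",
        "utilization_nonempty": "mean_utilization_nonempty",
        "position_error": "mean_position_error_deg",
        "color_error": "mean_color_error_rad",
        "view_time": "mean_view_time_ms",
    }
    for label, col in measures.items():
        wide = _wide(summary, col)
        for res in stats.anova_with_contrasts(
            wide, eta_sq=st.eta_sq, contrast_scheme=st.contrast_scheme, name=label
        ):
            results[res.name] = res.to_dict()
        ci = stats.within_subject_ci(wide, st.ci_level)
        results[f"{label}_ci"] = {
            "condition_means": ci["mean"].to_dict(),
            "ci_half_width": ci["ci_half_width"].to_dict(),
            "n": int(ci["n"].iloc[0]),
        }

    rel = stats.reliability_table(trial_scores, first_n=st.reliability_first_n)
    results["reliability_table"] = rel.to_dict(orient="records")

    kept = capacity_summary[~capacity_summary["excluded"]]
    results["capacity"] = {
        "mean_k": float(kept["mean_k"].mean()),
        "sd_k": float(kept["mean_k"].std(ddof=1)),
        "n_subjects": int(len(kept)),
        "n_excluded_negative_k": int(capacity_summary["excluded"].sum()),
        "split_half_reliability": stats.split_half_reliability_k(
            dataset["change_detection"][
                dataset["change_detection"]["subject_id"].isin(kept["subject_id"])
            ]
        ),
    }

    # Correlations at the largest reconstruction set size.
    ss_max = int(summary["set_size"].max())
    at_max = summary[summary["set_size"] == ss_max].set_index("subject_id")
    table = pd.DataFrame(
        {
            "capacity_k": kept.set_index("subject_id")["mean_k"],
            "utilization": at_max["mean_utilization"],
            "position_error": at_max["mean_position_error_deg"],
            "color_error": at_max["mean_color_error_rad"],
        }
    ).dropna()
    rel_max = rel[rel["set_size"] == ss_max].set_index("measure")["r_sb_all"]
    diagonal = {
        "capacity_k": results["capacity"]["split_half_reliability"],
        "utilization": float(rel_max.get("utilization", np.nan)),
        "position_error": float(rel_max.get("position_error", np.nan)),
        "color_error": float(rel_max.get("color_error", np.nan)),
    }
    mat, corr_results = stats.correlation_matrix(
        table, list(table.columns), reliabilities=diagonal
    )
    results["correlation_set_size"] = ss_max
    results["correlation_matrix"] = mat.round(6).to_dict()
    for res in corr_results:
        results[res.name] = res.to_dict()
    return results


def _plain_report(results: dict) -> str:
    lines = ["VWM utilization pipeline report", "=" * 34, ""]
    capn = results["capacity"]
    lines.append(
        f"Change detection: mean K = {capn['mean_k']:.3f} "
        f"(SD {capn['sd_k']:.3f}, n = {capn['n_subjects']}), "
        f"split-half reliability = {capn['split_half_reliability']:.3f}"
    )
    for variant in ("utilization", "utilization_nonempty"):
        ci = results[f"{variant}_ci"]
        means = ", ".join(
            f"{k}: {v:.3f} ± {ci['ci_half_width'][k]:.3f}"
            for k, v in ci["condition_means"].items()
        )
        aov = results[f"{variant}_anova"]
        lines.append(
            f"{variant} (mean ± 95% within-subject CI): {means}; "
            f"F({aov['df']:.0f}, {aov['df2']:.0f}) = {aov['value']:.2f}, "
            f"p = {aov['p']:.4g}, eta_sq = {aov['eta_sq']:.2f}"
        )
    lines.append("")
    lines.append("Reliability (Spearman-Brown corrected split-half):")
    for row in results["reliability_table"]:
        extra = [f"{k} = {v:.3f}" for k, v in row.items() if k.startswith("r_sb_first")]
        lines.append(
            f"  SS{row['set_size']} {row['measure']}: all trials = "
            f"{row['r_sb_all']:.3f}" + ("; " + "; ".join(extra) if extra else "")
        )
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage and write all outputs under ``out_dir``.

    If ``config.io.data_dir`` is set, the dataset is read (and validated)
    from there; otherwise a synthetic cohort is generated with the config's
    seed.  Returns a dict with the dataset, all derived tables and the stats
    results.
    """
    out_dir = Path(out_dir if out_dir is not None else config.io.out_dir)

    if config.io.data_dir:
        dataset = vio.read_dataset(config.io.data_dir, config.io.column_map)
        logger.info("loaded dataset from %s", config.io.data_dir)
    else:
        dataset = simulate_stage(config)
        logger.info("simulated cohort of %d subjects", config.simulate.n_subjects)

    scored = score_stage(dataset, config)
    n_excl = scored["trial_scores"]["excluded"].sum()
    logger.info(
        "scored %d trials, excluded %d (%s)",
        len(scored["trial_scores"]), n_excl,
        scored["trial_scores"].loc[
            scored["trial_scores"]["excluded"], "exclusion_reason"
        ].value_counts().to_dict(),
    )
    capacity_summary = capacity_stage(dataset, config)
    logger.info(
        "capacity: %d subjects, %d flagged for negative K",
        len(capacity_summary), capacity_summary["excluded"].sum(),
    )
    results = stats_stage(scored, capacity_summary, dataset, config)

    out_dir.mkdir(parents=True, exist_ok=True)
    vio.write_dataset(dataset, out_dir)
    scored["trial_scores"].to_csv(out_dir / "trial_scores.csv", index=False)
    scored["subject_summary"].to_csv(out_dir / "subject_summary.csv", index=False)
    scored["exclusion_report"].to_csv(out_dir / "exclusion_report.csv", index=False)
    capacity_summary.to_csv(out_dir / "capacity_summary.csv", index=False)
    with open(out_dir / "stats_report.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=float)
    (out_dir / "report.txt").write_text(_plain_report(results))
    if config.io.figures:
        from .plots import save_figures

        save_figures(scored, results, out_dir)

    return {
        "dataset": dataset,
        **scored,
        "capacity_summary": capacity_summary,
        "stats": results,
    }
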