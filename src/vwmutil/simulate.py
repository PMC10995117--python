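"""Synthetic observers for the reconstruction and change-detection tasks.

Real data for these tasks come from humans; the simulator exists so every
scoring and statistics path can be validated by *parameter recovery*: agents
are generated with known capacity, utilization and noise parameters, their
event logs are scored with the same pipeline used for human logs, and the
recovered quantities are checked against the ground truth.

The generative model is deliberately minimal and standard:

* Reconstruction: per model view the agent encodes up to ``utilization_u``
  not-yet-placed items and places each with isotropic Gaussian position noise
  (``sigma_pos_deg``) and von Mises hue noise (concentration
  ``kappa_color``).  With probability ``p_empty_review`` a view is followed
  by another view with zero placements in between (observers sometimes
  return to the model without placing anything — this is what pulls measured
  utilization at set size 1 below 1).  Non-integer ``utilization_u`` is
  realised by stochastic rounding of the per-view encoded count.
* Change detection: a slot model.  The probed item is in memory with
  probability min(capacity_k / N, 1); if so the response is correct,
  otherwise the agent responds "change" with probability
  ``guess_change_rate``.  Cowan's K recovers ``capacity_k`` in expectation
  because guessing cancels in H - FA.
* RTs and viewing durations are log-normal; they exist so the RT-trimming
  and viewing-time analysis paths are exercised, and model no psychology.

Three strategy variants formalise, as generative options, informal accounts
of why observers under-utilize memory; they are labeled formalizations, not
fitted models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import ReconstructionTrial, TrialEvent
from .stimuli import GeometryConfig, TargetModel, build_palette, generate_target_model

__all__ = [
    "AgentParams",
    "StrategyVariant",
    "CohortDesign",
    "CHANGE_DETECTION_COLORS",
    "simulate_reconstruction_trial",
    "simulate_change_detection_trial",
    "simulate_change_detection_block",
    "simulate_cohort",
    "sample_params",
    "DEFAULT_PARAM_DISTRIBUTIONS",
]

#: Probe/array colors of the change-detection task, as (name, RGB).  The task
#: description announces "eight highly distinguishable colors" but then lists
#: these nine names and nine RGB triplets; the nine listed values are carried
#: here verbatim.
CHANGE_DETECTION_COLORS: tuple[tuple[str, tuple[int, int, int]], ...] = (
    ("black", (0, 0, 0)),
    ("blue", (68, 114, 196)),
    ("brown", (128, 64, 0)),
    ("cyan", (0, 255, 255)),
    ("green", (0, 176, 80)),
    ("magenta", (255, 0, 254)),
    ("orange", (255, 128, 65)),
    ("red", (254, 0, 0)),
    ("yellow", (255, 255, 0)),
)


@dataclass(frozen=True)
class AgentParams:
    """Ground-truth parameters of one synthetic observer.

    capacity_k
        Slot capacity (items) driving change-detection performance.
    utilization_u
        Items encoded per model view in reconstruction; may be smaller than
        capacity (the paradigm's central phenomenon).  Non-integer values
        are realised by stochastic rounding per view.
    sigma_pos_deg
        SD of isotropic 2-D placement noise, degrees of visual angle.
    kappa_color
        Von Mises concentration of hue-report noise (infinite = noiseless).
    p_empty_review
        Probability that a view is followed by another view with nothing
        placed in between.
    guess_change_rate
        P(respond "change") when the probed item is not in memory.
    """

    capacity_k: float = 2.8
    utilization_u: float = 1.5
    sigma_pos_deg: float = 0.5
    kappa_color: float = 8.0
    p_empty_review: float = 0.05
    guess_change_rate: float = 0.5

    def __post_init__(self) -> None:
        if not self.capacity_k >= self.utilization_u >= 0:
            raise ValueError("need capacity_k >= utilization_u >= 0")
        if self.sigma_pos_deg < 0 or self.kappa_color < 0:
            raise ValueError("noise parameters must be >= 0")
        for p in (self.p_empty_review, self.guess_change_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


STRATEGY_NAMES = (
    "fixed_utilization",
    "item_selection",
    "narrow_resource",
    "partial_report",
)


@dataclass(frozen=True)
class StrategyVariant:
    """Generative strategy of a synthetic observer.

    ``fixed_utilization`` is the baseline: encode ``utilization_u`` fresh
    items per view, all at the same precision.  The other three formalise
    informal accounts of under-utilization:

    * ``item_selection`` — encode only ``utilization_u`` items per view but
      at full precision (``kappa_high``); unencoded items are simply absent
      until a later view (a discrete-slot reading).
    * ``narrow_resource`` — encode *all* items in one view with unevenly
      split precision: one item at ``kappa_high``, the rest at
      ``kappa_low`` (a continuous-resource reading).
    * ``partial_report`` — encode all items in one view, but place only the
      ``utilization_u`` currently most precise per view, re-viewing before
      reporting the remainder (a retrieval-stage reading).
    """

    name: str = "fixed_utilization"
    kappa_high: float = 50.0
    kappa_low: float = 2.0

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {self.name!r}")
        if self.kappa_high < 0 or self.kappa_low < 0:
            raise ValueError("kappa parameters must be >= 0")


def _stochastic_round(u: float, rng: np.random.Generator) -> int:
    lo = math.floor(u)
    frac = u - lo
    return lo + (1 if frac > 0 and rng.random() < frac else 0)


def _vonmises_noise(kappa: float, rng: np.random.Generator) -> float:
    """Hue perturbation in degrees; kappa = inf means noiseless."""
    if math.isinf(kappa):
        return 0.0
    if kappa == 0:
        return math.degrees(rng.uniform(-math.pi, math.pi))
    return math.degrees(rng.vonmises(0.0, kappa))


@dataclass(frozen=True)
class _Timing:
    """Log-normal event-timing parameters (ms); purely to exercise
    timestamp-dependent code paths (viewing-time analysis, monotonicity)."""

    view_mu: float = 8.1  # median ~3300 ms model viewing
    view_sigma: float = 0.3
    place_mu: float = 7.0  # median ~1100 ms per placement
    place_sigma: float = 0.4
    first_view_ms: float | None = None  # fixed brief exposure variant


def simulate_reconstruction_trial(
    agent: AgentParams,
    model: TargetModel,
    rng: np.random.Generator,
    strategy: StrategyVariant | None = None,
    geometry: GeometryConfig | None = None,
    timing: _Timing | None = None,
    subject_id: int = 0,
    trial_id: int = 0,
) -> ReconstructionTrial:
    """Generate one reconstruction event log.

    The log starts with a view event and ends when all items are placed;
    timestamps are strictly increasing.  In the noiseless limit (sigma 0,
    kappa infinite) every placement coincides exactly with a distinct model
    item, so scored errors are zero.
    """
    if agent.utilization_u <= 0:
        raise ValueError("reconstruction requires utilization_u > 0")
    if agent.p_empty_review >= 1.0:
        raise ValueError("p_empty_review must be < 1 or the trial never ends")
    strategy = strategy or StrategyVariant()
    geometry = geometry or GeometryConfig()
    timing = timing or _Timing()
    half = geometry.frame_deg / 2.0

    # Per-item hue-noise concentration by strategy.
    n = model.set_size
    if strategy.name in ("narrow_resource", "partial_report"):
        kappas = [strategy.kappa_high] + [strategy.kappa_low] * (n - 1)
        order = list(rng.permutation(n))
        item_kappa = {idx: k for idx, k in zip(order, kappas)}
    elif strategy.name == "item_selection":
        item_kappa = {i: strategy.kappa_high for i in range(n)}
    else:
        item_kappa = {i: agent.kappa_color for i in range(n)}

    # Items placed per view; narrow_resource reports everything at once.
    def n_to_place(remaining: int) -> int:
        if strategy.name == "narrow_resource":
            return remaining
        return max(1, min(_stochastic_round(agent.utilization_u, rng), remaining))

    # partial_report places the most precise remaining items first.
    if strategy.name == "partial_report":
        remaining = sorted(range(n), key=lambda i: -item_kappa[i])
    else:
        remaining = list(rng.permutation(n))

    events: list[TrialEvent] = []
    t = 0.0

    def emit_view() -> None:
        nonlocal t
        events.append(TrialEvent(event_type="view", t_ms=t))
        if timing.first_view_ms is not None and len(events) == 1:
            dur = timing.first_view_ms
        else:
            dur = rng.lognormal(timing.view_mu, timing.view_sigma)
        t += dur

    emit_view()
    while remaining:
        if rng.random() < agent.p_empty_review:
            emit_view()  # empty review: nothing placed since the last view
            continue
        for idx in remaining[: n_to_place(len(remaining))]:
            item = model.items[idx]
            x = item.x_deg + rng.normal(0.0, agent.sigma_pos_deg)
            y = item.y_deg + rng.normal(0.0, agent.sigma_pos_deg)
            hue = (item.hue_deg + _vonmises_noise(item_kappa[idx], rng)) % 360.0
            events.append(
                TrialEvent(
                    event_type="place",
                    t_ms=t,
                    x_deg=float(np.clip(x, -half, half)),
                    y_deg=float(np.clip(y, -half, half)),
                    hue_deg=float(hue),
                )
            )
            t += rng.lognormal(timing.place_mu, timing.place_sigma)
            remaining.remove(idx)
        if remaining:
            emit_view()

    return ReconstructionTrial(
        model=model, events=events, subject_id=subject_id, trial_id=trial_id
    )


def simulate_change_detection_trial(
    agent: AgentParams,
    n: int,
    is_change: bool,
    rng: np.random.Generator,
    rt_mu: float = 6.3,
    rt_sigma: float = 0.3,
) -> dict:
    """One slot-model change-detection trial.

    The probed item is in memory with probability min(capacity_k / n, 1);
    if in memory the response is correct, otherwise "change" is guessed with
    probability ``guess_change_rate``.  RT is log-normal (ms).
    """
    in_memory = rng.random() < min(agent.capacity_k / n, 1.0)
    if in_memory:
        response = "change" if is_change else "same"
    else:
        response = "change" if rng.random() < agent.guess_change_rate else "same"
    return {
        "set_size": n,
        "is_change": is_change,
        "response": response,
        "rt_ms": float(rng.lognormal(rt_mu, rt_sigma)),
    }


def simulate_change_detection_block(
    agent: AgentParams,
    rng: np.random.Generator,
    n_trials: int = 150,
    set_sizes: tuple[int, ...] = (4, 8),
    subject_id: int = 0,
) -> pd.DataFrame:
    """A full change-detection block: trials split evenly over set sizes,
    half change / half no-change within each, in shuffled order."""
    cells = []
    per_ss = n_trials // len(set_sizes)
    for n in set_sizes:
        n_change = per_ss // 2
        cells += [(n, True)] * n_change + [(n, False)] * (per_ss - n_change)
    rng.shuffle(cells)
    rows = []
    for trial_id, (n, is_change) in enumerate(cells):
        row = simulate_change_detection_trial(agent, n, is_change, rng)
        row.update(subject_id=subject_id, trial_id=trial_id)
        rows.append(row)
    return pd.DataFrame(rows)[
        ["subject_id", "trial_id", "set_size", "is_change", "response", "rt_ms"]
    ]


#: Default per-parameter sampling specs for a cohort.  Capacity centers near
#: 2.8 items with SD 0.9 (typical of change-detection studies) and measured
#: utilization comes out in the 1-2 items/view range.
DEFAULT_PARAM_DISTRIBUTIONS: dict[str, dict] = {
    "capacity_k": {"dist": "truncnorm", "mean": 2.8, "sd": 0.9, "low": 0.5, "high": 6.0},
    "utilization_u": {"dist": "truncnorm", "mean": 1.5, "sd": 0.7, "low": 1.0, "high": 4.0},
    "sigma_pos_deg": {"dist": "truncnorm", "mean": 0.5, "sd": 0.15, "low": 0.15, "high": 1.2},
    "kappa_color": {"dist": "truncnorm", "mean": 8.0, "sd": 3.0, "low": 2.0, "high": 20.0},
    "p_empty_review": {"dist": "constant", "value": 0.05},
    "guess_change_rate": {"dist": "constant", "value": 0.5},
}


def _sample_one(spec: dict, rng: np.random.Generator) -> float:
    if not isinstance(spec, dict) or "dist" not in spec:
        raise ValueError(f"invalid distribution spec: {spec!r}")
    kind = spec["dist"]
    if kind == "constant":
        return float(spec["value"])
    if kind == "uniform":
        return float(rng.uniform(spec["low"], spec["high"]))
    if kind == "normal":
        return float(rng.normal(spec["mean"], spec["sd"]))
    if kind == "truncnorm":
        lo, hi = spec["low"], spec["high"]
        for _ in range(1000):
            x = rng.normal(spec["mean"], spec["sd"])
            if lo <= x <= hi:
                return float(x)
        raise ValueError(f"truncnorm rejection failed for spec {spec!r}")
    if kind == "choice":
        values = spec["values"]
        p = spec.get("p")
        return float(rng.choice(values, p=p))
    raise ValueError(f"unknown distribution kind {kind!r}")


def sample_params(
    distributions: dict[str, dict], rng: np.random.Generator
) -> AgentParams:
    """Draw one agent's parameters.  capacity_k is raised to utilization_u
    when the draws would violate capacity_k >= utilization_u."""
    base = dict(DEFAULT_PARAM_DISTRIBUTIONS)
    unknown = set(distributions) - set(base)
    if unknown:
        raise ValueError(f"unknown parameter(s) in distribution spec: {sorted(unknown)}")
    base.update(distributions)
    vals = {name: _sample_one(spec, rng) for name, spec in base.items()}
    vals["capacity_k"] = max(vals["capacity_k"], vals["utilization_u"])
    return AgentParams(**vals)


@dataclass(frozen=True)
class CohortDesign:
    """Trial counts per condition: 30 reconstruction trials at each set size
    in {1, 2, 4} and a 150-trial change-detection block at N in {4, 8}."""

    recon_set_sizes: tuple[int, ...] = (1, 2, 4)
    trials_per_set_size: int = 30
    cd_set_sizes: tuple[int, ...] = (4, 8)
    cd_trials: int = 150


def simulate_cohort(
    n_subjects: int,
    rng: np.random.Generator | int,
    design: CohortDesign | None = None,
    param_distributions: dict[str, dict] | None = None,
    strategy: StrategyVariant | None = None,
    geometry: GeometryConfig | None = None,
    timing: _Timing | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate a full cohort over both tasks.

    Returns a dict of DataFrames: ``reconstruction_events`` and
    ``target_models`` (the reconstruction task logs), ``change_detection``,
    and ``truth_params`` (the ground-truth parameter table for recovery
    tests).  Fully reproducible for a fixed seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    design = design or CohortDesign()
    distributions = param_distributions or {}
    geometry = geometry or GeometryConfig()
    palette = build_palette()

    event_rows, model_rows, truth_rows = [], [], []
    cd_frames = []
    for subj in range(n_subjects):
        agent = sample_params(distributions, rng)
        truth_rows.append({"subject_id": subj, **agent.__dict__})

        trial_id = 0
        conditions = [
            ss for ss in design.recon_set_sizes for _ in range(design.trials_per_set_size)
        ]
        rng.shuffle(conditions)
        for ss in conditions:
            model = generate_target_model(ss, rng, geometry, palette)
            trial = simulate_reconstruction_trial(
                agent, model, rng, strategy, geometry, timing,
                subject_id=subj, trial_id=trial_id,
            )
            for i, item in enumerate(model.items):
                model_rows.append(
                    {
                        "subject_id": subj,
                        "trial_id": trial_id,
                        "set_size": ss,
                        "item_index": i,
                        "x_deg": item.x_deg,
                        "y_deg": item.y_deg,
                        "hue_deg": item.hue_deg,
                    }
                )
            for ei, ev in enumerate(trial.events):
                event_rows.append(
                    {
                        "subject_id": subj,
                        "trial_id": trial_id,
                        "set_size": ss,
                        "event_index": ei,
                        "event_type": ev.event_type,
                        "x_deg": ev.x_deg if ev.event_type == "place" else np.nan,
                        "y_deg": ev.y_deg if ev.event_type == "place" else np.nan,
                        "hue_deg": ev.hue_deg if ev.event_type == "place" else np.nan,
                        "t_ms": ev.t_ms,
                    }
                )
            trial_id += 1

        cd_frames.append(
            simulate_change_detection_block(
                agent, rng, design.cd_trials, design.cd_set_sizes, subject_id=subj
            )
        )

    return {
        "reconstruction_events": pd.DataFrame(event_rows),
        "target_models": pd.DataFrame(model_rows),
        "change_detection": pd.concat(cd_frames, ignore_index=True),
        "truth_params": pd.DataFrame(truth_rows),
    }
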