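"""Run configuration: one YAML-loadable object covering every option of the
simulate → score → capacity → stats pipeline.  Every field has a documented
default; unknown keys are rejected so typos fail loudly."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .scoring import TRIM_POPULATIONS

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometrySettings(_Strict):
    frame_deg: float = 13.47       # side of the black frame, deg visual angle
    square_deg: float = 0.85       # side of each colored square
    min_gap_deg: float = 0.0       # extra clearance beyond non-overlap
    ppd: float = 36.0              # pixels per degree for pixel logs


class PaletteSettings(_Strict):
    n_hues: int = 256              # evenly spaced HSV hues on the wheel


class SimulateSettings(_Strict):
    n_subjects: int = 30
    trials_per_set_size: int = 30          # reconstruction trials per SS
    recon_set_sizes: tuple[int, ...] = (1, 2, 4)
    cd_trials: int = 150                   # change-detection block length
    cd_set_sizes: tuple[int, ...] = (4, 8)
    strategy: str = "fixed_utilization"
    # per-parameter sampling specs, e.g. {"utilization_u": {"dist": "uniform",
    # "low": 1, "high": 4}}; unspecified parameters use package defaults
    param_distributions: dict[str, dict] = Field(default_factory=dict)


class ScoringSettings(_Strict):
    circular_color: bool = True            # wrap hue differences at 360
    threshold_sd: float = 3.0              # outlier trim, SDs above the mean
    trim_population: str = "subject_x_ss"  # one of TRIM_POPULATIONS

    def model_post_init(self, _ctx) -> None:
        if self.trim_population not in TRIM_POPULATIONS:
            raise ValueError(f"trim_population must be one of {TRIM_POPULATIONS}")


class CapacitySettings(_Strict):
    rt_threshold_sd: float = 3.0
    exclude_negative_k: bool = True
    negative_k_threshold: float = 0.0


class StatsSettings(_Strict):
    eta_sq: str = "partial"                # or "classical"
    contrast_scheme: str = "ss1_vs_mean"   # or "pairwise"
    ci_level: float = 0.95
    reliability_first_n: int = 15          # shortened-task reliability column


class IOSettings(_Strict):
    data_dir: str | None = None            # existing dataset to score
    out_dir: str = "results"
    column_map: dict[str, dict[str, str]] = Field(default_factory=dict)
    figures: bool = False


class RunConfig(_Strict):
    geometry: GeometrySettings = Field(default_factory=GeometrySettings)
    palette: PaletteSettings = Field(default_factory=PaletteSettings)
    simulate: SimulateSettings = Field(default_factory=SimulateSettings)
    scoring: ScoringSettings = Field(default_factory=ScoringSettings)
    capacity: CapacitySettings = Field(default_factory=CapacitySettings)
    stats: StatsSettings = Field(default_factory=StatsSettings)
    io: IOSettings = Field(default_factory=IOSettings)
    seed: int = 0


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config file (all keys optional) and apply overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    return RunConfig(**data)
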