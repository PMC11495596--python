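"""Configuration models for simulation, basis construction and the pipeline.

All user-facing knobs live here as pydantic models so that invalid settings
fail fast with an error naming the offending field.  The defaults describe the
world the analysis targets: 335 secondary medical areas (SMAs) nested in 47
prefectures, observed over 7 fiscal years starting FY2014, with four latent
trajectory groups whose shares are 62/20/5/13%.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

#: Trajectory-group mean curves on the logit scale, one row per group, evaluated
#: per period.  Qualitative shapes: a flat high group, a flat middle group, a
#: rising low-to-middle group and a flat low group; adjacent flat groups are
#: separated by >= 0.8 logit units.
DEFAULT_GROUP_LOGIT_LEVELS = (1.0, 0.2, None, -0.62)  # None: rising group, built per period
DEFAULT_RISING_START, DEFAULT_RISING_END = -0.45, 0.2

#: Per-covariate multiplicative (log-scale) shifts by latent group, ordered
#: high -> low trajectory groups.  Healthcare supply is richer in areas whose
#: indicator trajectories sit high.
DEFAULT_COVARIATE_EFFECTS = {
    "population_density": (0.5, 0.15, -0.1, -0.4),
    "physicians_per_100k": (0.25, 0.08, -0.05, -0.2),
    "cardiologists_per_100k": (0.5, 0.15, -0.1, -0.4),
    "emergency_hospitals_per_100k": (0.3, 0.1, -0.05, -0.25),
}


def default_group_logit_curves(n_periods: int) -> list[list[float]]:
    """Default per-group mean logit curves for ``n_periods`` fiscal years."""
    curves = []
    for level in DEFAULT_GROUP_LOGIT_LEVELS:
        if level is None:
            curves.append(list(np.linspace(DEFAULT_RISING_START, DEFAULT_RISING_END, n_periods)))
        else:
            curves.append([float(level)] * n_periods)
    return curves


class SimulationConfig(BaseModel):
    """World description for the synthetic claims-like panel generator."""

    n_regions: int = Field(default=47, ge=1)
    n_areas: int = Field(default=335, ge=1)
    n_periods: int = Field(default=7, ge=1)
    start_year: int = 2014
    group_probs: tuple[float, ...] = (0.62, 0.20, 0.05, 0.13)
    group_logit_curves: Optional[tuple[tuple[float, ...], ...]] = None
    area_random_sd: float = Field(default=0.05, ge=0.0)
    case_rate_per_100k: float = Field(default=60.0, gt=0.0)
    population_log_mean: float = math.log(250_000.0)
    population_log_sd: float = Field(default=0.2, ge=0.0)
    covariate_effects: Optional[dict[str, tuple[float, ...]]] = None
    seed: int = 0

    model_config = {"frozen": True}

    @field_validator("group_probs")
    @classmethod
    def _probs_valid(cls, v):
        if any(p <= 0 for p in v):
            raise ValueError("group_probs: all entries must be > 0")
        if abs(sum(v) - 1.0) > 1e-12:
            raise ValueError(f"group_probs: must sum to 1 within 1e-12, got {sum(v)!r}")
        return v

    @model_validator(mode="after")
    def _cross_field(self):
        if self.n_areas < self.n_regions:
            raise ValueError("n_areas: must be >= n_regions (every region gets an area)")
        if self.group_logit_curves is None:
            object.__setattr__(
                self,
                "group_logit_curves",
                tuple(tuple(c) for c in default_group_logit_curves(self.n_periods)),
            )
        if len(self.group_logit_curves) != len(self.group_probs):
            raise ValueError("group_logit_curves: need one curve per group in group_probs")
        for g, curve in enumerate(self.group_logit_curves):
            if len(curve) != self.n_periods:
                raise ValueError(
                    f"group_logit_curves: curve {g} has length {len(curve)}, expected n_periods={self.n_periods}"
                )
        if self.covariate_effects is None:
            # default gradient rescaled to however many groups are configured,
            # keeping the high-to-low ordering of the 4-group anchors
            k = len(self.group_probs)
            object.__setattr__(
                self,
                "covariate_effects",
                {
                    name: tuple(np.linspace(shifts[0], shifts[-1], k)) if k > 1 else (shifts[0],)
                    for name, shifts in DEFAULT_COVARIATE_EFFECTS.items()
                },
            )
        for name, effects in self.covariate_effects.items():
            if len(effects) != len(self.group_probs):
                raise ValueError(
                    f"covariate_effects: entry '{name}' needs one shift per group"
                )
        return self

    @property
    def n_groups(self) -> int:
        return len(self.group_probs)


class BasisSpec(BaseModel):
    """Time basis for the class mean curves.

    ``linear`` gives columns (1, t); ``quadratic`` (1, t, t²); ``spline`` a
    degree-3 B-spline basis of ``df`` columns with interior knots at equally
    spaced quantiles of the period range.  ``df`` counts total columns,
    intercept included.
    """

    kind: Literal["linear", "quadratic", "spline"] = "spline"
    df: int = Field(default=4, ge=2)
    include_intercept: bool = True

    model_config = {"frozen": True}

    @property
    def n_columns(self) -> int:
        base = {"linear": 2, "quadratic": 3}.get(self.kind, self.df)
        return base if self.include_intercept else base - 1


class PipelineConfig(BaseModel):
    """End-to-end run configuration; one root seed drives every stage."""

    out_dir: str = "qitraj_run"
    simulation: Optional[SimulationConfig] = SimulationConfig()
    panel_path: Optional[str] = None  # used instead of simulation when set
    covariates_path: Optional[str] = None
    zero_case_policy: Literal["region-fill", "drop-area", "error"] = "region-fill"
    basis: BasisSpec = BasisSpec()
    k_min: int = Field(default=1, ge=1)
    k_max: int = Field(default=5, ge=1)
    n_starts: int = Field(default=10, ge=1)
    seed: int = 0
    response_scale: Literal["proportion", "logit"] = "proportion"
    naming_thresholds: tuple[float, float] = (0.45, 0.60)
    make_plots: bool = False

    @model_validator(mode="after")
    def _check(self):
        if self.k_max < self.k_min:
            raise ValueError("k_max: must be >= k_min")
        lo, hi = self.naming_thresholds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("naming_thresholds: need 0 < low < high < 1")
        return self
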