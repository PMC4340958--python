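"""Schema-validated run configuration for the pipeline CLI.

A single hierarchical config (YAML or JSON) drives the three experiment
suites; every field has a typed default, so an empty config runs the
reference conditions.  Validation errors name the offending field path.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, ValidationError

__all__ = [
    "RunConfig",
    "FFLConfig",
    "NoiseConfig",
    "ReporterConfig",
    "ConstructSpec",
    "load_config",
    "config_hash",
]


class FFLConfig(BaseModel):
    """CD69 feed-forward-loop experiment: scenarios and ensemble size."""

    model_config = {"extra": "forbid"}

    n_runs: int = Field(10_000, ge=100)
    t_end: float = Field(5000.0, gt=0)
    n_boot: int = Field(20_000, ge=100)
    mrna_activated: float = Field(6.0, gt=0)
    mir_resting: float = Field(9.0, ge=0)
    mir_activated: float = Field(42.0, gt=0)
    protein_translation: float = Field(0.44, gt=0)


class PopulationConfig(BaseModel):
    model_config = {"extra": "forbid"}

    fraction: float = Field(1.0, ge=0, le=1)
    mean: float = Field(100.0, gt=0)
    cv: float = Field(20.0, ge=0)


class NoiseConfig(BaseModel):
    """Noise suite: channel pair, mixture, and unmixing conditions."""

    model_config = {"extra": "forbid"}

    n_events: int = Field(100_000, ge=1000)
    # CD8a/CD8b-like technical-noise control
    pair_mean_a: float = Field(500.0, gt=0)
    pair_mean_b: float = Field(500.0, gt=0)
    biological_cv: float = Field(30.0, ge=0)
    technical_cv: float = Field(5.0, ge=0)
    # two-component mixture (minority dimmer at a 2-fold mean difference)
    mixture: list[PopulationConfig] = Field(
        default_factory=lambda: [
            PopulationConfig(fraction=0.2, mean=100.0, cv=20.0),
            PopulationConfig(fraction=0.8, mean=200.0, cv=20.0),
        ]
    )
    # unmixing: contaminant fraction and removal grid
    unmix_contaminant_fraction: float = Field(0.1, ge=0, lt=1)
    unmix_fraction_max: float = Field(0.3, gt=0, lt=1)
    unmix_grid_points: int = Field(31, ge=2)
    unmix_requested_reduction: float = Field(1.0, gt=0)  # CV points
    n_bins: int = Field(256, ge=8)


class ConstructSpec(BaseModel):
    """A reporter construct: its true eGFP/mCherry slope per genotype."""

    model_config = {"extra": "forbid"}

    name: str
    slope_control: float = Field(gt=0)
    slope_deficient: float = Field(gt=0)


class ReporterConfig(BaseModel):
    """Reporter suite: constructs, generator noise, and gate thresholds."""

    model_config = {"extra": "forbid"}

    n_events: int = Field(20_000, ge=100)
    mcherry_mean: float = Field(1000.0, gt=0)
    mcherry_cv: float = Field(200.0, ge=0)
    residual_cv: float = Field(20.0, ge=0)
    untransduced_fraction: float = Field(0.3, ge=0, le=1)
    threshold_gfp: float = Field(30.0, gt=0)
    threshold_mcherry: float = Field(30.0, gt=0)
    constructs: list[ConstructSpec] = Field(
        default_factory=lambda: [
            ConstructSpec(name="empty", slope_control=1.0, slope_deficient=1.0),
            ConstructSpec(name="cd69_3utr", slope_control=0.5, slope_deficient=1.0),
        ]
    )
    empty_construct: str = "empty"


class RunConfig(BaseModel):
    """Top-level pipeline configuration."""

    model_config = {"extra": "forbid"}

    seed: int = Field(0, ge=0, lt=2**31)
    ffl: FFLConfig = Field(default_factory=FFLConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    reporter: ReporterConfig = Field(default_factory=ReporterConfig)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a config file (YAML/JSON); None gives defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        paths = "; ".join(
            "config." + ".".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in exc.errors()
        )
        raise ValueError(f"invalid configuration ({paths})") from exc


def config_hash(config: RunConfig) -> str:
    """Stable hash of the validated configuration, for provenance records."""
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
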