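"""Validated analysis configuration.

Every analysis constant and decision switch of the pipeline lives here so a
run is fully specified by one structured file; unknown keys are rejected on
load and the canonical JSON of the config is hashed into every output for
traceability.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class AnalysisConfig(BaseModel):
    """All knobs of the offline analysis, with the study's constants as defaults."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    band: tuple[float, float] = (8.0, 13.0)
    thresholds: tuple[float, ...] = (30.0, 50.0, 70.0)
    channels: tuple[str, ...] = ("AF3", "AF4")
    epoch_duration: float = 1.0
    target_rate: float = 250.0
    artifact_criterion: float = Field(100.0, gt=0)
    seed: int = 0

    # decision switches
    max_power_convention: Literal["tukey_fence", "literal_iqr"] = "tukey_fence"
    spectral_window: str = "boxcar"
    bin_agg: Literal["mean", "sum"] = "mean"
    tail_statistic: Literal["powerlaw_mle", "mean_median_ratio", "excess_kurtosis"] = "powerlaw_mle"
    include_boundary_dwells: bool = True
    pain_block: Literal["pre", "post", "mean"] = "pre"
    friedman_method: Literal["chi-square", "permutation"] = "chi-square"
    transition_smoothing: float = Field(0.0, ge=0)

    # paths (unused in in-memory synthetic runs)
    input_dir: Path | None = None
    output_dir: Path | None = None

    @model_validator(mode="after")
    def _check(self) -> "AnalysisConfig":
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ValueError("band must be an increasing positive pair")
        if hi >= self.target_rate / 2:
            raise ValueError("band upper edge must lie below the post-downsampling Nyquist")
        for t in self.thresholds:
            if not (0 < t <= 100):
                raise ValueError("thresholds are percentages in (0, 100]")
        if self.epoch_duration <= 0:
            raise ValueError("epoch_duration must be positive")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        """Short stable hash of the canonical config, embedded in outputs."""
        payload = self.model_dump_json()
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
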