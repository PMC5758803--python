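"""Run configuration: YAML-backed, schema-validated settings for the CLI.

Unknown keys and out-of-precondition values are rejected with the offending
field path, so typos never silently fall back to defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .calibration import PRESETS
from .errors import ConfigError
from .pipeline import AnalysisParams

__all__ = ["ProtocolConfig", "SessionConfig", "AnalysisConfig", "SpatialConfig", "RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_Strict):
    n_freqs: int = Field(11, ge=1)
    f_min_hz: float = Field(2000.0, gt=0)
    f_max_hz: float = Field(40000.0, gt=0)
    n_reps: int = Field(20, ge=1)
    isi_s: float = Field(2.0, gt=0)
    tone_dur_s: float = Field(0.1, gt=0)
    gap_s: float = Field(30.0, ge=0)
    first_onset_s: float = Field(30.0, ge=30.0)
    ramp_s: float = Field(0.01, ge=0)

    @model_validator(mode="after")
    def _check(self):
        if self.f_min_hz > self.f_max_hz:
            raise ValueError("f_min_hz must be <= f_max_hz")
        if self.isi_s <= self.tone_dur_s:
            raise ValueError("isi_s must exceed tone_dur_s")
        return self


class SessionConfig(_Strict):
    n_neurons: int = Field(100, ge=1)
    echo_fraction: float | None = Field(None, ge=0.0, le=1.0)
    preset: str = "anesthetized"
    frame_rate_hz: float = Field(40.0, gt=0)
    baseline_f: float = Field(100.0, gt=0)
    field_um: float = Field(200.0, gt=0)
    post_s: float = Field(15.0, ge=0)

    @model_validator(mode="after")
    def _check(self):
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")
        return self


class AnalysisConfig(_Strict):
    amp_thresh_sd: float = Field(3.0, gt=0)
    rise_thresh: float = Field(0.1, gt=0)
    min_dur_s: float = Field(0.1, gt=0)
    min_separation_s: float = Field(0.2, ge=0)
    sound_win_s: float = Field(0.5, gt=0)
    echo_halfwidth_s: float = Field(0.75, gt=0)
    k_max: int = Field(5, ge=0)
    alpha: float = Field(0.05, gt=0, lt=1)
    integral_dur_s: float = Field(0.5, gt=0)
    baseline_percentile: float = Field(25.0, gt=0, lt=100)

    def to_params(self) -> AnalysisParams:
        return AnalysisParams(
            amp_thresh_sd=self.amp_thresh_sd,
            rise_thresh=self.rise_thresh,
            min_dur_s=self.min_dur_s,
            min_separation_s=self.min_separation_s,
            sound_win_s=self.sound_win_s,
            echo_halfwidth_s=self.echo_halfwidth_s,
            k_max=self.k_max,
            alpha=self.alpha,
            integral_dur_s=self.integral_dur_s,
            baseline_percentile=self.baseline_percentile,
        )


class SpatialConfig(_Strict):
    r_um: float = Field(50.0, gt=0)
    n_perm: int = Field(9999, ge=999)


class RunConfig(_Strict):
    out_dir: str = "echotune_out"
    seed: int = Field(0, ge=0)
    protocol: ProtocolConfig = ProtocolConfig()
    session: SessionConfig = SessionConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    spatial: SpatialConfig = SpatialConfig()


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML config file (all keys optional) and apply CLI overrides."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = raw
    for key, value in overrides.items():
        if value is None:
            continue
        section, _, name = key.partition(".")
        if name:
            data.setdefault(section, {})[name] = value
        else:
            data[key] = value
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {locs}") from exc
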