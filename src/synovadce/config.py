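"""Run configuration: a single validated, serialisable object for a full run."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict

from . import synthetic
from .kinetics import DEFAULT_GAIN

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AIFConfig(_Strict):
    peak: float = 6.0
    rise_s: float = 8.0
    frac_fast: float = 0.7
    decay_fast_per_s: float = 0.02
    decay_slow_per_s: float = 0.0008

    def to_shape(self) -> synthetic.AIFShape:
        return synthetic.AIFShape(**self.model_dump())


class PopulationConfig(_Strict):
    ktrans_mean: float = 0.045
    ktrans_sd: float = 0.033
    ve_mean: float = 0.31
    ve_sd: float = 0.22
    vp_mean: float = 0.02
    vp_sd: float = 0.01
    volume_mean_mm3: float = 9601.0
    volume_sd_mm3: float = 5251.0
    koos_mean: float = 46.75
    koos_sd: float = 14.40
    s0: float = 100.0
    noise_sd: float = 2.0
    voxel_jitter_cv: float = 0.1

    def to_population(self) -> synthetic.Population:
        return synthetic.Population(**self.model_dump())


class EffectConfig(_Strict):
    ktrans_ratio: float = 0.029 / 0.045
    ve_ratio: float = 0.22 / 0.31
    vp_ratio: float = 0.85
    volume_ratio: float = 8119.0 / 9601.0
    subject_sd_log: float = 0.15

    def to_effect(self) -> synthetic.TreatmentEffect:
        return synthetic.TreatmentEffect(**self.model_dump())


class PainConfig(_Strict):
    mean_change: float = 22.93
    sd_change: float = 19.8
    target_r: float = -0.27

    def to_pain_model(self) -> synthetic.PainModel:
        return synthetic.PainModel(**self.model_dump())


class FitConfig(_Strict):
    gain: float = DEFAULT_GAIN
    fit_vp: bool = True


class StatsConfig(_Strict):
    panel_mode: str = "pooled"   # or "per_parameter"


class RunConfig(_Strict):
    """All knobs of a simulate -> extract -> stats run, JSON round-trippable."""

    n_subjects: int = 93
    protocol_mix: float = 16 / 93
    seed: int = 0
    grid_shape: tuple[int, int, int] = (32, 32, 8)
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 3.0)
    aif: AIFConfig = AIFConfig()
    population: PopulationConfig = PopulationConfig()
    effect: EffectConfig = EffectConfig()
    pain: PainConfig = PainConfig()
    fitting: FitConfig = FitConfig()
    stats: StatsConfig = StatsConfig()


def load_config(path: str | Path) -> RunConfig:
    """Parse a JSON config file; unknown keys are rejected."""
    with open(path) as fh:
        return RunConfig.model_validate(json.load(fh))


def config_hash(config: RunConfig) -> str:
    """Stable hash of the full configuration, recorded in run manifests."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
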