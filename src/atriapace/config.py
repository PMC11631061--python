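"""Schema-validated run configuration (YAML).

Unknown keys are rejected everywhere so a typo cannot silently fall back
to a default.  Units follow the library: ms, mmHg, mL, bpm.
"""
from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .exceptions import ConfigError

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Strict):
    heart_rate: float = 54.0
    pr_interval: float = 153.0
    lv_passive_stiffness_scale: float = 1.0
    lv_relaxation_tau_scale: float = 1.0
    lv_mass_scale: float = 1.0
    la_dilation_scale: float = 1.0
    atrial_contractility_fraction: float = 1.0
    pericardial_constraint_enabled: bool = True
    use_calibrated_phenotype: bool = True


class RegulationSection(_Strict):
    co_target: float = 5.0
    map_target: float = 92.0
    rel_tolerance: float = 0.005
    consecutive_beats_required: int = 3
    max_beats: int = 500


class SweepSection(_Strict):
    rates: List[float] = list(range(60, 141, 10))
    pr_values: List[float] = list(range(0, 301, 10))
    av_mode: str = "av_sequential"
    pr_anchors: List[Tuple[float, float]] = [(55.0, 153.0), (100.0, 228.0)]
    reference_rate: float = 54.0
    reference_pr: float = 153.0


class PipelineSection(_Strict):
    channel_map: dict = {"ecg": "ecg", "lap": "lap", "cs": "cs"}


class SynthSection(_Strict):
    n_patients: int = 1
    sinus_hr: float = 55.0
    m_sinus: float = 12.8
    depth: float = 2.3
    r_opt: float = 100.0
    width: float = 25.0
    pr0: float = 153.0
    pr_slope: float = 1.7
    wenckebach_rate: float = 140.0


class RunConfig(_Strict):
    model: ModelSection = ModelSection()
    regulation: RegulationSection = RegulationSection()
    sweep: SweepSection = SweepSection()
    pipeline: PipelineSection = PipelineSection()
    synth: SynthSection = SynthSection()
    seed: int = 0
    log_level: str = "INFO"


def load_config(path: Optional[str]) -> RunConfig:
    """Load and validate a YAML config; defaults when ``path`` is None."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
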