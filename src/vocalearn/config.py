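"""YAML configuration for the pipeline's tunable parameters.

A config file carries up to four sections, all optional:

    acoustics:   pitch_floor, pitch_ceiling, min_pitch_hnr, cog_power, target_db
    selection:   n_bins, top_k_parameters
    session:     tolerance_s, novel_pool_size, gellermann (rule toggles)
    criterion:   n_trials, threshold, run_required, chance_p

Unknown keys raise, so typos do not silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .criterion_stats import CriterionSpec
from .session_design import GellermannCriteria

__all__ = ["AcousticsConfig", "SelectionConfig", "SessionConfig", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class AcousticsConfig:
    pitch_floor: float = 50.0
    pitch_ceiling: float = 400.0
    min_pitch_hnr: float = 50.0
    cog_power: float = 2.0
    target_db: float = 70.0


@dataclass(frozen=True)
class SelectionConfig:
    n_bins: int = 16
    top_k_parameters: int = 2


@dataclass(frozen=True)
class SessionConfig:
    tolerance_s: float = 0.01
    novel_pool_size: int = 100  # per-seal novel-stimulus pool (protocol ambiguity: 100 vs 200)
    gellermann: GellermannCriteria = field(default_factory=GellermannCriteria)


@dataclass(frozen=True)
class PipelineConfig:
    acoustics: AcousticsConfig = field(default_factory=AcousticsConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    session: SessionConfig = field(default_factory=SessionConfig)
    criterion: CriterionSpec = field(default_factory=CriterionSpec)


def _build(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a pipeline config from YAML; None gives all defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - {"acoustics", "selection", "session", "criterion"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    session_raw = dict(raw.get("session", {}))
    gellermann = session_raw.pop("gellermann", None)
    session = _build(SessionConfig, session_raw)
    if gellermann is not None:
        if "alternation_range" in gellermann and gellermann["alternation_range"] is not None:
            gellermann["alternation_range"] = tuple(gellermann["alternation_range"])
        session = SessionConfig(
            tolerance_s=session.tolerance_s,
            novel_pool_size=session.novel_pool_size,
            gellermann=_build(GellermannCriteria, gellermann),
        )
    return PipelineConfig(
        acoustics=_build(AcousticsConfig, raw.get("acoustics", {})),
        selection=_build(SelectionConfig, raw.get("selection", {})),
        session=session,
        criterion=_build(CriterionSpec, raw.get("criterion", {})),
    )
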