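"""Run configuration: YAML round-trip, strict validation, hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from dualbasin.energy import ForceFieldParams

__all__ = ["RunConfig", "load_config", "save_config"]


def _from_dict(cls, d: dict):
    """Strict dataclass construction: unknown keys are an error."""
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown config keys {sorted(unknown)}")
    return cls(**d)


@dataclass
class LangevinConfig:
    dt: float = 5e-4
    friction: float = 0.25
    temperature: float = 1.0


@dataclass
class REMDSection:
    temperature_ladder: list = field(default_factory=lambda: [0.9, 1.0, 1.12, 1.25])
    exchange_interval: int = 5000
    total_steps: int = 50000
    stride: int = 100


@dataclass
class KineticsConfig:
    n_runs: int = 200
    max_steps: int = 200000
    d_start: float | None = None     # default: native separation + 30 A
    direction: str = "binding"       # or "dissociation"


@dataclass
class StateConfig:
    qa_hi: float = 0.8
    qib_hi: float = 0.8
    lo: float = 0.1
    zero_tol: float = 0.05


@dataclass
class StageConfig:
    d_free_offset: float = 15.0
    contact_cutoff: float = 8.0
    q_region: float = 0.6
    core_lo: float = 0.1
    q_bound: float = 0.8


@dataclass
class AnalysisConfig:
    formation_factor: float = 1.2
    contact_cutoff: float = 8.0
    wham_bins: int = 50
    wham_tol: float = 1e-7
    wham_max_iter: int = 100000
    state: StateConfig = field(default_factory=StateConfig)
    stage: StageConfig = field(default_factory=StageConfig)


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    forcefield: ForceFieldParams = field(default_factory=ForceFieldParams)
    langevin: LangevinConfig = field(default_factory=LangevinConfig)
    remd: REMDSection = field(default_factory=REMDSection)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"RunConfig: unknown config keys {sorted(unknown)}")
        if "forcefield" in d:
            d["forcefield"] = ForceFieldParams.from_dict(d["forcefield"])
        if "langevin" in d:
            d["langevin"] = _from_dict(LangevinConfig, d["langevin"])
        if "remd" in d:
            d["remd"] = _from_dict(REMDSection, d["remd"])
        if "kinetics" in d:
            d["kinetics"] = _from_dict(KineticsConfig, d["kinetics"])
        if "analysis" in d:
            a = dict(d["analysis"])
            if "state" in a:
                a["state"] = _from_dict(StateConfig, a["state"])
            if "stage" in a:
                a["stage"] = _from_dict(StageConfig, a["stage"])
            d["analysis"] = _from_dict(AnalysisConfig, a)
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
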