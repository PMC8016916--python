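"""Run configuration: a plain YAML document with every model constant
explicit, so a run can be diffed against the published constants.

Sections: ``parameters`` (the eight fitted quantities), ``network``
(fixed firing-rate constants), ``task`` (geometry and kinematics
constants) and ``run`` (condition, layout family, trial counts, master
seed, output paths).  Missing keys fall back to defaults; unknown keys
are rejected by name.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .network import NetworkParams
from .params import ParameterVector
from .task import LAYOUT_FAMILIES, TaskParams


@dataclass(frozen=True)
class RunSettings:
    condition: str = "test"
    layout: str = "exp1-standard"
    n: int = 1000
    n_runs: int = 30
    seed: int = 0
    out: str = "results"

    def __post_init__(self) -> None:
        if self.condition not in ("test", "easy", "conflict"):
            raise ValueError(f"run.condition: unknown condition {self.condition!r}")
        if self.layout not in LAYOUT_FAMILIES:
            raise ValueError(f"run.layout: unknown layout family {self.layout!r}")
        if self.n < 1 or self.n_runs < 1:
            raise ValueError("run.n and run.n_runs must be at least 1")


@dataclass
class RunConfig:
    parameters: ParameterVector
    network: NetworkParams = field(default_factory=NetworkParams)
    task: TaskParams = field(default_factory=TaskParams)
    run: RunSettings = field(default_factory=RunSettings)

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters.to_dict(),
            "network": asdict(self.network),
            "task": asdict(self.task),
            "run": asdict(self.run),
        }


_SECTIONS = {
    "parameters": (ParameterVector, None),
    "network": (NetworkParams, NetworkParams),
    "task": (TaskParams, TaskParams),
    "run": (RunSettings, RunSettings),
}


def _build_section(name: str, cls, default_cls, raw: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{name}: unknown keys {sorted(unknown)}")
    if default_cls is not None:
        base = {f.name: getattr(default_cls(), f.name) for f in fields(cls)}
    else:
        from .params import reference_parameters
        base = reference_parameters().to_dict()
    base.update(raw)
    try:
        return cls(**base)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{name}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields the full default configuration: the published
    fixed constants plus the package's reference-fit parameters.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of sections")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections {sorted(unknown)}")
    built = {}
    for name, (cls, default_cls) in _SECTIONS.items():
        section_raw = raw.get(name) or {}
        if not isinstance(section_raw, dict):
            raise ValueError(f"{name}: section must be a mapping")
        built[name] = _build_section(name, cls, default_cls, section_raw)
    return RunConfig(**built)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
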