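"""Run configuration: one structured document driving every command.

A configuration document (JSON or YAML) has per-module sections; every
field has a default, command-line flags override fields, and all randomness
flows from one master seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .engine import EngineSettings
from .lesions import LesionConfig
from .model import ConfigurationError, TaskParams

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class SessionConfig:
    n_trials: int = 64
    seed: int = 0
    distractor: str = "incongruent"


@dataclass(frozen=True)
class CvaConfig:
    k_neurons: int = 10
    snr: float = 8.0
    alpha: float = 0.05
    n_seeds: int = 100


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: model, engine, lesion, session."""

    task: TaskParams = field(default_factory=TaskParams)
    engine: EngineSettings = field(default_factory=EngineSettings)
    lesion: LesionConfig = field(default_factory=LesionConfig)
    session: SessionConfig = field(default_factory=SessionConfig)
    cva: CvaConfig = field(default_factory=CvaConfig)
    out_dir: str = "pfcsim-out"

    def resolved(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "task": TaskParams,
    "engine": EngineSettings,
    "lesion": LesionConfig,
    "session": SessionConfig,
    "cva": CvaConfig,
}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a JSON/YAML config document; keyword overrides win over the file.

    Overrides use dotted keys, e.g. ``load_config(p, **{"session.seed": 3})``
    or plain section dicts.
    """
    doc: dict = {}
    if path is not None:
        text = Path(path).read_text()
        doc = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        if not isinstance(doc, dict):
            raise ConfigurationError(f"config {path}: expected a mapping at top level")
    for key, value in overrides.items():
        if value is None:
            continue
        if "." in key:
            section, name = key.split(".", 1)
            doc.setdefault(section, {})[name] = value
        else:
            doc[key] = value

    kwargs = {}
    for section, cls in _SECTIONS.items():
        params = doc.get(section, {})
        if not isinstance(params, dict):
            raise ConfigurationError(f"config section {section!r}: expected a mapping")
        try:
            kwargs[section] = cls(**params)
        except TypeError as exc:
            raise ConfigurationError(f"config section {section!r}: {exc}") from exc
    return RunConfig(out_dir=doc.get("out_dir", "pfcsim-out"), **kwargs)
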