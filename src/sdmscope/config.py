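"""Session configuration: strict YAML/JSON schema, defaults, canonical hash.

Unknown keys are fatal (protects unattended runs); the hash is computed
over the canonicalized resolved content, so key order never matters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .sdm_engine import ScanSettings, TriggerMode
from .synthetic_scope import Modality, SimConfig, config_hash
from .classifiers import TrainConfig


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SessionConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    initial_scan: ScanSettings = field(default_factory=ScanSettings)
    optimized_scan: ScanSettings = field(default_factory=lambda: ScanSettings(
        modalities=(Modality.FLUOR, Modality.BRILLOUIN), n_frames=3))
    train: TrainConfig = field(default_factory=TrainConfig)
    mode: TriggerMode = TriggerMode.IMMEDIATE
    seed: int = 0
    model_path: Optional[str] = None
    out_dir: Optional[str] = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mode"] = TriggerMode(self.mode).value
        for key in ("initial_scan", "optimized_scan"):
            d[key]["modalities"] = [Modality(m).value
                                    for m in d[key]["modalities"]]
        return d

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def _build(cls, data: dict, path: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown key '{path}{key}'")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value under '{path.rstrip('.') or 'root'}': {exc}")


_SECTIONS = {
    "sim": SimConfig,
    "initial_scan": ScanSettings,
    "optimized_scan": ScanSettings,
    "train": TrainConfig,
}


def load_config(path: str | Path) -> SessionConfig:
    """Load a YAML or JSON session config; missing keys take defaults."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
        else json.loads(text or "{}")
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")

    top_fields = {f.name for f in dataclasses.fields(SessionConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise ConfigError(f"unknown key '{sorted(unknown)[0]}'")

    kwargs: dict[str, Any] = {}
    for name, value in data.items():
        if name in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"section '{name}' must be a mapping")
            if name in ("initial_scan", "optimized_scan") and "modalities" in value:
                value = dict(value)
                value["modalities"] = tuple(Modality(m) for m in value["modalities"])
            kwargs[name] = _build(_SECTIONS[name], value, f"{name}.")
        elif name == "mode":
            try:
                kwargs[name] = TriggerMode(value)
            except ValueError:
                raise ConfigError(f"invalid value for key 'mode': {value!r}")
        else:
            kwargs[name] = value
    try:
        return SessionConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc))
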