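"""Run configuration: one YAML/JSON grammar for model parameters, feeding
protocol (inline or preset + overrides) and run options."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import ModelParams
from .schedules import FeedingProtocol, build_preset

__all__ = ["RunConfig", "ConfigError", "load_config", "default_params"]


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


@dataclass
class RunConfig:
    params: ModelParams
    protocol: FeedingProtocol
    seed: int = 1
    sampling_interval: float = 1 / 6  # hours
    out_dir: str = "."

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "protocol": self.protocol.to_dict(),
            "seed": self.seed,
            "sampling_interval": self.sampling_interval,
            "out_dir": self.out_dir,
        }

    def config_hash(self) -> str:
        """Stable digest of the fully resolved configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build_params(d: dict) -> ModelParams:
    try:
        return ModelParams.from_dict(d)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"params: {exc}") from exc


def _build_protocol(d) -> FeedingProtocol:
    if isinstance(d, str):
        d = {"preset": d}
    if not isinstance(d, dict):
        raise ConfigError("protocol: expected a mapping or preset name")
    if "preset" in d:
        opts = {k: v for k, v in d.items() if k != "preset"}
        try:
            return build_preset(d["preset"], **opts)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"protocol.preset: {exc}") from exc
    try:
        return FeedingProtocol.from_dict(d)
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"protocol: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load a run configuration from YAML (JSON accepted)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    params = _build_params(raw.get("params", {}))
    if "protocol" not in raw:
        raise ConfigError("protocol: required")
    protocol = _build_protocol(raw["protocol"])
    seed = raw.get("seed", 1)
    if not isinstance(seed, int):
        raise ConfigError("seed: must be an integer")
    si = raw.get("sampling_interval", 1 / 6)
    if not (isinstance(si, (int, float)) and si > 0):
        raise ConfigError("sampling_interval: must be a positive number")
    return RunConfig(
        params=params,
        protocol=protocol,
        seed=seed,
        sampling_interval=float(si),
        out_dir=str(raw.get("out_dir", ".")),
    )


def default_params() -> ModelParams:
    """The shipped default parameter set."""
    path = Path(__file__).parent / "data" / "default_params.yaml"
    return ModelParams.from_file(path)
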