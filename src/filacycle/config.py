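"""Run configuration and result serialization.

Experiments are described by a :class:`RunConfig` that round-trips
losslessly through YAML or JSON.  Every result file embeds a metadata
header (config hash, master seed, package version, timestamp) so any
output can be traced back to an exact re-runnable configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .selection import Environment, LifeCycle

__all__ = ["RunConfig", "ConfigError", "load_config", "write_results", "write_summary"]

EXPERIMENT_KINDS = (
    "fitness",
    "landscape",
    "analytic",
    "spread-area",
    "extinct",
    "evolve",
)

_ALLOWED_KEYS = {
    "kind",
    "N",
    "k",
    "env",
    "s_c",
    "s_g",
    "seed",
    "out",
    "params",
}


class ConfigError(ValueError):
    """Malformed or inconsistent run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """A complete, seedable experiment description.

    ``env`` is either a preset name ("E_B", "E_C") or a mapping with
    keys a, b and optionally c, d, variant.  ``params`` carries
    module-specific options (grid sizes, replicate counts, ...).
    """

    kind: str
    N: int = 16
    k: int | None = None
    env: str | dict | None = None
    s_c: float = 0.0
    s_g: float = 0.0
    seed: int = 0
    out: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EXPERIMENT_KINDS:
            raise ConfigError(
                f"unknown experiment kind {self.kind!r}; expected one of "
                f"{EXPERIMENT_KINDS}"
            )

    def environment(self) -> Environment:
        return parse_environment(self.env)

    def life_cycle(self) -> LifeCycle:
        if self.k is None:
            raise ConfigError("this experiment requires a daughter count k")
        return LifeCycle(self.N, self.k)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def parse_environment(spec: str | dict | Environment | None) -> Environment:
    """Build an Environment from a preset name or explicit parameters."""
    if isinstance(spec, Environment):
        return spec
    if spec is None:
        raise ConfigError("an environment is required (preset name or {a, b, ...})")
    if isinstance(spec, str):
        try:
            return Environment.preset(spec)
        except KeyError as err:
            raise ConfigError(str(err)) from None
    if isinstance(spec, dict):
        allowed = {"a", "b", "c", "d", "variant"}
        unknown = set(spec) - allowed
        if unknown:
            raise ConfigError(f"unknown environment keys: {sorted(unknown)}")
        if "a" not in spec or "b" not in spec:
            raise ConfigError("explicit environment needs at least a and b")
        try:
            return Environment(**spec)
        except ValueError as err:
            raise ConfigError(str(err)) from None
    raise ConfigError(f"cannot interpret environment spec {spec!r}")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file; unknown keys are
    rejected with the offending names."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ConfigError(f"cannot parse {path}: {err}") from None
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    if "kind" not in raw:
        raise ConfigError(f"{path}: missing required key 'kind'")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def _metadata(config: RunConfig) -> dict:
    from . import __version__

    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "filacycle_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }


def write_results(table: pd.DataFrame, config: RunConfig, path: str | Path) -> None:
    """Write a tidy CSV with a commented metadata header."""
    path = Path(path)
    meta = _metadata(config)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        table.to_csv(fh, index=False)


def write_summary(payload: dict, config: RunConfig, path: str | Path | None) -> str:
    """Serialize a scalar-result summary as JSON (returned, and written
    to ``path`` when given)."""
    doc = {"metadata": _metadata(config), "config": config.to_dict(), **payload}
    text = json.dumps(doc, indent=2, default=float)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
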