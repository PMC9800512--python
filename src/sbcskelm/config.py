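"""Run configuration: YAML round-trip with strict key checking, and
provenance stamping of artifacts (every CSV/JSON the CLI writes embeds
the settings and seed that produced it)."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

__all__ = ["RunConfig", "load_config", "save_config", "write_csv", "write_json"]


@dataclass
class RunConfig:
    """Parameter blocks shared by the CLI subcommands."""

    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"
    optimizer: dict[str, Any] = field(default_factory=dict)
    classifier: dict[str, Any] = field(default_factory=dict)
    cv: dict[str, Any] = field(default_factory=dict)
    simulation: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config, rejecting unknown top-level keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def write_csv(df: pd.DataFrame, path: str | Path, provenance: dict[str, Any]) -> None:
    """Write a CSV with a '#'-prefixed provenance header block."""
    path = Path(path)
    header = "".join(f"# {k}: {v}\n" for k, v in provenance.items())
    path.write_text(header + df.to_csv(index=False))


def write_json(payload: dict[str, Any], path: str | Path, provenance: dict[str, Any]) -> None:
    out = {"provenance": provenance, **payload}
    Path(path).write_text(json.dumps(out, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
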