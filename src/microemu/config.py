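"""Structured YAML configuration shared by the CLI subcommands.

One section per stage; every key mirrors a dataclass field of the
corresponding module, so a config file documents a run completely.  CLI flags
override config values; defaults are the package defaults.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import yaml

from .md import SimulationConfig
from .potential import PotentialParams
from .sans import SANSModelParams

_SECTIONS = {
    "potential": PotentialParams,
    "md": SimulationConfig,
    "sans": SANSModelParams,
}


def load_config(path=None) -> dict:
    """Parse the YAML config into per-section dataclasses (defaults if absent)."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for section, cls in _SECTIONS.items():
        fields = {f.name for f in dataclasses.fields(cls) if f.init}
        values = {k: v for k, v in (raw.get(section) or {}).items() if k in fields}
        unknown = set((raw.get(section) or {})) - fields
        if unknown:
            raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
        out[section] = cls(**values)
    for key in ("hnc", "analysis", "campaign"):
        out[key] = dict(raw.get(key) or {})
    return out


def write_manifest(path, command: str, config: dict, seeds: dict,
                   outputs: list[str], t_start: float) -> None:
    """Machine-readable record tying every output file to its provenance."""
    from . import __version__

    manifest = {
        "command": command,
        "package_version": __version__,
        "wall_time_s": round(time.time() - t_start, 2),
        "seeds": seeds,
        "outputs": outputs,
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in config.items()
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
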