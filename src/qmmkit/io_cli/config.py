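"""Run configuration: TOML files with flat ``module.key`` namespacing,
strict key validation, and JSON provenance records."""

from __future__ import annotations

import hashlib
import json
import platform
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

TASKS = ("scf", "md", "umbrella", "wham", "rt", "ir", "ensemble")

KNOWN_KEYS = {
    "task", "seed", "output_dir",
    "system.xyz", "system.charge", "system.basis", "system.mm_table",
    "scf.functional", "scf.grid", "scf.conv_energy", "scf.conv_diis",
    "scf.max_iter",
    "md.nsteps", "md.dt_fs", "md.temperature", "md.gamma_au",
    "md.sample_every", "md.thermostat",
    "umbrella.atoms", "umbrella.k_umb", "umbrella.rc0",
    "wham.manifest", "wham.nbins", "wham.tol", "wham.temperature",
    "rt.dt", "rt.nsteps", "rt.propagator", "rt.magnus_order",
    "rt.kick_strength", "rt.kick_direction", "rt.damping_fs",
    "ir.series", "ir.dt_au", "ir.max_lag", "ir.window",
    "ensemble.manifest", "ensemble.search_lo", "ensemble.search_hi",
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    task: str
    options: dict
    seed: int = 0
    output_dir: str = "."

    def get(self, key, default=None):
        return self.options.get(key, default)

    def __getitem__(self, key):
        return self.options[key]


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


def load_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    flat = _flatten(raw)
    unknown = sorted(set(flat) - KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    task = flat.pop("task", None)
    if task not in TASKS:
        raise ConfigError(f"config must set task to one of {TASKS}, got {task!r}")
    seed = int(flat.pop("seed", 0))
    outdir = str(flat.pop("output_dir", "."))
    return RunConfig(task, flat, seed, outdir)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(
        {"task": cfg.task, "seed": cfg.seed, "options": cfg.options},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_provenance(path, cfg: RunConfig, extra: dict | None = None) -> None:
    from .. import __version__

    record = {
        "config_hash": config_hash(cfg),
        "task": cfg.task,
        "seed": cfg.seed,
        "options": {k: str(v) for k, v in cfg.options.items()},
        "versions": {
            "qmmkit": __version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
        "platform": platform.platform(),
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
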