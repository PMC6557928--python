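"""Tabular/config I/O, run manifests and optional plotting."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigurationError

__all__ = ["RunManifest", "write_manifest", "load_config", "sha256_file", "plot_trajectory"]


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record emitted once per CLI run."""

    command: str
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""
    inputs: dict = field(default_factory=dict)    # path -> sha256
    outputs: dict = field(default_factory=dict)   # path -> sha256

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True, default=str).encode()
        ).hexdigest()

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "config": self.config,
            "config_hash": self.config_hash(),
            "seeds": self.seeds,
            "version": self.version,
            "timestamp": self.timestamp,
            "inputs": self.inputs,
            "outputs": self.outputs,
        }


def write_manifest(
    path: str | Path,
    command: str,
    config: dict,
    seeds: dict | None = None,
    inputs: list | None = None,
    outputs: list | None = None,
) -> RunManifest:
    manifest = RunManifest(
        command=command,
        config=config,
        seeds=seeds or {},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        inputs={str(p): sha256_file(p) for p in inputs or [] if Path(p).exists()},
        outputs={str(p): sha256_file(p) for p in outputs or [] if Path(p).exists()},
    )
    Path(path).write_text(json.dumps(manifest.to_dict(), indent=2))
    return manifest


def load_config(path: str | Path) -> dict:
    """Structured config document (YAML; JSON is a YAML subset)."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file {path} does not exist")
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError("config document must be a mapping")
    return data


def plot_trajectory(trajectory, path: str | Path, species: list[str] | None = None) -> Path:
    """Concentration time courses to a vector image (format from suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = species or list(trajectory.concentrations.columns)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for sid in cols:
        ax.plot(trajectory.time, trajectory.concentrations[sid], label=sid)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("concentration (mmol/ml)")
    if len(cols) <= 12:
        ax.legend(fontsize=7, ncols=2)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
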