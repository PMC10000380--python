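"""Scenario configuration files and run manifests.

Scenario YAML schema (all keys optional except ``name`` and ``duration``; the
controller block defaults to the SFPIMRAC with its documented tuning)::

    name: track_95
    duration: 60.0
    dt: 0.001
    setpoint: [[0.0, 95.0]]
    cylinder_tau: 0.5
    condition: infected
    input_delay: 0.0
    intermediate_delay: 0.0
    gas_model: canonical
    controller: {type: sfpimrac, u_max: 200, theta0: 0.0}
    noise_std: 0.0
    noise_seed: null
    ref_drive: r

Unknown keys are rejected with a message naming the key; every validated
scenario echoes its fully defaulted form via ``Scenario.to_dict``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from . import __version__
from .simulate import Scenario

__all__ = ["load_config", "save_config", "RunManifest", "config_hash"]

_SCENARIO_KEYS = {
    "name", "duration", "setpoint", "dt", "cylinder_tau", "condition",
    "input_delay", "intermediate_delay", "gas_model", "controller",
    "noise_std", "noise_seed", "ref_drive", "disturbance",
}


def load_config(path: str | Path) -> Scenario:
    """Load and validate a scenario YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: scenario file must be a YAML mapping")
    unknown = set(raw) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(
            f"{path}: unknown scenario keys {sorted(unknown)}; "
            f"allowed keys are {sorted(_SCENARIO_KEYS)}"
        )
    for req in ("name", "duration"):
        if req not in raw:
            raise ValueError(f"{path}: missing required key {req!r}")
    return Scenario.from_dict(raw)


def save_config(sc: Scenario, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(sc.to_dict(), sort_keys=False))


def config_hash(sc: Scenario) -> str:
    """Stable SHA-256 over the canonical (fully defaulted) scenario form."""
    blob = json.dumps(sc.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written next to every simulation output."""

    scenario: str
    config_hash: str
    package_version: str
    seed: int | None
    outputs: tuple[str, ...]

    @classmethod
    def for_run(
        cls, sc: Scenario, outputs: list[str | Path], seed: int | None = None
    ) -> "RunManifest":
        return cls(
            scenario=sc.name,
            config_hash=config_hash(sc),
            package_version=__version__,
            seed=seed if seed is not None else sc.noise_seed,
            outputs=tuple(str(p) for p in outputs),
        )

    def write(self, path: str | Path) -> None:
        d = asdict(self)
        d["outputs"] = list(self.outputs)
        Path(path).write_text(json.dumps(d, indent=2) + "\n")
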