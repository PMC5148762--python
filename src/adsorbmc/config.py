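"""Flat-key YAML configuration loading for the CLI.

Recognized keys map onto :class:`~adsorbmc.mc.MCConfig` and
:class:`~adsorbmc.energy.EnergyConfig` fields; ``sigma_<group>`` keys
override surface tensions.  Missing keys keep packaged defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .energy import EnergyConfig, SigmaTable
from .mc import MCConfig
from .parameters import Group

__all__ = ["load_config", "config_summary"]

_MC_KEYS = {
    "temperature",
    "max_translation_step",
    "max_rotation_step",
    "large_move_probability",
    "large_translation_step",
    "large_rotation_step",
    "target_accepted_moves",
    "seed",
    "escape_distance",
    "escape_patience",
    "stall_proposal_budget",
}
_ENERGY_KEYS = {"probe_radius", "vdw_cutoff", "sasa_points", "sasa_smoothing"}


def load_config(path: str | Path | None) -> MCConfig:
    """Build an MCConfig (with nested EnergyConfig) from a flat YAML file."""
    data: dict = {}
    if path is not None:
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a flat key-value mapping")
    unknown = set(data) - _MC_KEYS - _ENERGY_KEYS - {
        f"sigma_{g.name.lower()}" for g in Group if g != Group.EXCLUDED
    }
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sigma_overrides = {}
    for group in Group:
        key = f"sigma_{group.name.lower()}"
        if key in data:
            sigma_overrides[group] = float(data[key])
    energy = EnergyConfig(
        **{k: data[k] for k in _ENERGY_KEYS if k in data},
        sigma=SigmaTable(sigma_overrides or None),
    )
    mc = MCConfig(**{k: data[k] for k in _MC_KEYS if k in data}, energy=energy)
    return mc


def config_summary(config: MCConfig) -> str:
    """Human-readable echo of the effective configuration."""
    lines = []
    for field in dataclasses.fields(config):
        if field.name == "energy":
            continue
        lines.append(f"{field.name} = {getattr(config, field.name)}")
    for field in dataclasses.fields(config.energy):
        if field.name == "sigma":
            continue
        lines.append(f"{field.name} = {getattr(config.energy, field.name)}")
    for group in Group:
        if group != Group.EXCLUDED:
            lines.append(f"sigma_{group.name.lower()} = {config.energy.sigma[group]}")
    return "\n".join(lines)
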