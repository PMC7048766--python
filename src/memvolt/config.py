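"""Flat key-value configuration for cells, media and solver settings.

Config files are one-level TOML (diff-friendly, units in the key names).
The bundled default encodes the reference cell parameterization: an
11 μm-diameter cell with a 5 nm membrane of conductivity 2.5e-7 S/m,
areal capacitance 0.01 F/m², cytoplasm at 0.5 S/m, suspended in a
0.05 S/m (HEPES-like) buffer.
"""

from __future__ import annotations

import tomllib
from importlib import resources
from pathlib import Path
from typing import Any

from .cell import CellModel, MediumModel

__all__ = [
    "CELL_KEYS",
    "default_config",
    "load_flat_config",
    "write_flat_config",
    "cell_from_config",
    "medium_from_config",
    "solver_config_from_config",
]

CELL_KEYS = [
    "radius_m",
    "membrane_thickness_m",
    "membrane_conductivity_S_per_m",
    "membrane_areal_capacitance_F_per_m2",
    "intracellular_conductivity_S_per_m",
]

_SOLVER_KEYS = {
    "domain_half_height_factor": "domain_half_height_factor",
    "domain_radius_factor": "domain_radius_factor",
    "interface_edge_frac": "interface_edge_frac",
    "dt_s": "dt",
    "linear_tol": "linear_tol",
    "theta_samples": "theta_samples",
}


def load_flat_config(path: str | Path) -> dict[str, Any]:
    """Read a flat TOML config; nested tables are rejected."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    for key, value in data.items():
        if isinstance(value, dict):
            raise ValueError(f"config must be flat; key {key!r} holds a table")
    return data


def write_flat_config(config: dict[str, Any], path: str | Path) -> None:
    lines = []
    for key, value in config.items():
        if isinstance(value, str):
            lines.append(f'{key} = "{value}"')
        elif isinstance(value, bool):
            lines.append(f"{key} = {str(value).lower()}")
        else:
            lines.append(f"{key} = {value!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def default_config() -> dict[str, Any]:
    """The bundled reference-cell configuration."""
    text = resources.files("memvolt.data").joinpath("default_cell.toml").read_bytes()
    return tomllib.loads(text.decode())


def cell_from_config(config: dict[str, Any]) -> CellModel:
    missing = [k for k in CELL_KEYS if k not in config]
    if missing:
        raise KeyError(f"config missing cell keys: {missing}")
    return CellModel(
        radius=float(config["radius_m"]),
        membrane_thickness=float(config["membrane_thickness_m"]),
        membrane_conductivity=float(config["membrane_conductivity_S_per_m"]),
        membrane_areal_capacitance=float(
            config["membrane_areal_capacitance_F_per_m2"]
        ),
        intracellular_conductivity=float(
            config["intracellular_conductivity_S_per_m"]
        ),
    )


def medium_from_config(config: dict[str, Any]) -> MediumModel:
    if "extracellular_conductivity_S_per_m" not in config:
        raise KeyError("config missing extracellular_conductivity_S_per_m")
    return MediumModel(
        conductivity=float(config["extracellular_conductivity_S_per_m"]),
        label=str(config.get("medium_label", "")),
    )


def solver_config_from_config(config: dict[str, Any]):
    """Build a :class:`memvolt.fem.SolverConfig` from flat config keys."""
    from .fem import SolverConfig

    kwargs = {}
    for key, attr in _SOLVER_KEYS.items():
        if key in config:
            value = config[key]
            kwargs[attr] = int(value) if attr == "theta_samples" else float(value)
    return SolverConfig(**kwargs)
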