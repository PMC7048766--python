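"""Containers for simulated transmembrane-voltage traces and sweep summaries.

A :class:`TMPTrace` holds the induced transmembrane voltage Vm(θ, t) of a
single cell, sampled on a time grid and a polar-angle grid (θ measured from
the +z pole, the direction of the applied field).  Both the closed-form and
the finite-element engines produce this container, so every downstream
statistic is engine-agnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["TMPTrace", "SweepResult", "SWEEP_COLUMNS"]


@dataclass(frozen=True)
class TMPTrace:
    """Induced transmembrane voltage Vm(θ, t).

    Parameters
    ----------
    t_grid : array of shape (n_t,)
        Strictly increasing sample times in seconds.
    theta_grid : array of shape (n_theta,)
        Polar angles in radians, within [0, π]; θ = 0 is the pole facing
        the field direction.
    vm : array of shape (n_t, n_theta)
        Transmembrane voltage in volts, inner-minus-outer convention.
    engine : str
        ``"analytic"`` or ``"fem"``.
    provenance : dict
        Cell, medium and waveform parameters that produced the trace.
    """

    t_grid: np.ndarray
    theta_grid: np.ndarray
    vm: np.ndarray
    engine: str
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t_grid, dtype=float)
        th = np.asarray(self.theta_grid, dtype=float)
        vm = np.asarray(self.vm, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("t_grid must be a non-empty 1-D array")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_grid must be strictly increasing")
        if th.ndim != 1 or th.size == 0:
            raise ValueError("theta_grid must be a non-empty 1-D array")
        if vm.shape != (t.size, th.size):
            raise ValueError(
                f"vm shape {vm.shape} inconsistent with grids "
                f"({t.size}, {th.size})"
            )
        object.__setattr__(self, "t_grid", t)
        object.__setattr__(self, "theta_grid", th)
        object.__setattr__(self, "vm", vm)

    @property
    def pole_index(self) -> int:
        """Index of the θ sample closest to the +z pole (must be ≈ 0)."""
        i = int(np.argmin(np.abs(self.theta_grid)))
        if abs(self.theta_grid[i]) > 1e-9:
            raise ValueError("trace does not contain a θ = 0 (pole) sample")
        return i

    def pole_vm(self) -> np.ndarray:
        """Vm(t) at the pole θ = 0."""
        return self.vm[:, self.pole_index]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns time_s, theta_rad, Vm_V."""
        tt, hh = np.meshgrid(self.t_grid, self.theta_grid, indexing="ij")
        return pd.DataFrame(
            {
                "time_s": tt.ravel(),
                "theta_rad": hh.ravel(),
                "Vm_V": self.vm.ravel(),
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def metadata(self) -> dict[str, Any]:
        return {
            "engine": self.engine,
            "n_time_samples": int(self.t_grid.size),
            "n_theta_samples": int(self.theta_grid.size),
            **self.provenance,
        }


SWEEP_COLUMNS = [
    "sigma_e_S_per_m",
    "protocol",
    "engine",
    "peak_pole_Vm_V",
    "t_peak_s",
    "t_plateau_fraction_s",
    "relax_half_time_s",
    "status",
]


@dataclass
class SweepResult:
    """Tabular summary of a conductivity × protocol sweep.

    One row per (σ_e, protocol, engine) combination with peak pole voltage,
    time to the plateau fraction, and post-pulse relaxation half-time.
    Values that a given run cannot produce (e.g. a plateau time for a pulse
    much shorter than the charging constant) are NaN and the row's status
    field says why.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SWEEP_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"sweep table missing columns: {missing}")
        self.table = self.table[SWEEP_COLUMNS].reset_index(drop=True)

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "SweepResult":
        return cls(pd.read_csv(path))

    def row(self, sigma_e: float, protocol: str, engine: str) -> pd.Series:
        t = self.table
        m = (
            np.isclose(t["sigma_e_S_per_m"], sigma_e)
            & (t["protocol"] == protocol)
            & (t["engine"] == engine)
        )
        hits = t[m]
        if len(hits) != 1:
            raise KeyError(
                f"expected exactly one row for ({sigma_e}, {protocol!r}, "
                f"{engine!r}); found {len(hits)}"
            )
        return hits.iloc[0]


def write_metadata(path: str | Path, meta: dict[str, Any]) -> None:
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
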