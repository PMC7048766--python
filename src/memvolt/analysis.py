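"""Summary statistics over TMP traces and the conductivity-sweep pipeline.

These operations condense a simulated Vm(θ, t) into the quantities the
conductivity study turns on: the peak pole voltage a pulse reaches, the
duration of the charging transient, the relative gain in peak voltage
between two media, and the post-pulse relaxation half-time.  The sweep
driver runs either engine over a protocol × conductivity grid and returns
the machine-readable summary table.

A first-order membrane never truly peaks during a pulse — it approaches
its plateau asymptotically — so "time to peak" is operationalized as the
first time the pole voltage reaches a configurable fraction of its
pulse-end plateau (default 0.995, about 5.3 charging constants; 0.99 gives
about 4.6).  The plateau is read off the trace at pulse end rather than
fitted, keeping the estimate assumption-free; an exponential-fit estimator
is provided separately for cross-checking.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .cell import CellModel, MediumModel, analytic_tmp_trace, charging_time_constant
from .pulses import PulseProtocol, Waveform
from .trace import SweepResult, TMPTrace

__all__ = [
    "peak_pole_tmp",
    "time_to_fraction_of_plateau",
    "relative_peak_increase",
    "relaxation_half_time",
    "fit_charging_tau",
    "run_conductivity_sweep",
]


def _waveform_from_trace(trace: TMPTrace) -> Waveform:
    segs = trace.provenance.get("waveform_segments")
    if not segs:
        raise ValueError("trace provenance does not record its waveform")
    return Waveform(tuple((f, d) for f, d in segs))


def peak_pole_tmp(trace: TMPTrace) -> tuple[float, float]:
    """Maximum pole voltage over time and the time it is attained.

    Ties break to the earliest sample.
    """
    v = trace.pole_vm()
    i = int(np.argmax(v))
    return float(v[i]), float(trace.t_grid[i])


def _interp_crossing(
    t: np.ndarray, v: np.ndarray, level: float, rising: bool
) -> float:
    """First time v crosses ``level`` (linear interpolation between samples)."""
    hit = v >= level if rising else v <= level
    if not np.any(hit):
        raise ValueError(f"level {level:.4g} V is never reached in the window")
    i = int(np.argmax(hit))
    if i == 0:
        return float(t[0])
    t0, t1 = t[i - 1], t[i]
    v0, v1 = v[i - 1], v[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (level - v0) / (v1 - v0) * (t1 - t0))


def time_to_fraction_of_plateau(trace: TMPTrace, fraction: float = 0.995) -> float:
    """First time the pole voltage reaches ``fraction`` of its plateau.

    The plateau is the pole voltage at the end of the driven part of the
    waveform; the pulse should last several charging constants (≥ 7τ
    recommended) for the plateau to be meaningful.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    wf = _waveform_from_trace(trace)
    t_end = wf.pulse_end()
    t = trace.t_grid
    v = trace.pole_vm()
    in_pulse = t <= t_end * (1 + 1e-12)
    plateau = float(np.interp(t_end, t, v))
    if plateau <= 0:
        raise ValueError("trace has a non-positive plateau; cannot normalize")
    return _interp_crossing(t[in_pulse], v[in_pulse], fraction * plateau, rising=True)


def relative_peak_increase(trace_low: TMPTrace, trace_high: TMPTrace) -> float:
    """Percent increase of peak pole voltage, 100·(peak_hi − peak_lo)/peak_lo."""
    if trace_low.engine != trace_high.engine:
        raise ValueError("traces must come from the same engine")
    if trace_low.provenance.get("waveform_segments") != trace_high.provenance.get(
        "waveform_segments"
    ):
        raise ValueError("traces must share the same waveform")
    peak_low, _ = peak_pole_tmp(trace_low)
    peak_high, _ = peak_pole_tmp(trace_high)
    if peak_low == 0:
        raise ValueError("reference trace has zero peak voltage")
    return 100.0 * (peak_high - peak_low) / peak_low


def relaxation_half_time(trace: TMPTrace, pulse_end: float | None = None) -> float:
    """Time after field-off for the pole voltage to halve.

    ``pulse_end`` defaults to the end of the waveform's driven part; the
    trace must extend far enough past it for the half-level to be reached
    (≥ 3τ recommended).
    """
    if pulse_end is None:
        pulse_end = _waveform_from_trace(trace).pulse_end()
    t = trace.t_grid
    v = trace.pole_vm()
    if not t[0] <= pulse_end <= t[-1]:
        raise ValueError("pulse_end lies outside the simulated window")
    v_end = float(np.interp(pulse_end, t, v))
    if v_end <= 0:
        raise ValueError("membrane never charged; relaxation half-time undefined")
    after = t >= pulse_end
    t_half = _interp_crossing(t[after], v[after], 0.5 * v_end, rising=False)
    return t_half - pulse_end


def fit_charging_tau(trace: TMPTrace) -> tuple[float, float]:
    """Least-squares fit of A·(1 − e^(−t/τ)) to the charging segment.

    Returns (A, τ).  Serves as an independent cross-check of the
    charging-constant formula; the initial guess comes from the 63.2%
    crossing of the trace itself.
    """
    wf = _waveform_from_trace(trace)
    t_end = wf.pulse_end()
    m = trace.t_grid <= t_end * (1 + 1e-12)
    t = trace.t_grid[m]
    v = trace.pole_vm()[m]
    plateau = v[-1]
    tau0 = _interp_crossing(t, v, (1 - np.exp(-1)) * plateau, rising=True)

    def model(tt, a, tau):
        return a * (1.0 - np.exp(-tt / tau))

    popt, _ = curve_fit(model, t, v, p0=(plateau, tau0))
    return float(popt[0]), float(popt[1])


def _analytic_grid(tau: float, waveform: Waveform) -> np.ndarray:
    """Segment-aligned time grid resolving both τ and each segment."""
    pieces = [np.array([0.0])]
    t0 = 0.0
    for _, duration in waveform.segments:
        dt = min(tau / 100.0, duration / 400.0)
        n = min(int(np.ceil(duration / dt)), 200_000)
        pieces.append(t0 + duration * np.arange(1, n + 1) / n)
        t0 += duration
    return np.concatenate(pieces)


def run_conductivity_sweep(
    cell: CellModel,
    protocols: Sequence[PulseProtocol],
    sigmas: Sequence[float],
    engine: str = "analytic",
    config=None,
    plateau_fraction: float = 0.995,
    tail_time_constants: float = 6.0,
) -> SweepResult:
    """Run every protocol in every medium and tabulate the summaries.

    One row per (σ_e, protocol) pair for the chosen engine, containing the
    peak pole voltage and its time, the time to ``plateau_fraction`` of the
    plateau (NaN when the pulse is shorter than 7τ, where no plateau
    exists), and the post-pulse relaxation half-time.  Per-row failures are
    recorded in the status column instead of aborting the sweep.
    """
    if engine not in ("analytic", "fem"):
        raise ValueError(f"unknown engine {engine!r}")
    if not protocols or not len(sigmas):
        raise ValueError("protocols and sigmas must be non-empty")

    rows = []
    for protocol in protocols:
        for sigma in sigmas:
            medium = MediumModel(conductivity=float(sigma))
            row = {
                "sigma_e_S_per_m": float(sigma),
                "protocol": protocol.label,
                "engine": engine,
                "peak_pole_Vm_V": np.nan,
                "t_peak_s": np.nan,
                "t_plateau_fraction_s": np.nan,
                "relax_half_time_s": np.nan,
                "status": "ok",
            }
            try:
                tau = charging_time_constant(cell, medium)
                tail = max(tail_time_constants * tau, 0.5 * protocol.pulse_duration)
                waveform = protocol.to_waveform(tail=tail)
                trace = simulate_trace(cell, medium, waveform, engine, config)
                peak, t_peak = peak_pole_tmp(trace)
                row["peak_pole_Vm_V"] = peak
                row["t_peak_s"] = t_peak
                if protocol.pulse_duration >= 7.0 * tau:
                    row["t_plateau_fraction_s"] = time_to_fraction_of_plateau(
                        trace, plateau_fraction
                    )
                else:
                    row["status"] = "no plateau: pulse shorter than 7 tau"
                row["relax_half_time_s"] = relaxation_half_time(trace)
            except Exception as exc:  # noqa: BLE001 - row-level failure record
                row["status"] = f"error: {exc}"
            rows.append(row)
    return SweepResult(pd.DataFrame(rows))


def simulate_trace(
    cell: CellModel,
    medium: MediumModel,
    waveform: Waveform,
    engine: str,
    config=None,
) -> TMPTrace:
    """Dispatch a single simulation to the requested engine."""
    if engine == "analytic":
        tau = charging_time_constant(cell, medium)
        t_grid = _analytic_grid(tau, waveform)
        theta = np.linspace(0.0, np.pi, 65)
        return analytic_tmp_trace(cell, medium, waveform, theta, t_grid)
    if engine == "fem":
        from .fem import SolverConfig, simulate_fem

        return simulate_fem(cell, medium, waveform, config or SolverConfig())
    raise ValueError(f"unknown engine {engine!r}")
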