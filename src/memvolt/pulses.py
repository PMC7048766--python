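"""Pulse waveforms and the catalog of named electroporation protocols.

Waveforms are idealized piecewise-constant fields (rectangular pulses with
zero rise time).  The catalog collects the named protocols used in the
sub-microsecond calcium-electroporation study this package models: eight
treatment protocols EP1–EP8 drawn from four parameter groups spanning 25 ns
to 100 μs, the three simulation cases the conductivity sweep is run on, and
the buffer conductivity fixtures (STM, HEPES, HEPES with 2/5 mM CaCl₂).

Fields are stored in V/m internally; the kV/cm unit customary in
electroporation work is accepted at the interface boundary
(1 kV/cm = 1e5 V/m).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "KV_PER_CM",
    "Waveform",
    "PulseProtocol",
    "rectangular_waveform",
    "protocol_catalog",
    "protocol_groups",
    "buffer_conductivities",
    "catalog_frame",
    "write_catalog_csv",
    "get_protocol",
]

#: 1 kV/cm expressed in V/m.
KV_PER_CM = 1.0e5


@dataclass(frozen=True)
class Waveform:
    """Piecewise-constant applied field E(t).

    ``segments`` is a sequence of (field V/m, duration s) pairs played back
    to back; every duration is strictly positive.
    """

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        segs = tuple((float(f), float(d)) for f, d in self.segments)
        if not segs:
            raise ValueError("waveform must contain at least one segment")
        for f, d in segs:
            if not np.isfinite(f):
                raise ValueError("segment field must be finite")
            if not np.isfinite(d) or d <= 0:
                raise ValueError(f"segment duration must be positive, got {d}")
        object.__setattr__(self, "segments", segs)

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.segments))

    def segment_starts(self) -> np.ndarray:
        """Start time of each segment."""
        durs = np.array([d for _, d in self.segments])
        return np.concatenate([[0.0], np.cumsum(durs)[:-1]])

    def field_at(self, t: float | np.ndarray) -> np.ndarray:
        """Applied field at time t (0 outside [0, total_duration])."""
        t = np.asarray(t, dtype=float)
        starts = self.segment_starts()
        fields = np.array([f for f, _ in self.segments])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
        out = fields[idx]
        out = np.where((t < 0) | (t > self.total_duration), 0.0, out)
        return out

    def pulse_end(self) -> float:
        """End time of the last segment with a nonzero field.

        This is the instant the drive switches off, from which post-pulse
        relaxation is measured.
        """
        starts = self.segment_starts()
        end = 0.0
        for (f, d), t0 in zip(self.segments, starts):
            if f != 0.0:
                end = t0 + d
        if end == 0.0:
            raise ValueError("waveform has no nonzero-field segment")
        return end


def rectangular_waveform(field: float, duration: float, tail: float = 0.0) -> Waveform:
    """Single rectangular pulse followed by an optional field-free tail.

    The tail allows simulating post-pulse membrane relaxation.  A zero tail
    yields a single-segment waveform.
    """
    if duration <= 0:
        raise ValueError(f"pulse duration must be positive, got {duration}")
    if tail < 0:
        raise ValueError(f"tail must be non-negative, got {tail}")
    segments = [(field, duration)]
    if tail > 0:
        segments.append((0.0, tail))
    return Waveform(tuple(segments))


@dataclass(frozen=True)
class PulseProtocol:
    """A named pulse train: amplitude, duration, count and repetition rate."""

    label: str
    field_strength: float  # V/m
    pulse_duration: float  # s
    pulse_count: int = 1
    repetition_frequency: float = 1.0  # Hz

    def __post_init__(self) -> None:
        if self.field_strength < 0 or not np.isfinite(self.field_strength):
            raise ValueError("field_strength must be finite and non-negative")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if self.pulse_count < 1:
            raise ValueError("pulse_count must be at least 1")
        if self.repetition_frequency <= 0:
            raise ValueError("repetition_frequency must be positive")
        if 1.0 / self.repetition_frequency < self.pulse_duration:
            raise ValueError(
                "repetition period must be at least the pulse duration"
            )

    @property
    def field_kv_per_cm(self) -> float:
        return self.field_strength / KV_PER_CM

    def to_waveform(self, tail: float | None = None) -> Waveform:
        """Single-pulse waveform with a relaxation tail.

        Pulses within a train are treated as independent: the shortest
        inter-pulse gap used anywhere (1 ms at 1 kHz) exceeds the longest
        membrane time constant (~0.7 μs) a thousand-fold, so the membrane
        fully discharges between pulses and one pulse represents the train.
        The default tail is 5 pulse durations.
        """
        if tail is None:
            tail = 5.0 * self.pulse_duration
        return rectangular_waveform(self.field_strength, self.pulse_duration, tail)


def _ep(label: str, kv_cm: float, duration: float, count: int, rep_hz: float) -> PulseProtocol:
    return PulseProtocol(label, kv_cm * KV_PER_CM, duration, count, rep_hz)


def protocol_catalog() -> list[PulseProtocol]:
    """All named protocols: EP1–EP8 plus the three simulation cases.

    Repetition frequencies of the EP protocols follow their parameter
    group: 1 Hz for the 100 μs group, 1 kHz for the 200 ns × 200 group,
    1 Hz for the 12 kV/cm × 100–900 ns group and 200 Hz for the
    60 kV/cm × 25 ns group.  The SIM-* entries are the single-pulse cases
    the conductivity sweep is evaluated on.
    """
    return [
        _ep("EP1", 0.8, 100e-6, 8, 1.0),
        _ep("EP2", 8.0, 200e-9, 200, 1e3),
        _ep("EP3", 12.0, 500e-9, 8, 1.0),
        _ep("EP4", 60.0, 25e-9, 400, 200.0),
        _ep("EP5", 1.2, 100e-6, 8, 1.0),
        _ep("EP6", 12.0, 200e-9, 200, 1e3),
        _ep("EP7", 12.0, 800e-9, 8, 1.0),
        _ep("EP8", 60.0, 25e-9, 1200, 200.0),
        _ep("SIM-200ns", 8.0, 200e-9, 1, 1.0),
        _ep("SIM-100us", 1.2, 100e-6, 1, 1.0),
        _ep("SIM-1us", 8.0, 1e-6, 1, 1.0),
    ]


def protocol_groups() -> list[dict]:
    """The four pulsing-parameter groups the named protocols are drawn from.

    Ranges are (min, max) envelopes: 1) 0.6–1.6 kV/cm × 100 μs × 8 at 1 Hz;
    2) 6–16 kV/cm × 200 ns × 200 at 1 kHz; 3) 12 kV/cm × 100–900 ns × 8 at
    1 Hz; 4) 60 kV/cm × 25 ns × 200–1200 at 200 Hz.
    """
    return [
        {"group": 1, "field_kV_per_cm": (0.6, 1.6), "duration_s": (100e-6, 100e-6),
         "count": (8, 8), "rep_freq_Hz": 1.0},
        {"group": 2, "field_kV_per_cm": (6.0, 16.0), "duration_s": (200e-9, 200e-9),
         "count": (200, 200), "rep_freq_Hz": 1e3},
        {"group": 3, "field_kV_per_cm": (12.0, 12.0), "duration_s": (100e-9, 900e-9),
         "count": (8, 8), "rep_freq_Hz": 1.0},
        {"group": 4, "field_kV_per_cm": (60.0, 60.0), "duration_s": (25e-9, 25e-9),
         "count": (200, 1200), "rep_freq_Hz": 200.0},
    ]


def buffer_conductivities() -> dict[str, float]:
    """Conductivities (S/m) of the experimental buffers."""
    return {
        "STM": 0.1,
        "HEPES": 0.05,
        "HEPES+2mM CaCl2": 0.08,
        "HEPES+5mM CaCl2": 0.1,
    }


def catalog_frame() -> pd.DataFrame:
    """Protocol catalog as a table (fields in kV/cm)."""
    rows = [
        {
            "label": p.label,
            "field_kV_per_cm": p.field_kv_per_cm,
            "duration_s": p.pulse_duration,
            "count": p.pulse_count,
            "rep_freq_Hz": p.repetition_frequency,
        }
        for p in protocol_catalog()
    ]
    return pd.DataFrame(rows)


def write_catalog_csv(path: str | Path) -> None:
    catalog_frame().to_csv(path, index=False)


def get_protocol(label: str) -> PulseProtocol:
    """Look up a catalog protocol by label."""
    for p in protocol_catalog():
        if p.label == label:
            return p
    known = ", ".join(p.label for p in protocol_catalog())
    raise KeyError(f"unknown protocol {label!r}; known: {known}")
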