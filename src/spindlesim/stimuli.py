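"""Stretch stimulus generation and I/O.

All stimuli are length-versus-time traces on a uniform grid. Length is
expressed as displacement from resting muscle length in millimetres, so every
protocol starts (and, for ramp-hold-release, ends) at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StretchStimulus",
    "RampSpec",
    "make_ramp_hold_release",
    "make_sinusoid",
    "read_stimulus_table",
    "write_stimulus_table",
]

#: default sample step for generated stimuli (s); resolves a 100 Hz vibration
#: with 100 samples per cycle and places ramp corners within 0.1 ms
DEFAULT_DT_S = 1e-4


class StimulusFormatError(ValueError):
    """Raised for malformed stimulus tables."""


@dataclass(frozen=True)
class StretchStimulus:
    """Imposed muscle length versus time.

    Attributes
    ----------
    t : np.ndarray
        Time grid in seconds, uniform step.
    length : np.ndarray
        Muscle length in mm relative to resting length.
    label : str
        Free-text protocol name.
    """

    t: np.ndarray
    length: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.length, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size or t.size < 2:
            raise ValueError("t and length must be 1-D, equal length, size >= 2")
        dt = np.diff(t)
        if not np.all(dt > 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time grid must have a constant step")
        if not np.all(np.isfinite(y)):
            raise ValueError("length trace must be finite everywhere")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "length", y)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def velocity(self) -> np.ndarray:
        """Length rate of change (mm/s) by central differences."""
        return np.gradient(self.length, self.t)


@dataclass(frozen=True)
class RampSpec:
    """Parameters of a ramp-hold-release stretch.

    The 20 mm/s default ramp velocity is the classical identification ramp
    for Ia afferents; amplitude and hold are calibration choices.
    """

    baseline_s: float = 0.5
    amplitude_mm: float = 3.0
    velocity_mm_per_s: float = 20.0
    hold_s: float = 1.0
    post_s: float = 0.5
    dt_s: float = DEFAULT_DT_S

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.velocity_mm_per_s <= 0:
            raise ValueError("velocity_mm_per_s must be positive")
        if self.amplitude_mm < 0:
            raise ValueError("amplitude_mm must be non-negative")
        if min(self.baseline_s, self.hold_s, self.post_s) < 0:
            raise ValueError("durations must be non-negative")

    @property
    def ramp_s(self) -> float:
        """Duration of the ramp (and of the release)."""
        return self.amplitude_mm / self.velocity_mm_per_s

    def phase_times(self) -> dict[str, float]:
        """Boundary times of the protocol phases (s from trace start)."""
        t0 = self.baseline_s
        return {
            "ramp_on": t0,
            "ramp_off": t0 + self.ramp_s,
            "release_on": t0 + self.ramp_s + self.hold_s,
            "release_off": t0 + 2.0 * self.ramp_s + self.hold_s,
        }


def make_ramp_hold_release(spec: RampSpec) -> StretchStimulus:
    """Generate a piecewise-linear ramp-hold-release stretch.

    Length is 0 during baseline, rises at ``velocity_mm_per_s`` to
    ``amplitude_mm``, holds, falls at the same speed back to 0 and stays there
    for ``post_s``.
    """
    total = spec.baseline_s + 2.0 * spec.ramp_s + spec.hold_s + spec.post_s
    n = int(round(total / spec.dt_s)) + 1
    t = np.arange(n) * spec.dt_s
    ph = spec.phase_times()
    y = np.zeros(n)
    v = spec.velocity_mm_per_s
    ramp = (t >= ph["ramp_on"]) & (t < ph["ramp_off"])
    hold = (t >= ph["ramp_off"]) & (t < ph["release_on"])
    rel = (t >= ph["release_on"]) & (t < ph["release_off"])
    y[ramp] = v * (t[ramp] - ph["ramp_on"])
    y[hold] = spec.amplitude_mm
    y[rel] = spec.amplitude_mm - v * (t[rel] - ph["release_on"])
    np.clip(y, 0.0, spec.amplitude_mm if spec.amplitude_mm > 0 else 0.0, out=y)
    return StretchStimulus(t=t, length=y, label="ramp_hold_release")


def make_sinusoid(
    freq_hz: float,
    amplitude_mm: float,
    duration_s: float,
    dt_s: float = DEFAULT_DT_S,
) -> StretchStimulus:
    """Zero-mean sinusoidal length vibration, e.g. the 100 Hz / 80 um
    identification vibration (amplitude 0.08 mm)."""
    if freq_hz <= 0:
        raise ValueError("freq_hz must be positive")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if dt_s >= 1.0 / (2.0 * freq_hz):
        raise ValueError(
            f"dt_s={dt_s} undersamples {freq_hz} Hz (Nyquist limit "
            f"{1.0 / (2.0 * freq_hz):.3g} s)"
        )
    n = int(round(duration_s / dt_s)) + 1
    t = np.arange(n) * dt_s
    y = amplitude_mm * np.sin(2.0 * np.pi * freq_hz * t)
    return StretchStimulus(t=t, length=y, label=f"sinusoid_{freq_hz:g}Hz")


def read_stimulus_table(source, label: str = "") -> StretchStimulus:
    """Read a two-column (t_s, length_mm) CSV into a :class:`StretchStimulus`.

    Accepts a path or file-like object; a single header row is optional.
    Non-uniform time grids are resampled to the median step by linear
    interpolation, preserving the endpoints.
    """
    try:
        df = pd.read_csv(source, header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise StimulusFormatError(f"could not parse stimulus table: {exc}") from exc
    # drop a header row if the first row is non-numeric
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise StimulusFormatError("stimulus table needs two columns (t_s, length_mm)")
    arr = df.iloc[:, :2].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise StimulusFormatError("stimulus table contains non-numeric entries")
    if arr.shape[0] < 2:
        raise StimulusFormatError("stimulus table must have at least 2 rows")
    t, y = arr[:, 0], arr[:, 1]
    if not np.all(np.diff(t) > 0):
        raise StimulusFormatError("time column must be strictly increasing")
    steps = np.diff(t)
    if np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
        return StretchStimulus(t=t, length=y, label=label)
    # uniform grid hitting both endpoints exactly, step near the median step
    span = t[-1] - t[0]
    n = max(2, int(round(span / float(np.median(steps)))) + 1)
    tu = np.linspace(t[0], t[-1], n)
    yu = np.interp(tu, t, y)
    return StretchStimulus(t=tu, length=yu, label=label)


def write_stimulus_table(stim: StretchStimulus, target) -> None:
    """Write ``t_s,length_mm`` CSV (full double precision, round-trip safe)."""
    df = pd.DataFrame({"t_s": stim.t, "length_mm": stim.length})
    df.to_csv(target, index=False, float_format="%.17g")
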