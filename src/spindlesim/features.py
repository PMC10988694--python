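"""Spike detection and the three headline Ia encoding features.

The features summarize the prototypical response to a ramp-hold-release
stretch: the *initial burst* (peak instantaneous rate in a 100 ms window at
ramp onset), the *peak dynamic rate* (max instantaneous rate anywhere in the
ramp), and the *static average* (mean instantaneous rate over the middle 80%
of the hold plateau). A silent window yields a 0 feature plus a flag (the
static-failure phenotype of high-KCNQ / low-Nav1.6 terminals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from spindlesim.stimuli import RampSpec, StretchStimulus

__all__ = [
    "SpikeTrain",
    "FiringFeatures",
    "detect_spikes",
    "instantaneous_rate",
    "extract_features",
    "feature_windows",
    "percent_change",
]

REFRACTORY_FLOOR_S = 0.5e-3


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (s) at a named recording site."""

    times: np.ndarray
    site: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size and np.any(np.diff(t) < REFRACTORY_FLOOR_S):
            raise ValueError("spike times must respect the 0.5 ms refractory floor")
        object.__setattr__(self, "times", t)

    @property
    def n(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class FiringFeatures:
    """The three headline encoding parameters (pps) plus their windows."""

    initial_burst_pps: float
    peak_dynamic_pps: float
    static_avg_pps: float
    flags: tuple[str, ...] = ()
    windows: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "initial_burst_pps": self.initial_burst_pps,
            "peak_dynamic_pps": self.peak_dynamic_pps,
            "static_avg_pps": self.static_avg_pps,
            "flags": list(self.flags),
            "windows": {k: list(v) for k, v in self.windows.items()},
        }


def detect_spikes(
    t: np.ndarray,
    v: np.ndarray,
    threshold_mv: float = -20.0,
    min_isi_ms: float = 1.0,
    site: str = "",
) -> SpikeTrain:
    """Upward threshold crossings with refractory enforcement.

    Spike time is the linearly interpolated crossing of ``threshold_mv``;
    crossings closer than ``min_isi_ms`` to the previous accepted spike are
    discarded. An empty train is a valid result.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    above = v >= threshold_mv
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return SpikeTrain(times=np.empty(0), site=site)
    frac = (threshold_mv - v[idx]) / (v[idx + 1] - v[idx])
    times = t[idx] + frac * (t[idx + 1] - t[idx])
    min_isi = min_isi_ms * 1e-3
    kept = [times[0]]
    for ts in times[1:]:
        if ts - kept[-1] >= min_isi:
            kept.append(ts)
    return SpikeTrain(times=np.array(kept), site=site)


def instantaneous_rate(s: SpikeTrain) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous firing rate 1/ISI (pps), assigned at the later spike of
    each interval. Fewer than 2 spikes gives empty series."""
    if s.n < 2:
        return np.empty(0), np.empty(0)
    isi = np.diff(s.times)
    return s.times[1:], 1.0 / isi


def feature_windows(spec: RampSpec, onset_window_s: float = 0.1,
                    static_fraction: float = 0.8,
                    dynamic_skip_fraction: float = 0.3) -> dict[str, tuple[float, float]]:
    """Analysis windows from the stimulus phase boundaries.

    The dynamic window covers the late ramp (after ``dynamic_skip_fraction``
    of the ramp, plus 20 ms of the early hold where the rate peak can land),
    so the onset burst and the end-of-ramp dynamic peak are measured as
    distinct quantities.
    """
    ph = spec.phase_times()
    hold = ph["release_on"] - ph["ramp_off"]
    margin = 0.5 * (1.0 - static_fraction) * hold
    ramp = ph["ramp_off"] - ph["ramp_on"]
    return {
        "onset": (ph["ramp_on"], ph["ramp_on"] + onset_window_s),
        "dynamic": (ph["ramp_on"] + dynamic_skip_fraction * ramp,
                    ph["ramp_off"] + 0.02),
        "static": (ph["ramp_off"] + margin, ph["release_on"] - margin),
    }


def extract_features(
    s: SpikeTrain,
    spec: RampSpec,
    windows: dict[str, tuple[float, float]] | None = None,
) -> FiringFeatures:
    """Extract initial burst, peak dynamic and static average rates.

    A window with no rate samples contributes a 0 feature and a flag.
    """
    if windows is None:
        windows = feature_windows(spec)
    t_ifr, ifr = instantaneous_rate(s)
    flags: list[str] = []

    def window_max(w):
        m = (t_ifr >= w[0]) & (t_ifr <= w[1])
        return float(ifr[m].max()) if m.any() else 0.0

    def window_mean(w):
        m = (t_ifr >= w[0]) & (t_ifr <= w[1])
        return float(ifr[m].mean()) if m.any() else 0.0

    burst = window_max(windows["onset"])
    peak_dyn = window_max(windows["dynamic"])
    static = window_mean(windows["static"])
    if burst == 0.0:
        flags.append("onset failure")
    if peak_dyn == 0.0:
        flags.append("dynamic failure")
    if static == 0.0:
        flags.append("static failure")
    return FiringFeatures(
        initial_burst_pps=burst,
        peak_dynamic_pps=peak_dyn,
        static_avg_pps=static,
        flags=tuple(flags),
        windows=dict(windows),
    )


def percent_change(test: float, base: float) -> float:
    """Percent reduction relative to base: 100*(base - test)/base.

    Positive values are reductions (the convention used throughout the
    sweep reports); negative values are increases.
    """
    if base == 0:
        raise ZeroDivisionError("base feature is 0; percent change undefined")
    return 100.0 * (base - test) / base
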