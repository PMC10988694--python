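"""Receptor-potential generation from intrafusal forces.

The mechanotransduction stage is phenomenological: the drive injected into
the sensory terminals is a conductance proportional to a weighted sum of the
half-wave rectified bag force, bag yank and chain force,

    g_drive = scale * (kfb * [F_bag]+ + kyb * [Y_bag]+ + kfc * [F_chain]+),

with each component rectified before weighting. The global ``scale`` factor
(default 2e5) carries the conversion from force units to conductance; the
weights are fixed once by calibration and held for all simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from spindlesim.intrafusal import ForceTrace

__all__ = [
    "ReceptorPotentialParams",
    "DriveSignal",
    "halfwave_rectify",
    "compute_receptor_drive",
]


class GridMismatchError(ValueError):
    """Bag and chain traces are not on the same time grid."""


@dataclass(frozen=True)
class ReceptorPotentialParams:
    """Weights of the force/yank to conductance map.

    ``scale`` converts (dimensionless) force units to uS of transduction
    conductance; ``e_rev_mV`` is the reversal potential of the transduction
    current (near 0 mV, generic cation).
    """

    kfb: float = 1.0       # weight on bag force
    kyb: float = 0.03      # weight on bag yank (units: per 1/s)
    kfc: float = 1.0       # weight on chain force
    scale: float = 2e5     # force -> conductance scale factor
    e_rev_mV: float = 0.0

    def __post_init__(self) -> None:
        if min(self.kfb, self.kyb, self.kfc) < 0:
            raise ValueError("weights must be non-negative")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass(frozen=True)
class DriveSignal:
    """Transduction conductance time series (uS), split evenly across the
    two terminal branches when injected."""

    t: np.ndarray
    g_drive: np.ndarray

    def __post_init__(self) -> None:
        if len(self.t) != len(self.g_drive):
            raise ValueError("t and g_drive must share the grid")
        if np.any(np.asarray(self.g_drive) < 0):
            raise ValueError("g_drive must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def halfwave_rectify(x: np.ndarray) -> np.ndarray:
    """Element-wise max(x, 0)."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def compute_receptor_drive(
    bag: ForceTrace,
    chain: ForceTrace,
    p: ReceptorPotentialParams,
    baseline_subtract: bool = False,
) -> DriveSignal:
    """Combine bag and chain force traces into the transduction conductance.

    By default forces enter raw, so the resting isometric force produces a
    tonic drive (background firing is a normal Ia phenotype). With
    ``baseline_subtract`` the resting force is removed from each component
    before rectification and the drive is zero at rest; yank is unaffected
    either way.
    """
    if bag.t.shape != chain.t.shape or not np.allclose(bag.t, chain.t):
        raise GridMismatchError("bag and chain traces must share the time grid")
    f_bag = bag.force - (bag.force[0] if baseline_subtract else 0.0)
    f_chain = chain.force - (chain.force[0] if baseline_subtract else 0.0)
    g = p.scale * (
        p.kfb * halfwave_rectify(f_bag)
        + p.kyb * halfwave_rectify(bag.yank)
        + p.kfc * halfwave_rectify(f_chain)
    )
    return DriveSignal(t=bag.t.copy(), g_drive=g)
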