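"""Shared fixtures.

The full-pipeline base run is expensive (seconds), so it is computed once
per session and shared; tests must not mutate it.
"""

from __future__ import annotations

import numpy as np
import pytest

from spindlesim import config as cfgmod
from spindlesim import pipeline as pl
from spindlesim.stimuli import RampSpec, make_ramp_hold_release


@pytest.fixture(scope="session")
def base_config() -> dict:
    return cfgmod.default_config()


@pytest.fixture(scope="session")
def base_run(base_config):
    """Calibrated base model on the default ramp-hold-release stimulus."""
    return pl.run_pipeline(base_config)


@pytest.fixture(scope="session")
def short_ramp_spec() -> RampSpec:
    """A short ramp protocol for solver-level tests (cheap)."""
    return RampSpec(baseline_s=0.2, amplitude_mm=3.0, velocity_mm_per_s=20.0,
                    hold_s=0.3, post_s=0.1)


@pytest.fixture(scope="session")
def short_stimulus(short_ramp_spec):
    return make_ramp_hold_release(short_ramp_spec)


@pytest.fixture(scope="session")
def short_drive(base_config, short_stimulus):
    return pl.compute_drive(base_config, short_stimulus)


def build_uniform_passive_cable(n=25, length_um=1000.0, diam_um=1.5, g_leak=1e-4):
    """Unbranched passive cable as a CompartmentGraph, probes everywhere."""
    import math

    from spindlesim import neuron as nrn

    seg = length_um / n
    area = math.pi * diam_um * seg
    g_ax = nrn._axial_g_us(seg, diam_um, seg, diam_um, 100.0)
    g = nrn.CompartmentGraph(
        region=["terminal"] * n,
        parent=np.array(list(range(1, n)) + [-1], dtype=np.int32),
        g_ax=np.array([g_ax] * (n - 1) + [0.0]),
        area_um2=np.full(n, area),
        c_nf=np.full(n, 1.0 * area * 1e-5),
        g_leak_us=np.full(n, g_leak * area * 1e-2),
        e_leak=np.full(n, -65.0),
        probes={f"c{i}": i for i in range(n)},
    )
    nrn.assign_channels(g, {})   # passive: no channels anywhere
    return g, seg


@pytest.fixture(scope="session")
def passive_cable_builder():
    return build_uniform_passive_cable
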