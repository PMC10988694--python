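"""Voltage-gated and Ca-dependent conductance models of the Ia afferent.

Seven conductances are provided, each behind a uniform state-update/current
contract so the cable solver can treat them interchangeably:

* ``kv1``  — low-threshold delayed rectifier with slow partial inactivation
  (juxtaparanodal phenotype; dampens re-excitation after the spike).
* ``kv33`` — high-threshold, fast activating/deactivating Kv3 current
  (spike repolarization that permits fast firing).
* ``kcnq`` — non-inactivating M-current with slow kinetics (sub-threshold
  excitability brake; sets static-firing competence).
* ``sk2``  — Ca-activated K current gated by a Hill function of a local Ca
  pool (medium AHP, firing-rate adaptation).
* ``nav11``, ``nav16`` — 10-state Markov Na channels: an activation chain of
  three closed states, an allosterically coupled fast-inactivation tier, and
  two slow-inactivated states, one entered from the open state and one from
  the fast-inactivated state.
* ``nav17`` — 6-state Markov Na channel with a single slow-inactivated state
  reached through fast inactivation; low activation threshold (amplifies
  slow depolarizations such as the receptor potential).

The Markov topologies follow the allosteric scheme of Kuo & Bean (1994):
closed-state inactivation rates scale by a factor ``a`` per activation step,
which keeps the activation/inactivation loops thermodynamically consistent.
Rate constants are model parameters (exposed via the config system), not
measured quantities; they were set to give each isoform its qualitative
phenotype and then held fixed.

HH gates use x_inf(V) = 1/(1+exp((v_half - V)/slope)) (slope < 0 for
inactivation gates) and a bell-shaped tau(V) = tau_base +
tau_amp / cosh((V - tau_vhalf)/tau_scale). Units: mV, ms, uM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "HHGate",
    "HHChannel",
    "MarkovScheme",
    "MarkovChannel",
    "SKChannel",
    "gate_steady_state",
    "markov_rate_matrix",
    "markov_stationary",
    "step_channel",
    "channel_current",
    "voltage_clamp",
    "make_channel",
    "CHANNEL_NAMES",
]

E_NA = 60.0    # mV
E_K = -90.0    # mV


class SchemeError(ValueError):
    """A rate function produced an inadmissible (negative) rate."""


class StabilityError(RuntimeError):
    """Occupancy left the probability simplex beyond tolerance."""


# --------------------------------------------------------------------------
# HH gates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HHGate:
    """One Hodgkin-Huxley gate: Boltzmann steady state, bell-shaped tau."""

    v_half: float          # mV
    slope: float           # mV; > 0 activation, < 0 inactivation
    tau_base: float        # ms
    tau_amp: float = 0.0   # ms
    tau_vhalf: float = 0.0
    tau_scale: float = 20.0
    power: int = 1
    floor: float = 0.0     # residual non-inactivating fraction (h gates)

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be non-zero")
        if self.tau_base <= 0:
            raise ValueError("tau_base must be positive")

    def steady_state(self, v: float | np.ndarray) -> float | np.ndarray:
        x = 1.0 / (1.0 + np.exp((self.v_half - np.asarray(v, float)) / self.slope))
        return self.floor + (1.0 - self.floor) * x

    def tau(self, v: float | np.ndarray) -> float | np.ndarray:
        v = np.asarray(v, float)
        return self.tau_base + self.tau_amp / np.cosh((v - self.tau_vhalf) / self.tau_scale)


def gate_steady_state(gate: HHGate, v: float) -> tuple[float, float]:
    """(x_inf, tau_ms) of one gate at voltage ``v``."""
    return float(gate.steady_state(v)), float(gate.tau(v))


@dataclass(frozen=True)
class HHChannel:
    """Product-of-gates conductance."""

    name: str
    gates: tuple[HHGate, ...]
    e_rev: float

    @property
    def n_states(self) -> int:
        return len(self.gates)

    def init_state(self, v: float, ca: float = 0.0) -> np.ndarray:
        return np.array([g.steady_state(v) for g in self.gates])

    def step(self, state: np.ndarray, v: float, ca: float, dt: float) -> np.ndarray:
        out = np.empty_like(state)
        for i, g in enumerate(self.gates):
            inf = g.steady_state(v)
            out[i] = inf + (state[i] - inf) * np.exp(-dt / g.tau(v))
        return out

    def open_fraction(self, state: np.ndarray) -> float:
        o = 1.0
        for g, x in zip(self.gates, state):
            o *= float(x) ** g.power
        return o


# --------------------------------------------------------------------------
# Markov schemes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkovScheme:
    """Named-state kinetic scheme with voltage-dependent rates.

    ``rates(v)`` returns the off-diagonal rate matrix R with R[i, j] the
    i -> j transition rate (1/ms) at voltage ``v`` (mV).
    """

    name: str
    states: tuple[str, ...]
    rates: Callable[[float], np.ndarray]
    conducting: tuple[int, ...]

    @property
    def n_states(self) -> int:
        return len(self.states)


def markov_rate_matrix(scheme: MarkovScheme, v: float) -> np.ndarray:
    """Generator matrix Q at voltage ``v``: off-diagonals are the transition
    rates, each row sums to zero. Raises :class:`SchemeError` on a negative
    user-supplied rate."""
    r = np.array(scheme.rates(v), dtype=float)
    if r.shape != (scheme.n_states, scheme.n_states):
        raise SchemeError(f"{scheme.name}: rate matrix shape {r.shape}")
    np.fill_diagonal(r, 0.0)
    if np.any(r < 0):
        raise SchemeError(f"{scheme.name}: negative rate at V={v} mV")
    q = r.copy()
    np.fill_diagonal(q, -r.sum(axis=1))
    return q


def markov_stationary(scheme: MarkovScheme, v: float) -> np.ndarray:
    """Stationary occupancy at fixed voltage: null vector of Q^T constrained
    to the probability simplex (direct linear solve)."""
    q = markov_rate_matrix(scheme, v)
    n = scheme.n_states
    a = np.vstack([q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(a, b, rcond=None)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


@dataclass(frozen=True)
class MarkovChannel:
    name: str
    scheme: MarkovScheme
    e_rev: float

    @property
    def n_states(self) -> int:
        return self.scheme.n_states

    def init_state(self, v: float, ca: float = 0.0) -> np.ndarray:
        return markov_stationary(self.scheme, v)

    def step(self, state: np.ndarray, v: float, ca: float, dt: float) -> np.ndarray:
        q = markov_rate_matrix(self.scheme, v)
        n = self.n_states
        m = np.eye(n) - dt * q.T
        p = np.linalg.solve(m, state)
        s = p.sum()
        if not (0.5 < s < 2.0) or np.any(p < -1e-6):
            raise StabilityError(
                f"{self.name}: occupancy left simplex (sum={s:.3g}) at dt={dt}"
            )
        p = np.clip(p, 0.0, None)
        return p / p.sum()

    def open_fraction(self, state: np.ndarray) -> float:
        return float(sum(state[i] for i in self.scheme.conducting))


# --------------------------------------------------------------------------
# SK (Ca-gated)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SKChannel:
    """Ca-activated K channel; activation follows a Hill function of the
    local Ca pool with first-order kinetics."""

    name: str = "sk2"
    ca_half: float = 0.25  # uM
    hill: float = 2.0
    tau_ms: float = 20.0
    e_rev: float = E_K

    def __post_init__(self) -> None:
        if self.ca_half <= 0 or self.hill <= 0:
            raise ValueError("ca_half and hill must be positive")

    @property
    def n_states(self) -> int:
        return 1

    def activation_inf(self, ca: float) -> float:
        if ca <= 0:
            return 0.0
        c = (ca / self.ca_half) ** self.hill
        return c / (1.0 + c)

    def init_state(self, v: float, ca: float = 0.0) -> np.ndarray:
        return np.array([self.activation_inf(ca)])

    def step(self, state: np.ndarray, v: float, ca: float, dt: float) -> np.ndarray:
        inf = self.activation_inf(ca)
        return np.array([inf + (state[0] - inf) * np.exp(-dt / self.tau_ms)])

    def open_fraction(self, state: np.ndarray) -> float:
        return float(state[0])


# --------------------------------------------------------------------------
# Nav scheme builders
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NavRates:
    """Rate parameters of the allosteric Nav schemes (1/ms, mV).

    Activation steps use alpha(V) = alpha0*exp((V - v_shift)/ka) and
    beta(V) = beta0*exp(-(V - v_shift)/kb) with multiplicities 3:2:1 along
    the three-step chain. ``con``/``coff`` are closed-state inactivation
    rates, ``oon``/``ooff`` open-state fast inactivation; the allosteric
    factor a = (oon*coff/(con*ooff))**(1/3) couples the tiers. ``s*`` rates
    govern slow inactivation.
    """

    alpha0: float = 2.0
    ka: float = 12.0
    beta0: float = 2.0
    kb: float = 12.0
    v_shift: float = -45.0   # per-step activation midpoint (mV)
    con: float = 0.002
    coff: float = 0.1
    oon: float = 0.6
    ooff: float = 0.01
    allosteric: float = 4.0  # closed-state inactivation coupling factor
    s_on: float = 0.0025    # O -> slow inactivated
    s_off: float = 0.0005
    s2_on: float = 0.004    # fast-inactivated -> slow inactivated
    s2_off: float = 0.0008

    def alpha(self, v: float) -> float:
        return self.alpha0 * np.exp((v - self.v_shift) / self.ka)

    def beta(self, v: float) -> float:
        return self.beta0 * np.exp(-(v - self.v_shift) / self.kb)


def _nav10_rates(p: NavRates) -> Callable[[float], np.ndarray]:
    """10-state scheme: C1 C2 C3 O | IC1 IC2 IC3 IF | IS1 IS2.

    IS1 is entered from the open state, IS2 from the fast-inactivated state.
    """
    a = p.allosteric

    def rates(v: float) -> np.ndarray:
        r = np.zeros((10, 10))
        al, be = p.alpha(v), p.beta(v)
        # activation chain C1-C2-C3-O (indices 0-3)
        mult_f = (3.0, 2.0, 1.0)
        mult_b = (1.0, 2.0, 3.0)
        for i in range(3):
            r[i, i + 1] = mult_f[i] * al
            r[i + 1, i] = mult_b[i] * be
        # inactivated activation chain IC1-IC2-IC3-IF (indices 4-7)
        for i in range(3):
            r[4 + i, 5 + i] = mult_f[i] * al * a
            r[5 + i, 4 + i] = mult_b[i] * be / a
        # vertical coupling: closed-state inactivation, allosterically scaled
        for i in range(3):
            r[i, 4 + i] = p.con * a**i
            r[4 + i, i] = p.coff / a**i
        r[3, 7] = p.oon      # O -> IF
        r[7, 3] = p.ooff     # IF -> O
        # slow inactivation
        r[3, 8] = p.s_on     # O -> IS1
        r[8, 3] = p.s_off
        r[7, 9] = p.s2_on    # IF -> IS2
        r[9, 7] = p.s2_off
        return r

    return rates


def _nav6_rates(p: NavRates) -> Callable[[float], np.ndarray]:
    """6-state scheme: C1 C2 C3 O IF IS (slow inactivation via IF)."""

    def rates(v: float) -> np.ndarray:
        r = np.zeros((6, 6))
        al, be = p.alpha(v), p.beta(v)
        mult_f = (3.0, 2.0, 1.0)
        mult_b = (1.0, 2.0, 3.0)
        for i in range(3):
            r[i, i + 1] = mult_f[i] * al
            r[i + 1, i] = mult_b[i] * be
        r[3, 4] = p.oon
        r[4, 3] = p.ooff
        r[4, 5] = p.s2_on
        r[5, 4] = p.s2_off
        return r

    return rates


NAV10_STATES = ("C1", "C2", "C3", "O", "IC1", "IC2", "IC3", "IF", "IS1", "IS2")
NAV6_STATES = ("C1", "C2", "C3", "O", "IF", "IS")

#: per-isoform rate parameters (phenotype choices, see module docstring)
NAV_PARAMS: dict[str, NavRates] = {
    # Nav1.1: transient channel, higher threshold, strong slow inactivation
    # (contributes to the dynamic response, adapts away during the hold)
    "nav11": NavRates(v_shift=-40.0, coff=0.15, s_on=0.002, s2_on=0.006,
                      s_off=0.0005, s2_off=0.0005),
    # Nav1.6: low threshold, weak slow inactivation -> sustains repetitive
    # static-phase firing (the isoform that keeps the pacemaker alive)
    "nav16": NavRates(v_shift=-44.0, con=0.0015, coff=0.15, allosteric=3.0,
                      s_on=0.0003, s2_on=0.0005, s_off=0.001, s2_off=0.001),
    # Nav1.7: lowest threshold, amplifies slow ramp depolarizations, strong
    # slow inactivation entered through fast inactivation (onset transient)
    "nav17": NavRates(v_shift=-50.0, s2_on=0.008, s2_off=0.0004),
}


def nav_scheme(name: str, params: NavRates | None = None) -> MarkovScheme:
    p = params if params is not None else NAV_PARAMS[name]
    if name in ("nav11", "nav16"):
        return MarkovScheme(name, NAV10_STATES, _nav10_rates(p), conducting=(3,))
    if name == "nav17":
        return MarkovScheme(name, NAV6_STATES, _nav6_rates(p), conducting=(3,))
    raise KeyError(name)


# --------------------------------------------------------------------------
# K channel parameter sets
# --------------------------------------------------------------------------

def kv1_channel() -> HHChannel:
    """Low-threshold Kv1: activates near rest, slow partial inactivation."""
    return HHChannel(
        name="kv1",
        gates=(
            HHGate(v_half=-60.0, slope=5.0, tau_base=5.0, tau_amp=6.0,
                   tau_vhalf=-60.0, tau_scale=25.0, power=2),
        ),
        e_rev=E_K,
    )


def kv33_channel() -> HHChannel:
    """High-threshold Kv3.3: fast activation/deactivation, no inactivation."""
    return HHChannel(
        name="kv33",
        gates=(
            HHGate(v_half=-25.0, slope=6.0, tau_base=0.6, tau_amp=2.0,
                   tau_vhalf=-30.0, tau_scale=20.0, power=2),
        ),
        e_rev=E_K,
    )


def kcnq_channel() -> HHChannel:
    """KCNQ M-current: slow, non-inactivating, sub-threshold activation."""
    return HHChannel(
        name="kcnq",
        gates=(
            HHGate(v_half=-48.0, slope=6.0, tau_base=15.0, tau_amp=110.0,
                   tau_vhalf=-48.0, tau_scale=22.0, power=1),
        ),
        e_rev=E_K,
    )


def sk2_channel() -> SKChannel:
    return SKChannel()


CHANNEL_NAMES = ("nav11", "nav16", "nav17", "kv1", "kv33", "sk2", "kcnq")


def make_channel(name: str):
    """Channel factory by canonical name."""
    if name in ("nav11", "nav16", "nav17"):
        return MarkovChannel(name=name, scheme=nav_scheme(name), e_rev=E_NA)
    if name == "kv1":
        return kv1_channel()
    if name == "kv33":
        return kv33_channel()
    if name == "kcnq":
        return kcnq_channel()
    if name == "sk2":
        return sk2_channel()
    raise KeyError(f"unknown channel {name!r}; known: {CHANNEL_NAMES}")


# --------------------------------------------------------------------------
# Uniform contract helpers
# --------------------------------------------------------------------------

def step_channel(channel, state: np.ndarray, v: float, ca: float, dt: float) -> np.ndarray:
    """Advance any channel one step of ``dt`` ms at fixed voltage/calcium.

    HH gates use the exact exponential update; Markov occupancies use
    backward Euler on the generator, renormalized to the simplex.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    return channel.step(state, v, ca, dt)


def channel_current(channel, state: np.ndarray, v: float, g_density: float,
                    area_um2: float, e_rev: float | None = None) -> float:
    """Ohmic current in nA: g_density [S/cm^2] * area [um^2] * p_open * (V - E).

    1 S/cm^2 * 1 um^2 = 1e-8 S, so the prefactor 1e-2 yields nA with V in mV.
    """
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    e = channel.e_rev if e_rev is None else e_rev
    return 1e-2 * g_density * area_um2 * channel.open_fraction(state) * (v - e)


def voltage_clamp(
    channel,
    holding_mv: float,
    steps: Sequence[tuple[float, float]],
    dt: float = 0.01,
    g_density: float = 0.01,
    area_um2: float = 100.0,
    ca: float = 0.0,
) -> list[dict]:
    """Voltage-clamp harness: from the stationary state at the holding
    potential, apply (voltage, duration_ms) steps and record the current.

    Returns one dict per step with keys ``t`` (ms), ``v`` (mV), ``i`` (nA)
    and ``open`` (open fraction).
    """
    state = channel.init_state(holding_mv, ca)
    out = []
    for v_step, dur in steps:
        if dur <= 0:
            raise ValueError("step durations must be positive")
        n = int(round(dur / dt))
        t = np.arange(n) * dt
        i_tr = np.empty(n)
        o_tr = np.empty(n)
        for k in range(n):
            state = step_channel(channel, state, v_step, ca, dt)
            o_tr[k] = channel.open_fraction(state)
            i_tr[k] = channel_current(channel, state, v_step, g_density, area_um2)
        out.append({"t": t, "v": v_step, "i": i_tr, "open": o_tr})
    return out
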