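"""Multicompartment cable model of the Ia afferent ending.

Morphology (fixed topology, dimension-configurable): two annulospiral
receptor terminals converge on a single preterminal axon that leads to a
heminode — the first node of Ranvier, where myelin begins — followed by four
further nodes, each flanked by paranodes and separated by myelinated
internodes. Channel densities are assigned per region; the four ordinary
nodes inherit the heminode's densities (the density table distinguishes only
terminal / preterminal / heminode / paranode; internodes are passive).

Compartments are indexed distal-to-proximal with every compartment's parent
closer to the root (the most proximal node, probe site ``node5``), which is
what the Hines solver in :mod:`spindlesim._core` requires.

Units: lengths um, Cm uF/cm^2, Ra Ohm*cm, densities S/cm^2 internally
(Nav densities are quoted in pS/um^2 at the config surface and converted via
1 pS/um^2 = 1e-4 S/cm^2), conductances uS, capacitance nF, current nA,
voltage mV, time ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from spindlesim import channels as ch
from spindlesim._core import integrate
from spindlesim.transduction import DriveSignal

__all__ = [
    "RegionSpec",
    "MorphologyConfig",
    "CompartmentGraph",
    "SimConfig",
    "SimResult",
    "build_morphology",
    "assign_channels",
    "simulate",
    "initiation_order",
    "PS_PER_UM2_TO_S_PER_CM2",
]

PS_PER_UM2_TO_S_PER_CM2 = 1e-4

REGION_KINDS = ("terminal", "preterminal", "heminode", "node", "paranode", "internode")

#: channels quoted in pS/um^2 in the density table (the Nav isoforms);
#: all others are quoted in S/cm^2
NAV_UNIT_CHANNELS = ("nav11", "nav16", "nav17")


class ConfigError(ValueError):
    pass


class CableStabilityError(RuntimeError):
    pass


@dataclass(frozen=True)
class RegionSpec:
    """Geometry and passive properties of one anatomical region."""

    kind: str
    length_um: float
    diam_um: float
    cm: float = 1.0          # uF/cm^2
    ra: float = 100.0        # Ohm*cm
    g_leak: float = 1e-4     # S/cm^2
    e_leak: float = -65.0    # mV
    max_seg_um: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ConfigError(f"unknown region kind {self.kind!r}")
        if self.length_um <= 0 or self.diam_um <= 0:
            raise ConfigError("length and diameter must be positive")

    def n_segments(self) -> int:
        """Segments so that no segment exceeds min(0.1 lambda_DC, max_seg)."""
        rm = 1.0 / self.g_leak                      # Ohm*cm^2
        lam_cm = math.sqrt(rm * (self.diam_um * 1e-4) / (4.0 * self.ra))
        cap = min(0.1 * lam_cm * 1e4, self.max_seg_um)
        return max(1, int(math.ceil(self.length_um / cap)))


def default_regions(
    terminal_length_multiplier: float = 1.0,
    preterminal_length_multiplier: float = 1.0,
) -> dict[str, RegionSpec]:
    """Base geometry (rat-scale defaults; sweeps are expressed as length
    multipliers relative to this base)."""
    if terminal_length_multiplier <= 0 or preterminal_length_multiplier <= 0:
        raise ConfigError("length multipliers must be positive")
    return {
        "terminal": RegionSpec("terminal", 240.0 * terminal_length_multiplier, 1.5),
        "preterminal": RegionSpec(
            "preterminal", 20.0 * preterminal_length_multiplier, 0.7
        ),
        "heminode": RegionSpec("heminode", 1.5, 1.2, max_seg_um=5.0),
        "node": RegionSpec("node", 1.5, 1.2, max_seg_um=5.0),
        # paranodes sit under the myelin edge: partial myelin attenuation
        "paranode": RegionSpec(
            "paranode", 3.0, 1.2, cm=0.2, g_leak=1e-5, max_seg_um=5.0
        ),
        # myelinated: 50x lower capacitance and leak, no channels
        "internode": RegionSpec(
            "internode", 100.0, 1.2, cm=1.0 / 50.0, g_leak=1e-4 / 50.0,
            max_seg_um=50.0,
        ),
    }


@dataclass(frozen=True)
class MorphologyConfig:
    terminal_length_multiplier: float = 1.0
    preterminal_length_multiplier: float = 1.0
    n_nodes: int = 5           # heminode + 4 further nodes
    regions: dict[str, RegionSpec] | None = None

    def region_set(self) -> dict[str, RegionSpec]:
        if self.regions is not None:
            return self.regions
        return default_regions(
            self.terminal_length_multiplier, self.preterminal_length_multiplier
        )


@dataclass
class CompartmentGraph:
    """Discretized morphology plus per-compartment channel placements."""

    region: list[str]                 # region kind per compartment
    parent: np.ndarray                # int32, parent index (root: -1)
    g_ax: np.ndarray                  # uS, axial conductance to parent
    area_um2: np.ndarray
    c_nf: np.ndarray                  # membrane capacitance (nF)
    g_leak_us: np.ndarray
    e_leak: np.ndarray
    probes: dict[str, int]            # site name -> compartment index
    # channel placements: name -> (comp_idx int32[:], gmax_uS float64[:])
    placements: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    densities: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def n_comp(self) -> int:
        return len(self.region)

    def terminal_indices(self) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(self.region) if r == "terminal"], dtype=np.int32
        )


def _axial_g_us(len1, diam1, len2, diam2, ra) -> float:
    """Axial conductance between centres of two adjacent compartments (uS)."""
    def half_res(length_um, diam_um):
        area_cm2 = math.pi * (diam_um * 1e-4) ** 2 / 4.0
        return ra * (length_um * 1e-4 / 2.0) / area_cm2  # Ohm
    return 1e6 / (half_res(len1, diam1) + half_res(len2, diam2))


def build_morphology(cfg: MorphologyConfig) -> CompartmentGraph:
    """Discretize the fixed Ia-ending topology into a compartment tree.

    Ordering: terminal branch A (tip -> junction), terminal branch B,
    preterminal (distal -> proximal), heminode, then per internodal span
    [paranode, internode segments, paranode, node] out to node 5 (root).
    """
    regions = cfg.region_set()
    specs: list[tuple[str, float, float, RegionSpec]] = []  # (kind, l, d, spec)
    branch_starts: list[int] = []

    def add_region(spec: RegionSpec) -> list[int]:
        nseg = spec.n_segments()
        idx = []
        for _ in range(nseg):
            specs.append((spec.kind, spec.length_um / nseg, spec.diam_um, spec))
            idx.append(len(specs) - 1)
        return idx

    term = regions["terminal"]
    idx_a = add_region(term)
    idx_b = add_region(term)
    idx_pre = add_region(regions["preterminal"])
    idx_hemi = add_region(regions["heminode"])
    chain = [idx_hemi[-1]]
    node_last = idx_hemi[-1]
    spans: list[list[int]] = []
    for _ in range(cfg.n_nodes - 1):
        span = []
        span += add_region(regions["paranode"])
        span += add_region(regions["internode"])
        span += add_region(regions["paranode"])
        span += add_region(regions["node"])
        spans.append(span)

    n = len(specs)
    parent = np.full(n, -1, dtype=np.int32)
    # within-branch chains
    for seq in (idx_a, idx_b, idx_pre, idx_hemi):
        for j in range(len(seq) - 1):
            parent[seq[j]] = seq[j + 1]
    parent[idx_a[-1]] = idx_pre[0]
    parent[idx_b[-1]] = idx_pre[0]
    parent[idx_pre[-1]] = idx_hemi[0]
    prev = idx_hemi[-1]
    for span in spans:
        parent[prev] = span[0]
        for j in range(len(span) - 1):
            parent[span[j]] = span[j + 1]
        prev = span[-1]
    root = prev
    parent[root] = -1
    if not np.all(parent[:-1] > np.arange(n - 1)):
        raise RuntimeError("compartment ordering violates child-before-parent")

    g_ax = np.zeros(n)
    for i in range(n - 1):
        ki, li, di, _ = specs[i]
        kp, lp, dp, _ = specs[parent[i]]
        g_ax[i] = _axial_g_us(li, di, lp, dp, specs[i][3].ra)

    area = np.array([math.pi * d * l for _, l, d, _ in specs])  # um^2
    cm = np.array([s.cm for _, _, _, s in specs])
    gl = np.array([s.g_leak for _, _, _, s in specs])
    el = np.array([s.e_leak for _, _, _, s in specs])
    c_nf = cm * area * 1e-8 * 1e3          # uF/cm^2 * cm^2 -> uF -> nF... (1e-8 cm^2/um^2, 1e3 nF/uF)
    g_leak_us = gl * area * 1e-8 * 1e6     # S/cm^2 * cm^2 -> S -> uS

    node_ids = [idx_hemi[-1]] + [span[-1] for span in spans]
    probes = {
        "terminal": idx_a[0],
        "heminode": idx_hemi[-1],
        "node5": node_ids[-1],
    }
    return CompartmentGraph(
        region=[k for k, _, _, _ in specs],
        parent=parent,
        g_ax=g_ax,
        area_um2=area,
        c_nf=c_nf,
        g_leak_us=g_leak_us,
        e_leak=el,
        probes=probes,
    )


def table1_densities() -> dict[str, dict[str, float]]:
    """Base channel density table, region -> channel -> density.

    Nav entries in pS/um^2, K/SK entries in S/cm^2 (the KCNQ figure is
    treated as S/cm^2). Ordinary nodes reuse the heminode row.
    """
    return {
        "terminal": {
            "nav11": 250.0, "nav16": 25.0, "nav17": 250.0,
            "kv33": 0.012, "sk2": 0.0025, "kcnq": 0.0005,
        },
        "preterminal": {"nav16": 250.0, "nav17": 500.0, "sk2": 0.0025},
        "heminode": {"nav16": 2500.0, "kv33": 0.012, "kcnq": 0.0005},
        # ordinary nodes: heminode Nav/Kv complement plus the KCNQ2/3
        # enrichment of mature nodes of Ranvier (prevents tonic nodal firing)
        "node": {"nav16": 1200.0, "kv33": 0.012, "kcnq": 0.05},
        "paranode": {"kv1": 0.01},
    }


def assign_channels(
    g: CompartmentGraph, table: dict[str, dict[str, float]] | None = None
) -> CompartmentGraph:
    """Attach channel conductances to compartments from a density table.

    Nav densities are converted from pS/um^2 to S/cm^2 internally; ordinary
    nodes inherit the heminode row.
    """
    if table is None:
        table = table1_densities()
    for region, row in table.items():
        if region not in REGION_KINDS:
            raise ConfigError(f"unknown region {region!r} in density table")
        for name in row:
            if name not in ch.CHANNEL_NAMES:
                raise ConfigError(f"unknown channel {name!r} in density table")
    placements: dict[str, list[tuple[int, float]]] = {n: [] for n in ch.CHANNEL_NAMES}
    for i, region in enumerate(g.region):
        row = table.get(region)
        if row is None and region == "node":
            row = table.get("heminode")
        if not row:
            continue
        for name, dens in row.items():
            if dens <= 0:
                continue
            d_s_cm2 = dens * PS_PER_UM2_TO_S_PER_CM2 if name in NAV_UNIT_CHANNELS else dens
            gmax_us = d_s_cm2 * g.area_um2[i] * 1e-2  # S/cm^2 * um^2 -> uS
            placements[name].append((i, gmax_us))
    g.placements = {
        name: (
            np.array([i for i, _ in lst], dtype=np.int32),
            np.array([v for _, v in lst], dtype=float),
        )
        for name, lst in placements.items()
    }
    g.densities = {r: dict(row) for r, row in table.items()}
    return g


@dataclass(frozen=True)
class SimConfig:
    dt_ms: float = 0.0125
    settle_ms: float = 500.0
    v_init: float = -65.0
    e_drive: float = 0.0
    ca_rest_um: float = 0.05
    tau_ca_ms: float = 50.0
    ca_phi: float = 0.04         # uM per (nA/um^2 * ms) influx gain
    record_sites: tuple[str, ...] = ("terminal", "heminode", "node5")

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ConfigError("dt must be positive")


@dataclass
class SimResult:
    """Voltage traces at probe sites on the stimulus time base (settling
    period discarded; t in seconds to match the stimulus)."""

    t: np.ndarray                  # s
    v: dict[str, np.ndarray]       # mV per probe site
    ca_terminal: np.ndarray        # uM at the terminal probe
    dt_ms: float


# voltage table span for channel-state tabulation
_VGRID = (-120.0, 80.0, 0.2)


def _build_tables(dt_ms: float):
    """Tabulate HH gate targets/decays and Markov backward-Euler propagators
    on the voltage grid, for one solver step."""
    v0, v1, dv = _VGRID
    vs = np.arange(v0, v1 + dv / 2, dv)
    nv = vs.size
    tables: dict[str, dict] = {}
    for name in ("nav11", "nav16", "nav17"):
        chan = ch.make_channel(name)
        ns = chan.n_states
        t = np.empty((nv, ns, ns))
        eye = np.eye(ns)
        for k, v in enumerate(vs):
            q = ch.markov_rate_matrix(chan.scheme, v)
            t[k] = np.linalg.inv(eye - dt_ms * q.T)
        tables[name] = {"prop": t, "chan": chan}
    for name in ("kv1", "kv33", "kcnq"):
        chan = ch.make_channel(name)
        ng = len(chan.gates)
        inf = np.empty((nv, ng))
        dec = np.empty((nv, ng))
        for gidx, gate in enumerate(chan.gates):
            inf[:, gidx] = gate.steady_state(vs)
            dec[:, gidx] = np.exp(-dt_ms / gate.tau(vs))
        tables[name] = {"inf": inf, "dec": dec, "chan": chan}
    tables["_grid"] = (v0, dv, nv)
    return tables


_TABLE_CACHE: dict[float, dict] = {}


def _tables_for(dt_ms: float) -> dict:
    if dt_ms not in _TABLE_CACHE:
        _TABLE_CACHE[dt_ms] = _build_tables(dt_ms)
    return _TABLE_CACHE[dt_ms]


def _placement(g: CompartmentGraph, name: str) -> tuple[np.ndarray, np.ndarray]:
    if name in g.placements:
        return g.placements[name]
    return np.empty(0, dtype=np.int32), np.empty(0)


def simulate(
    g: CompartmentGraph,
    drive: DriveSignal,
    cfg: SimConfig | None = None,
    drive_sites: np.ndarray | None = None,
) -> SimResult:
    """Integrate the cable model under a transduction-conductance drive.

    The drive (uS, on the stimulus grid in seconds) is linearly interpolated
    onto the solver grid and split across the terminal compartments in
    proportion to membrane area (half per branch). Before t = 0 the model
    settles for ``settle_ms`` at the initial drive level; the settling period
    is discarded from the returned traces.
    """
    if cfg is None:
        cfg = SimConfig()
    if not g.placements:
        assign_channels(g)
    dt = cfg.dt_ms
    tab = _tables_for(dt)
    v0, dv, nv = tab["_grid"]

    t_stim_ms = (drive.t - drive.t[0]) * 1e3
    n_stim = int(math.floor(t_stim_ms[-1] / dt)) + 1
    n_settle = int(round(cfg.settle_ms / dt))
    t_solver = np.arange(n_stim) * dt
    g_stim = np.interp(t_solver, t_stim_ms, drive.g_drive)
    drive_arr = np.concatenate([np.full(n_settle, g_stim[0]), g_stim])
    n_steps = drive_arr.size

    if drive_sites is None:
        dcomp = g.terminal_indices()
    else:
        dcomp = np.asarray(drive_sites, dtype=np.int32)
    if dcomp.size == 0:
        raise ConfigError("no compartments to inject the drive into")
    areas = g.area_um2[dcomp]
    dfrac = areas / areas.sum()

    n = g.n_comp
    v = np.full(n, cfg.v_init, dtype=float)
    ca = np.full(n, cfg.ca_rest_um, dtype=float)

    def markov_init(name):
        comp, gmax = _placement(g, name)
        chan = tab[name]["chan"]
        p = np.tile(chan.init_state(cfg.v_init), (comp.size, 1))
        return comp, gmax, np.ascontiguousarray(p), tab[name]["prop"]

    m11 = markov_init("nav11")
    m16 = markov_init("nav16")
    m17 = markov_init("nav17")

    def hh_init(name):
        comp, gmax = _placement(g, name)
        chan = tab[name]["chan"]
        x = np.tile(chan.init_state(cfg.v_init), (comp.size, 1))
        return comp, gmax, np.ascontiguousarray(x), tab[name]["inf"], tab[name]["dec"]

    kv1 = hh_init("kv1")
    kv33 = hh_init("kv33")
    kcnq = hh_init("kcnq")

    sk_comp, sk_g = _placement(g, "sk2")
    sk_chan = ch.make_channel("sk2")
    sk_a = np.full(sk_comp.size, sk_chan.activation_inf(cfg.ca_rest_um))
    sk_dec = math.exp(-dt / sk_chan.tau_ms)

    rec_names = [s for s in cfg.record_sites if s in g.probes]
    rec_idx = np.array([g.probes[s] for s in rec_names], dtype=np.int32)
    v_rec = np.empty((rec_idx.size, n_steps))
    ca_rec = np.empty(n_steps)

    status = integrate(
        v, g.parent, g.g_ax, g.c_nf / dt, g.g_leak_us, g.e_leak,
        drive_arr, dcomp, dfrac, cfg.e_drive,
        ca, cfg.ca_rest_um, cfg.tau_ca_ms, cfg.ca_phi, 1.0 / g.area_um2,
        v0, dv, nv,
        *m11, *m16, *m17, *kv1, *kv33, *kcnq,
        sk_comp, sk_g, sk_a, 1.0 / sk_chan.ca_half, sk_chan.hill, sk_dec,
        ch.E_NA, ch.E_K,
        rec_idx, dt, n_steps, v_rec, ca_rec,
    )
    if status != 0:
        raise CableStabilityError(
            f"voltage diverged (|V| > 200 mV); try a smaller dt than {dt} ms"
        )
    keep = slice(n_settle, None)
    return SimResult(
        t=t_solver * 1e-3 + drive.t[0],
        v={name: v_rec[k, keep] for k, name in enumerate(rec_names)},
        ca_terminal=ca_rec[keep],
        dt_ms=dt,
    )


def _crossings(t: np.ndarray, v: np.ndarray, thr: float) -> np.ndarray:
    """Upward threshold-crossing times, linearly interpolated."""
    above = v >= thr
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return np.empty(0)
    frac = (thr - v[idx]) / (v[idx + 1] - v[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def initiation_order(
    r: SimResult,
    threshold_mv: float = -20.0,
    window_s: float = 5e-3,
    max_spikes: int | None = None,
) -> list[list[str]]:
    """Per-spike ordering of probe sites by threshold-crossing time.

    Spikes are anchored at the site with the fewest crossings; for each
    anchor crossing, every site's crossing within ``window_s`` is collected
    and the sites are listed in order of crossing time (ties broken by the
    earlier anchor distance). Sites with no crossing in the window are
    reported as non-initiating (omitted from that spike's order).
    """
    cross = {s: _crossings(r.t, v, threshold_mv) for s, v in r.v.items()}
    if not cross:
        return []
    anchor_site = min(cross, key=lambda s: cross[s].size)
    orders: list[list[str]] = []
    for k, ta in enumerate(cross[anchor_site]):
        if max_spikes is not None and k >= max_spikes:
            break
        times = {}
        for s, ts in cross.items():
            if ts.size == 0:
                continue
            j = np.argmin(np.abs(ts - ta))
            if abs(ts[j] - ta) <= window_s:
                times[s] = ts[j]
        orders.append([s for s, _ in sorted(times.items(), key=lambda kv: kv[1])])
    return orders


def passive_cable_profile(
    length_um: float, diam_um: float, ra: float, g_leak: float, x_um: np.ndarray
) -> np.ndarray:
    """Closed-form steady-state voltage profile of a finite sealed-end cable
    with current injected at x=0, normalized to V(0)=1:
    V(x)/V(0) = cosh((L-x)/lambda) / cosh(L/lambda)."""
    rm = 1.0 / g_leak
    lam_um = math.sqrt(rm * (diam_um * 1e-4) / (4.0 * ra)) * 1e4
    return np.cosh((length_um - x_um) / lam_um) / np.cosh(length_um / lam_um)
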