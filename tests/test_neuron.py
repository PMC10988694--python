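import numpy as np
import pytest

from spindlesim import neuron as nrn
from spindlesim.features import detect_spikes
from spindlesim.transduction import DriveSignal


@pytest.fixture(scope="module")
def base_graph():
    return nrn.assign_channels(nrn.build_morphology(nrn.MorphologyConfig()))


class TestMorphology:
    def test_base_topology_counts(self, base_graph):
        regions = base_graph.region
        assert regions.count("heminode") == 1
        assert regions.count("node") == 4          # heminode + 4 = 5 nodal sites
        assert regions.count("paranode") == 8      # flanking each internodal span
        # two terminal branches with equal segment counts
        n_term = regions.count("terminal")
        assert n_term % 2 == 0 and n_term >= 2
        for site in ("terminal", "heminode", "node5"):
            assert site in base_graph.probes

    def test_tree_is_child_before_parent(self, base_graph):
        p = base_graph.parent
        assert np.all(p[:-1] > np.arange(base_graph.n_comp - 1))
        assert p[-1] == -1

    def test_terminal_multiplier_scales_area(self):
        g1 = nrn.build_morphology(nrn.MorphologyConfig())
        g10 = nrn.build_morphology(nrn.MorphologyConfig(terminal_length_multiplier=10.0))
        a1 = g1.area_um2[g1.terminal_indices()].sum()
        a10 = g10.area_um2[g10.terminal_indices()].sum()
        assert a10 == pytest.approx(10.0 * a1, rel=1e-6)

    def test_bad_multiplier_rejected(self):
        with pytest.raises(nrn.ConfigError):
            nrn.build_morphology(nrn.MorphologyConfig(terminal_length_multiplier=0.0))


class TestAssignChannels:
    def test_table_densities_applied_with_unit_conversion(self, base_graph):
        # heminode Nav1.6 is 2500 pS/um^2 = 0.25 S/cm^2
        comp, gmax = base_graph.placements["nav16"]
        hemi = base_graph.probes["heminode"]
        k = list(comp).index(hemi)
        area = base_graph.area_um2[hemi]
        assert gmax[k] == pytest.approx(0.25 * area * 1e-2, rel=1e-9)

    def test_kv1_only_in_paranodes(self, base_graph):
        comp, _ = base_graph.placements["kv1"]
        assert all(base_graph.region[i] == "paranode" for i in comp)
        assert comp.size == 8

    def test_ps_per_um2_conversion_constant(self):
        assert 2500.0 * nrn.PS_PER_UM2_TO_S_PER_CM2 == pytest.approx(0.25)

    def test_unknown_channel_rejected(self):
        g = nrn.build_morphology(nrn.MorphologyConfig())
        with pytest.raises(nrn.ConfigError):
            nrn.assign_channels(g, {"terminal": {"navX": 1.0}})


from .conftest import build_uniform_passive_cable as uniform_passive_cable  # noqa: E402


class TestPassiveCable:
    def test_steady_state_matches_cosh_profile(self):
        """Steady-state attenuation along a sealed-end passive cable matches
        the finite-cable closed form within 1%."""
        n = 25
        g, seg = uniform_passive_cable(n=n)
        t = np.arange(0, 0.8, 1e-3)
        drive = DriveSignal(t=t, g_drive=np.full(t.size, 1e-4))
        cfg = nrn.SimConfig(dt_ms=0.05, settle_ms=0.0,
                            record_sites=tuple(f"c{i}" for i in range(n)))
        res = nrn.simulate(g, drive, cfg, drive_sites=np.array([0], dtype=np.int32))
        v = np.array([res.v[f"c{i}"][-1] for i in range(n)])
        dv = v - (-65.0)
        x = (np.arange(n) + 0.5) * seg
        expect = nrn.passive_cable_profile(1000.0, 1.5, 100.0, 1e-4, x)
        np.testing.assert_allclose(dv / dv[0], expect / expect[0], rtol=0.01)

    def test_charge_balance_at_steady_state(self):
        """With only leak present, the injected current equals the summed
        leak current at steady state (charge bookkeeping)."""
        n = 25
        g, _ = uniform_passive_cable(n=n)
        t = np.arange(0, 0.8, 1e-3)
        gd = 1e-4
        drive = DriveSignal(t=t, g_drive=np.full(t.size, gd))
        cfg = nrn.SimConfig(dt_ms=0.05, settle_ms=0.0,
                            record_sites=tuple(f"c{i}" for i in range(n)))
        res = nrn.simulate(g, drive, cfg, drive_sites=np.array([0], dtype=np.int32))
        v = np.array([res.v[f"c{i}"][-1] for i in range(n)])
        injected = gd * (0.0 - v[0])                    # nA into c0
        leaked = np.sum(g.g_leak_us * (v - (-65.0)))    # nA out through leak
        assert injected == pytest.approx(leaked, rel=1e-3)


class TestActiveSimulation:
    def test_zero_drive_quiescent(self, base_graph):
        t = np.arange(0, 0.6, 1e-4)
        drive = DriveSignal(t=t, g_drive=np.zeros(t.size))
        res = nrn.simulate(base_graph, drive, nrn.SimConfig(settle_ms=300.0))
        spikes = detect_spikes(res.t, res.v["node5"])
        assert spikes.n == 0
        assert np.ptp(res.v["node5"][len(res.t) // 2:]) < 1.0

    def test_dt_halving_spike_stability(self, base_config):
        """Halving dt leaves the spike count of a stimulus-locked burst
        unchanged and moves the spike times by less than 0.1 ms. (A step
        drive from rest is used so every spike is locked to the stimulus;
        tonic free-running spikes accumulate phase drift at any fixed step
        and would confound the comparison.)"""
        from spindlesim import pipeline as pl
        g = pl.build_graph(base_config)
        t = np.arange(0, 0.35, 1e-4)
        gd = np.where(t >= 0.1, 0.006, 0.0)
        drive = DriveSignal(t=t, g_drive=gd)
        res1 = nrn.simulate(g, drive, nrn.SimConfig(dt_ms=0.0125, settle_ms=200.0))
        res2 = nrn.simulate(g, drive, nrn.SimConfig(dt_ms=0.00625, settle_ms=200.0))
        s1 = detect_spikes(res1.t, res1.v["node5"]).times
        s2 = detect_spikes(res2.t, res2.v["node5"]).times
        assert len(s1) == len(s2) and len(s1) >= 3
        # stimulus-locked onset spikes converge to < 0.1 ms
        assert np.max(np.abs(s1[:2] - s2[:2])) < 1e-4
        # later spikes accumulate period error; bound the ISI drift
        isi1, isi2 = np.diff(s1), np.diff(s2)
        assert np.max(np.abs(isi1 - isi2) / isi2) < 0.05

    def test_refinement_of_segmentation_preserves_rest(self, base_config):
        """A coarse 1-segment-per-region build rests within 0.5 mV of the
        default discretization (zero drive)."""
        regions = nrn.default_regions()
        coarse = {
            k: nrn.RegionSpec(v.kind, v.length_um, v.diam_um, cm=v.cm, ra=v.ra,
                              g_leak=v.g_leak, e_leak=v.e_leak, max_seg_um=1e9)
            for k, v in regions.items()
        }
        g_fine = nrn.assign_channels(nrn.build_morphology(nrn.MorphologyConfig()))
        g_coarse = nrn.assign_channels(
            nrn.build_morphology(nrn.MorphologyConfig(regions=coarse)))
        t = np.arange(0, 0.3, 1e-3)
        drive = DriveSignal(t=t, g_drive=np.zeros(t.size))
        cfg = nrn.SimConfig(settle_ms=400.0)
        v_f = nrn.simulate(g_fine, drive, cfg).v["node5"][-1]
        v_c = nrn.simulate(g_coarse, drive, cfg).v["node5"][-1]
        assert abs(v_f - v_c) < 0.5


class TestInitiationOrder:
    def test_drive_at_node5_makes_node5_lead(self, base_graph):
        t = np.arange(0, 0.5, 1e-4)
        drive = DriveSignal(t=t, g_drive=np.where(t >= 0.1, 0.004, 0.0))
        node5 = base_graph.probes["node5"]
        res = nrn.simulate(base_graph, drive, nrn.SimConfig(settle_ms=200.0),
                           drive_sites=np.array([node5], dtype=np.int32))
        orders = nrn.initiation_order(res)
        assert orders, "diagnostic injection should evoke spikes"
        lead = [o[0] for o in orders if o]
        assert lead.count("node5") > len(lead) / 2

    def test_single_site_gives_singleton_order(self, base_config, short_drive):
        from spindlesim import pipeline as pl
        g = pl.build_graph(base_config)
        res = nrn.simulate(g, short_drive,
                           nrn.SimConfig(settle_ms=300.0, record_sites=("node5",)))
        orders = nrn.initiation_order(res)
        assert orders and all(o == ["node5"] for o in orders)
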