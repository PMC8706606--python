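import numpy as np
import pytest

from fatecycle import (
    CouplingSchedule,
    NetworkSpec,
    SignalProtocol,
    build_network,
    effective_coupling,
)
from fatecycle.network import NetworkError


class TestBuildNetwork:
    def test_classic_repressilator(self):
        spec = build_network({"n_genes": 3, "topology": "cyclic", "gate": "OR", "coupling": 1.0})
        assert np.all(spec.coupling_reverse == 0)
        W = spec.relative_coupling()
        # each gene repressed only by its upstream neighbour
        for i in range(3):
            assert W[i, (i - 1) % 3] == 1.0
        assert W.sum() == 3.0

    def test_equal_strength_double_repressilator(self):
        spec = build_network(
            {
                "n_genes": 3,
                "topology": "all_pairs",
                "gate": "OR",
                "coupling_forward": 1.0,
                "coupling_reverse": 1.0,
            }
        )
        W = spec.relative_coupling()
        assert np.allclose(W + np.eye(3), np.ones((3, 3)))

    def test_scalar_coupling_expands_per_edge(self):
        spec = build_network({"n_genes": 4, "topology": "ring_neighbors", "gate": "OR", "coupling": 2.0})
        assert spec.coupling_forward.shape == (4,)
        assert np.all(spec.coupling_forward == 2.0)

    @pytest.mark.parametrize(
        "config, match",
        [
            ({"n_genes": 1, "topology": "cyclic", "gate": "OR"}, "n_genes"),
            ({"n_genes": 2, "topology": "cyclic", "gate": "AND"}, "AND"),
            ({"n_genes": 3, "topology": "cyclic", "gate": "OR", "degradation": -1.0}, "degradation"),
            ({"n_genes": 3, "topology": "cyclic", "gate": "OR", "hill_coefficient": -2}, "hill"),
            ({"n_genes": 3, "topology": "cyclic", "gate": "OR", "bogus": 1}, "bogus"),
            ({"n_genes": 3, "topology": "cyclic", "gate": "OR", "coupling_reverse": 0.5}, "reverse"),
            ({"n_genes": 3, "topology": "hexagon", "gate": "OR"}, "topology"),
        ],
    )
    def test_invalid_configs_rejected(self, config, match):
        with pytest.raises(NetworkError, match=match):
            build_network(config)

    def test_knockout_all_genes_refused(self):
        spec = build_network({"n_genes": 3, "topology": "cyclic", "gate": "OR"})
        with pytest.raises(NetworkError):
            spec.with_knockout(0, 1, 2)

    def test_relabel_permutes_coupling_matrix(self):
        spec = NetworkSpec(
            n_genes=3, topology="all_pairs", gate="OR",
            coupling_forward=np.array([2.0, 1.0, 1.0]),
            coupling_reverse=np.array([0.2, 0.1, 0.1]),
        )
        W = spec.relative_coupling()
        shifted = spec.relabel(1).relative_coupling()
        perm = (np.arange(3) + 1) % 3
        assert np.allclose(shifted, W[np.ix_(perm, perm)])


class TestEffectiveCoupling:
    def test_zero_coupling_gives_zero_matrix(self):
        spec = build_network({"n_genes": 3, "topology": "all_pairs", "gate": "OR"})
        sched = CouplingSchedule(kind="constant", g_start=0.0)
        assert np.all(effective_coupling(spec, sched, 10.0) == 0)

    def test_linear_ramp_midpoint(self):
        spec = build_network({"n_genes": 3, "topology": "cyclic", "gate": "OR", "coupling": 1.0})
        sched = CouplingSchedule(kind="linear_ramp", g_start=0.0, g_end=10.0, t_start=0.0, t_end=100.0)
        W = effective_coupling(spec, sched, 50.0)
        assert np.allclose(W[W > 0], 5.0)

    def test_asymmetric_strengths_scale(self):
        spec = NetworkSpec(n_genes=3, topology="all_pairs", gate="OR",
                           coupling_forward=1.0, coupling_reverse=0.5)
        W = effective_coupling(spec, CouplingSchedule(kind="constant", g_start=4.0), 0.0)
        assert W[1, 0] == 4.0  # forward edge 0 -> 1
        assert W[0, 1] == 2.0  # reverse edge 1 -> 0

    def test_knockout_does_not_alter_coupling(self):
        spec = build_network({"n_genes": 3, "topology": "all_pairs", "gate": "OR"})
        sched = CouplingSchedule(kind="constant", g_start=2.0)
        assert np.allclose(
            effective_coupling(spec, sched, 0.0),
            effective_coupling(spec.with_knockout(1), sched, 0.0),
        )


class TestSchedules:
    def test_constant_reproduces_autonomous_value(self):
        s = CouplingSchedule(kind="constant", g_start=0.7)
        assert s(0.0) == s(1e6) == 0.7

    def test_ramp_is_clamped_and_nondecreasing(self):
        s = CouplingSchedule(kind="linear_ramp", g_start=1.0, g_end=3.0, t_start=10.0, t_end=20.0)
        t = np.linspace(-5, 35, 101)
        g = s(t)
        assert g[0] == 1.0 and g[-1] == 3.0
        assert np.all(np.diff(g) >= 0)

    def test_decreasing_ramp_rejected(self):
        with pytest.raises(NetworkError, match="nondecreasing"):
            CouplingSchedule(kind="linear_ramp", g_start=2.0, g_end=1.0, t_start=0, t_end=10)

    def test_piecewise_interpolates_and_crossing_time(self):
        s = CouplingSchedule(kind="piecewise_linear", points=[(0, 0.0), (10, 1.0), (30, 1.0)])
        assert s(5.0) == pytest.approx(0.5)
        assert s.crossing_time(0.25) == pytest.approx(2.5)
        ramp = CouplingSchedule(kind="linear_ramp", g_start=0.0, g_end=10.0, t_start=0, t_end=100)
        assert ramp.crossing_time(5.0) == pytest.approx(50.0)
        assert ramp.crossing_time(11.0) is None


class TestSignalProtocol:
    def test_invalid_signals_rejected(self):
        with pytest.raises(NetworkError):
            SignalProtocol(target_gene=0, amplitude=-1.0)
        with pytest.raises(NetworkError):
            SignalProtocol(target_gene=0, amplitude=1.0, t_on=5.0, t_off=5.0)

    def test_activation_window(self):
        sig = SignalProtocol(target_gene=1, amplitude=2.0, t_on=1.0, t_off=4.0)
        assert not sig.active(0.5) and sig.active(1.0) and not sig.active(4.0)
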