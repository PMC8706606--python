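import numpy as np
import pytest
from scipy.optimize import brentq

from fatecycle import (
    CouplingSchedule,
    IntegratorSettings,
    NetworkSpec,
    SignalProtocol,
    Trajectory,
    build_network,
    integrate,
    rhs_and,
    rhs_or,
)

CONST = lambda g: CouplingSchedule(kind="constant", g_start=g)


def random_spec(rng, gate="OR", n=3):
    return NetworkSpec(
        n_genes=n,
        topology="all_pairs",
        gate=gate,
        coupling_forward=float(rng.uniform(0.5, 2.0)),
        coupling_reverse=float(rng.uniform(0.05, 0.5)) if gate == "OR" else 1.0,
        hill_coefficient=float(rng.uniform(2.5, 3.5)),
        production_max=float(rng.uniform(5, 15)),
        production_basal=float(rng.uniform(0.01, 0.1)),
    )


class TestRightHandSides:
    def test_no_repression_at_zero_state(self):
        spec = build_network({"n_genes": 3, "topology": "all_pairs", "gate": "OR"})
        dx = rhs_or(spec, CONST(5.0), (), 0.0, np.zeros(3))
        assert np.allclose(dx, spec.production_basal + spec.production_max)

    def test_or_symmetric_fixed_point_from_scalar_root(self):
        # oracle: the all-equal equilibrium solves x = a0 + b/(1 + m*g*x^h)
        spec = NetworkSpec(n_genes=3, topology="all_pairs", gate="OR",
                           coupling_forward=1.0, coupling_reverse=1.0)
        g, m = 0.8, 2.0
        a0, b, h = 0.05, 10.0, 3.0
        xstar = brentq(lambda x: x - a0 - b / (1 + m * g * x**h), 0, a0 + b)
        dx = rhs_or(spec, CONST(g), (), 0.0, np.full(3, xstar))
        assert np.abs(dx).max() < 1e-12

    def test_and_symmetric_fixed_point_from_scalar_root(self):
        spec = NetworkSpec(n_genes=3, topology="all_pairs", gate="AND",
                           coupling_forward=1.0, coupling_reverse=1.0,
                           hill_coefficient=3.0, hill_reverse=1.5)
        g = 1e-3
        a0, b = 0.05, 10.0
        xstar = brentq(lambda x: x - a0 - b / (1 + g * x**4.5), 0, a0 + b)
        dx = rhs_and(spec, CONST(g), (), 0.0, np.full(3, xstar))
        assert np.abs(dx).max() < 1e-12

    def test_knockout_gene_decays_exactly(self):
        spec = build_network({"n_genes": 3, "topology": "all_pairs", "gate": "OR"}).with_knockout(1)
        x = np.array([2.0, 1.5, 0.3])
        dx = rhs_or(spec, CONST(1.0), (), 0.0, x)
        assert dx[1] == pytest.approx(-spec.degradation[1] * x[1], abs=0)

    def test_and_fails_with_one_low_input(self):
        spec = NetworkSpec(n_genes=3, topology="all_pairs", gate="AND",
                           coupling_forward=1.0, coupling_reverse=1.0)
        x = np.array([1.0, 8.0, 0.0])  # one repressor of gene 0 is silent
        dx = rhs_and(spec, CONST(100.0), (), 0.0, x)
        expect = spec.production_basal[0] + spec.production_max[0] - spec.degradation[0] * x[0]
        assert dx[0] == pytest.approx(expect, rel=1e-12)

    def test_zero_amplitude_signal_is_bitwise_identical(self):
        spec = build_network({"n_genes": 3, "topology": "all_pairs", "gate": "OR"})
        x0 = np.array([1.0, 1.05, 0.95])
        base = integrate(spec, CONST(0.15), x0, (0, 50))
        sig = SignalProtocol(target_gene=0, amplitude=0.0, t_on=0.0, t_off=25.0)
        with_sig = integrate(spec, CONST(0.15), x0, (0, 50), signals=[sig])
        assert np.array_equal(base.x, with_sig.x)


class TestIntegrate:
    def test_zero_coupling_decouples_all_genes(self):
        # with g = 0 every gene relaxes to (alpha0 + beta)/delta
        for topology in ("cyclic", "all_pairs"):
            spec = build_network({"n_genes": 3, "topology": topology, "gate": "OR"})
            x0 = np.array([0.1, 7.0, 3.0])
            traj = integrate(spec, CONST(0.0), x0, (0, 40))
            target = (spec.production_basal + spec.production_max) / spec.degradation
            assert np.allclose(traj.x[-1], target, rtol=1e-6)

    def test_nonnegativity_and_bound(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            spec = random_spec(rng)
            x0 = rng.uniform(0, 12, size=3)
            traj = integrate(spec, CONST(rng.uniform(0.05, 2.0)), x0, (0, 200))
            assert traj.x.min() >= 0.0
            bound = ((spec.production_basal + spec.production_max) / spec.degradation).max()
            assert traj.x[traj.t > 20].max() <= bound + 1e-6

    def test_halving_tolerances_changes_little(self):
        spec = build_network({"n_genes": 3, "topology": "all_pairs", "gate": "OR"})
        x0 = np.array([3.0, 3.1, 2.9])
        a = integrate(spec, CONST(0.15), x0, (0, 150),
                      settings=IntegratorSettings(rtol=1e-8, atol=1e-10))
        b = integrate(spec, CONST(0.15), x0, (0, 150),
                      settings=IntegratorSettings(rtol=5e-9, atol=5e-11))
        rel = np.abs(a.x - b.x).max() / np.abs(a.x).max()
        assert rel < 1e-5

    def test_cyclic_relabeling_equivariance(self):
        """Relabeling genes commutes with simulating (symmetric spec)."""
        spec = build_network({"n_genes": 3, "topology": "all_pairs", "gate": "OR",
                              "coupling_forward": 1.0, "coupling_reverse": 0.1})
        x0 = np.array([1.0, 2.0, 3.0])
        shift = 1
        perm = (np.arange(3) + shift) % 3
        a = integrate(spec, CONST(0.15), x0, (0, 100))
        b = integrate(spec.relabel(shift), x0=x0[perm], schedule=CONST(0.15), t_span=(0, 100))
        assert np.allclose(a.x[:, perm], b.x, atol=1e-7)

    def test_rejects_bad_inputs(self):
        spec = build_network({"n_genes": 3, "topology": "cyclic", "gate": "OR"})
        with pytest.raises(ValueError):
            integrate(spec, CONST(1.0), np.array([-1.0, 0, 0]), (0, 10))
        with pytest.raises(ValueError):
            integrate(spec, CONST(1.0), np.zeros(3), (10, 0))


class TestTrajectoryIO:
    def test_csv_round_trip(self, tmp_path):
        spec = build_network({"n_genes": 3, "topology": "all_pairs", "gate": "OR"})
        traj = integrate(spec, CONST(0.15), np.array([1.0, 1.1, 0.9]), (0, 20),
                         settings=IntegratorSettings(n_points=200))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        import pandas as pd

        t, x = Trajectory.frame_to_arrays(pd.read_csv(path))
        assert np.allclose(t, traj.t)
        assert np.allclose(x, traj.x)

    def test_strictly_increasing_grid_enforced(self):
        spec = build_network({"n_genes": 2, "topology": "cyclic", "gate": "OR"})
        with pytest.raises(ValueError, match="strictly increasing"):
            Trajectory(t=np.array([0.0, 0.0, 1.0]), x=np.zeros((3, 2)),
                       spec=spec, schedule=CONST(1.0))
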