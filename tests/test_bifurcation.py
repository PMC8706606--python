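import dataclasses

import numpy as np
import pytest
from scipy.optimize import brentq

from fatecycle import (
    NetworkSpec,
    build_network,
    equilibrium_branch,
    find_boundaries,
    get_preset,
    jacobian,
    leading_eigenvalue,
    solve_symmetric,
    specialised_equilibrium,
)
from fatecycle.bifurcation import BifurcationError, probe_label
from fatecycle.dynamics import make_rhs
from fatecycle.network import CouplingSchedule


def random_symmetric_spec(rng, gate="OR"):
    return NetworkSpec(
        n_genes=3,
        topology="all_pairs",
        gate=gate,
        coupling_forward=float(rng.uniform(0.5, 2.0)),
        coupling_reverse=float(rng.uniform(0.05, 0.4)) if gate == "OR" else 1.0,
        hill_coefficient=float(rng.uniform(2.8, 3.4)),
        production_max=float(rng.uniform(6, 14)),
        production_basal=float(rng.uniform(0.02, 0.08)),
    )


def fd_jacobian(spec, g, x, eps=1e-6):
    rhs = make_rhs(spec, CouplingSchedule(kind="constant", g_start=g))
    n = len(x)
    J = np.zeros((n, n))
    for j in range(n):
        dx = np.zeros(n)
        dx[j] = eps * max(abs(x[j]), 1.0)
        J[:, j] = (rhs(0.0, x + dx) - rhs(0.0, x - dx)) / (2 * dx[j])
    return J


class TestSolveSymmetric:
    def test_uncoupled_limit_is_exact(self):
        spec = build_network({"n_genes": 3, "topology": "all_pairs", "gate": "OR"})
        assert solve_symmetric(spec, 0.0) == pytest.approx(
            float(spec.production_basal[0] + spec.production_max[0]), rel=1e-14
        )

    def test_root_verified_by_substitution(self):
        spec = NetworkSpec(n_genes=3, topology="all_pairs", gate="OR",
                           coupling_forward=1.0, coupling_reverse=1.0,
                           production_basal=0.0, hill_coefficient=2.0)
        # x (1 + 2 x^2) = 10 at g = 1, m = 2 repressors
        x = solve_symmetric(spec, 1.0)
        assert abs(x * (1 + 2 * x**2) - 10.0) < 1e-12
        oracle = brentq(lambda y: y * (1 + 2 * y**2) - 10.0, 0, 10)
        assert x == pytest.approx(oracle, rel=1e-12)

    def test_monotone_decreasing_towards_basal_leak(self):
        spec = build_network({"n_genes": 3, "topology": "all_pairs", "gate": "OR"})
        gs = [0.01, 0.1, 1.0, 10.0, 1e8]
        xs = [solve_symmetric(spec, g) for g in gs]
        assert all(a > b for a, b in zip(xs, xs[1:]))
        assert xs[-1] < 2 * float(spec.production_basal[0] + 1e-2)

    def test_requires_symmetric_spec(self):
        spec = NetworkSpec(n_genes=3, topology="all_pairs", gate="OR",
                           coupling_forward=np.array([2.0, 1.0, 1.0]),
                           coupling_reverse=0.1)
        with pytest.raises(BifurcationError):
            solve_symmetric(spec, 0.1)


class TestJacobian:
    def test_uncoupled_jacobian_is_minus_degradation(self):
        spec = build_network({"n_genes": 3, "topology": "all_pairs", "gate": "OR"})
        J = jacobian(spec, 0.0, np.array([1.0, 2.0, 3.0]))
        assert np.allclose(J, -np.diag(spec.degradation))

    @pytest.mark.parametrize("gate", ["OR", "AND"])
    def test_matches_finite_differences(self, gate):
        rng = np.random.default_rng(42)
        for _ in range(10):
            spec = random_symmetric_spec(rng, gate=gate)
            g = rng.uniform(0.05, 1.0) if gate == "OR" else rng.uniform(1e-4, 1e-2)
            x = rng.uniform(0.2, 8.0, size=3)
            J = jacobian(spec, g, x)
            Jfd = fd_jacobian(spec, g, x)
            assert np.abs(J - Jfd).max() / np.abs(J).max() < 1e-6

    def test_circulant_structure_and_eigenvalues(self):
        """At the symmetric equilibrium of a symmetric spec the Jacobian is
        circulant and its spectrum matches the closed form sum_l a_l w^(kl)."""
        spec = NetworkSpec(n_genes=3, topology="all_pairs", gate="OR",
                           coupling_forward=1.0, coupling_reverse=0.1)
        g = 0.2
        xs = solve_symmetric(spec, g)
        J = jacobian(spec, g, np.full(3, xs))
        row = J[0]
        assert np.allclose(J[1], np.roll(row, 1))
        assert np.allclose(J[2], np.roll(row, 2))
        w = np.exp(2j * np.pi / 3)
        closed = [sum(row[l] * w ** (k * l) for l in range(3)) for k in range(3)]
        eig = np.sort_complex(np.linalg.eigvals(J))
        assert np.allclose(np.sort_complex(np.array(closed)), eig, atol=1e-12)


class TestSpecialisedEquilibria:
    def test_residual_and_stability_at_high_coupling(self, double_or):
        found = specialised_equilibrium(double_or.spec, 1.0)
        assert found is not None
        x, lead = found
        rhs = make_rhs(double_or.spec, CouplingSchedule(kind="constant", g_start=1.0))
        assert np.abs(rhs(0.0, x)).max() < 1e-10
        assert lead < 0  # stable winner-take-all
        assert np.sort(x)[-1] / np.sort(x)[-2] > 3

    def test_absent_for_classic_repressilator(self):
        spec = get_preset("repressilator").spec
        for g in (0.1, 1.0, 10.0, 100.0):
            assert specialised_equilibrium(spec, g) is None

    def test_branch_table(self, double_or):
        grid = np.geomspace(0.02, 1.0, 8)
        sym = equilibrium_branch(double_or.spec, grid, kind="symmetric")
        assert sym.states.shape == (8, 3)
        assert np.isfinite(sym.states).all()
        spc = equilibrium_branch(double_or.spec, grid, kind="specialised")
        assert spc.kind == "winner_take_all"
        assert np.isnan(spc.states[0]).all()  # absent at very low coupling
        assert np.isfinite(spc.states[-1]).all()


class TestBoundaries:
    def test_classic_repressilator_has_no_upper_boundary(self):
        p = get_preset("repressilator")
        b = find_boundaries(p.spec, p.g_scan)
        assert b.g_lower is not None and b.g_lower > 0
        assert b.g_upper is None
        assert b.specialised_stable_from is None
        assert any("g_upper absent" in n for n in b.notes)

    def test_double_repressilator_window_is_ordered(self, double_or_boundaries):
        b = double_or_boundaries
        assert b.has_window
        assert 0 < b.g_lower < b.g_upper
        lo, hi = b.g_upper_bracket
        assert (hi - lo) / hi < 2e-3

    def test_probes_agree_with_boundaries(self, double_or, double_or_boundaries):
        b = double_or_boundaries
        assert probe_label(double_or.spec, 0.5 * b.g_lower) == "multipotent"
        mid = float(np.sqrt(b.g_lower * b.g_upper))
        assert probe_label(double_or.spec, mid) == "oscillatory"
        assert probe_label(double_or.spec, 1.5 * b.g_upper) == "differentiated"

    def test_invariant_under_joint_rate_rescaling(self, double_or, double_or_boundaries):
        """Multiplying every rate by 2 is a pure time rescaling and leaves
        the boundary couplings unchanged."""
        spec = double_or.spec
        fast = dataclasses.replace(
            spec,
            production_max=spec.production_max * 2,
            production_basal=spec.production_basal * 2,
            degradation=spec.degradation * 2,
        )
        g = double_or_boundaries.g_lower
        # leading eigenvalue scales by 2 but its zero crossing does not move
        assert leading_eigenvalue(fast, 0.9 * g) < 0 < leading_eigenvalue(fast, 1.1 * g)
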