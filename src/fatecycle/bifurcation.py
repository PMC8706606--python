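"""Equilibria, linear stability, and regime boundaries in coupling strength.

For a cyclically symmetric network the symmetric (all-equal) equilibrium
solves a scalar fixed-point equation and the Jacobian there is circulant,
so the lower regime boundary -- the coupling ``g_lower`` at which the
multipotent state loses stability -- follows from a one-dimensional root
find on its leading eigenvalue.

The upper boundary is subtler.  In this model family the fate-specialised
equilibria (one gene high for OR gates, a co-dominant pair for AND gates)
become stable at couplings far below the oscillation onset, so the
oscillatory regime coexists with stable differentiated states.  What ends
the oscillatory regime as g grows is not the appearance of those equilibria
but the loss of the limit cycle's ability to hold a trajectory started near
the symmetric state.  ``find_boundaries`` therefore locates ``g_upper``
empirically: a standardised probe simulation (seeded 1% perturbation of the
symmetric equilibrium, fixed horizon) is classified at each coupling, and
the oscillatory/differentiated transition is bracketed by bisection.  The
coupling at which a stable fate-specialised equilibrium first *exists* is
computed independently and reported as ``specialised_stable_from``, making
any bistable overlap visible rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from .dynamics import IntegratorSettings, Trajectory, integrate, make_rhs
from .network import CouplingSchedule, NetworkSpec
from .regimes import ClassifierThresholds, classify

__all__ = [
    "solve_symmetric",
    "jacobian",
    "leading_eigenvalue",
    "specialised_equilibrium",
    "equilibrium_branch",
    "EquilibriumBranch",
    "RegimeBoundaries",
    "find_boundaries",
]

_RESIDUAL_TOL = 1e-10


class BifurcationError(RuntimeError):
    pass


# ----------------------------------------------------------------------
def _symmetric_params(spec: NetworkSpec) -> tuple[float, float, float, float, float]:
    """(alpha0, beta, delta, strength, exponent) of the scalar fixed-point
    equation x = alpha0 + beta / (1 + g * strength * x**exponent)."""
    alpha0 = float(spec.production_basal[0])
    beta = float(spec.production_max[0])
    delta = float(spec.degradation[0])
    W = spec.relative_coupling()
    if spec.gate == "OR":
        strength = float(W.sum(axis=1)[0])
        exponent = spec.hill_coefficient
    else:
        mask = W[0] > 0
        strength = float(np.exp(np.log(W[0][mask]).mean()))
        exponent = float(spec.exponents()[0].sum())
    return alpha0, beta, delta, strength, exponent


def solve_symmetric(spec: NetworkSpec, g: float, strict: bool = True) -> float:
    """Equilibrium level of the all-equal state at coupling g.

    The fixed-point map x -> alpha0 + beta/(1 + g*S*x**E) is monotone
    decreasing in x, so the root is unique; it is found by bracketed root
    finding on [0, alpha0 + beta].  With ``strict`` the network must be
    cyclically symmetric; otherwise row-averaged strengths are used (useful
    only as an initial-condition heuristic for mildly asymmetric specs).
    """
    if strict and not spec.is_cyclically_symmetric():
        raise BifurcationError("symmetric equilibrium requires a cyclically symmetric spec")
    alpha0, beta, delta, S, E = _symmetric_params(spec)
    if not spec.is_cyclically_symmetric():
        W = spec.relative_coupling()
        if spec.gate == "OR":
            S = float(W.sum(axis=1).mean())
        alpha0 = float(spec.production_basal.mean())
        beta = float(spec.production_max.mean())
        delta = float(spec.degradation.mean())
    g = float(g)
    if g < 0:
        raise ValueError("coupling must be >= 0")
    hi = (alpha0 + beta) / delta
    f = lambda x: delta * x - alpha0 - beta / (1.0 + g * S * x**E)
    if f(hi) < 0:  # no repression at all (g*S == 0)
        return hi
    lo = 0.0
    try:
        return float(brentq(f, lo, hi, xtol=1e-14, rtol=1e-15))
    except ValueError as err:  # pragma: no cover - bracket always valid for monotone f
        raise BifurcationError(f"bracket failure on [{lo}, {hi}]: {err}") from err


def jacobian(spec: NetworkSpec, g: float, x: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the autonomous system at state x, coupling g.

    Validated against central finite differences in the test suite.
    """
    x = np.asarray(x, float)
    n = spec.n_genes
    kappa = (~spec.knockout_mask).astype(float)
    beta = spec.production_max * kappa
    W = spec.relative_coupling()
    J = np.diag(-spec.degradation.astype(float))
    eps = 1e-300
    if spec.gate == "OR":
        h = spec.hill_coefficient
        den = 1.0 + g * (W @ np.clip(x, 0, None) ** h)
        dpow = h * np.maximum(x, eps) ** (h - 1.0)
        J += -(beta * g / den**2)[:, None] * W * dpow[None, :]
        return J
    H = spec.exponents()
    mask = W > 0
    with np.errstate(divide="ignore"):
        wbar = np.exp(np.where(mask, np.log(np.where(mask, W, 1.0)), 0.0).sum(1) / mask.sum(1))
    for i in range(n):
        reps = np.flatnonzero(mask[i])
        P = np.prod(np.clip(x[reps], 0, None) ** H[i, reps])
        den = 1.0 + g * wbar[i] * P
        for j in reps:
            others = reps[reps != j]
            dP = H[i, j] * np.maximum(x[j], eps) ** (H[i, j] - 1.0) * np.prod(
                np.clip(x[others], 0, None) ** H[i, others]
            )
            J[i, j] += -beta[i] * g * wbar[i] * dP / den**2
    return J


def leading_eigenvalue(spec: NetworkSpec, g: float, x: np.ndarray | None = None) -> float:
    """Largest real part among the Jacobian eigenvalues at the symmetric
    equilibrium (or at a supplied state)."""
    if x is None:
        x = np.full(spec.n_genes, solve_symmetric(spec, g))
    return float(np.linalg.eigvals(jacobian(spec, g, x)).real.max())


# ----------------------------------------------------------------------
def _rhs_residual(spec: NetworkSpec, g: float) -> Callable[[np.ndarray], np.ndarray]:
    rhs = make_rhs(spec, CouplingSchedule(kind="constant", g_start=g))
    return lambda x: rhs(0.0, x)


def specialised_equilibrium(
    spec: NetworkSpec,
    g: float,
    dominance_ratio: float = 3.0,
) -> tuple[np.ndarray, float] | None:
    """Fate-specialised equilibrium at coupling g, or None if absent.

    Solves the full fixed-point system from the high/low symmetry ansatz
    (one gene high for OR; the co-dominant pair high for AND) and accepts
    the root only when the residual is below 1e-10 and the solution shows
    the expected dominance pattern.  Returns (state, leading eigenvalue
    real part); stability is ``leading < 0``.
    """
    alpha0, beta, delta, _, _ = _symmetric_params(spec)
    n = spec.n_genes
    n_high = 2 if spec.gate == "AND" else 1
    x0 = np.full(n, alpha0 + 0.05 * beta)
    x0[:n_high] = (alpha0 + beta) / delta
    if spec.gate == "AND" and n > 3:
        # co-dominant genes sit non-adjacently on the ring
        x0[:] = alpha0 + 0.05 * beta
        x0[0] = x0[2] = (alpha0 + beta) / delta
    F = _rhs_residual(spec, g)
    sol = root(F, x0, method="hybr", tol=1e-13)
    x = sol.x
    if not sol.success or np.abs(F(x)).max() > _RESIDUAL_TOL or np.any(x < 0):
        return None
    srt = np.sort(x)[::-1]
    if srt[n_high - 1] / max(srt[n_high], 1e-300) < dominance_ratio:
        return None
    lead = float(np.linalg.eigvals(jacobian(spec, g, x)).real.max())
    return x, lead


@dataclass(frozen=True)
class EquilibriumBranch:
    """A branch of equilibria tracked over a coupling grid."""

    kind: str  # symmetric | winner_take_all | pair_high
    g: np.ndarray
    states: np.ndarray  # (len(g), n) with NaN rows where the branch is absent
    leading: np.ndarray
    stable: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n = self.states.shape[1]
        df = pd.DataFrame(self.states, columns=[f"x{i}" for i in range(n)])
        df.insert(0, "g", self.g)
        df["leading_eigenvalue"] = self.leading
        df["stable"] = self.stable
        return df


def equilibrium_branch(spec: NetworkSpec, g_grid, kind: str = "symmetric") -> EquilibriumBranch:
    """Track one equilibrium branch over a grid of couplings.

    ``kind='symmetric'`` follows the all-equal state; ``'specialised'`` (or
    the explicit names ``'winner_take_all'`` / ``'pair_high'``) follows the
    fate-specialised state, with NaN rows where it does not exist.  Every
    reported point satisfies the fixed-point equations to < 1e-10.
    """
    g_grid = np.asarray(g_grid, float)
    n = spec.n_genes
    states = np.full((g_grid.size, n), np.nan)
    leading = np.full(g_grid.size, np.nan)
    if kind == "symmetric":
        for k, g in enumerate(g_grid):
            xs = solve_symmetric(spec, g)
            x = np.full(n, xs)
            resid = np.abs(_rhs_residual(spec, g)(x)).max()
            if resid > _RESIDUAL_TOL:  # pragma: no cover
                raise BifurcationError(f"symmetric residual {resid:.2e} at g={g}")
            states[k] = x
            leading[k] = leading_eigenvalue(spec, g, x)
    else:
        if kind == "specialised":
            kind = "pair_high" if spec.gate == "AND" else "winner_take_all"
        for k, g in enumerate(g_grid):
            found = specialised_equilibrium(spec, g)
            if found is not None:
                states[k], leading[k] = found
    return EquilibriumBranch(
        kind=kind, g=g_grid, states=states, leading=leading, stable=leading < 0
    )


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class RegimeBoundaries:
    """Boundaries of the oscillatory window in coupling strength.

    ``g_lower`` -- symmetric equilibrium loses stability (eigenvalue root,
    None when the symmetric state is stable across the range).
    ``g_upper`` -- upper edge of the oscillatory regime from the probe
    protocol (None when no differentiated outcome occurs in range).
    ``specialised_stable_from`` -- smallest grid coupling at which a stable
    fate-specialised equilibrium exists; if this lies below ``g_upper`` the
    oscillatory window is bistable with differentiation.
    """

    g_lower: float | None
    g_upper: float | None
    g_lower_bracket: tuple[float, float] | None = None
    g_upper_bracket: tuple[float, float] | None = None
    specialised_stable_from: float | None = None
    notes: tuple[str, ...] = ()
    method: dict = field(default_factory=dict)

    @property
    def has_window(self) -> bool:
        return self.g_lower is not None and self.g_upper is not None and self.g_lower < self.g_upper

    def to_dict(self) -> dict:
        return {
            "g_lower": self.g_lower,
            "g_upper": self.g_upper,
            "g_lower_bracket": self.g_lower_bracket,
            "g_upper_bracket": self.g_upper_bracket,
            "specialised_stable_from": self.specialised_stable_from,
            "notes": list(self.notes),
            "method": self.method,
        }


_PROBE_SEED = 715891  # fixed: the probe protocol is part of the boundary definition


def probe_label(
    spec: NetworkSpec,
    g: float,
    horizon: float = 600.0,
    scale: float = 0.01,
    thresholds: ClassifierThresholds | None = None,
    settings: IntegratorSettings | None = None,
) -> str:
    """Label of the standardised constant-coupling probe simulation."""
    rng = np.random.default_rng(_PROBE_SEED)
    xs = solve_symmetric(spec, g, strict=False)
    x0 = np.clip(xs * (1.0 + scale * rng.standard_normal(spec.n_genes)), 0.0, None)
    settings = settings or IntegratorSettings(rtol=1e-7, atol=1e-9, n_points=1500)
    traj = integrate(
        spec, CouplingSchedule(kind="constant", g_start=g), x0, (0.0, horizon), settings=settings
    )
    return classify(traj, thresholds=thresholds).label


def find_boundaries(
    spec: NetworkSpec,
    g_range: tuple[float, float],
    n_scan: int = 16,
    rel_width: float = 1e-3,
    horizon: float = 600.0,
    thresholds: ClassifierThresholds | None = None,
) -> RegimeBoundaries:
    """Locate the oscillatory window of a cyclically symmetric network.

    ``g_lower`` comes from a bracketed root find on the leading eigenvalue
    of the symmetric branch over a geometric scan grid; ``g_upper`` from
    bisection on the probe-simulation outcome (oscillatory vs
    differentiated), both to relative width < ``rel_width``.  Absent
    boundaries are reported as None with an explanatory note.
    """
    if not spec.is_cyclically_symmetric():
        raise BifurcationError("find_boundaries requires a cyclically symmetric spec")
    g_min, g_max = map(float, g_range)
    if not 0 < g_min < g_max:
        raise ValueError("g_range must satisfy 0 < g_min < g_max")
    grid = np.geomspace(g_min, g_max, n_scan)
    notes: list[str] = []

    # -- lower boundary: eigenvalue sign change along the symmetric branch
    lead = np.array([leading_eigenvalue(spec, g) for g in grid])
    g_lower = lower_bracket = None
    sign_change = np.flatnonzero((lead[:-1] < 0) & (lead[1:] >= 0))
    if lead[0] >= 0:
        notes.append(f"symmetric state already unstable at g={g_min:g}; g_lower below range")
    elif sign_change.size == 0:
        notes.append("symmetric state stable across range; oscillatory regime absent")
    else:
        a, b = grid[sign_change[0]], grid[sign_change[0] + 1]
        g_lower = float(brentq(lambda g: leading_eigenvalue(spec, g), a, b, rtol=rel_width / 4))
        lower_bracket = (g_lower * (1 - rel_width), g_lower * (1 + rel_width))

    # -- fate-specialised branch onset (existence + stability)
    specialised_from = None
    for g in grid:
        found = specialised_equilibrium(spec, g)
        if found is not None and found[1] < 0:
            specialised_from = float(g)
            break
    if specialised_from is None:
        notes.append("no stable fate-specialised equilibrium in range")

    # -- upper boundary: probe-simulation bisection
    g_upper = upper_bracket = None
    start = g_lower if g_lower is not None else g_min
    probe_grid = [g for g in grid if g > start * 1.02] or [g_max]
    labels = {g: probe_label(spec, g, horizon=horizon, thresholds=thresholds) for g in probe_grid}
    osc_gs = [g for g, lab in labels.items() if lab == "oscillatory"]
    diff_gs = [g for g, lab in labels.items() if lab == "differentiated"]
    if not diff_gs:
        notes.append("no differentiated probe outcome in range; g_upper absent")
    else:
        lo = max(osc_gs) if osc_gs else start
        hi = min(g for g in diff_gs if g > lo)
        while (hi - lo) > rel_width * hi:
            mid = 0.5 * (lo + hi)
            if probe_label(spec, mid, horizon=horizon, thresholds=thresholds) == "differentiated":
                hi = mid
            else:
                lo = mid
        g_upper = 0.5 * (lo + hi)
        upper_bracket = (lo, hi)
        if not osc_gs:
            notes.append("no oscillatory probe outcome below g_upper; window may be empty")
        if specialised_from is not None and g_upper is not None and specialised_from < g_upper:
            notes.append(
                "stable fate-specialised equilibria coexist with the oscillatory "
                f"regime from g={specialised_from:g} (bistable overlap)"
            )

    return RegimeBoundaries(
        g_lower=g_lower,
        g_upper=g_upper,
        g_lower_bracket=lower_bracket,
        g_upper_bracket=upper_bracket,
        specialised_stable_from=specialised_from,
        notes=tuple(notes),
        method={
            "g_range": [g_min, g_max],
            "n_scan": n_scan,
            "rel_width": rel_width,
            "probe_horizon": horizon,
            "probe_seed": _PROBE_SEED,
            "g_lower_method": "eigenvalue root on symmetric branch",
            "g_upper_method": "bisection on probe-simulation outcome",
        },
    )
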