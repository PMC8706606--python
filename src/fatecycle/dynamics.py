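"""Right-hand sides and deterministic integration.

The model is a nondimensionalised protein-only Hill-repression ODE.  For an
OR gate the repressor inputs of gene i add inside one saturating term:

    dx_i/dt = kappa_i * ( alpha0_i + beta_i / (1 + sum_j w_ij(t) x_j^h) )
              - delta_i x_i + s_i(t)

with w_ij(t) = g(t) * W_ij the effective repression strengths, kappa_i the
knockout multiplier (0 for a null allele, else 1) and s_i(t) an additive
fate-specific signal.  For an AND gate the inputs combine multiplicatively,

    dx_i/dt = kappa_i * ( alpha0_i + beta_i /
              (1 + g(t) wbar_i prod_j x_j^{H_ij}) ) - delta_i x_i + s_i(t)

where wbar_i is the geometric mean of the nonzero relative strengths into
gene i and H_ij are per-edge exponents (clockwise inputs use h, the
anticlockwise input uses the smaller ``hill_reverse`` exponent).  A low
level of any single repressor collapses the product, so repression requires
all inputs high -- AND semantics.

Time is measured in units of the protein lifetime (degradation defaults
to 1); expression levels are dimensionless, bounded by
(alpha0 + beta + s)/delta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import CouplingSchedule, NetworkSpec, SignalProtocol

__all__ = [
    "IntegratorSettings",
    "Trajectory",
    "rhs_or",
    "rhs_and",
    "make_rhs",
    "integrate",
    "perturbed_symmetric_state",
]

log = logging.getLogger(__name__)

# Levels are bounded by (alpha0+beta+s)/delta, a few tens at most; clip far
# above that so x^h cannot overflow even transiently.
_X_CLIP = 1e12
_NEG_TOL = 1e-9


@dataclass(frozen=True)
class IntegratorSettings:
    """Solver configuration; stored with every trajectory so a run can be
    reproduced bit-for-bit."""

    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"
    n_points: int = 2000
    max_step: float = np.inf

    def asdict(self) -> dict:
        return {
            "rtol": self.rtol,
            "atol": self.atol,
            "method": self.method,
            "n_points": self.n_points,
            "max_step": self.max_step,
        }


@dataclass(frozen=True)
class Trajectory:
    """Time grid + per-gene expression levels + the protocol that made them."""

    t: np.ndarray
    x: np.ndarray  # shape (len(t), n_genes)
    spec: NetworkSpec
    schedule: CouplingSchedule
    signals: tuple[SignalProtocol, ...] = ()
    settings: IntegratorSettings = field(default_factory=IntegratorSettings)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, float)
        x = np.asarray(self.x, float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if x.shape != (t.size, self.spec.n_genes):
            raise ValueError(f"samples {x.shape} do not match grid {t.size} x {self.spec.n_genes}")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)

    @property
    def n_genes(self) -> int:
        return self.spec.n_genes

    def g_values(self) -> np.ndarray:
        return np.asarray(self.schedule(self.t), float)

    def signal_values(self) -> np.ndarray:
        s = np.zeros_like(self.x)
        for sig in self.signals:
            mask = (self.t >= sig.t_on) & (self.t < sig.t_off)
            s[mask, sig.target_gene % self.n_genes] += sig.amplitude
        return s

    def window(self, t0: float, t1: float) -> "Trajectory":
        m = (self.t >= t0) & (self.t <= t1)
        return replace(self, t=self.t[m], x=self.x[m])

    # -- tidy export ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        n_t, n = self.x.shape
        g = self.g_values()
        s = self.signal_values()
        return pd.DataFrame(
            {
                "time": np.repeat(self.t, n),
                "gene": np.tile(np.arange(n), n_t),
                "level": self.x.ravel(),
                "g_value": np.repeat(g, n),
                "signal_value": s.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def frame_to_arrays(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Rebuild (t, x) from a tidy frame written by :meth:`to_csv`."""
        wide = frame.pivot(index="time", columns="gene", values="level").sort_index()
        return wide.index.to_numpy(), wide.to_numpy()


# ----------------------------------------------------------------------
def _signal_fn(spec: NetworkSpec, signals: Sequence[SignalProtocol]):
    n = spec.n_genes
    active = [s for s in signals if s.amplitude > 0]
    if not active:
        zero = np.zeros(n)
        return lambda t: zero
    idx = np.array([s.target_gene % n for s in active])
    amp = np.array([s.amplitude for s in active])
    t_on = np.array([s.t_on for s in active])
    t_off = np.array([s.t_off for s in active])

    def s_of_t(t: float) -> np.ndarray:
        out = np.zeros(n)
        on = (t >= t_on) & (t < t_off)
        np.add.at(out, idx[on], amp[on])
        return out

    return s_of_t


def make_rhs(
    spec: NetworkSpec,
    schedule: CouplingSchedule,
    signals: Sequence[SignalProtocol] = (),
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build the ODE right-hand side f(t, x) for this network and protocol."""
    n = spec.n_genes
    kappa = (~spec.knockout_mask).astype(float)
    alpha0 = spec.production_basal * kappa
    beta = spec.production_max * kappa
    delta = spec.degradation
    h = spec.hill_coefficient
    s_of_t = _signal_fn(spec, signals)

    if spec.gate == "OR":
        W = spec.relative_coupling()

        def rhs(t: float, x: np.ndarray) -> np.ndarray:
            xc = np.clip(x, 0.0, _X_CLIP)
            den = 1.0 + float(schedule(t)) * (W @ (xc**h))
            return alpha0 + beta / den - delta * x + s_of_t(t)

        return rhs

    # AND gate: per-target geometric-mean strength, per-edge exponents.
    W = spec.relative_coupling()
    H = spec.exponents()
    mask = W > 0
    if not mask.any(axis=1).all():
        raise ValueError("AND gate requires every gene to have repressors")
    with np.errstate(divide="ignore"):
        wbar = np.exp(np.where(mask, np.log(np.where(mask, W, 1.0)), 0.0).sum(1) / mask.sum(1))
    rows = [np.flatnonzero(mask[i]) for i in range(n)]
    exps = [H[i, rows[i]] for i in range(n)]

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, 0.0, _X_CLIP)
        g = float(schedule(t))
        den = np.empty(n)
        for i in range(n):
            den[i] = 1.0 + g * wbar[i] * np.prod(xc[rows[i]] ** exps[i])
        return alpha0 + beta / den - delta * x + s_of_t(t)

    return rhs


def rhs_or(spec, schedule, signals, t, x) -> np.ndarray:
    """OR-gate time derivative at (t, x); see module docstring for the form."""
    if spec.gate != "OR":
        raise ValueError("rhs_or requires an OR-gate spec")
    return make_rhs(spec, schedule, signals)(t, np.asarray(x, float))


def rhs_and(spec, schedule, signals, t, x) -> np.ndarray:
    """AND-gate time derivative at (t, x)."""
    if spec.gate != "AND":
        raise ValueError("rhs_and requires an AND-gate spec")
    return make_rhs(spec, schedule, signals)(t, np.asarray(x, float))


class IntegrationError(RuntimeError):
    pass


def integrate(
    spec: NetworkSpec,
    schedule: CouplingSchedule,
    x0: np.ndarray,
    t_span: tuple[float, float],
    signals: Sequence[SignalProtocol] = (),
    settings: IntegratorSettings | None = None,
) -> Trajectory:
    """Integrate the network deterministically and sample on a uniform grid.

    Uses an adaptive stiff-capable solver (LSODA by default).  The reported
    grid has ``settings.n_points`` samples; interpolation comes from the
    solver's dense output, so no accuracy is lost to the reporting grid.
    Raises :class:`IntegrationError` on solver failure or non-finite states;
    small negative excursions (< 1e-9) are clamped to zero and logged.
    """
    settings = settings or IntegratorSettings()
    t0, t1 = map(float, t_span)
    if not np.isfinite([t0, t1]).all() or t1 <= t0:
        raise ValueError(f"invalid t_span {t_span}")
    x0 = np.asarray(x0, float)
    if x0.shape != (spec.n_genes,):
        raise ValueError(f"x0 must have shape ({spec.n_genes},)")
    if np.any(x0 < 0):
        raise ValueError("x0 must be nonnegative")

    rhs = make_rhs(spec, schedule, signals)
    t_eval = np.linspace(t0, t1, settings.n_points)
    sol = solve_ivp(
        rhs,
        (t0, t1),
        x0,
        method=settings.method,
        rtol=settings.rtol,
        atol=settings.atol,
        max_step=settings.max_step,
        t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message} (t reached {sol.t[-1]:.4g})")
    x = sol.y.T
    if not np.all(np.isfinite(x)):
        bad = np.flatnonzero(~np.isfinite(x).all(axis=1))[0]
        raise IntegrationError(f"non-finite state at t={t_eval[bad]:.4g}")
    neg = x < 0
    if neg.any():
        worst = x[neg].min()
        if worst < -_NEG_TOL:
            log.warning("negative excursion %.3e beyond tolerance; clamping", worst)
        x = np.where(neg, 0.0, x)
    return Trajectory(
        t=t_eval, x=x, spec=spec, schedule=schedule, signals=tuple(signals), settings=settings
    )


def perturbed_symmetric_state(
    spec: NetworkSpec,
    g: float,
    rng: np.random.Generator,
    scale: float = 0.01,
) -> np.ndarray:
    """Initial condition: the symmetric equilibrium at coupling g with a
    small multiplicative perturbation.

    The exactly symmetric state is dynamically invariant for symmetric
    networks and would never desymmetrise deterministically, so ensemble
    and demo runs start from seeded perturbations around it.
    """
    from .bifurcation import solve_symmetric

    xs = solve_symmetric(spec, g, strict=False)
    x0 = xs * (1.0 + scale * rng.standard_normal(spec.n_genes))
    return np.clip(x0, 0.0, None)
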