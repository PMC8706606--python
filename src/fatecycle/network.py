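"""Network specifications for mutual-repression gene circuits.

A :class:`NetworkSpec` describes a ring of N transcription-factor genes in
which every gene is repressed by some subset of the others.  Edges are
organised by *lag*: the edge ``j -> i`` has lag ``(i - j) mod N``, so lag 1 is
repression by the immediate upstream ("clockwise") neighbour, lag N-1 is
repression by the downstream ("anticlockwise") neighbour, and intermediate
lags connect non-neighbouring genes.  Three canonical topologies are exposed:

``cyclic``
    the classic repressilator -- each gene repressed only by its upstream
    neighbour (lag 1);
``ring_neighbors``
    repression by both immediate neighbours (lags 1 and N-1);
``all_pairs``
    repression by every other gene (all lags), the "double repressilator"
    family.

Repression strengths are *relative*; the dimensionless global coupling g(t)
from a :class:`CouplingSchedule` multiplies all of them, and is the control
parameter that moves the circuit between its multipotent, oscillatory and
differentiated regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "NetworkSpec",
    "CouplingSchedule",
    "SignalProtocol",
    "build_network",
    "effective_coupling",
]

TOPOLOGIES = ("cyclic", "ring_neighbors", "all_pairs")
GATES = ("OR", "AND")


class NetworkError(ValueError):
    """Raised when a network specification is invalid."""


def _per_gene(value, n: int, name: str) -> np.ndarray:
    """Expand a scalar to a length-n vector; validate an explicit vector."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise NetworkError(f"{name}: expected scalar or length-{n} vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise NetworkError(f"{name}: entries must be finite")
    return arr


@dataclass(frozen=True)
class NetworkSpec:
    """A validated mutual-repression network.

    Parameters
    ----------
    n_genes
        Number of transcription-factor genes (>= 2).
    topology
        ``cyclic``, ``ring_neighbors`` or ``all_pairs``.
    gate
        How multiple repressor inputs combine: ``OR`` (any high repressor
        silences the target; additive Hill terms in one denominator) or
        ``AND`` (all repressors must be high; product of repressor powers).
    coupling_forward
        Relative strength of the lag-1 edge into each gene, i.e.
        ``coupling_forward[i]`` scales the edge ``i-1 -> i``.
    coupling_reverse
        Relative strength of the lag-(N-1) edge into each gene
        (``i+1 -> i``).  Must be zero for ``cyclic`` topology.
    coupling_extra
        Strengths of non-neighbour edges, keyed by lag (2 .. N-2).  A scalar
        applies to every extra lag.  Only meaningful for ``all_pairs``.
    hill_coefficient
        Cooperativity h > 0 of the repression nonlinearity.
    hill_reverse
        Cooperativity applied to "anticlockwise-side" repressor inputs of an
        AND gate (lags above N/2).  Defaults to ``hill_coefficient / 2``.
        Ignored by OR gates.  Setting it equal to ``hill_coefficient``
        recovers a fully direction-symmetric AND gate, which never
        oscillates (see docs/methods.md).
    production_max, production_basal, degradation
        Per-gene kinetic constants (scalars are broadcast).
    knockout_mask
        Per-gene booleans; ``True`` silences that gene's production (both
        basal and maximal), modelling a null allele.
    """

    n_genes: int
    topology: str
    gate: str
    coupling_forward: np.ndarray = 1.0  # type: ignore[assignment]
    coupling_reverse: np.ndarray = 0.0  # type: ignore[assignment]
    coupling_extra: Mapping[int, np.ndarray] = field(default_factory=dict)
    hill_coefficient: float = 3.0
    hill_reverse: float | None = None
    production_max: np.ndarray = 10.0  # type: ignore[assignment]
    production_basal: np.ndarray = 0.05  # type: ignore[assignment]
    degradation: np.ndarray = 1.0  # type: ignore[assignment]
    knockout_mask: np.ndarray = False  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.n_genes
        if not isinstance(n, (int, np.integer)) or n < 2:
            raise NetworkError(f"n_genes must be an integer >= 2, got {n!r}")
        if self.topology not in TOPOLOGIES:
            raise NetworkError(f"unknown topology {self.topology!r}; choose from {TOPOLOGIES}")
        if self.gate not in GATES:
            raise NetworkError(f"unknown gate {self.gate!r}; choose from {GATES}")
        if self.gate == "AND" and self.topology == "cyclic":
            raise NetworkError("AND gate requires >= 2 repressors per gene; cyclic topology has 1")

        object.__setattr__(self, "coupling_forward", _per_gene(self.coupling_forward, n, "coupling_forward"))
        object.__setattr__(self, "coupling_reverse", _per_gene(self.coupling_reverse, n, "coupling_reverse"))
        extra_in = self.coupling_extra
        if not isinstance(extra_in, Mapping):
            extra_in = {lag: extra_in for lag in range(2, n - 1)}
        extra = {}
        for lag, val in extra_in.items():
            lag = int(lag)
            if not 2 <= lag <= n - 2:
                raise NetworkError(f"coupling_extra lag {lag} outside non-neighbour range 2..{n - 2}")
            extra[lag] = _per_gene(val, n, f"coupling_extra[{lag}]")
        object.__setattr__(self, "coupling_extra", extra)

        for name in ("coupling_forward", "coupling_reverse"):
            if np.any(getattr(self, name) < 0):
                raise NetworkError(f"{name}: strengths must be >= 0")
        for lag, val in self.coupling_extra.items():
            if np.any(val < 0):
                raise NetworkError(f"coupling_extra[{lag}]: strengths must be >= 0")

        h = float(self.hill_coefficient)
        if not np.isfinite(h) or h <= 0:
            raise NetworkError(f"hill_coefficient must be finite and > 0, got {h}")
        object.__setattr__(self, "hill_coefficient", h)
        hr = self.hill_reverse
        hr = h / 2.0 if hr is None else float(hr)
        if not np.isfinite(hr) or hr <= 0:
            raise NetworkError(f"hill_reverse must be finite and > 0, got {hr}")
        object.__setattr__(self, "hill_reverse", hr)

        object.__setattr__(self, "production_max", _per_gene(self.production_max, n, "production_max"))
        object.__setattr__(self, "production_basal", _per_gene(self.production_basal, n, "production_basal"))
        object.__setattr__(self, "degradation", _per_gene(self.degradation, n, "degradation"))
        if np.any(self.production_max < 0) or np.any(self.production_basal < 0):
            raise NetworkError("production rates must be >= 0")
        if np.any(self.degradation <= 0):
            raise NetworkError("degradation rates must be > 0")

        ko = np.asarray(self.knockout_mask)
        if ko.ndim == 0:
            ko = np.full(n, bool(ko))
        if ko.shape != (n,):
            raise NetworkError(f"knockout_mask: expected length-{n} booleans")
        object.__setattr__(self, "knockout_mask", ko.astype(bool))

        if self.topology == "cyclic":
            if np.any(self.coupling_reverse != 0):
                raise NetworkError("cyclic topology requires coupling_reverse == 0")
            if any(np.any(v != 0) for v in self.coupling_extra.values()):
                raise NetworkError("cyclic topology requires coupling_extra == 0")
        if self.topology == "ring_neighbors":
            if any(np.any(v != 0) for v in self.coupling_extra.values()):
                raise NetworkError("ring_neighbors topology requires coupling_extra == 0")

    # ------------------------------------------------------------------
    @property
    def active_lags(self) -> tuple[int, ...]:
        n = self.n_genes
        if self.topology == "cyclic":
            return (1,)
        if self.topology == "ring_neighbors":
            return (1, n - 1) if n > 2 else (1,)
        return tuple(range(1, n))

    def lag_strength(self, lag: int) -> np.ndarray:
        """Per-target strengths of the edges with the given lag."""
        n = self.n_genes
        if lag == 1:
            return self.coupling_forward
        if lag == n - 1 and n > 2:
            return self.coupling_reverse
        return self.coupling_extra.get(lag, np.zeros(n))

    def relative_coupling(self) -> np.ndarray:
        """The n x n matrix W of relative strengths, W[i, j] for edge j -> i."""
        n = self.n_genes
        W = np.zeros((n, n))
        for lag in self.active_lags:
            s = self.lag_strength(lag)
            for i in range(n):
                W[i, (i - lag) % n] += s[i]
        return W

    def exponents(self) -> np.ndarray:
        """Per-edge Hill exponents H[i, j] (zero where no edge).

        OR gates use ``hill_coefficient`` on every edge.  AND gates apply
        ``hill_coefficient`` to clockwise-side inputs (lag <= N/2) and
        ``hill_reverse`` to anticlockwise-side inputs, which breaks the
        direction symmetry of the product gate and permits oscillation.
        """
        n = self.n_genes
        H = np.zeros((n, n))
        for lag in self.active_lags:
            s = self.lag_strength(lag)
            if self.gate == "OR":
                h = self.hill_coefficient
            else:
                h = self.hill_coefficient if lag <= n / 2 else self.hill_reverse
            for i in range(n):
                if s[i] > 0:
                    H[i, (i - lag) % n] = h
        return H

    def is_cyclically_symmetric(self, rtol: float = 1e-12) -> bool:
        """True if all per-lag strength vectors and kinetics are uniform."""
        uniform = lambda v: np.allclose(v, v[0], rtol=rtol, atol=0)
        return (
            all(uniform(self.lag_strength(lag)) for lag in self.active_lags)
            and uniform(self.production_max)
            and uniform(self.production_basal)
            and uniform(self.degradation)
            and not self.knockout_mask.any()
        )

    def with_knockout(self, *genes: int) -> "NetworkSpec":
        """Return a copy with the given genes silenced (null alleles)."""
        mask = self.knockout_mask.copy()
        for g in genes:
            mask[int(g) % self.n_genes] = True
        if mask.all():
            raise NetworkError("refusing to knock out every gene")
        return replace(self, knockout_mask=mask)

    def relabel(self, shift: int) -> "NetworkSpec":
        """Cyclically relabel genes: new gene i is old gene (i + shift) mod N.

        Relabeling commutes with simulation: simulating the relabeled spec
        from relabeled initial conditions reproduces the relabeled
        trajectories of the original.
        """
        n = self.n_genes
        perm = (np.arange(n) + shift) % n
        return replace(
            self,
            coupling_forward=self.coupling_forward[perm],
            coupling_reverse=self.coupling_reverse[perm],
            coupling_extra={lag: v[perm] for lag, v in self.coupling_extra.items()},
            production_max=self.production_max[perm],
            production_basal=self.production_basal[perm],
            degradation=self.degradation[perm],
            knockout_mask=self.knockout_mask[perm],
        )


@dataclass(frozen=True)
class CouplingSchedule:
    """Global coupling multiplier g(t).

    ``constant``: g(t) = g_start everywhere.
    ``linear_ramp``: g_start before t_start, linear to g_end at t_end,
    g_end afterwards; requires g_end >= g_start.
    ``piecewise_linear``: linear interpolation through ``points``
    (a sequence of (t, g) pairs), clamped at the ends.
    """

    kind: str = "constant"
    g_start: float = 1.0
    g_end: float | None = None
    t_start: float = 0.0
    t_end: float | None = None
    points: Sequence[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear_ramp", "piecewise_linear"):
            raise NetworkError(f"unknown schedule kind {self.kind!r}")
        if self.g_start < 0:
            raise NetworkError("g_start must be >= 0")
        if self.kind == "linear_ramp":
            if self.g_end is None or self.t_end is None:
                raise NetworkError("linear_ramp requires g_end and t_end")
            if self.g_end < self.g_start:
                raise NetworkError("linear_ramp requires g_end >= g_start (nondecreasing)")
            if self.t_end <= self.t_start:
                raise NetworkError("linear_ramp requires t_end > t_start")
        if self.kind == "piecewise_linear":
            pts = self.points
            if not pts or len(pts) < 2:
                raise NetworkError("piecewise_linear requires >= 2 (t, g) points")
            ts = [p[0] for p in pts]
            gs = [p[1] for p in pts]
            if any(t2 <= t1 for t1, t2 in zip(ts, ts[1:])):
                raise NetworkError("piecewise_linear times must be strictly increasing")
            if any(g < 0 for g in gs):
                raise NetworkError("piecewise_linear g values must be >= 0")
            object.__setattr__(self, "points", tuple((float(t), float(g)) for t, g in pts))

    def __call__(self, t):
        if self.kind == "constant":
            return self.g_start if np.ndim(t) == 0 else np.full(np.shape(t), self.g_start)
        if self.kind == "linear_ramp":
            frac = np.clip((np.asarray(t, float) - self.t_start) / (self.t_end - self.t_start), 0.0, 1.0)
            out = self.g_start + (self.g_end - self.g_start) * frac
            return float(out) if np.ndim(t) == 0 else out
        ts = np.array([p[0] for p in self.points])
        gs = np.array([p[1] for p in self.points])
        out = np.interp(t, ts, gs)
        return float(out) if np.ndim(t) == 0 else out

    def is_constant_over(self, t0: float, t1: float, rtol: float = 1e-12) -> bool:
        probe = self(np.linspace(t0, t1, 17))
        return bool(np.ptp(probe) <= rtol * max(abs(np.max(probe)), 1.0))

    def crossing_time(self, g_value: float) -> float | None:
        """First time g(t) reaches g_value (None if never reached)."""
        if self.kind == "constant":
            return None
        if self.kind == "linear_ramp":
            if not self.g_start <= g_value <= self.g_end:
                return None
            if self.g_end == self.g_start:
                return self.t_start
            return self.t_start + (g_value - self.g_start) / (self.g_end - self.g_start) * (
                self.t_end - self.t_start
            )
        ts = np.array([p[0] for p in self.points])
        gs = np.array([p[1] for p in self.points])
        for k in range(len(ts) - 1):
            lo, hi = sorted((gs[k], gs[k + 1]))
            if lo <= g_value <= hi and gs[k + 1] != gs[k]:
                return float(ts[k] + (g_value - gs[k]) / (gs[k + 1] - gs[k]) * (ts[k + 1] - ts[k]))
        return None


@dataclass(frozen=True)
class SignalProtocol:
    """A fate-specific external signal: an additive production boost
    ``amplitude`` delivered to ``target_gene`` during [t_on, t_off)."""

    target_gene: int
    amplitude: float
    t_on: float = 0.0
    t_off: float = np.inf

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise NetworkError("signal amplitude must be >= 0")
        if self.t_off <= self.t_on:
            raise NetworkError("signal requires t_off > t_on")

    def active(self, t: float) -> bool:
        return self.t_on <= t < self.t_off


# ----------------------------------------------------------------------
_NETWORK_KEYS = {
    "n_genes",
    "topology",
    "gate",
    "coupling",
    "coupling_forward",
    "coupling_reverse",
    "coupling_extra",
    "hill_coefficient",
    "hill_reverse",
    "production_max",
    "production_basal",
    "degradation",
    "knockout_mask",
}


def build_network(config: Mapping) -> NetworkSpec:
    """Build and validate a :class:`NetworkSpec` from a plain mapping.

    ``coupling`` is a convenience scalar: it sets ``coupling_forward`` and,
    for non-cyclic topologies, scales the default reverse (0.1 x forward)
    and extra strengths.  Unknown keys are rejected.
    """
    unknown = set(config) - _NETWORK_KEYS
    if unknown:
        raise NetworkError(f"unknown network config keys: {sorted(unknown)}")
    for key in ("n_genes", "topology", "gate"):
        if key not in config:
            raise NetworkError(f"network config requires {key!r}")

    cfg = dict(config)
    n = cfg.pop("n_genes")
    topology = cfg.pop("topology")
    gate = cfg.pop("gate")
    coupling = cfg.pop("coupling", None)

    kwargs: dict = {}
    if coupling is not None:
        c = float(coupling)
        kwargs["coupling_forward"] = c
        if topology != "cyclic":
            kwargs["coupling_reverse"] = 0.1 * c
        if topology == "all_pairs" and n > 3:
            kwargs["coupling_extra"] = 0.1 * c
    if topology == "cyclic":
        kwargs.setdefault("coupling_reverse", 0.0)
    elif "coupling_reverse" not in cfg:
        kwargs.setdefault("coupling_reverse", 0.1)
    if topology == "all_pairs" and n > 3 and "coupling_extra" not in cfg:
        kwargs.setdefault("coupling_extra", 0.1)
    kwargs.setdefault("coupling_forward", 1.0)
    kwargs.update(cfg)
    return NetworkSpec(n_genes=n, topology=topology, gate=gate, **kwargs)


def effective_coupling(
    spec: NetworkSpec, schedule: CouplingSchedule, t: float
) -> np.ndarray:
    """Pairwise repression strengths w_ij(t) = g(t) * relative strength.

    Knockouts do not enter: they silence production, not edges (the mutant
    gene's repressive influence vanishes dynamically as its level decays).
    """
    return float(schedule(t)) * spec.relative_coupling()
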