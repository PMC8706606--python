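"""In-silico experiments: ramp-driven fate choice, signal-driven exit,
knockout phenotypes, and topology scans.

The experiments realise the qualitative predictions of the cyclical
fate-restriction picture: a slowly rising coupling carries a cell from the
multipotent equilibrium through the oscillatory (fate-biased) regime to a
stable differentiated state, and the fate adopted is set by which gene
dominates when the coupling crosses the upper regime boundary; a sustained
fate-specific production boost can pull the oscillation into the targeted
fate from any phase once its amplitude exceeds a threshold; and a null
allele removes its own fate while lengthening the dwell of the sub-state
that precedes it in the cycling order.

All ensembles are reproducible bit-for-bit: per-run random streams are
spawned from the master seed with ``numpy.random.SeedSequence``, so results
do not depend on execution order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .bifurcation import RegimeBoundaries, find_boundaries, probe_label, solve_symmetric
from .dynamics import IntegratorSettings, Trajectory, integrate
from .network import CouplingSchedule, NetworkSpec, SignalProtocol
from .regimes import (
    ClassifierThresholds,
    classify,
    cycle_order,
    dwell_fractions,
    period,
)

__all__ = [
    "FateOutcome",
    "EnsembleSummary",
    "ramp_ensemble",
    "signal_exit",
    "SignalExitResult",
    "knockout_experiment",
    "KnockoutReport",
    "topology_scan",
]

_ENSEMBLE_SETTINGS = IntegratorSettings(rtol=1e-7, atol=1e-9, n_points=3000)


class ExperimentError(RuntimeError):
    pass


@dataclass(frozen=True)
class FateOutcome:
    """Outcome of one ramp run."""

    seed: int
    final_label: str
    final_dominant: tuple[int, ...] | None
    state_at_crossing: tuple[float, ...] | None
    t_crossing: float | None
    t_commit: float | None

    @property
    def predicted_fate(self) -> int | None:
        """argmax expression at the moment the ramp crossed g_upper."""
        if self.state_at_crossing is None:
            return None
        return int(np.argmax(self.state_at_crossing))


@dataclass(frozen=True)
class EnsembleSummary:
    """Aggregated fate statistics for an ensemble of runs."""

    outcomes: tuple[FateOutcome, ...]
    counts: dict
    proportions: dict
    confidence_intervals: dict
    n_undetermined: int
    predictor_agreement: float | None
    metadata: dict = field(default_factory=dict)

    @property
    def n_runs(self) -> int:
        return len(self.outcomes)

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "counts": {str(k): v for k, v in self.counts.items()},
            "proportions": {str(k): v for k, v in self.proportions.items()},
            "confidence_intervals": {str(k): list(v) for k, v in self.confidence_intervals.items()},
            "n_undetermined": self.n_undetermined,
            "predictor_agreement": self.predictor_agreement,
            "metadata": self.metadata,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def runs_frame(self) -> pd.DataFrame:
        rows = []
        for o in self.outcomes:
            rows.append(
                {
                    "seed": o.seed,
                    "final_label": o.final_label,
                    "final_dominant": "+".join(map(str, o.final_dominant)) if o.final_dominant else None,
                    "predicted_fate": o.predicted_fate,
                    "t_crossing": o.t_crossing,
                    "t_commit": o.t_commit,
                }
            )
        return pd.DataFrame(rows)


def _exact_ci(k: int, n: int) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    return (float(ci.low), float(ci.high))


def _summarise(outcomes: Sequence[FateOutcome], metadata: dict) -> EnsembleSummary:
    n = len(outcomes)
    counts: dict = {}
    for o in outcomes:
        key = o.final_dominant if o.final_label == "differentiated" else o.final_label
        counts[key] = counts.get(key, 0) + 1
    proportions = {k: v / n for k, v in counts.items()} if n else {}
    cis = {k: _exact_ci(v, n) for k, v in counts.items()}
    n_und = sum(1 for o in outcomes if o.final_label != "differentiated")
    pairs = [
        (o.predicted_fate, o.final_dominant)
        for o in outcomes
        if o.final_label == "differentiated" and o.predicted_fate is not None
    ]
    agreement = None
    if pairs:
        agreement = float(np.mean([p == d[0] for p, d in pairs if len(d) == 1])) if any(
            len(d) == 1 for _, d in pairs
        ) else None
    return EnsembleSummary(
        outcomes=tuple(outcomes),
        counts=counts,
        proportions=proportions,
        confidence_intervals=cis,
        n_undetermined=n_und,
        predictor_agreement=agreement,
        metadata=metadata,
    )


# ----------------------------------------------------------------------
def _probe_trajectory(spec: NetworkSpec, g: float, settings: IntegratorSettings,
                      horizon: float = 400.0, seed: int = 715891) -> Trajectory:
    """Standardised constant-coupling run from a perturbed symmetric start."""
    rng = np.random.default_rng(seed)
    xs = solve_symmetric(spec, g, strict=False)
    x0 = np.clip(xs * (1.0 + 0.01 * rng.standard_normal(spec.n_genes)), 0.0, None)
    return integrate(
        spec, CouplingSchedule(kind="constant", g_start=g), x0, (0.0, horizon), settings=settings
    )


def _tail_report(traj: Trajectory, g_tail: float, frac: float = 0.15,
                 t_from: float | None = None,
                 thresholds: ClassifierThresholds | None = None):
    """Classify the final stretch of a run as if at constant coupling.

    ``t_from`` pins the window start (e.g. the end of a ramp, so that the
    drift of equilibria tracking the ramp is excluded); otherwise the last
    ``frac`` of the horizon is used.
    """
    t0 = t_from if t_from is not None else traj.t[-1] - frac * (traj.t[-1] - traj.t[0])
    tail = traj.window(t0, traj.t[-1])
    frozen = Trajectory(
        t=tail.t, x=tail.x, spec=traj.spec,
        schedule=CouplingSchedule(kind="constant", g_start=g_tail),
        signals=traj.signals, settings=traj.settings,
    )
    return classify(frozen, thresholds=thresholds, transient_fraction=0.0)


def _commitment_time(traj: Trajectory, ratio: float, sustain_fraction: float = 0.05) -> float | None:
    """First time the dominance ratio reaches ``ratio`` and stays there for
    at least ``sustain_fraction`` of the horizon."""
    X = traj.x
    part = np.partition(X, -2, axis=1)
    top, second = part[:, -1], part[:, -2]
    r = top / np.maximum(second, 1e-12)
    ok = r >= ratio
    need = max(1, int(sustain_fraction * len(ok)))
    csum = np.convolve(ok.astype(int), np.ones(need, dtype=int), mode="valid")
    hits = np.flatnonzero(csum == need)
    return float(traj.t[hits[0]]) if hits.size else None


def _run_seeds(master_seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(master_seed).spawn(n)]


def ramp_ensemble(
    spec: NetworkSpec,
    ramp: CouplingSchedule,
    n_runs: int,
    seed: int,
    boundaries: RegimeBoundaries | None = None,
    settle: float = 100.0,
    ic_scale: float = 0.01,
    settings: IntegratorSettings | None = None,
    thresholds: ClassifierThresholds | None = None,
    mutant: NetworkSpec | None = None,
) -> EnsembleSummary | tuple[EnsembleSummary, EnsembleSummary]:
    """Ensemble of coupling-ramp runs ending in fate commitment.

    Initial conditions are seeded perturbations of the symmetric state at
    the ramp's starting coupling.  Each run records the expression state at
    the moment g(t) first exceeds the upper regime boundary (the fate
    predictor) and the final regime after the ramp settles.  Runs that do
    not differentiate are counted, not dropped.

    When ``mutant`` is given, every initial condition is run through both
    the wild-type ``spec`` and the mutant spec (paired design, identical
    seeds), and a pair of summaries is returned.
    """
    if ramp.kind == "constant":
        raise ExperimentError("ramp_ensemble requires a non-constant schedule")
    if boundaries is None:
        g_end = float(ramp(np.inf))
        boundaries = find_boundaries(spec, (max(float(ramp(0.0)), 1e-4 * g_end), g_end))
    if boundaries.g_upper is None:
        raise ExperimentError("no upper regime boundary: the ramp cannot drive differentiation")
    t_cross = ramp.crossing_time(boundaries.g_upper)
    if t_cross is None:
        raise ExperimentError(
            f"ramp never crosses g_upper={boundaries.g_upper:g}; extend its range"
        )
    settings = settings or _ENSEMBLE_SETTINGS
    th = thresholds or ClassifierThresholds()
    g0 = float(ramp(0.0))
    g_end = float(ramp(np.inf))
    t_end = ramp.t_end if ramp.kind == "linear_ramp" else ramp.points[-1][0]
    horizon = (0.0, float(t_end) + settle)
    xs = solve_symmetric(spec, g0, strict=False)

    # A ramped trajectory can express the boundary crossing only with the
    # resolution of one oscillation period, so the fate-predictor state is
    # sampled one boundary-period after g(t) first exceeds g_upper.
    try:
        boundary_period = period(
            _probe_trajectory(spec, 0.9 * boundaries.g_upper, settings), thresholds=th
        )
    except Exception:
        boundary_period = 0.0
    t_sample = t_cross + boundary_period

    meta = {
        "schedule": asdict(ramp),
        "master_seed": seed,
        "n_runs": n_runs,
        "g_upper": boundaries.g_upper,
        "boundary_period": boundary_period,
        "crossing_definition": "state sampled one boundary period after g(t) exceeds g_upper",
        "ic_scale": ic_scale,
        "settings": settings.asdict(),
    }
    specs = [spec] if mutant is None else [spec, mutant]
    all_outcomes: list[list[FateOutcome]] = [[] for _ in specs]
    seeds = np.random.SeedSequence(seed).spawn(max(n_runs, 0))
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        x0 = np.clip(xs * (1.0 + ic_scale * rng.standard_normal(spec.n_genes)), 0.0, None)
        for which, sp in enumerate(specs):
            traj = integrate(sp, ramp, x0, horizon, settings=settings)
            xc = np.array([np.interp(t_sample, traj.t, traj.x[:, j]) for j in range(sp.n_genes)])
            rep = _tail_report(traj, g_end, t_from=float(t_end), thresholds=th)
            dominant = rep.dominant if rep.label == "differentiated" else None
            all_outcomes[which].append(
                FateOutcome(
                    seed=i,
                    final_label=rep.label,
                    final_dominant=dominant,
                    state_at_crossing=tuple(np.round(xc, 12)),
                    t_crossing=float(t_sample),
                    t_commit=_commitment_time(traj, th.dominance_ratio),
                )
            )
    if mutant is None:
        return _summarise(all_outcomes[0], meta)
    return (
        _summarise(all_outcomes[0], {**meta, "arm": "wild_type"}),
        _summarise(all_outcomes[1], {**meta, "arm": "mutant"}),
    )


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SignalExitResult:
    """Bracketed amplitude threshold for signal-driven exit."""

    target_gene: int
    g_const: float
    threshold_bracket: tuple[float, float]
    commit_fraction_above: float  # at 1.05 x bracket top, full phase set
    zero_amplitude_label: str
    n_phases: int
    amplitudes_tested: tuple[tuple[float, float], ...]  # (amplitude, commit fraction)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def signal_exit(
    spec: NetworkSpec,
    g_const: float,
    target_gene: int,
    seed: int = 0,
    n_phases: int = 50,
    n_phases_bracket: int = 16,
    amp_init: float = 0.25,
    signal_horizon: float = 300.0,
    settings: IntegratorSettings | None = None,
    thresholds: ClassifierThresholds | None = None,
) -> SignalExitResult:
    """Find the signal amplitude above which the targeted fate is adopted
    from every oscillation phase.

    The unsignalled system must be oscillatory at ``g_const``.  Initial
    conditions sample one full period of the settled cycle; a sustained
    production boost to ``target_gene`` is then applied and each run
    classified.  The threshold is bracketed by doubling then bisection
    (bracket phases ``n_phases_bracket``; the final verification at 1.05x
    the bracket top uses the full ``n_phases``).
    """
    if probe_label(spec, g_const) != "oscillatory":
        raise ExperimentError(f"system is not oscillatory at g={g_const:g}")
    settings = settings or _ENSEMBLE_SETTINGS
    th = thresholds or ClassifierThresholds()
    target_gene = int(target_gene) % spec.n_genes
    sched = CouplingSchedule(kind="constant", g_start=g_const)

    rng = np.random.default_rng(seed)
    xs = solve_symmetric(spec, g_const, strict=False)
    x0 = np.clip(xs * (1.0 + 0.01 * rng.standard_normal(spec.n_genes)), 0.0, None)
    base = integrate(spec, sched, x0, (0.0, 400.0), settings=settings)
    per = period(base, thresholds=th)

    def phase_states(k: int) -> np.ndarray:
        t_samples = base.t[-1] - per * np.arange(k) / k
        return np.vstack(
            [[np.interp(t, base.t, base.x[:, j]) for j in range(spec.n_genes)] for t in t_samples]
        )

    def commit_fraction(amp: float, k: int) -> float:
        if amp == 0.0:
            return 0.0
        sig = SignalProtocol(target_gene=target_gene, amplitude=amp, t_on=0.0)
        hits = 0
        for ic in phase_states(k):
            traj = integrate(spec, sched, ic, (0.0, signal_horizon), signals=[sig], settings=settings)
            rep = _tail_report(traj, g_const, thresholds=th)
            hits += rep.label == "differentiated" and rep.dominant == (target_gene,)
        return hits / k

    tested: list[tuple[float, float]] = []
    beta = float(spec.production_max.max())
    amp = amp_init
    lo, hi = 0.0, None
    while amp <= 8.0 * beta:
        frac = commit_fraction(amp, n_phases_bracket)
        tested.append((amp, frac))
        if frac == 1.0:
            hi = amp
            break
        lo = amp
        amp *= 2.0
    if hi is None:
        raise ExperimentError("no amplitude up to 8*beta commits every phase")
    for _ in range(6):
        mid = 0.5 * (lo + hi)
        frac = commit_fraction(mid, n_phases_bracket)
        tested.append((mid, frac))
        if frac == 1.0:
            hi = mid
        else:
            lo = mid

    above = commit_fraction(1.05 * hi, n_phases)
    zero_rep = _tail_report(
        integrate(spec, sched, phase_states(1)[0], (0.0, signal_horizon), settings=settings),
        g_const,
        frac=0.6,
        thresholds=th,
    )
    return SignalExitResult(
        target_gene=target_gene,
        g_const=g_const,
        threshold_bracket=(lo, hi),
        commit_fraction_above=above,
        zero_amplitude_label=zero_rep.label,
        n_phases=n_phases,
        amplitudes_tested=tuple(tested),
        metadata={"seed": seed, "period": per, "signal_horizon": signal_horizon},
    )


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class KnockoutReport:
    """Paired wild-type vs null-allele comparison."""

    gene: int
    context: str  # "dwell" | "ramp"
    wt_label: str
    mut_label: str
    preceding: tuple[int, ...] | None
    wt_dwell: dict | None = None
    mut_dwell: dict | None = None
    cycle_order_wt: tuple | None = None
    cycle_order_mut: tuple | None = None
    wt_summary: EnsembleSummary | None = None
    mut_summary: EnsembleSummary | None = None
    notes: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        fmt = lambda d: {"+".join(map(str, k)): v for k, v in d.items()} if d else None
        return {
            "gene": self.gene,
            "context": self.context,
            "wt_label": self.wt_label,
            "mut_label": self.mut_label,
            "preceding": list(self.preceding) if self.preceding else None,
            "wt_dwell": fmt(self.wt_dwell),
            "mut_dwell": fmt(self.mut_dwell),
            "cycle_order_wt": [list(s) for s in self.cycle_order_wt] if self.cycle_order_wt else None,
            "cycle_order_mut": [list(s) for s in self.cycle_order_mut] if self.cycle_order_mut else None,
            "wt_summary": self.wt_summary.to_dict() if self.wt_summary else None,
            "mut_summary": self.mut_summary.to_dict() if self.mut_summary else None,
            "notes": list(self.notes),
            "metadata": self.metadata,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _preceding_substate(order: Sequence[tuple[int, ...]], gene: int) -> tuple[int, ...] | None:
    """Sub-state immediately before gene's own sub-state in the measured
    wild-type cycling order."""
    for pos, ident in enumerate(order):
        if gene in ident:
            return tuple(order[(pos - 1) % len(order)])
    return None


def knockout_experiment(
    spec: NetworkSpec,
    gene: int,
    context: str = "dwell",
    g: float | None = None,
    ramp: CouplingSchedule | None = None,
    boundaries: RegimeBoundaries | None = None,
    n_runs: int = 300,
    seed: int = 0,
    horizon: float = 1200.0,
    settings: IntegratorSettings | None = None,
    thresholds: ClassifierThresholds | None = None,
) -> KnockoutReport:
    """Compare wild type against a null allele of ``gene``.

    ``context='dwell'``: both genotypes run from identical initial
    conditions at constant coupling ``g``; the report compares dwell
    fractions, with the wild-type cycling order defining which sub-state
    "precedes" the knocked-out gene's.  A mutant that stops cycling is
    reported as a regime change, not an error.

    ``context='ramp'``: paired ramp ensembles (identical seeds per run);
    the report carries both fate distributions.
    """
    gene = int(gene) % spec.n_genes
    mutant = spec.with_knockout(gene)
    th = thresholds or ClassifierThresholds()
    settings = settings or _ENSEMBLE_SETTINGS

    if context == "dwell":
        if g is None:
            raise ValueError("dwell context requires a constant coupling g")
        sched = CouplingSchedule(kind="constant", g_start=g)
        rng = np.random.default_rng(seed)
        xs = solve_symmetric(spec, g, strict=False)
        x0 = np.clip(xs * (1.0 + 0.01 * rng.standard_normal(spec.n_genes)), 0.0, None)
        wt = integrate(spec, sched, x0, (0.0, horizon), settings=settings)
        wt_rep = classify(wt, thresholds=th)
        if wt_rep.label != "oscillatory":
            return KnockoutReport(
                gene=gene,
                context="dwell",
                wt_label=wt_rep.label,
                mut_label="not_run",
                preceding=None,
                notes=(f"regime change: {wt_rep.label}; no oscillation to analyse",),
                metadata={"g": g, "seed": seed, "horizon": horizon},
            )
        from .regimes import dwell_times

        wt_states = dwell_times(wt, thresholds=th)
        order_wt = cycle_order(wt_states)
        preceding = _preceding_substate(order_wt, gene)
        mut = integrate(mutant, sched, x0, (0.0, horizon), settings=settings)
        mut_rep = classify(mut, thresholds=th)
        notes = []
        mut_dwell = order_mut = None
        if mut_rep.label == "oscillatory":
            mut_states = dwell_times(mut, thresholds=th)
            mut_dwell = {s: f for s, f in _dwell_of(mut_states).items()}
            order_mut = tuple(cycle_order(mut_states))
        else:
            notes.append(f"regime change: mutant is {mut_rep.label}; no dwell comparison")
        return KnockoutReport(
            gene=gene,
            context="dwell",
            wt_label=wt_rep.label,
            mut_label=mut_rep.label,
            preceding=preceding,
            wt_dwell=_dwell_of(wt_states),
            mut_dwell=mut_dwell,
            cycle_order_wt=tuple(order_wt),
            cycle_order_mut=order_mut,
            notes=tuple(notes),
            metadata={"g": g, "seed": seed, "horizon": horizon},
        )

    if context == "ramp":
        if ramp is None:
            raise ValueError("ramp context requires a CouplingSchedule ramp")
        wt_sum, mut_sum = ramp_ensemble(
            spec, ramp, n_runs, seed, boundaries=boundaries,
            settings=settings, thresholds=th, mutant=mutant,
        )
        return KnockoutReport(
            gene=gene,
            context="ramp",
            wt_label="ensemble",
            mut_label="ensemble",
            preceding=None,
            wt_summary=wt_sum,
            mut_summary=mut_sum,
            metadata={"seed": seed, "n_runs": n_runs},
        )

    raise ValueError(f"unknown context {context!r}; use 'dwell' or 'ramp'")


def _dwell_of(states) -> dict:
    total = sum(s.duration for s in states)
    acc: dict = {}
    for s in states:
        acc[s.genes] = acc.get(s.genes, 0.0) + s.duration
    return {k: v / total for k, v in sorted(acc.items())} if total else {}


# ----------------------------------------------------------------------
def _canonical_spec(n: int, topology: str, gate: str) -> NetworkSpec:
    """Default strengths used by the topology scan."""
    kw: dict = {}
    if gate == "AND":
        kw = {"coupling_reverse": 0.0 if topology == "cyclic" else 1.0, "hill_reverse": 1.5}
    else:
        kw = {"coupling_reverse": 0.0 if topology == "cyclic" else 0.2}
    if topology == "all_pairs" and n > 3:
        if n == 4:
            kw["coupling_extra"] = 1.5
        else:
            kw["coupling_extra"] = {lag: (0.3 if lag <= n // 2 else 0.05) for lag in range(2, n - 1)}
        if gate == "OR":
            kw["coupling_reverse"] = 0.1
    return NetworkSpec(n_genes=n, topology=topology, gate=gate, **kw)


def topology_scan(
    n_list: Sequence[int],
    topologies: Sequence[str],
    gate: str = "OR",
    g_grid: Sequence[float] | None = None,
    n_seeds: int = 2,
    horizon: float = 600.0,
    thresholds: ClassifierThresholds | None = None,
) -> pd.DataFrame:
    """Scan circuit sizes and topologies for oscillatory behaviour.

    Each (N, topology) cell is probed at every grid coupling from
    ``n_seeds`` perturbed-symmetric starts; the cell oscillates if any
    probe classifies as oscillatory.  Absence of oscillation is a result,
    not an error.  Returns a table with the supporting couplings.
    """
    if g_grid is None:
        g_grid = np.geomspace(1e-3, 3.0, 10) if gate == "OR" else np.geomspace(3e-6, 0.03, 10)
    th = thresholds or ClassifierThresholds()
    settings = IntegratorSettings(rtol=1e-7, atol=1e-9, n_points=1500)
    rows = []
    for n in n_list:
        for topology in topologies:
            if gate == "AND" and topology == "cyclic":
                continue
            spec = _canonical_spec(int(n), topology, gate)
            support = []
            for g in g_grid:
                found = False
                for s in range(n_seeds):
                    rng = np.random.default_rng(1000 + s)
                    xs = solve_symmetric(spec, g, strict=False)
                    x0 = np.clip(xs * (1 + 0.01 * rng.standard_normal(spec.n_genes)), 0, None)
                    traj = integrate(
                        spec, CouplingSchedule(kind="constant", g_start=float(g)), x0,
                        (0.0, horizon), settings=settings,
                    )
                    if classify(traj, thresholds=th).label == "oscillatory":
                        found = True
                        break
                if found:
                    support.append(float(g))
            rows.append(
                {
                    "n_genes": int(n),
                    "topology": topology,
                    "gate": gate,
                    "oscillates": bool(support),
                    "g_support": support,
                }
            )
    return pd.DataFrame(rows)
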