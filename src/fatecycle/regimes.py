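"""Classify trajectories into response modes and quantify sub-state structure.

A mutual-repression circuit at constant coupling g shows one of three
responses: a *multipotent* equilibrium with all genes co-expressed at
similar levels, an *oscillatory* regime cycling through transient
fate-biased sub-states, or a *differentiated* equilibrium in which one gene
(or, for AND gates and some larger rings, a co-dominant pair) sits far
above the rest.  The thresholds that draw these lines are explicit,
configurable and reported with every classification; trajectories whose
amplitude falls inside the hysteresis band between "steady" and
"oscillating" are labelled ``undetermined`` rather than guessed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .dynamics import Trajectory

__all__ = [
    "ClassifierThresholds",
    "RegimeReport",
    "SubState",
    "classify",
    "classify_windows",
    "dwell_times",
    "dwell_fractions",
    "period",
    "PeriodError",
]


class RegimeError(ValueError):
    pass


class PeriodError(RegimeError):
    """Period requested for a non-oscillatory trajectory."""


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision rules for regime classification.

    oscillatory   : post-transient amplitude >= ``osc_rel_amp`` of that
                    gene's mean on at least one gene, with >= ``min_peaks``
                    detected peaks;
    multipotent   : steady (every gene's amplitude < ``steady_rel_amp`` of
                    the grand mean level, so residual drift on a silenced
                    gene is judged on the overall expression scale) and all
                    means within ``multipotent_tol`` of the grand mean;
    differentiated: steady and dominance ratio (top mean / second mean, or
                    second / third for a co-dominant pair) >= ``dominance_ratio``.

    ``hysteresis`` is the relative band used for sub-state assignment: the
    incumbent dominant gene keeps its sub-state until a challenger exceeds
    it by this fraction, suppressing chatter at crossings.
    """

    osc_rel_amp: float = 0.05
    steady_rel_amp: float = 1e-3
    multipotent_tol: float = 0.05
    dominance_ratio: float = 3.0
    hysteresis: float = 0.02
    min_peaks: int = 3
    transient_fraction: float = 0.5

    def asdict(self) -> dict:
        return {
            "osc_rel_amp": self.osc_rel_amp,
            "steady_rel_amp": self.steady_rel_amp,
            "multipotent_tol": self.multipotent_tol,
            "dominance_ratio": self.dominance_ratio,
            "hysteresis": self.hysteresis,
            "min_peaks": self.min_peaks,
            "transient_fraction": self.transient_fraction,
        }


@dataclass(frozen=True)
class SubState:
    """A contiguous stretch of the oscillation dominated by one gene
    (OR gate) or one co-expressed pair (AND gate)."""

    genes: tuple[int, ...]
    t_entry: float
    t_exit: float

    @property
    def duration(self) -> float:
        return self.t_exit - self.t_entry


@dataclass(frozen=True)
class RegimeReport:
    label: str  # multipotent | oscillatory | differentiated | undetermined
    means: np.ndarray
    amplitudes: np.ndarray
    period: float | None = None
    dominant: tuple[int, ...] | None = None
    dwell: dict | None = None  # identity -> fraction of classified time
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    g_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "means": list(np.round(self.means, 10)),
            "amplitudes": list(np.round(self.amplitudes, 10)),
            "period": self.period,
            "dominant": list(self.dominant) if self.dominant is not None else None,
            "dwell": {"+".join(map(str, k)): v for k, v in (self.dwell or {}).items()} or None,
            "g_value": self.g_value,
            "thresholds": self.thresholds.asdict(),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ----------------------------------------------------------------------
def _post_transient(traj: Trajectory, transient_fraction: float) -> Trajectory:
    t0, t1 = traj.t[0], traj.t[-1]
    return traj.window(t0 + transient_fraction * (t1 - t0), t1)


def _peak_count(y: np.ndarray, amp: float) -> int:
    if amp <= 0:
        return 0
    peaks, _ = find_peaks(y, prominence=0.1 * amp)
    return len(peaks)


def classify(
    traj: Trajectory,
    thresholds: ClassifierThresholds | None = None,
    transient_fraction: float | None = None,
) -> RegimeReport:
    """Classify a constant-coupling trajectory into one of the response modes.

    Raises :class:`RegimeError` for ramped trajectories; use
    :func:`classify_windows` to classify a ramp piecewise.
    """
    th = thresholds or ClassifierThresholds()
    tf = th.transient_fraction if transient_fraction is None else transient_fraction
    if not traj.schedule.is_constant_over(traj.t[0], traj.t[-1]):
        raise RegimeError("trajectory is under a coupling ramp; classify piecewise instead")

    post = _post_transient(traj, tf)
    means = post.x.mean(axis=0)
    amps = post.x.max(axis=0) - post.x.min(axis=0)
    rel_amp = amps / np.maximum(means, 1e-12)
    g_val = float(traj.schedule(post.t[0]))

    report = dict(means=means, amplitudes=amps, thresholds=th, g_value=g_val)

    lead = int(np.argmax(rel_amp))
    if rel_amp[lead] >= th.osc_rel_amp and _peak_count(post.x[:, lead], amps[lead]) >= th.min_peaks:
        states = dwell_times(traj, thresholds=th, transient_fraction=tf)
        dwell = _fractions(states)
        try:
            per = period(traj, thresholds=th, transient_fraction=tf)
        except PeriodError:
            per = None
        return RegimeReport(label="oscillatory", period=per, dwell=dwell, **report)

    steady = bool(np.all(amps < th.steady_rel_amp * max(means.mean(), 1e-12)))
    order = np.argsort(means)[::-1]
    m = means[order]
    if steady:
        if m[1] > 0 and m[0] / m[1] >= th.dominance_ratio:
            return RegimeReport(label="differentiated", dominant=(int(order[0]),), **report)
        if len(m) > 2 and m[2] > 0 and m[1] / m[2] >= th.dominance_ratio:
            return RegimeReport(
                label="differentiated", dominant=tuple(sorted(map(int, order[:2]))), **report
            )
        if (means.max() - means.min()) <= th.multipotent_tol * means.mean():
            return RegimeReport(label="multipotent", **report)
    return RegimeReport(label="undetermined", **report)


def classify_windows(
    traj: Trajectory,
    n_windows: int = 8,
    thresholds: ClassifierThresholds | None = None,
) -> list[tuple[float, float, str]]:
    """Piecewise classification of a (possibly ramped) trajectory.

    Splits the horizon into ``n_windows`` equal windows and labels each one.
    Under a ramp the equilibria themselves drift with g(t), so the window
    rules work on the between-gene differences (common-mode removed):
    oscillatory when the differences swing with detected peaks, multipotent
    when the genes track each other closely, differentiated when one gene
    (or pair) steadily dominates.  Returns (t_start, t_end, label) triples
    in temporal order.
    """
    th = thresholds or ClassifierThresholds()
    edges = np.linspace(traj.t[0], traj.t[-1], n_windows + 1)
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        w = traj.window(a, b)
        if w.t.size < 8:
            continue
        means = w.x.mean(axis=0)
        grand = max(means.mean(), 1e-12)
        diffs = w.x - w.x.mean(axis=1, keepdims=True)
        damp = diffs.max(axis=0) - diffs.min(axis=0)
        lead = int(np.argmax(damp))
        if damp[lead] >= th.osc_rel_amp * grand and _peak_count(w.x[:, lead], damp[lead]) >= 2:
            label = "oscillatory"
        else:
            order = np.argsort(means)[::-1]
            m = means[order]
            if m[1] > 0 and m[0] / m[1] >= th.dominance_ratio:
                label = "differentiated"
            elif len(m) > 2 and m[2] > 0 and m[1] / m[2] >= th.dominance_ratio:
                label = "differentiated"
            elif (means.max() - means.min()) <= th.multipotent_tol * grand:
                label = "multipotent"
            else:
                label = "undetermined"
        out.append((float(a), float(b), label))
    return out


# ----------------------------------------------------------------------
def dwell_times(
    traj: Trajectory,
    gate: str | None = None,
    thresholds: ClassifierThresholds | None = None,
    transient_fraction: float | None = None,
) -> list[SubState]:
    """Partition the post-transient window into dominant sub-states.

    OR-gate identity is the argmax gene; AND-gate identity is the pair of
    genes above the co-expression threshold (operationally the top two).
    A challenger replaces the incumbent only after exceeding it by the
    relative hysteresis band, so no zero-duration states occur and exact
    ties resolve to the incumbent.
    """
    th = thresholds or ClassifierThresholds()
    tf = th.transient_fraction if transient_fraction is None else transient_fraction
    gate = gate or traj.spec.gate
    post = _post_transient(traj, tf)
    t, X = post.t, post.x
    if t.size < 3:
        return []
    k_dom = 2 if gate == "AND" else 1

    ident = _hysteresis_path(X, k_dom, th.hysteresis)
    states: list[SubState] = []
    start = 0
    for i in range(1, len(ident)):
        if ident[i] != ident[start]:
            states.append(SubState(genes=ident[start], t_entry=float(t[start]), t_exit=float(t[i])))
            start = i
    states.append(SubState(genes=ident[start], t_entry=float(t[start]), t_exit=float(t[-1])))
    if len(states) == 1:
        import warnings

        warnings.warn("no sub-state transitions detected in the analysis window")
    return states


def _hysteresis_path(X: np.ndarray, k: int, hyst: float) -> list[tuple[int, ...]]:
    """Sequence of dominant identities (size-k gene sets) with hysteresis."""
    current = list(np.argsort(X[0])[::-1][:k])
    path = [tuple(sorted(int(g) for g in current))]
    for row in X[1:]:
        # weakest incumbent may be displaced by the strongest outsider
        changed = True
        while changed:
            changed = False
            inc = min(current, key=lambda g: row[g])
            outsiders = [g for g in range(len(row)) if g not in current]
            if not outsiders:
                break
            challenger = max(outsiders, key=lambda g: row[g])
            if row[challenger] > row[inc] * (1.0 + hyst):
                current[current.index(inc)] = challenger
                changed = True
        path.append(tuple(sorted(int(g) for g in current)))
    return path


def _fractions(states: Sequence[SubState]) -> dict:
    total = sum(s.duration for s in states)
    if total <= 0:
        return {}
    acc: dict[tuple[int, ...], float] = {}
    for s in states:
        acc[s.genes] = acc.get(s.genes, 0.0) + s.duration
    return {k: v / total for k, v in sorted(acc.items())}


def dwell_fractions(
    traj: Trajectory,
    gate: str | None = None,
    thresholds: ClassifierThresholds | None = None,
    transient_fraction: float | None = None,
) -> dict:
    """Fraction of post-transient time spent in each sub-state; sums to 1."""
    return _fractions(dwell_times(traj, gate=gate, thresholds=thresholds, transient_fraction=transient_fraction))


def dwell_table(states: Sequence[SubState]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "substate": ["+".join(map(str, s.genes)) for s in states],
            "t_entry": [s.t_entry for s in states],
            "t_exit": [s.t_exit for s in states],
            "duration": [s.duration for s in states],
        }
    )


def cycle_order(states: Sequence[SubState]) -> list[tuple[int, ...]]:
    """The repeating sequence of sub-state identities, starting from the
    first visited; empty if the visit sequence is not periodic."""
    seq = [states[0].genes] if states else []
    for s in states[1:]:
        if s.genes != seq[-1]:
            seq.append(s.genes)
    uniq = list(dict.fromkeys(seq))
    k = len(uniq)
    if k < 2 or len(seq) < 2 * k:
        return uniq
    # verify the sequence actually repeats with period k
    for i in range(len(seq) - k):
        if seq[i + k] != seq[i]:
            return []
    return seq[:k]


def period(
    traj: Trajectory,
    gene: int = 0,
    thresholds: ClassifierThresholds | None = None,
    transient_fraction: float | None = None,
) -> float:
    """Median peak-to-peak interval of one gene's post-transient trace.

    Raises :class:`PeriodError` when fewer than ``min_peaks`` peaks exist
    (non-oscillatory input has no defined period).
    """
    th = thresholds or ClassifierThresholds()
    tf = th.transient_fraction if transient_fraction is None else transient_fraction
    post = _post_transient(traj, tf)
    y = post.x[:, gene]
    amp = y.max() - y.min()
    if amp <= 0 or amp / max(y.mean(), 1e-12) < th.osc_rel_amp:
        raise PeriodError("trajectory is not oscillatory on the requested gene")
    peaks, _ = find_peaks(y, prominence=0.1 * amp)
    if len(peaks) < th.min_peaks:
        raise PeriodError(f"only {len(peaks)} peaks detected; period undefined")
    return float(np.median(np.diff(post.t[peaks])))
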