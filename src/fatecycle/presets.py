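"""Named, versioned parameter presets.

The model family is qualitative -- what matters is which regimes a circuit
can express and in what order they appear as the global coupling g grows.
These presets pin down one concrete, well-characterised parameter point per
circuit variant so that demonstrations, experiments and tests all speak
about the same objects.  All share the default kinetics

    alpha0 = 0.05, beta = 10, h = 3, delta = 1  (per gene)

chosen so that expression levels are O(1)-O(10), time is measured in
protein lifetimes, and the oscillatory window sits at sub-unity couplings.
A cooperativity of h = 3 is the smallest integer Hill exponent that lets a
protein-only repression loop oscillate at all: the off-diagonal Jacobian
gain of the saturating repression term is bounded by h divided by the
repressor count, so h = 2 can never overcome unit degradation (see
docs/methods.md).

Directional asymmetry is likewise essential, not decorative: with exactly
equal clockwise and anticlockwise strengths the Jacobian at the symmetric
state is symmetric, its eigenvalues real, and the circuit pitchforks
straight from multipotent to differentiated with no oscillatory regime in
between.  The double-repressilator presets therefore use a weak
anticlockwise coupling (0.1-0.2 of the clockwise strength), which preserves
cyclic symmetry -- sub-states remain equally weighted -- while opening a
wide oscillatory window.

Each preset records the coupling values at which it shows its regimes
(``g_*`` attributes), determined by ``find_boundaries`` and used as
defaults by the experiment layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import CouplingSchedule, NetworkSpec

__all__ = ["Preset", "get_preset", "preset_names", "PRESET_VERSION"]

PRESET_VERSION = "1"


@dataclass(frozen=True)
class Preset:
    name: str
    spec: NetworkSpec
    g_multipotent: float
    g_oscillatory: float
    g_differentiated: float | None
    g_scan: tuple[float, float]
    description: str

    def ramp(self, n_periods_factor: float = 1.0, period_estimate: float = 12.0) -> CouplingSchedule:
        """A slow linear ramp spanning the full regime sequence.

        The default duration gives >= 20 oscillation periods inside the
        window (scaled by ``n_periods_factor``).
        """
        g_hi = self.g_differentiated if self.g_differentiated is not None else self.g_scan[1]
        # the oscillatory window occupies roughly half the ramped g range,
        # so 40 periods of total duration give >= 20 inside the window
        t_end = max(40.0 * period_estimate * n_periods_factor, 100.0)
        return CouplingSchedule(
            kind="linear_ramp",
            g_start=self.g_multipotent,
            g_end=1.3 * g_hi,
            t_start=0.0,
            t_end=t_end,
        )


def _make_presets() -> dict[str, Preset]:
    presets = {}

    presets["repressilator"] = Preset(
        name="repressilator",
        spec=NetworkSpec(n_genes=3, topology="cyclic", gate="OR", coupling_forward=1.0,
                         coupling_reverse=0.0),
        g_multipotent=0.01,
        g_oscillatory=1.0,
        g_differentiated=None,  # no fate-specialised equilibria exist
        g_scan=(0.005, 30.0),
        description=(
            "Classic three-gene repression ring. Oscillates for all couplings above "
            "onset; has no fate-specialised equilibria, so it can model cycling but "
            "not differentiation."
        ),
    )

    presets["double-or"] = Preset(
        name="double-or",
        spec=NetworkSpec(n_genes=3, topology="all_pairs", gate="OR",
                         coupling_forward=1.0, coupling_reverse=0.1),
        g_multipotent=0.03,
        g_oscillatory=0.15,
        g_differentiated=0.5,
        g_scan=(0.01, 1.0),
        description=(
            "Three-gene double repressilator, OR gate, anticlockwise strength 0.1. "
            "Multipotent below g~0.055, oscillatory with three singleton sub-states "
            "up to g~0.37, winner-take-all differentiation above."
        ),
    )

    biased = NetworkSpec(
        n_genes=3, topology="all_pairs", gate="OR",
        coupling_forward=np.array([2.0, 1.0, 1.0]),
        coupling_reverse=np.array([0.2, 0.1, 0.1]),
    )
    presets["double-or-biased"] = Preset(
        name="double-or-biased",
        spec=biased,
        g_multipotent=0.02,
        g_oscillatory=0.1,
        g_differentiated=0.3,
        g_scan=(0.01, 1.0),
        description=(
            "double-or with both repression edges into gene 0 doubled (2:1 edge "
            "asymmetry). Cycling persists but dwell is biased: gene 0's sub-state "
            "shrinks and its cycle predecessor's grows."
        ),
    )

    presets["double-and"] = Preset(
        name="double-and",
        spec=NetworkSpec(n_genes=3, topology="all_pairs", gate="AND",
                         coupling_forward=1.0, coupling_reverse=1.0,
                         hill_reverse=1.5),
        g_multipotent=3e-4,
        g_oscillatory=3e-3,
        g_differentiated=None,
        g_scan=(3e-5, 0.3),
        description=(
            "Three-gene double repressilator with AND-gate repression (both other "
            "genes must be high). Oscillates between the three two-gene co-expressed "
            "sub-states; differentiated states co-express a pair. Couplings are small "
            "because AND repression scales with the product of two levels."
        ),
    )

    presets["ring5-or"] = Preset(
        name="ring5-or",
        spec=NetworkSpec(n_genes=5, topology="ring_neighbors", gate="OR",
                         coupling_forward=1.0, coupling_reverse=0.2),
        g_multipotent=0.005,
        g_oscillatory=0.03,
        g_differentiated=0.1,
        g_scan=(0.002, 1.0),
        description=(
            "Five genes with nearest-neighbour repression only. Oscillates (odd ring); "
            "at high coupling settles to a two-high pattern of non-adjacent genes."
        ),
    )

    presets["ring4-or"] = Preset(
        name="ring4-or",
        spec=NetworkSpec(n_genes=4, topology="ring_neighbors", gate="OR",
                         coupling_forward=1.0, coupling_reverse=0.2),
        g_multipotent=0.005,
        g_oscillatory=0.05,  # nominal; this even ring never oscillates
        g_differentiated=1.0,
        g_scan=(0.002, 3.0),
        description=(
            "Four genes with nearest-neighbour repression. The even ring admits an "
            "alternating two-high pattern and shows no oscillatory regime."
        ),
    )

    presets["square4-or"] = Preset(
        name="square4-or",
        spec=NetworkSpec(n_genes=4, topology="all_pairs", gate="OR",
                         coupling_forward=1.0, coupling_reverse=0.2,
                         coupling_extra=1.5),
        g_multipotent=0.01,
        g_oscillatory=0.05,
        g_differentiated=0.3,
        g_scan=(0.005, 1.0),
        description=(
            "Four genes, all-pairs repression with strong diagonal (opposite-gene) "
            "coupling 1.5. The diagonal edges restore oscillation, which the even "
            "nearest-neighbour ring lacks."
        ),
    )

    presets["ring5-and"] = Preset(
        name="ring5-and",
        spec=NetworkSpec(n_genes=5, topology="ring_neighbors", gate="AND",
                         coupling_forward=1.0, coupling_reverse=1.0,
                         hill_reverse=1.5),
        g_multipotent=3e-5,
        g_oscillatory=1e-3,
        g_differentiated=None,
        g_scan=(1e-5, 0.1),
        description=(
            "Five-gene nearest-neighbour ring with AND-gate repression. Oscillates "
            "between two-gene co-expressed sub-states whose members are non-adjacent "
            "on the ring."
        ),
    )

    presets["pentad-or"] = Preset(
        name="pentad-or",
        spec=NetworkSpec(n_genes=5, topology="all_pairs", gate="OR",
                         coupling_forward=1.0, coupling_reverse=0.1,
                         coupling_extra={2: 0.05, 3: 0.3}),
        g_multipotent=0.002,
        g_oscillatory=0.15,
        g_differentiated=6.0,
        g_scan=(0.001, 10.0),
        description=(
            "Five-gene all-pairs network with graded long-range strengths, the "
            "standard context for knockout experiments: the wild type cycles through "
            "five singleton sub-states, and the four-gene circuit left by a null "
            "allele still cycles instead of freezing."
        ),
    )

    return presets


_PRESETS = _make_presets()


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def get_preset(name: str) -> Preset:
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}") from None
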