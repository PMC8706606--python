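# fatecycle

Deterministic simulation of **cyclical fate restriction** in
mutual-repression gene-regulatory circuits.

Multipotent progenitor cells (the motivating system is the neural crest and
its pigment-cell and neural derivatives) often express low levels of *many*
fate-specific transcription factors at once, yet snapshots catch individual
cells apparently biased towards one fate or another. One parsimonious
explanation is dynamic: the fate-determining transcription factors mutually
repress each other, and as the overall repression strength rises — for
example under accumulating environmental signals — the circuit passes from
a **multipotent** equilibrium (all factors co-expressed), through an
**oscillatory** regime in which the cell cycles through transient
fate-*biased* sub-states, to stable **differentiated** states in which a
single factor (or a combinatorial pair) dominates. `fatecycle` implements
this model family and the in-silico experiments that probe its predictions:
coupling ramps, fate-specific signals, gene knockouts, and network-topology
scans.

## The model

Each of N genes follows a nondimensionalised Hill-repression ODE. With OR
gating (any high repressor silences its target),

$$\dot x_i \;=\; \kappa_i\Bigl(\alpha_0 + \frac{\beta}{1 + g(t)\sum_{j}
W_{ij}\,x_j^{\,h}}\Bigr) \;-\; \delta\, x_i \;+\; s_i(t),$$

and with AND gating (repression requires *all* inputs high) the repressor
terms multiply inside a single saturating term,
$1 + g(t)\,\bar w_i \prod_j x_j^{H_{ij}}$. Here `W` holds the relative
edge strengths on the ring (clockwise / anticlockwise / longer-range),
`g(t)` is the global coupling schedule — the control parameter of the whole
theory — `κ_i ∈ {0,1}` implements null-allele knockouts, and `s_i(t)` is an
additive fate-specific signal. Time is measured in protein lifetimes
(δ = 1); the default kinetics are α₀ = 0.05, β = 10, h = 3.

The `bifurcation` module locates the regime boundaries in g (eigenvalues of
the circulant Jacobian for the lower boundary, a standardised probe
simulation for the upper one), `regimes` classifies trajectories and
measures sub-state dwell times, and `experiments` runs seeded,
bit-reproducible ensembles.

## Worked example

```python
import numpy as np
from fatecycle import (get_preset, find_boundaries, ramp_ensemble,
                       knockout_experiment)

p = get_preset("double-or")            # 3 genes, all-pairs repression, OR
b = find_boundaries(p.spec, p.g_scan)
print(f"oscillatory window: g in [{b.g_lower:.3f}, {b.g_upper:.3f}]")

ens = ramp_ensemble(p.spec, p.ramp(), n_runs=300, seed=2024, boundaries=b)
print("fate proportions:", {k[0]: round(v, 3) for k, v in ens.proportions.items()})
print("predictor agreement:", ens.predictor_agreement)

ko = knockout_experiment(get_preset("pentad-or").spec, gene=1,
                         context="dwell", g=0.15, seed=8)
print("preceding sub-state dwell, wild type vs mutant:",
      round(ko.wt_dwell[ko.preceding], 3), "->",
      round(ko.mut_dwell[ko.preceding], 3))
```

prints

```
oscillatory window: g in [0.054, 0.369]
fate proportions: {1: 0.31, 2: 0.397, 0: 0.293}
predictor agreement: 0.9866666666666667
preceding sub-state dwell, wild type vs mutant: 0.205 -> 0.724
```

Reading: below g ≈ 0.054 the circuit rests in the multipotent equilibrium
and above g ≈ 0.369 a slow ramp locks into one winner-take-all fate; the
300-run ensemble distributes fates evenly across the three genes (cyclic
symmetry), and the gene dominating when the ramp clears the upper boundary
is the fate actually adopted. Knocking out one gene of the five-gene
network roughly triples the time the mutant lingers in the sub-state that
precedes the missing gene's — while cycling continues through the remaining
sub-states rather than freezing.

A command-line interface wraps the same operations
(`fatecycle simulate --preset double-or`, `fatecycle boundaries`,
`fatecycle ramp-ensemble`, `fatecycle knockout`, `fatecycle topology-scan`,
`fatecycle signal-exit`); every run writes a manifest with the resolved
configuration, seed and package version next to its outputs.

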