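# Methods

## Model

`fatecycle` simulates N fate-determining transcription factors that
mutually repress one another on a ring. The state is the vector of
dimensionless expression levels x ∈ R₊ᴺ and the dynamics are protein-only
ordinary differential equations — no transcription/translation split, no
delays, no stochasticity (a chemical-Langevin or Gillespie layer would be a
natural extension but is deliberately out of scope, since every claim the
package tests is about deterministic response modes).

For OR gating, gene i obeys

    dx_i/dt = kappa_i * ( alpha0 + beta / (1 + g(t) * sum_j W_ij x_j^h) )
              - delta * x_i + s_i(t)

where `W_ij >= 0` is the relative strength of the repression edge j -> i,
organised by lag on the ring ((i-j) mod N: lag 1 is the clockwise
neighbour, lag N-1 the anticlockwise neighbour, other lags are
longer-range), `g(t) >= 0` is the global coupling schedule that scales all
repression simultaneously, `kappa_i ∈ {0,1}` silences production for
null-allele knockouts, and `s_i(t)` is an additive fate-specific signal.
For AND gating the repressor inputs multiply inside one saturating term,
`1 + g(t) * wbar_i * prod_j x_j^{H_ij}`, with `wbar_i` the geometric mean
of the nonzero strengths into gene i, so a single silent repressor
abolishes repression (true AND semantics).

Units: time is measured in protein lifetimes (delta = 1 by default);
expression levels are scaled so the uncoupled steady state is
alpha0 + beta. Calibration to wall-clock minutes is intentionally not
attempted; only the time-unit convention is fixed.

## Parameters and defaults, and why they are what they are

| parameter | default | meaning |
|---|---|---|
| alpha0 | 0.05 | basal (leaky) production, per gene |
| beta | 10 | maximal production |
| delta | 1 | first-order decay; sets the time unit |
| h | 3 | Hill cooperativity of repression |
| h_rev (AND only) | h/2 | cooperativity of the anticlockwise AND input |
| forward strength | 1 | clockwise (lag-1) edge weight |
| reverse strength | 0.1–0.2 | anticlockwise (lag-(N-1)) edge weight |
| g(t) | schedule | global coupling, the control parameter |

Two of these defaults are forced by the mathematics rather than chosen for
convenience, and that is worth recording:

**Cooperativity h = 3.** For the saturating repression term used here, the
off-diagonal Jacobian gain at the symmetric equilibrium is bounded by
(h/m) · u/(1+u) · (x−alpha0)/x < h/m, where m is the number of repressors
per gene and u the total repression in the denominator. Instability of the
symmetric state requires this gain (times a topology factor ≤ 1) to exceed
delta, so h = 2 can never destabilise a protein-only repression ring with
unit degradation: there would be no oscillatory regime at all. h = 3 is
the smallest integer cooperativity that opens one.

**Directional asymmetry.** With exactly equal clockwise and anticlockwise
strengths the Jacobian at the symmetric state of the all-pairs circuit is a
symmetric matrix; its eigenvalues are real, the instability is a pitchfork,
and the circuit falls straight from multipotency into a winner-take-all
state — no oscillatory regime in between. (For the AND gate the argument
is stronger: the geometric-mean form makes the dynamics invariant under
*all* gene permutations, so no parameter choice of that form oscillates.)
A weak anticlockwise coupling — reverse/forward = 0.1 by default — makes
the relevant eigenvalue pair complex (a Hopf scenario) while preserving
cyclic symmetry, so the three sub-states remain exactly equivalent; it also
pushes the winner-take-all branch to higher coupling, which widens the
oscillatory window. For AND gates the same symmetry is broken through the
exponents instead (forward input h, anticlockwise input h_rev = h/2),
because any product-form gate has direction-independent gains at the
symmetric point whatever its strengths. Setting h_rev = h recovers the
direction-symmetric gate for comparison.

Presets (`fatecycle.presets`) pin one characterised parameter point per
circuit variant — classic repressilator, symmetric and biased double
repressilator, AND-gate variants, even/odd rings, and a five-gene
"pentad" with graded long-range strengths (lag-2: 0.05, lag-3: 0.3,
lag-4: 0.1) whose four-gene knockout remnant still oscillates, making it
the standard context for knockout experiments. Preset coupling values are
the `g_*` attributes; all were verified against `find_boundaries`.

## Regime classification

At constant coupling a trajectory is classified from its post-transient
half (`transient_fraction = 0.5`):

- **oscillatory** — some gene's amplitude ≥ 5% of its mean, with ≥ 3
  detected peaks (scipy `find_peaks`, prominence 10% of amplitude);
- **multipotent** — steady (every amplitude < 0.1% of the grand mean
  level) and all means within 5% of the grand mean;
- **differentiated** — steady with dominance ratio top/second ≥ 3
  (or second/third ≥ 3 for a co-dominant pair, the AND-gate and even-ring
  outcome);
- **undetermined** — anything inside the hysteresis band between those
  rules. Undetermined is returned, never guessed away.

Steadiness is judged against the *grand mean* level rather than each
gene's own mean so that picometre-scale drift on a silenced gene does not
veto an otherwise differentiated state. Sub-state identity uses argmax
(top-2 for AND) with a 2% relative hysteresis band and incumbent-wins tie
breaking, which guarantees no zero-duration sub-states and a stable cyclic
order; dwell fractions are durations over the analysed window and sum to 1
by construction. The period is the median peak-to-peak interval of one
gene (cross-gene agreement within 1% for symmetric circuits is enforced in
the tests). Ramped trajectories are refused by `classify` and handled by
`classify_windows`, which works on between-gene differences (common-mode
removed) because the equilibria themselves drift with g(t).

## Regime boundaries

`g_lower` is found by a bracketed root find on the leading eigenvalue of
the analytic Jacobian along the symmetric branch (the symmetric equilibrium
itself is the unique root of a monotone scalar fixed-point equation, found
by `brentq` to 1e-14). `g_upper` is defined *operationally*: a
standardised probe run (fixed-seed 1% perturbation of the symmetric state,
horizon 600) is classified at each coupling and the
oscillatory-to-differentiated transition is bisected to relative width
1e-3.

The operational definition is a deliberate choice. In this model family
the fate-specialised equilibria become stable far below the oscillation
window's end, so "stable winner-take-all appears" would put the upper
boundary *below* the lower one. What actually ends the oscillatory regime
as g rises is the limit cycle's loss of the ability to hold a trajectory;
near that point the period grows steeply (the cycle passes close to the
saddle points that are the differentiated states — the sub-states *are*
the neighbourhoods of those saddles). The coupling at which a stable
specialised equilibrium first exists is computed independently (full
fixed-point solve from the high/low ansatz, residual < 1e-10, analytic
eigenvalues) and reported as `specialised_stable_from`, so the bistable
overlap is visible rather than suppressed. The classic repressilator has
no specialised equilibria at any coupling and its `g_upper` is reported as
absent.

Consequence for ramp experiments: a ramped trajectory can express the
boundary crossing only with the resolution of one oscillation period, so
the fate-predictor state is sampled one boundary-period after g(t) first
exceeds `g_upper`. Sampling at the bare crossing instant lands,
deterministically, mid-escape — the adopted fate is then systematically the
*next* sub-state in cycle order, at every ramp speed tested. Both the
sampling time and the boundary period are recorded in the ensemble
metadata.

## Experiments

All ensembles draw per-run streams from `numpy.random.SeedSequence(seed)`,
so results are bit-reproducible and independent of execution order;
wild-type/mutant comparisons reuse identical initial conditions (paired
design). Fate proportions carry exact (Clopper-Pearson) binomial
intervals; uniformity tests use chi-square at alpha = 0.01. Runs that do
not differentiate are counted as their own category, not dropped.

- **Ramp ensembles** start from seeded 1% perturbations of the symmetric
  state and ramp g linearly across the window; the default ramp length
  gives ≥ 20 oscillation periods inside the window. Commitment time is the
  first moment the dominance ratio ≥ 3 is sustained for ≥ 5% of the
  horizon.
- **Signal exit** verifies the system oscillates at the chosen g, samples
  initial states across one full period, then brackets (doubling + 6
  bisection steps) the smallest sustained production boost that commits
  *every* phase to the targeted fate; the verification at 1.05x the
  bracket top uses 50 phases.
- **Knockouts** are null alleles (production zeroed; edges untouched — the
  mutant's repressive output dies dynamically as its level decays). The
  "preceding" sub-state is read off the *measured* wild-type cycling
  order, never assumed from edge direction. A mutant that stops cycling is
  reported as a regime change. Which sub-state gains dwell under a given
  asymmetry pattern, and the mutant's cycling order, are likewise measured
  outputs, not assumptions.
- **Topology scans** probe each (N, topology) cell over a geometric g grid
  with two seeded starts per point; absence of oscillation is a result.

## Numerical choices

Integration uses scipy `solve_ivp` (LSODA, stiff-capable) at rtol 1e-8 /
atol 1e-10 for single trajectories and rtol 1e-7 / atol 1e-9 for
ensembles; halving tolerances changes trajectories by < 1e-5 relative
(tested). Reporting grids are 2000–5000 points from the solver's dense
interpolation, with the denser grids used for dwell analysis to avoid
aliasing. Levels are clipped at zero when sampling the Hill terms;
negative excursions beyond 1e-9 are clamped and logged. `x^h` is guarded
against overflow by clipping the base far above the dynamical bound
(alpha0 + beta + s)/delta. Exactly symmetric states are dynamically
invariant, so demonstration and ensemble runs always start from seeded
multiplicative perturbations (scale 0.01) of the symmetric equilibrium.

Problem sizes used by the shipped analyses: 300-run ramp ensembles for
fate statistics, 150-run paired ensembles for knockout ramps, 50-phase
signal verification, 50 random circuits for Jacobian validation, horizons
of 400–2000 time units depending on the period of the circuit concerned.

## What the experiments do and do not show

The simulated conditions are idealised: every cell is the same circuit,
initial heterogeneity is a small symmetric perturbation, the coupling ramp
is spatially uniform, and there is no intrinsic noise, cell division,
migration or niche geometry. Passing tests therefore demonstrate that the
*circuit logic* can produce the claimed phenomenology — a multipotent →
oscillatory → differentiated progression, equally- or biased-weighted
sub-states, combinatorial co-expression under AND gating, knockout
lingering with continued cycling, and signal-selectable fates — not that
real progenitor populations realise these dynamics or these parameter
values. Timescale calibration, stochastic effects (which would blur the
sharp fate-predictor agreement and dwell fractions), and spatial signal
fields are all outside the model.

## Known limitations

- The upper boundary is protocol-dependent by design (probe horizon and
  perturbation scale are part of its definition and are recorded in the
  method metadata); near-boundary classifications are only meaningful at
  the 1e-3 relative bracket width reported.
- No limit-cycle continuation or Floquet analysis: periods and dwell times
  are empirical, and the Hopf character of the lower boundary is assumed
  from the complex eigenvalue pair, not proven.
- The AND gate needs unequal directional cooperativity to cycle; the
  direction-symmetric AND gate (h_rev = h) is expressible but goes
  straight to a co-dominant pair equilibrium.
- For strongly asymmetric (non-circulant) networks `solve_symmetric` has
  no exact meaning; the row-averaged surrogate is used only to seed
  initial conditions.
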