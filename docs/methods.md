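# Methods

This note records the model, the estimators, the numerical choices, and the
known limitations of the package, in enough detail that results can be
interpreted (and distrusted) correctly.

## Network construction

Regions are placed on a unit-spaced `√z × √z` lattice, indexed left to
right, top down; the origin is the top-left corner, `x` increases rightward
and `y` downward. `σ` is expressed in lattice units.

Within a region, the graph is a classic Watts–Strogatz small world: a ring
lattice in which every node is joined to its `k_ring = round_even(c·(m−1))`
nearest neighbours (`c = 0.1`, `m = 100` gives `k_ring = 10`, i.e. exactly
1000 directed edges per region after reciprocal expansion, density
`k_ring/m = 0.1`), followed by random rewiring of each undirected edge with
probability `p`, rejection-resampling collisions. Rewiring conserves the
edge count exactly. The undirected graph is expanded to reciprocal directed
edges because strengths are defined per incoming connection. The generator
delegates to `networkx.watts_strogatz_graph`, whose rewiring dialect matches
this description.

Between regions, every *ordered* cross-region neuron pair is sampled
independently with the exponential-distance-rule probability evaluated at
the two regions' coordinates. Sampling ordered pairs (rather than sampling
unordered pairs and symmetrizing) is the reading consistent with the
directed, incoming-strength definition of the connectivity matrix; it is
exposed as the only sampling mode.

Strengths: `1/m` for within-region edges; `1/N_in(i)` for inter-regional
edges into neuron `i`, where `N_in(i)` counts *all* of `i`'s in-edges,
local and inter-regional. The macroscale matrix `R` keeps its diagonal
(within-region block sums, `R_ii = k_ring·m/m = 10` at the defaults).

## Spiking dynamics

The membrane equation integrated is

    dv_i/dt = −(v_i − V_R)/τ − G_i(t)·(v_i − V_E),
    G_i(t) = f_i·g_E,i(t) + g_rec · Σ_k A_ik g_S,k(t),

with `V_R = 0`, `V_T = 1`, `V_E = 3`, `τ = 20 ms`. All conductances are in
units of 1/ms, alongside the leak conductance `1/τ = 0.05/ms`; kernels are
unit-area alpha functions (`τ_E = 2.728 ms` external, `τ_S = 1 ms`
recurrent). Excitatory input therefore *depolarizes* (drives `v` toward
`V_E`); a `literal_sign` flag flips the conductance sign to the
hyperpolarizing variant for comparison runs.

Two scale conventions deserve explicit statement, because the
nondimensionalized form of the equation underdetermines them:

- **External drive.** With `f_E = 0.1` and `ν_E = 500/s`, the mean external
  conductance is `f_E·ν_E = 0.05/ms` — exactly the leak conductance. This
  is the only scaling under which the stated parameters produce the model's
  intended operating point: an isolated neuron fires at a moderate rate
  (≈ 90 Hz) with irregular, fluctuation-sensitive interspike intervals
  (ISI CV ≈ 0.55). Scaling the external conductance down by a further
  1/τ leaves the neuron ≈ 39 standard deviations below threshold and
  permanently silent.
- **Recurrent drive** enters through `g_rec` (default 1.0): a presynaptic
  spike across an edge of strength `A_ik` contributes a unit-area alpha
  conductance transient of total size `g_rec·A_ik`, on the same scale as
  the external synapses.

A consequence of the default recurrent scale is worth knowing before
running sweeps. The synaptic-scaling rule makes each neuron's total
in-strength approach ≈ 1 as inter-regional connectivity densifies, and a
purely excitatory network with leak-scale total coupling loses its
stationary asynchronous state: the self-consistency condition
`r = F(g_ext + β·g_rec·r)` for the population rate `r` (with `β` the total
in-strength and `F` the single-neuron rate function, slope ≈ 2.5 spikes per
unit conductance·ms near the operating point) has no solution once
`β·g_rec ≳ 0.4`. At `ρ = 0.9` this threshold is crossed near `σ ≈ 0.35`:
the network transitions from asynchronous irregular firing to a
synchronous, high-firing regime in which every neuron fires as fast as the
integration step allows (the rate is bounded by `1/dt`, since at most one
spike per neuron is emitted per step). There is no mechanism in the base
model — no refractory period, no inhibition, no delays — to arrest this
recruitment, so the high-`σ` regime should be read qualitatively (densely
coupled ⇒ synchronized, high-rate) rather than quantitatively. The
transition itself, not the saturated rate, is the scientifically meaningful
object.

### Integration scheme

Fixed step `dt = 0.1 ms` (default). Each alpha-kernel class is realized as
two linear filter states per neuron (`dh/dt = −h/τ_x + impulses/τ_x`,
`dg/dt = −g/τ_x + h/τ_x`), advanced with the exact exponential propagator
in two half-steps per step; the voltage is advanced with the closed-form
solution of the linear ODE holding the conductance at its mid-step value
(second-order accurate). Threshold crossings within a step are located by
linear interpolation; the membrane resets to `V_R` at the crossing and is
integrated for the remainder of the step, so recorded voltages remain
informative in high-rate regimes. Recurrent impulses reach postsynaptic
filters at the next step boundary, *pre-aged* by the lag between the
interpolated firing time and the boundary — the kernel is anchored at the
true firing time, which keeps self-convergence under `dt`-halving at the
integrator's order. External Poisson events are drawn per step
(`rate·dt` counts per neuron); frozen event lists are binned to the nearest
step boundary. Spike-time trajectories through long chains of crossings are
chaotic in the usual way (near-grazing crossings amplify perturbations), so
convergence statements hold for short horizons, not for entire long runs.

Defaults: `duration = 4000 ms`, `transient = 500 ms` (discarded before any
statistic), `record_dt = 1 ms`. Region weights `w_g ~ U[0.8, 1.2]` are
drawn once per simulation from the simulation seed.

## Complexity estimators

All information quantities are in nats (natural logarithm), using the
Gaussian forms throughout.

- `gaussian_entropy`: `0.5·ln[(2πe)^d |Σ|]` via `slogdet`; inputs are
  validated symmetric (1e−10 relative) and positive definite, with the
  offending eigenvalue reported otherwise.
- `integration_gaussian`: `0.5(Σ ln var_i − ln|Σ|) ≥ 0`.
- `neural_complexity_exact`: direct enumeration of all principal
  submatrices, hard-capped at `d = 20` (the `z = 9` use case costs 510
  determinants). A second, independently coded route via per-subset
  integrations is kept for cross-checking the two printed forms of the
  definition; they agree to 1e−10 on random SPD inputs.
- `structural_complexity`: the second-order weak-coupling expansion
  `C* + C**`, computed with matrix-product identities (`Σ_{i≠j}` and
  `Σ_{i≠j≠k}` realized through a zero-diagonal copy of `W`, which makes
  coincident-index terms vanish identically); validated against an explicit
  triple loop. The `(d+1)` prefactors use the dimension of the matrix
  passed in — `z` when applied to the macroscale matrix.
- `ou_stationary_covariance`: solves the continuous Lyapunov equation
  `(W−I)Σ + Σ(W−I)ᵀ + s²I = 0` (unit isotropic noise by default) after
  verifying the drift is stable. Channel-standardizing this covariance and
  applying the exact complexity reproduces `C* + C**` up to a residual that
  scales as the fourth power of the coupling scale (log–log slope ≈ 4
  measured over ε ∈ [0.025, 0.2]); this is the oracle that justifies the
  structural approximation.
- `dynamical_complexity`: exact complexity of the sample covariance
  (denominator N−1) of the `z` region-averaged voltage series, post
  transient — subsets of *regions*, hence 2^z work. Degenerate inputs
  (identical traces) raise; an optional ridge (`1e−10·trace/z`) is off by
  default.

**Input to structural complexity in the pipeline:** the per-neuron-scaled
macroscale matrix `R/m`, diagonal retained. Raw `R` entries (diagonal 10)
violate the weak-coupling premise of the expansion; dividing by `m` brings
entries to O(0.01–0.3), inside its domain of validity. This scaling is a
package decision, exposed as `macroscale_matrix(conn, "per_neuron")` vs
`"raw"`; strength statistics (variance, order-of-magnitude span, in-edge
counts) are computed on raw `R`, whose off-diagonal statistics they
describe. The span `log10(max/min)` is scale-invariant.

## Synchrony, ISI, and macroscale statistics

- Synchrony is the ratio of the variance of the channel-mean series to the
  mean per-channel variance; variances are population-form time averages
  (denominator N). The same operator serves neuron-level `ω` and
  region-level `Ω`; values lie in [0, 1], 1 for identical channels, ≈ 1/n
  for independent ones. Recorded samples at `record_dt` stand in for
  continuous time. The measure is blind to synchrony faster than the
  sampling interval: in the saturated lockstep regime the sampled voltages
  are nearly constant and `Ω` stays near 1/z.
- ISIs are pooled across all neurons of the whole network; moments are the
  population central-moment estimators exactly as defined (no bias
  correction); kurtosis is non-excess (Gaussian → 3). Variance requires 2
  intervals; skewness/kurtosis are reported only from 20 intervals up.
- Macroscale strength statistics use off-diagonal entries of `R` only
  (within-region blocks are not "inter-regional"); the order-of-magnitude
  span uses nonzero entries and is reported as 0 with a flag when no
  off-diagonal edge exists; a region receives an in-edge from another iff
  the corresponding `R` entry is nonzero.

## Sweeps and seeding

Structural sweeps cover `ρ ∈ {0.1, …, 0.9}` (step 0.1) and
`σ ∈ {0.1, …, 1.0}` (step 0.05) with 10 replicates by default; these grid
ranges are package choices anchored to the reference parameter examples
(`ρ = 0.9`, `σ ∈ {0.2, 0.35, 0.5}`), chosen to bracket the uncoupled and
densely coupled limits. Dynamics sweeps default to the coarse transect
`σ ∈ {0.2, 0.35, 0.5, 0.65, 0.8}` so a 5-replicate ensemble at 4 s per
simulation stays desk-scale (minutes, not hours).

Per-cell randomness derives from
`SeedSequence(base_seed, spawn_key=(ρ-index, σ-index, replicate))`, split
into independent connectome and simulation streams — cells are reproducible
in isolation and independent of execution order. Identical seeds give
bit-identical tables.

`locate_optimum` breaks ties toward smaller `σ`, then smaller `ρ`.

## What the generator does and does not emulate

The synthetic network emulates: spatial decay of inter-regional connection
probability, sparse small-world local circuitry, synaptic-scaling strength
normalization, regionally heterogeneous external drive. It does not
emulate: inhibitory populations, synaptic delays, refractory dynamics,
distance dependence *within* regions, non-square lattices, or any empirical
connectome. Consequently, passing tests demonstrate internal consistency of
the model and its estimators — e.g. that strength heterogeneity spanning
three-plus orders of magnitude *emerges* from distance dependence at
intermediate σ — not agreement with any particular biological dataset.

## Known limitations

- The excitatory-only network has no stable asynchronous state beyond the
  coupling threshold described above; quantities measured in the saturated
  regime (rates near 1/dt, near-zero ISI variance, `Ω` insensitive to
  lockstep synchrony at the sampling interval) characterize the integrator's
  bounded version of a divergent ODE system, and are flagged as such.
- Pooled ISI variance is dominated by the slow, irregular firing of weakly
  coupled networks; it *decreases* monotonically along the coupling
  transect rather than peaking at intermediate σ, because the model passes
  directly from asynchronous to saturated with no intermittent-burst
  regime in between.
- Exact complexity is exponential in the channel count (capped at 20);
  dynamical complexity inherits the Gaussianity assumption and is computed
  on sampled, time-averaged voltages.
- The OU oracle uses unit isotropic noise; channel standardization absorbs
  the noise scale, but anisotropic noise is not modelled.
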