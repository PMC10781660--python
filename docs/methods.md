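# Methods

## Model

A simulation space is an undirected graph over lattice sites. Two
neighborhood orders are carried separately because they answer different
questions:

- **connectivity** (default von Neumann; 6-neighborhood in 3D) defines what
  a *connected cell* is — it drives the fragmentation guard and division;
- **interaction** (default Moore; 26-neighborhood in 3D) defines which site
  pairs enter the adhesion sum and the perimeter count.

Whenever the interaction order contains the connectivity order (the default),
interaction adjacency is a superset of connectivity adjacency. Periodic
boundaries are edges joining opposite faces; mask-derived domains are always
closed (the mask geometry *is* the domain, nothing wraps). Coordinates are
0-based row-major and node id = linear index, so grids round-trip exactly
through array export.

State is one integer per site (0 = medium) plus a cell table (type, target
volume, optional target perimeter, arbitrary numeric custom properties).
Cached per-cell volume and perimeter are maintained incrementally by the
engine and are contractually identical to their from-scratch definitions at
all times (the suite recomputes them at checkpoints).

## Dynamics

One Monte Carlo step (MCS) = `flips_per_mcs` flip attempts (default: the
node count). A proposal is drawn uniformly over *directed heterotypic
connectivity pairs* — equivalently, a uniform random boundary edge with a
random direction — and copies the source id into the target site. Boundary
sampling concentrates work where updates are possible; its uniformity over
edges is itself tested. Acceptance follows the Metropolis rule
`min(1, exp(-ΔH/T))`.

Penalty terms are composable objects with a pure `delta(proposal)` and an
`after_accept` hook; custom penalties implement the same two-method
contract. Built-ins: adhesion (type-indexed symmetric J with medium as type
0; same-id contacts contribute nothing), volume and perimeter (quadratic in
the deviation from target), Act-model migration (activity memory `max_act`
decaying 1/MCS; ΔH = −(λ/max_act)(GM_source − GM_target) with geometric
means over the site and its same-cell connectivity neighbors), and
chemotaxis (ΔH = −λ(τ_gainer)(c_target − c_source) on a supplied field;
positive λ climbs gradients). Migration and chemotaxis are delta-only
biases — they have no global Hamiltonian, matching their canonical
formulations — so their tests validate the delta definition itself by
independent recomputation, while adhesion/volume/perimeter are checked
against full-Hamiltonian differences.

### Fragmentation guard

A flip that removes a site from a cell is vetoed (counted as a rejection
regardless of ΔH) unless the cell provably stays connected:

1. **Local test.** If the same-cell sites in the flipped site's Moore ring
   form at most one contiguous cyclic arc, every same-cell connectivity
   neighbor remains connected through that arc, so removal is safe. The
   test returns only `safe` or `inconclusive`: no purely local pattern can
   prove *dis*connection (two local arcs may be joined around the far side
   of the cell). 3D sites, and sites whose ring is distorted by wrap-around
   on a length-2 periodic axis, are always `inconclusive`.
2. **Exact fallback.** On `inconclusive`, a BFS over the cell's remaining
   sites decides connectivity exactly.

A cell's last site can never be flipped away: cells vanish only through
explicit death, keeping grid and table consistent. Together this makes
fragmentation impossible at any temperature, which the suite audits at
T = 10, 100, and 1000.

### Division

`divide_cell` partitions the cell's induced connectivity subgraph into two
connected parts whose sizes differ by at most `max(1, 5%)` of the parent
volume. The heuristic runs up to 20 randomized restarts of two polynomial
attempts, each polished by boundary-swap refinement (move a
non-articulation node of the larger side that touches the smaller side,
preferring moves that shorten the cut):

- **guarded accretion** — grow one side from a random non-articulation seed
  toward half the nodes, only ever taking nodes whose removal keeps the
  complement connected, preferring compact growth with random tie-breaks;
- **spanning-tree cut** — the best single-edge cut of a randomized DFS
  spanning tree, which finds "neck" splits accretion can miss.

Both attempts maintain two connected sides by construction, so any returned
partition is valid; restarts drive the balance inside tolerance. Daughter 1
keeps the parent id; daughter 2 gets a fresh id (ids are never reused) and a
row inheriting type and target volume (halving the target is a config flag,
off by default — a growing population keeps similarly sized cells).
Conserved custom properties are split with a fresh uniform fraction per
property; the rest are copied.

**Exact conservation.** A naive `x1 = f·x; x2 = x − x1` does not guarantee
`x1 + x2 == x` in floating point. Splits are therefore done on the integer
significand: writing x = m·2^e with integer m, a uniform integer k in
(0, m) yields shares k·2^e and (m−k)·2^e whose sum is bitwise exact, with
k/m uniform to 2⁻⁵³.

## Intracellular ODEs and events

Each cell carries a state vector advanced over one `mcs_duration` (default
1.0 continuous time unit) after every MCS, using adaptive explicit
Runge–Kutta (`scipy.integrate.solve_ivp`, RK45, default rtol 1e-6) with
terminal events `x[component] − threshold` located by the integrator's
root-finding. Integration halts at each event, the action fires, and
integration resumes — divisions therefore change the number of state
vectors mid-interval, and both daughters continue from the event time.
Cells too small to divide (one site) defer the event: the state is kept,
the event is suppressed for the rest of the interval and re-arms at the
start of the next one. Built-in right-hand sides selectable by name:
`constant` (dX/dt = α) and `exponential` (dX/dt = αX); arbitrary rhs
callables are accepted programmatically (but cannot be serialized into a
model file).

The growing-population demonstration uses dX/dt = αX with α = 0.1 and
founder X(0) ~ U(0, 0.5), dividing at X ≥ 1 with random apportioning. The
rate gives a doubling time of ≈ 7 MCS, so a 40–60 MCS run shows several
asynchronous division rounds on a 50×50 grid without saturating it; the
random inheritance desynchronizes the division staircase after the first
round.

## Recording

A history is the initial snapshot plus, per MCS, the accepted flips in
order (node, old id, new id) and the discrete events (division: parent,
daughter, daughter's node set and row, post-split properties; death: id and
node set), plus full checkpoints every 100 MCS (configurable — the interval
trades reconstruction speed for file size). Reconstruction replays forward
from the nearest prior checkpoint and is bit-exact against a truncated
rerun from the same seed. Containers are single HDF5 files tagged with a
magic string and format version; model files additionally carry all RNG
states, so save → load → run continues the exact trajectory.

## Determinism

All randomness derives from one seed through independent child streams
(placement, flips, events, compiled kernel). The Metropolis inner loop for
the built-in penalty set is compiled (numba) and uses an explicit
xorshift64* stream whose state is serialized with the model; models with
custom penalties run on the pure-Python path, which has identical semantics
but its own PCG stream — each path is exactly reproducible given (config,
seed), and the path choice is itself recorded.

## Fixture parameters

Cell sorting: 50×50 periodic grid, 20 cells per type, target volume 25,
T = 20, J homotypic 4 / heterotypic 11 / cell–medium 8, λ_v = 5. The λ_v
default comes from a mean-field balance: boundary-contact pressure of order
J·dP/dv ≈ 10 must be met by the volume restoring force 2λ_v·Δv within a
node or two of target, keeping equilibrium volumes well inside 10% of
target at T = 20; thermal volume fluctuations then have σ ≈ √(T/2λ_v) ≈ 1.4
sites. Cells start as a compact aggregate with types assigned to slots by a
seeded shuffle: the canonical sorting experiment begins from a mixed
aggregate, and a dispersed start would confound sorting with aggregation
(any cell–cell contact, J = 11, beats two medium-exposed surfaces, 2×8).
Random-shuffle mixing also puts the initial A–B interface at the
random-mixing level, which the neutral-J control preserves in expectation —
so the control cleanly separates differential adhesion from generic
dynamics.

Random test shapes come from surface-tension-weighted accretion (boundary
sites sampled ∝ occupied-neighbor count²). This keeps shapes cell-like —
rough and frequently concave (the suite audits that non-convex shapes
occur) — while avoiding width-1 spider arms, for which *no* balanced
connected bipartition exists at all (verified by exhaustive enumeration on
small instances); such filaments are also not shapes a CPM cell with a
volume constraint adopts.

## What the synthetic models do and do not show

The fixtures emulate the qualitative phenomena the simulator is built for —
differential-adhesion sorting, temperature-independent cell integrity,
population growth driven by intracellular state — under controlled,
seed-reproducible conditions. They do not calibrate to any measured tissue:
energies are in arbitrary units, time is in MCS, and no physical unit
handling is attempted. Passing tests demonstrate algorithmic correctness
(exact deltas, guaranteed connectivity, valid partitions, conservative
splits, bit-exact replay) and the expected emergent trends, not agreement
with particular biological measurements.

## Numerical choices and limitations

- Energy deltas are exact local computations (tested to 1e-9 against
  brute-force oracles); no energy caching beyond volume/perimeter counts.
- `accept_probability` underflows to 0 beyond ΔH/T > 700 to avoid overflow.
- Proposal sampling rejects homotypic draws; a bounded miss streak triggers
  an exact scan so a uniform grid terminates the step cleanly.
- Problem sizes in the test suite (grids up to 50×50, 1,000–2,000 MCS,
  5-seed replicates, 100-shape audits) were chosen to exercise the full
  fixture conditions while keeping the whole suite around half a minute.
- Not covered by design: hexagonal/off-lattice spaces, growing domains,
  reaction–diffusion fields (chemotaxis fields are supplied, static or
  externally updated), stochastic chemical kinetics, oriented division,
  detailed-balance-exact sampling under the connectivity constraint, and
  physical units.
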