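# pottsgraph

A graph-based **Cellular Potts Model** (CPM) simulator for multiscale cell
biology: cell sorting, adhesion, growth, migration, chemotaxis, and
division driven by intracellular dynamics.

In a CPM, an integer lattice holds one cell id per site (0 = medium);
contiguous sites sharing an id form one cell. The lattice evolves by
Metropolis–Hastings copy flips: a site adopts a neighbor's id with
probability `min(1, exp(-ΔH/T))`, where the Hamiltonian is a sum of
penalties

```
H = Σ_{⟨i,j⟩} J[τ(σᵢ), τ(σⱼ)] (1 − δ(σᵢ, σⱼ))     adhesion
  + Σ_c λ_v (v_c − V_c)²                           volume
  + Σ_c λ_p (p_c − P_c)²                           perimeter
  + Act-model migration and chemotaxis biases
```

Encoding the lattice as a **graph** (periodic boundaries are just edges
between opposite faces; image masks are just graphs with fewer nodes) buys
three things that array-based CPMs struggle with:

- **No cell fragmentation, at any temperature.** Before a flip removes a
  site from a cell, the engine checks whether that site is an articulation
  point of the cell's subgraph — a fast local Moore-ring test handles the
  common cases, an exact connectivity check the rest. Fragmenting flips are
  vetoed outright instead of being discouraged by lowering T.
- **Division of arbitrarily shaped cells.** A cell divides by a balanced
  connected 2-way partition of its induced subgraph (guarded accretion with
  randomized restarts plus spanning-tree cuts and boundary-swap refinement),
  which works for concave and tunneled shapes where cleavage-line methods
  fail.
- **Arbitrary geometries.** Rectangular 2D/3D spaces with periodic or
  closed boundaries, or any domain given as a binary mask (PNG or CSV).

Each cell can carry an ODE state vector (e.g. a protein amount) advanced
between Monte Carlo steps with adaptive error-controlled integration;
threshold crossings are located by root-finding and can trigger division,
with the protein split randomly (and exactly conservatively) between
daughters.

Simulations are recorded as **deltas** (initial snapshot + accepted flips +
events + periodic checkpoints), so files grow with activity, not with
duration × grid size, and any past state can be reconstructed bit-exactly.

## Worked example: cell sorting

```python
import pottsgraph as pg
from pottsgraph.fixtures import make_cell_sorting_model
from pottsgraph.cell_state import heterotypic_boundary_length

model = make_cell_sorting_model(seed=1)   # 50x50 torus, 2x20 cells, J = 4/11/8
h0 = heterotypic_boundary_length(model.space, model.state, model.table)
history = pg.run(model, 2000)
hT = heterotypic_boundary_length(model.space, model.state, model.table)
df = pg.export_summary(history)
print(f"cells: {len(model.table)}")
print(f"heterotypic boundary: {h0} -> {hT} ({hT/h0:.2f}x)")
print(f"mean volume A: {df.mean_volume_A.iloc[-1]:.2f} (target 25)")
print(f"accepted flips recorded: {history.n_recorded_flips}")
```

prints

```
cells: 40
heterotypic boundary: 350 -> 107 (0.31x)
mean volume A: 24.75 (target 25)
accepted flips recorded: 2455165
```

The two cell types start as a randomly mixed aggregate; because heterotypic
contact (J = 11) costs more than homotypic contact (J = 4), the A–B
interface shrinks to roughly a third of its initial length by 2,000 MCS —
the classic differential-adhesion sorting result. Volumes stay pinned to
their targets by the quadratic volume penalty. With a neutral J matrix
(heterotypic = homotypic) the interface does not shrink.

## Command line

Models are TOML configs with `[space]`, `[[cells.groups]]`, `[penalties.*]`,
`[engine]`, `[ode]`, and `[recording]` blocks (fixtures can emit complete
examples via `make_cell_sorting_config()` / `make_growing_population_config()`):

```bash
pottsgraph run model.toml --seed 1 --mcs 2000 --out run.h5 --summary run.csv
pottsgraph replay run.h5 --mcs 500 --out frame.png   # or .csv of raw ids
pottsgraph summarize run.h5 --out summary.csv
```

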