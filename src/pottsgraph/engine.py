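"""Metropolis–Hastings dynamics with a fragmentation guard.

Updates are copy flips: a random heterotypic connectivity edge is drawn, and
the source node's cell id is copied into the target node.  The proposal is
scored by the total penalty change dH and accepted with probability
min(1, exp(-dH / T)).  Before scoring, any flip that would disconnect the
losing cell is vetoed — the guard first runs a local Moore-ring test
(:func:`local_topology_check`) and falls back to an exact connectivity check
on the cell's induced subgraph when the local pattern is inconclusive.  This
makes fragmentation impossible at any temperature.

One Monte Carlo step (MCS) is ``flips_per_mcs`` flip attempts (default: the
node count).  Between MCS the engine advances per-cell ODEs, fires division
events, applies Act-activity decay, and appends accepted flips to the history.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np

from . import _kernel
from .cell_state import (
    CellTable,
    LatticeState,
    apply_flip,
    initialize_cells,
    recompute_statistics,
)
from .division_death import divide_cell
from .errors import ConfigurationError, ContractViolationError
from .lattice_graph import SpaceGraph
from .ode_coupling import IntracellularModel, advance, on_division_event
from .penalties import (
    ActMigrationPenalty,
    AdhesionPenalty,
    ChemotaxisPenalty,
    Penalty,
    PerimeterPenalty,
    VolumePenalty,
    per_type_array,
    total_delta,
)
from .recording_io import History

__all__ = [
    "Proposal",
    "ModelParams",
    "Model",
    "propose",
    "accept_probability",
    "local_topology_check",
    "is_safe_removal",
    "step",
    "run",
]

SAFE = "safe"
UNSAFE = "unsafe"
INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class Proposal:
    """Copy sigma[source_node] into target_node."""

    target_node: int
    source_node: int
    old_id: int
    new_id: int


@dataclass
class ModelParams:
    temperature: float = 20.0
    flips_per_mcs: int | None = None  # None -> node count
    rng_seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be positive")
        if self.flips_per_mcs is not None and self.flips_per_mcs < 1:
            raise ConfigurationError("flips_per_mcs must be >= 1")


# ---------------------------------------------------------------------------
# elementary operations


def propose(space: SpaceGraph, state: LatticeState, rng) -> Proposal | None:
    """Uniform random heterotypic connectivity edge as a copy flip.

    Sampling is uniform over *directed* pairs whose endpoints differ, i.e.
    every heterotypic edge is equally likely and carries a random direction.
    Returns None when the grid is uniform (no such edge exists).
    """
    sigma = state.sigma
    conn = space.conn
    n, kc = conn.shape
    for _ in range(64):
        node = int(rng.integers(n))
        nbr = int(conn[node, rng.integers(kc)])
        if nbr >= 0 and sigma[node] != sigma[nbr]:
            return Proposal(node, nbr, int(sigma[node]), int(sigma[nbr]))
    # rare path: verify a heterotypic edge exists at all before looping on
    valid = conn >= 0
    hetero = valid & (sigma[:, None] != sigma[np.where(valid, conn, 0)])
    if not hetero.any():
        return None
    while True:
        node = int(rng.integers(n))
        nbr = int(conn[node, rng.integers(kc)])
        if nbr >= 0 and sigma[node] != sigma[nbr]:
            return Proposal(node, nbr, int(sigma[node]), int(sigma[nbr]))


def accept_probability(delta_H: float, T: float) -> float:
    """Metropolis rule min(1, exp(-dH/T))."""
    if T <= 0:
        raise ConfigurationError("temperature must be positive")
    if delta_H <= 0:
        return 1.0
    x = delta_H / T
    return 0.0 if x > 700 else float(np.exp(-x))


def local_topology_check(space: SpaceGraph, state: LatticeState,
                         node: int) -> str:
    """Purely local screen for fragmentation risk.

    Examines the node's Moore-ring occupancy: if the same-cell ring sites form
    at most one contiguous cyclic arc, every same-cell connectivity neighbor
    stays connected through that arc after removal, so the flip is 'safe'.
    Any other pattern (or a 3D space, or a ring distorted by wrap-around on a
    length-2 periodic axis) is 'inconclusive' — two local arcs may still be
    joined elsewhere around the cell, so no local pattern can prove
    disconnection.  Never contradicts the exact articulation oracle.
    """
    cid = int(state.sigma[node])
    if cid == 0:
        raise ContractViolationError("topology query on a medium node")
    if space.ring is None or not space.ring_valid[node]:
        return INCONCLUSIVE
    sigma = state.sigma
    ring = space.ring[node]
    same = [(r >= 0 and sigma[r] == cid) for r in ring]
    arcs = sum(1 for i in range(8) if same[i] and not same[(i + 1) % 8])
    return SAFE if arcs <= 1 else INCONCLUSIVE


def _cell_connected_without(space, sigma, cid, removed, vol) -> bool:
    """Exact oracle: is the cell still one component after removing `removed`?"""
    start = -1
    for v in space.conn[removed]:
        if v >= 0 and sigma[v] == cid:
            start = int(v)
            break
    if start < 0:
        return False
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in space.conn[u]:
            v = int(v)
            if v >= 0 and v != removed and sigma[v] == cid and v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == vol - 1


def is_safe_removal(space: SpaceGraph, state: LatticeState, node: int) -> bool:
    """True iff the node's cell stays connected when the node is removed.

    A 1-node cell's last node is never safe to remove: cells cannot vanish
    through flips, only through explicit death.
    """
    cid = int(state.sigma[node])
    if cid == 0:
        raise ContractViolationError("removal query on a medium node")
    vol = int(state.volume[cid])
    if vol <= 1:
        return False
    if local_topology_check(space, state, node) == SAFE:
        return True
    return _cell_connected_without(space, state.sigma, cid, node, vol)


def step(space, state, table, penalties, params: ModelParams, rng):
    """One propose -> guard -> score -> accept cycle (pure-Python path).

    Returns (state, accepted, proposal); guard vetoes count as rejections
    regardless of dH.  On acceptance the cached statistics and every
    penalty's internal state are updated incrementally.
    """
    p = propose(space, state, rng)
    if p is None:
        return state, False, None
    if p.old_id != 0 and not is_safe_removal(space, state, p.target_node):
        return state, False, p
    dh = total_delta(penalties, space, state, table, p)
    if rng.random() >= accept_probability(dh, params.temperature):
        return state, False, p
    apply_flip(space, state, p.target_node, p.old_id, p.new_id)
    for pen in penalties:
        pen.after_accept(space, state, table, p)
    return state, True, p


# ---------------------------------------------------------------------------
# model container


def derived_rngs(seed: int):
    """Independent child streams for placement, flips, events, kernel."""
    ss = np.random.SeedSequence(seed)
    c_place, c_flip, c_event, c_kernel = ss.spawn(4)
    kstate = c_kernel.generate_state(1, dtype=np.uint64)
    if kstate[0] == 0:
        kstate[0] = np.uint64(0x9E3779B97F4A7C15)
    return (np.random.default_rng(c_place), np.random.default_rng(c_flip),
            np.random.default_rng(c_event), kstate)


_KERNEL_KINDS = (AdhesionPenalty, VolumePenalty, PerimeterPenalty,
                 ActMigrationPenalty, ChemotaxisPenalty)


class Model:
    """Everything needed to evolve a simulation: space, state, table,
    penalties, parameters, and (optionally) per-cell intracellular ODEs."""

    def __init__(self, space, state, table, penalties, params,
                 intracellular: IntracellularModel | None = None, *,
                 checkpoint_every: int = 100,
                 halve_target_on_division: bool = False,
                 stochastic_division: bool = False,
                 record_ode: bool = True,
                 compiled: bool | None = None):
        self.space = space
        self.state = state
        self.table = table
        self.penalties = list(penalties)
        self.params = params
        self.intracellular = intracellular
        self.checkpoint_every = int(checkpoint_every)
        self.halve_target_on_division = bool(halve_target_on_division)
        self.stochastic_division = bool(stochastic_division)
        self.record_ode = bool(record_ode)
        for pen in self.penalties:
            pen.bind(space)
        if compiled is None:
            compiled = all(isinstance(p, _KERNEL_KINDS) for p in self.penalties)
        self.compiled = bool(compiled)
        self.mcs = 0
        self.t = 0.0
        self.placement_rng, self.flip_rng, self.event_rng, self.kernel_rng_state = (
            derived_rngs(params.rng_seed))

    @property
    def flips_per_mcs(self) -> int:
        return self.params.flips_per_mcs or self.space.n_nodes

    def find_penalty(self, cls):
        for p in self.penalties:
            if isinstance(p, cls):
                return p
        return None


def _kernel_arrays(model: Model):
    """Flat parameter arrays for the compiled MCS kernel."""
    table = model.table
    state = model.state
    n_types = max(table.max_type_index, 1)
    cap = state.volume.size
    table._ensure_capacity(cap - 1)

    adh = model.find_penalty(AdhesionPenalty)
    J = np.zeros((n_types + 1, n_types + 1))
    if adh is not None:
        if adh.J.shape[0] < n_types + 1:
            raise ConfigurationError("J matrix smaller than max type index + 1")
        J = adh.J[: n_types + 1, : n_types + 1].copy()

    volp = model.find_penalty(VolumePenalty)
    lam_v = per_type_array(volp.lambda_volume if volp else 0.0, n_types)
    lam_v[0] = 0.0

    perp = model.find_penalty(PerimeterPenalty)
    lam_p = per_type_array(perp.lambda_perimeter if perp else 0.0, n_types)
    lam_p[0] = 0.0
    if perp is not None:
        for cid in table.cell_ids:
            if lam_p[table.type_of(cid)] and np.isnan(
                    table.target_perimeter_array[cid]):
                raise ConfigurationError(
                    f"cell {cid} lacks target_perimeter under a perimeter penalty")

    act = model.find_penalty(ActMigrationPenalty)
    chem = model.find_penalty(ChemotaxisPenalty)
    return dict(
        type_of=table.type_of_array[:cap].astype(np.int32),
        tvol=table.target_volume_array[:cap],
        tperi=table.target_perimeter_array[:cap],
        J=J, lam_v=lam_v,
        use_perim=perp is not None, lam_p=lam_p,
        use_act=act is not None,
        activity=act.activity if act else np.zeros(1, dtype=np.int32),
        lam_act=act.lambda_act if act else 0.0,
        max_act=float(act.max_act) if act else 1.0,
        use_chem=chem is not None,
        chem=chem.field if chem else np.zeros(1),
        lam_chem=per_type_array(chem.lambda_chem if chem else 0.0, n_types,
                                medium_zero=np.isscalar(chem.lambda_chem) if chem else True),
    )


def _division_handler(model: Model, events_out: list):
    """Event-action callback: divide on the grid, split the ODE state."""

    def handle(cell_id, event, t):
        if event.action != "divide":
            return None
        if cell_id not in model.table or model.state.volume[cell_id] < 2:
            return "defer"  # re-armed on the next advance call
        d1, d2 = divide_cell(model.space, model.state, model.table, cell_id,
                             model.event_rng,
                             halve_target=model.halve_target_on_division)
        nodes2 = np.flatnonzero(model.state.sigma == d2).astype(np.int64)
        rec2 = model.table[d2]
        events_out.append({
            "kind": "division", "mcs": model.mcs, "t": float(t),
            "parent": int(d1), "daughter": int(d2),
            "nodes": nodes2.tolist(),
            "parent_properties": dict(model.table[d1].properties),
            "parent_target_volume": float(model.table[d1].target_volume),
            "daughter_row": {
                "type": rec2.type_name,
                "target_volume": rec2.target_volume,
                "target_perimeter": rec2.target_perimeter,
                "properties": dict(rec2.properties),
            },
        })
        return d1, d2

    return handle


def _stochastic_divisions(model: Model, events_out: list):
    """Per-MCS probabilistic division using the 'division_rate' property."""
    for cid in list(model.table.cell_ids):
        rate = model.table[cid].properties.get("division_rate", 0.0)
        if rate <= 0.0 or model.state.volume[cid] < 2:
            continue
        if model.event_rng.random() < rate:
            handler = _division_handler(model, events_out)

            class _E:
                action = "divide"

            out = handler(cid, _E(), model.t)
            if isinstance(out, tuple) and model.intracellular is not None:
                on_division_event(model.intracellular, cid, out, model.event_rng)


def run(model: Model, n_mcs: int, *, progress: bool = False) -> History:
    """Evolve the model ``n_mcs`` Monte Carlo steps, recording deltas.

    Fully reproducible given the model seed.  The compiled kernel handles the
    built-in penalty set; any custom penalty switches the loop to the
    pure-Python :func:`step` path with identical semantics.
    """
    if n_mcs < 0:
        raise ValueError("n_mcs must be >= 0")
    space, state, table = model.space, model.state, model.table
    if model.intracellular is not None:
        model.intracellular.ensure_states(table, model.event_rng)
    history = History(space, state, table,
                      checkpoint_every=model.checkpoint_every)
    n_flips = model.flips_per_mcs
    out_node = np.empty(n_flips, dtype=np.int32)
    out_old = np.empty(n_flips, dtype=np.int32)
    out_new = np.empty(n_flips, dtype=np.int32)
    queue = np.empty(space.n_nodes, dtype=np.int64)
    visited = np.zeros(space.n_nodes, dtype=np.int64)
    stamp = np.zeros(1, dtype=np.int64)
    has_ring = space.ring is not None
    ring = space.ring if has_ring else np.empty((1, 8), dtype=np.int32)
    ring_valid = (space.ring_valid if has_ring
                  else np.zeros(1, dtype=bool))

    for _ in range(n_mcs):
        model.mcs += 1
        events: list = []
        if model.compiled:
            ka = _kernel_arrays(model)
            n_acc, _exhausted = _kernel.run_mcs(
                state.sigma, space.conn, space.inter, ring, ring_valid,
                has_ring,
                ka["type_of"], ka["tvol"], ka["tperi"],
                state.volume, state.perimeter,
                ka["J"], ka["lam_v"], ka["use_perim"], ka["lam_p"],
                ka["use_act"], ka["activity"], ka["lam_act"], ka["max_act"],
                ka["use_chem"], ka["chem"], ka["lam_chem"],
                model.params.temperature, n_flips, model.kernel_rng_state,
                out_node, out_old, out_new, queue, visited, stamp)
            nodes = out_node[:n_acc].copy()
            olds = out_old[:n_acc].copy()
            news = out_new[:n_acc].copy()
        else:
            acc_n, acc_o, acc_w = [], [], []
            for _ in range(n_flips):
                _, accepted, p = step(space, state, table, model.penalties,
                                      model.params, model.flip_rng)
                if accepted:
                    acc_n.append(p.target_node)
                    acc_o.append(p.old_id)
                    acc_w.append(p.new_id)
            nodes = np.asarray(acc_n, dtype=np.int32)
            olds = np.asarray(acc_o, dtype=np.int32)
            news = np.asarray(acc_w, dtype=np.int32)

        for pen in model.penalties:
            pen.on_mcs_end(space, state, table)

        if model.stochastic_division:
            _stochastic_divisions(model, events)

        if model.intracellular is not None:
            intra = model.intracellular
            t0 = model.t
            model.t = t0 + intra.mcs_duration
            advance(intra, table, t0, model.t, rng=model.event_rng,
                    on_event=_division_handler(model, events))
        else:
            model.t += 1.0

        ode_sample = None
        if model.record_ode and model.intracellular is not None:
            ode_sample = {int(c): np.asarray(x).tolist()
                          for c, x in model.intracellular.state_of.items()}
        history.append_mcs(nodes, olds, news, events, ode_sample=ode_sample)
        if model.checkpoint_every and model.mcs % model.checkpoint_every == 0:
            history.add_checkpoint(model.mcs, state, table)
        if progress:
            print(f"mcs {model.mcs}: {len(nodes)}/{n_flips} flips accepted, "
                  f"{len(table)} cells", file=sys.stderr)
    return history


def build_model(space, table, penalties, params, positions=None,
                intracellular=None, **options) -> Model:
    """Convenience constructor: place cells (seed-derived) and wrap a Model."""
    place_rng, _, _, _ = derived_rngs(params.rng_seed)
    state = initialize_cells(space, table, positions=positions, rng=place_rng)
    return Model(space, state, table, penalties, params,
                 intracellular=intracellular, **options)
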