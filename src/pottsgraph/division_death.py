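"""Cell division by balanced connected graph bipartition, and cell death.

Division must split an arbitrarily shaped cell — concave, tunneled, anything
the dynamics produced — into two connected daughters of near-equal size.
Cut-line methods fail on concave shapes; partitioning the cell's induced
subgraph handles any shape.  The 2-way partition here is a polynomial-time
heuristic: two far-apart seeds grow alternately (both sides connected by
construction), then boundary-swap refinement moves non-articulation nodes
from the larger to the smaller side until the sizes balance.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .cell_state import CellTable, LatticeState, recompute_statistics
from .errors import MissingCellError, TooSmallToDivideError
from .lattice_graph import SpaceGraph

__all__ = ["divide_cell", "apportion_properties", "kill_cell",
           "balanced_connected_bipartition"]


def _guarded_accretion(G: nx.Graph, rng, m: int):
    """Grow side A from a random seed toward exactly m nodes.

    Only nodes whose removal keeps the complement connected may cross over,
    so both sides are connected at every step (A by construction, B by the
    articulation-point guard).  May stop early in a local minimum; the caller
    restarts with fresh randomness.
    """
    # seed must not be an articulation point, or B starts disconnected
    arts0 = set(nx.articulation_points(G))
    nodes = sorted(set(G) - arts0)
    s1 = nodes[int(rng.integers(len(nodes)))]
    A = {s1}
    B = set(G) - A
    while len(A) < m:
        arts = set(nx.articulation_points(G.subgraph(B))) if len(B) > 1 else set()
        cands = [u for u in B if u not in arts and any(v in A for v in G[u])]
        if not cands:
            break
        # prefer compact growth (most neighbors already in A), random tie-break
        score = [sum(1 for v in G[u] if v in A) for u in cands]
        best = max(score)
        pool = [u for u, s in zip(cands, score) if s == best]
        u = pool[int(rng.integers(len(pool)))]
        B.discard(u)
        A.add(u)
    return A, B


def _tree_cut(G: nx.Graph, rng):
    """Best single-edge cut of a random spanning tree.

    Removing one tree edge splits the graph into two G-connected parts; a
    randomized DFS tree explores 'neck' cuts that accretion can miss.
    """
    nodes = sorted(G)
    root = nodes[int(rng.integers(len(nodes)))]
    parent = {root: None}
    order = []
    stack = [root]
    while stack:
        u = stack.pop()
        order.append(u)
        nbrs = sorted(G[u])
        perm = rng.permutation(len(nbrs))
        for i in perm:
            v = nbrs[int(i)]
            if v not in parent:
                parent[v] = u
                stack.append(v)
    size = {u: 1 for u in nodes}
    for u in reversed(order):
        if parent[u] is not None:
            size[parent[u]] += size[u]
    n = len(nodes)
    u_best = min(order[1:], key=lambda u: (abs(n - 2 * size[u]), u))
    children = {}
    for v, p in parent.items():
        if p is not None:
            children.setdefault(p, []).append(v)
    A = set()
    stack = [u_best]
    while stack:
        u = stack.pop()
        A.add(u)
        stack.extend(children.get(u, ()))
    return A, set(nodes) - A


def _refine(G: nx.Graph, A: set, B: set, tol: int, max_moves: int):
    """Move boundary nodes from the larger to the smaller side, preserving
    connectivity of both, until sizes differ by at most tol."""
    for _ in range(max_moves):
        if abs(len(A) - len(B)) <= tol:
            break
        L, S = (A, B) if len(A) > len(B) else (B, A)
        if len(L) < 2:
            break
        arts = set(nx.articulation_points(G.subgraph(L)))
        cands = [u for u in L if u not in arts and any(v in S for v in G[u])]
        if not cands:
            break
        u = max(cands, key=lambda n: (sum(1 for v in G[n] if v in S), -n))
        L.remove(u)
        S.add(u)
    return A, B


def balanced_connected_bipartition(G: nx.Graph, rng, tol: int | None = None,
                                   max_restarts: int = 20):
    """Partition a connected graph into two connected parts whose sizes differ
    by at most ``tol`` (default max(1, 5% of n)).  Returns (part1, part2)."""
    n = G.number_of_nodes()
    if tol is None:
        tol = max(1, int(0.05 * n))
    best = None
    best_diff = None
    for attempt in range(max_restarts):
        for A, B in (_guarded_accretion(G, rng, n // 2), _tree_cut(G, rng)):
            A, B = _refine(G, A, B, tol, max_moves=4 * n)
            diff = abs(len(A) - len(B))
            if best is None or diff < best_diff:
                best, best_diff = (set(A), set(B)), diff
            if diff <= tol:
                return best
    return best


def _cell_subgraph(space: SpaceGraph, state: LatticeState, cell_id: int):
    nodes = np.flatnonzero(state.sigma == cell_id)
    G = nx.Graph()
    G.add_nodes_from(int(n) for n in nodes)
    node_set = set(int(n) for n in nodes)
    for u in nodes:
        for v in space.conn[u]:
            v = int(v)
            if v >= 0 and v in node_set and v > u:
                G.add_edge(int(u), v)
    return G


def divide_cell(space: SpaceGraph, state: LatticeState, table: CellTable,
                cell_id: int, rng, *, halve_target: bool = False):
    """Split a cell into two connected, size-balanced daughters.

    Daughter 1 keeps the parent id; daughter 2 gets a fresh id and a table row
    inheriting type and target volume (optionally halved).  Conserved custom
    properties are split randomly between daughters, others are copied.
    Returns (daughter_id_1, daughter_id_2).
    """
    rec = table[cell_id]
    G = _cell_subgraph(space, state, cell_id)
    if G.number_of_nodes() < 2:
        raise TooSmallToDivideError(f"cell {cell_id} has fewer than 2 nodes")
    part1, part2 = balanced_connected_bipartition(G, rng)
    # daughter 1 keeps the parent id; assign it the part containing the lowest
    # node id so the outcome does not depend on set iteration order
    if min(part2) < min(part1):
        part1, part2 = part2, part1

    props1, props2 = apportion_properties(rec.properties, rng,
                                          table.conserved_properties)
    tvol = rec.target_volume / 2 if halve_target else rec.target_volume
    rec.properties = props1
    rec.target_volume = tvol
    table.target_volume_array[cell_id] = tvol
    daughter = table.add_cell(rec.type_name, tvol, rec.target_perimeter,
                              props2)
    state.ensure_capacity(daughter)
    state.sigma[sorted(part2)] = daughter
    recompute_statistics(space, state)
    return cell_id, daughter


def random_split(x: float, rng):
    """Split x into two nonnegative shares (f*x, (1-f)*x), f ~ uniform (0, 1),
    with the totals conserved *bitwise*.

    Naive ``x1 = f*x; x2 = x - x1`` does not guarantee ``x1 + x2 == x`` in
    floating point, so the split is done on the integer significand instead:
    x = m * 2^e with integer m, a uniform integer k in (0, m) gives shares
    k * 2^e and (m-k) * 2^e whose sum is exactly x.
    """
    import math

    if x == 0.0:
        return 0.0, 0.0
    sign = 1.0 if x > 0 else -1.0
    man, exp = math.frexp(abs(x))
    m = int(man * (1 << 53))
    exp -= 53
    k = int(rng.integers(1, m)) if m > 1 else m
    return sign * math.ldexp(k, exp), sign * math.ldexp(m - k, exp)


def apportion_properties(parent_properties: dict, rng, conserved=frozenset()):
    """Split conserved numeric properties x into (f*x, (1-f)*x) with f uniform
    on (0, 1), drawn once per property; copy the rest to both daughters.
    Conserved totals are preserved exactly (see :func:`random_split`)."""
    p1, p2 = {}, {}
    for key, value in parent_properties.items():
        if key in conserved:
            p1[key], p2[key] = random_split(float(value), rng)
        else:
            p1[key] = value
            p2[key] = value
    return p1, p2


def kill_cell(space: SpaceGraph, state: LatticeState, table: CellTable,
              cell_id: int) -> LatticeState:
    """Remove a cell: its nodes become medium, its table row is dropped."""
    if cell_id not in table:
        raise MissingCellError(cell_id)
    table.remove_cell(cell_id)
    state.sigma[state.sigma == cell_id] = 0
    recompute_statistics(space, state)
    return state
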