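"""Shared fixtures and independent brute-force oracles.

The oracle functions here recompute energies and connectivity from first
principles (full sums over the whole grid, BFS from scratch) and are kept
deliberately independent of the incremental code paths they are used to
check.
"""

import numpy as np
import pytest

from pottsgraph import CellTable, LatticeState, build_rectangular, recompute_statistics


# ---------------------------------------------------------------------------
# brute-force energy oracles (full-grid sums, no incremental shortcuts)


def brute_adhesion_H(space, sigma, type_of, J):
    """Full adhesion Hamiltonian: sum over undirected interaction pairs."""
    H = 0.0
    for u in range(space.n_nodes):
        su = int(sigma[u])
        for v in space.inter[u]:
            v = int(v)
            if v <= u:
                continue
            sv = int(sigma[v])
            if su != sv:
                H += J[type_of[su], type_of[sv]]
    return H


def brute_volume_H(sigma, table, lam_by_type):
    H = 0.0
    for cid in table.cell_ids:
        v = int(np.count_nonzero(sigma == cid))
        t = table.type_of(cid)
        H += lam_by_type[t] * (v - table[cid].target_volume) ** 2
    return H


def brute_perimeter_of(space, sigma, cid):
    """Perimeter of one cell: interaction edges leaving it, counted directly."""
    p = 0
    for u in np.flatnonzero(sigma == cid):
        for v in space.inter[u]:
            if v >= 0 and sigma[v] != cid:
                p += 1
    return p


def brute_perimeter_H(space, sigma, table, lam_by_type):
    H = 0.0
    for cid in table.cell_ids:
        t = table.type_of(cid)
        H += lam_by_type[t] * (
            brute_perimeter_of(space, sigma, cid) - table[cid].target_perimeter
        ) ** 2
    return H


def brute_act_gm(space, sigma, activity, node):
    """Geometric mean of activity over node + same-cell connectivity
    neighbors, recomputed with explicit lists (independent code path)."""
    cid = sigma[node]
    if cid == 0:
        return 0.0
    vals = [float(activity[node])]
    vals += [float(activity[v]) for v in space.conn[node]
             if v >= 0 and sigma[v] == cid]
    return float(np.prod(vals)) ** (1.0 / len(vals))


# ---------------------------------------------------------------------------
# connectivity oracle


def cell_components(space, sigma, cid):
    """Number of connectivity-order components of a cell, via fresh BFS."""
    nodes = set(int(n) for n in np.flatnonzero(sigma == cid))
    comps = 0
    left = set(nodes)
    while left:
        comps += 1
        stack = [left.pop()]
        while stack:
            u = stack.pop()
            for v in space.conn[u]:
                v = int(v)
                if v in left:
                    left.discard(v)
                    stack.append(v)
    return comps


def fragmented_cells(space, state, table):
    return [c for c in table.cell_ids
            if cell_components(space, state.sigma, c) != 1]


# ---------------------------------------------------------------------------
# random two-type test states


def random_two_type_state(rng, dims=(8, 8), periodic=True, n_cells=4):
    """Random (generally disconnected) lattice occupancy with two cell types;
    ids 1..n//2 are type A, the rest type B.  Suitable for penalty-delta
    oracles, which do not require contiguous cells."""
    space = build_rectangular(dims, periodic=periodic)
    table = CellTable()
    for i in range(n_cells):
        table.add_cell("A" if i < n_cells // 2 else "B",
                       target_volume=int(rng.integers(3, 15)),
                       target_perimeter=int(rng.integers(5, 30)))
    state = LatticeState(space.n_nodes)
    state.sigma = rng.integers(0, n_cells + 1, size=space.n_nodes).astype(np.int32)
    recompute_statistics(space, state)
    return space, state, table


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
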