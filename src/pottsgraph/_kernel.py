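"""Compiled Metropolis inner loop for the built-in penalty set.

One call executes a full Monte Carlo step (``n_flips`` proposal attempts) on
flat arrays.  Semantics mirror the pure-Python path in :mod:`engine`:
heterotypic-boundary-edge proposals, fragmentation guard (local Moore-ring arc
test with exact BFS fallback), Boltzmann acceptance, incremental statistics.

The RNG is an explicit xorshift64* stream whose state is carried in a one-
element uint64 array, so trajectories are exactly reproducible and the state
can be serialized with a saved model.
"""

import numpy as np
from numba import njit

U1 = np.uint64(1)


@njit(cache=True, inline="always")
def _next_u64(rstate):
    x = rstate[0]
    x ^= x >> np.uint64(12)
    x ^= (x << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(27)
    rstate[0] = x
    return (x * np.uint64(2685821657736338717)) & np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _rand(rstate):
    return float(_next_u64(rstate) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _ring_arcs(sigma, ring, node, cid):
    """Number of cyclic arcs of same-cell sites around the node's Moore ring;
    -1 if the node has no same-cell ring neighbor at all."""
    n_same = 0
    arcs = 0
    for i in range(8):
        r = ring[node, i]
        same_i = r >= 0 and sigma[r] == cid
        r2 = ring[node, (i + 1) % 8]
        same_j = r2 >= 0 and sigma[r2] == cid
        if same_i:
            n_same += 1
            if not same_j:
                arcs += 1
    if n_same == 0:
        return -1
    return arcs


@njit(cache=True)
def _connected_without(sigma, conn, cid, removed, vol, queue, visited, stamp):
    """True iff the cell's nodes minus `removed` form one connected component."""
    start = -1
    for j in range(conn.shape[1]):
        v = conn[removed, j]
        if v >= 0 and sigma[v] == cid:
            start = v
            break
    if start < 0:
        return False
    stamp[0] += 1
    tag = stamp[0]
    head = 0
    tail = 0
    queue[tail] = start
    tail += 1
    visited[start] = tag
    reached = 1
    while head < tail:
        u = queue[head]
        head += 1
        for j in range(conn.shape[1]):
            v = conn[u, j]
            if v >= 0 and v != removed and sigma[v] == cid and visited[v] != tag:
                visited[v] = tag
                queue[tail] = v
                tail += 1
                reached += 1
    return reached == vol - 1


@njit(cache=True)
def run_mcs(sigma, conn, inter, ring, ring_valid, has_ring,
            type_of, tvol, tperi, volume, perimeter,
            J, lam_v, use_perim, lam_p,
            use_act, activity, lam_act, max_act,
            use_chem, chem, lam_chem,
            temperature, n_flips, rstate,
            out_node, out_old, out_new,
            queue, visited, stamp):
    """One Monte Carlo step; returns (n_accepted, exhausted).

    exhausted=True means no heterotypic connectivity edge exists (uniform
    grid) and no further flips are possible until an external event changes
    the lattice.
    """
    n_nodes = sigma.shape[0]
    kc = conn.shape[1]
    n_acc = 0
    for _ in range(n_flips):
        # -- propose: uniform over directed heterotypic connectivity pairs
        target = -1
        source = -1
        tries = 0
        while True:
            node = int(_next_u64(rstate) % np.uint64(n_nodes))
            slot = int(_next_u64(rstate) % np.uint64(kc))
            nbr = conn[node, slot]
            if nbr >= 0 and sigma[node] != sigma[nbr]:
                target = node
                source = nbr
                break
            tries += 1
            if tries >= 4096:
                # exact emptiness scan
                found = False
                for u in range(n_nodes):
                    for j in range(kc):
                        v = conn[u, j]
                        if v >= 0 and sigma[u] != sigma[v]:
                            found = True
                            break
                    if found:
                        break
                if not found:
                    return n_acc, True
                tries = 0
        old = sigma[target]
        new = sigma[source]

        # -- fragmentation guard (vetoes count as rejections)
        if old != 0:
            if volume[old] <= 1:
                continue  # cells never vanish through flips
            safe = False
            if has_ring and ring_valid[target]:
                arcs = _ring_arcs(sigma, ring, target, old)
                safe = arcs <= 1  # one contiguous arc (or leaf) => safe
            if not safe:
                if not _connected_without(sigma, conn, old, target,
                                          volume[old], queue, visited, stamp):
                    continue

        # -- score
        t_old = type_of[old]
        t_new = type_of[new]
        dh = 0.0
        cnt_old = 0
        cnt_new = 0
        k = 0
        for j in range(inter.shape[1]):
            v = inter[target, j]
            if v < 0:
                continue
            k += 1
            s = sigma[v]
            t = type_of[s]
            if s != new:
                dh += J[t_new, t]
            if s != old:
                dh -= J[t_old, t]
            if s == old:
                cnt_old += 1
            if s == new:
                cnt_new += 1
        if old != 0:
            v0 = float(volume[old])
            tv = tvol[old]
            dh += lam_v[t_old] * ((v0 - 1.0 - tv) ** 2 - (v0 - tv) ** 2)
        if new != 0:
            v0 = float(volume[new])
            tv = tvol[new]
            dh += lam_v[t_new] * ((v0 + 1.0 - tv) ** 2 - (v0 - tv) ** 2)
        dp_old = 2 * cnt_old - k
        dp_new = k - 2 * cnt_new
        if use_perim:
            if old != 0 and lam_p[t_old] != 0.0:
                p0 = float(perimeter[old])
                tp = tperi[old]
                dh += lam_p[t_old] * ((p0 + dp_old - tp) ** 2 - (p0 - tp) ** 2)
            if new != 0 and lam_p[t_new] != 0.0:
                p0 = float(perimeter[new])
                tp = tperi[new]
                dh += lam_p[t_new] * ((p0 + dp_new - tp) ** 2 - (p0 - tp) ** 2)
        if use_act:
            gm_src = 0.0
            if new != 0:
                prod = float(activity[source])
                cnt = 1
                for j in range(kc):
                    v = conn[source, j]
                    if v >= 0 and sigma[v] == new:
                        prod *= float(activity[v])
                        cnt += 1
                gm_src = prod ** (1.0 / cnt)
            gm_tgt = 0.0
            if old != 0:
                prod = float(activity[target])
                cnt = 1
                for j in range(kc):
                    v = conn[target, j]
                    if v >= 0 and sigma[v] == old:
                        prod *= float(activity[v])
                        cnt += 1
                gm_tgt = prod ** (1.0 / cnt)
            dh += -(lam_act / max_act) * (gm_src - gm_tgt)
        if use_chem:
            dh += -lam_chem[t_new] * (chem[target] - chem[source])

        # -- Boltzmann acceptance
        if dh > 0.0:
            if _rand(rstate) >= np.exp(-dh / temperature):
                continue
        sigma[target] = new
        if old != 0:
            volume[old] -= 1
            perimeter[old] += dp_old
        if new != 0:
            volume[new] += 1
            perimeter[new] += dp_new
        if use_act:
            activity[target] = max_act if new != 0 else 0
        out_node[n_acc] = target
        out_old[n_acc] = old
        out_new[n_acc] = new
        n_acc += 1
    return n_acc, False
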