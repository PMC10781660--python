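"""Simulation spaces as graphs.

A Cellular Potts lattice is encoded as an undirected graph: nodes are lattice
sites, edges encode adjacency.  Periodic boundaries are realized purely as
extra edges joining opposite faces, and arbitrary domains (e.g. drawn from a
binary image mask) are just graphs with fewer nodes — downstream code never
needs to know which kind of space it is running on.

Two neighborhood orders are carried separately:

* **connectivity** (default von Neumann, 6-neighborhood in 3D) defines what a
  *connected cell* means — it is used by the fragmentation guard and by cell
  division.
* **interaction** (default Moore, 26-neighborhood in 3D) defines which node
  pairs enter adhesion/perimeter sums.

Whenever interaction order >= connectivity order, the interaction adjacency is
a superset of the connectivity adjacency.
"""

from __future__ import annotations

import csv

import numpy as np

from .errors import (
    ConfigurationError,
    EmptyDomainError,
    InvalidSizeError,
    UnsupportedDimensionError,
)

__all__ = [
    "SpaceGraph",
    "build_rectangular",
    "build_from_mask",
    "load_mask_png",
    "load_mask_csv",
]

_VON_NEUMANN = {
    2: ((-1, 0), (1, 0), (0, -1), (0, 1)),
    3: ((-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)),
}


def _moore_offsets(ndim: int):
    out = []
    for off in np.ndindex(*(3,) * ndim):
        o = tuple(int(x) - 1 for x in off)
        if any(o):
            out.append(o)
    return tuple(out)


_MOORE = {2: _moore_offsets(2), 3: _moore_offsets(3)}

# Moore ring of a 2D node in cyclic order; consecutive entries are 4-adjacent,
# which is what the local arc test in the engine relies on.
_RING_2D = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))

_ORDERS = {"von_neumann": _VON_NEUMANN, "moore": _MOORE}


def neighborhood_offsets(order: str, ndim: int):
    """Integer offsets of a named neighborhood order ('von_neumann' | 'moore')."""
    try:
        return _ORDERS[order][ndim]
    except KeyError:
        raise ConfigurationError(
            f"unknown neighborhood order {order!r} for {ndim}D"
        ) from None


def _shift_axis_closed(a: np.ndarray, off: int, ax: int) -> np.ndarray:
    """a shifted so out[c] = a[c + off] along ax, filling with -1 at the edge."""
    out = np.full_like(a, -1)
    n = a.shape[ax]
    if abs(off) >= n:
        return out
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if off > 0:
        dst[ax] = slice(0, n - off)
        src[ax] = slice(off, n)
    else:
        dst[ax] = slice(-off, n)
        src[ax] = slice(0, n + off)
    out[tuple(dst)] = a[tuple(src)]
    return out


def _shifted(id_grid: np.ndarray, offset, periodic) -> np.ndarray:
    """Neighbor-id grid: out[c] = id_grid[c + offset] honoring boundaries."""
    out = id_grid
    for ax, off in enumerate(offset):
        if off == 0:
            continue
        if periodic[ax]:
            out = np.roll(out, -off, axis=ax)
        else:
            out = _shift_axis_closed(out, off, ax)
    return out


def _neighbor_table(id_grid, offsets, periodic, fg_mask) -> np.ndarray:
    cols = [_shifted(id_grid, off, periodic)[fg_mask] for off in offsets]
    return np.ascontiguousarray(np.stack(cols, axis=1).astype(np.int32))


def _dedupe_rows(table: np.ndarray, self_ids: np.ndarray) -> None:
    """Drop duplicate neighbor entries (tiny periodic axes) and self loops."""
    for i in range(table.shape[0]):
        seen = set()
        for j in range(table.shape[1]):
            v = table[i, j]
            if v < 0:
                continue
            if v == self_ids[i] or v in seen:
                table[i, j] = -1
            else:
                seen.add(v)


class SpaceGraph:
    """Lattice-as-graph with two neighborhood orders.

    Attributes
    ----------
    n_nodes : int
    coords : (n_nodes, ndim) int array, 0-based row-major coordinates
    conn, inter : (n_nodes, k) int32 neighbor tables padded with -1
    ring : (n_nodes, 8) int32 or None
        Cyclic Moore ring of every node (2D spaces only), used by the local
        topology test.  ``ring_valid[i]`` is False where wrap-around makes ring
        entries collide (periodic axes of length 2), forcing the exact check.
    dims : tuple or "mask"
    periodic : tuple of bool per axis
    """

    def __init__(self, id_grid, periodic, connectivity_order, interaction_order,
                 is_mask):
        ndim = id_grid.ndim
        fg = id_grid >= 0
        self.ndim = ndim
        self.shape = id_grid.shape
        self.is_mask = bool(is_mask)
        self.dims = "mask" if is_mask else tuple(id_grid.shape)
        self.periodic = tuple(bool(p) for p in periodic)
        self.connectivity_order = connectivity_order
        self.interaction_order = interaction_order
        self._id_grid = np.ascontiguousarray(id_grid.astype(np.int64))
        self.n_nodes = int(fg.sum())
        self.coords = np.argwhere(fg).astype(np.int64)  # row-major == id order

        self.conn = _neighbor_table(
            id_grid, neighborhood_offsets(connectivity_order, ndim), self.periodic, fg)
        self.inter = _neighbor_table(
            id_grid, neighborhood_offsets(interaction_order, ndim), self.periodic, fg)
        ids = np.arange(self.n_nodes)
        if any(p and s <= 2 for p, s in zip(self.periodic, self.shape)):
            _dedupe_rows(self.conn, ids)
            _dedupe_rows(self.inter, ids)

        if ndim == 2:
            self.ring = _neighbor_table(id_grid, _RING_2D, self.periodic, fg)
            valid = np.ones(self.n_nodes, dtype=bool)
            if any(p and s <= 2 for p, s in zip(self.periodic, self.shape)):
                for i in range(self.n_nodes):
                    row = self.ring[i]
                    live = row[row >= 0]
                    if live.size != np.unique(live).size or i in live:
                        valid[i] = False
            self.ring_valid = valid
        else:
            self.ring = None
            self.ring_valid = None

        self._adj_conn = None
        self._adj_inter = None

    # -- convenience views ------------------------------------------------

    def neighbors(self, node: int, order: str = "connectivity"):
        table = self.conn if order == "connectivity" else self.inter
        row = table[node]
        return [int(v) for v in row if v >= 0]

    @staticmethod
    def _as_dict(table):
        return {
            i: frozenset(int(v) for v in row if v >= 0)
            for i, row in enumerate(table)
        }

    @property
    def adjacency_connectivity(self):
        if self._adj_conn is None:
            self._adj_conn = self._as_dict(self.conn)
        return self._adj_conn

    @property
    def adjacency_interaction(self):
        if self._adj_inter is None:
            self._adj_inter = self._as_dict(self.inter)
        return self._adj_inter

    def edges(self, order: str = "connectivity"):
        """Set of undirected edges (u, v) with u < v."""
        table = self.conn if order == "connectivity" else self.inter
        out = set()
        for u in range(self.n_nodes):
            for v in table[u]:
                if v >= 0:
                    out.add((min(u, int(v)), max(u, int(v))))
        return out

    def n_edges(self, order: str = "connectivity") -> int:
        table = self.conn if order == "connectivity" else self.inter
        return int((table >= 0).sum()) // 2

    def node_at(self, coord) -> int:
        """Node id at a coordinate (periodic axes wrap); -1 if background."""
        c = []
        for ax, x in enumerate(coord):
            n = self.shape[ax]
            if self.periodic[ax]:
                x = int(x) % n
            elif not 0 <= int(x) < n:
                return -1
            c.append(int(x))
        return int(self._id_grid[tuple(c)])

    def spec(self) -> dict:
        """Serializable description sufficient to rebuild this space."""
        d = {
            "connectivity": self.connectivity_order,
            "interaction": self.interaction_order,
        }
        if self.is_mask:
            d["mask_shape"] = list(self.shape)
        else:
            d["dims"] = list(self.shape)
            d["periodic"] = list(self.periodic)
        return d


def build_rectangular(dims, periodic=True, connectivity_order="von_neumann",
                      interaction_order="moore") -> SpaceGraph:
    """Rectangular 2D/3D lattice; ``periodic`` may be a bool or per-axis tuple.

    Periodic boundaries become edges joining opposite faces.  Each axis that
    wraps must have length >= 2 so no doubled edges arise.
    """
    dims = tuple(int(d) for d in dims)
    if not 2 <= len(dims) <= 3:
        raise UnsupportedDimensionError(f"need 2 or 3 dims, got {len(dims)}")
    if any(d < 1 for d in dims):
        raise InvalidSizeError(f"all dims must be >= 1, got {dims}")
    if isinstance(periodic, (bool, np.bool_)):
        periodic = (bool(periodic),) * len(dims)
    periodic = tuple(bool(p) for p in periodic)
    if len(periodic) != len(dims):
        raise ConfigurationError("periodic flags must match number of dims")
    if any(p and d < 2 for p, d in zip(periodic, dims)):
        raise InvalidSizeError("periodic axes need length >= 2")
    id_grid = np.arange(int(np.prod(dims)), dtype=np.int64).reshape(dims)
    return SpaceGraph(id_grid, periodic, connectivity_order, interaction_order,
                      is_mask=False)


def build_from_mask(mask, connectivity_order="von_neumann",
                    interaction_order="moore") -> SpaceGraph:
    """Space from a 2D boolean mask: nodes are foreground pixels, boundaries
    are always closed (mask geometry defines the domain, nothing wraps)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise UnsupportedDimensionError("mask must be a 2D array")
    mask = mask.astype(bool)
    n_fg = int(mask.sum())
    if n_fg == 0:
        raise EmptyDomainError("mask has no foreground pixels")
    id_grid = np.full(mask.shape, -1, dtype=np.int64)
    id_grid[mask] = np.arange(n_fg)
    return SpaceGraph(id_grid, (False,) * 2, connectivity_order,
                      interaction_order, is_mask=True)


def load_mask_png(path) -> np.ndarray:
    """Read a PNG into a boolean mask (any nonzero channel value = foreground)."""
    from PIL import Image

    img = np.asarray(Image.open(path))
    if img.ndim == 3:
        img = img[..., :3].max(axis=-1)
    return img > 0


def load_mask_csv(path) -> np.ndarray:
    """Read a CSV of 0/1 values into a boolean mask."""
    with open(path, newline="") as fh:
        rows = [[float(x) for x in row] for row in csv.reader(fh) if row]
    return np.asarray(rows) != 0
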