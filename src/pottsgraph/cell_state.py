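"""Integer grid state and the per-cell table.

``LatticeState`` holds the node -> cell-id map (0 = medium, i.e. sites where
no cell is present) plus cached per-cell statistics: volume (node count) and
perimeter (count of interaction-order edges leaving the cell).  The caches are
maintained incrementally by the engine; :func:`recompute_statistics` is the
from-scratch definition used to (re)establish them.

``CellTable`` stores one record per cell: type name/index, target volume,
optional target perimeter, and arbitrary numeric custom properties (division
rate, protein amount, ...).  Type index 0 is reserved for the medium, which
has no table row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigurationError,
    CrowdingError,
    MissingCellError,
    PlacementConflictError,
)
from .lattice_graph import SpaceGraph

__all__ = [
    "CellRecord",
    "CellTable",
    "LatticeState",
    "initialize_cells",
    "recompute_statistics",
    "apply_flip",
    "heterotypic_boundary_length",
]


@dataclass
class CellRecord:
    cell_id: int
    type_name: str
    type_index: int
    target_volume: float
    target_perimeter: float | None = None
    properties: dict = field(default_factory=dict)
    position: tuple | None = None

    def copy(self) -> "CellRecord":
        return CellRecord(self.cell_id, self.type_name, self.type_index,
                          self.target_volume, self.target_perimeter,
                          dict(self.properties),
                          tuple(self.position) if self.position else None)


class CellTable:
    """Per-cell records with a stable type registry and fresh-id counter.

    Ids are positive integers and are never reused, even after cell death, so
    recorded histories stay unambiguous.  ``conserved_properties`` names the
    custom properties that are split (not copied) between daughters at
    division.
    """

    def __init__(self, conserved_properties=()):
        self._records: dict[int, CellRecord] = {}
        self._types: dict[str, int] = {}
        self.conserved_properties = set(conserved_properties)
        self._next_id = 1
        cap = 16
        self._type_of = np.zeros(cap, dtype=np.int32)
        self._tvol = np.zeros(cap, dtype=np.float64)
        self._tperi = np.full(cap, np.nan, dtype=np.float64)

    # -- registry ---------------------------------------------------------

    def type_index(self, name: str) -> int:
        if name not in self._types:
            self._types[name] = len(self._types) + 1  # 0 reserved for medium
        return self._types[name]

    @property
    def type_names(self) -> dict[str, int]:
        return dict(self._types)

    @property
    def max_type_index(self) -> int:
        return max(self._types.values(), default=0)

    # -- record access ----------------------------------------------------

    def __contains__(self, cell_id) -> bool:
        return int(cell_id) in self._records

    def __getitem__(self, cell_id) -> CellRecord:
        try:
            return self._records[int(cell_id)]
        except KeyError:
            raise MissingCellError(int(cell_id)) from None

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(sorted(self._records))

    def records(self):
        return [self._records[i] for i in sorted(self._records)]

    @property
    def cell_ids(self):
        return sorted(self._records)

    def new_id(self) -> int:
        nid = self._next_id
        self._next_id += 1
        return nid

    def _ensure_capacity(self, cell_id: int) -> None:
        cap = self._type_of.size
        if cell_id < cap:
            return
        new = max(2 * cap, cell_id + 1)
        self._type_of = np.resize(self._type_of, new)
        self._type_of[cap:] = 0
        self._tvol = np.resize(self._tvol, new)
        self._tvol[cap:] = 0.0
        self._tperi = np.resize(self._tperi, new)
        self._tperi[cap:] = np.nan

    def add_cell(self, type_name, target_volume, target_perimeter=None,
                 properties=None, position=None, cell_id=None) -> int:
        if target_volume < 1:
            raise ConfigurationError("target_volume must be >= 1")
        if cell_id is None:
            cell_id = self.new_id()
        else:
            cell_id = int(cell_id)
            if cell_id in self._records:
                raise ConfigurationError(f"duplicate cell id {cell_id}")
            self._next_id = max(self._next_id, cell_id + 1)
        rec = CellRecord(cell_id, type_name, self.type_index(type_name),
                         float(target_volume),
                         None if target_perimeter is None else float(target_perimeter),
                         dict(properties or {}),
                         tuple(position) if position is not None else None)
        self._records[cell_id] = rec
        self._ensure_capacity(cell_id)
        self._type_of[cell_id] = rec.type_index
        self._tvol[cell_id] = rec.target_volume
        self._tperi[cell_id] = np.nan if rec.target_perimeter is None else rec.target_perimeter
        return cell_id

    def remove_cell(self, cell_id) -> CellRecord:
        rec = self[cell_id]
        del self._records[rec.cell_id]
        self._type_of[rec.cell_id] = 0
        self._tvol[rec.cell_id] = 0.0
        self._tperi[rec.cell_id] = np.nan
        return rec

    # -- fast arrays (indexed by cell id; 0 row is the medium) -------------

    @property
    def type_of_array(self) -> np.ndarray:
        return self._type_of

    @property
    def target_volume_array(self) -> np.ndarray:
        return self._tvol

    @property
    def target_perimeter_array(self) -> np.ndarray:
        return self._tperi

    def type_of(self, cell_id: int) -> int:
        return 0 if cell_id == 0 else int(self._type_of[cell_id])

    # -- construction -----------------------------------------------------

    @classmethod
    def from_groups(cls, groups, conserved_properties=()) -> "CellTable":
        """Expand group rows (name, count, target_volume, ...) into cells.

        Each group is a mapping; recognized keys are ``name``, ``count``,
        ``target_volume``, ``target_perimeter``, ``positions`` (list of
        coordinate tuples, one per cell).  Any other numeric key becomes a
        custom property shared by all cells of the group.
        """
        table = cls(conserved_properties)
        for g in groups:
            g = dict(g)
            name = g.pop("name")
            count = int(g.pop("count", 1))
            tvol = g.pop("target_volume")
            tperi = g.pop("target_perimeter", None)
            positions = g.pop("positions", None)
            props = {k: float(v) for k, v in g.items()}
            for i in range(count):
                pos = None
                if positions is not None and i < len(positions):
                    pos = tuple(int(x) for x in positions[i])
                table.add_cell(name, tvol, tperi, props, pos)
        return table

    @classmethod
    def from_csv(cls, path, conserved_properties=()) -> "CellTable":
        """Cell table from CSV columns: name, count, target_volume,
        [target_perimeter], [x, y, z], plus extra columns as properties."""
        import pandas as pd

        df = pd.read_csv(path)
        groups = []
        for _, row in df.iterrows():
            g = {"name": row["name"], "count": int(row.get("count", 1)),
                 "target_volume": float(row["target_volume"])}
            if "target_perimeter" in df.columns and not pd.isna(row["target_perimeter"]):
                g["target_perimeter"] = float(row["target_perimeter"])
            axes = [a for a in ("x", "y", "z") if a in df.columns]
            if axes and not any(pd.isna(row[a]) for a in axes):
                g["positions"] = [tuple(int(row[a]) for a in axes)]
            for col in df.columns:
                if col in ("name", "count", "target_volume", "target_perimeter",
                           "x", "y", "z"):
                    continue
                if not pd.isna(row[col]):
                    g[col] = float(row[col])
            groups.append(g)
        return cls.from_groups(groups, conserved_properties)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "types": dict(self._types),
            "next_id": self._next_id,
            "conserved": sorted(self.conserved_properties),
            "cells": [
                {
                    "id": r.cell_id,
                    "type": r.type_name,
                    "target_volume": r.target_volume,
                    "target_perimeter": r.target_perimeter,
                    "properties": dict(r.properties),
                    "position": list(r.position) if r.position else None,
                }
                for r in self.records()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellTable":
        table = cls(d.get("conserved", ()))
        table._types = {str(k): int(v) for k, v in d["types"].items()}
        for c in d["cells"]:
            table.add_cell(c["type"], c["target_volume"], c["target_perimeter"],
                           c.get("properties"), c.get("position"),
                           cell_id=c["id"])
        table._next_id = max(int(d["next_id"]), table._next_id)
        return table

    def equals(self, other: "CellTable") -> bool:
        return self.to_dict() == other.to_dict()


class LatticeState:
    """Node -> cell id map with cached per-cell volume and perimeter."""

    def __init__(self, n_nodes: int, capacity: int = 16):
        self.sigma = np.zeros(n_nodes, dtype=np.int32)
        self.volume = np.zeros(capacity, dtype=np.int64)
        self.perimeter = np.zeros(capacity, dtype=np.int64)

    def ensure_capacity(self, cell_id: int) -> None:
        cap = self.volume.size
        if cell_id < cap:
            return
        new = max(2 * cap, cell_id + 1)
        self.volume = np.resize(self.volume, new)
        self.volume[cap:] = 0
        self.perimeter = np.resize(self.perimeter, new)
        self.perimeter[cap:] = 0

    def copy(self) -> "LatticeState":
        st = LatticeState(self.sigma.size, self.volume.size)
        st.sigma = self.sigma.copy()
        st.volume = self.volume.copy()
        st.perimeter = self.perimeter.copy()
        return st

    @property
    def cached_volume(self) -> dict:
        ids = np.flatnonzero(self.volume)
        return {int(i): int(self.volume[i]) for i in ids if i > 0}

    @property
    def cached_perimeter(self) -> dict:
        ids = np.flatnonzero(self.volume)
        return {int(i): int(self.perimeter[i]) for i in ids if i > 0}

    def cells_present(self) -> np.ndarray:
        return np.flatnonzero(self.volume[1:]) + 1 if self.volume.size > 1 else np.array([], int)


# ---------------------------------------------------------------------------
# statistics


def recompute_statistics(space: SpaceGraph, state: LatticeState) -> LatticeState:
    """Set cached volume/perimeter to their from-scratch definitions.

    Perimeter of cell c counts interaction-order edges (u, v) with u in c and
    v carrying any other id (medium included).
    """
    sigma = state.sigma
    max_id = int(sigma.max(initial=0))
    state.ensure_capacity(max_id)
    vol = np.bincount(sigma[sigma > 0], minlength=state.volume.size)
    state.volume[:] = 0
    state.volume[: vol.size] = vol

    peri = np.zeros(state.perimeter.size, dtype=np.int64)
    n = sigma.size
    idx = np.arange(n)
    for col in space.inter.T:
        valid = col >= 0
        u = idx[valid]
        su = sigma[u]
        sv = sigma[col[valid]]
        hit = (su != sv) & (su > 0)
        np.add.at(peri, su[hit], 1)
    state.perimeter[:] = peri
    return state


def heterotypic_boundary_length(space: SpaceGraph, state: LatticeState,
                                table: CellTable, by: str = "type") -> int:
    """Count interaction-order boundary edges.

    by='type': edges between nodes of *different, nonzero* type indices (the
    standard cell-sorting statistic).  by='id': edges between different cell
    ids, medium included.
    """
    sigma = state.sigma
    if by == "type":
        lab = table.type_of_array[sigma]
    elif by == "id":
        lab = sigma
    else:
        raise ValueError("by must be 'type' or 'id'")
    total = 0
    idx = np.arange(sigma.size)
    for col in space.inter.T:
        valid = col >= 0
        u = idx[valid]
        lu = lab[u]
        lv = lab[col[valid]]
        if by == "type":
            total += int(np.count_nonzero((lu != lv) & (lu > 0) & (lv > 0)))
        else:
            total += int(np.count_nonzero(lu != lv))
    return total // 2


def apply_flip(space: SpaceGraph, state: LatticeState, node: int,
               old_id: int, new_id: int) -> None:
    """Set sigma[node] = new_id, updating cached statistics incrementally."""
    sigma = state.sigma
    row = space.inter[node]
    cnt_old = 0
    cnt_new = 0
    k = 0
    for v in row:
        if v < 0:
            continue
        k += 1
        s = sigma[v]
        if s == old_id:
            cnt_old += 1
        if s == new_id:
            cnt_new += 1
    sigma[node] = new_id
    if old_id != 0:
        state.volume[old_id] -= 1
        state.perimeter[old_id] += 2 * cnt_old - k
    if new_id != 0:
        state.ensure_capacity(new_id)
        state.volume[new_id] += 1
        state.perimeter[new_id] += k - 2 * cnt_new


# ---------------------------------------------------------------------------
# initial placement


def _block_offsets(volume: int, ndim: int):
    """First `volume` coordinates of a most-square (most-cubic) filling box."""
    if ndim == 2:
        w = math.ceil(math.sqrt(volume))
        coords = [(i, j) for i in range(math.ceil(volume / w)) for j in range(w)]
    else:
        w = math.ceil(volume ** (1 / 3))
        per_plane = w * w
        coords = [
            (k, i, j)
            for k in range(math.ceil(volume / per_plane))
            for i in range(w)
            for j in range(w)
        ]
    return coords[:volume]


def _block_nodes(space: SpaceGraph, anchor, offsets):
    """Node ids of anchor+offsets, or None if any falls outside the domain."""
    nodes = []
    for off in offsets:
        c = tuple(a + o for a, o in zip(anchor, off))
        nid = space.node_at(c)
        if nid < 0:
            return None
        nodes.append(nid)
    return nodes


def initialize_cells(space: SpaceGraph, table: CellTable, positions=None,
                     rng=None, seed=None, max_retries: int = 10_000) -> LatticeState:
    """Place every cell as a compact block of exactly its target volume.

    Cells with a position (per-record or via ``positions``, a cell-id ->
    coordinate mapping) are anchored there (the coordinate is the block's
    minimum corner); the rest get non-overlapping random anchors found by
    rejection sampling with a bounded retry count.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    total = sum(int(round(r.target_volume)) for r in table.records())
    if total > space.n_nodes:
        raise CrowdingError(
            f"requested volume {total} exceeds {space.n_nodes} available nodes")

    state = LatticeState(space.n_nodes)
    positions = dict(positions or {})

    placed_first = [r for r in table.records()
                    if r.cell_id in positions or r.position is not None]
    random_later = [r for r in table.records()
                    if r.cell_id not in positions and r.position is None]

    for rec in placed_first:
        v = int(round(rec.target_volume))
        offsets = _block_offsets(v, space.ndim)
        anchor = tuple(positions.get(rec.cell_id, rec.position))
        nodes = _block_nodes(space, anchor, offsets)
        if nodes is None:
            raise PlacementConflictError(
                f"cell {rec.cell_id} block at {anchor} leaves the domain")
        if any(state.sigma[n] != 0 for n in nodes):
            raise PlacementConflictError(
                f"cell {rec.cell_id} at {anchor} overlaps another cell")
        state.ensure_capacity(rec.cell_id)
        state.sigma[nodes] = rec.cell_id

    for rec in random_later:
        v = int(round(rec.target_volume))
        offsets = _block_offsets(v, space.ndim)
        ok = False
        for _ in range(max_retries):
            anchor = tuple(int(rng.integers(s)) for s in space.shape)
            nodes = _block_nodes(space, anchor, offsets)
            if nodes is None or any(state.sigma[n] != 0 for n in nodes):
                continue
            state.ensure_capacity(rec.cell_id)
            state.sigma[nodes] = rec.cell_id
            ok = True
            break
        if not ok:
            raise CrowdingError(
                f"no room for cell {rec.cell_id} after {max_retries} tries")

    return recompute_statistics(space, state)
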