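"""Delta-compressed recording, reconstruction, model save/load, exports.

A simulation is recorded as its initial snapshot plus ordered per-MCS deltas
(accepted flips and discrete events), not as full copies of the grid at every
timepoint — storage grows with the number of accepted flips, not with
duration x grid size.  Any past state is reconstructed by replaying deltas
forward from the nearest prior checkpoint, bit-exactly.

File containers are HDF5 (single file, versioned with a magic string); model
specifications are also expressible as TOML config files readable by the CLI.
"""

from __future__ import annotations

import io
import json

import numpy as np

from .cell_state import (
    CellTable,
    LatticeState,
    heterotypic_boundary_length,
    recompute_statistics,
)
from .errors import ConfigurationError, LoadError
from .lattice_graph import SpaceGraph, build_from_mask, build_rectangular

__all__ = [
    "History", "reconstruct", "export_summary",
    "save_history", "load_history", "save_model", "load_model",
    "model_from_config", "dump_toml", "export_frame_csv", "export_frame_png",
]

HISTORY_MAGIC = "pottsgraph-history"
MODEL_MAGIC = "pottsgraph-model"
FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# history


class History:
    """Initial snapshot + ordered deltas + periodic full checkpoints.

    Per MCS m (1-based) the record holds the accepted flips, in order, as
    (node, old id, new id) arrays, followed by the discrete events (division,
    death) of that MCS.  Replaying records 1..m from the initial snapshot
    reproduces the live state at MCS m exactly.
    """

    def __init__(self, space: SpaceGraph, state: LatticeState,
                 table: CellTable, checkpoint_every: int = 100):
        self.space = space
        self.space_spec = space.spec()
        self.mask = None
        if space.is_mask:
            self.mask = (space._id_grid >= 0)
        self.initial_sigma = state.sigma.copy()
        self.initial_table = table.to_dict()
        self.checkpoint_every = int(checkpoint_every)
        self.flip_nodes: list[np.ndarray] = []
        self.flip_olds: list[np.ndarray] = []
        self.flip_news: list[np.ndarray] = []
        self.events: list[list[dict]] = []
        self.ode_samples: list[dict | None] = []
        self.checkpoints: dict[int, tuple[np.ndarray, dict]] = {}

    @property
    def n_mcs(self) -> int:
        return len(self.flip_nodes)

    @property
    def n_recorded_flips(self) -> int:
        return int(sum(a.size for a in self.flip_nodes))

    def append_mcs(self, nodes, olds, news, events, ode_sample=None) -> None:
        self.flip_nodes.append(np.asarray(nodes, dtype=np.int32))
        self.flip_olds.append(np.asarray(olds, dtype=np.int32))
        self.flip_news.append(np.asarray(news, dtype=np.int32))
        self.events.append(list(events))
        self.ode_samples.append(ode_sample)

    def add_checkpoint(self, mcs: int, state: LatticeState,
                       table: CellTable) -> None:
        self.checkpoints[int(mcs)] = (state.sigma.copy(), table.to_dict())


def _apply_mcs(sigma: np.ndarray, table: CellTable, history: History,
               mcs: int) -> None:
    """Apply the deltas of MCS `mcs` (1-based) in recorded order."""
    i = mcs - 1
    nodes = history.flip_nodes[i]
    news = history.flip_news[i]
    for n, w in zip(nodes, news):
        sigma[n] = w
    for ev in history.events[i]:
        if ev["kind"] == "division":
            parent, daughter = ev["parent"], ev["daughter"]
            sigma[np.asarray(ev["nodes"], dtype=np.int64)] = daughter
            row = ev["daughter_row"]
            table.add_cell(row["type"], row["target_volume"],
                           row["target_perimeter"], row["properties"],
                           cell_id=daughter)
            prec = table[parent]
            prec.properties = dict(ev["parent_properties"])
            prec.target_volume = float(ev["parent_target_volume"])
            table.target_volume_array[parent] = prec.target_volume
        elif ev["kind"] == "death":
            sigma[np.asarray(ev["nodes"], dtype=np.int64)] = 0
            table.remove_cell(ev["cell"])


def reconstruct(history: History, mcs: int):
    """State and table exactly as the live simulation held them at `mcs`.

    Uses the nearest prior checkpoint, then replays deltas forward.
    """
    if not 0 <= mcs <= history.n_mcs:
        raise IndexError(
            f"mcs {mcs} outside recorded range 0..{history.n_mcs}")
    cps = [m for m in history.checkpoints if m <= mcs]
    if cps:
        start = max(cps)
        sigma, table_dict = history.checkpoints[start]
        sigma = sigma.copy()
        table = CellTable.from_dict(table_dict)
    else:
        start = 0
        sigma = history.initial_sigma.copy()
        table = CellTable.from_dict(history.initial_table)
    for m in range(start + 1, mcs + 1):
        _apply_mcs(sigma, table, history, m)
    state = LatticeState(sigma.size)
    state.sigma = sigma
    recompute_statistics(history.space, state)
    return state, table


def export_summary(history: History, path=None):
    """Per-MCS time series: cell count, per-type mean volume, heterotypic
    boundary length, and (when recorded) intracellular totals.

    Computed by a single forward replay of the deltas.  Returns a DataFrame;
    writes CSV when `path` is given.
    """
    import pandas as pd

    space = history.space
    sigma = history.initial_sigma.copy()
    table = CellTable.from_dict(history.initial_table)
    type_names = sorted(table.type_names, key=table.type_names.get)

    rows = []

    def snapshot(mcs, ode_sample):
        state = LatticeState(sigma.size)
        state.sigma = sigma
        vol = np.bincount(sigma[sigma > 0]) if (sigma > 0).any() else np.array([0])
        row = {"mcs": mcs, "n_cells": len(table),
               "hetero_boundary": heterotypic_boundary_length(
                   space, state, table, by="type")}
        for tname in type_names:
            vols = [vol[c] if c < vol.size else 0
                    for c in table.cell_ids
                    if table[c].type_name == tname]
            row[f"mean_volume_{tname}"] = float(np.mean(vols)) if vols else 0.0
        if ode_sample is not None:
            arr = np.asarray(list(ode_sample.values()), dtype=float)
            for comp in range(arr.shape[1] if arr.size else 0):
                row[f"ode_total_{comp}"] = float(arr[:, comp].sum())
        rows.append(row)

    snapshot(0, None)
    for m in range(1, history.n_mcs + 1):
        _apply_mcs(sigma, table, history, m)
        snapshot(m, history.ode_samples[m - 1])
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# space / penalty (de)serialization helpers


def _space_from_spec(spec: dict, mask=None) -> SpaceGraph:
    if "dims" in spec:
        return build_rectangular(spec["dims"], tuple(spec["periodic"]),
                                 spec["connectivity"], spec["interaction"])
    if mask is None:
        raise LoadError("mask-based space requires the stored mask")
    return build_from_mask(mask, spec["connectivity"], spec["interaction"])


def _penalties_from_config(blocks, space):
    from .penalties import PENALTY_KINDS

    out = []
    for blk in blocks:
        blk = dict(blk)
        kind = blk.pop("kind")
        if kind not in PENALTY_KINDS:
            raise ConfigurationError(f"unknown penalty {kind!r}")
        cls = PENALTY_KINDS[kind]
        if kind == "adhesion":
            pen = cls(np.asarray(blk["J"], dtype=np.float64))
        elif kind in ("volume", "perimeter"):
            pen = cls(blk["lambda"])
        elif kind == "act":
            pen = cls(blk["lambda"], blk["max_act"])
        elif kind == "chemotaxis":
            field = blk.get("field")
            if field is None:
                field = np.zeros(space.n_nodes)
            pen = cls(blk["lambda"], np.asarray(field, dtype=np.float64))
        pen.bind(space)
        out.append(pen)
    return out


def _json_attr(obj) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    return json.dumps(obj, default=default)


# ---------------------------------------------------------------------------
# history files


def save_history(history: History, path) -> None:
    import h5py

    flat_nodes = (np.concatenate(history.flip_nodes)
                  if history.flip_nodes else np.empty(0, np.int32))
    flat_olds = (np.concatenate(history.flip_olds)
                 if history.flip_olds else np.empty(0, np.int32))
    flat_news = (np.concatenate(history.flip_news)
                 if history.flip_news else np.empty(0, np.int32))
    offsets = np.zeros(history.n_mcs + 1, dtype=np.int64)
    np.cumsum([a.size for a in history.flip_nodes], out=offsets[1:])

    with h5py.File(path, "w") as f:
        f.attrs["magic"] = HISTORY_MAGIC
        f.attrs["version"] = FORMAT_VERSION
        f.attrs["space_spec"] = _json_attr(history.space_spec)
        f.attrs["checkpoint_every"] = history.checkpoint_every
        if history.mask is not None:
            f.create_dataset("mask", data=history.mask.astype(np.uint8))
        f.create_dataset("initial/sigma", data=history.initial_sigma)
        f.create_dataset("initial/table",
                         data=np.bytes_(_json_attr(history.initial_table)))
        g = f.create_group("flips")
        g.create_dataset("nodes", data=flat_nodes)
        g.create_dataset("olds", data=flat_olds)
        g.create_dataset("news", data=flat_news)
        g.create_dataset("offsets", data=offsets)
        f.create_dataset("events", data=np.bytes_(_json_attr(history.events)))
        f.create_dataset("ode_samples",
                         data=np.bytes_(_json_attr(history.ode_samples)))
        cg = f.create_group("checkpoints")
        for m, (sig, tdict) in history.checkpoints.items():
            sg = cg.create_group(str(m))
            sg.create_dataset("sigma", data=sig)
            sg.create_dataset("table", data=np.bytes_(_json_attr(tdict)))


def load_history(path) -> History:
    import h5py

    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise LoadError(f"cannot open history file: {exc}") from exc
    with f:
        if f.attrs.get("magic") != HISTORY_MAGIC:
            raise LoadError("not a history file (bad magic string)")
        if int(f.attrs.get("version", -1)) != FORMAT_VERSION:
            raise LoadError(f"unsupported history version {f.attrs.get('version')}")
        spec = json.loads(f.attrs["space_spec"])
        mask = f["mask"][...].astype(bool) if "mask" in f else None
        space = _space_from_spec(spec, mask)
        sigma0 = f["initial/sigma"][...]
        table0 = json.loads(bytes(f["initial/table"][()]).decode())
        state0 = LatticeState(sigma0.size)
        state0.sigma = sigma0.copy()
        hist = History(space, state0, CellTable.from_dict(table0),
                       checkpoint_every=int(f.attrs["checkpoint_every"]))
        hist.initial_table = table0
        nodes = f["flips/nodes"][...]
        olds = f["flips/olds"][...]
        news = f["flips/news"][...]
        offsets = f["flips/offsets"][...]
        for i in range(offsets.size - 1):
            lo, hi = offsets[i], offsets[i + 1]
            hist.flip_nodes.append(nodes[lo:hi])
            hist.flip_olds.append(olds[lo:hi])
            hist.flip_news.append(news[lo:hi])
        hist.events = json.loads(bytes(f["events"][()]).decode())
        ode = json.loads(bytes(f["ode_samples"][()]).decode())
        hist.ode_samples = [
            None if s is None else {int(k): v for k, v in s.items()}
            for s in ode]
        for m in f["checkpoints"]:
            sg = f["checkpoints"][m]
            hist.checkpoints[int(m)] = (
                sg["sigma"][...],
                json.loads(bytes(sg["table"][()]).decode()))
    return hist


# ---------------------------------------------------------------------------
# model files


def save_model(model, path) -> None:
    """Persist the full live model; loading resumes the exact trajectory."""
    import h5py

    pens = []
    act_activity = None
    chem_field = None
    for pen in model.penalties:
        cfg = pen.config()
        if cfg is None:
            raise ConfigurationError(
                "custom penalties cannot be serialized; save a config instead")
        pens.append(cfg)
        if cfg["kind"] == "act":
            act_activity = pen.activity
        if cfg["kind"] == "chemotaxis":
            chem_field = pen.field

    with h5py.File(path, "w") as f:
        f.attrs["magic"] = MODEL_MAGIC
        f.attrs["version"] = FORMAT_VERSION
        f.attrs["space_spec"] = _json_attr(model.space.spec())
        if model.space.is_mask:
            f.create_dataset("mask",
                             data=(model.space._id_grid >= 0).astype(np.uint8))
        f.create_dataset("sigma", data=model.state.sigma)
        f.create_dataset("table", data=np.bytes_(_json_attr(model.table.to_dict())))
        f.attrs["penalties"] = _json_attr(pens)
        if act_activity is not None:
            f.create_dataset("act_activity", data=act_activity)
        if chem_field is not None:
            f.create_dataset("chem_field", data=chem_field)
        f.attrs["params"] = _json_attr({
            "temperature": model.params.temperature,
            "flips_per_mcs": model.params.flips_per_mcs,
            "rng_seed": model.params.rng_seed,
        })
        f.attrs["options"] = _json_attr({
            "checkpoint_every": model.checkpoint_every,
            "halve_target_on_division": model.halve_target_on_division,
            "stochastic_division": model.stochastic_division,
            "record_ode": model.record_ode,
            "compiled": model.compiled,
            "mcs": model.mcs,
            "t": model.t,
        })
        f.attrs["rng"] = _json_attr({
            "flip": model.flip_rng.bit_generator.state,
            "event": model.event_rng.bit_generator.state,
            "placement": model.placement_rng.bit_generator.state,
            "kernel": int(model.kernel_rng_state[0]),
        })
        intra = model.intracellular
        if intra is not None:
            cfg = intra.config()
            if cfg is None:
                raise ConfigurationError(
                    "custom intracellular rhs cannot be serialized")
            f.attrs["ode"] = _json_attr({
                **cfg,
                "n_components": intra.n_components,
                "conserved": intra.conserved,
                "mcs_duration": intra.mcs_duration,
                "rtol": intra.rtol, "atol": intra.atol,
                "events": [
                    {"component": e.component, "threshold": e.threshold,
                     "direction": e.direction, "action": e.action}
                    for e in intra.events],
            })
            ids = sorted(intra.state_of)
            f.create_dataset("ode_ids", data=np.asarray(ids, dtype=np.int64))
            f.create_dataset("ode_states", data=np.asarray(
                [intra.state_of[i] for i in ids], dtype=np.float64).reshape(
                    len(ids), intra.n_components))


def load_model(path):
    import h5py

    from .engine import Model, ModelParams
    from .ode_coupling import IntracellularModel, ThresholdEvent, make_rhs

    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise LoadError(f"cannot open model file: {exc}") from exc
    with f:
        if f.attrs.get("magic") != MODEL_MAGIC:
            raise LoadError("not a model file (bad magic string)")
        if int(f.attrs.get("version", -1)) != FORMAT_VERSION:
            raise LoadError(f"unsupported model version {f.attrs.get('version')}")
        spec = json.loads(f.attrs["space_spec"])
        mask = f["mask"][...].astype(bool) if "mask" in f else None
        space = _space_from_spec(spec, mask)
        table = CellTable.from_dict(json.loads(bytes(f["table"][()]).decode()))
        sigma = f["sigma"][...]
        state = LatticeState(sigma.size)
        state.sigma = sigma.copy()
        recompute_statistics(space, state)
        pen_cfg = json.loads(f.attrs["penalties"])
        if "chem_field" in f:
            for blk in pen_cfg:
                if blk["kind"] == "chemotaxis":
                    blk["field"] = f["chem_field"][...]
        penalties = _penalties_from_config(pen_cfg, space)
        if "act_activity" in f:
            for pen in penalties:
                if getattr(pen, "kind", None) == "act":
                    pen.activity = f["act_activity"][...].astype(np.int32)
        prm = json.loads(f.attrs["params"])
        params = ModelParams(prm["temperature"], prm["flips_per_mcs"],
                             prm["rng_seed"])
        opts = json.loads(f.attrs["options"])
        intra = None
        if "ode" in f.attrs:
            ocfg = json.loads(f.attrs["ode"])
            rhs = make_rhs(ocfg["rhs"], alpha=ocfg.get("alpha", 0.1))
            intra = IntracellularModel(
                rhs, n_components=ocfg["n_components"],
                events=[ThresholdEvent(e["component"], e["threshold"],
                                       e["direction"], e["action"])
                        for e in ocfg["events"]],
                conserved=ocfg["conserved"],
                mcs_duration=ocfg["mcs_duration"],
                rtol=ocfg["rtol"], atol=ocfg["atol"],
                config={"rhs": ocfg["rhs"], "alpha": ocfg.get("alpha", 0.1)})
            if "ode_ids" in f:
                ids = f["ode_ids"][...]
                states = f["ode_states"][...]
                intra.state_of = {int(i): states[k].copy()
                                  for k, i in enumerate(ids)}
        model = Model(space, state, table, penalties, params,
                      intracellular=intra,
                      checkpoint_every=opts["checkpoint_every"],
                      halve_target_on_division=opts["halve_target_on_division"],
                      stochastic_division=opts["stochastic_division"],
                      record_ode=opts["record_ode"],
                      compiled=opts["compiled"])
        model.mcs = int(opts["mcs"])
        model.t = float(opts["t"])
        rng = json.loads(f.attrs["rng"])
        model.flip_rng.bit_generator.state = rng["flip"]
        model.event_rng.bit_generator.state = rng["event"]
        model.placement_rng.bit_generator.state = rng["placement"]
        model.kernel_rng_state[0] = np.uint64(rng["kernel"])
    return model


# ---------------------------------------------------------------------------
# TOML config


def dump_toml(d: dict) -> str:
    """Emit the restricted config schema (scalars, lists, nested tables,
    arrays of tables) as TOML text."""

    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, (int, float, np.integer, np.floating)):
            return repr(float(v)) if isinstance(v, (float, np.floating)) else str(int(v))
        if isinstance(v, str):
            return json.dumps(v)
        if isinstance(v, (list, tuple, np.ndarray)):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        raise TypeError(f"cannot serialize {type(v)} to TOML")

    out = io.StringIO()

    def emit(prefix, table):
        scalars = {k: v for k, v in table.items()
                   if not isinstance(v, dict)
                   and not (isinstance(v, list) and v
                            and isinstance(v[0], dict))}
        if prefix and (scalars or not table):
            out.write(f"[{prefix}]\n")
        for k, v in scalars.items():
            out.write(f"{k} = {fmt(v)}\n")
        if scalars:
            out.write("\n")
        for k, v in table.items():
            if isinstance(v, dict):
                emit(f"{prefix}.{k}" if prefix else k, v)
            elif isinstance(v, list) and v and isinstance(v[0], dict):
                name = f"{prefix}.{k}" if prefix else k
                for item in v:
                    out.write(f"[[{name}]]\n")
                    for kk, vv in item.items():
                        out.write(f"{kk} = {fmt(vv)}\n")
                    out.write("\n")

    emit("", d)
    return out.getvalue()


def parse_config(source) -> dict:
    """Config dict from TOML text, a path, or a dict (passed through)."""
    import tomllib

    if isinstance(source, dict):
        return source
    text = source
    try:
        if "\n" not in str(source) and not str(source).lstrip().startswith("["):
            with open(source, "rb") as fh:
                return tomllib.load(fh)
    except (OSError, TypeError):
        pass
    return tomllib.loads(text)


def model_from_config(source, *, seed=None, overrides=None):
    """Build a ready-to-run Model from a config (TOML path/text or dict).

    Blocks: [space], [[cells.groups]], [penalties.*], [engine], [ode],
    [recording].  Returns (model, n_mcs).
    """
    from .engine import Model, ModelParams, derived_rngs
    from .cell_state import initialize_cells
    from .ode_coupling import IntracellularModel, ThresholdEvent, make_rhs

    cfg = dict(parse_config(source))
    if overrides:
        for key, val in overrides.items():
            sect, _, name = key.partition(".")
            cfg.setdefault(sect, {})[name] = val

    sp = cfg.get("space", {})
    if "mask" in sp:
        from .lattice_graph import load_mask_csv, load_mask_png

        p = str(sp["mask"])
        mask = load_mask_png(p) if p.endswith(".png") else load_mask_csv(p)
        space = build_from_mask(mask, sp.get("connectivity", "von_neumann"),
                                sp.get("interaction", "moore"))
    else:
        space = build_rectangular(sp.get("dims", [50, 50]),
                                  sp.get("periodic", True),
                                  sp.get("connectivity", "von_neumann"),
                                  sp.get("interaction", "moore"))

    cells = cfg.get("cells", {})
    table = CellTable.from_groups(cells.get("groups", []),
                                  cells.get("conserved", ()))

    pen_blocks = []
    for kind, blk in cfg.get("penalties", {}).items():
        pen_blocks.append({"kind": kind, **blk})
    penalties = _penalties_from_config(pen_blocks, space)

    eng = cfg.get("engine", {})
    if seed is None:
        seed = int(eng.get("seed", 0))
    params = ModelParams(float(eng.get("temperature", 20.0)),
                         eng.get("flips_per_mcs"), int(seed))
    n_mcs = int(eng.get("mcs", 100))

    intra = None
    if "ode" in cfg:
        o = cfg["ode"]
        rhs = make_rhs(o.get("rhs", "exponential"), alpha=o.get("alpha", 0.1))
        x0 = o.get("x0", [0.0, 0.5])

        def init_state(rec, rng, _lo=float(x0[0]), _hi=float(x0[1])):
            return np.array([rng.uniform(_lo, _hi)])

        intra = IntracellularModel(
            rhs, n_components=1,
            events=[ThresholdEvent(0, float(o.get("threshold", 1.0)), 1,
                                   "divide")],
            conserved=[bool(o.get("conserved", True))],
            mcs_duration=float(o.get("mcs_duration", 1.0)),
            rtol=float(o.get("rtol", 1e-6)),
            init_state=init_state, config=rhs.config)

    rec_blk = cfg.get("recording", {})
    place_rng, _, _, _ = derived_rngs(params.rng_seed)
    state = initialize_cells(space, table, rng=place_rng)
    model = Model(space, state, table, penalties, params, intracellular=intra,
                  checkpoint_every=int(rec_blk.get("checkpoint_every", 100)),
                  halve_target_on_division=bool(
                      cfg.get("division", {}).get("halve_target", False)),
                  stochastic_division=bool(
                      cfg.get("division", {}).get("stochastic", False)))
    return model, n_mcs


# ---------------------------------------------------------------------------
# frame export


def _sigma_grid(space: SpaceGraph, state: LatticeState) -> np.ndarray:
    """Grid of cell ids in lattice layout; -1 marks background (mask only)."""
    grid = np.full(space.shape, -1, dtype=np.int64)
    fg = space._id_grid >= 0
    grid[fg] = state.sigma[space._id_grid[fg]]
    return grid


def export_frame_csv(space, state, path) -> None:
    grid = _sigma_grid(space, state)
    if grid.ndim == 3:
        grid = grid.reshape(grid.shape[0] * grid.shape[1], grid.shape[2])
    np.savetxt(path, grid, fmt="%d", delimiter=",")


def export_frame_png(space, state, path) -> None:
    """Ids mapped to colors deterministically (medium black, background grey)."""
    from PIL import Image
    from matplotlib import colormaps

    grid = _sigma_grid(space, state)
    if grid.ndim == 3:
        grid = grid[grid.shape[0] // 2]
    cmap = colormaps["tab20"]
    rgb = np.zeros(grid.shape + (3,), dtype=np.uint8)
    ids = np.unique(grid)
    for cid in ids:
        m = grid == cid
        if cid < 0:
            rgb[m] = (80, 80, 80)
        elif cid == 0:
            rgb[m] = (0, 0, 0)
        else:
            rgb[m] = tuple(int(255 * c) for c in cmap((int(cid) - 1) % 20)[:3])
    Image.fromarray(rgb).save(path)
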