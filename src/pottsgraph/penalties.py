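"""Composable energy terms.

Each penalty computes the exact change dH induced by one proposed node flip
(the ``delta`` contract, pure) and may keep internal state that is updated
only when a flip is accepted (``after_accept``).  The Metropolis loop is
penalty-agnostic: summing deltas over any list of Penalty objects gives the
total dH.  User-defined penalties subclass :class:`Penalty`.

Built-in terms and their conventions
------------------------------------

adhesion      H = sum over interaction-order pairs {i, j} of
              J[tau(sigma_i), tau(sigma_j)] * (1 - delta(sigma_i, sigma_j));
              J is symmetric, indexed by type, with index 0 = medium.
volume        H = sum_c lambda_v(tau_c) * (v_c - V_c)^2 over cells (not medium).
perimeter     Same quadratic form on the heterotypic-edge count p_c.
migration     Act model: recently gained sites carry an activity counter that
              decays by 1 per MCS from max_act; a copy from source u into
              target n is biased by
              dH = -(lambda_act / max_act) * (GM(u) - GM(n)),
              GM = geometric mean of activity over the node and its same-cell
              connectivity neighbors.
chemotaxis    dH = -lambda_chem(tau_gainer) * (c(target) - c(source)); positive
              lambda moves cells up-gradient.  The field is supplied, static
              or externally updated.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError
from .cell_state import CellTable, LatticeState
from .lattice_graph import SpaceGraph

__all__ = [
    "Penalty",
    "AdhesionPenalty",
    "VolumePenalty",
    "PerimeterPenalty",
    "ActMigrationPenalty",
    "ChemotaxisPenalty",
    "delta_adhesion",
    "delta_volume",
    "delta_perimeter",
    "delta_act",
    "delta_chemotaxis",
    "total_delta",
    "per_type_array",
]


def per_type_array(value, n_types: int, medium_zero: bool = False) -> np.ndarray:
    """Scalar or sequence -> float array indexed by type (0 = medium)."""
    out = np.zeros(n_types + 1, dtype=np.float64)
    if np.isscalar(value):
        out[:] = float(value)
        if medium_zero:
            out[0] = 0.0
    else:
        arr = np.asarray(value, dtype=np.float64)
        out[: arr.size] = arr
    return out


class Penalty:
    """Extension contract: a pure ``delta`` plus an ``after_accept`` hook."""

    def delta(self, space, state, table, proposal) -> float:
        raise NotImplementedError

    def after_accept(self, space, state, table, proposal) -> None:
        """Called exactly once per accepted proposal (after the flip)."""

    def on_mcs_end(self, space, state, table) -> None:
        """Called once at the end of every Monte Carlo step."""

    def bind(self, space: SpaceGraph) -> None:
        """Attach to a space (allocate per-node buffers if needed)."""

    def config(self) -> dict | None:
        """Named parameter block for serialization; None if not serializable."""
        return None


# ---------------------------------------------------------------------------
# free functions (one per energy term)


def delta_adhesion(space, state, table, proposal, J) -> float:
    """Adhesion dH of one flip, summed over the flipped node's interaction
    neighborhood only (all other contacts are unchanged)."""
    J = np.asarray(J, dtype=np.float64)
    sigma = state.sigma
    old, new = proposal.old_id, proposal.new_id
    t_old, t_new = table.type_of(old), table.type_of(new)
    if max(t_old, t_new) >= J.shape[0]:
        raise ConfigurationError(
            f"J matrix of dim {J.shape[0]} too small for type index "
            f"{max(t_old, t_new)}")
    dh = 0.0
    for v in space.inter[proposal.target_node]:
        if v < 0:
            continue
        s = int(sigma[v])
        t = table.type_of(s)
        if t >= J.shape[0]:
            raise ConfigurationError(f"type index {t} outside J matrix")
        if s != new:
            dh += J[t_new, t]
        if s != old:
            dh -= J[t_old, t]
    return dh


def delta_volume(state, table, proposal, lambda_volume) -> float:
    """Quadratic volume dH over the (at most two) cells whose volume changes."""
    lam = np.asarray(lambda_volume, dtype=np.float64)
    dh = 0.0
    for cid, dv in ((proposal.old_id, -1), (proposal.new_id, +1)):
        if cid == 0:
            continue
        t = table.type_of(cid)
        lv = float(lam[t]) if lam.ndim else float(lam)
        v = float(state.volume[cid])
        target = float(table.target_volume_array[cid])
        dh += lv * ((v + dv - target) ** 2 - (v - target) ** 2)
    return dh


def _local_counts(space, sigma, node, old, new):
    cnt_old = cnt_new = k = 0
    for v in space.inter[node]:
        if v < 0:
            continue
        k += 1
        s = sigma[v]
        if s == old:
            cnt_old += 1
        if s == new:
            cnt_new += 1
    return cnt_old, cnt_new, k


def delta_perimeter(space, state, table, proposal, lambda_perimeter) -> float:
    """Quadratic perimeter dH; perimeter counts heterotypic interaction edges.

    Only the losing and gaining cells' perimeters change: for any third cell
    the flipped node is foreign both before and after.
    """
    lam = np.asarray(lambda_perimeter, dtype=np.float64)
    old, new = proposal.old_id, proposal.new_id
    cnt_old, cnt_new, k = _local_counts(space, state.sigma,
                                        proposal.target_node, old, new)
    dh = 0.0
    for cid, dp in ((old, 2 * cnt_old - k), (new, k - 2 * cnt_new)):
        if cid == 0:
            continue
        t = table.type_of(cid)
        lp = float(lam[t]) if lam.ndim else float(lam)
        if lp == 0.0:
            continue
        target = float(table.target_perimeter_array[cid])
        if np.isnan(target):
            raise ConfigurationError(
                f"cell {cid} has no target_perimeter but a perimeter penalty")
        p = float(state.perimeter[cid])
        dh += lp * ((p + dp - target) ** 2 - (p - target) ** 2)
    return dh


def _act_gm(space, sigma, activity, node) -> float:
    """Geometric mean of activity over node + same-cell connectivity neighbors;
    medium nodes have no activity (GM = 0)."""
    cid = sigma[node]
    if cid == 0:
        return 0.0
    prod = float(activity[node])
    cnt = 1
    for v in space.conn[node]:
        if v >= 0 and sigma[v] == cid:
            prod *= float(activity[v])
            cnt += 1
    return prod ** (1.0 / cnt)


def delta_act(space, state, proposal, activity, lambda_act, max_act) -> float:
    if lambda_act == 0.0:
        return 0.0
    gm_src = _act_gm(space, state.sigma, activity, proposal.source_node)
    gm_tgt = _act_gm(space, state.sigma, activity, proposal.target_node)
    return -(float(lambda_act) / float(max_act)) * (gm_src - gm_tgt)


def delta_chemotaxis(state, table, proposal, field, lambda_chem) -> float:
    lam = np.asarray(lambda_chem, dtype=np.float64)
    t_new = table.type_of(proposal.new_id)
    lv = float(lam[t_new]) if lam.ndim else (float(lam) if t_new else 0.0)
    if lv == 0.0:
        return 0.0
    c_t = float(field[proposal.target_node])
    c_s = float(field[proposal.source_node])
    return -lv * (c_t - c_s)


def total_delta(penalties, space, state, table, proposal) -> float:
    """Sum of individual deltas; order-independent by construction."""
    return sum(sorted(p.delta(space, state, table, proposal) for p in penalties))


# ---------------------------------------------------------------------------
# penalty objects


class AdhesionPenalty(Penalty):
    """Contact-energy penalty with a symmetric type-indexed J matrix."""

    kind = "adhesion"

    def __init__(self, J):
        J = np.asarray(J, dtype=np.float64)
        if J.ndim != 2 or J.shape[0] != J.shape[1]:
            raise ConfigurationError("J must be a square matrix")
        if not np.allclose(J, J.T):
            raise ConfigurationError("J must be symmetric")
        self.J = J

    def delta(self, space, state, table, proposal) -> float:
        return delta_adhesion(space, state, table, proposal, self.J)

    def config(self):
        return {"kind": self.kind, "J": self.J.tolist()}


class VolumePenalty(Penalty):
    kind = "volume"

    def __init__(self, lambda_volume):
        lam = np.asarray(lambda_volume, dtype=np.float64)
        if np.any(lam < 0):
            raise ConfigurationError("lambda_volume must be nonnegative")
        self.lambda_volume = lambda_volume

    def delta(self, space, state, table, proposal) -> float:
        return delta_volume(state, table, proposal, self.lambda_volume)

    def config(self):
        lam = self.lambda_volume
        return {"kind": self.kind,
                "lambda": lam if np.isscalar(lam) else np.asarray(lam).tolist()}


class PerimeterPenalty(Penalty):
    kind = "perimeter"

    def __init__(self, lambda_perimeter):
        lam = np.asarray(lambda_perimeter, dtype=np.float64)
        if np.any(lam < 0):
            raise ConfigurationError("lambda_perimeter must be nonnegative")
        self.lambda_perimeter = lambda_perimeter

    def delta(self, space, state, table, proposal) -> float:
        return delta_perimeter(space, state, table, proposal,
                               self.lambda_perimeter)

    def config(self):
        lam = self.lambda_perimeter
        return {"kind": self.kind,
                "lambda": lam if np.isscalar(lam) else np.asarray(lam).tolist()}


class ActMigrationPenalty(Penalty):
    """Act-model random migration: protrusive memory with decay.

    A node gained by a cell is stamped with activity ``max_act``; activities
    decay by 1 per MCS (floored at 0).  Copies from high-activity into
    low-activity regions are favored, producing persistent random motion.
    """

    kind = "act"

    def __init__(self, lambda_act, max_act):
        if max_act < 1:
            raise ConfigurationError("max_act must be a positive integer")
        if lambda_act < 0:
            raise ConfigurationError("lambda_act must be nonnegative")
        self.lambda_act = float(lambda_act)
        self.max_act = int(max_act)
        self.activity = None

    def bind(self, space: SpaceGraph) -> None:
        if self.activity is None or self.activity.size != space.n_nodes:
            self.activity = np.zeros(space.n_nodes, dtype=np.int32)

    def delta(self, space, state, table, proposal) -> float:
        if self.activity is None:
            self.bind(space)
        return delta_act(space, state, proposal, self.activity,
                         self.lambda_act, self.max_act)

    def after_accept(self, space, state, table, proposal) -> None:
        self.activity[proposal.target_node] = (
            self.max_act if proposal.new_id != 0 else 0)

    def on_mcs_end(self, space, state, table) -> None:
        np.subtract(self.activity, 1, out=self.activity,
                    where=self.activity > 0)

    def config(self):
        return {"kind": self.kind, "lambda": self.lambda_act,
                "max_act": self.max_act}


class ChemotaxisPenalty(Penalty):
    """Linear gradient-following bias on a supplied concentration field."""

    kind = "chemotaxis"

    def __init__(self, lambda_chem, field):
        self.lambda_chem = lambda_chem
        field = np.asarray(field, dtype=np.float64).ravel()
        if not np.all(np.isfinite(field)):
            raise ConfigurationError("concentration field must be finite")
        self.field = field

    def delta(self, space, state, table, proposal) -> float:
        return delta_chemotaxis(state, table, proposal, self.field,
                                self.lambda_chem)

    def config(self):
        lam = self.lambda_chem
        return {"kind": self.kind,
                "lambda": lam if np.isscalar(lam) else np.asarray(lam).tolist()}


PENALTY_KINDS = {
    "adhesion": AdhesionPenalty,
    "volume": VolumePenalty,
    "perimeter": PerimeterPenalty,
    "act": ActMigrationPenalty,
    "chemotaxis": ChemotaxisPenalty,
}
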