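"""Per-cell ODEs coupled to the lattice through threshold events.

Every living cell carries a continuous state vector advanced between Monte
Carlo steps with adaptive, error-controlled integration (one MCS spans
``mcs_duration`` continuous time units).  Threshold-crossing events are
located by root-finding on the event component; integration stops at each
event, the discrete action fires (e.g. cell division, which changes the set
of state vectors mid-flight), and integration resumes.

Division semantics follow the conserved-quantity rule: the parent vector is
removed and each conserved component x is split into f*x and (1-f)*x with f
uniform on (0, 1); non-conserved components are copied to both daughters.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationFailureError

__all__ = ["ThresholdEvent", "IntracellularModel", "advance",
           "on_division_event", "make_rhs"]


@dataclass(frozen=True)
class ThresholdEvent:
    """Fire ``action`` when state[component] crosses ``threshold``.

    direction: +1 upward crossings, -1 downward, 0 both.
    """

    component: int = 0
    threshold: float = 1.0
    direction: int = 1
    action: str = "divide"

    def crossed(self, x) -> bool:
        v = float(x[self.component]) - self.threshold
        if self.direction > 0:
            return v >= 0.0
        if self.direction < 0:
            return v <= 0.0
        return v == 0.0


class IntracellularModel:
    """Cell id -> state vector map plus the shared dynamics definition.

    Parameters
    ----------
    rhs : callable(t, x, cell_record) -> dx/dt
    n_components : int
    events : sequence of ThresholdEvent
    conserved : sequence of bool per component (default: all conserved)
    mcs_duration : continuous time units per Monte Carlo step
    rtol, atol : adaptive integration tolerances
    init_state : callable(cell_record, rng) -> initial vector for a cell that
        has no state yet (founders); default all zeros.
    """

    def __init__(self, rhs, n_components=1, events=(), conserved=None,
                 mcs_duration=1.0, rtol=1e-6, atol=1e-9, init_state=None,
                 method="RK45", config=None):
        self.rhs = rhs
        self.n_components = int(n_components)
        self.events = list(events)
        if conserved is None:
            conserved = [True] * self.n_components
        self.conserved = list(conserved)
        self.mcs_duration = float(mcs_duration)
        self.rtol = float(rtol)
        self.atol = float(atol)
        self.init_state = init_state
        self.method = method
        self.state_of: dict[int, np.ndarray] = {}
        self._config = config  # serializable description for named rhs

    def ensure_states(self, table, rng) -> None:
        for cid in table.cell_ids:
            if cid not in self.state_of:
                if self.init_state is not None:
                    x = np.asarray(self.init_state(table[cid], rng),
                                   dtype=np.float64)
                else:
                    x = np.zeros(self.n_components)
                self.state_of[cid] = x

    def remove_cell(self, cell_id) -> None:
        self.state_of.pop(cell_id, None)

    def total(self, component: int = 0) -> float:
        return float(sum(x[component] for x in self.state_of.values()))

    def config(self):
        return self._config


def make_rhs(name: str, **params):
    """Built-in right-hand sides selectable by name.

    'constant'     dX/dt = alpha
    'exponential'  dX/dt = alpha * X
    """
    alpha = float(params.get("alpha", 0.1))
    if name == "constant":
        def rhs(t, x, rec):
            return np.full_like(np.asarray(x, dtype=float), alpha)
    elif name == "exponential":
        def rhs(t, x, rec):
            return alpha * np.asarray(x, dtype=float)
    else:
        raise ValueError(f"unknown rhs name {name!r}")
    rhs.config = {"rhs": name, "alpha": alpha}
    return rhs


def on_division_event(intracellular: IntracellularModel, parent_id,
                      daughters, rng) -> None:
    """Replace the parent's vector by two daughter vectors.

    Conserved components are split with a fresh uniform fraction per
    component, the totals preserved bitwise (integer-significand split);
    non-conserved components are copied.
    """
    from .division_death import random_split

    x = intracellular.state_of.pop(parent_id)
    d1, d2 = daughters
    x1 = np.empty_like(x)
    x2 = np.empty_like(x)
    for i, v in enumerate(x):
        if intracellular.conserved[i]:
            x1[i], x2[i] = random_split(float(v), rng)
        else:
            x1[i] = v
            x2[i] = v
    intracellular.state_of[d1] = x1
    intracellular.state_of[d2] = x2


def _event_funcs(events, suppressed, cell_id):
    funcs = []
    index = []
    for ei, e in enumerate(events):
        if (cell_id, ei) in suppressed:
            continue

        def g(t, y, _e=e):
            return float(y[_e.component]) - _e.threshold

        g.terminal = True
        g.direction = float(e.direction)
        funcs.append(g)
        index.append(ei)
    return funcs, index


def advance(intracellular: IntracellularModel, table, t_from: float,
            t_to: float, *, on_event=None, rng=None):
    """Integrate every cell's ODE over [t_from, t_to], firing events.

    ``on_event(cell_id, event, t)`` decides the discrete action:

    * return ``(d1, d2)``  — the cell divided on the grid; the state map is
      split via :func:`on_division_event` and both daughters continue
      integrating from the event time;
    * return ``"defer"``  — the action could not run (e.g. a 1-node cell);
      the state is kept and the event re-arms on the next advance call;
    * return ``None``      — event recorded, integration continues.

    Returns the fired events as dicts sorted by event time.
    """
    if t_to < t_from:
        raise ValueError("t_to must be >= t_from")
    if rng is None:
        rng = np.random.default_rng()
    events = intracellular.events
    fired: list[dict] = []
    suppressed: set = set()
    pending = deque((cid, t_from) for cid in sorted(intracellular.state_of))

    def fire(cid, ei, t):
        e = events[ei]
        outcome = on_event(cid, e, t) if on_event is not None else None
        fired.append({"t": float(t), "cell": int(cid),
                      "component": e.component, "action": e.action,
                      "outcome": "divided" if isinstance(outcome, tuple)
                      else (outcome or "fired")})
        if isinstance(outcome, tuple):
            on_division_event(intracellular, cid, outcome, rng)
            pending.append((outcome[0], t))
            pending.append((outcome[1], t))
            return "divided"
        suppressed.add((cid, ei))  # no refire within this interval
        return outcome

    while pending:
        cid, t = pending.popleft()
        if cid not in intracellular.state_of:
            continue
        rec = table[cid] if (table is not None and cid in table) else None
        divided = False
        while True:
            x = intracellular.state_of[cid]
            # events already beyond threshold (deferred earlier) fire now
            armed = next((ei for ei, e in enumerate(events)
                          if (cid, ei) not in suppressed and e.crossed(x)),
                         None)
            if armed is not None:
                if fire(cid, armed, t) == "divided":
                    divided = True
                    break
                continue
            if t >= t_to:
                break
            funcs, index = _event_funcs(events, suppressed, cid)
            sol = solve_ivp(lambda tt, yy: intracellular.rhs(tt, yy, rec),
                            (t, t_to), x, method=intracellular.method,
                            rtol=intracellular.rtol, atol=intracellular.atol,
                            events=funcs or None)
            if not sol.success or not np.all(np.isfinite(sol.y)):
                raise IntegrationFailureError(
                    f"ODE integration failed for cell {cid}: {sol.message}")
            if sol.status == 1:  # terminal event located by root-finding
                hits = [(te[0], k) for k, te in enumerate(sol.t_events) if te.size]
                te, k = min(hits)
                intracellular.state_of[cid] = sol.y_events[k][0].copy()
                t = float(te)
                if fire(cid, index[k], t) == "divided":
                    divided = True
                    break
            else:
                intracellular.state_of[cid] = sol.y[:, -1].copy()
                t = t_to
        if divided:
            continue
    fired.sort(key=lambda d: d["t"])
    return fired
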