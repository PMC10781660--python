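"""Energy terms: local deltas vs independent brute-force oracles."""

import numpy as np
import pytest

from conftest import (
    brute_act_gm,
    brute_adhesion_H,
    brute_perimeter_H,
    brute_volume_H,
    random_two_type_state,
)
from pottsgraph import (
    ActMigrationPenalty,
    AdhesionPenalty,
    ChemotaxisPenalty,
    PerimeterPenalty,
    Proposal,
    VolumePenalty,
    total_delta,
)
from pottsgraph.cell_state import apply_flip, recompute_statistics
from pottsgraph.errors import ConfigurationError
from pottsgraph.penalties import (
    delta_act,
    delta_adhesion,
    delta_chemotaxis,
    delta_perimeter,
    delta_volume,
)

J2 = np.array([[0.0, 8.0, 8.0], [8.0, 4.0, 11.0], [8.0, 11.0, 4.0]])


def random_proposal(space, state, rng):
    """A random adjacent heterotypic copy flip (fresh sampling, no engine)."""
    while True:
        node = int(rng.integers(space.n_nodes))
        nbr = int(space.conn[node, rng.integers(space.conn.shape[1])])
        if nbr >= 0 and state.sigma[node] != state.sigma[nbr]:
            return Proposal(node, nbr, int(state.sigma[node]),
                            int(state.sigma[nbr]))


def type_lookup(table):
    return lambda cid: table.type_of(cid)


class TestAdhesion:
    def test_zero_matrix_gives_zero_delta(self, rng):
        space, state, table = random_two_type_state(rng)
        p = random_proposal(space, state, rng)
        assert delta_adhesion(space, state, table, p, np.zeros((3, 3))) == 0.0

    def test_isolated_cell_dissolving_releases_all_contacts(self):
        # 1-node cell of type A in a closed von Neumann-interaction grid
        # interior: 4 heterotypic contacts at J=2 vanish -> dH = -8
        from pottsgraph import CellTable, LatticeState, build_rectangular

        space = build_rectangular((5, 5), periodic=False,
                                  interaction_order="von_neumann")
        table = CellTable()
        cid = table.add_cell("A", 1)
        state = LatticeState(space.n_nodes)
        center = space.node_at((2, 2))
        state.sigma[center] = cid
        recompute_statistics(space, state)
        J = np.array([[0.0, 2.0], [2.0, 0.0]])
        p = Proposal(center, space.node_at((2, 3)), cid, 0)
        assert delta_adhesion(space, state, table, p, J) == -8.0

    def test_local_delta_equals_full_hamiltonian_difference(self, rng):
        mism = 0.0
        for _ in range(300):
            space, state, table = random_two_type_state(rng)
            tlk = [0] + [table[c].type_index for c in table.cell_ids]
            p = random_proposal(space, state, rng)
            h0 = brute_adhesion_H(space, state.sigma, tlk, J2)
            after = state.sigma.copy()
            after[p.target_node] = p.new_id
            h1 = brute_adhesion_H(space, after, tlk, J2)
            mism = max(mism, abs(delta_adhesion(space, state, table, p, J2)
                                 - (h1 - h0)))
        assert mism <= 1e-9

    def test_type_index_outside_matrix_is_config_error(self, rng):
        space, state, table = random_two_type_state(rng)
        p = random_proposal(space, state, rng)
        with pytest.raises(ConfigurationError):
            delta_adhesion(space, state, table, p, np.zeros((1, 1)))


class TestVolume:
    def test_shrink_and_grow_from_target_are_symmetric(self):
        from pottsgraph import CellTable, LatticeState, build_rectangular

        space = build_rectangular((5, 5), periodic=False)
        table = CellTable()
        cid = table.add_cell("A", 5)
        state = LatticeState(space.n_nodes)
        state.sigma[:5] = cid
        recompute_statistics(space, state)
        lam = np.array([0.0, 1.0])
        shrink = Proposal(0, 5, cid, 0)
        grow = Proposal(5, 4, 0, cid)
        assert delta_volume(state, table, shrink, lam) == 1.0
        assert delta_volume(state, table, grow, lam) == 1.0

    def test_zero_weight_is_free(self, rng):
        space, state, table = random_two_type_state(rng)
        p = random_proposal(space, state, rng)
        assert delta_volume(state, table, p, np.zeros(3)) == 0.0

    def test_matches_full_recomputation(self, rng):
        lam = np.array([0.0, 1.0, 0.5])
        for _ in range(300):
            space, state, table = random_two_type_state(rng)
            p = random_proposal(space, state, rng)
            h0 = brute_volume_H(state.sigma, table, lam)
            after = state.sigma.copy()
            after[p.target_node] = p.new_id
            h1 = brute_volume_H(after, table, lam)
            assert abs(delta_volume(state, table, p, lam) - (h1 - h0)) <= 1e-9


class TestPerimeter:
    def test_zero_weight_is_free(self, rng):
        space, state, table = random_two_type_state(rng)
        p = random_proposal(space, state, rng)
        assert delta_perimeter(space, state, table, p, np.zeros(3)) == 0.0

    def test_matches_full_recomputation(self, rng):
        lam = np.array([0.0, 0.7, 1.3])
        for _ in range(300):
            space, state, table = random_two_type_state(rng)
            p = random_proposal(space, state, rng)
            h0 = brute_perimeter_H(space, state.sigma, table, lam)
            after = state.copy()
            apply_flip(space, after, p.target_node, p.old_id, p.new_id)
            h1 = brute_perimeter_H(space, after.sigma, table, lam)
            assert abs(delta_perimeter(space, state, table, p, lam)
                       - (h1 - h0)) <= 1e-9

    def test_missing_target_perimeter_is_config_error(self, rng):
        from pottsgraph import CellTable, LatticeState, build_rectangular

        space = build_rectangular((4, 4), periodic=False)
        table = CellTable()
        cid = table.add_cell("A", 4)  # no target_perimeter
        state = LatticeState(space.n_nodes)
        state.sigma[:4] = cid
        recompute_statistics(space, state)
        with pytest.raises(ConfigurationError):
            delta_perimeter(space, state, table, Proposal(0, 4, cid, 0),
                            np.array([0.0, 1.0]))


class TestAct:
    def _setup(self, rng):
        space, state, table = random_two_type_state(rng)
        activity = rng.integers(0, 21, size=space.n_nodes).astype(np.int32)
        return space, state, table, activity

    def test_zero_activity_or_weight_is_free(self, rng):
        space, state, table, activity = self._setup(rng)
        p = random_proposal(space, state, rng)
        assert delta_act(space, state, p, np.zeros_like(activity), 100.0, 20) == 0.0
        assert delta_act(space, state, p, activity, 0.0, 20) == 0.0

    def test_uniform_activity_is_symmetric(self, rng):
        space, state, table = random_two_type_state(rng)
        activity = np.full(space.n_nodes, 7, dtype=np.int32)
        for _ in range(50):
            p = random_proposal(space, state, rng)
            if p.old_id != 0 and p.new_id != 0:
                assert delta_act(space, state, p, activity, 50.0, 20) == pytest.approx(0.0)

    def test_matches_independent_geometric_means(self, rng):
        for _ in range(300):
            space, state, table, activity = self._setup(rng)
            p = random_proposal(space, state, rng)
            expect = -(50.0 / 20.0) * (
                (brute_act_gm(space, state.sigma, activity, p.source_node)
                 if p.new_id else 0.0)
                - (brute_act_gm(space, state.sigma, activity, p.target_node)
                   if p.old_id else 0.0))
            got = delta_act(space, state, p, activity, 50.0, 20)
            assert abs(got - expect) <= 1e-9


class TestChemotaxis:
    def test_uniform_field_and_zero_weight_are_free(self, rng):
        space, state, table = random_two_type_state(rng)
        p = random_proposal(space, state, rng)
        assert delta_chemotaxis(state, table, p, np.full(space.n_nodes, 3.3),
                                np.array([0.0, 2.0, 2.0])) == 0.0
        assert delta_chemotaxis(state, table, p,
                                np.arange(space.n_nodes, dtype=float),
                                np.zeros(3)) == 0.0

    def test_upgradient_extension_is_favored(self, rng):
        for _ in range(200):
            space, state, table = random_two_type_state(rng)
            field = space.coords[:, 1].astype(float)  # increases with column
            p = random_proposal(space, state, rng)
            if p.new_id == 0:
                continue
            dh = delta_chemotaxis(state, table, p, field,
                                  np.array([0.0, 2.0, 2.0]))
            gain = field[p.target_node] - field[p.source_node]
            if gain > 0:
                assert dh < 0
            elif gain < 0:
                assert dh > 0


class TestComposition:
    def test_empty_list_is_zero(self, rng):
        space, state, table = random_two_type_state(rng)
        p = random_proposal(space, state, rng)
        assert total_delta([], space, state, table, p) == 0.0

    def test_additivity_and_permutation_invariance(self, rng):
        adh = AdhesionPenalty(J2)
        vol = VolumePenalty(np.array([0.0, 1.0, 0.5]))
        per = PerimeterPenalty(np.array([0.0, 0.3, 0.3]))
        for _ in range(100):
            space, state, table = random_two_type_state(rng)
            p = random_proposal(space, state, rng)
            parts = [pen.delta(space, state, table, p) for pen in (adh, vol, per)]
            t1 = total_delta([adh, vol, per], space, state, table, p)
            t2 = total_delta([per, adh, vol], space, state, table, p)
            assert t1 == t2  # bit-identical under permutation
            assert t1 == pytest.approx(sum(parts), abs=1e-12)

    def test_flip_between_identical_ids_never_proposed_but_would_be_free(self, rng):
        space, state, table = random_two_type_state(rng)
        node = 0
        cid = int(state.sigma[node])
        p = Proposal(node, 1, cid, cid)
        assert delta_adhesion(space, state, table, p, J2) == 0.0


class TestValidation:
    def test_asymmetric_J_rejected(self):
        with pytest.raises(ConfigurationError):
            AdhesionPenalty([[0, 1], [2, 0]])

    def test_negative_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            VolumePenalty(-1.0)
        with pytest.raises(ConfigurationError):
            PerimeterPenalty([-0.1])
        with pytest.raises(ConfigurationError):
            ActMigrationPenalty(-1.0, 20)

    def test_nonfinite_chemo_field_rejected(self):
        with pytest.raises(ConfigurationError):
            ChemotaxisPenalty(1.0, np.array([1.0, np.inf]))
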