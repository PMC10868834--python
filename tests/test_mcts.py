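"""Entropy-reduction tree search: policy, expansion, backup, recovery."""

import numpy as np
import pytest

import rnadistgen.mcts as mcts
from rnadistgen.generator import PartialState
from rnadistgen.mcts import (Edge, SearchConfig, SearchNode, backup,
                             backup_terminal, expand_leaf, finalize_map,
                             init_tree, run_search, select_action,
                             total_entropy, value_of_state)

from oracles import PlantedOracle, UniformModel, random_planted_map


class TestEntropy:
    def test_uniform_closed_form(self):
        L, K = 6, 3
        probs = np.full((L, L, K), 1.0 / K)
        N = L * (L - 1) / 2
        assert total_entropy(probs) == pytest.approx(N * np.log(K))

    def test_delta_probs_zero(self):
        L = 5
        probs = np.zeros((L, L, 3))
        probs[..., 1] = 1.0
        assert total_entropy(probs) == pytest.approx(0.0)

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(3), size=(5, 5))
        want = 0.0
        for i in range(5):
            for j in range(i + 1, 5):
                for k in range(3):
                    want -= probs[i, j, k] * np.log(probs[i, j, k])
        assert total_entropy(probs) == pytest.approx(want)


class TestValue:
    def test_entropy_halved_in_one_action(self):
        assert value_of_state(10.0, 5.0, 1) == pytest.approx(0.5)

    def test_two_actions_to_zero(self):
        assert value_of_state(10.0, 0.0, 2) == pytest.approx(0.5)

    def test_unchanged_entropy_is_zero(self):
        assert value_of_state(10.0, 10.0, 1) == 0.0

    def test_degenerate_start_entropy(self):
        assert value_of_state(0.0, 0.0, 3) == 0.0


class TestInitTree:
    def test_diagonal_set_to_nearest_class(self):
        root = init_tree(5, UniformModel(), nearest_class=2)
        assert np.all(np.diag(root.state.state) == 2)
        assert len(root.state.history) == 0

    def test_offdiagonal_masked_without_contacts(self):
        root = init_tree(4, UniformModel(), nearest_class=0)
        off = ~np.eye(4, dtype=bool)
        assert np.all(root.state.state[off] == -1)

    def test_fixed_contact_pixels_revealed(self):
        root = init_tree(4, UniformModel(), nearest_class=0, fixed={(0, 2): 1})
        assert root.state.state[0, 2] == 1 and root.state.state[2, 0] == 1


class TestSelectAction:
    def _node(self, edges):
        n = SearchNode(PartialState.empty(3), depth=0, expanded=True)
        n.edges = {a: Edge(N, Q, SearchNode(PartialState.empty(3), 1))
                   for a, (N, Q) in edges.items()}
        return n

    def test_zero_cp_is_greedy_on_q(self):
        n = self._node({(0, 1, 0): (100, 0.3), (0, 2, 1): (1, 0.8)})
        assert select_action(n, SearchConfig(c_p=0.0)) == (0, 2, 1)

    def test_exploration_prefers_rare_edge_on_equal_q(self):
        n = self._node({(0, 1, 0): (100, 0.5), (0, 2, 1): (1, 0.5)})
        assert select_action(n, SearchConfig(c_p=1.0)) == (0, 2, 1)

    def test_matches_exhaustive_evaluation(self):
        rng = np.random.default_rng(1)
        cfg = SearchConfig(c_p=0.7)
        for _ in range(20):
            edges = {(0, int(j), int(k)): (int(rng.integers(1, 50)),
                                           float(rng.normal()))
                     for j, k in zip(rng.integers(1, 3, 4), rng.integers(0, 3, 4))}
            n = self._node(edges)
            total = sum(e.N for e in n.edges.values())
            scores = {a: e.Q + cfg.c_p * np.sqrt(total) / (1 + e.N)
                      for a, e in n.edges.items()}
            best = max(sorted(scores), key=lambda a: scores[a] - 1e-12 * sorted(scores).index(a))
            got = select_action(n, cfg)
            assert scores[got] == pytest.approx(max(scores.values()))

    def test_unexpanded_node_rejected(self):
        n = SearchNode(PartialState.empty(3), 0)
        with pytest.raises(RuntimeError):
            select_action(n, SearchConfig())


class TestExpandLeaf:
    def test_boundary_reduction_not_sufficient(self):
        """Reducing exactly ln K per action does not qualify (strict >)."""
        leaf = init_tree(5, UniformModel(), 0)
        rng = np.random.default_rng(2)
        s_h = expand_leaf(leaf, UniformModel(), SearchConfig(s_r_size=4),
                          rng, H0=total_entropy(UniformModel()(leaf.state)))
        # uniform model: setting one pixel removes exactly ln K
        assert s_h == [] and leaf.is_terminal

    def test_collapsing_pixel_enters_s_h(self):
        rng = np.random.default_rng(3)
        L = 8
        planted = random_planted_map(L, rng)
        oracle = PlantedOracle([planted], base=0.4, sharp_at=0.05)
        leaf = init_tree(L, oracle, 0)
        leaf_probs = oracle(leaf.state)
        s_h = expand_leaf(leaf, oracle, SearchConfig(s_r_size=4, seed=0), rng,
                          H0=total_entropy(leaf_probs))
        assert len(s_h) >= 1
        for a in s_h:
            assert leaf.edges[a].N == 1  # children initialised with N = 1

    def test_complete_map_marks_terminal(self):
        L = 3
        s = np.ones((L, L), dtype=np.int8)
        leaf = SearchNode(PartialState(s), depth=3)
        rng = np.random.default_rng(4)
        s_h = expand_leaf(leaf, UniformModel(), SearchConfig(), rng, H0=1.0)
        assert s_h == [] and leaf.is_terminal


class TestBackup:
    def _path(self, n_edges=1, N=1, Q=0.0):
        nodes = []
        for _ in range(n_edges):
            n = SearchNode(PartialState.empty(3), 0, expanded=True)
            n.edges = {(0, 1, 0): Edge(N, Q, SearchNode(PartialState.empty(3), 1))}
            nodes.append((n, (0, 1, 0)))
        return nodes

    def test_update_formula_arithmetic(self):
        path = self._path(N=1, Q=0.0)
        backup(path, n_new=1, v_star=0.4)
        e = path[0][0].edges[(0, 1, 0)]
        assert e.N == 2 and e.Q == pytest.approx(0.2)

    def test_terminal_leaves_q_unchanged(self):
        path = self._path(N=3, Q=0.7)
        backup_terminal(path, SearchConfig(n_expl=10))
        e = path[0][0].edges[(0, 1, 0)]
        assert e.N == 13 and e.Q == 0.7

    def test_q_stays_within_backed_up_range(self):
        rng = np.random.default_rng(5)
        path = self._path(N=1, Q=0.5)
        values = [0.5]
        for _ in range(50):
            v = float(rng.uniform(0, 1))
            values.append(v)
            backup(path, n_new=int(rng.integers(1, 5)), v_star=v)
            q = path[0][0].edges[(0, 1, 0)].Q
            assert min(values) - 1e-12 <= q <= max(values) + 1e-12


class TestFinalize:
    def test_no_masked_pixels_is_identity(self):
        s = np.ones((4, 4), dtype=np.int8)
        cm = finalize_map(PartialState(s), UniformModel())
        np.testing.assert_array_equal(cm.classes, s)

    def test_uniform_model_fills_lowest_class(self):
        state = init_tree(4, UniformModel(), 1).state
        cm = finalize_map(state, UniformModel())
        off = ~np.eye(4, dtype=bool)
        assert np.all(cm.classes[off] == 0)  # argmax tie -> lowest class
        assert np.all(np.diag(cm.classes) == 1)

    def test_planted_oracle_recovers_planted_map(self):
        rng = np.random.default_rng(6)
        planted = random_planted_map(10, rng)
        oracle = PlantedOracle([planted], base=0.8)
        state = init_tree(10, oracle, 0).state
        cm = finalize_map(state, oracle)
        off = ~np.eye(10, dtype=bool)
        np.testing.assert_array_equal(cm.classes[off], planted[off])


class TestRunSearch:
    def test_planted_recovery(self):
        rng = np.random.default_rng(7)
        planted = random_planted_map(12, rng)
        res = run_search(12, PlantedOracle([planted]),
                         SearchConfig(budget=200, max_terminals=2, seed=0),
                         nearest_class=0)
        off = ~np.eye(12, dtype=bool)
        best = max((cm.classes[off] == planted[off]).mean() for cm in res.maps)
        assert best >= 0.99

    def test_same_seed_identical_ensembles(self):
        rng = np.random.default_rng(8)
        planted = random_planted_map(10, rng)
        cfg = SearchConfig(budget=150, max_terminals=3, seed=4)
        r1 = run_search(10, PlantedOracle([planted]), cfg, 0)
        r2 = run_search(10, PlantedOracle([planted]), cfg, 0)
        assert len(r1.maps) == len(r2.maps)
        for a, b in zip(r1.maps, r2.maps):
            np.testing.assert_array_equal(a.classes, b.classes)

    def test_actions_never_overwrite(self):
        """Every terminal path consists of distinct, initially-masked pixels."""
        rng = np.random.default_rng(9)
        planted = random_planted_map(10, rng)
        res = run_search(10, PlantedOracle([planted]),
                         SearchConfig(budget=200, max_terminals=3, seed=1), 0)
        for t in res.terminals:
            seen = set()
            for (i, j, _) in t.history:
                assert i != j and (i, j) not in seen
                seen.add((i, j))


def _instrumented_search(L, seed, budget=120):
    """Run a search while logging every backup event for replay."""
    rng = np.random.default_rng(seed)
    planted = random_planted_map(L, rng)
    oracle = PlantedOracle([planted], base=0.4,
                           sharp_at=float(rng.uniform(0.1, 0.4)))
    events = []
    orig_backup, orig_terminal = mcts.backup, mcts.backup_terminal

    def rec_backup(path, n_new, v_star):
        events.append(("expand", [(id(n), a) for n, a in path], n_new, v_star))
        orig_backup(path, n_new, v_star)

    def rec_terminal(path, config):
        events.append(("terminal", [(id(n), a) for n, a in path],
                       config.n_expl, None))
        orig_terminal(path, config)

    mcts.backup, mcts.backup_terminal = rec_backup, rec_terminal
    try:
        cfg = SearchConfig(budget=budget, max_terminals=4, seed=seed,
                           s_r_size=4)
        res = run_search(L, oracle, cfg, nearest_class=0)
    finally:
        mcts.backup, mcts.backup_terminal = orig_backup, orig_terminal
    return res, events


@pytest.mark.parametrize("seed", range(6))
def test_bookkeeping_invariants_over_random_searches(seed):
    """Visit counts equal initial values plus all routed increments, and
    Q values stay within the range of backed-up values."""
    res, events = _instrumented_search(L=8, seed=seed)
    increments: dict = {}
    vstars: dict = {}
    for kind, path, n_new, v_star in events:
        for key in path:
            increments[key] = increments.get(key, 0) + n_new
            if kind == "expand":
                vstars.setdefault(key, []).append(v_star)

    def walk(node):
        for a, e in node.edges.items():
            key = (id(node), a)
            assert e.N == 1 + increments.get(key, 0)
            vs = vstars.get(key, []) + [e.Q]
            lo = min(vs + [0.0])
            hi = max(vs + [1.0])
            assert lo - 1e-9 <= e.Q <= hi + 1e-9
            walk(e.child)

    walk(res.root)


def test_q_bounded_by_backed_up_values():
    """Each edge's Q is a convex combination of its initial value and the
    v* values routed through it."""
    res, events = _instrumented_search(L=8, seed=42)
    routed: dict = {}
    for kind, path, n_new, v_star in events:
        if kind != "expand":
            continue
        for key in path:
            routed.setdefault(key, []).append(v_star)

    def walk(node):
        for a, e in node.edges.items():
            vs = routed.get((id(node), a))
            if vs:
                # initial Q was some child value in [0, 1]
                assert e.Q <= max(max(vs), 1.0) + 1e-9
                assert e.Q >= min(min(vs), 0.0) - 1e-9
            walk(e.child)

    walk(res.root)
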