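"""Tree-search state transitions, action legality, UCT selection and the
full assembly loop on noise-free fixtures."""

import math

import numpy as np
import pytest

from mcassembly.combinatorics import stoichiometry_of
from mcassembly.fixtures import ComplexSpec, make_complex, slice_subcomponents
from mcassembly.interfaces import interface_contacts
from mcassembly.mcts import (
    AssemblyState,
    MCTSConfig,
    PairLibrary,
    SearchNode,
    apply_action,
    assemble,
    initial_state,
    legal_actions,
    run_mcts,
    select_ucb,
)
from mcassembly.processing import extract_pairs


@pytest.fixture(scope="module")
def c6_lib(c6_reference):
    subs = slice_subcomponents(c6_reference, k=2, seed=0, n_models=1)
    pairs = extract_pairs(subs[0])
    return PairLibrary(pairs)


@pytest.fixture(scope="module")
def config():
    return MCTSConfig(iterations=60, max_chains=30)


class TestLegalActions:
    def test_balanced_tally_filter(self, c6_reference, config):
        # alternate ring chains: every anchor has free neighbour positions,
        # so eligibility is decided by the tally filter alone
        state = AssemblyState.from_chains(c6_reference.chains[::2], config)
        lib = PairLibrary(extract_pairs(
            slice_subcomponents(c6_reference, k=2, seed=0, n_models=1)[0]
        ))
        # artificial tallies {2, 4, 4}: only the tally-2 chain is eligible
        state.contact_tally = np.array([2, 4, 4])
        anchors = {a.anchor_chain_index
                   for a in legal_actions(state, lib, heuristic_on=True)}
        assert anchors == {0}
        # tallies {3, 3, 4}: min+1 = 4 admits every chain
        state.contact_tally = np.array([3, 3, 4])
        anchors = {a.anchor_chain_index
                   for a in legal_actions(state, lib, heuristic_on=True)}
        assert anchors == {0, 1, 2}

    def test_heuristic_off_equals_brute_force(self, c6_reference, c6_lib,
                                              config):
        state = AssemblyState.from_chains(c6_reference.chains[:2], config)
        actions = legal_actions(state, c6_lib, heuristic_on=False)
        # brute force: every (anchor, pair, side) whose placement is clash-free
        expected = 0
        for i, placed in enumerate(state.chains):
            for pair in c6_lib.pairs:
                for flipped in (False, True):
                    mount, _ = pair.oriented(flipped)
                    if mount.entity != placed.entity:
                        continue
                    chain = c6_lib.placed_chain(placed, pair, flipped)
                    expected += not state.placement_clashes(chain)
        assert len(actions) == expected > 0

    def test_full_state_terminal(self, c6_reference, c6_lib, config):
        state = AssemblyState.from_chains(
            c6_reference.chains, MCTSConfig(max_chains=6))
        assert legal_actions(state, c6_lib) == []


class TestApplyAction:
    def test_two_chain_placement_matches_pair_frame(self, c6_lib, config):
        pair = c6_lib.pairs[0]
        state = AssemblyState.from_chain(pair.anchor, config)
        action = legal_actions(state, c6_lib)[0]
        new = apply_action(state, action, c6_lib)
        assert new.n_chains == 2
        # anchor already sits in the pair frame, so the partner lands exactly
        placed = new.chains[1]
        src = pair.oriented(action.flipped)[1]
        assert np.abs(placed.ca - src.ca).max() < 1e-6

    def test_parent_state_never_mutated(self, c6_lib, config):
        pair = c6_lib.pairs[0]
        state = AssemblyState.from_chain(pair.anchor, config)
        h0 = state.coordinate_hash()
        t0 = state.contact_tally.copy()
        action = legal_actions(state, c6_lib)[0]
        apply_action(state, action, c6_lib)
        assert state.coordinate_hash() == h0
        assert state.n_chains == 1
        assert np.array_equal(state.contact_tally, t0)

    def test_ring_closure_by_repeated_pair_use(self, c6_lib, config):
        pair = c6_lib.pairs[0]
        state = AssemblyState.from_chain(pair.anchor, config)
        for _ in range(5):
            # always extend from the latest chain with the unflipped side
            acts = [a for a in legal_actions(state, c6_lib, heuristic_on=False)
                    if a.anchor_chain_index == state.n_chains - 1
                    and not a.flipped]
            state = apply_action(state, acts[0], c6_lib)
        assert state.n_chains == 6
        closure = interface_contacts(state.chains[5], state.chains[0], 8.0)
        assert closure.n_contacts > 0

    def test_same_pair_reused_from_different_anchors(self, c6_lib, config):
        pair = c6_lib.pairs[0]
        state = AssemblyState.from_chain(pair.anchor, config)
        a1 = legal_actions(state, c6_lib, heuristic_on=False)[0]
        state = apply_action(state, a1, c6_lib)
        anchors_used = set()
        for a in legal_actions(state, c6_lib, heuristic_on=False):
            if a.pair_id == pair.pair_id:
                anchors_used.add(a.anchor_chain_index)
        assert len(anchors_used) == 2  # both placed chains accept the pair

    def test_tally_consistent_with_recomputation(self, c6_reference, config):
        state = AssemblyState.from_chains(c6_reference.chains,
                                          MCTSConfig(max_chains=6))
        for i, chain in enumerate(state.chains):
            total = sum(
                interface_contacts(chain, other, state.contact_cutoff).n_contacts
                for j, other in enumerate(state.chains) if j != i
            )
            assert state.contact_tally[i] == total


class TestSelectUcb:
    def _node(self, rewards_visits, parent_visits):
        root = SearchNode.__new__(SearchNode)
        root.visits = parent_visits
        root.total_reward = 0.0
        root.untried = []
        root.children = {}
        root.state = None
        for i, (r, v) in enumerate(rewards_visits):
            child = SearchNode.__new__(SearchNode)
            child.visits = v
            child.total_reward = r * v
            child.children = {}
            child.untried = []
            child.state = None
            root.children[(f"p{i}", i, False)] = child
        return root

    def test_exploitation_only(self):
        root = self._node([(0.5, 10), (0.9, 10)], 20)
        best = select_ucb(root, 0.0)
        assert best.mean_reward() == pytest.approx(0.9)

    def test_unvisited_child_wins(self):
        root = self._node([(0.9, 10), (0.0, 0)], 10)
        best = select_ucb(root, 1.0)
        assert best.visits == 0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            k = int(rng.integers(2, 6))
            rv = [(float(rng.random()), int(rng.integers(1, 30)))
                  for _ in range(k)]
            parent = sum(v for _, v in rv)
            c = float(rng.random() * 2)
            root = self._node(rv, parent)
            got = select_ucb(root, c)
            vals = [r + c * math.sqrt(math.log(parent) / v) for r, v in rv]
            assert got.mean_reward() == pytest.approx(rv[int(np.argmax(vals))][0])

    def test_unexpanded_node_rejected(self, c6_lib, config):
        node = SearchNode(initial_state(c6_lib, config))
        with pytest.raises(RuntimeError):
            select_ucb(node, 1.0)


class TestRunMcts:
    def test_single_pair_dimer(self, c6_lib):
        cfg = MCTSConfig(iterations=20, max_chains=2)
        state = run_mcts(initial_state(c6_lib, cfg), c6_lib, cfg, seed=0)
        assert state.n_chains == 2
        assert str(stoichiometry_of(state)) == "A2"

    def test_c6_recovery_and_geometry(self, c6_reference, c6_lib):
        from mcassembly.evaluation import evaluate

        cfg = MCTSConfig(iterations=60, max_chains=30)
        state = run_mcts(initial_state(c6_lib, cfg), c6_lib, cfg, seed=3)
        assert str(stoichiometry_of(state)) == "A6"
        report = evaluate(state, c6_reference.chains)
        assert max(report.per_chain_rmsd) < 1.0

    def test_determinism(self, c6_lib):
        cfg = MCTSConfig(iterations=40, max_chains=30)
        runs = [run_mcts(initial_state(c6_lib, cfg), c6_lib, cfg, seed=11)
                for _ in range(2)]
        assert runs[0].actions_taken == runs[1].actions_taken
        assert (str(stoichiometry_of(runs[0]))
                == str(stoichiometry_of(runs[1])))

    def test_impossible_assembly_returns_monomer(self, c6_lib, config):
        # an initial chain of an entity no pair can mount
        from conftest import make_chain

        lonely = make_chain(np.random.default_rng(0).normal(size=(5, 3)),
                            entity="Z")
        state = AssemblyState.from_chain(lonely, config)
        with pytest.warns(UserWarning, match="monomer"):
            final = run_mcts(state, c6_lib, config, seed=0)
        assert final.n_chains == 1

    def test_empty_pair_library_rejected(self, config):
        with pytest.raises(ValueError):
            initial_state([], config)


class TestSearchQuality:
    def test_beats_random_assembly(self, c6_reference, c6_lib):
        """Mean final reward of the search is at least that of pure random
        assembly over matched seeds."""
        cfg = MCTSConfig(iterations=40, max_chains=30)

        def random_rollout(seed):
            rng = np.random.default_rng(seed)
            state = initial_state(c6_lib, cfg)
            while state.n_chains < cfg.max_chains:
                acts = legal_actions(state, c6_lib, heuristic_on=True)
                if not acts:
                    break
                state = apply_action(
                    state, acts[int(rng.integers(len(acts)))], c6_lib)
            return state.reward

        seeds = range(5)
        mcts_mean = np.mean([
            run_mcts(initial_state(c6_lib, cfg), c6_lib, cfg, seed=s).reward
            for s in seeds
        ])
        rand_mean = np.mean([random_rollout(s) for s in seeds])
        assert mcts_mean >= rand_mean - 1e-9

    def test_balanced_heuristic_limits_tally_spread(self, c6_reference,
                                                    c6_lib):
        cfg = MCTSConfig(iterations=60, max_chains=30, heuristic_on=True)
        state = run_mcts(initial_state(c6_lib, cfg), c6_lib, cfg, seed=5)
        ref_state = AssemblyState.from_chains(c6_reference.chains,
                                              MCTSConfig(max_chains=6))
        spread = state.contact_tally.max() - state.contact_tally.min()
        ref_spread = ref_state.contact_tally.max() - ref_state.contact_tally.min()
        assert spread <= max(2 * ref_spread, 2)
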