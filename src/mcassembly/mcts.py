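"""Complex assembly by Monte Carlo Tree Search over chain-addition moves.

A state is a partial assembly: chains already placed in a global frame.  An
action superposes one side of an interaction pair onto a placed chain of
the matching entity (CA atoms only) and adds the pair's other chain in the
implied position.  Pairs may be reused any number of times, so the copy
number of each entity — the stoichiometry — is an *outcome* of the search,
not an input: closed (point-group) complexes stop growing when every
remaining placement clashes with chains already present, open (helical)
ones when the chain budget is reached.

The search is plain UCT: UCB1 selection, single-action expansion,
uniform-random rollouts to a depth cap, mean-reward backup.  After each
iteration budget the best root action (highest mean reward) is committed
and its subtree reused.  A balanced-interface heuristic — only chains whose
interface-contact tally is within one of the current minimum are eligible
anchors — prunes the action space; it exploits the evenly shared interfaces
of symmetric complexes and can be disabled for asymmetric targets.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .interfaces import (
    DEFAULT_CLASH_CUTOFF,
    DEFAULT_CLASH_TOLERANCE,
    DEFAULT_CONTACT_CUTOFF,
)
from .processing import InteractionPair
from .structures import ChainModel, kabsch_superpose

__all__ = [
    "MCTSConfig",
    "AssemblyState",
    "AssemblyAction",
    "SearchNode",
    "PairLibrary",
    "PlacementClashError",
    "legal_actions",
    "apply_action",
    "select_ucb",
    "run_mcts",
    "initial_state",
    "assemble",
]


class PlacementClashError(RuntimeError):
    """Exact placement of an action clashed with the existing assembly."""


@dataclass
class MCTSConfig:
    """Tree-search settings; every field is echoed in run reports."""

    iterations: int = 100          # UCT simulations per committed move
    c_explore: float = math.sqrt(2.0)
    max_chains: int = 30
    rollout_depth: int = 6         # chains added per random playout
    heuristic_on: bool = True      # balanced-interface anchor filter
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF
    clash_tolerance: float = DEFAULT_CLASH_TOLERANCE
    time_limit: Optional[float] = None  # seconds, optional wall-clock cap
    n_restarts: int = 1


@dataclass(frozen=True, order=True)
class AssemblyAction:
    """Add one chain: superpose the pair's ``flipped`` side onto the placed
    chain at ``anchor_chain_index`` and append the other side."""

    pair_id: str
    anchor_chain_index: int
    flipped: bool
    partner_entity: str = field(compare=False, default="")


class PairLibrary:
    """Interaction pairs indexed by id and by mountable entity.

    Placements are memoised: superposing a given pair side onto a given
    placed chain always yields the same moved chain, and placed chains are
    shared between states in the search tree, so the cache hit rate during
    selection/expansion is high.  Cached entries hold a reference to the
    anchor chain, keeping ``id()`` keys valid.
    """

    _CACHE_LIMIT = 60000

    def __init__(self, pairs: Sequence[InteractionPair]):
        self.pairs = list(pairs)
        self.by_id = {p.pair_id: p for p in self.pairs}
        if len(self.by_id) != len(self.pairs):
            raise ValueError("pair ids must be unique")
        self._sides: dict[str, list[tuple[InteractionPair, bool]]] = {}
        for p in self.pairs:
            self._sides.setdefault(p.anchor.entity, []).append((p, False))
            self._sides.setdefault(p.partner.entity, []).append((p, True))
        self._placement_cache: dict = {}

    def __len__(self) -> int:
        return len(self.pairs)

    def sides_for_entity(self, entity: str) -> list[tuple[InteractionPair, bool]]:
        return self._sides.get(entity, [])

    def entity_pair_counts(self) -> dict[str, int]:
        return {e: len(v) for e, v in self._sides.items()}

    def placed_chain(self, target: ChainModel, pair: InteractionPair,
                     flipped: bool) -> ChainModel:
        """The pair's added chain after superposing its mount side onto
        ``target`` (memoised)."""
        key = (id(target), pair.pair_id, flipped)
        hit = self._placement_cache.get(key)
        if hit is not None:
            return hit[1]
        mount, added = pair.oriented(flipped)
        if mount.entity != target.entity:
            raise ValueError("action anchor entity does not match placed chain")
        transform, _ = kabsch_superpose(mount.ca, target.ca)
        moved = added.transformed(transform)
        if len(self._placement_cache) >= self._CACHE_LIMIT:
            self._placement_cache.clear()
        self._placement_cache[key] = (target, moved)
        return moved


class AssemblyState:
    """Immutable partial assembly.

    ``contact_tally[i]`` is chain i's total interface-contact count against
    the rest of the assembly; ``pair_scores`` caches the interface score of
    every contacting chain pair, so the reward is an O(1) lookup.
    """

    __slots__ = (
        "chains", "contact_tally", "pair_scores", "actions_taken",
        "max_chains", "contact_cutoff", "clash_cutoff", "clash_tolerance",
        "_ca_stack", "_cb_stack", "_bounds", "_uniform_len", "search_log",
    )

    def __init__(self, chains, contact_tally, pair_scores, actions_taken,
                 max_chains, contact_cutoff, clash_cutoff, clash_tolerance):
        if not 1 <= len(chains) <= max_chains:
            raise ValueError("state must hold between 1 and max_chains chains")
        self.chains = tuple(chains)
        self.contact_tally = contact_tally
        self.pair_scores = pair_scores
        self.actions_taken = tuple(actions_taken)
        self.max_chains = max_chains
        self.contact_cutoff = contact_cutoff
        self.clash_cutoff = clash_cutoff
        self.clash_tolerance = clash_tolerance
        self._ca_stack = np.concatenate([c.ca for c in self.chains])
        self._cb_stack = np.concatenate([c.cb for c in self.chains])
        bounds = np.cumsum([0] + [len(c) for c in self.chains])
        self._bounds = bounds
        lengths = {len(c) for c in self.chains}
        self._uniform_len = lengths.pop() if len(lengths) == 1 else 0
        self.search_log = None

    @classmethod
    def from_chain(cls, chain: ChainModel, config: MCTSConfig) -> "AssemblyState":
        return cls(
            [chain], np.zeros(1, dtype=int), {}, [],
            config.max_chains, config.contact_cutoff,
            config.clash_cutoff, config.clash_tolerance,
        )

    @classmethod
    def from_chains(cls, chains: Sequence[ChainModel],
                    config: MCTSConfig) -> "AssemblyState":
        """Build a state from already-placed chains, recomputing tallies and
        interface scores from the coordinates."""
        state = cls.from_chain(chains[0], config)
        for ch in chains[1:]:
            state = state.extended(ch, None)
        return state

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def reward(self) -> float:
        if not self.pair_scores:
            return 0.0
        return (
            float(np.mean(list(self.pair_scores.values())))
            * self.n_chains / self.max_chains
        )

    def coordinate_hash(self) -> int:
        return hash(self._ca_stack.tobytes())

    def _segment(self, d: np.ndarray, i: int) -> np.ndarray:
        return d[:, self._bounds[i]: self._bounds[i + 1]]

    def placement_clashes(self, chain: ChainModel) -> bool:
        """True if the candidate chain's clash fraction against any placed
        chain exceeds the tolerance."""
        d = cdist(chain.ca, self._ca_stack)
        if d.min() > self.clash_cutoff:
            return False
        L = self._uniform_len
        if L and len(chain) == L:
            per_chain = d.reshape(len(chain), -1, L).min(axis=2)
            frac = (per_chain <= self.clash_cutoff).mean(axis=0)
            return bool((frac > self.clash_tolerance).any())
        for i, placed in enumerate(self.chains):
            seg = self._segment(d, i)
            if len(chain) <= len(placed):
                frac = (seg.min(axis=1) <= self.clash_cutoff).mean()
            else:
                frac = (seg.min(axis=0) <= self.clash_cutoff).mean()
            if frac > self.clash_tolerance:
                return True
        return False

    def _extended_nocheck(self, chain: ChainModel, action) -> "AssemblyState":
        """Append ``chain`` without re-running the clash check; interface
        scores and tallies are updated incrementally."""
        n_new = len(self.chains)
        d = cdist(chain.cb, self._cb_stack) <= self.contact_cutoff
        tally = np.append(self.contact_tally, 0)
        scores = dict(self.pair_scores)
        L = self._uniform_len
        if L and len(chain) == L:
            seg3 = d.reshape(len(chain), -1, L)
            counts = seg3.sum(axis=(0, 2))
            touched = np.flatnonzero(counts)
        else:
            seg3 = None
            touched = range(len(self.chains))
        for i in touched:
            seg = seg3[:, i, :] if seg3 is not None else self._segment(d, i)
            n = int(seg.sum()) if seg3 is None else int(counts[i])
            if n == 0:
                continue
            placed = self.chains[i]
            rows = seg.any(axis=1)
            cols = seg.any(axis=0)
            s = chain.plddt[rows].sum() + placed.plddt[cols].sum()
            avg = float(s) / (int(rows.sum()) + int(cols.sum()))
            scores[(i, n_new)] = math.log10(n) * avg if n > 1 else 0.0
            tally[i] += n
            tally[n_new] += n
        actions = self.actions_taken + ((action,) if action is not None else ())
        return AssemblyState(
            self.chains + (chain,), tally, scores, actions,
            self.max_chains, self.contact_cutoff,
            self.clash_cutoff, self.clash_tolerance,
        )

    def extended(self, chain: ChainModel, action) -> "AssemblyState":
        """New state with ``chain`` appended; raises
        :class:`PlacementClashError` on clash.  The parent is unmodified."""
        if self.placement_clashes(chain):
            raise PlacementClashError(
                f"placement of entity {chain.entity} clashes"
            )
        return self._extended_nocheck(chain, action)


def _eligible_anchor_indices(state: AssemblyState, heuristic_on: bool) -> list[int]:
    if not heuristic_on or state.n_chains == 1:
        return list(range(state.n_chains))
    floor = int(state.contact_tally.min()) + 1
    return [i for i in range(state.n_chains) if state.contact_tally[i] <= floor]


def _candidate_actions(
    state: AssemblyState, lib: PairLibrary, heuristic_on: bool
) -> list[AssemblyAction]:
    """All (anchor, pair, side) combinations before the clash check."""
    out: list[AssemblyAction] = []
    for i in _eligible_anchor_indices(state, heuristic_on):
        ent = state.chains[i].entity
        for pair, flipped in lib.sides_for_entity(ent):
            mount, added = pair.oriented(flipped)
            out.append(AssemblyAction(pair.pair_id, i, flipped, added.entity))
    return out


def _place(state: AssemblyState, action: AssemblyAction,
           lib: PairLibrary) -> ChainModel:
    pair = lib.by_id[action.pair_id]
    target = state.chains[action.anchor_chain_index]
    return lib.placed_chain(target, pair, action.flipped)


def legal_actions(
    state: AssemblyState, pairs, heuristic_on: bool = True
) -> list[AssemblyAction]:
    """Clash-free chain additions from ``state``.

    Anchors are the placed chains; with ``heuristic_on`` only chains whose
    contact tally is at most (minimum tally + 1) are eligible.  An empty
    list marks a terminal state.
    """
    if state.n_chains >= state.max_chains:
        return []
    lib = pairs if isinstance(pairs, PairLibrary) else PairLibrary(pairs)
    out = []
    for action in _candidate_actions(state, lib, heuristic_on):
        chain = _place(state, action, lib)
        if not state.placement_clashes(chain):
            out.append(action)
    return out


def apply_action(state: AssemblyState, action: AssemblyAction,
                 pairs) -> AssemblyState:
    """Apply one chain addition; the input state is never mutated.

    Raises :class:`PlacementClashError` if the exact placement clashes
    (the caller may treat the action as illegal)."""
    lib = pairs if isinstance(pairs, PairLibrary) else PairLibrary(pairs)
    chain = _place(state, action, lib)
    return state.extended(chain, (action.pair_id, action.anchor_chain_index,
                                  action.flipped))


class SearchNode:
    """UCT bookkeeping for one assembly state."""

    __slots__ = ("state", "visits", "total_reward", "children", "untried")

    def __init__(self, state: AssemblyState):
        self.state = state
        self.visits = 0
        self.total_reward = 0.0
        self.children: dict[AssemblyAction, SearchNode] = {}
        self.untried: Optional[list[AssemblyAction]] = None  # lazy

    def mean_reward(self) -> float:
        return self.total_reward / self.visits if self.visits else 0.0

    def ensure_expandable(self, lib: PairLibrary, heuristic_on: bool) -> None:
        if self.untried is None:
            self.untried = legal_actions(self.state, lib, heuristic_on)

    def is_terminal(self) -> bool:
        return self.untried == [] and not self.children


def select_ucb(node: SearchNode, c_explore: float) -> SearchNode:
    """UCB1 child selection; an unvisited child wins outright; ties break
    on the lowest action key."""
    if node.untried is None or node.untried:
        raise RuntimeError("select_ucb requires a fully expanded node")
    if not node.children:
        raise RuntimeError("select_ucb requires children")
    items = sorted(node.children.items())
    for _, child in items:
        if child.visits == 0:
            return child
    log_n = math.log(node.visits)
    best, best_val = None, -math.inf
    for _, child in items:
        val = child.mean_reward() + c_explore * math.sqrt(log_n / child.visits)
        if val > best_val:
            best, best_val = child, val
    return best


def _rollout(state: AssemblyState, lib: PairLibrary, config: MCTSConfig,
             rng: np.random.Generator, log: dict) -> float:
    """Uniform-random playout: candidate actions are tried in a random
    order and the first clash-free one applied (equivalent to sampling
    uniformly from the legal actions)."""
    depth = 0
    while depth < config.rollout_depth and state.n_chains < state.max_chains:
        cands = _candidate_actions(state, lib, config.heuristic_on)
        if not cands:
            break
        order = rng.permutation(len(cands))
        nxt = None
        for k in order:
            action = cands[k]
            chain = _place(state, action, lib)
            if state.placement_clashes(chain):
                continue
            nxt = state._extended_nocheck(
                chain,
                (action.pair_id, action.anchor_chain_index, action.flipped),
            )
            break
        if nxt is None:
            break
        state = nxt
        log["first_reach"].setdefault(state.n_chains, log["iterations_total"])
        depth += 1
    return state.reward


def _simulate(root: SearchNode, lib: PairLibrary, config: MCTSConfig,
              rng: np.random.Generator, log: dict) -> None:
    node = root
    path = [root]
    node.ensure_expandable(lib, config.heuristic_on)
    while not node.untried and node.children:
        node = select_ucb(node, config.c_explore)
        node.ensure_expandable(lib, config.heuristic_on)
        path.append(node)
    if node.untried:
        idx = int(rng.integers(len(node.untried)))
        action = node.untried.pop(idx)
        try:
            child_state = apply_action(node.state, action, lib)
        except PlacementClashError:
            child_state = None
        if child_state is not None:
            child = SearchNode(child_state)
            node.children[action] = child
            node = child
            path.append(node)
            log["first_reach"].setdefault(
                child_state.n_chains, log["iterations_total"]
            )
    reward = _rollout(node.state, lib, config, rng, log)
    for n in path:
        n.visits += 1
        n.total_reward += reward


def _best_child(node: SearchNode) -> tuple[AssemblyAction, SearchNode]:
    """Committed move: highest mean reward, ties by lowest action key."""
    return max(
        sorted(node.children.items()),
        key=lambda kv: kv[1].mean_reward(),
    )


def run_mcts(
    initial: AssemblyState,
    pairs,
    config: MCTSConfig | None = None,
    seed: int = 0,
) -> AssemblyState:
    """Assemble a complex from ``initial`` by committed-move UCT.

    Per committed move, ``config.iterations`` simulations refine the tree;
    the best child by mean reward becomes the new root (subtree reused).
    The loop ends when the state is terminal: no clash-free addition exists
    or the chain budget is reached.  Bit-reproducible for a fixed seed.
    """
    config = config or MCTSConfig()
    lib = pairs if isinstance(pairs, PairLibrary) else PairLibrary(pairs)
    if len(lib) == 0:
        raise ValueError("pair library is empty")
    rng = np.random.default_rng(seed)
    log = {"iterations_total": 0, "first_reach": {initial.n_chains: 0},
           "seed": seed}
    t0 = time.monotonic()
    root = SearchNode(initial)
    root.ensure_expandable(lib, config.heuristic_on)
    if root.is_terminal() and initial.n_chains == 1:
        warnings.warn("no legal action from the initial chain; "
                      "assembly impossible, returning the monomer")
        initial.search_log = log
        return initial
    while not root.is_terminal():
        budget_exhausted = False
        for _ in range(config.iterations):
            if (config.time_limit is not None
                    and time.monotonic() - t0 > config.time_limit):
                budget_exhausted = True
                break
            _simulate(root, lib, config, rng, log)
            log["iterations_total"] += 1
        if not root.children:
            break
        _, root = _best_child(root)
        root.ensure_expandable(lib, config.heuristic_on)
        if budget_exhausted:
            break
    state = root.state
    state.search_log = log
    return state


def initial_state(pairs, config: MCTSConfig | None = None) -> AssemblyState:
    """Seed the search with one chain of the entity appearing in the most
    pairs (ties broken lexicographically), recentred at the origin."""
    config = config or MCTSConfig()
    lib = pairs if isinstance(pairs, PairLibrary) else PairLibrary(pairs)
    if len(lib) == 0:
        raise ValueError("pair library is empty")
    counts = lib.entity_pair_counts()
    entity = max(sorted(counts), key=lambda e: counts[e])
    best = None
    for p in lib.pairs:
        for side in (p.anchor, p.partner):
            if side.entity == entity:
                key = (-p.pdockq, p.pair_id)
                if best is None or key < best[0]:
                    best = (key, side)
    chain = best[1]
    from .structures import RigidTransform

    recenter = RigidTransform(np.eye(3), -chain.centroid())
    return AssemblyState.from_chain(chain.transformed(recenter), config)


def assemble(pairs, config: MCTSConfig | None = None,
             seed: int = 0) -> AssemblyState:
    """Convenience wrapper: seeded restarts of :func:`run_mcts` from the
    default initial state; the highest-reward final state wins."""
    config = config or MCTSConfig()
    lib = pairs if isinstance(pairs, PairLibrary) else PairLibrary(pairs)
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(max(1, config.n_restarts)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        state = run_mcts(initial_state(lib, config), lib, config, sub_seed)
        if best is None or state.reward > best.reward:
            best = state
    return best
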