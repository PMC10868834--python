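"""Entropy-reduction Monte Carlo tree search over autoregressive orderings.

Actions assign a distance class to a masked nucleotide pair.  The
search looks for orderings under which the generator's predictive
distribution sharpens fast: an expansion keeps only candidate actions
whose one-step lookahead removes more than λ·ln K nats of total
predictive entropy, values states by their fractional entropy
reduction per action, and treats "no candidate qualifies" as a
terminal — the map is then completed in parallel by argmax.  Terminal
visits add an exploration bonus N_expl along their path (Q untouched)
so later simulations spread into alternative distance maps; the
collected terminals form the structural ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .generator import PartialState
from .vqvae import ClassMap

log = logging.getLogger(__name__)


@dataclass
class SearchConfig:
    c_p: float = 1e-4           # matched to the entropy-reduction-rate value scale
    lam: float = 1.0            # entropy threshold factor λ
    n_expl: int = 10            # terminal exploration bonus
    s_r_size: int = 4           # candidate pixels per expansion
    budget: int = 400           # max simulations
    max_terminals: int = 10
    seed: int = 0
    K: int = 3
    candidate_sampling: str = "argmax"  # or "sample" for stochastic candidates

    def __post_init__(self):
        if self.c_p < 0 or self.n_expl < 1 or self.s_r_size < 1:
            raise ValueError("invalid search configuration")


@dataclass
class Edge:
    N: int
    Q: float
    child: "SearchNode"


@dataclass
class SearchNode:
    state: PartialState
    depth: int  # number of off-diagonal actions from the root
    edges: dict = field(default_factory=dict)  # action -> Edge
    is_terminal: bool = False
    expanded: bool = False
    H: float | None = None  # cached total entropy at this state


def total_entropy(probs: np.ndarray, state: PartialState | None = None) -> float:
    """Total predictive entropy (nats) over upper-triangle pixels.

    Already-set pixels contribute whatever (near-delta) entropy the
    model assigns them.
    """
    L = probs.shape[0]
    iu, ju = np.triu_indices(L, k=1)
    p = probs[iu, ju]
    return float(-(p * np.log(np.maximum(p, 1e-300))).sum())


def value_of_state(H0: float, H: float, depth: int) -> float:
    """Fractional entropy reduction per action: (H0 - H) / (H0 * depth)."""
    if H0 <= 0.0:
        return 0.0
    return (H0 - H) / (H0 * max(depth, 1))


def init_tree(seq_or_L, model, nearest_class: int,
              fixed: dict | None = None) -> SearchNode:
    """Root node: diagonal set to the nearest distance class, rest masked."""
    L = seq_or_L if isinstance(seq_or_L, int) else len(seq_or_L)
    state = PartialState.empty(L, fixed)
    s = state.state.copy()
    np.fill_diagonal(s, nearest_class)
    return SearchNode(PartialState(s, state.fixed_pairs), depth=0)


def select_action(node: SearchNode, config: SearchConfig):
    """PUCT rule: argmax Q + c_p * sqrt(sum_a N) / (1 + N); deterministic ties."""
    if not node.edges:
        raise RuntimeError("select_action on unexpanded node")
    total_n = sum(e.N for e in node.edges.values())
    best, best_score = None, -np.inf
    for action in sorted(node.edges):  # (i, j, k) sort = pixel then class tie-break
        e = node.edges[action]
        score = e.Q + config.c_p * np.sqrt(total_n) / (1 + e.N)
        if score > best_score + 1e-12:
            best, best_score = action, score
    return best


def _candidate_actions(node: SearchNode, probs: np.ndarray,
                       config: SearchConfig, rng: np.random.Generator):
    masked = node.state.masked_pairs()
    if not masked:
        return []
    take = min(config.s_r_size, len(masked))
    pick = rng.choice(len(masked), size=take, replace=False)
    actions = []
    for idx in sorted(pick.tolist()):
        i, j = masked[idx]
        if config.candidate_sampling == "sample":
            p = np.maximum(probs[i, j], 0)
            k = int(rng.choice(len(p), p=p / p.sum()))
        else:
            k = int(np.argmax(probs[i, j]))  # ties -> lowest class
        actions.append((i, j, k))
    return actions


def expand_leaf(leaf: SearchNode, model, config: SearchConfig,
                rng: np.random.Generator, H0: float) -> list:
    """Expand: keep lookahead actions with entropy reduction > λ ln K.

    Returns the list of qualifying actions (S_H); empty marks the leaf
    terminal.  New children start with N = 1 and Q = v(child).
    """
    probs = model(leaf.state)
    if leaf.H is None:
        leaf.H = total_entropy(probs, leaf.state)
    candidates = _candidate_actions(leaf, probs, config, rng)
    leaf.expanded = True
    if not candidates:
        leaf.is_terminal = True  # complete map
        return []
    children = [leaf.state.with_action(*a) for a in candidates]
    child_probs = model(children)
    threshold = config.lam * np.log(config.K)
    s_h = []
    for action, child_state, cp in zip(candidates, children, child_probs):
        H_child = total_entropy(cp, child_state)
        if leaf.H - H_child > threshold:
            child = SearchNode(child_state, depth=leaf.depth + 1, H=H_child)
            v = value_of_state(H0, H_child, child.depth)
            leaf.edges[action] = Edge(N=1, Q=v, child=child)
            s_h.append(action)
    if not s_h:
        leaf.is_terminal = True
    return s_h


def backup(path: list, n_new: int, v_star: float) -> None:
    """Route an expansion through the path: N += |S_H|, Q convex-updated."""
    for node, action in path:
        e = node.edges[action]
        e.N += n_new
        e.Q += (n_new / e.N) * (v_star - e.Q)


def backup_terminal(path: list, config: SearchConfig) -> None:
    """Terminal visit: N += N_expl along the path, Q unchanged."""
    for node, action in path:
        node.edges[action].N += config.n_expl


def finalize_map(terminal: PartialState, model) -> ClassMap:
    """Fill remaining masked pixels in parallel with their argmax class."""
    probs = model(terminal)
    K = probs.shape[-1]
    s = terminal.state.astype(np.int64).copy()
    pred = probs.argmax(axis=-1)  # ties -> lowest class
    fill = s == -1
    s[fill] = pred[fill]
    s = np.where(np.triu(np.ones_like(s, dtype=bool)), s, s.T)  # exact symmetry
    return ClassMap(np.minimum(s, K - 1), K)


@dataclass
class SearchResult:
    maps: list[ClassMap]
    terminals: list[PartialState]
    root: SearchNode
    n_simulations: int
    metadata: list[dict]


def run_search(seq_or_L, model, config: SearchConfig,
               nearest_class: int = 0, fixed: dict | None = None) -> SearchResult:
    """Repeat select → expand → backup; return finalized terminal maps.

    ``model`` maps a PartialState (or list of them) to class
    probabilities.  Deterministic given ``config.seed``.  If the budget
    produces no terminal, the best-Q leaf is finalized with a warning.
    """
    rng = np.random.default_rng(config.seed)
    root = init_tree(seq_or_L, model, nearest_class, fixed)
    root_probs = model(root.state)
    root.H = total_entropy(root_probs, root.state)
    H0 = root.H
    terminals: list[PartialState] = []
    maps: list[ClassMap] = []
    metadata: list[dict] = []
    map_keys: set[bytes] = set()
    sims = 0
    while sims < config.budget and len(maps) < config.max_terminals:
        sims += 1
        node, path = root, []
        while node.expanded and not node.is_terminal and node.edges:
            action = select_action(node, config)
            path.append((node, action))
            node = node.edges[action].child
        if node.is_terminal:
            backup_terminal(path, config)
            continue
        s_h = expand_leaf(node, model, config, rng, H0)
        if node.is_terminal:
            terminals.append(node.state)
            cm = finalize_map(node.state, model)
            if cm.key() not in map_keys:  # ensemble cap counts unique maps
                map_keys.add(cm.key())
                maps.append(cm)
                metadata.append({"depth": len(node.state.history),
                                 "terminal": True,
                                 "path_length": len(node.state.history)})
            backup_terminal(path, config)
        else:
            v_star = max(node.edges[a].Q for a in s_h)
            backup(path, len(s_h), v_star)
    if not maps:
        log.warning("no terminal found within budget; finalizing best-Q leaf")
        node = root
        while node.edges:
            best = max(sorted(node.edges), key=lambda a: node.edges[a].Q)
            node = node.edges[best].child
        maps = [finalize_map(node.state, model)]
        metadata = [{"depth": len(node.state.history), "terminal": False,
                     "path_length": len(node.state.history)}]
    return SearchResult(maps, terminals, root, sims, metadata)
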