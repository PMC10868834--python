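"""Mock generator models used by the tree-search tests.

These oracles emulate the qualitative behaviour of a trained masked
generator: probability mass concentrated on one (or two) planted
symmetric class maps, sharpening toward a delta once a fraction of the
pixels has been revealed, with revealed pixels always predicted as
near-deltas on their assigned class.
"""

from __future__ import annotations

import numpy as np

from rnadistgen.generator import PartialState


class UniformModel:
    """Uniform class probabilities for masked pixels, deltas for set ones."""

    def __init__(self, K: int = 3, eps: float = 1e-9):
        self.K, self.eps = K, eps

    def _one(self, state: PartialState) -> np.ndarray:
        L, K = state.L, self.K
        probs = np.full((L, L, K), 1.0 / K)
        s = state.state
        m = s != -1
        sharp = np.full((L, L, K), self.eps / (K - 1))
        np.put_along_axis(sharp, np.where(m, s, 0)[..., None].astype(int),
                          1 - self.eps, axis=-1)
        probs[m] = sharp[m]
        return probs

    def __call__(self, states):
        if isinstance(states, PartialState):
            return self._one(states)
        return np.stack([self._one(s) for s in states])


class PlantedOracle:
    """Sharpening oracle with one or two planted symmetric class maps.

    Base probability mass ``base`` sits on the planted class of each
    pixel; once the fraction of revealed pixels exceeds ``sharp_at``
    the distribution collapses to a delta on the planted map.  With two
    planted maps the mixture weight follows agreement between revealed
    pixels and each map (the hinge pixels where the maps differ decide
    the mode).
    """

    def __init__(self, planted_list, base=0.4, sharp_at=0.3, K=3,
                 eps=1e-6, beta=12.0):
        self.pls = [np.asarray(p) for p in planted_list]
        self.base, self.sharp_at, self.K, self.eps, self.beta = \
            base, sharp_at, K, eps, beta
        self.differ = (self.pls[0] != self.pls[1]) if len(self.pls) > 1 else None
        self.n_calls = 0

    def _weights(self, state: PartialState) -> np.ndarray:
        if len(self.pls) == 1:
            return np.ones(1)
        dh = [(i, j, k) for (i, j, k) in state.history if self.differ[i, j]]
        if not dh:
            return np.full(len(self.pls), 1.0 / len(self.pls))
        ag = np.array([sum(1 for (i, j, k) in dh if pl[i, j] == k) / len(dh)
                       for pl in self.pls])
        w = np.exp(self.beta * (ag - ag.max()))
        return w / w.sum()

    def _one(self, state: PartialState) -> np.ndarray:
        self.n_calls += 1
        L, K = state.L, self.K
        n_offdiag = L * (L - 1) / 2
        f = len(state.history) / max(n_offdiag, 1)
        p = self.base + (1 - self.base) * min(f / self.sharp_at, 1.0)
        w = self._weights(state)
        probs = np.zeros((L, L, K))
        for wi, pl in zip(w, self.pls):
            q = np.full((L, L, K), (1 - p) / (K - 1))
            np.put_along_axis(q, pl[..., None], p, axis=-1)
            probs += wi * q
        s = state.state
        m = s != -1
        sharp = np.full((L, L, K), self.eps / (K - 1))
        np.put_along_axis(sharp, np.where(m, s, 0)[..., None].astype(int),
                          1 - self.eps, axis=-1)
        probs[m] = sharp[m]
        return probs

    def __call__(self, states):
        if isinstance(states, PartialState):
            return self._one(states)
        return np.stack([self._one(s) for s in states])


def random_planted_map(L: int, rng: np.random.Generator, K: int = 3) -> np.ndarray:
    m = rng.integers(0, K, size=(L, L))
    return np.triu(m) + np.triu(m, 1).T
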