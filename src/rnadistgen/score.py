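"""Pairwise discriminator ranking distance-class maps against a sequence.

A small residual CNN maps a class map (one-hot, K channels) stacked
with the 8-channel sequence bit pattern to an L x L x 1 logit map whose
sum is the scalar score f(s, x).  Two maps are compared through
D(sA, sB; x) = sigmoid(f(sA, x) - f(sB, x)); training maximises
E[log D(true, false)] + E[log(1 - D(false, true))] over true/corrupted
pairs.  Negatives come from drift-structure encodings, symmetric pixel
flips of true maps, and generator argmax predictions at low reveal
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .generator import (MASKED, GeneratorModel, PartialState,
                        encode_sequence_bitpattern)
from .vqvae import ClassMap, VqVae


@dataclass
class ScoreConfig:
    K: int = 3
    max_len: int = 100
    batch: int = 100
    lr: float = 1e-3
    weight_decay: float = 1e-4
    lr_decay: float = 0.9988
    betas: tuple[float, float] = (0.9, 0.997)
    eps: float = 1e-9
    steps: int = 500


@dataclass
class ScorePair:
    s_true: ClassMap
    s_false: ClassMap
    seq: str
    corruption: str  # drift | pixel_flip | generator_argmax

    def __post_init__(self):
        if self.s_true.L != self.s_false.L or self.s_true.K != self.s_false.K:
            raise ValueError("paired maps must share L and K")


def _build_net(cfg: ScoreConfig, rng: np.random.Generator) -> nn.Sequential:
    # conv [3x3,5]; 4 ResBlocks [3x3,5] with a dilated second half; 1x1 to 100 to 1
    return nn.Sequential(
        nn.Conv2d(cfg.K + 8, 5, 3, rng=rng),
        *[layer for _ in range(4) for layer in (
            nn.ResBlock(5, 5, 5, 3, 3, rng=rng),
            nn.ResBlock(5, 5, 5, 3, 3, dilation2=2, rng=rng))],
        nn.BatchNorm2d(5), nn.ReLU(),
        nn.Conv2d(5, 100, 1, rng=rng), nn.ReLU(),
        nn.Conv2d(100, 1, 1, rng=rng),
    )


class ScoreNet:
    def __init__(self, config: ScoreConfig, seed: int = 0):
        self.config = config
        self.net = _build_net(config, np.random.default_rng(seed))
        self.history: list[float] = []

    def parameters(self):
        return self.net.parameters()

    def features(self, cm: ClassMap, seq: str) -> np.ndarray:
        mx = self.config.max_len
        onehot = np.zeros((mx, mx, self.config.K), dtype=np.float32)
        onehot[: cm.L, : cm.L] = cm.one_hot()
        return np.concatenate(
            [onehot, encode_sequence_bitpattern(seq, mx)], axis=-1)

    def logit_map(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(batch, train=train)

    def save(self, path) -> None:
        import json
        from dataclasses import asdict

        arrays = {f"net.{k}": v for k, v in self.net.state_arrays().items()}
        cfg = asdict(self.config)
        cfg["betas"] = list(cfg["betas"])
        arrays["config"] = np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8)
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "ScoreNet":
        import json

        data = np.load(path)
        cfg = json.loads(bytes(data["config"]).decode())
        cfg["betas"] = tuple(cfg["betas"])
        model = cls(ScoreConfig(**cfg), seed=0)
        model.net.load_state_arrays(
            {k[4:]: data[k] for k in data.files if k.startswith("net.")})
        return model


def score_f(cm: ClassMap, seq: str, net: ScoreNet) -> float:
    """Scalar match score: sum of the L x L logit map."""
    if len(seq) != cm.L:
        raise ValueError("sequence length does not match map")
    logits = net.logit_map(net.features(cm, seq)[None])[0, : cm.L, : cm.L, 0]
    return float(logits.sum())


def pairwise_D(sA: ClassMap, sB: ClassMap, seq: str, net: ScoreNet) -> float:
    """D = sigmoid(f(sA) - f(sB)): probability that sA is the better match."""
    diff = score_f(sB, seq, net) - score_f(sA, seq, net)
    return float(1.0 / (1.0 + np.exp(diff)))


def flip_pixels(cm: ClassMap, fraction: float, rng: np.random.Generator) -> ClassMap:
    """Symmetrically reassign a fraction of upper-triangle pixels (>= 1 pair)."""
    iu, ju = np.triu_indices(cm.L)
    n = max(1, int(round(fraction * len(iu))))
    pick = rng.choice(len(iu), size=min(n, len(iu)), replace=False)
    s = cm.classes.copy()
    for c in pick:
        i, j = iu[c], ju[c]
        new = (s[i, j] + 1 + rng.integers(cm.K - 1)) % cm.K
        s[i, j] = s[j, i] = new
    return ClassMap(s, cm.K)


def make_negatives(dataset, vqvae_model: VqVae, rng: np.random.Generator,
                   generator: GeneratorModel | None = None,
                   n_flips: int = 10, flip_fraction=(0.05, 0.35),
                   reveal_fractions=(0.0, 0.05, 0.10, 0.15, 0.20)) -> list[ScorePair]:
    """Build true/corrupted pairs from (seq, tensor[, drift tensors]) items.

    Per structure: one pair per encoded drift variant, ``n_flips``
    pixel-flipped copies (``flip_fraction`` may be a scalar or a
    (lo, hi) range sampled per copy — varied corruption strengths keep
    the discriminator from memorising specific negatives), and — when a
    generator is supplied — one argmax prediction per reveal fraction.
    """
    pairs: list[ScorePair] = []
    for item in dataset:
        seq, tensor = item[0], item[1]
        drifts = item[2] if len(item) > 2 else []
        true_cm = vqvae_model.encode(tensor)
        for d in drifts:
            pairs.append(ScorePair(true_cm, vqvae_model.encode(d), seq, "drift"))
        for _ in range(n_flips):
            if np.ndim(flip_fraction) > 0:
                frac = float(rng.uniform(flip_fraction[0], flip_fraction[1]))
            else:
                frac = float(flip_fraction)
            pairs.append(ScorePair(true_cm, flip_pixels(true_cm, frac, rng),
                                   seq, "pixel_flip"))
        if generator is not None:
            L = len(seq)
            iu, ju = np.triu_indices(L)
            for frac in reveal_fractions:
                n_show = int(round(frac * len(iu)))
                s = np.full((L, L), MASKED, dtype=np.int8)
                if n_show:
                    shown = rng.choice(len(iu), size=n_show, replace=False)
                    for c in shown:
                        i, j = iu[c], ju[c]
                        s[i, j] = s[j, i] = true_cm.classes[i, j]
                state = PartialState(s)
                probs = generator.predict(seq, state)
                pred = probs.argmax(axis=-1)
                keep = s != MASKED
                pred[keep] = s[keep]
                pred = np.where(np.triu(np.ones_like(pred, dtype=bool)), pred, pred.T)
                pairs.append(ScorePair(true_cm, ClassMap(pred, true_cm.K), seq,
                                       "generator_argmax"))
    return pairs


def pair_objective(pair: ScorePair, net: ScoreNet, train: bool = False):
    """J terms for one pair; returns (term1, term2, backward_closure).

    term1 = log D(true, false), term2 = log(1 - D(false, true)); both
    equal log sigmoid(f_true - f_false) analytically.
    """
    xt = net.features(pair.s_true, pair.seq)
    xf = net.features(pair.s_false, pair.seq)
    batch = np.stack([xt, xf])
    logits = net.logit_map(batch, train=train)
    Lq = pair.s_true.L
    f_t = float(logits[0, :Lq, :Lq, 0].sum())
    f_f = float(logits[1, :Lq, :Lq, 0].sum())
    delta = f_t - f_f
    # log sigmoid, numerically stable
    term1 = -np.logaddexp(0.0, -delta)
    # computed through its own route; analytically identical to term1
    d_false_true = 1.0 / (1.0 + np.exp(min(delta, 500.0)))
    term2 = np.log1p(-min(d_false_true, 1.0 - 1e-300))

    def backward():
        # d(-J)/d delta = -(1 - sigmoid(delta)) per term; two identical terms
        sig = 1.0 / (1.0 + np.exp(-delta))
        g = -2.0 * (1.0 - sig)
        dlog = np.zeros_like(logits)
        dlog[0, :Lq, :Lq, 0] = g
        dlog[1, :Lq, :Lq, 0] = -g
        net.net.backward(dlog.astype(np.float32))

    return float(term1), float(term2), backward


def train_score(pairs: list[ScorePair], config: ScoreConfig, seed: int = 0) -> ScoreNet:
    """Maximise J(D) over true/corrupted pairs; deterministic given seed."""
    if not pairs:
        raise ValueError("no training pairs")
    rng = np.random.default_rng(seed)
    net = ScoreNet(config, seed=seed)
    opt = nn.Adam(net.parameters(), lr=config.lr, betas=config.betas,
                  eps=config.eps, weight_decay=config.weight_decay,
                  schedule=nn.exponential_decay(config.lr_decay))
    for step in range(config.steps):
        idx = rng.choice(len(pairs), size=min(config.batch, len(pairs)),
                         replace=len(pairs) < config.batch)
        for p in net.parameters():
            p.zero_grad()
        total = 0.0
        for i in idx:
            t1, t2, back = pair_objective(pairs[i], net, train=True)
            if not np.isfinite(t1):
                raise RuntimeError("score training diverged (NaN loss)")
            total += -(t1 + t2)
            back()
        net.history.append(total / len(idx))
        opt.step()
    return net


def rank_ensemble(maps: list[ClassMap], seq: str, net: ScoreNet) -> list[tuple[int, ClassMap, float]]:
    """Sort maps by descending f (stable; ties keep input order)."""
    if not maps:
        raise ValueError("empty ensemble")
    scored = [(i, m, score_f(m, seq, net)) for i, m in enumerate(maps)]
    return sorted(scored, key=lambda t: -t[2])
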