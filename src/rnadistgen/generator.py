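"""Masked autoregressive model over distance-class maps.

The generator sees an L x L x 14 feature stack per nucleotide pair:

* 8 channels — directional sequence bit pattern (one-hot of residue i
  stacked with one-hot of residue j; padding is -1),
* 3 channels — the partially revealed class map (masked pixel (0,0,0);
  class c is +1 at channel c, -1 elsewhere),
* 2 channels — coordinate frames (diagonal; border box of side L;
  padding -1),
* 1 channel — a self-attention map computed from 50 aligned homologs
  plus a per-nucleotide SHAPE reactivity column.

It outputs a per-pixel softmax over the K distance classes,
symmetrised across the diagonal.  Training masks a truncated-normal
number of symmetric pixel pairs and minimises cross-entropy against
VQ-VAE class targets; fixed contact pairs are always revealed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from . import nn
from .vqvae import ClassMap, VqVae

log = logging.getLogger(__name__)

MASKED = -1
#: one-hot order of the sequence encoding
BASE_ORDER = "GCAU"
_BASE_VEC = {b: np.eye(4, dtype=np.float32)[i] for i, b in enumerate(BASE_ORDER)}
_BASE_VEC["N"] = np.full(4, 0.25, dtype=np.float32)
N_HOMOLOG_ROWS = 50


@dataclass
class GeneratorConfig:
    K: int = 3
    channels: int = 26
    blocks: int = 8
    max_len: int = 100
    batch: int = 500
    lr: float = 1e-3
    weight_decay: float = 0.01
    warmup_steps: int = 100_000
    steps: int = 5_000_000  # full-scale budget cap; scale down via config
    betas: tuple[float, float] = (0.9, 0.997)
    eps: float = 1e-8
    patience: int | None = None  # early stopping on validation loss
    eval_every: int = 50


@dataclass
class PartialState:
    """Symmetric partial class map: -1 means masked."""

    state: np.ndarray
    fixed_pairs: frozenset = frozenset()
    history: tuple = ()

    def __post_init__(self):
        self.state = np.asarray(self.state, dtype=np.int8)
        if not np.array_equal(self.state, self.state.T):
            raise ValueError("partial state must be symmetric")

    @property
    def L(self) -> int:
        return self.state.shape[0]

    @classmethod
    def empty(cls, L: int, fixed: dict[tuple[int, int], int] | None = None) -> "PartialState":
        s = np.full((L, L), MASKED, dtype=np.int8)
        fixed = fixed or {}
        for (i, j), k in fixed.items():
            s[i, j] = s[j, i] = k
        return cls(s, frozenset(fixed))

    def with_action(self, i: int, j: int, k: int) -> "PartialState":
        if self.state[i, j] != MASKED:
            raise ValueError(f"action would overwrite set pixel ({i}, {j})")
        s = self.state.copy()
        s[i, j] = s[j, i] = k
        return PartialState(s, self.fixed_pairs, self.history + ((i, j, k),))

    def masked_pairs(self) -> list[tuple[int, int]]:
        iu, ju = np.triu_indices(self.L, k=1)
        sel = self.state[iu, ju] == MASKED
        return list(zip(iu[sel].tolist(), ju[sel].tolist()))


def encode_sequence_bitpattern(seq: str, max_len: int | None = None) -> np.ndarray:
    """Directional (L x L x 8) bit pattern; optional -1 padding to max_len."""
    if not seq:
        raise ValueError("empty sequence")
    L = len(seq)
    onehot = np.stack([_BASE_VEC[b] for b in seq])  # (L, 4)
    rows = np.repeat(onehot[:, None, :], L, axis=1)  # channel 0-3: residue i
    feats = np.concatenate([rows, rows.transpose(1, 0, 2)], axis=-1)
    if max_len is None or max_len == L:
        return feats
    out = np.full((max_len, max_len, 8), -1.0, dtype=np.float32)
    out[:L, :L] = feats
    return out


def encode_state_channels(state: PartialState, K: int = 3,
                          max_len: int | None = None) -> np.ndarray:
    """(L x L x K): masked -> zeros; class c -> +1 at c, -1 elsewhere."""
    s = state.state
    if s.max() >= K:
        raise ValueError("state value out of range")
    L = s.shape[0]
    out_L = np.zeros((L, L, K), dtype=np.float32)
    set_px = s != MASKED
    out_L[set_px] = -1.0
    ii, jj = np.nonzero(set_px)
    out_L[ii, jj, s[ii, jj]] = 1.0
    if max_len is None or max_len == L:
        return out_L
    out = np.zeros((max_len, max_len, K), dtype=np.float32)
    out[:L, :L] = out_L
    return out


def sample_mask_count(L: int, rng: np.random.Generator) -> int:
    """Truncated normal(L^2/2, L^2/4) clipped at two standard deviations."""
    mean, sd = L * L / 2.0, L * L / 4.0
    x = truncnorm.rvs(-2.0, 2.0, loc=mean, scale=sd, random_state=rng)
    return int(np.clip(round(x), 0, L * L))


def make_coordinate_frames(L: int, max_len: int) -> np.ndarray:
    """(max_len x max_len x 2): identity diagonal + L-box border; padding -1."""
    if L > max_len:
        raise ValueError("L exceeds max_len")
    out = np.full((max_len, max_len, 2), -1.0, dtype=np.float32)
    out[:L, :L, :] = 0.0
    np.fill_diagonal(out[:L, :L, 0], 1.0)
    out[0, :L, 1] = out[L - 1, :L, 1] = 1.0
    out[:L, 0, 1] = out[:L, L - 1, 1] = 1.0
    return out


def homolog_onehot(rows: list[str], L: int) -> np.ndarray:
    """(L x 50 x 4) one-hot of aligned homologs; gaps/N -> 0.25 everywhere."""
    if len(rows) != N_HOMOLOG_ROWS:
        raise ValueError(f"expected exactly {N_HOMOLOG_ROWS} homolog rows")
    arr = np.empty((L, N_HOMOLOG_ROWS, 4), dtype=np.float32)
    for r, row in enumerate(rows):
        if len(row) != L:
            raise ValueError("homolog length mismatch")
        for i, b in enumerate(row):
            arr[i, r] = _BASE_VEC.get(b, _BASE_VEC["N"])
    return arr


def fill_homolog_rows(rows: list[str] | None, query: str) -> list[str]:
    """Pad (or create) the 50-row homolog array using the query sequence."""
    rows = list(rows or [])
    if len(rows) > N_HOMOLOG_ROWS:
        rows = rows[:N_HOMOLOG_ROWS]
    while len(rows) < N_HOMOLOG_ROWS:
        rows.append(query)
    return rows


class AttentionHead(nn.Module):
    """Homolog/SHAPE self-attention producing the (L x L x 1) input channel.

    Dense(4 -> 1) collapses the homolog one-hot; the SHAPE column is
    stacked; two Dense(51 -> 64) maps give query and key tensors for
    single-head scaled dot-product attention (1/sqrt(64) scaling).
    """

    DIM = 64

    def __init__(self, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.collapse = nn.Dense(4, 1, rng=rng)
        self.query = nn.Dense(N_HOMOLOG_ROWS + 1, self.DIM, rng=rng)
        self.key = nn.Dense(N_HOMOLOG_ROWS + 1, self.DIM, rng=rng)
        self._cache = None

    def forward(self, homolog_oh: np.ndarray, shape_vec: np.ndarray,
                train: bool = False) -> np.ndarray:
        L = homolog_oh.shape[0]
        dense = self.collapse.forward(homolog_oh)[..., 0]  # (L, 50)
        stacked = np.concatenate([dense, shape_vec[:, None]], axis=1)  # (L, 51)
        q = self.query.forward(stacked)
        k = self.key.forward(stacked)
        scores = q @ k.T / np.sqrt(self.DIM)
        scores -= scores.max(axis=1, keepdims=True)
        w = np.exp(scores)
        w /= w.sum(axis=1, keepdims=True)
        self._cache = (stacked, q, k, w, L)
        return w[..., None].astype(np.float32)

    def backward(self, dmap: np.ndarray) -> None:
        stacked, q, k, w, L = self._cache
        dw = dmap[..., 0]
        dscores = w * (dw - (dw * w).sum(axis=1, keepdims=True))
        dq = dscores @ k / np.sqrt(self.DIM)
        dk = dscores.T @ q / np.sqrt(self.DIM)
        dstacked = self.query.backward(dq) + self.key.backward(dk)
        ddense = dstacked[:, :N_HOMOLOG_ROWS]
        self.collapse.backward(ddense[..., None])


def build_attention_map(homologs, shape: np.ndarray | None, head: AttentionHead,
                        query: str | None = None) -> np.ndarray:
    """(L x L x 1) attention map; rows fill with the query, absent SHAPE -> 0."""
    rows = getattr(homologs, "rows", homologs)
    if query is None:
        if not rows:
            raise ValueError("need a query sequence or at least one homolog row")
        query = rows[0]
    rows = fill_homolog_rows(rows, query)
    L = len(query)
    shape_vec = np.zeros(L, dtype=np.float32) if shape is None else \
        np.asarray(shape, dtype=np.float32)
    if shape_vec.shape != (L,):
        raise ValueError("SHAPE vector length mismatch")
    return head.forward(homolog_onehot(rows, L), shape_vec)


def assemble_input(seq_feats: np.ndarray, state_chans: np.ndarray,
                   frames: np.ndarray, attention: np.ndarray) -> np.ndarray:
    """Concatenate the fixed channel order (8 seq, K state, 2 frames, 1 attn)."""
    parts = (seq_feats, state_chans, frames, attention)
    base = seq_feats.shape[:2]
    for p in parts:
        if p.shape[:2] != base:
            raise ValueError("feature blocks disagree on spatial shape")
    if seq_feats.shape[2] != 8 or frames.shape[2] != 2 or attention.shape[2] != 1:
        raise ValueError("unexpected channel counts")
    return np.concatenate(parts, axis=-1).astype(np.float32)


def _build_trunk(cfg: GeneratorConfig, rng: np.random.Generator) -> nn.Sequential:
    c = cfg.channels
    layers: list[nn.Module] = [nn.Conv2d(8 + cfg.K + 3, c, 3, rng=rng)]
    for _ in range(cfg.blocks):
        # ResBlock = 2x[BN, ELU, Conv] (+skip) then 1x conv + 1x dilated conv (+skip)
        layers.append(nn.ResBlock(c, c, c, 3, 3, act="elu", rng=rng))
        layers.append(nn.ResBlock(c, c, c, 3, 3, dilation2=2, act="elu", rng=rng))
    layers += [nn.BatchNorm2d(c), nn.ELU(), nn.Conv2d(c, cfg.K, 1, rng=rng)]
    return nn.Sequential(*layers)


class GeneratorModel:
    """Trunk CNN plus attention head, with MCTS-friendly cached inference."""

    def __init__(self, config: GeneratorConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.attention = AttentionHead(rng=rng)
        self.trunk = _build_trunk(config, rng)
        self.history: dict[str, list] = {"train": [], "val": []}

    def parameters(self):
        return self.trunk.parameters() + self.attention.parameters()

    # -- forward -------------------------------------------------------
    def forward_features(self, feats: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, mx, mx, 14) features -> per-pixel symmetric class probabilities."""
        logits = self.trunk.forward(feats, train=train)
        if not np.isfinite(logits).all():
            raise RuntimeError("NaN in generator forward pass")
        logits = logits - logits.max(axis=-1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=-1, keepdims=True)
        self._p_pre = p
        return 0.5 * (p + p.transpose(0, 2, 1, 3))

    def backward_from_probs(self, dprobs: np.ndarray) -> np.ndarray:
        """Backprop through symmetrisation and softmax; returns dfeatures."""
        dp = 0.5 * (dprobs + dprobs.transpose(0, 2, 1, 3))
        p = self._p_pre
        dlogits = p * (dp - (dp * p).sum(axis=-1, keepdims=True))
        return self.trunk.backward(dlogits.astype(np.float32))

    def static_features(self, seq: str, homologs=None, shape=None) -> dict:
        """Precompute per-sequence channels shared by every partial state."""
        mx = self.config.max_len
        attn = np.zeros((mx, mx, 1), dtype=np.float32)
        attn[: len(seq), : len(seq)] = build_attention_map(
            homologs, shape, self.attention, query=seq)
        return {
            "seq": encode_sequence_bitpattern(seq, mx),
            "frames": make_coordinate_frames(len(seq), mx),
            "attn": attn,
            "L": len(seq),
        }

    def probs_for_states(self, static: dict, states: list[PartialState]) -> np.ndarray:
        """Batched inference: (n_states, L, L, K) class probabilities."""
        mx, L = self.config.max_len, static["L"]
        feats = np.stack([
            assemble_input(static["seq"],
                           encode_state_channels(s, self.config.K, mx),
                           static["frames"], static["attn"])
            for s in states])
        probs = self.forward_features(feats, train=False)
        return probs[:, :L, :L, :]

    def predict(self, seq: str, state: PartialState | None = None,
                homologs=None, shape=None) -> np.ndarray:
        """(L, L, K) class probabilities for one sequence and partial state."""
        state = state or PartialState.empty(len(seq))
        static = self.static_features(seq, homologs, shape)
        return self.probs_for_states(static, [state])[0]

    def policy(self, seq: str, homologs=None, shape=None):
        """Callable state -> probs (and batch variant) for the tree search."""
        static = self.static_features(seq, homologs, shape)

        def fn(states):
            single = isinstance(states, PartialState)
            batch = [states] if single else list(states)
            out = self.probs_for_states(static, batch)
            return out[0] if single else out

        return fn

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        import json
        from dataclasses import asdict

        arrays = {f"trunk.{k}": v for k, v in self.trunk.state_arrays().items()}
        arrays.update({f"attn.{k}": v for k, v in self.attention.state_arrays().items()})
        cfg = asdict(self.config)
        cfg["betas"] = list(cfg["betas"])
        arrays["config"] = np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8)
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "GeneratorModel":
        import json

        data = np.load(path)
        cfg = json.loads(bytes(data["config"]).decode())
        cfg["betas"] = tuple(cfg["betas"])
        model = cls(GeneratorConfig(**cfg), seed=0)
        model.trunk.load_state_arrays(
            {k[6:]: data[k] for k in data.files if k.startswith("trunk.")})
        model.attention.load_state_arrays(
            {k[5:]: data[k] for k in data.files if k.startswith("attn.")})
        return model


@dataclass
class GeneratorExample:
    """One training item: sequence, class-map target and optional context."""

    seq: str
    target: ClassMap
    homologs: list[str] | None = None
    shape: np.ndarray | None = None
    fixed_pairs: dict = field(default_factory=dict)  # (i, j) -> class


def make_examples(dataset, vqvae_model: VqVae) -> list[GeneratorExample]:
    """Quantize (seq, DistanceTensor[, homologs, shape, fixed]) into targets."""
    out = []
    for item in dataset:
        seq, tensor = item[0], item[1]
        homologs = item[2] if len(item) > 2 else None
        shape = item[3] if len(item) > 3 else None
        fixed = item[4] if len(item) > 4 else {}
        out.append(GeneratorExample(seq, vqvae_model.encode(tensor),
                                    homologs, shape, fixed))
    return out


def _masked_state(ex: GeneratorExample, rng: np.random.Generator) -> PartialState:
    """Reveal the target except a truncated-normal number of masked pixels.

    Masking consumes symmetric pixel pairs (n pixels -> ceil(n/2) pairs)
    and never touches the fixed contact pairs.
    """
    L = len(ex.seq)
    n = sample_mask_count(L, rng)
    iu, ju = np.triu_indices(L)
    pair_ok = np.ones(len(iu), dtype=bool)
    for (i, j) in ex.fixed_pairs:
        pair_ok &= ~((iu == min(i, j)) & (ju == max(i, j)))
    cand = np.flatnonzero(pair_ok)
    n_pairs = min((n + 1) // 2, len(cand))
    chosen = rng.choice(cand, size=n_pairs, replace=False) if n_pairs else []
    s = ex.target.classes.astype(np.int8).copy()
    for c in chosen:
        s[iu[c], ju[c]] = s[ju[c], iu[c]] = MASKED
    for (i, j), k in ex.fixed_pairs.items():
        s[i, j] = s[j, i] = k
    return PartialState(s, frozenset(ex.fixed_pairs))


def _batch_loss_and_grad(model: GeneratorModel, batch: list[GeneratorExample],
                         rng: np.random.Generator, train: bool) -> float:
    mx, K = model.config.max_len, model.config.K
    feats, attn_sizes = [], []
    for ex in batch:
        state = _masked_state(ex, rng)
        static_attn = np.zeros((mx, mx, 1), dtype=np.float32)
        static_attn[: len(ex.seq), : len(ex.seq)] = build_attention_map(
            ex.homologs, ex.shape, model.attention, query=ex.seq)
        feats.append(assemble_input(
            encode_sequence_bitpattern(ex.seq, mx),
            encode_state_channels(state, K, mx),
            make_coordinate_frames(len(ex.seq), mx),
            static_attn))
        attn_sizes.append(len(ex.seq))
    x = np.stack(feats)
    probs = model.forward_features(x, train=train)

    total, count = 0.0, 0
    dprobs = np.zeros_like(probs)
    for b, ex in enumerate(batch):
        L = len(ex.seq)
        t = ex.target.classes
        p = probs[b, :L, :L]
        pt = np.take_along_axis(p, t[..., None], axis=-1)[..., 0]
        total += -np.log(np.maximum(pt, 1e-12)).sum()
        count += L * L
        if train:
            grad = np.zeros((mx, mx, K), dtype=np.float64)
            np.put_along_axis(grad[:L, :L], t[..., None],
                              (-1.0 / np.maximum(pt, 1e-12))[..., None], axis=-1)
            dprobs[b] = grad
    loss = total / max(count, 1)
    if train:
        dfeat = model.backward_from_probs(dprobs / max(count, 1))
        for b, ex in enumerate(batch):
            # re-run the (cheap) attention forward so its cache matches row b
            build_attention_map(ex.homologs, ex.shape, model.attention, query=ex.seq)
            model.attention.backward(
                dfeat[b, : attn_sizes[b], : attn_sizes[b], 13:14])
    return float(loss)


def train_generator(dataset, vqvae_model: VqVae, config: GeneratorConfig,
                    seed: int = 0, val=None) -> GeneratorModel:
    """Train the masked generator against VQ-VAE class targets."""
    examples = make_examples(dataset, vqvae_model)
    if not examples:
        raise ValueError("empty dataset")
    val_examples = make_examples(val, vqvae_model) if val else None
    rng = np.random.default_rng(seed)
    model = GeneratorModel(config, seed=seed)
    opt = nn.Adam(model.parameters(), lr=config.lr, betas=config.betas,
                  eps=config.eps, weight_decay=config.weight_decay,
                  schedule=nn.warmup_cosine(config.warmup_steps, config.steps))
    best_val, best_state, bad = np.inf, None, 0
    for step in range(config.steps):
        idx = rng.choice(len(examples), size=min(config.batch, len(examples)),
                         replace=len(examples) < config.batch)
        for p in model.parameters():
            p.zero_grad()
        loss = _batch_loss_and_grad(model, [examples[i] for i in idx], rng, True)
        opt.step()
        model.history["train"].append(loss)
        if val_examples and (step + 1) % config.eval_every == 0:
            vl = _batch_loss_and_grad(model, val_examples, rng, False)
            model.history["val"].append((step + 1, vl))
            if config.patience is not None:
                if vl < best_val - 1e-4:
                    best_val, bad = vl, 0
                    best_state = {k: v.copy() for k, v in
                                  model.trunk.state_arrays().items()}
                else:
                    bad += 1
                    if bad > config.patience:
                        log.info("early stopping at step %d", step + 1)
                        break
    if best_state is not None:
        model.trunk.load_state_arrays(best_state)
    return model


def fully_masked_accuracy(model: GeneratorModel, examples: list[GeneratorExample]) -> float:
    """Argmax accuracy predicting every pixel from sequence alone."""
    hits, count = 0, 0
    for ex in examples:
        state = PartialState.empty(len(ex.seq), dict(ex.fixed_pairs))
        probs = model.predict(ex.seq, state, ex.homologs, ex.shape)
        pred = probs.argmax(axis=-1)
        hits += (pred == ex.target.classes).sum()
        count += pred.size
    return hits / max(count, 1)


def chain_rule_loglik(trajectory, model, seq_or_L) -> float:
    """Sum of log P(a_t | s_{t-1}, x) over a complete upper-triangle trajectory.

    ``model`` is any callable mapping a PartialState to (L, L, K)
    probabilities (e.g. ``GeneratorModel.policy(seq)``).
    """
    L = seq_or_L if isinstance(seq_or_L, int) else len(seq_or_L)
    pairs = {(min(i, j), max(i, j)) for (i, j, _) in trajectory}
    need = {(i, j) for i in range(L) for j in range(i + 1, L)}
    if pairs != need:
        raise ValueError("trajectory must cover all L(L-1)/2 upper-triangle pixels")
    state = PartialState.empty(L)
    total = 0.0
    for (i, j, k) in trajectory:
        probs = model(state)
        total += float(np.log(max(probs[min(i, j), max(i, j), k], 1e-300)))
        state = state.with_action(min(i, j), max(i, j), k)
    return total
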