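"""Vector-quantised autoencoder over inter-nucleotide distance tensors.

The encoder compresses each pixel (nucleotide pair) of an L x L x 64
distance tensor into an 8-dimensional embedding; vector quantisation
against a K-entry codebook turns the embedding into one of K discrete
distance classes (K = 3 by default: near / intermediate / far), and the
decoder maps one-hot class maps back to distance tensors.  Codebook
vectors follow exponential-moving-average updates (decay 0.99); the
encoder receives gradients through a soft nearest-codebook assignment
(straight-through: the decoder consumes the hard one-hot, the backward
pass treats it as the softmax of negative squared distances).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .codec import DistanceTensor, symmetrize_tensor


@dataclass
class CodecConfig:
    K: int = 3
    embed_dim: int = 8
    ema_decay: float = 0.99
    lr: float = 1e-5
    batch: int = 100
    max_len: int = 100
    beta: float = 0.25  # commitment cost
    steps: int = 1000

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if not 0.0 < self.ema_decay < 1.0:
            raise ValueError("ema_decay must lie in (0, 1)")


@dataclass
class ClassMap:
    """Symmetric L x L map of distance classes in {0..K-1}."""

    classes: np.ndarray
    K: int

    def __post_init__(self):
        self.classes = np.asarray(self.classes, dtype=np.int64)
        if self.classes.ndim != 2 or self.classes.shape[0] != self.classes.shape[1]:
            raise ValueError("classes must be square")
        if self.classes.min() < 0 or self.classes.max() >= self.K:
            raise ValueError("class indices out of range")

    @property
    def L(self) -> int:
        return self.classes.shape[0]

    def one_hot(self) -> np.ndarray:
        return np.eye(self.K, dtype=np.float32)[self.classes]

    def key(self) -> bytes:
        return self.classes.tobytes()


@dataclass
class Codebook:
    vectors: np.ndarray  # (K, embed_dim)
    ema_counts: np.ndarray = field(default=None)
    ema_sums: np.ndarray = field(default=None)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        if self.ema_counts is None:
            self.ema_counts = np.zeros(len(self.vectors), dtype=np.float64)
        if self.ema_sums is None:
            self.ema_sums = self.vectors.astype(np.float64).copy()


def _build_encoder(rng: np.random.Generator) -> nn.Sequential:
    # conv 7x7x32, one block [5x5,16]/[3x3,8], four blocks [5x5,8]/[3x3,8]
    return nn.Sequential(
        nn.Conv2d(64, 32, 7, rng=rng),
        nn.ResBlock(32, 16, 8, 5, 3, rng=rng),
        *[nn.ResBlock(8, 8, 8, 5, 3, rng=rng) for _ in range(4)],
    )


def _build_decoder(K: int, rng: np.random.Generator) -> nn.Sequential:
    # feature maps double 8 -> 16 -> 32 -> 64 between 4-block residual groups
    layers: list[nn.Module] = [nn.Conv2d(K, 8, 5, rng=rng)]
    layers += [nn.ResBlock(8, 8, 8, 5, 5, rng=rng) for _ in range(4)]
    layers.append(nn.Conv2d(8, 16, 5, rng=rng))
    layers += [nn.ResBlock(16, 16, 16, 5, 5, rng=rng) for _ in range(4)]
    layers.append(nn.Conv2d(16, 32, 5, rng=rng))
    layers += [nn.ResBlock(32, 32, 32, 5, 5, rng=rng) for _ in range(4)]
    layers.append(nn.Conv2d(32, 64, 5, rng=rng))
    layers += [nn.ResBlock(64, 64, 64, 3, 3, rng=rng) for _ in range(4)]
    layers.append(nn.ReLU())
    return nn.Sequential(*layers)


def pad_tensor(t: DistanceTensor, max_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Zero-pad D and M out to (max_len, max_len, 64)."""
    if t.L > max_len:
        raise ValueError(f"tensor length {t.L} exceeds max_len {max_len}")
    D = np.zeros((max_len, max_len, 64), dtype=np.float32)
    M = np.zeros((max_len, max_len, 64), dtype=np.float32)
    D[: t.L, : t.L] = t.D
    M[: t.L, : t.L] = t.M
    return D, M


def symmetrize_embedding(e: np.ndarray) -> np.ndarray:
    """Average an (..., L, L, C) embedding with its pixel transpose."""
    if e.shape[-2] != e.shape[-3]:
        raise ValueError("embedding must be square in its pixel axes")
    return 0.5 * (e + np.swapaxes(e, -2, -3))


class VqVae:
    """Trained (or freshly initialised) distance-class codec."""

    def __init__(self, config: CodecConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.encoder = _build_encoder(rng)
        self.decoder = _build_decoder(config.K, rng)
        self.codebook = Codebook(
            rng.standard_normal((config.K, config.embed_dim)).astype(np.float32))
        self.history: dict[str, list[float]] = {"recon": [], "commit": []}

    # -- forward pieces ----------------------------------------------
    def encode_continuous(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        """Residual-network embedding of padded (N, max_len, max_len, 64) input."""
        if batch.shape[1] > self.config.max_len:
            raise ValueError("input exceeds max_len")
        return self.encoder.forward(batch.astype(np.float32), train=train)

    def quantize(self, e_sym: np.ndarray) -> np.ndarray:
        """Nearest-codebook class per pixel (ties -> lowest index)."""
        d2 = self._dist2(e_sym)
        return np.argmin(d2, axis=-1)

    def _dist2(self, e: np.ndarray) -> np.ndarray:
        c = self.codebook.vectors  # (K, d)
        return ((e[..., None, :] - c) ** 2).sum(axis=-1)

    def decode(self, onehot: np.ndarray, train: bool = False) -> np.ndarray:
        """Map (N, L, L, K) one-hot class maps to distance reconstructions."""
        if onehot.shape[-1] != self.config.K:
            raise ValueError("class-count mismatch with trained decoder")
        return self.decoder.forward(onehot.astype(np.float32), train=train)

    # -- public per-structure API ------------------------------------
    def encode(self, t: DistanceTensor) -> ClassMap:
        D, M = pad_tensor(t, self.config.max_len)
        e = self.encode_continuous((D * M)[None])
        e = symmetrize_embedding(e)[0]
        classes = self.quantize(e)[: t.L, : t.L]
        return ClassMap(classes, self.config.K)

    def reconstruct(self, t: DistanceTensor) -> DistanceTensor:
        recon = self.decode_classmap(self.encode(t), mask=t.M)
        return DistanceTensor(recon, t.M.copy(), t.L)

    def decode_classmap(self, cm: ClassMap, mask: np.ndarray | None = None) -> np.ndarray:
        """Decode a class map (padded internally) to an L x L x 64 array."""
        pad = np.zeros((self.config.max_len, self.config.max_len), dtype=np.int64)
        pad[: cm.L, : cm.L] = cm.classes
        onehot = np.eye(self.config.K, dtype=np.float32)[pad]
        recon = self.decode(onehot[None])[0][: cm.L, : cm.L].astype(float)
        recon = symmetrize_tensor(recon)
        if mask is not None:
            recon = recon * mask
        return recon

    def class_distance_means(self, tensors: list[DistanceTensor]) -> np.ndarray:
        """Mean decoded distance per class over a reference set."""
        sums = np.zeros(self.config.K)
        counts = np.zeros(self.config.K)
        for t in tensors:
            cm = self.encode(t)
            recon = self.decode_classmap(cm, mask=t.M)
            mvalid = t.M.sum(axis=-1)
            vals = np.where(mvalid > 0, recon.sum(axis=-1) / np.maximum(mvalid, 1), 0.0)
            for k in range(self.config.K):
                sel = (cm.classes == k) & (mvalid > 0)
                sums[k] += vals[sel].sum()
                counts[k] += sel.sum()
        return sums / np.maximum(counts, 1)

    def nearest_class(self, tensors: list[DistanceTensor]) -> int:
        """Class whose mean decoded distance is smallest ('near')."""
        return int(np.argmin(self.class_distance_means(tensors)))

    # -- persistence --------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"enc.{k}": v for k, v in self.encoder.state_arrays().items()}
        arrays.update({f"dec.{k}": v for k, v in self.decoder.state_arrays().items()})
        arrays["codebook.vectors"] = self.codebook.vectors
        arrays["codebook.ema_counts"] = self.codebook.ema_counts
        arrays["codebook.ema_sums"] = self.codebook.ema_sums
        arrays["config"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "VqVae":
        data = np.load(path)
        cfg = CodecConfig(**json.loads(bytes(data["config"]).decode()))
        model = cls(cfg, seed=0)
        model.encoder.load_state_arrays(
            {k[4:]: data[k] for k in data.files if k.startswith("enc.")})
        model.decoder.load_state_arrays(
            {k[4:]: data[k] for k in data.files if k.startswith("dec.")})
        model.codebook = Codebook(data["codebook.vectors"],
                                  data["codebook.ema_counts"],
                                  data["codebook.ema_sums"])
        return model


def ema_update(codebook: Codebook, assignments: np.ndarray, embeddings: np.ndarray,
               decay: float, rng: np.random.Generator | None = None) -> None:
    """EMA codebook step: counts/sums decay toward the batch statistics.

    Codes unused in this batch whose EMA count has decayed to (almost)
    nothing are revived at a random batch embedding.
    """
    K = len(codebook.vectors)
    counts = np.bincount(assignments, minlength=K).astype(np.float64)
    sums = np.zeros_like(codebook.ema_sums)
    np.add.at(sums, assignments, embeddings.astype(np.float64))
    codebook.ema_counts = decay * codebook.ema_counts + (1 - decay) * counts
    codebook.ema_sums = decay * codebook.ema_sums + (1 - decay) * sums
    codebook.vectors = (codebook.ema_sums /
                        np.maximum(codebook.ema_counts, 1e-5)[:, None]).astype(np.float32)
    if rng is None:
        return
    mean_count = max(codebook.ema_counts.mean(), 1e-9)
    for k in range(K):
        if counts[k] == 0 and codebook.ema_counts[k] < 0.01 * mean_count:
            pick = embeddings[rng.integers(len(embeddings))].astype(np.float64)
            codebook.vectors[k] = pick.astype(np.float32)
            codebook.ema_sums[k] = pick * mean_count
            codebook.ema_counts[k] = mean_count


def _kmeanspp_init(points: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    from sklearn.cluster import kmeans_plusplus

    centers, _ = kmeans_plusplus(points.astype(np.float64), n_clusters=K,
                                 random_state=int(rng.integers(2 ** 31 - 1)))
    return centers.astype(np.float32)


def train_vqvae(dataset: list[DistanceTensor], config: CodecConfig,
                seed: int = 0) -> VqVae:
    """Train encoder, decoder and codebook on a set of distance tensors.

    Reconstruction loss is a mask-weighted squared error, so padded and
    missing-atom entries carry no gradient.  Deterministic given seed.
    """
    if not dataset:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    model = VqVae(config, seed=seed)
    padded = [pad_tensor(t, config.max_len) for t in dataset]
    Ds = np.stack([d * m for d, m in padded])
    Ms = np.stack([m for _, m in padded])

    opt = nn.Adam(model.encoder.parameters() + model.decoder.parameters(),
                  lr=config.lr)
    eyeK = np.eye(config.K, dtype=np.float32)

    # codebook init: k-means++ on the first batch's embeddings
    first = rng.choice(len(dataset), size=min(config.batch, len(dataset)), replace=False)
    e0 = symmetrize_embedding(model.encode_continuous(Ds[first]))
    pv0 = Ms[first].any(axis=-1)
    model.codebook = Codebook(_kmeanspp_init(e0[pv0], config.K, rng))

    decay = config.ema_decay
    for step in range(config.steps):
        idx = rng.choice(len(dataset), size=min(config.batch, len(dataset)),
                         replace=len(dataset) < config.batch)
        x, m = Ds[idx], Ms[idx]
        pv = m.any(axis=-1)  # (N, mx, mx) valid-pixel mask

        e = model.encode_continuous(x, train=True)
        e_sym = symmetrize_embedding(e)
        d2 = model._dist2(e_sym)  # (N, mx, mx, K)
        assign = np.argmin(d2, axis=-1)
        onehot = eyeK[assign]
        recon = model.decode(onehot, train=True)

        denom = max(m.sum(), 1.0)
        resid = (recon - x) * m
        loss_recon = float((resid ** 2).sum() / denom)
        q = model.codebook.vectors[assign]
        commit_resid = (e_sym - q) * pv[..., None]
        loss_commit = float((commit_resid ** 2).sum() / max(pv.sum(), 1))
        if not np.isfinite(loss_recon) or not np.isfinite(loss_commit):
            raise RuntimeError(f"training diverged (NaN loss) at step {step}")
        model.history["recon"].append(loss_recon)
        model.history["commit"].append(loss_commit)

        # backward: decoder -> straight-through softmax -> encoder
        model.encoder.zero_grad()
        model.decoder.zero_grad()
        d_recon = (2.0 / denom) * resid
        d_onehot = model.decoder.backward(d_recon.astype(np.float32))
        # adaptive temperature keeps the soft assignment from saturating
        # (a near-delta softmax would starve the encoder of gradient)
        tau = max(float(np.median(d2[pv])), 1e-6)
        logits = -d2 / tau
        p = np.exp(logits - logits.max(axis=-1, keepdims=True))
        p /= p.sum(axis=-1, keepdims=True)
        dp = d_onehot
        d_logits = p * (dp - (dp * p).sum(axis=-1, keepdims=True))
        d_d2 = -d_logits / tau
        de_sym = 2.0 * (d_d2[..., None] * (e_sym[..., None, :] -
                                           model.codebook.vectors)).sum(axis=-2)
        de_sym += (2.0 * config.beta / max(pv.sum(), 1)) * commit_resid
        de = symmetrize_embedding(de_sym)
        model.encoder.backward(de.astype(np.float32))
        opt.step()

        # EMA codebook update over valid pixels
        ema_update(model.codebook, assign[pv], e_sym[pv], decay, rng)
    return model


def masked_rmse(t: DistanceTensor, recon: np.ndarray) -> float:
    sel = t.M.astype(bool)
    return float(np.sqrt(np.mean((t.D[sel] - recon[sel]) ** 2)))


def reconstruction_error(model: VqVae, heldout: list[DistanceTensor]) -> float:
    """Median over structures of the valid-entry RMSE after encode/decode."""
    if not heldout:
        raise ValueError("empty held-out set")
    errs = []
    for t in heldout:
        cm = model.encode(t)
        recon = model.decode_classmap(cm, mask=t.M)
        errs.append(masked_rmse(t, recon))
    return float(np.median(errs))
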