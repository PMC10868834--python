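"""Shared fixtures: synthetic datasets and (expensive) trained models.

Model-training fixtures are session-scoped so the distance-class codec,
generator and score model are trained once and reused across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from rnadistgen.codec import build_distance_tensor
from rnadistgen.generator import GeneratorConfig, make_examples, train_generator
from rnadistgen.score import ScoreConfig, flip_pixels, make_negatives, train_score
from rnadistgen.synthetic import make_fixture_dataset
from rnadistgen.vqvae import CodecConfig, train_vqvae


@pytest.fixture(scope="session")
def fixture_dataset():
    """Small clustered fixture collection for pipeline-level tests."""
    return make_fixture_dataset(20, (10, 13), seed=11, n_drift=4)


@pytest.fixture(scope="session")
def random_structures():
    """Structures with random (non-folded) coordinates for codec oracles."""
    from rnadistgen import codec

    rng = np.random.default_rng(42)
    out = []
    for _ in range(12):
        L = int(rng.integers(4, 9))
        seq = "".join(rng.choice(list("ACGU"), size=L))
        residues = []
        for b in seq:
            fam = codec.PURINE_SLOTS if b in "AG" else codec.PYRIMIDINE_SLOTS
            atoms = {n: rng.normal(scale=9, size=3) for n in fam}
            if rng.random() < 0.3:
                atoms.pop("P")  # emulate the missing leading phosphate
            residues.append(codec.encode_residue(b, atoms))
        out.append(codec.Structure3D(seq, residues, id=f"rand{len(out)}"))
    return out


@pytest.fixture(scope="session")
def e2e():
    """End-to-end chain: 10 fixtures -> VQ-VAE -> generator -> score model."""
    ds = make_fixture_dataset(10, (10, 12), seed=7, n_drift=3)
    data = [(f.sequence, build_distance_tensor(f.structure)) for f in ds.fixtures]
    tensors = [t for _, t in data]
    vq = train_vqvae(tensors, CodecConfig(K=3, max_len=12, lr=1e-3, batch=8,
                                          steps=120), seed=0)
    gen = train_generator(
        data, vq,
        GeneratorConfig(max_len=12, batch=5, lr=1e-3, weight_decay=1e-4,
                        warmup_steps=50, steps=320), seed=0)
    examples = make_examples(data, vq)
    rng = np.random.default_rng(5)
    drift_items = [(f.sequence, build_distance_tensor(f.structure),
                    [build_distance_tensor(d) for d in f.drifts[:2]])
                   for f in ds.fixtures]
    pairs = make_negatives(drift_items, vq, rng, generator=None, n_flips=10)
    net = train_score(pairs, ScoreConfig(max_len=12, batch=24, steps=250), seed=0)
    return {
        "dataset": ds,
        "data": data,
        "tensors": tensors,
        "vqvae": vq,
        "generator": gen,
        "examples": examples,
        "score": net,
    }


def make_flipped(cm, fraction, seed):
    return flip_pixels(cm, fraction, np.random.default_rng(seed))
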