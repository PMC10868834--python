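"""Synthetic RNA-like fixtures: structures, drift variants, homologs, SHAPE.

The generator builds geometrically consistent (not thermodynamically
realistic) 3D folds from nested dot-bracket secondary structures: a
C4' backbone trace is obtained by minimising a spring energy with
backbone-bond, base-pair and excluded-volume terms, and the remaining
reduced-representation atoms are placed in local backbone frames.
Paired residues end up close (stems), unpaired distant residues far —
the statistical structure every downstream module assumes.

Drift variants emulate coarse-grained MD "drift" runs by chain-smoothed
Gaussian displacements rescaled to an exact target RMSD, optionally
weighted by per-residue flexibility (loops drift more than stems) so
that simulated SHAPE profiles correlate with secondary structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize

from .codec import ResidueCoords, Structure3D, build_distance_tensor
from .pipeline import HomologSet, similarity_matrix, cluster_sequences, \
    split_by_cluster, simulate_shape

log = logging.getLogger(__name__)

# backbone geometry constants (Å) — chosen once for geometric consistency
BOND_DIST = 5.9        # consecutive C4'-C4'
PAIR_DIST = 10.5       # C4'-C4' across a base pair
NEXT2_DIST = 9.5       # loose i,i+2 stiffness target
REPULSION_FLOOR = 13.0  # soft excluded volume for distant residues


@dataclass
class ToySpec:
    length: int
    secondary_structure: str
    helix_rise: float = 2.8
    helix_twist: float = 32.7
    seed: int = 0

    def __post_init__(self):
        if self.length != len(self.secondary_structure):
            raise ValueError("length does not match secondary structure")
        parse_dotbracket(self.secondary_structure)  # validates balance


@dataclass
class DriftSpec:
    target_rmsd: float = 3.0
    n_variants: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.target_rmsd < 0:
            raise ValueError("target_rmsd must be nonnegative")


#: presets: a few medium drifts vs the full augmentation ladder
DRIFT_PRESET_MAIN = [DriftSpec(3.0, 5)]
DRIFT_PRESET_AUGMENT = [DriftSpec(r, 100) for r in (1.0, 3.0, 5.0, 10.0)]


def parse_dotbracket(db: str) -> list[tuple[int, int]]:
    """Nested dot-bracket -> base-pair list; unbalanced input rejected."""
    stack, pairs = [], []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced brackets")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"unexpected character {c!r}")
    if stack:
        raise ValueError("unbalanced brackets")
    return sorted(pairs)


def _backbone_trace(L: int, pairs: list[tuple[int, int]],
                    rng: np.random.Generator) -> np.ndarray:
    """C4' trace minimising bond/pair/stiffness/excluded-volume springs."""
    paired = set()
    for i, j in pairs:
        paired.add((i, j))
    # init: open circle with radius matching the bond length, 3D jitter
    theta = np.linspace(0.0, 1.5 * np.pi, L)
    r = BOND_DIST / max(2 * np.sin(0.75 * np.pi / max(L - 1, 1)), 1e-6)
    X0 = np.stack([r * np.cos(theta), r * np.sin(theta),
                   rng.normal(scale=1.0, size=L)], axis=1)

    bonds = [(i, i + 1, BOND_DIST, 10.0) for i in range(L - 1)]
    bonds += [(i, i + 2, NEXT2_DIST, 0.5) for i in range(L - 2)]
    bonds += [(i, j, PAIR_DIST, 10.0) for i, j in pairs]
    rep = [(i, j) for i in range(L) for j in range(i + 3, L)
           if (i, j) not in paired]
    bi = np.array([b[0] for b in bonds])
    bj = np.array([b[1] for b in bonds])
    bd = np.array([b[2] for b in bonds])
    bw = np.array([b[3] for b in bonds])
    ri = np.array([p[0] for p in rep], dtype=int)
    rj = np.array([p[1] for p in rep], dtype=int)

    def energy(flat):
        X = flat.reshape(L, 3)
        g = np.zeros_like(X)
        d = X[bi] - X[bj]
        dist = np.sqrt((d ** 2).sum(1)) + 1e-9
        resid = dist - bd
        e = float((bw * resid ** 2).sum())
        coef = (2 * bw * resid / dist)[:, None] * d
        np.add.at(g, bi, coef)
        np.add.at(g, bj, -coef)
        if len(ri):
            d2 = X[ri] - X[rj]
            dist2 = np.sqrt((d2 ** 2).sum(1)) + 1e-9
            viol = np.maximum(REPULSION_FLOOR - dist2, 0.0)
            e += float((viol ** 2).sum())
            coef2 = (-2 * viol / dist2)[:, None] * d2
            np.add.at(g, ri, coef2)
            np.add.at(g, rj, -coef2)
        return e, g.ravel()

    res = minimize(energy, X0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-12})
    return res.x.reshape(L, 3)


_PURINE_BASE_SLOTS = (4, 2, 3)     # N9 (glycosidic), C2, C6
_PYRIMIDINE_BASE_SLOTS = (7, 6, 5)  # N1 (glycosidic), C4, C2


def _place_atoms(seq: str, trace: np.ndarray,
                 pairs: list[tuple[int, int]]) -> Structure3D:
    L = len(seq)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    residues = []
    for i, base in enumerate(seq):
        lo, hi = max(i - 1, 0), min(i + 1, L - 1)
        t = trace[hi] - trace[lo]
        t /= np.linalg.norm(t) + 1e-9
        if i in partner:
            toward = trace[partner[i]] - trace[i]
        else:
            toward = trace[i] - trace.mean(axis=0)  # loops point outward
        n = toward - (toward @ t) * t
        norm = np.linalg.norm(n)
        n = n / norm if norm > 1e-6 else np.array([t[1], -t[0], 0.0])
        b = np.cross(t, n)
        coords = np.zeros((8, 3))
        # P bridges the previous residue; C4' sits on the trace
        coords[0] = (trace[max(i - 1, 0)] + trace[i]) / 2.0 + 1.2 * b
        coords[1] = trace[i]
        glyco, ring1, ring2 = (_PURINE_BASE_SLOTS if base in "AG"
                               else _PYRIMIDINE_BASE_SLOTS)
        coords[glyco] = trace[i] + 3.4 * n
        coords[ring1] = trace[i] + 4.6 * n + 1.2 * t
        coords[ring2] = trace[i] + 4.9 * n - 1.1 * t
        mask = np.zeros(8, dtype=np.int8)
        mask[[0, 1, glyco, ring1, ring2]] = 1
        residues.append(ResidueCoords(base, coords * mask[:, None], mask))
    return Structure3D(seq, residues)


def gen_toy_structure(spec: ToySpec, sequence: str | None = None) -> Structure3D:
    """Deterministic RNA-like structure for a dot-bracket specification."""
    pairs = parse_dotbracket(spec.secondary_structure)
    rng = np.random.default_rng(spec.seed)
    if sequence is None:
        sequence = design_sequence(spec.secondary_structure, rng)
    if len(sequence) != spec.length:
        raise ValueError("sequence length mismatch")
    trace = _backbone_trace(spec.length, pairs, rng)
    s = _place_atoms(sequence, trace, pairs)
    s.id = f"toy-{spec.seed}"
    return s


_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def design_sequence(db: str, rng: np.random.Generator) -> str:
    """Random sequence compatible with the dot-bracket (paired = WC).

    Stems are GC-biased (70%) so the designed hairpin is also the
    minimum-free-energy structure for realistic folding engines.
    """
    letters = [""] * len(db)
    for i, j in parse_dotbracket(db):
        b = ("GC"[rng.integers(2)] if rng.random() < 0.7
             else "AU"[rng.integers(2)])
        letters[i], letters[j] = b, _COMPLEMENT[b]
    for i, c in enumerate(db):
        if c == ".":
            letters[i] = "ACGU"[rng.integers(4)]
    return "".join(letters)


def fold_sequence(seq: str) -> str:
    """Minimum-free-energy secondary structure (nested) for a sequence."""
    try:
        import RNA

        db, _ = RNA.fold(seq)
        return db
    except ImportError:  # pragma: no cover - fallback DP
        return _nussinov(seq)


def _nussinov(seq: str, min_loop: int = 3) -> str:
    """Base-pair-maximising fallback fold (Nussinov recursion)."""
    L = len(seq)
    can = lambda a, b: _COMPLEMENT.get(a) == b or {a, b} == {"G", "U"}
    dp = np.zeros((L, L), dtype=int)
    for span in range(min_loop + 1, L):
        for i in range(L - span):
            j = i + span
            best = dp[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if can(seq[i], seq[k]):
                    left = dp[i + 1, k - 1] if k - 1 > i else 0
                    right = dp[k + 1, j] if k + 1 <= j else 0
                    best = max(best, 1 + left + right)
            dp[i, j] = best
    db = ["."] * L

    def trace(i, j):
        if j - i <= min_loop:
            return
        if dp[i, j] == dp[i + 1, j]:
            trace(i + 1, j)
            return
        for k in range(i + min_loop + 1, j + 1):
            if can(seq[i], seq[k]):
                left = dp[i + 1, k - 1] if k - 1 > i else 0
                right = dp[k + 1, j] if k + 1 <= j else 0
                if dp[i, j] == 1 + left + right:
                    db[i], db[k] = "(", ")"
                    trace(i + 1, k - 1)
                    trace(k + 1, j)
                    return

    trace(0, L - 1)
    return "".join(db)


def flexibility_weights(db: str, stem: float = 0.4, loop: float = 2.0) -> np.ndarray:
    """Per-residue drift amplitude: loops more mobile than stems."""
    return np.array([loop if c == "." else stem for c in db])


def gen_drift(structure: Structure3D, spec: DriftSpec,
              flex: np.ndarray | None = None) -> list[Structure3D]:
    """Chain-smoothed Gaussian drift variants at an exact target RMSD."""
    rng = np.random.default_rng(spec.seed)
    L = len(structure)
    mask = structure.mask_array().astype(bool)  # (L, 8)
    n_atoms = mask.sum()
    out = []
    for v in range(spec.n_variants):
        if spec.target_rmsd == 0:
            out.append(structure.transformed(np.eye(3), np.zeros(3)))
            continue
        disp = gaussian_filter1d(rng.normal(size=(L, 3)), sigma=2.0, axis=0)
        if flex is not None:
            disp = disp * np.asarray(flex)[:, None]
        # per-residue rigid displacement; exact rescale to the target RMSD
        sq = (disp ** 2).sum(axis=1) @ mask.sum(axis=1)
        realized = np.sqrt(sq / n_atoms)
        disp *= spec.target_rmsd / max(realized, 1e-12)
        residues = []
        for i, r in enumerate(structure.residues):
            c = (r.coords + disp[i]) * r.atom_mask[:, None]
            residues.append(ResidueCoords(r.base, c, r.atom_mask.copy()))
        out.append(Structure3D(structure.sequence, residues,
                               id=f"{structure.id}-drift{v}"))
    return out


def gen_homolog_alignment(seq: str, n: int, sub_rate: float, del_rate: float,
                          seed: int = 0) -> tuple[list[str], list[float]]:
    """Gapped homolog rows (substitutions + deletions, never insertions).

    Every row carries at least one substitution; synthetic E-values are
    all below the 0.01 acceptance threshold.
    """
    if n < 1:
        raise ValueError("need at least one homolog")
    if not 0 <= sub_rate < 1 or not 0 <= del_rate < 1:
        raise ValueError("rates must lie in [0, 1)")
    if sub_rate == 0:
        raise ValueError("sub_rate 0 cannot satisfy the >=1 substitution rule")
    rng = np.random.default_rng(seed)
    rows, evals = [], []
    for _ in range(n):
        while True:
            chars, n_subs = [], 0
            for b in seq:
                if rng.random() < del_rate:
                    chars.append("-")
                elif rng.random() < sub_rate:
                    chars.append("ACGU"[(("ACGU".index(b)) +
                                         1 + rng.integers(3)) % 4])
                    n_subs += 1
                else:
                    chars.append(b)
            if n_subs >= 1:
                break
        rows.append("".join(chars))
        evals.append(float(10.0 ** rng.uniform(-10, -3)))
    return rows, evals


def write_homolog_alignment(path, rows: list[str], e_values: list[float]) -> None:
    with open(path, "w") as fh:
        for r, e in zip(rows, e_values):
            fh.write(f"{r}\t{e:.3e}\n")


def homolog_set_from_rows(rows: list[str], e_values: list[float],
                          query: str) -> HomologSet:
    from .generator import fill_homolog_rows

    clean = [r.replace("-", "N") for r in rows]
    filled = fill_homolog_rows(clean, query)
    evals = list(e_values) + [0.0] * (len(filled) - len(clean))
    return HomologSet(filled, evals)


@dataclass
class Fixture:
    """One synthetic study item with everything downstream modules need."""

    id: str
    sequence: str
    secondary_structure: str
    structure: Structure3D
    drifts: list[Structure3D]
    shape_sim: np.ndarray
    homologs: HomologSet
    cluster_id: int = -1
    split: str = ""


@dataclass
class FixtureDataset:
    fixtures: list[Fixture]
    manifest: dict = field(default_factory=dict)

    def tensors(self, split: str | None = None):
        return [build_distance_tensor(f.structure) for f in self.fixtures
                if split is None or f.split == split]

    def by_split(self, split: str) -> list[Fixture]:
        return [f for f in self.fixtures if f.split == split]


def _random_dotbracket(L: int, rng: np.random.Generator) -> str:
    """Hairpin with random stem/loop/tail partition (nested, balanced)."""
    stem = int(rng.integers(3, max(4, (L - 4) // 2) + 1))
    stem = min(stem, (L - 3) // 2)
    loop = L - 2 * stem
    loop_used = int(rng.integers(3, max(4, loop - 1) + 1)) if loop > 4 else loop
    tail = loop - loop_used
    t5 = int(rng.integers(0, tail + 1))
    t3 = tail - t5
    return "." * t5 + "(" * stem + "." * loop_used + ")" * stem + "." * t3


def make_fixture_dataset(n_structures: int, length_range: tuple[int, int],
                         seed: int = 0, n_drift: int = 5,
                         drift_rmsd: float = 3.0, n_homologs: int = 8,
                         refold: bool = True) -> FixtureDataset:
    """Generate a clustered, split, fully annotated fixture collection.

    Secondary structures are sampled as hairpins, sequences designed
    Watson-Crick-compatible and (optionally) refolded so the mapping
    sequence -> structure is deterministic and learnable.
    """
    if n_structures < 1:
        raise ValueError("need at least one structure")
    rng = np.random.default_rng(seed)
    fixtures = []
    for i in range(n_structures):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        db = _random_dotbracket(L, rng)
        seq = design_sequence(db, rng)
        if refold:
            db2 = fold_sequence(seq)
            if "(" in db2:
                db = db2
        spec = ToySpec(L, db, seed=int(rng.integers(2 ** 31 - 1)))
        structure = gen_toy_structure(spec, sequence=seq)
        structure.id = f"fix{i:04d}"
        flex = flexibility_weights(db)
        drifts = gen_drift(structure,
                           DriftSpec(drift_rmsd, n_drift,
                                     seed=int(rng.integers(2 ** 31 - 1))),
                           flex=flex)
        shape = simulate_shape(structure, drifts)
        rows, evals = gen_homolog_alignment(
            seq, n_homologs, sub_rate=0.15, del_rate=0.05,
            seed=int(rng.integers(2 ** 31 - 1)))
        fixtures.append(Fixture(structure.id, seq, db, structure, drifts,
                                shape, homolog_set_from_rows(rows, evals, seq)))
    S = similarity_matrix([[f.sequence] for f in fixtures])
    clusters = cluster_sequences(S) if n_structures > 1 else np.zeros(1, int)
    splits = split_by_cluster(clusters, [], rng)
    for f, c, sp in zip(fixtures, clusters, splits):
        f.cluster_id, f.split = int(c), str(sp)
    manifest = {
        "n_structures": n_structures,
        "entries": [{
            "id": f.id, "sequence": f.sequence,
            "secondary_structure": f.secondary_structure,
            "cluster": f.cluster_id, "split": f.split,
            "length": len(f.sequence),
            "n_drifts": len(f.drifts),
            "shape_sim": [round(float(x), 4) for x in f.shape_sim],
        } for f in fixtures],
        "similarity_cutoff": 0.7,
    }
    return FixtureDataset(fixtures, manifest)
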