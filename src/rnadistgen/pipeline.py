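"""Dataset engineering: filtering, clustering, leakage-free splits,
cropping with contact flags, sampling weights, SHAPE handling, homologs.

The curation rules mirror how crystallographic/NMR RNA collections are
prepared for structure learning: RNA-only entries, standard residues,
minimum chain lengths, hierarchical sequence-similarity clustering at
0.7 with whole clusters assigned to one split (so no near-duplicate
sequence leaks across train/validation/test), random 100-nt crops of
long chains with "contact nucleotides" (< 3.3 Å to the discarded
remainder) flagged, and two-stage sampling weights (uniform over
clusters, length-proportional within).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .codec import Structure3D

log = logging.getLogger(__name__)

RNA_ALPHABET = set("ACGU")


@dataclass
class StructureRecord:
    """Metadata wrapper used by the filtering stage."""

    id: str
    chains: list[str]  # chain sequences (may contain non-ACGU letters)
    method: str | None = None  # "diffraction" | "NMR" | other
    resolution: float | None = None
    rna_only: bool = True
    structures: list[Structure3D] | None = None


@dataclass
class CropRecord:
    chain_index: int
    start: int
    length: int
    contact_flags: np.ndarray
    kept: bool


@dataclass
class HomologSet:
    """Gap-free-width alignment rows (gaps already replaced by 'N')."""

    rows: list[str]
    e_values: list[float] = field(default_factory=list)

    def __post_init__(self):
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("homolog rows differ in length")


@dataclass
class DatasetEntry:
    record: StructureRecord
    cluster_id: int = -1
    split: str = ""
    bgsu_class: str | None = None
    crops: list[CropRecord] = field(default_factory=list)
    drifts: list[Structure3D] = field(default_factory=list)
    shape_sim: np.ndarray | None = None

    @property
    def length(self) -> int:
        return sum(len(c) for c in self.record.chains)


# ---------------------------------------------------------------- filtering

ACCEPTED_METHODS = {"diffraction", "x-ray", "xray", "nmr"}


def filter_structures(records: list[StructureRecord],
                      resolution_cutoff: float = 4.0):
    """Apply the curation rules; returns (kept, rejection log).

    Keep iff: RNA-only entry; X-ray/NMR when the method is known;
    resolution < cutoff when known; residues all A/C/G/U; every chain
    >= 14 nt (>= 7 nt for multi-chain entries); for >= 3 chains all
    chain sequences unique.
    """
    kept, rejected = [], []
    for rec in records:
        rule = None
        n_chains = len(rec.chains)
        min_len = 7 if n_chains > 1 else 14
        if not rec.rna_only:
            rule = "i:not-rna-only"
        elif rec.method is not None and rec.method.lower() not in ACCEPTED_METHODS:
            rule = "ii:method"
        elif rec.resolution is not None and rec.resolution >= resolution_cutoff:
            rule = "resolution"
        elif any(set(c) - RNA_ALPHABET for c in rec.chains):
            rule = "iv:non-acgu"
        elif n_chains == 0 or any(len(c) < min_len for c in rec.chains):
            rule = "v:too-short"
        elif n_chains >= 3 and len(set(rec.chains)) != n_chains:
            rule = "vi:duplicate-chains"
        if rule is None:
            kept.append(rec)
        else:
            rejected.append((rec.id, rule))
            log.info("rejected %s (%s)", rec.id, rule)
    return kept, rejected


# ---------------------------------------------------------------- similarity

def _aligner():
    from Bio import Align

    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -1
    a.extend_gap_score = 0
    return a


def similarity_score(seq_a: str, seq_b: str) -> float:
    """Global-alignment score (match +1, mismatch/open -1, extend 0)
    normalised by the longer sequence length."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    score = _aligner().score(seq_a, seq_b)
    return float(score) / max(len(seq_a), len(seq_b))


def structure_similarity(chains_a: list[str], chains_b: list[str]) -> float:
    """Multichain similarity: chain scores summed before normalisation."""
    aligner = _aligner()
    total = 0.0
    remaining = list(chains_b)
    for ca in chains_a:
        if not remaining:
            break
        scores = [aligner.score(ca, cb) for cb in remaining]
        best = int(np.argmax(scores))
        total += scores[best]
        remaining.pop(best)
    la = max(sum(len(c) for c in chains_a), sum(len(c) for c in chains_b))
    return total / la


def similarity_matrix(seq_lists: list[list[str]]) -> np.ndarray:
    n = len(seq_lists)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = structure_similarity(seq_lists[i], seq_lists[j])
    return S


def cluster_sequences(score_matrix: np.ndarray, cutoff: float = 0.7) -> np.ndarray:
    """Complete-linkage clustering on 1 - similarity, cut at 1 - cutoff.

    Complete linkage guarantees within-cluster minimum similarity >= cutoff.
    Returns 0-based cluster ids.
    """
    S = np.asarray(score_matrix, dtype=float)
    if S.shape[0] != S.shape[1] or not np.allclose(S, S.T):
        raise ValueError("score matrix must be square and symmetric")
    if S.shape[0] == 1:
        return np.zeros(1, dtype=int)
    D = np.clip(1.0 - S, 0.0, None)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="complete")
    ids = fcluster(Z, t=1.0 - cutoff, criterion="distance")
    return ids - 1


def split_by_cluster(clusters: np.ndarray, test_anchor_ids,
                     rng: np.random.Generator,
                     fractions: tuple[float, float] = (0.75, 0.2)) -> np.ndarray:
    """Assign whole clusters to train/val/test; anchors force test.

    ``test_anchor_ids`` are entry indices whose clusters go to the test
    split entirely.  Remaining clusters are shuffled and assigned
    train/val by the given fractions, the rest to test.
    Returns an array of split labels per entry.
    """
    clusters = np.asarray(clusters)
    anchor_clusters = {int(clusters[i]) for i in test_anchor_ids}
    other = sorted(set(clusters.tolist()) - anchor_clusters)
    other = [other[i] for i in rng.permutation(len(other))]
    n = len(other)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    assignment: dict[int, str] = {c: "test" for c in anchor_clusters}
    for k, c in enumerate(other):
        assignment[c] = "train" if k < n_train else (
            "val" if k < n_train + n_val else "test")
    return np.array([assignment[int(c)] for c in clusters])


def audit_split_leakage(splits: np.ndarray, score_matrix: np.ndarray,
                        cutoff: float = 0.7) -> list[tuple[int, int]]:
    """Cross-split entry pairs with similarity >= cutoff (should be empty)."""
    bad = []
    n = len(splits)
    for i in range(n):
        for j in range(i + 1, n):
            if splits[i] != splits[j] and score_matrix[i, j] >= cutoff:
                bad.append((i, j))
    return bad


# ---------------------------------------------------------------- cropping

CONTACT_DISTANCE = 3.3  # Å


def _valid_coords(s: Structure3D) -> list[np.ndarray]:
    out = []
    for r in s.residues:
        sel = r.atom_mask.astype(bool)
        out.append(r.coords[sel])
    return out


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0 or len(b) == 0:
        return np.inf
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).min())


def select_chain_and_crop(chains: list[Structure3D], rng: np.random.Generator,
                          max_len: int = 100,
                          contact_max_fraction: float = 0.05):
    """Length-proportional chain choice, random crop, contact flags.

    Residues of the crop closer than 3.3 Å (any represented-atom pair)
    to the remaining structure are flagged; the crop is kept only if
    the flagged fraction is below 5%.  A single short chain is returned
    as an identity crop with no flags.
    """
    if not chains:
        raise ValueError("no chains")
    lengths = np.array([len(c) for c in chains], dtype=float)
    if len(chains) == 1 and lengths[0] <= max_len:
        sub = chains[0]
        rec = CropRecord(0, 0, len(sub), np.zeros(len(sub), dtype=bool), True)
        return rec, sub
    ci = int(rng.choice(len(chains), p=lengths / lengths.sum()))
    chain = chains[ci]
    if len(chain) > max_len:
        start = int(rng.integers(0, len(chain) - max_len + 1))
        length = max_len
    else:
        start, length = 0, len(chain)
    sub = Structure3D(chain.sequence[start:start + length],
                      chain.residues[start:start + length],
                      id=f"{chain.id}[{start}:{start + length}]")
    crop_atoms = _valid_coords(sub)
    rest: list[np.ndarray] = []
    for k, other in enumerate(chains):
        coords = _valid_coords(other)
        if k == ci:
            coords = coords[:start] + coords[start + length:]
        rest.extend(coords)
    rest_arr = np.concatenate(rest) if rest else np.zeros((0, 3))
    flags = np.array([_min_dist(c, rest_arr) < CONTACT_DISTANCE for c in crop_atoms])
    kept = flags.mean() < contact_max_fraction if length else False
    return CropRecord(ci, start, length, flags, bool(kept)), sub


def contact_fixed_pairs(flags: np.ndarray, classmap) -> dict:
    """(i, j) -> class for all pairs of flagged (contact) residues."""
    idx = np.flatnonzero(flags)
    return {(int(i), int(j)): int(classmap.classes[i, j])
            for a, i in enumerate(idx) for j in idx[a + 1:]}


# ---------------------------------------------------------------- weights

def sampling_weights(cluster_ids: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Uniform over clusters, length-proportional within; sums to one."""
    cluster_ids = np.asarray(cluster_ids)
    lengths = np.asarray(lengths, dtype=float)
    weights = np.zeros(len(cluster_ids))
    uniq = np.unique(cluster_ids)
    for c in uniq:
        sel = cluster_ids == c
        total = lengths[sel].sum()
        if total <= 0:
            continue
        weights[sel] = (1.0 / len(uniq)) * lengths[sel] / total
    return weights / weights.sum()


# ---------------------------------------------------------------- SHAPE

def _kabsch_align(mobile: Structure3D, ref: Structure3D) -> Structure3D:
    """Proper-rotation superposition of mobile onto ref (shared valid atoms)."""
    mm = mobile.mask_array().astype(bool) & ref.mask_array().astype(bool)
    sel = mm.reshape(-1)
    P = ref.coords_array().reshape(-1, 3)[sel]
    Q = mobile.coords_array().reshape(-1, 3)[sel]
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - qc).T @ (P - pc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det((U @ Vt).T))
    R = (U @ np.diag([1.0, 1.0, d]) @ Vt).T
    return mobile.transformed(R, pc - R @ qc)


def simulate_shape(original: Structure3D, drifts: list[Structure3D]) -> np.ndarray:
    """Per-nucleotide mean positional deviation across aligned drift variants.

    A proxy for SHAPE reactivity: flexible (loop) residues drift more
    than base-paired (stem) residues, so their deviation is larger.
    """
    if not drifts:
        raise ValueError("no drift structures supplied")
    L = len(original)
    acc = np.zeros(L)
    for d in drifts:
        if len(d) != L:
            raise ValueError("drift length mismatch")
        aligned = _kabsch_align(d, original)
        for i in range(L):
            m = (original.residues[i].atom_mask.astype(bool)
                 & aligned.residues[i].atom_mask.astype(bool))
            diff = original.residues[i].coords[m] - aligned.residues[i].coords[m]
            acc[i] += np.sqrt((diff ** 2).sum(axis=1).mean())
    return acc / len(drifts)


def rescale_experimental_shape(exp: np.ndarray, sim_reference: np.ndarray) -> np.ndarray:
    """Quantile-map experimental reactivities onto the simulated distribution.

    Each experimental value is replaced by the simulated distribution's
    value at the same percentile (linear interpolation), so any
    monotone transform of the input yields the same output.
    """
    exp = np.asarray(exp, dtype=float)
    ref = np.sort(np.asarray(sim_reference, dtype=float))
    if len(ref) == 0:
        raise ValueError("empty reference distribution")
    if len(exp) == 0:
        return exp.copy()
    from scipy.stats import rankdata

    if len(exp) == 1:
        pct = np.array([0.5])
    else:
        pct = (rankdata(exp, method="average") - 1.0) / (len(exp) - 1.0)
    return np.quantile(ref, pct, method="linear")


# ---------------------------------------------------------------- homologs

E_VALUE_CUTOFF = 0.01


def load_homologs(path, query: str) -> HomologSet:
    """Read `gapped-sequence  e-value` rows; filter, gap->N, fill to 50.

    Kept rows need E < 0.01, the exact alignment width of the query (no
    insertion columns) and at least one mutation other than a deletion.
    """
    rows, evals = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            seq = parts[0].upper()
            e = float(parts[1]) if len(parts) > 1 else 0.0
            if e >= E_VALUE_CUTOFF:
                continue
            if len(seq) != len(query):
                log.info("dropping homolog row %d: width mismatch", lineno)
                continue
            if not any(c not in ("-", ".") and c != q
                       for c, q in zip(seq, query)):
                continue  # needs >= 1 mutation other than a deletion
            rows.append(seq.replace("-", "N").replace(".", "N"))
            evals.append(e)
    n_real = len(rows)
    from .generator import N_HOMOLOG_ROWS

    while len(rows) < N_HOMOLOG_ROWS:
        rows.append(query)
        evals.append(0.0)
    hs = HomologSet(rows[:N_HOMOLOG_ROWS], evals[:N_HOMOLOG_ROWS])
    log.info("loaded %d homologs (+%d query fill rows)", n_real,
             len(hs.rows) - n_real)
    return hs
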