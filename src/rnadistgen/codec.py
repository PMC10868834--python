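"""Reduced-atom RNA structure representation and distance tensors.

Each nucleotide is pinned in space by 5 of its atoms.  Purines (A/G)
use P, C4', C2, C6, N9; pyrimidines (C/U) use P, C4', C2, C4, N1.
Because the base C2 sits at a different ring position in the two
families, the two atom sets occupy disjoint slots of a shared 8-slot
layout (P and C4' are common):

    slot 0  P            slot 4  N9  (purine)
    slot 1  C4'          slot 5  C2  (pyrimidine)
    slot 2  C2 (purine)  slot 6  C4  (pyrimidine)
    slot 3  C6 (purine)  slot 7  N1  (pyrimidine)

A length-L chain becomes an L x L x 64 tensor of inter-atom Euclidean
distances (channel 8p+q pairs slot p of residue i with slot q of
residue j) together with a binary validity mask.  The tensor is an
exact, rotation/translation-invariant encoding; `embed_structure`
inverts it by classical multidimensional scaling plus stress
minimisation, recovering coordinates up to a rigid motion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize

log = logging.getLogger(__name__)

PURINES = "AG"
PYRIMIDINES = "CU"

#: atom-name -> slot index, per base family
PURINE_SLOTS = {"P": 0, "C4'": 1, "C2": 2, "C6": 3, "N9": 4}
PYRIMIDINE_SLOTS = {"P": 0, "C4'": 1, "C2": 5, "C4": 6, "N1": 7}

PURINE_MASK = np.array([1, 1, 1, 1, 1, 0, 0, 0], dtype=np.int8)
PYRIMIDINE_MASK = np.array([1, 1, 0, 0, 0, 1, 1, 1], dtype=np.int8)

#: slot index -> atom name, resolved per family
SLOT_ATOM_NAMES = {0: "P", 1: "C4'", 2: "C2", 3: "C6", 4: "N9", 5: "C2", 6: "C4", 7: "N1"}


@dataclass
class ResidueCoords:
    """One nucleotide: base letter, 8x3 coordinates (Å) and slot mask."""

    base: str
    coords: np.ndarray  # (8, 3) float
    atom_mask: np.ndarray  # (8,) {0,1}

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(8, 3)
        self.atom_mask = np.asarray(self.atom_mask, dtype=np.int8).reshape(8)


@dataclass
class Structure3D:
    """An RNA chain in the reduced representation."""

    sequence: str
    residues: list[ResidueCoords]
    id: str = ""
    flagged: bool = False  # set when the source chain contained non-A/C/G/U residues

    def __post_init__(self):
        if len(self.residues) != len(self.sequence):
            raise ValueError("sequence and residue list lengths differ")

    def __len__(self) -> int:
        return len(self.sequence)

    def coords_array(self) -> np.ndarray:
        return np.stack([r.coords for r in self.residues])  # (L, 8, 3)

    def mask_array(self) -> np.ndarray:
        return np.stack([r.atom_mask for r in self.residues])  # (L, 8)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure3D":
        """Apply a rigid motion (masked slots stay zeroed)."""
        out = []
        for r in self.residues:
            c = r.coords @ rotation.T + translation
            c = c * r.atom_mask[:, None]
            out.append(ResidueCoords(r.base, c, r.atom_mask.copy()))
        return Structure3D(self.sequence, out, id=self.id, flagged=self.flagged)


@dataclass
class DistanceTensor:
    """L x L x 64 inter-atom distances (Å) with a binary validity mask."""

    D: np.ndarray
    M: np.ndarray
    L: int = field(default=0)

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        self.M = np.asarray(self.M, dtype=np.int8)
        if self.D.shape != self.M.shape or self.D.ndim != 3 or self.D.shape[2] != 64:
            raise ValueError("D and M must share shape (L, L, 64)")
        if self.D.shape[0] != self.D.shape[1]:
            raise ValueError("first two axes must be square")
        if self.D.shape[0] == 0:
            raise ValueError("empty tensor (L = 0)")
        self.L = self.D.shape[0]


def encode_residue(base: str, atoms: dict[str, np.ndarray]) -> ResidueCoords:
    """Place named atoms into the 8-slot layout of the reduced representation.

    Atoms outside the 5 selected names are ignored; selected atoms that
    are absent (commonly the leading phosphate) leave their slot zeroed
    with mask 0.
    """
    base = base.upper()
    if base in PURINES:
        slots, family_mask = PURINE_SLOTS, PURINE_MASK
    elif base in PYRIMIDINES:
        slots, family_mask = PYRIMIDINE_SLOTS, PYRIMIDINE_MASK
    else:
        raise ValueError(f"unknown base letter {base!r}")
    coords = np.zeros((8, 3))
    mask = np.zeros(8, dtype=np.int8)
    for name, xyz in atoms.items():
        slot = slots.get(name)
        if slot is None:
            continue
        coords[slot] = np.asarray(xyz, dtype=float)
        mask[slot] = 1
    mask &= family_mask  # family layout is authoritative
    coords *= mask[:, None]
    return ResidueCoords(base, coords, mask)


_RESNAME_TO_BASE = {"A": "A", "C": "C", "G": "G", "U": "U"}


def read_pdb(path) -> list[Structure3D]:
    """Parse a PDB file into one Structure3D per chain (models separate).

    Chains containing residues outside {A, C, G, U} are returned with
    ``flagged=True`` (the non-standard residues are skipped); empty
    chains are dropped with a log entry.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("pdb", str(path))
    out: list[Structure3D] = []
    multi_model = len(structure) > 1
    for model in structure:
        for chain in model:
            seq, residues, flagged = [], [], False
            for res in chain:
                if res.id[0].strip():  # heteroatoms / waters
                    flagged = True
                    continue
                name = res.get_resname().strip()
                base = _RESNAME_TO_BASE.get(name)
                if base is None:
                    flagged = True
                    continue
                atoms = {a.get_name(): a.get_coord() for a in res}
                seq.append(base)
                residues.append(encode_residue(base, atoms))
            if not residues:
                log.info("skipping empty chain %s in %s", chain.id, path)
                continue
            label = f"{path}:{chain.id}" + (f":model{model.id}" if multi_model else "")
            out.append(Structure3D("".join(seq), residues, id=label, flagged=flagged))
    return out


def write_pdb(structure: Structure3D, path) -> None:
    """Write the reduced representation as ATOM records (masked slots omitted)."""
    lines = []
    serial = 1
    for i, res in enumerate(structure.residues):
        if not res.atom_mask.any():
            warnings.warn(f"residue {i} of {structure.id or 'structure'} has no atoms")
        for slot in range(8):
            if not res.atom_mask[slot]:
                continue
            name = SLOT_ATOM_NAMES[slot]
            x, y, z = res.coords[slot]
            element = name[0]
            lines.append(
                f"ATOM  {serial:>5} {name:<4} {res.base:>3} A{i + 1:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2}"
            )
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _swap_channels(t: np.ndarray) -> np.ndarray:
    """Reindex channels 8p+q -> 8q+p."""
    perm = np.arange(64).reshape(8, 8).T.reshape(64)
    return t[:, :, perm]


def symmetrize_tensor(t: np.ndarray) -> np.ndarray:
    """Enforce the symmetry of the underlying 8L x 8L atom-pair matrix.

    Entry (i, j, 8p+q) and entry (j, i, 8q+p) describe the same atom
    pair; symmetrisation averages the two.  On tensors computed from
    coordinates this is a no-op; on decoder reconstructions it removes
    the (small) asymmetry of the network output.  This exchange rule is
    what keeps the tensor exactly invertible by distance geometry — a
    plain per-channel transpose average would merge the two *different*
    distances d(p_i, q_j) and d(p_j, q_i).
    """
    return 0.5 * (t + _swap_channels(np.swapaxes(t, 0, 1)))


def build_distance_tensor(structure: Structure3D) -> DistanceTensor:
    """Compute the L x L x 64 distance tensor and its validity mask."""
    L = len(structure)
    if L == 0:
        raise ValueError("empty structure")
    coords = structure.coords_array().reshape(L * 8, 3)
    mask = structure.mask_array().reshape(L * 8)
    diff = coords[:, None, :] - coords[None, :, :]
    dmat = np.sqrt((diff ** 2).sum(axis=-1))  # (8L, 8L)
    mmat = np.outer(mask, mask)
    D = dmat.reshape(L, 8, L, 8).transpose(0, 2, 1, 3).reshape(L, L, 64)
    M = mmat.reshape(L, 8, L, 8).transpose(0, 2, 1, 3).reshape(L, L, 64)
    D = symmetrize_tensor(D)
    M = symmetrize_tensor(M.astype(float))
    M = (M > 0.5).astype(np.int8)
    D = D * M
    return DistanceTensor(D, M, L)


def rmse_between(a: DistanceTensor, b: DistanceTensor) -> float:
    """Root-mean-square difference over entries valid in both tensors."""
    if a.L != b.L:
        raise ValueError("tensors differ in L")
    if not np.array_equal(a.M, b.M):
        raise ValueError("tensors differ in mask")
    sel = a.M.astype(bool)
    if not sel.any():
        raise ValueError("empty mask")
    diff = a.D[sel] - b.D[sel]
    return float(np.sqrt(np.mean(diff ** 2)))


def _tensor_to_atom_matrix(t: DistanceTensor) -> tuple[np.ndarray, np.ndarray]:
    """(8L x 8L distance matrix, 8L atom-validity vector) from a tensor."""
    L = t.L
    A = t.D.reshape(L, L, 8, 8).transpose(0, 2, 1, 3).reshape(8 * L, 8 * L)
    # per-atom validity from the self-distance channels of the mask
    Mm = t.M.reshape(L, L, 8, 8).transpose(0, 2, 1, 3).reshape(8 * L, 8 * L)
    valid = np.diag(Mm) > 0
    return A, valid


def embed_structure(tensor: DistanceTensor, sequence: str,
                    refine_iters: int = 200) -> tuple[Structure3D, dict]:
    """Recover 3D coordinates from a distance tensor.

    Classical MDS on the valid-atom distance submatrix gives an initial
    configuration; L-BFGS on the raw stress ``sum (|xi-xj| - d_ij)^2``
    refines it.  The result is defined up to a rigid motion and
    reflection.  Returns the structure and an info dict with the final
    ``stress`` and the monotone ``stress_history`` of the refinement.
    """
    if len(sequence) != tensor.L:
        raise ValueError("sequence length does not match tensor")
    A, valid = _tensor_to_atom_matrix(tensor)
    idx = np.flatnonzero(valid)
    if idx.size < 4:
        raise ValueError("mask covers too few atoms for embedding")
    D = A[np.ix_(idx, idx)]
    D = 0.5 * (D + D.T)
    # classical MDS: double-centred squared distances -> top-3 eigenpairs
    D2 = D ** 2
    J = np.eye(len(idx)) - 1.0 / len(idx)
    B = -0.5 * J @ D2 @ J
    w, v = eigh(B)
    order = np.argsort(w)[::-1][:3]
    lam = np.clip(w[order], 0.0, None)
    X0 = v[:, order] * np.sqrt(lam)

    iu, ju = np.triu_indices(len(idx), k=1)
    target = D[iu, ju]
    history: list[float] = []

    def stress_and_grad(flat):
        X = flat.reshape(-1, 3)
        diff = X[iu] - X[ju]
        dist = np.sqrt((diff ** 2).sum(axis=1)) + 1e-12
        resid = dist - target
        s = float((resid ** 2).sum())
        g = np.zeros_like(X)
        coef = (2.0 * resid / dist)[:, None] * diff
        np.add.at(g, iu, coef)
        np.add.at(g, ju, -coef)
        return s, g.ravel()

    def record(flat):
        history.append(stress_and_grad(flat)[0])

    res = minimize(stress_and_grad, X0.ravel(), jac=True, method="L-BFGS-B",
                   callback=record, options={"maxiter": refine_iters, "ftol": 1e-14,
                                             "gtol": 1e-12})
    X = res.x.reshape(-1, 3)

    coords = np.zeros((tensor.L * 8, 3))
    coords[idx] = X
    coords = coords.reshape(tensor.L, 8, 3)
    maskL = valid.reshape(tensor.L, 8).astype(np.int8)
    residues = [ResidueCoords(b, coords[i], maskL[i]) for i, b in enumerate(sequence)]
    info = {"stress": float(res.fun), "stress_history": history}
    return Structure3D(sequence, residues, id="embedded"), info


def superpose_rmsd(a: Structure3D, b: Structure3D) -> float:
    """All-valid-atom RMSD after optimal superposition (Kabsch, with reflection
    allowed so distance-geometry mirror solutions compare as equal)."""
    ma, mb = a.mask_array().astype(bool), b.mask_array().astype(bool)
    sel = (ma & mb).reshape(-1)
    P = a.coords_array().reshape(-1, 3)[sel]
    Q = b.coords_array().reshape(-1, 3)[sel]
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    for mirror in (False, True):
        Qm = Q * np.array([1.0, 1.0, -1.0]) if mirror else Q
        H = Qm.T @ P
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(U @ Vt))
        R = U @ np.diag([1.0, 1.0, d]) @ Vt
        r = float(np.sqrt(np.mean(((Qm @ R) - P) ** 2) * 3))
        if not mirror or r < best:
            best = r
    return best
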