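"""Structure codec: slot encoding, distance tensors, embedding round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnadistgen import codec


def _random_structure(rng, L=5, drop_p=False):
    seq, residues = [], []
    for i in range(L):
        b = "ACGU"[rng.integers(4)]
        fam = codec.PURINE_SLOTS if b in "AG" else codec.PYRIMIDINE_SLOTS
        atoms = {n: rng.normal(scale=9, size=3) for n in fam}
        if drop_p and i == 0:
            atoms.pop("P")
        seq.append(b)
        residues.append(codec.encode_residue(b, atoms))
    return codec.Structure3D("".join(seq), residues)


class TestEncodeResidue:
    def test_purine_full_slot_layout(self):
        atoms = {n: [float(i), 0.0, 0.0] for i, n in
                 enumerate(["P", "C4'", "C2", "C6", "N9"])}
        r = codec.encode_residue("G", atoms)
        assert r.atom_mask.tolist() == [1, 1, 1, 1, 1, 0, 0, 0]
        # slots 3-5 (1-based) hold C2, C6, N9
        assert r.coords[2, 0] == 2.0 and r.coords[3, 0] == 3.0 and r.coords[4, 0] == 4.0

    def test_pyrimidine_missing_phosphate(self):
        atoms = {n: [1.0, 2.0, 3.0] for n in ["C4'", "C2", "C4", "N1"]}
        r = codec.encode_residue("U", atoms)
        assert r.atom_mask.tolist() == [0, 1, 0, 0, 0, 1, 1, 1]
        assert np.all(r.coords[0] == 0.0)

    def test_slot_assignment_matches_independent_lookup(self):
        # brute-force oracle: place each named atom via an explicit table
        rng = np.random.default_rng(0)
        atoms = {n: rng.normal(size=3) for n in ["P", "C4'", "C2", "C4", "N1"]}
        r = codec.encode_residue("C", atoms)
        oracle = np.zeros((8, 3))
        for name, slot in [("P", 0), ("C4'", 1), ("C2", 5), ("C4", 6), ("N1", 7)]:
            oracle[slot] = atoms[name]
        np.testing.assert_allclose(r.coords, oracle)

    def test_unknown_base_rejected_and_extra_atoms_ignored(self):
        with pytest.raises(ValueError):
            codec.encode_residue("X", {})
        r = codec.encode_residue("A", {"O5'": [1, 1, 1], "N9": [2, 2, 2]})
        assert r.atom_mask.sum() == 1


class TestDistanceTensor:
    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(3)
        s = _random_structure(rng, L=4, drop_p=True)
        t = codec.build_distance_tensor(s)
        C, Mk = s.coords_array(), s.mask_array()
        for i in range(4):
            for j in range(4):
                for p in range(8):
                    for q in range(8):
                        want = (np.linalg.norm(C[i, p] - C[j, q])
                                if Mk[i, p] and Mk[j, q] else 0.0)
                        assert abs(t.D[i, j, 8 * p + q] - want) < 1e-9

    def test_phosphate_channel_symmetry_example(self):
        rng = np.random.default_rng(1)
        s = _random_structure(rng, L=6)
        t = codec.build_distance_tensor(s)
        want = np.linalg.norm(s.residues[0].coords[0] - s.residues[-1].coords[0])
        assert t.D[0, 5, 0] == pytest.approx(want)
        assert t.D[0, 5, 0] == pytest.approx(t.D[5, 0, 0])

    def test_self_distance_channels_zero(self):
        rng = np.random.default_rng(2)
        t = codec.build_distance_tensor(_random_structure(rng))
        for p in range(8):
            assert np.all(t.D[np.arange(t.L), np.arange(t.L), 8 * p + p] == 0)

    def test_mask_zero_coupling_and_exchange_symmetry(self):
        rng = np.random.default_rng(4)
        t = codec.build_distance_tensor(_random_structure(rng, drop_p=True))
        assert np.all(t.D[t.M == 0] == 0)
        perm = np.arange(64).reshape(8, 8).T.reshape(64)
        np.testing.assert_allclose(t.D, np.swapaxes(t.D, 0, 1)[:, :, perm])
        np.testing.assert_array_equal(t.M, np.swapaxes(t.M, 0, 1)[:, :, perm])

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        s = _random_structure(rng, L=5)
        t1 = codec.build_distance_tensor(s)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        t2 = codec.build_distance_tensor(s.transformed(R, np.array([3.0, -1.0, 8.0])))
        assert np.abs(t1.D - t2.D).max() < 1e-9

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            codec.DistanceTensor(np.zeros((0, 0, 64)), np.zeros((0, 0, 64)))


class TestRmse:
    def test_identity_and_single_entry(self):
        rng = np.random.default_rng(6)
        t = codec.build_distance_tensor(_random_structure(rng))
        assert codec.rmse_between(t, t) == 0.0
        D2 = t.D.copy()
        sel = next(x for x in np.argwhere(t.M) if x[0] != x[1])
        # bump one atom pair (both symmetric copies) by 2 Å
        i, j, k = sel
        p, q = divmod(k, 8)
        D2[i, j, k] += 2.0
        D2[j, i, 8 * q + p] += 2.0
        t2 = codec.DistanceTensor(D2, t.M.copy())
        n = t.M.sum()
        assert codec.rmse_between(t, t2) == pytest.approx(np.sqrt(4.0 * 2 / n))

    def test_matches_hand_rolled_loop(self):
        rng = np.random.default_rng(7)
        a = codec.build_distance_tensor(_random_structure(rng))
        D2 = a.D + rng.normal(scale=0.1, size=a.D.shape) * a.M
        b = codec.DistanceTensor(D2, a.M.copy())
        acc, n = 0.0, 0
        for i in range(a.L):
            for j in range(a.L):
                for k in range(64):
                    if a.M[i, j, k]:
                        acc += (a.D[i, j, k] - b.D[i, j, k]) ** 2
                        n += 1
        assert codec.rmse_between(a, b) == pytest.approx(np.sqrt(acc / n))

    def test_mask_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        t = codec.build_distance_tensor(_random_structure(rng))
        M2 = t.M.copy()
        M2[0, 1, 9] = 1 - M2[0, 1, 9]
        M2[1, 0, 9] = M2[0, 1, 9]
        with pytest.raises(ValueError):
            codec.rmse_between(t, codec.DistanceTensor(t.D, M2))


class TestPdbRoundTrip:
    def test_write_read_recovers_coordinates(self, tmp_path):
        rng = np.random.default_rng(9)
        s = _random_structure(rng, L=4, drop_p=True)
        codec.write_pdb(s, tmp_path / "s.pdb")
        back = codec.read_pdb(tmp_path / "s.pdb")
        assert len(back) == 1 and back[0].sequence == s.sequence
        assert np.abs(back[0].coords_array() - s.coords_array()).max() < 1.5e-3
        np.testing.assert_array_equal(back[0].mask_array(), s.mask_array())

    def test_atom_line_counts(self, tmp_path):
        rng = np.random.default_rng(10)
        atoms = {n: rng.normal(size=3) for n in ["P", "C4'", "C2", "C6", "N9"]}
        full = codec.Structure3D("G", [codec.encode_residue("G", atoms)])
        codec.write_pdb(full, tmp_path / "full.pdb")
        lines = [l for l in (tmp_path / "full.pdb").read_text().splitlines()
                 if l.startswith("ATOM")]
        assert len(lines) == 5
        atoms.pop("P")
        part = codec.Structure3D("G", [codec.encode_residue("G", atoms)])
        codec.write_pdb(part, tmp_path / "part.pdb")
        lines = [l for l in (tmp_path / "part.pdb").read_text().splitlines()
                 if l.startswith("ATOM")]
        assert len(lines) == 4

    def test_modified_residue_flags_chain(self, tmp_path):
        text = (
            "ATOM      1 P     G A   1       0.000   0.000   0.000  1.00  0.00           P\n"
            "ATOM      2 P   PSU A   2       5.000   0.000   0.000  1.00  0.00           P\n"
            "END\n")
        (tmp_path / "mod.pdb").write_text(text)
        chains = codec.read_pdb(tmp_path / "mod.pdb")
        assert chains[0].flagged

    def test_multi_chain_order_preserved(self, tmp_path):
        rng = np.random.default_rng(11)
        a = _random_structure(rng, L=3)
        b = _random_structure(rng, L=2)
        lines = []
        serial = 1
        for cid, s in (("A", a), ("B", b)):
            for i, res in enumerate(s.residues):
                for slot in range(8):
                    if not res.atom_mask[slot]:
                        continue
                    name = codec.SLOT_ATOM_NAMES[slot]
                    x, y, z = res.coords[slot]
                    lines.append(
                        f"ATOM  {serial:>5} {name:<4} {res.base:>3} {cid}{i + 1:>4}"
                        f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                        f" {name[0]:>1}")
                    serial += 1
        (tmp_path / "mc.pdb").write_text("\n".join(lines) + "\nEND\n")
        chains = codec.read_pdb(tmp_path / "mc.pdb")
        assert [c.sequence for c in chains] == [a.sequence, b.sequence]


class TestEmbedding:
    def test_round_trip_identity_up_to_rigid_motion(self):
        rng = np.random.default_rng(12)
        s = _random_structure(rng, L=5)
        t = codec.build_distance_tensor(s)
        e, info = codec.embed_structure(t, s.sequence)
        assert codec.superpose_rmsd(s, e) < 1e-3
        t2 = codec.build_distance_tensor(e)
        assert codec.rmse_between(t, t2) < 1e-3

    def test_exact_four_point_recovery(self):
        pts = np.array([[0.0, 0, 0], [3, 0, 0], [0, 4, 0], [1, 1, 5]])
        residues = [codec.encode_residue("G", {"P": p}) for p in pts]
        s = codec.Structure3D("GGGG", residues)
        t = codec.build_distance_tensor(s)
        e, _ = codec.embed_structure(t, s.sequence)
        assert codec.superpose_rmsd(s, e) < 1e-6

    def test_stress_history_monotone_on_noisy_input(self):
        rng = np.random.default_rng(13)
        s = _random_structure(rng, L=5)
        t = codec.build_distance_tensor(s)
        D = t.D + rng.normal(scale=0.3, size=t.D.shape) * t.M
        D = codec.symmetrize_tensor(D) * t.M
        noisy = codec.DistanceTensor(np.abs(D), t.M.copy())
        _, info = codec.embed_structure(noisy, s.sequence)
        h = info["stress_history"]
        assert len(h) > 1
        assert all(h[i + 1] <= h[i] + 1e-9 for i in range(len(h) - 1))

    def test_all_masked_rejected(self):
        t = codec.DistanceTensor(np.zeros((3, 3, 64)), np.zeros((3, 3, 64)))
        with pytest.raises(ValueError):
            codec.embed_structure(t, "AAA")


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10 ** 6), L=st.integers(2, 7))
def test_tensor_invariants_hold_for_random_structures(seed, L):
    """Symmetry and mask-zero coupling hold for arbitrary structures."""
    rng = np.random.default_rng(seed)
    t = codec.build_distance_tensor(_random_structure(rng, L=L, drop_p=True))
    perm = np.arange(64).reshape(8, 8).T.reshape(64)
    assert np.abs(t.D - np.swapaxes(t.D, 0, 1)[:, :, perm]).max() < 1e-12
    assert np.all(t.D[t.M == 0] == 0)
    assert np.all(t.D >= 0)


def test_fixture_structures_satisfy_codec_invariants(fixture_dataset):
    for f in fixture_dataset.fixtures[:6]:
        s = f.structure
        for r in s.residues:
            fam = (codec.PURINE_MASK if r.base in "AG" else codec.PYRIMIDINE_MASK)
            np.testing.assert_array_equal(r.atom_mask, fam)
            assert np.all(r.coords[r.atom_mask == 0] == 0)
        t = codec.build_distance_tensor(s)
        assert np.all(t.D[t.M == 0] == 0)
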