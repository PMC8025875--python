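import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from cryofit.structure import (Structure, pair_residues, read_pdb, rmsd,
                               superpose, write_pdb)


def _random_structure(n, seed):
    rng = np.random.default_rng(seed)
    return Structure(
        positions=rng.normal(scale=5.0, size=(n, 3)),
        residue_ids=np.arange(1, n + 1),
        chain_ids=np.full(n, "A"),
        names=np.full(n, "CA"),
        res_names=np.full(n, "ALA"),
        masses=np.full(n, 110.0),
    )


class TestReadPdb:
    def test_ca_selection_one_bead_per_residue(self, toy_pdb):
        s = read_pdb(toy_pdb, selection="CA")
        assert len(s) == 3
        assert set(s.names) == {"CA"}

    def test_all_atom_selection(self, toy_pdb):
        s = read_pdb(toy_pdb, selection=None)
        assert len(s) == 6

    def test_chain_ids_preserved_in_order(self, tmp_path):
        lines = []
        for serial, (chain, resid) in enumerate(
                [("A", 1), ("A", 2), ("B", 1), ("B", 2)], start=1):
            lines.append(
                f"ATOM  {serial:>5}  CA  ALA {chain}{resid:>4}    "
                f"{serial:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C")
        path = tmp_path / "two_chains.pdb"
        path.write_text("\n".join(lines) + "\nEND\n")
        s = read_pdb(path)
        assert list(s.chain_ids) == ["A", "A", "B", "B"]

    def test_empty_selection_raises(self, toy_pdb):
        with pytest.raises(ValueError, match="matched no atoms"):
            read_pdb(toy_pdb, selection="CG")

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        lines = [
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C",
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.70  0.00           C",
        ]
        path = tmp_path / "altloc.pdb"
        path.write_text("\n".join(lines) + "\nEND\n")
        s = read_pdb(path)
        assert len(s) == 1
        assert s.positions[0, 0] == pytest.approx(5.0)


class TestSuperpose:
    def test_pure_translation_recovered(self):
        a = _random_structure(8, 0)
        b = a.with_positions(a.positions + np.array([5.0, 0.0, 0.0]))
        rot, trans, rmsd_after = superpose(b, a)
        assert rmsd_after == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(rot, np.eye(3), atol=1e-10)

    def test_pure_rotation_recovered(self):
        a = _random_structure(8, 1)
        r90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        b = a.with_positions(a.positions @ r90.T)
        _, _, rmsd_after = superpose(b, a)
        assert rmsd_after == pytest.approx(0.0, abs=1e-10)

    def test_rotation_is_proper(self, rng):
        a = _random_structure(10, 2)
        b = _random_structure(10, 3)
        rot, _, _ = superpose(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(rot @ rot.T, np.eye(3), atol=1e-10)

    def test_matches_bruteforce_rotation_search(self):
        # independent oracle: minimize RMSD over Euler angles from a grid
        # of starting points
        rng = np.random.default_rng(42)
        a = rng.normal(scale=3.0, size=(4, 3))
        b = a + rng.normal(scale=0.5, size=(4, 3))
        _, _, kabsch_rmsd = superpose(a, b)

        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)

        def cost(angles):
            rot = Rotation.from_euler("xyz", angles).as_matrix()
            return np.sqrt((((ac @ rot.T) - bc) ** 2).sum() / len(a))

        best = np.inf
        grid = np.linspace(-np.pi, np.pi, 7)
        for ax in grid:
            for ay in grid:
                for az in grid:
                    res = minimize(cost, [ax, ay, az], method="Nelder-Mead",
                                   options={"xatol": 1e-8, "fatol": 1e-12})
                    best = min(best, res.fun)
        assert kabsch_rmsd == pytest.approx(best, abs=1e-3)

    def test_idempotent(self):
        a = _random_structure(10, 4)
        b = _random_structure(10, 5)
        rot, trans, _ = superpose(a, b)
        moved = a.transformed(rot, trans)
        rot2, trans2, _ = superpose(moved, b)
        assert np.allclose(rot2, np.eye(3), atol=1e-8)
        assert np.allclose(trans2, 0.0, atol=1e-8)

    def test_collinear_points_raise(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            superpose(pts, pts + 1.0)

    def test_subset_length_mismatch(self):
        a = _random_structure(5, 0)
        b = _random_structure(6, 1)
        with pytest.raises(ValueError, match="mismatch|needs"):
            superpose(a, b)


class TestRmsd:
    def test_identical_is_zero(self):
        a = _random_structure(12, 6)
        assert rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_displacement_no_fit(self):
        a = np.array([[0.0, 0, 0], [3.8, 0, 0]])
        b = a + np.array([0.0, 2.0, 0.0])
        assert rmsd(a, b, fit=False) == pytest.approx(2.0)

    def test_fit_never_exceeds_no_fit(self, rng):
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        assert rmsd(a, b, fit=True) <= rmsd(a, b, fit=False) + 1e-12

    def test_symmetry_with_fit(self, rng):
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        assert rmsd(a, b, fit=True) == pytest.approx(rmsd(b, a, fit=True),
                                                     abs=1e-9)

    def test_empty_subset_raises(self):
        a = _random_structure(5, 7)
        with pytest.raises(ValueError, match="empty"):
            rmsd(a, a, subset=[])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), angle=st.floats(-180, 180),
           shift=st.floats(-50, 50))
    def test_invariant_under_rigid_transforms(self, seed, angle, shift):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        base = rmsd(a, b, fit=True)
        rot = Rotation.from_euler("y", angle, degrees=True).as_matrix()
        moved = a @ rot.T + shift
        assert rmsd(moved, b, fit=True) == pytest.approx(base, abs=1e-8)


class TestPdbRoundTrip:
    def test_single_and_multi_model(self, toy, tmp_path):
        p1 = tmp_path / "one.pdb"
        write_pdb(p1, toy.state_a)
        back = read_pdb(p1)
        assert np.allclose(back.positions, toy.state_a.positions, atol=1e-3)
        assert (back.res_names == toy.state_a.res_names).all()

        p2 = tmp_path / "two.pdb"
        write_pdb(p2, [toy.state_a, toy.state_b], remarks=["cc=0.9"])
        frame2 = read_pdb(p2, model=2)
        assert np.allclose(frame2.positions, toy.state_b.positions, atol=1e-3)
        assert "cc=0.9" in p2.read_text()


def test_pair_residues_by_chain_resid_icode():
    a = _random_structure(4, 8)
    b = a.select(np.array([0, 1, 3]))  # drop residue 3
    ia, ib = pair_residues(a, b)
    assert list(a.residue_ids[ia]) == [1, 2, 4]
    assert len(ia) == len(ib) == 3
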