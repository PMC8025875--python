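import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cryofit.gomodel import (ChainBreakWarning, GoModel, GoModelParams,
                             build_go_model, combine_chains, energy_forces,
                             scale_contacts)
from cryofit.structure import Structure


def _ca_structure(positions, chain="A", resid_start=1, res_names=None):
    positions = np.atleast_2d(np.asarray(positions, float))
    n = len(positions)
    return Structure(
        positions=positions,
        residue_ids=np.arange(resid_start, resid_start + n),
        chain_ids=np.full(n, chain),
        names=np.full(n, "CA"),
        res_names=np.full(n, "ALA") if res_names is None else np.asarray(res_names),
        masses=np.full(n, 110.0))


def _straight_chain(n, spacing=3.8):
    return _ca_structure([[i * spacing, 0.0, 0.0] for i in range(n)])


def _brute_force_ca_contacts(s, cutoff=6.5, min_sep=4):
    out = set()
    for i in range(len(s)):
        for j in range(i + 1, len(s)):
            same = s.chain_ids[i] == s.chain_ids[j]
            if same and j - i < min_sep:
                continue
            if np.linalg.norm(s.positions[i] - s.positions[j]) < cutoff:
                out.add((i, j))
    return out


class TestBuildGoModel:
    def test_straight_chain_has_no_contacts(self):
        m = build_go_model(_straight_chain(4))
        assert m.n_contacts == 0

    def test_contacts_match_bruteforce_oracle(self, rng):
        # compact random coil
        pos = np.cumsum(rng.normal(scale=2.2, size=(10, 3)), axis=0)
        pos *= 0.8
        s = _ca_structure(pos)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ChainBreakWarning)
            m = build_go_model(s)
        got = set(zip(m.con_i.tolist(), m.con_j.tolist()))
        assert got == _brute_force_ca_contacts(s)

    def test_bond_lengths_are_native(self, toy, toy_model):
        d = np.linalg.norm(
            toy.state_a.positions[toy_model.bond_j]
            - toy.state_a.positions[toy_model.bond_i], axis=1)
        assert np.allclose(toy_model.bond_r0, d, atol=1e-12)

    def test_chain_break_skips_bond(self):
        pos = [[0, 0, 0], [3.8, 0, 0], [3.8 + 6.0, 0, 0], [3.8 + 9.8, 0, 0]]
        with pytest.warns(ChainBreakWarning):
            m = build_go_model(_ca_structure(pos))
        assert len(m.bond_i) == 2  # the long pseudo-bond is skipped

    def test_mj_weighted_eps_mean_equals_base(self, toy_model):
        params = GoModelParams()
        assert toy_model.con_eps.mean() == pytest.approx(params.base_epsilon)
        assert toy_model.con_eps.std() > 0  # MJ weighting differentiates pairs

    def test_heavy_atom_contact_detection(self):
        # two far CA beads whose side-chain atoms touch
        ca = _ca_structure([[0, 0, 0], [4, 0, 0], [8, 0, 0],
                            [12, 0, 0], [16, 0, 0]])
        aa_pos = list(ca.positions) + [[0.5, 2.0, 0.0], [15.5, 2.0, 0.0]]
        # no CA pair within 6.5 at separation >= 4; add a fake heavy-atom
        # bridge between residues 1 and 5
        aa = Structure(
            positions=np.array(aa_pos, float),
            residue_ids=np.array([1, 2, 3, 4, 5, 1, 5]),
            chain_ids=np.full(7, "A"),
            names=np.array(["CA"] * 5 + ["CB", "CB"]),
            res_names=np.full(7, "ALA"),
            masses=np.full(7, 110.0))
        aa.positions[5] = [1.0, 1.0, 0.0]
        aa.positions[6] = [2.0, 1.0, 0.0]  # within 4.5 A of residue-1 CB
        m = build_go_model(ca, all_atom_native=aa)
        assert (0, 4) in set(zip(m.con_i.tolist(), m.con_j.tolist()))


class TestEnergyForces:
    def test_native_is_stationary_minimum(self, toy, toy_model):
        e, f = energy_forces(toy_model, toy.state_a.positions)
        assert e == pytest.approx(-toy_model.con_eps.sum(), abs=1e-9)
        assert np.linalg.norm(f, axis=1).max() <= 1e-6

    @pytest.mark.parametrize("seed", [0, 1])
    def test_forces_match_finite_differences(self, toy, toy_model, seed):
        rng = np.random.default_rng(seed)
        pos = toy.state_a.positions + rng.normal(scale=0.3,
                                                 size=(len(toy.state_a), 3))
        e0, f0 = energy_forces(toy_model, pos)
        h = 1e-5
        for b in rng.choice(len(pos), size=6, replace=False):
            for c in range(3):
                p = pos.copy()
                p[b, c] += h
                ep, _ = energy_forces(toy_model, p)
                p[b, c] -= 2 * h
                em, _ = energy_forces(toy_model, p)
                fd = -(ep - em) / (2 * h)
                assert fd == pytest.approx(f0[b, c], rel=1e-5, abs=1e-7)

    def test_energy_invariant_forces_equivariant_under_rigid_motion(
            self, toy, toy_model, rng):
        pos = toy.state_a.positions + rng.normal(scale=0.2,
                                                 size=(len(toy.state_a), 3))
        e0, f0 = energy_forces(toy_model, pos)
        rot = Rotation.from_euler("xyz", [0.3, -1.2, 2.0]).as_matrix()
        shift = np.array([10.0, -3.0, 7.0])
        e1, f1 = energy_forces(toy_model, pos @ rot.T + shift)
        assert e1 == pytest.approx(e0, abs=1e-9)
        assert np.allclose(f1, f0 @ rot.T, atol=1e-9)

    def test_pair_energy_continuous_at_cutoff(self):
        # contact-only two-bead model: energy must go smoothly to zero
        # across the 18-20 A switching window
        m = GoModel(n_beads=2,
                    con_i=np.array([0]), con_j=np.array([1]),
                    con_r0=np.array([15.2]), con_eps=np.array([1.0]))

        def e_at(r):
            e, _ = energy_forces(m, np.array([[0.0, 0, 0], [r, 0, 0]]))
            return e

        assert e_at(20.0 - 1e-7) == pytest.approx(e_at(20.0 + 1e-7), abs=1e-6)
        assert e_at(20.5) == 0.0
        assert e_at(17.0) != 0.0

    def test_coincident_beads_raise(self, toy_model, toy):
        pos = toy.state_a.positions.copy()
        pos[5] = pos[20]
        with pytest.raises(ValueError, match="coincident"):
            energy_forces(toy_model, pos)


class TestScaleContacts:
    def test_factor_one_is_identity(self, toy_model):
        out = scale_contacts(toy_model, range(15), range(15, 30), 1.0)
        assert np.array_equal(out.con_eps, toy_model.con_eps)

    def test_selected_pair_scaled_others_bit_identical(self, toy_model):
        i0, j0 = int(toy_model.con_i[0]), int(toy_model.con_j[0])
        out = scale_contacts(toy_model, [i0], [j0], 3.0)
        assert out.con_eps[0] == pytest.approx(3.0 * toy_model.con_eps[0])
        assert np.array_equal(out.con_eps[1:], toy_model.con_eps[1:])

    def test_native_contact_energy_scales(self, toy, toy_model):
        sel_a = list(range(15))
        sel_b = list(range(15, 30))
        out = scale_contacts(toy_model, sel_a, sel_b, 3.0)
        e0, _ = energy_forces(toy_model, toy.state_a.positions)
        e1, _ = energy_forces(out, toy.state_a.positions)
        cross = [(i in sel_a and j in sel_b) or (i in sel_b and j in sel_a)
                 for i, j in zip(toy_model.con_i, toy_model.con_j)]
        expected = e0 - 2.0 * toy_model.con_eps[np.array(cross)].sum()
        assert e1 == pytest.approx(expected, abs=1e-9)

    def test_empty_selection_warns_and_is_noop(self, toy_model):
        with pytest.warns(UserWarning, match="empty selection"):
            out = scale_contacts(toy_model, [], [1], 3.0)
        assert np.array_equal(out.con_eps, toy_model.con_eps)

    def test_nonpositive_factor_raises(self, toy_model):
        with pytest.raises(ValueError):
            scale_contacts(toy_model, [0], [10], 0.0)


class TestCombineChains:
    def _dimer(self, gap):
        a = _ca_structure(np.cumsum(np.tile([[2.8, 2.0, 1.0]], (6, 1)), axis=0),
                          chain="A")
        b_pos = a.positions + np.array([gap, 0.0, 0.0])
        b = _ca_structure(b_pos, chain="B")
        complex_s = Structure(
            positions=np.vstack([a.positions, b.positions]),
            residue_ids=np.concatenate([a.residue_ids, b.residue_ids]),
            chain_ids=np.array(["A"] * 6 + ["B"] * 6),
            names=np.full(12, "CA"), res_names=np.full(12, "ALA"),
            masses=np.full(12, 110.0))
        return a, b, complex_s

    def test_far_apart_chains_no_inter_contacts(self):
        a, b, cplx = self._dimer(gap=100.0)
        ma, mb = build_go_model(a), build_go_model(b)
        m = combine_chains([ma, mb], cplx)
        assert m.n_beads == 12
        assert len(m.bond_i) == len(ma.bond_i) + len(mb.bond_i)
        assert len(m.ang_i) == len(ma.ang_i) + len(mb.ang_i)
        assert m.n_contacts == ma.n_contacts + mb.n_contacts

    def test_interfacial_contacts_match_bruteforce(self):
        a, b, cplx = self._dimer(gap=5.5)
        ma, mb = build_go_model(a), build_go_model(b)
        m = combine_chains([ma, mb], cplx)
        got = set(zip(m.con_i.tolist(), m.con_j.tolist()))
        intra = set(zip(ma.con_i.tolist(), ma.con_j.tolist())) | {
            (i + 6, j + 6) for i, j in zip(mb.con_i, mb.con_j)}
        inter_expected = {p for p in _brute_force_ca_contacts(cplx)
                          if (p[0] < 6) != (p[1] < 6)}
        assert got == intra | inter_expected
        assert len(inter_expected) > 0

    def test_combine_single_model_is_identity(self, toy_model):
        m = combine_chains([toy_model])
        assert np.array_equal(m.con_i, toy_model.con_i)
        assert np.array_equal(m.bond_r0, toy_model.bond_r0)
        assert np.array_equal(m.nn_i, toy_model.nn_i)


def test_text_serialization_round_trip(toy_model):
    text = toy_model.to_text()
    back = GoModel.from_text(text)
    for name in ("bond_i", "bond_j", "ang_i", "dih_i", "con_i", "nn_i"):
        assert np.array_equal(getattr(back, name), getattr(toy_model, name))
    assert np.allclose(back.con_eps, toy_model.con_eps, atol=1e-8)
    assert back.cutoff == toy_model.cutoff
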