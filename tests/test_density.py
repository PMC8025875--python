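import math

import numpy as np
import pytest

from cryofit.density import (DensityGrid, cc_gradient, cross_correlation,
                             read_mrc, read_situs, remove_negative,
                             sigma_from_resolution, simulate_map,
                             truncation_radius, write_mrc, write_situs)
from cryofit.structure import Structure


def _point_structure(points, **kw):
    points = np.atleast_2d(points)
    n = len(points)
    return Structure(
        positions=points, residue_ids=np.arange(1, n + 1),
        chain_ids=np.full(n, "A"), names=np.full(n, "CA"),
        res_names=np.full(n, "ALA"), masses=np.full(n, 110.0))


class TestSimulateMap:
    def test_single_bead_peak_at_its_voxel(self):
        s = _point_structure([[0.0, 0.0, 0.0]])
        g = simulate_map(s, resolution=5.0, voxel=2.0, padding=8.0)
        peak = np.unravel_index(np.argmax(g.values), g.shape)
        centers = g.origin[None, :] + np.array(peak) * g.spacing
        assert np.all(np.abs(centers - 0.0) <= g.spacing / 2 + 1e-9)

    def test_linearity_two_coincident_beads(self):
        s1 = _point_structure([[1.0, 2.0, 3.0]])
        s2 = _point_structure([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        g1 = simulate_map(s1, 5.0, 2.0, 8.0)
        g2 = simulate_map(s2, 5.0, 2.0, 8.0, lattice=g1)
        assert np.allclose(g2.values, 2.0 * g1.values, rtol=1e-12)

    def test_total_density_matches_gaussian_integral(self, toy):
        # closed-form oracle: each untruncated Gaussian integrates to
        # (2 pi sigma^2)^(3/2)
        sigma = sigma_from_resolution(5.0)
        g = simulate_map(toy.state_a, resolution=5.0, voxel=1.0,
                         padding=4.0 * sigma, truncate_fraction=0.0)
        total = g.values.sum() * g.voxel_volume
        expected = len(toy.state_a) * (2 * math.pi * sigma ** 2) ** 1.5
        assert total == pytest.approx(expected, rel=0.02)

    def test_integer_voxel_translation_equivariance(self, toy):
        g0 = simulate_map(toy.state_a, 5.0, 2.0, 8.0)
        shifted = toy.state_a.with_positions(
            toy.state_a.positions + np.array([2.0, 4.0, -2.0]))
        lattice = DensityGrid(np.zeros(g0.shape),
                              g0.origin + np.array([2.0, 4.0, -2.0]),
                              g0.spacing)
        g1 = simulate_map(shifted, 5.0, 2.0, 8.0, lattice=lattice)
        assert np.allclose(g1.values, g0.values, atol=1e-12)

    def test_voxel_larger_than_box_raises(self):
        s = _point_structure([[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="voxel"):
            simulate_map(s, resolution=5.0, voxel=50.0, padding=1.0)


class TestTruncation:
    def test_fraction_zero_identical(self, toy):
        full = simulate_map(toy.state_a, 5.0, 2.0, 8.0, truncate_fraction=0.0)
        again = simulate_map(toy.state_a, 5.0, 2.0, 8.0, truncate_fraction=0.0)
        assert np.array_equal(full.values, again.values)

    def test_support_radius_closed_form(self):
        sigma = sigma_from_resolution(5.0)
        # solve exp(-r^2/(2 s^2)) = f analytically
        assert truncation_radius(sigma, 0.01) == pytest.approx(
            sigma * math.sqrt(-2.0 * math.log(0.01)))
        assert truncation_radius(sigma, 0.0) == np.inf
        with pytest.raises(ValueError):
            truncation_radius(sigma, 1.0)

    def test_truncated_map_close_to_full(self):
        s = _point_structure([[0.0, 0.0, 0.0]])
        full = simulate_map(s, 5.0, 2.0, 10.0, truncate_fraction=0.0)
        trunc = simulate_map(s, 5.0, 2.0, 10.0, truncate_fraction=0.01,
                             lattice=full)
        assert cross_correlation(full, trunc) >= 0.999


class TestRemoveNegative:
    def test_positive_map_unchanged(self, fitting_case):
        _, tmap, _ = fitting_case
        out = remove_negative(tmap)
        assert np.array_equal(out.values, tmap.values)

    def test_clamps_negatives(self):
        g = DensityGrid(np.array([[[-1.0, 2.0]]]), np.zeros(3), 1.0)
        out = remove_negative(g)
        assert out.values.tolist() == [[[0.0, 2.0]]]
        assert g.values[0, 0, 0] == -1.0  # input untouched

    def test_output_nonnegative_random(self, rng):
        g = DensityGrid(rng.normal(size=(4, 5, 6)), np.zeros(3), 2.0)
        assert remove_negative(g).values.min() >= 0.0


class TestCrossCorrelation:
    def test_self_correlation_is_one(self, fitting_case):
        _, tmap, _ = fitting_case
        assert cross_correlation(tmap, tmap) == pytest.approx(1.0)

    def test_disjoint_support_is_zero(self):
        a = DensityGrid(np.array([[[1.0, 0.0]]]), np.zeros(3), 1.0)
        b = DensityGrid(np.array([[[0.0, 1.0]]]), np.zeros(3), 1.0)
        assert cross_correlation(a, b) == 0.0

    def test_scale_invariance(self, fitting_case, rng):
        _, tmap, _ = fitting_case
        other = DensityGrid(rng.random(tmap.shape), tmap.origin, tmap.spacing)
        base = cross_correlation(tmap, other)
        scaled = DensityGrid(3.0 * other.values, tmap.origin, tmap.spacing)
        assert cross_correlation(tmap, scaled) == pytest.approx(base, abs=1e-12)
        assert cross_correlation(other, tmap) == pytest.approx(base, abs=1e-12)

    def test_bounded_by_one(self, rng):
        a = DensityGrid(rng.normal(size=(5, 5, 5)), np.zeros(3), 1.0)
        b = DensityGrid(rng.normal(size=(5, 5, 5)), np.zeros(3), 1.0)
        assert abs(cross_correlation(a, b)) <= 1.0 + 1e-12

    def test_lattice_mismatch_raises(self, fitting_case):
        _, tmap, _ = fitting_case
        other = DensityGrid(tmap.values, tmap.origin + 0.5, tmap.spacing)
        with pytest.raises(ValueError, match="lattice"):
            cross_correlation(tmap, other)

    def test_zero_map_raises(self):
        z = DensityGrid(np.zeros((2, 2, 2)), np.zeros(3), 1.0)
        g = DensityGrid(np.ones((2, 2, 2)), np.zeros(3), 1.0)
        with pytest.raises(ValueError, match="zero"):
            cross_correlation(z, g)


class TestCcGradient:
    def test_stationary_at_generating_positions(self, toy):
        tmap = simulate_map(toy.state_b, 5.0, 2.0, 8.0, truncate_fraction=0.01)
        cc, grad = cc_gradient(tmap, toy.state_b, resolution=5.0)
        assert cc == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(grad, axis=1).max() <= 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_finite_differences(self, toy, fitting_case, seed):
        _, tmap, _ = fitting_case
        rcut = truncation_radius(sigma_from_resolution(5.0), 0.01)
        rng = np.random.default_rng(seed)
        s = toy.state_a.with_positions(
            toy.state_a.positions + rng.normal(scale=0.5, size=(len(toy.state_a), 3)))
        cc0, grad = cc_gradient(tmap, s)
        h = 1e-4
        axes = [tmap.origin[i] + np.arange(tmap.shape[i]) * tmap.spacing[i]
                for i in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        checked = 0
        for b in rng.choice(len(s), size=8, replace=False):
            # skip beads with a voxel center within 10 h of the truncation
            # sphere: finite differences are invalid across the edge of
            # the compact support
            d = np.sqrt((gx - s.positions[b, 0]) ** 2
                        + (gy - s.positions[b, 1]) ** 2
                        + (gz - s.positions[b, 2]) ** 2)
            if np.abs(d - rcut).min() <= 10 * h:
                continue
            checked += 1
            for c in range(3):
                p = s.positions.copy()
                p[b, c] += h
                ccp, _ = cc_gradient(tmap, s.with_positions(p))
                p[b, c] -= 2 * h
                ccm, _ = cc_gradient(tmap, s.with_positions(p))
                fd = (ccp - ccm) / (2 * h)
                assert fd == pytest.approx(grad[b, c],
                                           rel=1e-5, abs=1e-10)
        assert checked >= 3

    def test_displaced_bead_pulled_back(self):
        s0 = _point_structure([[0.0, 0.0, 0.0]])
        tmap = simulate_map(s0, 5.0, 2.0, 10.0, truncate_fraction=0.01)
        displaced = s0.with_positions(np.array([[1.5, 0.0, 0.0]]))
        cc, grad = cc_gradient(tmap, displaced)
        assert cc < 1.0
        assert grad[0, 0] < 0.0  # moving back in -x increases CC

    def test_bead_outside_support_zero_gradient(self, fitting_case):
        _, tmap, _ = fitting_case
        far = _point_structure([[0.0, 0.0, 0.0], [500.0, 500.0, 500.0]])
        cc, grad = cc_gradient(tmap, far)
        assert np.allclose(grad[1], 0.0)

    def test_zero_density_raises(self, fitting_case):
        _, tmap, _ = fitting_case
        outside = _point_structure([[900.0, 900.0, 900.0]])
        with pytest.raises(ValueError, match="zero"):
            cc_gradient(tmap, outside)


class TestIO:
    def test_mrc_round_trip(self, fitting_case, tmp_path):
        _, tmap, _ = fitting_case
        path = tmp_path / "map.mrc"
        write_mrc(path, tmap)
        back = read_mrc(path)
        assert back.shape == tmap.shape
        assert np.allclose(back.origin, tmap.origin, atol=1e-4)
        assert np.allclose(back.spacing, tmap.spacing, atol=1e-6)
        assert np.allclose(back.values, tmap.values, atol=1e-4)

    def test_situs_round_trip(self, fitting_case, tmp_path):
        _, tmap, _ = fitting_case
        path = tmp_path / "map.sit"
        write_situs(path, tmap)
        back = read_situs(path)
        assert back.shape == tmap.shape
        assert np.allclose(back.values, tmap.values, atol=1e-5)
        assert np.allclose(back.origin, tmap.origin, atol=1e-5)
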