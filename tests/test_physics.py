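"""Sphere mechanics: neighbor index, pair forces, integration, division."""

import numpy as np
import pytest

from cortigen import Body, Bond, Domain, ForceConstants, SpatialIndex
from cortigen.physics import (SimulationAbort, bond_forces, divide_body,
                              integrate_step, neighbors_within, pairwise_force,
                              pairwise_forces)


def brute_force_neighbors(positions, p, r):
    d = np.linalg.norm(positions - np.asarray(p), axis=1)
    return np.flatnonzero(d <= r)


class TestNeighborIndex:
    def test_empty_index(self):
        idx = SpatialIndex(np.empty((0, 3)))
        assert len(neighbors_within(idx, [0, 0, 0], 10.0)) == 0

    def test_boundary_inclusive(self):
        pos = np.array([[0, 0, 0], [0, 0, 19.9], [0, 0, 40.0]])
        idx = SpatialIndex(pos)
        hits = idx.neighbors_within([0, 0, 0], 20.0, exclude=0)
        assert list(hits) == [1]
        hits = idx.neighbors_within([0, 0, 0], 19.8, exclude=0)
        assert list(hits) == []

    def test_matches_brute_force_scan(self, rng):
        pos = rng.uniform(0, 100, size=(500, 3))
        idx = SpatialIndex(pos)
        for _ in range(25):
            p = rng.uniform(0, 100, size=3)
            r = rng.uniform(1, 40)
            np.testing.assert_array_equal(
                idx.neighbors_within(p, r), brute_force_neighbors(pos, p, r))

    def test_pairs_match_brute_force(self, rng):
        pos = rng.uniform(0, 50, size=(120, 3))
        idx = SpatialIndex(pos)
        pairs = {tuple(p) for p in idx.pairs_within(12.0)}
        expected = {(i, j) for i in range(120) for j in range(i + 1, 120)
                    if np.linalg.norm(pos[i] - pos[j]) <= 12.0}
        assert pairs == expected

    def test_invalid_radius(self):
        idx = SpatialIndex(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            idx.neighbors_within([0, 0, 0], 0.0)


class TestPairwiseForce:
    consts = ForceConstants(k_rep=2.0, k_adh=1.0, g_max=1.0)

    def test_touching_without_adherence_is_zero(self):
        a = Body([0, 0, 0], 10.0, adherence=0.0)
        b = Body([10, 0, 0], 10.0, adherence=0.0)
        np.testing.assert_allclose(pairwise_force(a, b, self.consts), 0.0)

    def test_overlap_magnitude(self):
        a = Body([0, 0, 0], 10.0)
        b = Body([9, 0, 0], 10.0)  # 1 um overlap
        f = pairwise_force(a, b, self.consts)
        assert np.linalg.norm(f) == pytest.approx(2.0)
        assert f[0] < 0  # pushes a away from b

    def test_adhesion_inside_range_only(self):
        a = Body([0, 0, 0], 10.0)
        near = Body([10.5, 0, 0], 10.0)   # gap 0.5 <= g_max
        far = Body([11.5, 0, 0], 10.0)    # gap 1.5 > g_max
        f_near = pairwise_force(a, near, self.consts)
        assert f_near[0] > 0  # pulls a toward near
        np.testing.assert_allclose(pairwise_force(a, far, self.consts), 0.0)

    def test_antisymmetry(self, rng):
        for _ in range(30):
            a = Body(rng.uniform(0, 12, 3), rng.uniform(5, 15),
                     adherence=rng.uniform(0, 1), force_coefficient=rng.uniform(0, 1))
            b = Body(rng.uniform(0, 12, 3), rng.uniform(5, 15),
                     adherence=rng.uniform(0, 1), force_coefficient=rng.uniform(0, 1))
            np.testing.assert_allclose(pairwise_force(a, b), -pairwise_force(b, a))

    def test_minimum_coefficient_scales_pair(self):
        a = Body([0, 0, 0], 10.0, force_coefficient=1e-4)
        b = Body([9, 0, 0], 10.0, force_coefficient=1.0)
        assert np.linalg.norm(pairwise_force(a, b, self.consts)) == pytest.approx(2e-4)

    def test_coincident_centers_deterministic(self):
        a = Body([5, 5, 5], 10.0)
        b = Body([5, 5, 5], 10.0)
        f1 = pairwise_force(a, b, self.consts)
        f2 = pairwise_force(a, b, self.consts)
        assert np.linalg.norm(f1) > 0
        np.testing.assert_array_equal(f1, f2)

    def test_vectorised_matches_scalar(self, rng):
        n = 40
        pos = rng.uniform(0, 30, size=(n, 3))
        diam = rng.uniform(5, 15, size=n)
        adh = rng.uniform(0, 1, size=n)
        fc = rng.uniform(0, 1, size=n)
        idx = SpatialIndex(pos)
        pairs = idx.pairs_within(16.0)
        forces = pairwise_forces(pos, diam, adh, fc, pairs, self.consts)
        expected = np.zeros_like(pos)
        for i in range(n):
            for j in range(n):
                if i != j and np.linalg.norm(pos[i] - pos[j]) <= 16.0:
                    a = Body(pos[i], diam[i], adherence=adh[i], force_coefficient=fc[i])
                    b = Body(pos[j], diam[j], adherence=adh[j], force_coefficient=fc[j])
                    expected[i] += pairwise_force(a, b, self.consts)
        np.testing.assert_allclose(forces, expected, atol=1e-10)


class TestIntegration:
    domain = Domain(300, 300, 1400)

    def test_mass_scales_displacement(self):
        pos = np.array([[100.0, 100, 100], [100.0, 100, 200]])
        forces = np.array([[1e-4, 0, 0], [1e-4, 0, 0]])
        masses = np.array([10.0, 0.0001])
        new = integrate_step(pos, masses, forces, 1.0, self.domain)
        dx = new[:, 0] - pos[:, 0]
        assert dx[1] / dx[0] == pytest.approx(1e5)

    def test_zero_force_zero_motion(self):
        pos = np.array([[10.0, 10, 10]])
        new = integrate_step(pos, np.array([1.0]), np.zeros((1, 3)), 1.0, self.domain)
        np.testing.assert_array_equal(new, pos)

    def test_displacement_capped(self):
        pos = np.array([[100.0, 100, 100]])
        new = integrate_step(pos, np.array([1e-6]), np.array([[1.0, 0, 0]]), 1.0,
                             self.domain, max_displacement=3.0)
        assert np.linalg.norm(new - pos) == pytest.approx(3.0)

    def test_lateral_reflection_and_z_clamp(self):
        pos = np.array([[1.0, 299.0, 1399.5]])
        forces = np.array([[-4.0, 4.0, 4.0]])
        new = integrate_step(pos, np.array([1.0]), forces, 1.0, self.domain)
        assert 0 <= new[0, 0] <= 300 and 0 <= new[0, 1] <= 300
        assert new[0, 2] == 1400.0

    def test_non_finite_aborts(self):
        with pytest.raises(SimulationAbort):
            integrate_step(np.zeros((1, 3)), np.array([1.0]),
                           np.array([[np.nan, 0, 0]]), 1.0, self.domain)


class TestBonds:
    def test_stretched_bond_pulls_together(self):
        pos = np.array([[0.0, 0, 0], [16.5, 0, 0]])
        bonds = [Bond(0, 1, rest_length=15.0)]
        f = bond_forces(pos, bonds)
        assert f[0, 0] > 0 and f[1, 0] < 0
        assert f[0, 0] == pytest.approx(1.5)  # spring constant 1, 10% strain

    def test_breakage_is_permanent(self):
        pos = np.array([[0.0, 0, 0], [80.0, 0, 0]])
        bonds = [Bond(0, 1, rest_length=15.0)]  # 533% strain > 500%
        f = bond_forces(pos, bonds)
        np.testing.assert_array_equal(f, 0.0)
        assert bonds[0].broken
        pos2 = np.array([[0.0, 0, 0], [16.0, 0, 0]])
        np.testing.assert_array_equal(bond_forces(pos2, bonds), 0.0)


class TestDivision:
    def test_volume_conserved(self, rng):
        b = Body([50, 50, 50], 10.0)
        d1, d2 = divide_body(b, rng)
        assert d1.diameter == pytest.approx(10 / 2 ** (1 / 3))
        assert d1.diameter == pytest.approx(7.937, abs=5e-4)
        vol = lambda d: d**3  # proportionality suffices
        assert vol(d1.diameter) + vol(d2.diameter) == pytest.approx(vol(10.0))

    def test_daughters_inside_domain(self, rng):
        domain = Domain(300, 300, 1400)
        b = Body([0.1, 299.9, 0.0], 10.0)
        for _ in range(20):
            d1, d2 = divide_body(b, rng, domain=domain)
            for d in (d1, d2):
                assert domain.contains(d.position)

    def test_attributes_copied(self, rng):
        b = Body([1, 2, 3], 10.0, mass=7.0, adherence=0.25, force_coefficient=0.5)
        d1, _ = divide_body(b, rng)
        assert (d1.mass, d1.adherence, d1.force_coefficient) == (7.0, 0.25, 0.5)


class TestRelaxation:
    def test_overlapping_cluster_relaxes_monotonically(self, rng):
        """With repulsion only, total overlap never increases step to step."""
        n = 30
        pos = rng.uniform(30, 70, size=(n, 3)) + np.array([0, 0, 500.0])
        diam = np.full(n, 10.0)
        adh = np.zeros(n)
        fc = np.ones(n)
        masses = np.ones(n)
        domain = Domain(300, 300, 1400)
        consts = ForceConstants()

        def total_overlap(p):
            tot = 0.0
            for i in range(n):
                d = np.linalg.norm(p - p[i], axis=1)
                gap = d - 0.5 * (diam + diam[i])
                tot += np.sum(np.clip(-gap[np.arange(n) != i], 0, None) ** 2)
            return tot

        prev = total_overlap(pos)
        for _ in range(150):
            pairs = SpatialIndex(pos).pairs_within(11.0)
            forces = pairwise_forces(pos, diam, adh, fc, pairs, consts)
            pos = integrate_step(pos, masses, forces, 1.0, domain, max_displacement=1.0)
            cur = total_overlap(pos)
            assert cur <= prev + 1e-9
            prev = cur
        assert prev < 1e-6
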