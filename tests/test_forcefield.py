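import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import direct_image_sum
from dendrion.errors import OverstretchError, ParameterError
from dendrion.forcefield import (ForceFieldParams, bonded_potential_minimum,
                                 coulomb_pair, ewald_electrostatics,
                                 fene_pair, mixing_diameter,
                                 total_energy_forces, wca_pair)
from dendrion.system import ParticleSystem


def _charged_system(positions, charges, L):
    n = len(positions)
    return ParticleSystem(np.asarray(positions, float),
                          np.array(["c"] * n), np.asarray(charges, float),
                          np.zeros(n), np.zeros((0, 2), int), L)


class TestWCA:
    def test_zero_at_cutoff(self):
        e, f = wca_pair(2 ** (1 / 6) * 1.3, 1.3)
        assert e == 0.0 and f == 0.0

    def test_contact_energy_equals_epsilon(self):
        # r = sigma: the r-terms cancel, the shift leaves exactly epsilon
        e, _ = wca_pair(1.0, 1.0, epsilon=1.0)
        assert e == pytest.approx(1.0, abs=1e-14)
        e2, _ = wca_pair(2.0, 2.0, epsilon=0.7)
        assert e2 == pytest.approx(0.7, abs=1e-14)

    def test_beyond_cutoff_zero(self):
        assert wca_pair(3.0, 1.0) == (0.0, 0.0)

    def test_continuity_at_cutoff(self):
        rc = 2 ** (1 / 6)
        e_in, _ = wca_pair(rc * (1 - 1e-9), 1.0)
        assert abs(e_in) < 1e-6

    @given(st.floats(0.4, 1.1219))
    def test_nonnegative_and_monotone(self, r):
        e, f = wca_pair(r, 1.0)
        e2, _ = wca_pair(min(r + 1e-4, 2 ** (1 / 6)), 1.0)
        assert e >= 0.0
        assert e2 <= e + 1e-12  # non-increasing toward the cutoff
        assert f >= 0.0         # purely repulsive

    def test_domain_error(self):
        with pytest.raises(ParameterError):
            wca_pair(0.0, 1.0)


class TestMixing:
    @pytest.mark.parametrize("a,b,expected", [(1, 1, 1), (1, 2, 1.5), (1, 3, 2)])
    def test_arithmetic_mean(self, a, b, expected):
        assert mixing_diameter(a, b) == expected

    def test_positive_required(self):
        with pytest.raises(ParameterError):
            mixing_diameter(1.0, 0.0)


class TestFENE:
    def test_zero_at_origin(self):
        assert fene_pair(0.0)[0] == 0.0

    def test_value_at_unit_extension(self):
        # -0.5*30*1.5^2 * ln(1 - 1/2.25) = -33.75 ln(5/9)
        e, _ = fene_pair(1.0, k=30.0, R0=1.5)
        assert e == pytest.approx(-33.75 * math.log(5.0 / 9.0), rel=1e-12)
        assert e == pytest.approx(19.8378, abs=5e-5)

    @pytest.mark.parametrize("r", [1.5, 1.6, 10.0])
    def test_overstretch_is_an_error(self, r):
        with pytest.raises(OverstretchError):
            fene_pair(r, k=30.0, R0=1.5)


class TestCoulombPair:
    @pytest.mark.parametrize("r,zi,zj,lb,expected", [
        (1.0, 1, -1, 1.0, -1.0),
        (2.0, 1, 1, 16.0, 8.0),
        (5.0, 1, -1, 0.0, 0.0),
    ])
    def test_values(self, r, zi, zj, lb, expected):
        assert coulomb_pair(r, zi, zj, lb) == pytest.approx(expected)

    def test_domain_error(self):
        with pytest.raises(ParameterError):
            coulomb_pair(0.0, 1, -1, 1.0)


def test_combined_bond_minimum_in_kremer_grest_range():
    r_min, _ = bonded_potential_minimum()
    assert 0.95 < r_min < 0.97


class TestEwald:
    def test_dipole_pair_large_box_matches_bare_coulomb(self):
        sys = _charged_system([[50, 50, 50], [51, 50, 50]], [1, -1], 100.0)
        ff = ForceFieldParams(lambda_B=1.0, ewald_accuracy=1e-6, r_cut_real=10.0)
        e, _ = ewald_electrostatics(sys, ff)
        assert e == pytest.approx(-1.0, rel=0.01)
        oracle = direct_image_sum(sys.positions, sys.charges, 100.0, 1.0, 5)
        assert e == pytest.approx(oracle, rel=1e-4)

    def test_square_small_box_matches_image_sum(self):
        a = 1.0
        pos = [[2, 2, 2], [2 + a, 2, 2], [2 + a, 2 + a, 2], [2, 2 + a, 2]]
        sys = _charged_system(pos, [1, -1, 1, -1], 5.0)
        ff = ForceFieldParams(lambda_B=1.0, ewald_accuracy=1e-7, r_cut_real=2.4)
        e, _ = ewald_electrostatics(sys, ff)
        oracle = direct_image_sum(pos, [1, -1, 1, -1], 5.0, 1.0, 16)
        assert abs(e - oracle) / abs(oracle) < 1e-5

    def test_random_neutral_ten_particles_match_image_sum(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 10, (10, 3))
        q = np.array([1.0, -1.0] * 5)
        sys = _charged_system(pos, q, 10.0)
        ff = ForceFieldParams(lambda_B=2.0, ewald_accuracy=1e-7,
                              r_cut_real=4.9)
        e, _ = ewald_electrostatics(sys, ff)
        oracle = direct_image_sum(pos, q, 10.0, 2.0, 26)
        assert abs(e - oracle) / abs(oracle) < 1e-5

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 10, (8, 3))
        q = np.array([1.0, -1.0] * 4)
        ff = ForceFieldParams(lambda_B=1.0, ewald_accuracy=1e-6, r_cut_real=4.9)
        e0, _ = ewald_electrostatics(_charged_system(pos, q, 10.0), ff)
        e1, _ = ewald_electrostatics(
            _charged_system(pos + np.array([1.7, -0.4, 2.2]), q, 10.0), ff)
        assert abs(e1 - e0) < 1e-6

    def test_force_sum_vanishes(self):
        rng = np.random.default_rng(4)
        pos = rng.uniform(0, 10, (10, 3))
        q = np.array([1.0, -1.0] * 5)
        ff = ForceFieldParams(lambda_B=3.0, ewald_accuracy=1e-5, r_cut_real=4.9)
        _, f = ewald_electrostatics(_charged_system(pos, q, 10.0), ff)
        assert np.abs(f.sum(axis=0)).max() < 1e-10

    def test_forces_are_negative_energy_gradient(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(0, 10, (6, 3))
        q = np.array([1.0, -1.0] * 3)
        ff = ForceFieldParams(lambda_B=2.0, ewald_accuracy=1e-8, r_cut_real=4.9)
        _, f = ewald_electrostatics(_charged_system(pos, q, 10.0), ff)
        h = 1e-6
        for i, d in ((0, 0), (3, 1), (5, 2)):
            pp, pm = pos.copy(), pos.copy()
            pp[i, d] += h
            pm[i, d] -= h
            ep, _ = ewald_electrostatics(_charged_system(pp, q, 10.0), ff)
            em, _ = ewald_electrostatics(_charged_system(pm, q, 10.0), ff)
            assert -(ep - em) / (2 * h) == pytest.approx(f[i, d], rel=1e-4)

    def test_non_neutral_rejected(self):
        sys = _charged_system([[1, 1, 1], [2, 2, 2]], [1, 1], 10.0)
        with pytest.raises(ParameterError):
            ewald_electrostatics(sys, ForceFieldParams(lambda_B=1.0))


class TestTotalEnergyForces:
    def test_isolated_particle_all_zero(self):
        sys = ParticleSystem(np.array([[5.0, 5, 5]]), np.array(["m"]),
                             np.zeros(1), np.ones(1), np.zeros((0, 2), int),
                             20.0)
        e, f = total_energy_forces(sys, ForceFieldParams())
        assert e == {"wca": 0.0, "fene": 0.0, "coulomb": 0.0}
        assert not np.any(f)

    def test_neutral_bonded_dimer_at_wca_cutoff(self):
        r = 2 ** (1 / 6)
        sys = ParticleSystem(np.array([[5.0, 5, 5], [5 + r, 5, 5]]),
                             np.array(["m", "m"]), np.zeros(2), np.ones(2),
                             np.array([[0, 1]]), 20.0)
        e, _ = total_energy_forces(sys, ForceFieldParams())
        from dendrion.forcefield import fene_pair
        assert e["wca"] == pytest.approx(0.0, abs=1e-12)
        assert e["coulomb"] == 0.0
        assert e["fene"] == pytest.approx(fene_pair(r)[0], rel=1e-12)

    def test_forces_match_finite_differences(self):
        # random neutral 20-particle system with bonds, charges and both ion
        # sizes; analytic forces vs central differences of the total energy
        rng = np.random.default_rng(7)
        n = 20
        # jittered grid keeps nonbonded pairs outside the hard core so the
        # energy surface is smooth enough for central differences
        grid = np.array([[x, y, z] for x in range(3) for y in range(3)
                         for z in range(3)], float)[:n] * 4.0 + 2.0
        pos = grid + rng.uniform(-0.5, 0.5, (n, 3))
        charges = np.array([1.0, -1.0] * (n // 2))
        diam = np.where(rng.random(n) < 0.3, 2.0, 1.0)
        bonds = np.array([[i, i + 1] for i in range(0, 6, 2)])
        # bonded pairs at ~0.95 sigma, inside the FENE range
        for i, j in bonds:
            u = rng.normal(size=3)
            pos[j] = pos[i] + 0.95 * u / np.linalg.norm(u)
        sys = ParticleSystem(pos, np.array(["m"] * n), charges, diam, bonds,
                             24.0)
        ff = ForceFieldParams(lambda_B=2.0, ewald_accuracy=1e-7,
                              r_cut_real=11.9)
        _, f = total_energy_forces(sys, ff)

        def energy(p):
            s = ParticleSystem(p, np.array(["m"] * n), charges, diam, bonds,
                               24.0)
            e, _ = total_energy_forces(s, ff)
            return e["wca"] + e["fene"] + e["coulomb"]

        h = 1e-6
        rng2 = np.random.default_rng(8)
        for _ in range(6):
            i = int(rng2.integers(n))
            d = int(rng2.integers(3))
            pp, pm = pos.copy(), pos.copy()
            pp[i, d] += h
            pm[i, d] -= h
            fd = -(energy(pp) - energy(pm)) / (2 * h)
            denom = max(1.0, abs(f[i, d]))
            assert abs(fd - f[i, d]) / denom < 1e-4

    def test_overstretched_bond_raises(self):
        sys = ParticleSystem(np.array([[5.0, 5, 5], [6.6, 5, 5]]),
                             np.array(["m", "m"]), np.zeros(2), np.ones(2),
                             np.array([[0, 1]]), 20.0)
        with pytest.raises(OverstretchError):
            total_energy_forces(sys, ForceFieldParams())
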