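import numpy as np
import pytest

from dendrion import observables as obs
from dendrion.errors import (InsufficientStatisticsError, ParameterError,
                             UnwrapError)
from dendrion.synthetic import (make_core_shell_config, make_planted_ion_config,
                                make_uniform_gas)
from dendrion.system import Frame
from dendrion.topology import build_dendrimer, compose_ion_mixture


class TestRadiusOfGyration:
    def test_single_particle_zero(self):
        assert obs.radius_of_gyration(np.array([[1.0, 2, 3]])) == 0.0

    def test_symmetric_dimer(self):
        pos = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert obs.radius_of_gyration(pos) == pytest.approx(1.5)

    def test_square_corners(self):
        a = 2.0
        pos = np.array([[0, 0, 0], [a, 0, 0], [a, a, 0], [0, a, 0]], float)
        assert obs.radius_of_gyration(pos) == pytest.approx(a / np.sqrt(2))

    def test_unwrap_restores_wrapped_chain(self):
        # a straight trimer that crosses the periodic boundary
        L = 10.0
        pos = np.array([[9.5, 5, 5], [0.4, 5, 5], [1.3, 5, 5]])
        bonds = np.array([[0, 1], [1, 2]])
        un = obs.unwrap_bonded(pos, bonds, L)
        d = np.diff(un[:, 0])
        assert np.allclose(d, 0.9)
        assert obs.radius_of_gyration(un) == pytest.approx(
            obs.radius_of_gyration(np.array([[0.0, 0, 0], [0.9, 0, 0],
                                             [1.8, 0, 0]])))

    def test_disconnected_long_bond_detected(self):
        # even after minimum image this "bond" spans more than L/2
        pos = np.array([[0.0, 0, 0], [6.1, 6.1, 6.1]])
        with pytest.raises(UnwrapError):
            obs.unwrap_bonded(pos, np.array([[0, 1]]), 10.0)


class TestSwellingFactor:
    @pytest.mark.parametrize("rg,rg0,expected", [
        (2.0, 2.0, 1.0), (3.0, 2.0, 1.5), (2.0, 4.0, 0.5)])
    def test_ratio(self, rg, rg0, expected):
        assert obs.swelling_factor(rg, rg0) == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(ParameterError):
            obs.swelling_factor(1.0, 0.0)


@pytest.fixture(scope="module")
def planted_g4s4():
    topo = build_dendrimer(4, 4)
    ions = compose_ion_mixture(62, 0.32, 2.0)  # 42 conventional, 20 bulky
    return make_planted_ion_config(topo, ions, {"c": 10, "b": 5},
                                   {"c": 4, "b": 2}, seed=17)


class TestCounting:
    def test_planted_counts_exact(self, planted_g4s4):
        fr = planted_g4s4.system.frame()
        r_abs = planted_g4s4.expected["absorption_radius"]
        assert obs.absorbed_counts(fr, "c", r_abs) == 10
        assert obs.absorbed_counts(fr, "b", r_abs) == 5
        assert obs.condensed_counts(fr, "c") == 4
        assert obs.condensed_counts(fr, "b") == 2

    def test_absorption_boundary_is_strict(self):
        # ions exactly at 2 Rg are NOT absorbed
        L = 50.0
        mono = np.array([[24.0, 25, 25], [26.0, 25, 25]])  # Rg = 1
        ions = np.array([[27.0, 25, 25], [25.0, 27.0, 25]])  # both at r = 2Rg
        pos = np.vstack([mono, ions])
        fr = Frame(pos, np.array(["m", "m", "c", "c"]),
                   np.array([1.0, 1.0, -1.0, -1.0]), np.ones(4),
                   np.array([[0, 1]]), L)
        assert obs.absorbed_counts(fr, "c", 2.0) == 0
        assert obs.absorbed_counts(fr, "c", 2.0 + 1e-9) == 2

    def test_condensation_thresholds_per_species(self):
        # conventional at 1.2 (< 1.5) condensed; bulky at 2.1 (>= 2.0) not
        L = 50.0
        pos = np.array([[25.0, 25, 25], [26.2, 25, 25], [25.0, 27.1, 25]])
        fr = Frame(pos, np.array(["m", "c", "b"]),
                   np.array([1.0, -1.0, -1.0]), np.array([1.0, 1.0, 2.0]),
                   np.zeros((0, 2), int), L)
        assert obs.condensed_counts(fr, "c") == 1
        assert obs.condensed_counts(fr, "b") == 0

    def test_ion_touching_two_monomers_counted_once(self):
        L = 50.0
        pos = np.array([[24.5, 25, 25], [25.5, 25, 25], [25.0, 25.5, 25]])
        fr = Frame(pos, np.array(["m", "m", "c"]),
                   np.array([1.0, 1.0, -1.0]), np.ones(3),
                   np.array([[0, 1]]), L)
        assert obs.condensed_counts(fr, "c") == 1

    def test_empty_species_counts_zero(self, g2s2_topology):
        ions = compose_ion_mixture(14, 1.0, 2.0)  # f_b = 1: no conventional
        fix = make_planted_ion_config(g2s2_topology, ions, {"b": 4}, {"b": 1},
                                      seed=2, L=40.0)
        fr = fix.system.frame()
        assert obs.absorbed_counts(fr, "c", 5.0) == 0
        assert obs.condensed_counts(fr, "c") == 0


class TestFractionReport:
    def test_planted_fractions_and_identities(self, planted_g4s4):
        traj = planted_g4s4.as_trajectory(n_frames=10)
        rep = obs.fraction_report(traj)
        assert rep.f_in == pytest.approx(10 / 62, abs=1e-15)
        assert rep.f_cond == pytest.approx(4 / 62, abs=1e-15)
        assert rep.f_d == pytest.approx(6 / 62, abs=1e-15)
        # identity chain holds to machine precision
        assert rep.f_oin == rep.f_in + rep.f_bin
        assert rep.f_ocond == rep.f_cond + rep.f_bcond
        assert rep.f_d == rep.f_in - rep.f_cond
        assert rep.f_od == rep.f_d + rep.f_bd
        for k in rep.FIELDS:
            assert 0.0 <= getattr(rep, k) <= 1.0

    def test_no_bulky_species_means_zero_bulky_fractions(self, g2s2_topology):
        ions = compose_ion_mixture(14, 0.0, 2.0)
        fix = make_planted_ion_config(g2s2_topology, ions, {"c": 5}, {"c": 2},
                                      seed=3, L=40.0)
        rep = obs.fraction_report(fix.as_trajectory(10))
        assert rep.f_bin == rep.f_bcond == rep.f_bd == 0.0

    def test_short_trajectory_rejected(self, planted_g4s4):
        with pytest.raises(InsufficientStatisticsError):
            obs.fraction_report(planted_g4s4.as_trajectory(n_frames=3))

    def test_all_far_ions_give_zero_fractions(self, g2s2_topology):
        ions = compose_ion_mixture(14, 0.5, 2.0)
        fix = make_planted_ion_config(g2s2_topology, ions, {}, {}, seed=4,
                                      L=40.0)
        rep = obs.fraction_report(fix.as_trajectory(10))
        assert all(getattr(rep, k) == 0.0 for k in rep.FIELDS)


class TestProfiles:
    def test_uniform_gas_pair_correlation_is_unity(self):
        traj = make_uniform_gas(500, 20.0, 300, seed=2)
        g = obs.com_radial_profile(traj, "c", bin_width=0.5,
                                   center="box-center")
        shell = 4.0 / 3.0 * np.pi * np.diff(g.bin_edges**3)
        expected_counts = shell * 500 / 20.0**3 * 300
        mask = expected_counts >= 2000
        assert mask.any()
        assert np.all(np.abs(g.values[mask] - 1.0) < 0.05)

    def test_planted_shell_has_confined_support(self, g2s2_topology):
        ions = compose_ion_mixture(14, 1.0, 2.0)
        fix = make_core_shell_config(g2s2_topology, ions, R_core=2.0,
                                     R_shell_inner=4.9, R_shell_outer=5.1,
                                     seed=5, L=40.0)
        g = obs.com_radial_profile(fix.as_trajectory(5), "b", bin_width=0.1)
        centers = g.bin_centers
        inside = (centers > 4.8) & (centers < 5.2)
        assert g.values[~inside].sum() == 0.0
        assert g.values[inside].sum() > 0.0

    def test_density_profile_conserves_particle_number(self, g2s2_topology):
        ions = compose_ion_mixture(14, 0.5, 2.0)
        fix = make_core_shell_config(g2s2_topology, ions, 2.0, 4.0, 6.0,
                                     seed=6, L=40.0)
        rho = obs.com_radial_profile(fix.as_trajectory(5), "m", bin_width=0.25,
                                     normalization="number-density")
        assert rho.integrated_count() == pytest.approx(26, rel=0.02)

    def test_core_shell_segregation_orders_peaks(self, g2s2_topology):
        ions = compose_ion_mixture(14, 0.5, 2.0)
        fix = make_core_shell_config(g2s2_topology, ions, 2.0, 4.0, 6.0,
                                     seed=7, L=40.0)
        traj = fix.as_trajectory(5)
        pc = obs.com_radial_profile(traj, "c", bin_width=0.25)
        pb = obs.com_radial_profile(traj, "b", bin_width=0.25)
        assert pc.argmax_radius() < pb.argmax_radius()

    def test_single_fixed_ion_around_charged_monomer(self):
        L = 30.0
        pos = np.array([[15.0, 15, 15], [16.0, 15, 15]])
        from dendrion.simulator import Trajectory
        traj = Trajectory(steps=np.array([1]), positions=pos[None],
                          species=np.array(["m", "c"]),
                          charges=np.array([1.0, -1.0]), diameters=np.ones(2),
                          bonds=np.zeros((0, 2), int), box_length=L,
                          params={}, logs=None)
        g = obs.charged_monomer_profile(traj, "c", bin_width=0.1)
        assert g.bin_centers[int(np.argmax(g.values))] == pytest.approx(1.05)
        assert (g.values > 0).sum() == 1

    def test_empty_species_marked_empty_not_nan(self, g2s2_topology):
        ions = compose_ion_mixture(14, 0.0, 2.0)
        fix = make_planted_ion_config(g2s2_topology, ions, {"c": 3}, {"c": 1},
                                      seed=8, L=40.0)
        g = obs.com_radial_profile(fix.as_trajectory(5), "b")
        assert g.empty
        assert not np.any(np.isnan(g.values))
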