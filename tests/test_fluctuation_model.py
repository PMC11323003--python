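"""The two-strand charge-fluctuation lattice model against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import k0

from lipodna import electrolyte as el
from lipodna import fluctuation_model as fm


def brute_force_corr(config, spacing, params):
    """Plain-loop screened-Coulomb sum, independent of the vectorized path."""
    lb = params.coupling_bjerrum
    b = params.site_spacing
    km = params.kappa_model
    a = params.counterion_valence
    c1 = [s * a - 1.0 for s in config.occupancy_strand1]
    c2 = [s * a - 1.0 for s in config.occupancy_strand2]
    e = 0.0
    for i, qi in enumerate(c1):
        for j, qj in enumerate(c2):
            r = math.sqrt(spacing**2 + (b * (i - j)) ** 2)
            e += qi * qj * lb * math.exp(-km * r) / r
    if params.include_intra_strand:
        for c in (c1, c2):
            for i in range(len(c)):
                for j in range(i + 1, len(c)):
                    r = b * (j - i)
                    e += c[i] * c[j] * lb * math.exp(-km * r) / r
    return e


def all_configs(n):
    for s1 in itertools.product((0, 1), repeat=n):
        for s2 in itertools.product((0, 1), repeat=n):
            yield fm.BindingConfiguration(s1, s2)


class TestSiteCharge:
    @pytest.mark.parametrize("sigma, alpha, expected", [(1, 2, 1.0), (0, 2, -1.0), (1, 3, 2.0)])
    def test_occupied_and_empty_sites(self, sigma, alpha, expected):
        assert fm.site_charge(sigma, alpha) == expected

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            fm.site_charge(2, 2)


class TestCorrelationEnergy:
    def test_single_unlike_pair_is_minus_bjerrum_over_x(self):
        # monovalent coupling scale recovers c1 c2 lB(1e)/x exactly
        params = fm.LatticeParams(n_sites=1, kappa_model=0.0, coupling_valence=1)
        config = fm.BindingConfiguration((1,), (0,))
        x = 2.5
        lb = el.bjerrum_length(1.0, el.ElectrolyteCondition(
            (el.IonSpecies("x", 0.1, 1),), params.epsilon_r, params.temperature))
        assert fm.correlation_energy(config, x, params) == pytest.approx(-lb / x, rel=1e-12)

    def test_global_sign_flip_invariance(self):
        params = fm.LatticeParams(n_sites=4, kappa_model=0.0)
        config = fm.BindingConfiguration((1, 0, 0, 1), (0, 1, 1, 1))
        flipped = fm.BindingConfiguration(
            tuple(1 - s for s in config.occupancy_strand1),
            tuple(1 - s for s in config.occupancy_strand2),
        )
        e1 = fm.correlation_energy(config, 3.0, params)
        e2 = fm.correlation_energy(flipped, 3.0, params)
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_strand_swap_symmetry(self):
        params = fm.LatticeParams(n_sites=4)
        config = fm.BindingConfiguration((1, 1, 0, 1), (0, 0, 1, 0))
        swapped = fm.BindingConfiguration(
            config.occupancy_strand2, config.occupancy_strand1)
        assert fm.correlation_energy(config, 2.8, params) == pytest.approx(
            fm.correlation_energy(swapped, 2.8, params), rel=1e-12)

    def test_alternating_beats_all_occupied_among_n2_configs(self):
        # brute force over all 16 N=2 configurations at lipid permittivity
        params = fm.LatticeParams(n_sites=2, epsilon_r=40.1, kappa_model=0.0)
        energies = {
            (c.occupancy_strand1, c.occupancy_strand2): brute_force_corr(c, 3.0, params)
            for c in all_configs(2)
        }
        alternating = energies[((0, 1), (1, 0))]
        all_occupied = energies[((1, 1), (1, 1))]
        assert alternating < all_occupied
        assert alternating == pytest.approx(min(energies.values()), rel=1e-12)

    @given(
        occ=st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=5),
        spacing=st.floats(0.5, 8.0),
        intra=st.booleans(),
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_plain_loop_oracle(self, occ, spacing, intra):
        n = len(occ)
        params = fm.LatticeParams(n_sites=n, include_intra_strand=intra)
        config = fm.BindingConfiguration(
            tuple(s[0] for s in occ), tuple(s[1] for s in occ))
        assert fm.correlation_energy(config, spacing, params) == pytest.approx(
            brute_force_corr(config, spacing, params), rel=1e-10, abs=1e-12)

    def test_nonpositive_spacing_rejected(self):
        params = fm.LatticeParams(n_sites=2)
        with pytest.raises(ValueError):
            fm.correlation_energy(fm.BindingConfiguration((1, 0), (0, 1)), 0.0, params)


class TestRodRepulsion:
    def make_rods(self, nu=-3.5):
        kappa = 1.0 / el.debye_length(el.mgcl2(0.05, epsilon_r=92.2, temperature=300.0))
        return fm.RodParams(nu_eff_free=nu, d_free=4.0, strand_length=6.8,
                            kappa=kappa, epsilon_r=92.2, temperature=300.0)

    def test_uncharged_rods_do_not_interact(self):
        rods = self.make_rods(nu=0.0)
        assert all(fm.rod_repulsion(x, rods) == 0.0 for x in (1.0, 3.0, 5.0))

    def test_closed_form_at_solution_parameters(self):
        rods = self.make_rods()
        lb = el.bjerrum_length(1.0, el.ElectrolyteCondition(
            (el.IonSpecies("x", 0.1, 1),), 92.2, 300.0))
        x = 3.0
        expected = 2.0 * lb * (3.5 / 6.8) ** 2 * 6.8 * k0(rods.kappa * x)
        assert fm.rod_repulsion(x, rods) == pytest.approx(expected, rel=1e-12)

    def test_positive_and_strictly_decreasing(self):
        rods = self.make_rods()
        xs = np.linspace(1.0, 6.0, 40)
        u = [fm.rod_repulsion(x, rods) for x in xs]
        assert all(v > 0 for v in u)
        assert all(a > b for a, b in zip(u, u[1:]))


class TestEffectiveCharge:
    def make(self):
        return fm.RodParams(nu_eff_free=-1.0, d_free=4.0, nu_eff_condensed=0.17,
                            d_condensed=3.0, strand_length=6.8, kappa=1.8,
                            epsilon_r=40.1)

    def test_anchors_and_midpoint(self):
        rods = self.make()
        assert fm.effective_charge(4.0, rods) == pytest.approx(-1.0)
        assert fm.effective_charge(3.0, rods) == pytest.approx(0.17)
        assert fm.effective_charge(3.5, rods) == pytest.approx((-1.0 + 0.17) / 2)

    def test_constant_without_condensed_anchor(self):
        rods = fm.RodParams(nu_eff_free=-3.5, d_free=4.0, strand_length=6.8,
                            kappa=1.2, epsilon_r=92.2)
        assert fm.effective_charge(2.0, rods) == fm.effective_charge(6.0, rods) == -3.5


class TestPartitionFreeEnergy:
    def setup_method(self):
        self.lattice, self.rods = fm.lipid_preset()

    def test_equals_brute_force_sum_for_n2(self):
        lattice = fm.LatticeParams(n_sites=2, epsilon_r=40.1, chemical_potential=0.3)
        x = 3.0
        z = sum(
            math.exp(-brute_force_corr(c, x, lattice) + 0.3 * c.n_bound)
            for c in all_configs(2)
        )
        expected = fm.rod_repulsion(x, self.rods) - math.log(z)
        assert fm.partition_free_energy(x, lattice, self.rods) == pytest.approx(
            expected, abs=1e-10)

    def test_vanishing_coupling_leaves_rod_term_plus_lattice_entropy(self):
        # epsilon_r -> infinity sends every pair coupling to zero
        lattice = fm.LatticeParams(n_sites=4, epsilon_r=1e12)
        x = 3.0
        f = fm.partition_free_energy(x, lattice, self.rods)
        assert f + math.log(4.0**4) == pytest.approx(
            fm.rod_repulsion(x, self.rods), abs=1e-9)

    def test_strong_negative_chemical_potential_selects_empty_lattice(self):
        lattice = fm.LatticeParams(n_sites=3, chemical_potential=-60.0)
        x = 2.5
        empty = fm.BindingConfiguration((0, 0, 0), (0, 0, 0))
        expected = fm.rod_repulsion(x, self.rods) + fm.correlation_energy(empty, x, lattice)
        assert fm.partition_free_energy(x, lattice, self.rods) == pytest.approx(
            expected, abs=1e-6)

    def test_enumeration_cap_enforced(self):
        lattice = fm.LatticeParams(n_sites=13)
        with pytest.raises(ValueError, match="transfer_matrix"):
            fm.partition_free_energy(3.0, lattice, self.rods)

    def test_free_energy_bounded_by_extreme_configurations(self):
        # E_ground <= F - U_rod + 2N ln2 and F - U_rod <= E_ground
        lattice, rods = fm.lipid_preset()
        for x in (2.0, 3.0, 4.5, 6.0):
            e_ground = fm.ground_state(x, lattice)[1]
            f_corr = fm.partition_free_energy(x, lattice, rods) - fm.rod_repulsion(x, rods)
            assert f_corr <= e_ground + 1e-12
            assert f_corr >= e_ground - 2 * lattice.n_sites * 2 * math.log(2) - 1e-12


class TestTransferMatrix:
    def setup_method(self):
        self.rods = fm.lipid_preset()[1]

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    @pytest.mark.parametrize("cutoff", [0, 1, 2])
    def test_agrees_with_enumeration_under_shared_cutoff(self, n, cutoff):
        lattice = fm.LatticeParams(n_sites=n, chemical_potential=0.2)
        if cutoff > n:
            pytest.skip("cutoff exceeds site count")
        a = fm.partition_free_energy(3.1, lattice, self.rods, offset_cutoff=cutoff)
        b = fm.transfer_matrix_free_energy(3.1, lattice, self.rods, offset_cutoff=cutoff)
        assert b == pytest.approx(a, abs=1e-10)

    def test_single_column_lattice_equals_enumeration(self):
        lattice = fm.LatticeParams(n_sites=1)
        a = fm.partition_free_energy(2.5, lattice, self.rods)
        b = fm.transfer_matrix_free_energy(2.5, lattice, self.rods, offset_cutoff=1)
        assert b == pytest.approx(a, abs=1e-12)

    def test_zero_coupling_gives_ideal_lattice_entropy(self):
        lattice = fm.LatticeParams(n_sites=6, epsilon_r=1e12)
        f = fm.transfer_matrix_free_energy(4.0, lattice, self.rods, offset_cutoff=1)
        expected = fm.rod_repulsion(4.0, self.rods) - math.log(2.0 ** (2 * 6))
        assert f == pytest.approx(expected, abs=1e-9)

    def test_cutoff_beyond_site_count_rejected(self):
        lattice = fm.LatticeParams(n_sites=3)
        with pytest.raises(ValueError):
            fm.transfer_matrix_free_energy(3.0, lattice, self.rods, offset_cutoff=4)


class TestGroundState:
    def test_lipid_defaults_alternate_across_strands(self):
        lattice = fm.lipid_preset()[0]
        config, _ = fm.ground_state(3.0, lattice)
        assert config.occupancy_strand1 in [(0, 1, 0, 1), (1, 0, 1, 0)]
        assert config.occupancy_strand2 == tuple(
            1 - s for s in config.occupancy_strand1)

    def test_single_site_pair_binds_one_ion(self):
        lattice = fm.LatticeParams(n_sites=1)
        config, energy = fm.ground_state(3.0, lattice)
        assert sorted((config.occupancy_strand1[0], config.occupancy_strand2[0])) == [0, 1]
        assert energy < 0

    def test_not_beaten_by_random_configurations(self, rng):
        lattice = fm.LatticeParams(n_sites=5, epsilon_r=60.0, kappa_model=0.2)
        _, e_ground = fm.ground_state(2.7, lattice)
        for _ in range(1000):
            occ = rng.integers(0, 2, size=(2, 5))
            c = fm.BindingConfiguration(tuple(occ[0]), tuple(occ[1]))
            assert fm.correlation_energy(c, 2.7, lattice) >= e_ground - 1e-12


class TestFreeEnergyProfile:
    def test_lipid_preset_is_attractive(self):
        prof = fm.free_energy_profile(fm.default_spacing_grid(), *fm.lipid_preset())
        assert prof.classification == "attractive"
        assert prof.minimum_depth < -0.5

    def test_solution_preset_is_repulsive_and_monotone(self):
        prof = fm.free_energy_profile(fm.default_spacing_grid(), *fm.solution_preset())
        assert prof.classification == "repulsive"
        # free energy only rises as the duplexes approach
        assert np.all(np.diff(prof.free_energy) <= 1e-9)

    def test_lipid_minimum_tracks_ground_state_energy(self):
        lattice, rods = fm.lipid_preset()
        prof = fm.free_energy_profile(fm.default_spacing_grid(), lattice, rods)
        x_min = prof.minimum_spacing
        f = fm.partition_free_energy(x_min, lattice, rods)
        e_ground = fm.ground_state(x_min, lattice)[1] + fm.rod_repulsion(x_min, rods)
        assert abs(e_ground - f) < 1.0

    def test_uncoupled_lattice_profile_is_flat_and_repulsive(self):
        lattice = fm.LatticeParams(n_sites=4, epsilon_r=1e12)
        rods = fm.RodParams(nu_eff_free=0.0, d_free=4.0, strand_length=6.8,
                            kappa=1.8, epsilon_r=1e12)
        prof = fm.free_energy_profile(fm.default_spacing_grid(), lattice, rods)
        assert prof.classification == "repulsive"
        assert np.allclose(prof.free_energy, 0.0, atol=1e-9)

    def test_short_grid_rejected(self):
        with pytest.raises(ValueError):
            fm.free_energy_profile([2.0, 3.0], *fm.lipid_preset())


class TestSampling:
    def test_marginals_match_enumeration(self, rng):
        lattice = fm.lipid_preset()[0]
        x = 3.0
        n_draws = 100_000
        draws = fm.sample_configurations(x, lattice, n_draws, rng)
        energies, n_bound = fm.configuration_energies(x, lattice)
        w = np.exp(-(energies - energies.min()) + lattice.chemical_potential * n_bound)
        p = w / w.sum()
        n = lattice.n_sites
        bits = ((np.arange(p.size)[:, None] >> np.arange(2 * n - 1, -1, -1)) & 1)
        expected = p @ bits
        observed = draws.mean(axis=0)
        sigma = np.sqrt(expected * (1 - expected) / n_draws)
        assert np.all(np.abs(observed - expected) < 3 * np.maximum(sigma, 1e-4))
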