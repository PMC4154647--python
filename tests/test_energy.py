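"""Hamiltonian terms, decomposition bookkeeping, screening and forces."""

import numpy as np
import pytest

from dualbasin.energy import (
    ForceFieldParams,
    TopologySystem,
    debye_length_from_salt,
)
from dualbasin.geometry import rotation_matrix
from dualbasin.topology import BasinClass, Bead, BeadKind, BondTerm, ContactPair, TwoBasinTopology


def _pair_topology(r0=5.0, charges=(0, 0), contact=True, sep=None):
    """Two beads on the x axis, optionally in contact and/or charged."""
    res = {1: "ARG", -1: "ASP", 0: "GLY"}
    sep = r0 if sep is None else sep
    beads = [
        Bead(0, "A", 1, res[charges[0]], BeadKind.CA, charges[0], [0.0, 0.0, 0.0]),
        Bead(1, "A", 10, res[charges[1]], BeadKind.CA, charges[1], [sep, 0.0, 0.0]),
    ]
    contacts = [ContactPair(0, 1, r0, BasinClass.SHARED)] if contact else []
    return TwoBasinTopology(beads=beads, contacts=contacts)


class TestPairPotentials:
    def test_contact_minimum_is_minus_eps(self, nocut_params):
        system = TopologySystem(_pair_topology(r0=5.0), nocut_params)
        x = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        assert system.contact_energy(x) == pytest.approx(-nocut_params.eps, abs=1e-12)

    def test_contact_decays_to_zero(self, nocut_params):
        system = TopologySystem(_pair_topology(r0=5.0), nocut_params)
        x = np.array([[0.0, 0, 0], [5e4, 0, 0]])
        assert abs(system.contact_energy(x)) < 1e-12

    def test_contact_12_10_closed_form_on_random_pairs(self, nocut_params):
        rng = np.random.default_rng(0)
        for _ in range(100):
            r0 = rng.uniform(3.5, 9.0)
            r = rng.uniform(0.6 * r0, 2.5 * r0)
            system = TopologySystem(_pair_topology(r0=r0), nocut_params)
            x = np.array([[0.0, 0, 0], [r, 0, 0]])
            expect = nocut_params.eps * (5 * (r0 / r) ** 12 - 6 * (r0 / r) ** 10)
            got = system.contact_energy(x)
            assert got == pytest.approx(expect, rel=1e-10)

    def test_overlapping_contact_beads_rejected(self, nocut_params):
        system = TopologySystem(_pair_topology(r0=5.0), nocut_params)
        with pytest.raises(ValueError, match="overlap"):
            system.contact_energy(np.zeros((2, 3)))

    def test_excluded_volume_at_sigma_equals_eps(self, nocut_params):
        system = TopologySystem(_pair_topology(contact=False), nocut_params)
        x = np.array([[0.0, 0, 0], [nocut_params.sigma_excl, 0, 0]])
        assert system.excluded_volume_energy(x) == pytest.approx(
            nocut_params.eps, rel=1e-12
        )

    def test_fully_native_pair_has_no_repulsion(self, nocut_params):
        system = TopologySystem(_pair_topology(contact=True), nocut_params)
        x = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert system.excluded_volume_energy(x) == 0.0

    def test_excluded_volume_matches_naive_double_loop(self, nocut_params):
        rng = np.random.default_rng(3)
        n = 20
        pos = rng.uniform(0, 18, (n, 3))
        beads = [
            Bead(k, "A", k + 1, "GLY", BeadKind.CA, 0, pos[k]) for k in range(n)
        ]
        system = TopologySystem(TwoBasinTopology(beads=beads), nocut_params)
        expect = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                r = np.linalg.norm(pos[j] - pos[i])
                expect += nocut_params.eps * (nocut_params.sigma_excl / r) ** 12
        assert system.excluded_volume_energy(pos) == pytest.approx(expect, rel=1e-10)


class TestDebyeHueckel:
    def test_zero_salt_is_unscreened(self):
        assert debye_length_from_salt(0.0) == np.inf

    def test_quadrupling_salt_halves_debye_length(self):
        lam1 = debye_length_from_salt(0.05)
        lam4 = debye_length_from_salt(0.20)
        assert lam1 / lam4 == pytest.approx(2.0, rel=1e-12)

    def test_physiological_value_matches_kappa_formula(self):
        # independent evaluation of kappa^2 = 8 pi l_B N_A C
        from scipy import constants as const

        c, eps_r, temp = 0.1, 80.0, 298.0
        l_b = const.e**2 / (4 * np.pi * const.epsilon_0 * eps_r * const.k * temp) * 1e10
        expect = 1.0 / np.sqrt(8 * np.pi * l_b * c * const.N_A * 1e-27)
        assert debye_length_from_salt(c, eps_r, temp) == pytest.approx(expect, rel=1e-12)
        assert 9.0 < expect < 10.5  # the familiar ~9.6 A at 0.1 M

    def test_negative_salt_rejected(self):
        with pytest.raises(ValueError):
            debye_length_from_salt(-0.1)

    def test_unscreened_pair_follows_coulomb_law(self):
        params = ForceFieldParams(
            salt_concentration=0.0, lj_cutoff_factor=None,
            excl_cutoff_factor=None, dh_cutoff_factor=None,
        )
        topo = _pair_topology(charges=(1, -1), contact=False, sep=6.0)
        system = TopologySystem(topo, params)
        e1 = sum(system.electrostatic_energy(np.array([[0.0, 0, 0], [6.0, 0, 0]])))
        e2 = sum(system.electrostatic_energy(np.array([[0.0, 0, 0], [12.0, 0, 0]])))
        expect = -params.coulomb_prefactor / (params.dielectric * 6.0)
        assert e1 == pytest.approx(expect, rel=1e-12)
        assert e1 / e2 == pytest.approx(2.0, rel=1e-12)

    def test_neutral_pair_contributes_nothing(self, nocut_params):
        topo = _pair_topology(charges=(1, 0), contact=False, sep=6.0)
        system = TopologySystem(topo, nocut_params)
        assert sum(system.electrostatic_energy(np.array([[0.0, 0, 0], [6.0, 0, 0]]))) == 0.0

    def test_three_charge_hand_sum(self, nocut_params):
        positions = np.array([[0.0, 0, 0], [7.0, 0, 0], [0.0, 9.0, 0]])
        beads = [
            Bead(0, "A", 1, "ARG", BeadKind.CA, 1, positions[0]),
            Bead(1, "A", 8, "ASP", BeadKind.CA, -1, positions[1]),
            Bead(2, "A", 15, "GLU", BeadKind.CA, -1, positions[2]),
        ]
        system = TopologySystem(TwoBasinTopology(beads=beads), nocut_params)
        kappa = 1.0 / debye_length_from_salt(nocut_params.salt_concentration)
        pref = nocut_params.coulomb_prefactor / nocut_params.dielectric
        # hand-evaluated pair sum: (+-) at 7 A and (+-) at 9 A; (--) excluded
        expect = pref * (-np.exp(-kappa * 7.0) / 7.0 - np.exp(-kappa * 9.0) / 9.0)
        native, nonnative = system.electrostatic_energy(positions)
        assert native == 0.0
        assert nonnative == pytest.approx(expect, rel=1e-10)

    def test_screened_energy_magnitude_decreases_with_salt(self):
        topo = _pair_topology(charges=(1, -1), contact=False, sep=8.0)
        x = np.array([[0.0, 0, 0], [8.0, 0, 0]])
        mags = []
        for c_salt in [0.0, 0.05, 0.15, 0.5, 1.0]:
            params = ForceFieldParams(
                salt_concentration=c_salt, lj_cutoff_factor=None,
                excl_cutoff_factor=None, dh_cutoff_factor=None,
            )
            system = TopologySystem(topo, params)
            mags.append(abs(sum(system.electrostatic_energy(x))))
        assert all(a >= b for a, b in zip(mags, mags[1:]))


class TestScalingKnobs:
    def test_eps_b_scales_only_the_lf_f_contacts(self, toy):
        base = ForceFieldParams(lj_cutoff_factor=None, excl_cutoff_factor=None,
                                dh_cutoff_factor=None)
        doubled = ForceFieldParams(eps_B_scale=2.0, lj_cutoff_factor=None,
                                   excl_cutoff_factor=None, dh_cutoff_factor=None)
        s1 = TopologySystem(toy.topology, base)
        s2 = TopologySystem(toy.topology, doubled)
        lf_f = set(toy.topology.lf_f_contact_ids)
        rng = np.random.default_rng(8)
        x = toy.topology.ref_positions_B + 0.05 * rng.standard_normal(
            (toy.topology.n_beads, 3))
        e1, _ = s1._contact_energy_terms(x)
        e2, _ = s2._contact_energy_terms(x)
        for c_id in range(len(toy.topology.contacts)):
            if c_id in lf_f:
                assert e2[c_id] == pytest.approx(2.0 * e1[c_id], rel=1e-12)
            else:
                assert e2[c_id] == e1[c_id]  # bitwise identical

    def test_lambda_acts_only_on_linker_hinge_terms(self, toy):
        base = ForceFieldParams(lj_cutoff_factor=None, excl_cutoff_factor=None,
                                dh_cutoff_factor=None)
        stiff = ForceFieldParams(lambda_linker=10.0, lj_cutoff_factor=None,
                                 excl_cutoff_factor=None, dh_cutoff_factor=None)
        s1 = TopologySystem(toy.topology, base)
        s2 = TopologySystem(toy.topology, stiff)
        hinge = np.array([t.hinge for t in toy.topology.dihedrals])
        assert np.all(s2.dihedral_k[hinge] == 10.0 * s1.dihedral_k[hinge])
        assert np.all(s2.dihedral_k[~hinge] == s1.dihedral_k[~hinge])
        assert np.all(s2.angle_k == s1.angle_k)  # no hinge angles in this fixture

    def test_bias_basin_selects_hinge_reference(self, toy):
        to_a = TopologySystem(toy.topology, ForceFieldParams(bias_basin="A"))
        to_b = TopologySystem(toy.topology, ForceFieldParams(bias_basin="B"))
        hinge = np.array([t.hinge for t in toy.topology.dihedrals])
        assert not np.allclose(to_a.dihedral_phi0[hinge], to_b.dihedral_phi0[hinge])
        assert np.array_equal(to_a.dihedral_phi0[~hinge], to_b.dihedral_phi0[~hinge])


class TestBondedTerms:
    def test_bond_at_native_length_is_zero(self, nocut_params):
        topo = _pair_topology(contact=False)
        topo.bonds.append(BondTerm(0, 1, 5.0))
        system = TopologySystem(topo, nocut_params)
        x = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        assert system.bonded_energy(x)[0] == 0.0

    def test_dihedral_energy_is_2pi_periodic(self, complex_system, toy_complex):
        system = complex_system
        phi0 = system.dihedral_phi0.copy()
        x = toy_complex.topology.ref_positions_A
        e1 = system.bonded_energy(x)[1]["dihedrals"]
        system.dihedral_phi0 = phi0 + 2 * np.pi
        e2 = system.bonded_energy(x)[1]["dihedrals"]
        system.dihedral_phi0 = phi0
        assert e1 == pytest.approx(e2, abs=1e-9)

    def test_colinear_angle_gives_finite_energy_and_forces(self, nocut_params):
        from dualbasin.topology import AngleTerm

        beads = [
            Bead(k, "A", k + 1, "GLY", BeadKind.CA, 0, [3.8 * k, 0.0, 0.0])
            for k in range(3)
        ]
        topo = TwoBasinTopology(
            beads=beads,
            bonds=[BondTerm(0, 1, 3.8), BondTerm(1, 2, 3.8)],
            angles=[AngleTerm(0, 1, 2, np.pi, np.pi)],
        )
        system = TopologySystem(topo, nocut_params)
        x = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])  # exactly colinear
        e, _ = system.bonded_energy(x)
        f = system.forces(x)
        assert np.isfinite(e)
        assert np.all(np.isfinite(f))


class TestBreakdownAndInvariance:
    def test_components_resum_to_total(self, complex_system, toy_complex):
        rng = np.random.default_rng(12)
        x = toy_complex.topology.ref_positions_B + 0.2 * rng.standard_normal(
            (toy_complex.topology.n_beads, 3))
        b = complex_system.energy_breakdown(x)
        parts = b.bonded + b.native_LJ + b.nonnative_excl + b.native_elect + b.nonnative_elect
        assert b.total == pytest.approx(parts, rel=1e-12)
        assert b.nonnative_excl >= 0.0

    def test_native_contacts_at_b_reference_sum_to_well_depths(self, toy_complex):
        # at the bound reference all B-native and shared contacts sit at r0
        params = ForceFieldParams(lj_cutoff_factor=None, excl_cutoff_factor=None,
                                  dh_cutoff_factor=None)
        system = TopologySystem(toy_complex.topology, params)
        e, _ = system._contact_energy_terms(toy_complex.topology.ref_positions_B)
        t = toy_complex.topology
        ids = t.contact_ids_by_class(BasinClass.SHARED) + \
            t.contact_ids_by_class(BasinClass.INTRA_B) + t.interface_contact_ids()
        for c_id in ids:
            assert e[c_id] == pytest.approx(-system.contact_eps[c_id], rel=1e-9)

    def test_rigid_body_motion_changes_nothing(self, complex_system, toy_complex):
        x = toy_complex.topology.ref_positions_B
        b0 = complex_system.energy_breakdown(x)
        rot = rotation_matrix([0.3, -1.0, 0.7], 1.1)
        x2 = (x - x.mean(0)) @ rot.T + x.mean(0) + np.array([5.0, -3.0, 11.0])
        b1 = complex_system.energy_breakdown(x2)
        for key, val in b0.as_dict().items():
            assert b1.as_dict()[key] == pytest.approx(val, abs=1e-9)

    def test_interchain_breakdown_vanishes_when_separated(self, complex_system, toy_complex):
        t = toy_complex.topology
        x = t.ref_positions_B.copy()
        x[t.protein_mask] += 400.0
        b = complex_system.interchain_breakdown(x)
        assert abs(b.native_LJ) < 1e-6
        assert abs(b.nonnative_excl) < 1e-6
        assert abs(b.native_elect) + abs(b.nonnative_elect) < 1e-3


class TestForces:
    def test_forces_match_finite_differences(self, complex_system, toy_complex):
        rng = np.random.default_rng(2)
        t = toy_complex.topology
        h = 1e-5
        for _ in range(3):
            x = t.ref_positions_B + 0.1 * rng.standard_normal((t.n_beads, 3))
            f = complex_system.forces(x)
            scale = np.abs(f).max()
            mobile = np.where(~complex_system.frozen_mask)[0]
            for b in mobile[::5]:
                for d in range(3):
                    xp, xm = x.copy(), x.copy()
                    xp[b, d] += h
                    xm[b, d] -= h
                    fd = -(complex_system.energy(xp) - complex_system.energy(xm)) / (2 * h)
                    assert abs(fd - f[b, d]) / scale < 1e-5

    def test_frozen_dna_rows_are_exactly_zero(self, complex_system, toy_complex):
        rng = np.random.default_rng(9)
        t = toy_complex.topology
        x = t.ref_positions_A + rng.standard_normal((t.n_beads, 3))
        f = complex_system.forces(x)
        assert np.all(f[complex_system.frozen_mask] == 0.0)

    def test_contact_force_vanishes_at_native_distance(self, nocut_params):
        system = TopologySystem(_pair_topology(r0=5.0), nocut_params)
        x = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        f = np.zeros_like(x)
        system._add_pair_forces(f, x)
        assert np.abs(f).max() < 1e-12
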