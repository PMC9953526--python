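"""Hydrogen-bond criteria, counterion contacts, inter-group electrostatics."""

import numpy as np
import pytest

from gagtraj.interactions import (
    COULOMB_CONSTANT,
    HBondCriteria,
    InteractionError,
    detect_hbonds,
    electrostatic_repulsion_series,
    hbond_matrix,
    ion_contact_fractions,
)
from gagtraj.model import AtomRecord, ChargedGroup, ChargeMap, Residue, Topology, Trajectory


def _topology(atom_specs, residue_specs, charged_groups=()):
    atoms = [
        AtomRecord(i + 1, name, element, res, rname, charge)
        for i, (name, element, res, rname, charge) in enumerate(atom_specs)
    ]
    residues = [Residue(rname, role, tuple(idx)) for rname, role, idx in residue_specs]
    return Topology(atoms=atoms, residues=residues, rings={}, linkages=[],
                    charged_groups=list(charged_groups))


def hbond_toy(acceptor_xyz):
    """Donor O-H on residue 1, acceptor O on residue 2; H at the origin."""
    topo = _topology(
        [("O2", "O", 1, "GCU", None), ("HO2", "H", 1, "GCU", None),
         ("O5", "O", 2, "NG4", None)],
        [("GCU", "uronic_acid", [0, 1]), ("NG4", "hexosamine", [2])],
    )
    coords = np.array([[0.96, 0.0, 0.0], [0.0, 0.0, 0.0], list(acceptor_xyz)])
    return topo, coords


class TestHBondCriteria:
    def test_accepted_inside_both_cutoffs(self):
        # heavy distance 2.8 A, angle at H 180 deg
        topo, coords = hbond_toy((0.96 - 2.8, 0.0, 0.0))
        bonds = detect_hbonds(coords, topo, solute_indices=[0, 1, 2])
        assert bonds == [(0, 1, 2)]

    def test_rejected_beyond_distance_cutoff(self):
        topo, coords = hbond_toy((0.96 - 3.05, 0.0, 0.0))
        assert detect_hbonds(coords, topo, solute_indices=[0, 1, 2]) == []

    def test_rejected_below_angle_cutoff(self):
        # D-A 2.8 A but D-H-A = 120 deg at the hydrogen
        t = (-0.96 + np.sqrt(0.96**2 + 4 * (2.8**2 - 0.96**2))) / 2.0
        acceptor = t * np.array([np.cos(np.radians(120.0)), np.sin(np.radians(120.0)), 0.0])
        topo, coords = hbond_toy(tuple(acceptor))
        assert abs(np.linalg.norm(acceptor - coords_donor()) - 2.8) < 1e-12
        assert detect_hbonds(coords, topo, solute_indices=[0, 1, 2]) == []

    def test_boundaries_are_strict(self):
        crit = HBondCriteria()
        topo, coords = hbond_toy((0.96 - crit.distance_cutoff, 0.0, 0.0))
        assert detect_hbonds(coords, topo, crit, solute_indices=[0, 1, 2]) == []

    def test_missing_hydrogens_raise(self):
        topo = _topology(
            [("O2", "O", 1, "GCU", None), ("O5", "O", 2, "NG4", None)],
            [("GCU", "uronic_acid", [0]), ("NG4", "hexosamine", [1])],
        )
        with pytest.raises(InteractionError, match="explicit hydrogens"):
            detect_hbonds(np.zeros((2, 3)) + [[0, 0, 0], [2, 0, 0]], topo,
                          solute_indices=[0, 1])

    def test_invalid_criteria(self):
        with pytest.raises(InteractionError):
            HBondCriteria(distance_cutoff=-1.0)
        with pytest.raises(InteractionError):
            HBondCriteria(angle_cutoff=200.0)


def coords_donor():
    return np.array([0.96, 0.0, 0.0])


class TestHBondMatrix:
    def test_zero_matrix_without_close_geometry(self):
        topo, coords = hbond_toy((10.0, 0.0, 0.0))
        traj = Trajectory(np.repeat(coords[None], 4, axis=0),
                          solute_indices=np.arange(3))
        hm = hbond_matrix(traj, topo)
        assert np.all(hm.matrix == 0.0)

    def test_summed_fraction_can_exceed_one(self):
        # two simultaneous donor-acceptor pairs between residues 1 and 2
        topo = _topology(
            [("O2", "O", 1, "GCU", None), ("HO2", "H", 1, "GCU", None),
             ("O3", "O", 1, "GCU", None), ("HO3", "H", 1, "GCU", None),
             ("O5", "O", 2, "NG4", None), ("O7", "O", 2, "NG4", None)],
            [("GCU", "uronic_acid", [0, 1, 2, 3]), ("NG4", "hexosamine", [4, 5])],
        )
        coords = np.array([
            [0.96, 0.0, 0.0], [0.0, 0.0, 0.0], [0.96, 50.0, 0.0], [0.0, 50.0, 0.0],
            [-1.84, 0.0, 0.0], [-1.84, 50.0, 0.0],
        ])
        traj = Trajectory(np.repeat(coords[None], 5, axis=0),
                          solute_indices=np.arange(6))
        hm = hbond_matrix(traj, topo)
        i, j = 0, 1
        assert hm.matrix[i, j] == pytest.approx(2.0)
        assert hm.matrix[j, i] == pytest.approx(2.0)

    def test_recovers_planted_fractions(self, recovery_run):
        spec, topo, traj, _, truth = recovery_run
        hm = hbond_matrix(traj, topo)
        n = len(topo.sugar_residue_indices())
        expected = np.zeros((n, n))
        for hb, flags in zip(spec.hbond_truth, truth.hbond_flags):
            i, j = hb.donor_residue - 1, hb.acceptor_residue - 1
            expected[i, j] += flags.mean()
            if i != j:
                expected[j, i] += flags.mean()
        se = 3.0 * np.sqrt(0.7 * 0.3 / traj.n_frames)
        assert np.abs(hm.matrix - expected).max() <= se

    def test_water_hbond_mean_matches_planted(self, recovery_run):
        spec, topo, traj, _, truth = recovery_run
        hm = hbond_matrix(traj, topo)
        planted = float(np.mean(truth.water_flags.sum(axis=0)))
        assert hm.water_hbonds_per_frame == pytest.approx(planted, abs=0.05)


def ion_toy(ion_positions):
    """One carboxyl (residue 1) and one sulfate (residue 2), 50 A apart."""
    specs = [("C6", "C", 1, "GCU", None), ("O6A", "O", 1, "GCU", None),
             ("O6B", "O", 1, "GCU", None),
             ("S", "S", 2, "NG4", None), ("O1S", "O", 2, "NG4", None),
             ("O2S", "O", 2, "NG4", None), ("O3S", "O", 2, "NG4", None)]
    specs += [("NA", "NA", 3 + k, "NA+", None) for k in range(len(ion_positions))]
    residues = [("GCU", "uronic_acid", [0, 1, 2]), ("NG4", "hexosamine", [3, 4, 5, 6])]
    residues += [("NA+", "ion", [7 + k]) for k in range(len(ion_positions))]
    groups = [ChargedGroup("carboxyl", (0, 1, 2), 1), ChargedGroup("sulfate", (3, 4, 5, 6), 2)]
    topo = _topology(specs, residues, groups)
    coords = np.zeros((len(specs), 3))
    coords[3:7] = [50.0, 0.0, 0.0]     # sulfate group collapsed at x=50
    for k, pos in enumerate(ion_positions):
        coords[7 + k] = pos
    traj = Trajectory(coords[None], solute_indices=np.arange(7),
                      ion_indices=np.arange(7, 7 + len(ion_positions)))
    return topo, traj


class TestIonContacts:
    def test_carboxyl_contact_inside_cutoff(self):
        topo, traj = ion_toy([(3.9, 0.0, 0.0)])
        stats = ion_contact_fractions(traj, topo)
        frac = {k: f for k, _, f in stats.per_group}
        assert frac["carboxyl"] == 1.0
        assert frac["sulfate"] == 0.0

    def test_kind_specific_cutoffs_at_4p1(self):
        # 4.1 A: outside the carboxyl cutoff (4.0) but inside sulfate's (4.2)
        topo, traj = ion_toy([(4.1, 0.0, 0.0), (50.0 + 4.1, 0.0, 0.0)])
        stats = ion_contact_fractions(traj, topo)
        frac = {k: f for k, _, f in stats.per_group}
        assert frac["carboxyl"] == 0.0
        assert frac["sulfate"] == 1.0

    def test_no_ions_raises_distinct_error(self):
        topo, traj = ion_toy([(3.9, 0.0, 0.0)])
        no_ions = Trajectory(traj.coordinates[:, :7], solute_indices=np.arange(7))
        with pytest.raises(InteractionError, match="no counterions"):
            ion_contact_fractions(no_ions, topo)

    def test_recovers_planted_contact_rate(self, recovery_run):
        spec, topo, traj, _, truth = recovery_run
        stats = ion_contact_fractions(traj, topo)
        for kind, residue, frac in stats.per_group:
            planted = truth.ion_flags[(kind, residue)].mean()
            se = np.sqrt(planted * (1 - planted) / traj.n_frames)
            assert abs(frac - planted) <= 3.0 * se + 1e-12

    def test_adding_an_ion_never_decreases_fractions(self):
        topo1, traj1 = ion_toy([(10.0, 0.0, 0.0)])
        topo2, traj2 = ion_toy([(10.0, 0.0, 0.0), (3.0, 0.0, 0.0)])
        f1 = {k: f for k, _, f in ion_contact_fractions(traj1, topo1).per_group}
        f2 = {k: f for k, _, f in ion_contact_fractions(traj2, topo2).per_group}
        assert all(f2[k] >= f1[k] for k in f1)


class TestElectrostatics:
    def _toy(self, r):
        topo, _ = ion_toy([])
        coords = np.zeros((7, 3))
        coords[1] = [0.0, 0.0, 0.0]                  # charged carboxyl oxygen
        coords[0] = [0.0, 30.0, 0.0]
        coords[2] = [0.0, 60.0, 0.0]
        coords[4] = [r, 0.0, 0.0]                    # charged sulfate oxygen
        coords[3] = [r, -30.0, 0.0]
        coords[5] = [r, -60.0, 0.0]
        coords[6] = [r, -90.0, 0.0]
        charges = ChargeMap({("GCU", n): 0.0 for n in ("C6", "O6B")}
                            | {("GCU", "O6A"): -1.0}
                            | {("NG4", n): 0.0 for n in ("S", "O2S", "O3S")}
                            | {("NG4", "O1S"): -1.0})
        traj = Trajectory(coords[None], solute_indices=np.arange(7))
        return topo, traj, charges

    def test_single_pair_value_at_1_angstrom(self):
        topo, traj, charges = self._toy(1.0)
        e = electrostatic_repulsion_series(traj, topo, charges).values[0]
        assert e == pytest.approx(COULOMB_CONSTANT, rel=1e-3)

    def test_inverse_distance_scaling(self):
        topo, t1, charges = self._toy(1.0)
        _, t2, _ = self._toy(2.0)
        e1 = electrostatic_repulsion_series(t1, topo, charges).values[0]
        e2 = electrostatic_repulsion_series(t2, topo, charges).values[0]
        assert e2 == pytest.approx(e1 / 2.0, rel=1e-3)

    def test_matches_naive_double_loop(self, recovery_run):
        _, topo, traj, charge_map, _ = recovery_run
        sub = Trajectory(traj.coordinates[:5], traj.solute_indices,
                         traj.ion_indices, traj.water_indices)
        series = electrostatic_repulsion_series(sub, topo, charge_map)
        atom_idx, group_id = [], []
        for g, grp in enumerate(topo.charged_groups):
            atom_idx.extend(grp.atom_indices)
            group_id.extend([g] * len(grp.atom_indices))
        q = charge_map.resolve(topo, atom_idx)
        for f in range(5):
            e = 0.0
            for a in range(len(atom_idx)):
                for b in range(a + 1, len(atom_idx)):
                    if group_id[a] == group_id[b]:
                        continue
                    r = np.linalg.norm(sub.coordinates[f, atom_idx[a]]
                                       - sub.coordinates[f, atom_idx[b]])
                    e += COULOMB_CONSTANT * q[a] * q[b] / r
            assert series.values[f] == pytest.approx(e, rel=1e-8)

    def test_like_charges_repel_and_decay(self):
        topo, traj, charges = self._toy(5.0)
        e5 = electrostatic_repulsion_series(traj, topo, charges).values[0]
        _, t8, _ = self._toy(8.0)
        e8 = electrostatic_repulsion_series(t8, topo, charges).values[0]
        assert e5 > e8 > 0.0

    def test_missing_charge_raises(self, recovery_run):
        _, topo, traj, _, _ = recovery_run
        with pytest.raises(KeyError):
            electrostatic_repulsion_series(traj, topo, ChargeMap({}))
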