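import numpy as np
import pandas as pd
import pytest

from globulebind.binding import (
    BindingParams,
    InteractionRecord,
    bound_fraction,
    conditional_probability,
    kd_from_bound_fraction,
    pair_simultaneous_contact_map,
    proximity_fraction,
    residue_contact_matrix,
    rg_vs_min_contacts,
)
from globulebind.ensemble_model import ObservableSeries

from conftest import make_simple_ensemble


def _two_residue_system(separation):
    """One protein residue (single C atom) + one ligand atom at a given
    separation (angstrom)."""
    atoms = [("CA", "C", 1, "ALA"), ("C1", "C", 2, "LIG")]
    coords = [[[0.0, 0.0, 0.0], [separation, 0.0, 0.0]]]
    return make_simple_ensemble(atoms, coords, ligand_residues=("LIG",))


class TestContactMatrix:
    def test_inside_cutoff_is_contact(self):
        assert residue_contact_matrix(_two_residue_system(5.9))[0, 0]

    def test_outside_cutoff_is_not(self):
        assert not residue_contact_matrix(_two_residue_system(6.1))[0, 0]

    def test_hydrogens_excluded_by_default(self):
        atoms = [("HA", "H", 1, "ALA"), ("CA", "C", 1, "ALA"),
                 ("C1", "C", 2, "LIG")]
        coords = [[[0, 0, 0], [10, 0, 0], [3, 0, 0]]]
        ens = make_simple_ensemble(atoms, coords, ligand_residues=("LIG",))
        assert not residue_contact_matrix(ens)[0, 0]

    def test_matches_brute_force_oracle(self, bound_system):
        ens = bound_system
        contacts = residue_contact_matrix(ens)
        top = ens.topology
        lig_heavy = [i for i in top.ligand_atoms if top.atoms[i].heavy]
        atom_res = top.atom_residue_indices()
        rng = np.random.default_rng(0)
        for f in rng.choice(ens.n_frames, size=5, replace=False):
            for col, ri in enumerate(top.protein_residue_indices()):
                found = False
                for i in np.where(atom_res == ri)[0]:
                    if not top.atoms[i].heavy or i in top.ligand_atoms:
                        continue
                    for j in lig_heavy:
                        d = np.sqrt(np.sum(
                            (ens.coordinates[f, i] - ens.coordinates[f, j])**2))
                        if d < 6.0:
                            found = True
                assert contacts[f, col] == found

    def test_no_ligand_errors(self, ideal_helix):
        with pytest.raises(ValueError, match="no ligand"):
            residue_contact_matrix(ideal_helix)


class TestBoundFraction:
    def test_all_contacting_gives_one(self):
        contacts = np.ones((10, 3), dtype=bool)
        assert bound_fraction(contacts).mean == 1.0

    def test_alternating_gives_half(self):
        contacts = np.zeros((20, 2), dtype=bool)
        contacts[::2, 0] = True
        assert bound_fraction(contacts).mean == pytest.approx(0.5)

    def test_known_rate_recovered_within_3se(self, bound_system):
        ens = bound_system
        pb = bound_fraction(residue_contact_matrix(ens),
                            weights=ens.frame_weights)
        rate = 0.43
        se = np.sqrt(rate * (1 - rate) / ens.n_frames)
        assert abs(pb.mean - rate) < 3 * se


class TestKd:
    def test_box_concentration_is_3_93_mM(self):
        res = kd_from_bound_fraction(0.5, 7.5)
        assert res.c_box * 1e3 == pytest.approx(3.93, abs=0.01)

    def test_half_bound_kd_equals_box_concentration(self):
        res = kd_from_bound_fraction(0.5, 7.5)
        assert res.kd == pytest.approx(res.c_box, rel=1e-12)

    def test_two_thirds_bound(self):
        res = kd_from_bound_fraction(0.67, 7.5)
        assert res.kd * 1e3 == pytest.approx(1.94, abs=0.01)

    def test_no_binding_errors(self):
        with pytest.raises(ValueError, match="no binding"):
            kd_from_bound_fraction(0.0, 7.5)

    def test_fully_bound_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="fully bound"):
            assert kd_from_bound_fraction(1.0, 7.5).kd == 0.0

    def test_kd_strictly_decreasing_in_bound_fraction(self):
        pbs = np.linspace(0.05, 0.95, 15)
        kds = [kd_from_bound_fraction(p, 7.5).kd for p in pbs]
        assert np.all(np.diff(kds) < 0)
        # K_D * P_b / (1 - P_b) is the box concentration for every P_b
        for p, kd in zip(pbs, kds):
            assert kd * p / (1 - p) == pytest.approx(
                kd_from_bound_fraction(0.5, 7.5).c_box, rel=1e-12)

    def test_box_must_exceed_cutoff(self):
        with pytest.raises(ValueError, match="box edge"):
            BindingParams(contact_cutoff=6.0, box_edge=0.5)


class TestPairMap:
    def test_single_residue_contact_has_empty_off_diagonal(self):
        contacts = np.zeros((6, 3), dtype=bool)
        contacts[np.arange(6), np.arange(6) % 3] = True
        pair = pair_simultaneous_contact_map(contacts)
        off = pair - np.diag(np.diag(pair))
        assert np.all(off == 0.0)

    def test_always_joint_contact_gives_one(self):
        contacts = np.zeros((5, 4), dtype=bool)
        contacts[:, 1] = contacts[:, 2] = True
        pair = pair_simultaneous_contact_map(contacts)
        assert pair[1, 2] == 1.0

    def test_matches_brute_force_and_frechet_bound(self):
        rng = np.random.default_rng(4)
        contacts = rng.random((200, 8)) < 0.3
        pair = pair_simultaneous_contact_map(contacts)
        marginals = contacts.mean(axis=0)
        for i in range(8):
            assert pair[i, i] == pytest.approx(marginals[i], abs=1e-12)
            for j in range(8):
                expected = np.mean(contacts[:, i] & contacts[:, j])
                assert pair[i, j] == pytest.approx(expected, abs=1e-12)
                assert pair[i, j] <= min(marginals[i], marginals[j]) + 1e-15
        assert np.allclose(pair, pair.T)


class TestConditionalProbability:
    def test_self_conditioning_is_one(self):
        rec = InteractionRecord("a", np.array([1, 0, 1, 1], dtype=bool))
        assert conditional_probability(rec, rec) == 1.0

    def test_disjoint_records_give_zero(self):
        a = InteractionRecord("a", np.array([1, 0, 0, 0], dtype=bool))
        b = InteractionRecord("b", np.array([0, 1, 1, 0], dtype=bool))
        assert conditional_probability(a, b) == 0.0

    def test_independent_records_within_3se(self):
        rng = np.random.default_rng(9)
        n = 4000
        a = InteractionRecord("a", rng.random(n) < 0.3)
        b = InteractionRecord("b", rng.random(n) < 0.5)
        se = np.sqrt(0.3 * 0.7 / (0.5 * n))
        assert abs(conditional_probability(a, b) - 0.3) < 3 * se

    def test_zero_probability_condition_errors(self):
        a = InteractionRecord("a", np.array([True]))
        b = InteractionRecord("b", np.array([False]))
        with pytest.raises(ValueError, match="zero probability"):
            conditional_probability(a, b)


class TestRgVsMinContacts:
    def _ensemble_with_rg(self, n_frames):
        atoms = [("CA", "C", 1, "ALA"), ("C1", "C", 2, "LIG")]
        coords = np.zeros((n_frames, 2, 3))
        return make_simple_ensemble(atoms, coords, ligand_residues=("LIG",))

    def test_identical_frames_give_equal_rows(self, bound_system):
        contacts = residue_contact_matrix(bound_system)
        first = np.repeat(contacts[:1], 10, axis=0)
        rg = ObservableSeries("Rg", np.full(10, 1.17))
        ens = self._ensemble_with_rg(10)
        table, _ = rg_vs_min_contacts(ens, first, rg)
        assert np.allclose(table["mean_rg_nm"], 1.17)

    def test_k0_row_is_global_mean(self):
        rng = np.random.default_rng(2)
        contacts = rng.random((50, 4)) < 0.4
        rg = ObservableSeries("Rg", rng.uniform(1.0, 2.0, 50))
        ens = self._ensemble_with_rg(50)
        table, _ = rg_vs_min_contacts(ens, contacts, rg)
        assert table.loc[table["min_contacts"] == 0,
                         "mean_rg_nm"].iloc[0] == pytest.approx(
            rg.values.mean(), abs=1e-12)

    def test_compact_high_contact_frames_monotone(self):
        n = 60
        counts = np.repeat(np.arange(6), 10)
        contacts = np.zeros((n, 6), dtype=bool)
        for f in range(n):
            contacts[f, :counts[f]] = True
        rg = ObservableSeries("Rg", 2.0 - 0.12 * counts)
        ens = self._ensemble_with_rg(n)
        table, unbound = rg_vs_min_contacts(ens, contacts, rg)
        assert np.all(np.diff(table["mean_rg_nm"]) <= 1e-12)
        assert unbound == pytest.approx(2.0)


class TestProximityFraction:
    def _tagged(self, separations):
        atoms = [("SG", "S", 1, "CYS"), ("CL1", "Cl", 2, "LIG")]
        coords = [[[0, 0, 0], [d, 0, 0]] for d in separations]
        ens = make_simple_ensemble(atoms, coords, ligand_residues=("LIG",))
        ens.topology.special_atoms = {"CYS_SG": 0, "chlorohydrin_Cl": 1}
        return ens

    def test_inside_cutoff(self):
        frac, _, _ = proximity_fraction(self._tagged([8.0] * 8),
                                        "CYS_SG", "chlorohydrin_Cl", 10.0)
        assert frac.mean == 1.0

    def test_outside_cutoff(self):
        frac, _, _ = proximity_fraction(self._tagged([12.0] * 8),
                                        "CYS_SG", "chlorohydrin_Cl", 10.0)
        assert frac.mean == 0.0

    def test_mixture_rate_recovered(self):
        rng = np.random.default_rng(3)
        near = rng.random(600) < 0.23
        seps = np.where(near, 8.0, 14.0)
        frac, d, hist = proximity_fraction(self._tagged(seps),
                                           "CYS_SG", "chlorohydrin_Cl", 10.0)
        se = np.sqrt(0.23 * 0.77 / 600)
        assert abs(frac.mean - 0.23) < 3 * se
        assert hist["probability"].sum() == pytest.approx(1.0)

    def test_missing_tag_errors(self):
        with pytest.raises(KeyError, match="no special atom"):
            proximity_fraction(self._tagged([8.0]), "nope", "CYS_SG", 10.0)
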