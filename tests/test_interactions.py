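import numpy as np
import pytest

from globulebind.binding import residue_contact_matrix
from globulebind.interactions import (
    FIGURE_CUTOFFS,
    StackingCutoffs,
    StackingGeometry,
    classify_stacking,
    hydrogen_bonds,
    hydrophobic_contacts,
    stacking_fes,
    stacking_geometry,
    stacking_populations,
)
from globulebind.synthetic_data import place_ligand

from conftest import make_simple_ensemble


def _pair(elem_a, elem_b, distance, name_a="CA", name_b="X1"):
    atoms = [(name_a, elem_a, 1, "ALA"), (name_b, elem_b, 2, "LIG")]
    coords = [[[0, 0, 0], [distance, 0, 0]]]
    ens = make_simple_ensemble(atoms, coords, ligand_residues=("LIG",),
                               annotate=True,
                               annotation={"residue_name": "LIG", "rings": {},
                                           "donors": [], "acceptors": [],
                                           "hydrophobic": [name_b],
                                           "special": {}})
    return ens


class TestHydrophobic:
    def test_carbon_carbon_inside_cutoff(self):
        table, records = hydrophobic_contacts(_pair("C", "C", 3.9))
        assert records["any"].mask[0]
        assert table["population"].iloc[0] == 1.0

    def test_carbon_carbon_outside_cutoff(self):
        _, records = hydrophobic_contacts(_pair("C", "C", 4.1))
        assert not records["any"].mask[0]

    def test_nitrogen_not_hydrophobic(self):
        # protein nitrogen at 3.0 A from a ligand carbon is not a
        # hydrophobic contact (only carbons count on the protein side)
        ens = _pair("N", "C", 3.0, name_a="N")
        _, records = hydrophobic_contacts(ens)
        assert not records["any"].mask[0]

    def test_matches_brute_force_oracle(self, bound_system):
        ens = bound_system
        top = ens.topology
        _, records = hydrophobic_contacts(ens)
        lig_set = set(top.ligand_atoms)
        lig_hydro = [i for i in top.hydrophobic_atoms if i in lig_set]
        atom_res = top.atom_residue_indices()
        rng = np.random.default_rng(1)
        for f in rng.choice(ens.n_frames, size=4, replace=False):
            for ri in list(rng.choice(top.protein_residue_indices(), 6)):
                res = top.residues[ri]
                atoms = [i for i in top.hydrophobic_atoms
                         if i not in lig_set and atom_res[i] == ri]
                expected = any(
                    np.linalg.norm(ens.coordinates[f, i]
                                   - ens.coordinates[f, j]) < 4.0
                    for i in atoms for j in lig_hydro)
                assert records[res.author_index].mask[f] == expected


class TestHydrogenBonds:
    def _donor_acceptor(self, ha_distance, angle_deg):
        """Protein O-H donor and ligand O acceptor at a set geometry."""
        h = np.array([0.0, 0.0, 0.0])
        d = np.array([-0.97, 0.0, 0.0])
        ang = np.deg2rad(angle_deg)
        a = h + ha_distance * np.array([np.cos(np.pi - ang),
                                        np.sin(np.pi - ang), 0.0])
        # donor-H-acceptor angle measured at H between (d-h) and (a-h)
        atoms = [("OG", "O", 1, "SER"), ("HG", "H", 1, "SER"),
                 ("O1", "O", 2, "LIG")]
        coords = [[d, h, a]]
        return make_simple_ensemble(
            atoms, coords, ligand_residues=("LIG",), annotate=True,
            annotation={"residue_name": "LIG", "rings": {}, "donors": [],
                        "acceptors": ["O1"], "hydrophobic": [],
                        "special": {}})

    def test_collinear_short_bond_detected(self):
        _, pairs, records = hydrogen_bonds(self._donor_acceptor(2.0, 180.0))
        assert records["any"].mask[0]
        assert len(pairs) == 1

    def test_bent_geometry_rejected(self):
        _, pairs, records = hydrogen_bonds(self._donor_acceptor(2.0, 140.0))
        assert not records["any"].mask[0]

    def test_geometry_sweep_matches_direct_evaluation(self):
        for dist in (1.8, 2.5, 3.4, 3.6, 4.5):
            for ang in (120.0, 145.0, 151.0, 165.0, 179.0):
                _, _, records = hydrogen_bonds(self._donor_acceptor(dist, ang))
                expected = (dist < 3.5) and (ang > 150.0)
                assert records["any"].mask[0] == expected, (dist, ang)

    def test_ligand_donor_direction(self, bound_system):
        # the toy ligand hydroxyl can donate to protein backbone oxygens
        _, pairs, _ = hydrogen_bonds(bound_system)
        if len(pairs):
            assert set(pairs["direction"]) <= {"protein-donor",
                                               "ligand-donor"}


def _ring_pair(R=4.0, theta=0.0, phi=0.0):
    """Two hexagonal rings at an exact (R, theta, phi) geometry."""
    from globulebind.synthetic_data import _hexagon, _rotation_about

    z = np.array([0.0, 0.0, 1.0])
    x = np.array([1.0, 0.0, 0.0])
    ring_a = _hexagon(np.zeros(3), z, x)
    axis = np.array([0.0, 1.0, 0.0])
    center_b = R * (_rotation_about(axis, phi) @ z)
    normal_b = _rotation_about(axis, theta) @ z
    ring_b = _hexagon(center_b, normal_b, x)
    atoms = [(f"CR{i+1}", "C", 1, "PHE") for i in range(6)]
    atoms += [(f"C{i+1}", "C", 2, "LIG") for i in range(6)]
    coords = np.vstack([ring_a, ring_b])[None]
    ens = make_simple_ensemble(atoms, coords, ligand_residues=("LIG",))
    ens.topology.ring_groups = {"protein": list(range(6)),
                                "ligand": list(range(6, 12))}
    return ens


class TestStackingGeometry:
    def test_parallel_offset_along_normal(self):
        geom = stacking_geometry(_ring_pair(4.0, 0.0, 0.0),
                                 "protein", "ligand")
        assert geom.R[0] == pytest.approx(4.0, abs=1e-9)
        assert geom.theta[0] == pytest.approx(0.0, abs=1e-6)
        assert geom.phi[0] == pytest.approx(0.0, abs=1e-6)

    def test_perpendicular_rings_in_plane(self):
        geom = stacking_geometry(_ring_pair(5.0, 90.0, 90.0),
                                 "protein", "ligand")
        assert geom.theta[0] == pytest.approx(90.0, abs=1e-6)
        assert geom.phi[0] == pytest.approx(90.0, abs=1e-6)

    def test_global_rotation_invariance(self):
        ens = _ring_pair(5.5, 40.0, 25.0)
        rng = np.random.default_rng(12)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rotated = make_simple_ensemble(
            [(a.name, a.element, 1 + a.residue_index,
              ens.topology.residues[a.residue_index].name)
             for a in ens.topology.atoms],
            ens.coordinates @ q.T + 7.0,
            ligand_residues=("LIG",))
        rotated.topology.ring_groups = dict(ens.topology.ring_groups)
        g0 = stacking_geometry(ens, "protein", "ligand")
        g1 = stacking_geometry(rotated, "protein", "ligand")
        assert g1.R[0] == pytest.approx(g0.R[0], abs=1e-9)
        assert g1.theta[0] == pytest.approx(g0.theta[0], abs=1e-6)
        assert g1.phi[0] == pytest.approx(g0.phi[0], abs=1e-6)

    def test_angles_always_folded(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            geom = stacking_geometry(
                _ring_pair(rng.uniform(3, 9), rng.uniform(0, 180),
                           rng.uniform(0, 180)), "protein", "ligand")
            assert 0.0 <= geom.theta[0] <= 90.0
            assert 0.0 <= geom.phi[0] <= 90.0

    def test_collinear_ring_errors(self):
        atoms = [(f"CR{i+1}", "C", 1, "PHE") for i in range(3)]
        coords = np.array([[[0, 0, 0], [1, 0, 0], [2, 0, 0]]], dtype=float)
        ens = make_simple_ensemble(atoms, coords)
        ens.topology.ring_groups = {"bad": [0, 1, 2]}
        with pytest.raises(ValueError, match="collinear"):
            stacking_geometry(ens, "bad", "bad")


class TestClassification:
    @pytest.mark.parametrize("r,theta,phi,expected", [
        (4.0, 10.0, 10.0, "parallel"),
        (7.0, 85.0, 30.0, "t_stacked"),
        (7.0, 50.0, 30.0, "none"),    # theta between the two bands
        (8.0, 10.0, 10.0, "none"),    # beyond both distance cutoffs
    ])
    def test_band_assignment(self, r, theta, phi, expected):
        geom = StackingGeometry(R=np.array([r]), theta=np.array([theta]),
                                phi=np.array([phi]))
        assert classify_stacking(geom)[0] == expected

    def test_parallel_and_t_mutually_exclusive(self):
        rng = np.random.default_rng(5)
        geom = StackingGeometry(R=rng.uniform(2, 10, 500),
                                theta=rng.uniform(0, 90, 500),
                                phi=rng.uniform(0, 90, 500))
        labels = classify_stacking(geom)
        # labels are single-valued by construction; verify the bands are
        # disjoint by applying both predicates independently
        par = (geom.R < 6.5) & (geom.theta < 60) & (geom.phi < 45)
        tst = (geom.R < 7.5) & (geom.theta > 75) & (geom.phi < 45)
        assert not np.any(par & tst)
        assert np.all(labels[par] == "parallel")
        assert np.all(labels[tst] == "t_stacked")

    def test_figure_preset_differs_from_methods(self):
        geom = StackingGeometry(R=np.array([5.0]), theta=np.array([50.0]),
                                phi=np.array([50.0]))
        assert classify_stacking(geom, "methods")[0] == "none"
        assert classify_stacking(geom, FIGURE_CUTOFFS)[0] == "none"
        geom2 = StackingGeometry(R=np.array([5.0]), theta=np.array([50.0]),
                                 phi=np.array([30.0]))
        assert classify_stacking(geom2, "methods")[0] == "parallel"
        assert classify_stacking(geom2, "figure")[0] == "none"

    def test_overlapping_theta_bands_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            StackingCutoffs(parallel_theta=80.0, t_theta=75.0)


class TestStackingImpliesContact:
    def test_stacked_ligand_is_residue_contact(self, ring_helix):
        ring = next(iter(ring_helix.topology.ring_groups))
        for r, theta in ((4.0, 0.0), (7.0, 90.0)):
            ens = place_ligand(ring_helix, R=r, theta=theta, phi=0.0,
                               target_ring=ring)
            geom = stacking_geometry(ens, ring, "ligand:ring1")
            labels = classify_stacking(geom)
            contacts = residue_contact_matrix(ens)
            ring_res_col = 5  # the ring lives on residue index 5
            assert np.all(contacts[labels != "none", ring_res_col])


class TestStackingFes:
    @staticmethod
    def _isotropic_geometry(n, seed=0):
        """(R, theta) sampled from the geometrically unbiased measure:
        p(R) ~ R^2 on [2, 10], p(theta) ~ sin(theta) folded to [0, 90]."""
        rng = np.random.default_rng(seed)
        u = rng.random(n)
        r = (2.0**3 + u * (10.0**3 - 2.0**3)) ** (1.0 / 3.0)
        theta = np.degrees(np.arccos(rng.random(n)))
        phi = np.degrees(np.arccos(rng.random(n)))
        return StackingGeometry(R=r, theta=theta, phi=phi)

    def test_isotropic_orientations_give_flat_surface(self):
        geom = self._isotropic_geometry(150_000, seed=3)
        surf = stacking_fes(geom, bins_r=12, bins_theta=9)
        f = surf.free_energy[surf.occupied]
        assert f.max() - f.min() < 0.25  # kcal/mol, sampling noise only

    def test_single_configuration_single_bin(self):
        geom = StackingGeometry(R=np.full(10, 4.2), theta=np.full(10, 15.0),
                                phi=np.full(10, 5.0))
        with pytest.warns(UserWarning, match="degenerate"):
            surf = stacking_fes(geom)
        assert surf.occupied.sum() == 1
        assert surf.free_energy[surf.occupied][0] == 0.0
        assert np.all(np.isnan(surf.free_energy[~surf.occupied]))

    def test_two_cluster_minima_at_injected_centers(self):
        rng = np.random.default_rng(8)
        n = 4000
        r = np.concatenate([rng.normal(4.0, 0.15, n), rng.normal(7.0, 0.15, n)])
        theta = np.concatenate([rng.normal(10.0, 2.0, n),
                                np.abs(rng.normal(80.0, 2.0, n))])
        geom = StackingGeometry(R=r, theta=np.clip(theta, 0, 90),
                                phi=np.zeros(2 * n))
        surf = stacking_fes(geom, bins_r=16, bins_theta=18)
        f = np.where(surf.occupied, surf.free_energy, np.inf)
        i, j = np.unravel_index(np.argmin(f), f.shape)
        rc, tc = surf.centers
        # global minimum sits in one injected cluster; the other cluster
        # also hosts a local minimum within its region
        assert min(abs(rc[i] - 4.0), abs(rc[i] - 7.0)) < 0.5
        region = (np.abs(rc[:, None] - (11.0 - rc[i])) < 1.0)
        assert np.isfinite(f[region.repeat(f.shape[1], 1)]).any()


class TestStackingPopulations:
    def test_census_on_bound_system(self, bound_system):
        table, records = stacking_populations(bound_system)
        assert {"parallel_population", "t_stacked_population",
                "stacked_population"} <= set(table.columns)
        assert (table["stacked_population"] + 1e-12
                >= table["parallel_population"]).all()
        assert "any" in records
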