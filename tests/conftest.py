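import numpy as np
import pytest
from hypothesis import settings

from globulebind.ensemble_model import Atom, Ensemble, Residue, Topology
from globulebind.synthetic_data import (
    HelixSpec,
    MixtureSpec,
    build_chain,
    make_binding_ensemble,
    sample_two_state_ensemble,
)

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


def make_simple_ensemble(atoms, coordinates, ligand_residues=(),
                         box_edge=None, annotate=False, annotation=None):
    """Hand-build a small ensemble for geometric unit tests.

    ``atoms`` is a list of (atom_name, element, author_residue_index,
    residue_name) tuples; ``coordinates`` has shape (frames, n_atoms, 3) in
    angstrom; residues whose name is in ``ligand_residues`` become the
    ligand.
    """
    from globulebind.ensemble_model import annotate_topology

    residues, atom_objs, ligand_atoms = [], [], []
    res_key = None
    for name, element, res_author, res_name in atoms:
        if (res_author, res_name) != res_key:
            residues.append(Residue(author_index=res_author, name=res_name,
                                    is_ligand=res_name in ligand_residues))
            res_key = (res_author, res_name)
        ri = len(residues) - 1
        atom_objs.append(Atom(name=name, element=element, residue_index=ri,
                              heavy=element.upper() != "H"))
        if res_name in ligand_residues:
            ligand_atoms.append(len(atom_objs) - 1)
    top = Topology(residues=residues, atoms=atom_objs,
                   ligand_atoms=ligand_atoms)
    coordinates = np.asarray(coordinates, dtype=float)
    if annotate:
        annotate_topology(top, coordinates[0], annotation)
    return Ensemble(topology=top, coordinates=coordinates, box_edge=box_edge)


@pytest.fixture(scope="session")
def ideal_helix():
    """56-residue chain with every residue at ideal helical dihedrals."""
    return build_chain(HelixSpec(n_residues=56))


@pytest.fixture(scope="session")
def extended_chain():
    return build_chain(HelixSpec(n_residues=56, phi=-150.0, psi=150.0))


@pytest.fixture(scope="session")
def ring_helix():
    """Short helix with a hexagonal aromatic ring on residue 5."""
    return build_chain(HelixSpec(n_residues=12, aromatic_residues=(5,),
                                 author_start=1))


@pytest.fixture(scope="session")
def two_state_404():
    """Two-state mixture at the apo helical-globule population (40.4%)."""
    return sample_two_state_ensemble(
        MixtureSpec(p=0.404, n_frames=400, seed=11))


@pytest.fixture(scope="session")
def bound_system():
    """Two-state protein + toy ligand placed bound at a 43% rate."""
    return make_binding_ensemble(p_globule=0.404, bound_rate=0.43,
                                 n_frames=450, seed=23)
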