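"""Core data model: topologies, conformational ensembles, observables, reports.

The in-memory containers are deliberately small: a :class:`Topology` holding
residue/atom identity plus the chemical annotations every interaction
definition needs (aromatic rings, hydrogen-bond donors/acceptors, hydrophobic
atoms, ligand membership), and an :class:`Ensemble` holding frames x atoms x 3
Cartesian coordinates in angstroms together with per-frame weights, the cubic
box edge and the temperature.  File I/O (PDB/GRO topologies; XTC/DCD/
multi-model PDB trajectories) is delegated to mdtraj behind this surface.

Author residue numbering (e.g. 391-446 for the androgen-receptor Tau-5
fragment studied here) is preserved in all outputs; internal indexing is
0-based; ACE/NH2 caps are flagged and excluded from per-residue tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .units import angstrom_to_nm

STANDARD_RESIDUES = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

CAP_RESIDUES = {"ACE", "NH2", "NME", "NMA"}

# Aromatic ring atom names for standard sidechains.  TRP contributes two
# rings (five- and six-membered), reported separately and combined by OR in
# per-residue stacking statistics.
RESIDUE_RINGS = {
    "PHE": {"6ring": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]},
    "TYR": {"6ring": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]},
    "TRP": {
        "5ring": ["CG", "CD1", "NE1", "CE2", "CD2"],
        "6ring": ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"],
    },
    "HIS": {"5ring": ["CG", "ND1", "CD2", "CE1", "NE2"]},
}

ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "CL": 35.45, "P": 30.974, "F": 18.998, "I": 126.904,
}

_TWO_LETTER_ELEMENTS = ("CL", "BR", "NA", "MG", "ZN", "FE", "SE")


def element_from_name(name: str) -> str:
    """Infer an element symbol from a PDB-style atom name."""
    stripped = name.strip().upper()
    lead = stripped.lstrip("0123456789")
    if lead[:2] in _TWO_LETTER_ELEMENTS:
        return lead[0] + lead[1].lower()
    return lead[0]


@dataclass
class Residue:
    author_index: int           # author numbering, e.g. 391..446
    name: str                   # 3-letter code
    code: str = "X"             # 1-letter code
    is_cap: bool = False
    is_ligand: bool = False


@dataclass
class Atom:
    name: str
    element: str
    residue_index: int          # 0-based index into Topology.residues
    heavy: bool = True


@dataclass
class Topology:
    """Residue/atom identity plus interaction annotations."""

    residues: list[Residue]
    atoms: list[Atom]
    ring_groups: dict[str, list[int]] = field(default_factory=dict)
    donors: list[tuple[int, int]] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)
    hydrophobic_atoms: list[int] = field(default_factory=list)
    ligand_atoms: list[int] = field(default_factory=list)
    special_atoms: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- derived views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.heavy for a in self.atoms], dtype=bool)

    @property
    def ligand_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_atoms, dtype=bool)
        mask[list(self.ligand_atoms)] = True
        return mask

    @property
    def protein_atom_indices(self) -> np.ndarray:
        return np.where(~self.ligand_mask)[0]

    def atom_residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    def protein_residue_indices(self) -> list[int]:
        """0-based indices of non-cap, non-ligand residues."""
        return [i for i, r in enumerate(self.residues)
                if not r.is_cap and not r.is_ligand]

    def author_numbers(self) -> list[int]:
        return [self.residues[i].author_index
                for i in self.protein_residue_indices()]

    def select_atoms(self, name: str, residues: list[int] | None = None) -> np.ndarray:
        """Indices of atoms with the given name, optionally restricted to
        0-based residue indices."""
        out = []
        for i, a in enumerate(self.atoms):
            if a.name == name and (residues is None or a.residue_index in residues):
                out.append(i)
        return np.array(out, dtype=int)

    def calpha_indices(self) -> np.ndarray:
        """CA atoms of non-cap protein residues, in residue order."""
        keep = set(self.protein_residue_indices())
        idx = [i for i, a in enumerate(self.atoms)
               if a.name == "CA" and a.residue_index in keep]
        return np.array(idx, dtype=int)

    def validate(self) -> None:
        n = self.n_atoms
        for a in self.atoms:
            if not 0 <= a.residue_index < self.n_residues:
                raise ValueError(f"atom {a.name}: residue index out of range")
        prot = [r.author_index for r in self.residues
                if not r.is_ligand and not r.is_cap]
        if any(b <= a for a, b in zip(prot, prot[1:])):
            raise ValueError("author residue numbering must be strictly increasing")
        lig = set(self.ligand_atoms)
        for name, group in self.ring_groups.items():
            if len(set(group)) < 3:
                raise ValueError(f"ring group {name!r} needs >=3 distinct atoms")
            owners = {self.atoms[i].residue_index for i in group}
            in_lig = {i in lig for i in group}
            if len(owners) > 1 and in_lig != {True}:
                raise ValueError(f"ring group {name!r} spans residues")
        for heavy, hyd in self.donors:
            if self.atoms[hyd].element.upper() != "H":
                raise ValueError("donor hydrogen is not a hydrogen atom")
        for i in lig:
            if not 0 <= i < n:
                raise ValueError("ligand atom index out of range")


@dataclass
class Ensemble:
    """Conformational ensemble: coordinates in angstroms, weights, box, T."""

    topology: Topology
    coordinates: np.ndarray          # (frames, atoms, 3), angstrom
    box_edge: float | None = None    # cubic box edge, nm
    temperature: float = 300.0       # K
    frame_weights: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"atom count mismatch: trajectory has {self.coordinates.shape[1]} "
                f"atoms, topology has {self.topology.n_atoms}")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        if self.frame_weights is None:
            self.frame_weights = np.full(self.n_frames, 1.0 / self.n_frames)
        else:
            w = np.asarray(self.frame_weights, dtype=float)
            if w.shape != (self.n_frames,):
                raise ValueError("frame_weights length must equal frame count")
            if np.any(w < 0):
                raise ValueError("frame_weights must be nonnegative")
            self.frame_weights = w / w.sum()

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class ObservableSeries:
    """A named per-frame scalar series."""

    name: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("ObservableSeries values must be 1-D")

    def __len__(self):
        return len(self.values)


@dataclass
class AnalysisReport:
    """Scalar summaries + per-residue/per-pair tables + provenance."""

    scalars: dict[str, dict] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def add_scalar(self, name: str, value: float, error: float | None = None,
                   units: str = "", block_size: int | None = None) -> None:
        entry = {"value": float(value), "units": units}
        if error is not None:
            entry["error"] = float(error)
            if block_size is not None:
                entry["block_size"] = int(block_size)
        self.scalars[name] = entry

    def write(self, outdir: str | Path) -> None:
        """Write report.json (scalars + provenance) and one CSV per table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = {"scalars": self.scalars, "provenance": self.provenance}
        with open(outdir / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        for name, table in sorted(self.tables.items()):
            table.to_csv(outdir / f"{name}.csv", index=False,
                         float_format="%.10g")


# ---------------------------------------------------------------------------
# chemistry annotation
# ---------------------------------------------------------------------------

def load_ligand_annotation(path: str | Path) -> dict:
    """Read a ligand annotation file (YAML/JSON).

    Keys: ``residue_name``, ``rings`` (name -> atom-name list), ``donors``
    (list of [heavy, hydrogen] name pairs), ``acceptors``, ``hydrophobic``
    (atom-name lists), ``special`` (tag -> atom name).
    """
    with open(path) as fh:
        ann = yaml.safe_load(fh)
    ann.setdefault("rings", {})
    ann.setdefault("donors", [])
    ann.setdefault("acceptors", [])
    ann.setdefault("hydrophobic", [])
    ann.setdefault("special", {})
    return ann


def annotate_topology(top: Topology, coords0: np.ndarray,
                      ligand_annotation: dict | None = None) -> None:
    """Populate ring/donor/acceptor/hydrophobic/special annotations in place.

    Protein annotations come from a built-in residue chemistry table plus
    geometric inference of donor hydrogens (H within 1.25 A of N/O/S in the
    first frame).  Ligand annotations come from the annotation mapping.
    """
    lig = set(top.ligand_atoms)
    res_atoms: dict[int, dict[str, int]] = {}
    for i, a in enumerate(top.atoms):
        res_atoms.setdefault(a.residue_index, {})[a.name] = i

    # rings from the chemistry table
    for ri, res in enumerate(top.residues):
        rings = RESIDUE_RINGS.get(res.name)
        if not rings or res.is_ligand:
            continue
        for tag, names in rings.items():
            idx = [res_atoms[ri].get(n) for n in names]
            if all(i is not None for i in idx):
                top.ring_groups[f"{res.name}{res.author_index}:{tag}"] = idx

    # hydrophobic / acceptors / donors on the protein side
    elements = [a.element.upper() for a in top.atoms]
    for i, a in enumerate(top.atoms):
        if i in lig:
            continue
        if elements[i] == "C":
            top.hydrophobic_atoms.append(i)
        if elements[i] in ("N", "O", "S"):
            top.acceptors.append(i)
    # donor pairs by geometry in the first frame
    hydro = [i for i in range(top.n_atoms) if elements[i] == "H" and i not in lig]
    polar = [i for i in range(top.n_atoms)
             if elements[i] in ("N", "O", "S") and i not in lig]
    if hydro and polar:
        d = np.linalg.norm(coords0[np.array(hydro)][:, None, :]
                           - coords0[np.array(polar)][None, :, :], axis=-1)
        hi, pi = np.where(d < 1.25)
        for h, p in zip(hi, pi):
            top.donors.append((polar[p], hydro[h]))

    # ligand side
    if ligand_annotation is not None and lig:
        lig_res = {top.atoms[i].residue_index for i in lig}
        name_to_idx = {}
        for ri in lig_res:
            name_to_idx.update(res_atoms[ri])
        for tag, names in ligand_annotation["rings"].items():
            top.ring_groups[f"ligand:{tag}"] = [name_to_idx[n] for n in names]
        for heavy, hyd in ligand_annotation["donors"]:
            top.donors.append((name_to_idx[heavy], name_to_idx[hyd]))
        for n in ligand_annotation["acceptors"]:
            top.acceptors.append(name_to_idx[n])
        for n in ligand_annotation["hydrophobic"]:
            top.hydrophobic_atoms.append(name_to_idx[n])
        for tag, n in ligand_annotation["special"].items():
            top.special_atoms[tag] = name_to_idx[n]
    top.validate()


# ---------------------------------------------------------------------------
# I/O via mdtraj
# ---------------------------------------------------------------------------

def _topology_from_mdtraj(mtop, ligand_annotation: dict | None) -> Topology:
    lig_name = (ligand_annotation or {}).get("residue_name")
    residues, atoms, ligand_atoms = [], [], []
    for res in mtop.residues:
        name = res.name.upper()
        is_cap = name in CAP_RESIDUES
        is_lig = False
        if name not in STANDARD_RESIDUES and not is_cap:
            if lig_name is not None and name == lig_name.upper():
                is_lig = True
            else:
                raise ValueError(
                    f"unknown residue {name}{res.resSeq} and no ligand "
                    f"annotation declares it")
        residues.append(Residue(author_index=res.resSeq, name=name,
                                code=STANDARD_RESIDUES.get(name, "X"),
                                is_cap=is_cap, is_ligand=is_lig))
        ri = len(residues) - 1
        for atom in res.atoms:
            elem = atom.element.symbol if atom.element is not None \
                else element_from_name(atom.name)
            atoms.append(Atom(name=atom.name, element=elem, residue_index=ri,
                              heavy=elem.upper() != "H"))
            if is_lig:
                ligand_atoms.append(len(atoms) - 1)
    return Topology(residues=residues, atoms=atoms, ligand_atoms=ligand_atoms)


def load_ensemble(topology_path: str | Path,
                  trajectory_path: str | Path | None = None,
                  box_edge: float | None = None,
                  temperature: float = 300.0,
                  ligand_annotation: str | Path | dict | None = None) -> Ensemble:
    """Load a conformational ensemble from disk.

    Parameters
    ----------
    topology_path : PDB or GRO file defining residues/atoms.
    trajectory_path : XTC/DCD/multi-model PDB with the frames; if omitted the
        topology file's own coordinates are the (possibly multi-model) frames.
    box_edge : cubic box edge in nm (read from the file when absent there).
    ligand_annotation : path to a YAML/JSON annotation file, or the parsed
        mapping, declaring the ligand residue and its chemistry.
    """
    import mdtraj as md

    if isinstance(ligand_annotation, (str, Path)):
        ligand_annotation = load_ligand_annotation(ligand_annotation)

    mtop = md.load_topology(str(topology_path))
    if trajectory_path is None:
        traj = md.load(str(topology_path))
    else:
        suffix = Path(str(trajectory_path)).suffix.lower()
        if suffix in (".pdb", ".gro"):
            traj = md.load(str(trajectory_path))
            if traj.n_atoms != mtop.n_atoms:
                raise ValueError(
                    f"atom count mismatch: trajectory has {traj.n_atoms} "
                    f"atoms, topology has {mtop.n_atoms}")
        else:
            try:
                traj = md.load(str(trajectory_path), top=mtop)
            except ValueError as exc:
                raise ValueError(
                    f"atom count mismatch between trajectory and topology "
                    f"({mtop.n_atoms} topology atoms): {exc}") from exc

    top = _topology_from_mdtraj(mtop, ligand_annotation)
    coords = np.asarray(traj.xyz, dtype=float) * 10.0  # nm -> angstrom
    annotate_topology(top, coords[0], ligand_annotation)
    if box_edge is None and traj.unitcell_lengths is not None:
        box_edge = float(traj.unitcell_lengths[0, 0])
    return Ensemble(topology=top, coordinates=coords, box_edge=box_edge,
                    temperature=temperature)


def to_mdtraj(ensemble: Ensemble):
    """Convert an :class:`Ensemble` to an ``mdtraj.Trajectory``."""
    import mdtraj as md
    from mdtraj.core import element as md_element

    mtop = md.Topology()
    chain_protein = mtop.add_chain()
    chain_ligand = None
    md_residues = []
    for res in ensemble.topology.residues:
        if res.is_ligand:
            if chain_ligand is None:
                chain_ligand = mtop.add_chain()
            chain = chain_ligand
        else:
            chain = chain_protein
        md_residues.append(mtop.add_residue(res.name, chain, resSeq=res.author_index))
    for atom in ensemble.topology.atoms:
        elem = md_element.get_by_symbol(atom.element.capitalize())
        mtop.add_atom(atom.name, elem, md_residues[atom.residue_index])
    xyz = ensemble.coordinates / 10.0  # angstrom -> nm
    traj = md.Trajectory(xyz=xyz.astype(np.float32), topology=mtop)
    if ensemble.box_edge is not None:
        edge = float(ensemble.box_edge)
        traj.unitcell_lengths = np.tile([edge, edge, edge], (ensemble.n_frames, 1))
        traj.unitcell_angles = np.tile([90.0, 90.0, 90.0], (ensemble.n_frames, 1))
    return traj


def save_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write the ensemble to disk (format chosen by extension, e.g. .pdb)."""
    to_mdtraj(ensemble).save(str(path))


# ---------------------------------------------------------------------------
# geometry observables
# ---------------------------------------------------------------------------

def radius_of_gyration(ensemble: Ensemble,
                       selection: np.ndarray | None = None,
                       mass_weighted: bool = False) -> ObservableSeries:
    """Per-frame radius of gyration of an atom selection, in nm.

    The default selection is the protein CA atoms, unweighted.  The
    ``mass_weighted`` flag switches to a mass-weighted R_g over all protein
    heavy atoms (an alternative convention some ensemble summaries use).
    """
    top = ensemble.topology
    if selection is None:
        if mass_weighted:
            selection = np.array([i for i in top.protein_atom_indices
                                  if top.atoms[i].heavy], dtype=int)
        else:
            selection = top.calpha_indices()
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection for radius of gyration")
    xyz = ensemble.coordinates[:, selection, :]
    if mass_weighted:
        m = np.array([ELEMENT_MASSES.get(top.atoms[i].element.upper(), 12.0)
                      for i in selection])
        w = m / m.sum()
    else:
        w = np.full(selection.size, 1.0 / selection.size)
    center = np.einsum("fas,a->fs", xyz, w)
    dev = xyz - center[:, None, :]
    rg2 = np.einsum("fas,fas,a->f", dev, dev, w)
    return ObservableSeries(name="Rg", values=angstrom_to_nm(np.sqrt(rg2)),
                            units="nm")
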