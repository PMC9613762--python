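"""Intermolecular contact statistics, bound-state classification and K_D.

A protein residue is "in contact" with the ligand in a frame when any of its
heavy (non-hydrogen) atoms lies within 6.0 A of any ligand heavy atom; a
frame is "bound" when at least one residue is in contact.  The dissociation
constant follows from the bound/unbound odds and the concentration of a
single molecule in the simulation cell:

    K_D = (P_u / P_b) * (v c0 N_A)^-1

with v the cubic box volume, c0 = 1 mol/L and N_A Avogadro's number.  For
the 7.5 nm box used in the source simulations (v N_A)^-1 = 3.93 mM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble_model import Ensemble, ObservableSeries, radius_of_gyration
from .thermo_stats import blocking
from .units import single_molecule_concentration

DEFAULT_CONTACT_CUTOFF = 6.0  # angstrom, heavy-heavy


@dataclass
class BindingParams:
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    box_edge: float | None = None        # nm
    include_hydrogens: bool = False      # laxer all-protein-atom variant

    def __post_init__(self):
        if self.contact_cutoff <= 0:
            raise ValueError("contact cutoff must be positive")
        if self.box_edge is not None and \
                self.box_edge * 10.0 <= self.contact_cutoff:
            raise ValueError("box edge must exceed the contact cutoff")


@dataclass
class InteractionRecord:
    """Per-frame boolean incidence of a defined interaction."""

    name: str
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    def probability(self, weights: np.ndarray | None = None) -> float:
        if weights is None:
            return float(self.mask.mean())
        w = np.asarray(weights, dtype=float)
        return float((w / w.sum()) @ self.mask)


def _pairwise_within(coords: np.ndarray, idx_a: np.ndarray,
                     idx_b: np.ndarray, cutoff: float,
                     chunk: int = 256) -> np.ndarray:
    """Per-frame any-pair-within-cutoff between two atom sets: (F,) bool."""
    out = np.zeros(coords.shape[0], dtype=bool)
    for f0 in range(0, coords.shape[0], chunk):
        block = coords[f0:f0 + chunk]
        d = np.linalg.norm(block[:, idx_a, None, :] - block[:, None, idx_b, :],
                           axis=-1)
        out[f0:f0 + chunk] = (d < cutoff).any(axis=(1, 2))
    return out


def residue_contact_matrix(ensemble: Ensemble,
                           params: BindingParams | None = None) -> np.ndarray:
    """Frames x residues boolean matrix of ligand heavy-atom contacts.

    Columns follow the non-cap protein residues in author order.  Hydrogens
    are excluded on both sides by default (the ``include_hydrogens`` flag
    relaxes the protein side only).
    """
    params = params or BindingParams()
    top = ensemble.topology
    lig_heavy = np.array([i for i in top.ligand_atoms if top.atoms[i].heavy],
                         dtype=int)
    if lig_heavy.size == 0:
        raise ValueError("ensemble has no ligand heavy atoms")
    res_idx = top.protein_residue_indices()
    atom_res = top.atom_residue_indices()
    lig_set = set(top.ligand_atoms)
    out = np.zeros((ensemble.n_frames, len(res_idx)), dtype=bool)
    for col, ri in enumerate(res_idx):
        atoms = [i for i in np.where(atom_res == ri)[0]
                 if i not in lig_set
                 and (params.include_hydrogens or top.atoms[i].heavy)]
        out[:, col] = _pairwise_within(ensemble.coordinates,
                                       np.array(atoms, dtype=int), lig_heavy,
                                       params.contact_cutoff)
    return out


def per_residue_contact_probabilities(ensemble: Ensemble,
                                      contacts: np.ndarray) -> pd.DataFrame:
    """Weighted per-residue contact probabilities with blocking errors."""
    top = ensemble.topology
    rows = []
    for col, ri in enumerate(top.protein_residue_indices()):
        res = top.residues[ri]
        b = blocking(contacts[:, col].astype(float),
                     weights=ensemble.frame_weights)
        rows.append({"residue": res.author_index, "name": res.name,
                     "probability": b.mean, "se": b.se,
                     "block_size": b.optimal_block_size})
    return pd.DataFrame(rows)


def bound_record(contacts: np.ndarray) -> InteractionRecord:
    return InteractionRecord(name="bound", mask=contacts.any(axis=1))


def bound_fraction(contacts: np.ndarray,
                   weights: np.ndarray | None = None):
    """Bound population P_b (weighted fraction of frames with >=1 residue
    contact) with a blocking error; returns a BlockingResult."""
    if contacts.shape[0] < 1:
        raise ValueError("need at least one frame")
    ind = contacts.any(axis=1).astype(float)
    return blocking(ind, weights=weights)


@dataclass
class KdResult:
    kd: float          # mol/L
    c_box: float       # mol/L, single-molecule box concentration
    p_bound: float


def kd_from_bound_fraction(p_bound: float, box_edge: float) -> KdResult:
    """Dissociation constant from the bound fraction and the box edge (nm)."""
    c_box = single_molecule_concentration(box_edge)
    if p_bound <= 0.0:
        raise ValueError("no binding observed (P_b = 0); K_D is undefined")
    if p_bound >= 1.0:
        warnings.warn("fully bound ensemble (P_b = 1); K_D reported as 0")
        return KdResult(kd=0.0, c_box=c_box, p_bound=1.0)
    kd = (1.0 - p_bound) / p_bound * c_box
    return KdResult(kd=kd, c_box=c_box, p_bound=p_bound)


def pair_simultaneous_contact_map(contacts: np.ndarray,
                                  weights: np.ndarray | None = None) -> np.ndarray:
    """P(residues i and j both contact the ligand in the same frame).

    Symmetric; the diagonal equals the per-residue contact probability; every
    entry is bounded above by the smaller of the two marginals.
    """
    c = contacts.astype(float)
    if weights is None:
        weights = np.full(c.shape[0], 1.0 / c.shape[0])
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    return (c * w[:, None]).T @ c


def conditional_probability(record_a: InteractionRecord,
                            record_b: InteractionRecord,
                            weights: np.ndarray | None = None) -> float:
    """Weighted P(A | B) for two per-frame interaction records."""
    a, b = record_a.mask, record_b.mask
    if len(a) != len(b):
        raise ValueError("interaction records must be aligned")
    if weights is None:
        weights = np.full(len(a), 1.0 / len(a))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    pb = float(w @ b)
    if pb <= 0.0:
        raise ValueError(f"conditioning event {record_b.name!r} has zero probability")
    return float(w @ (a & b)) / pb


def rg_vs_min_contacts(ensemble: Ensemble, contacts: np.ndarray,
                       rg: ObservableSeries | None = None):
    """Mean and variance of R_g over frames with >= k distinct residue
    contacts, for k = 0, 1, 2, ...; strata with no frames are omitted.

    Returns (table, unbound_mean_rg); the k = 0 row is the global mean.
    """
    if rg is None:
        rg = radius_of_gyration(ensemble)
    vals = rg.values
    w = ensemble.frame_weights
    counts = contacts.sum(axis=1)
    rows = []
    for k in range(0, int(counts.max()) + 1 if counts.size else 1):
        sel = counts >= k
        if not sel.any():
            continue
        ws = w[sel] / w[sel].sum()
        mean = float(ws @ vals[sel])
        var = float(ws @ (vals[sel] - mean) ** 2)
        rows.append({"min_contacts": k, "n_frames": int(sel.sum()),
                     "mean_rg_nm": mean, "var_rg_nm2": var})
    unbound = counts == 0
    if unbound.any():
        wu = w[unbound] / w[unbound].sum()
        unbound_mean = float(wu @ vals[unbound])
    else:
        unbound_mean = np.nan
    return pd.DataFrame(rows), unbound_mean


def proximity_fraction(ensemble: Ensemble, atom_a: str | int,
                       atom_b: str | int, cutoff: float,
                       bins: int = 50):
    """Weighted fraction of frames with distance(a, b) < cutoff (angstrom),
    plus the full distance histogram.

    Atoms may be given as special-atom tags (e.g. "chlorohydrin_Cl",
    "CYS404_SG") or raw indices.  Returns (BlockingResult for the fraction,
    distance series (A), histogram DataFrame).
    """
    top = ensemble.topology
    idx = []
    for atom in (atom_a, atom_b):
        if isinstance(atom, str):
            if atom not in top.special_atoms:
                raise KeyError(f"no special atom tagged {atom!r}")
            idx.append(top.special_atoms[atom])
        else:
            idx.append(int(atom))
    d = np.linalg.norm(ensemble.coordinates[:, idx[0], :]
                       - ensemble.coordinates[:, idx[1], :], axis=-1)
    frac = blocking((d < cutoff).astype(float), weights=ensemble.frame_weights)
    hist, edges = np.histogram(d, bins=bins, weights=ensemble.frame_weights)
    table = pd.DataFrame({"distance_A": 0.5 * (edges[1:] + edges[:-1]),
                          "probability": hist / hist.sum()})
    return frac, d, table
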