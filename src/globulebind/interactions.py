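"""Typed protein-ligand interaction censuses.

Three interaction classes, each with the geometric definition used
throughout the analysis:

* hydrophobic contact — any protein carbon within 4.0 A of a ligand carbon
  or chlorine atom;
* hydrogen bond — donor-hydrogen ... acceptor distance < 3.5 A and
  donor-H-acceptor angle > 150 deg, donors being N/O/S atoms with an
  attached hydrogen and acceptors any N/O/S heavy atom, in both directions
  (protein donor and ligand donor);
* aromatic stacking — classified from the ring-pair geometry (R, theta,
  phi): center-center distance, interplane normal angle and the angle
  between the protein normal and the center-connecting vector, with both
  angles folded into [0, 90] via absolute dot products.  Parallel (face-to-
  face) and T-shaped bands are mutually exclusive by construction since
  their theta ranges are disjoint.

Orientation free-energy surfaces over (R, theta) are Jacobian-normalized by
R^2 sin(theta) so geometrically unbiased configurations give a flat profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding import InteractionRecord, _pairwise_within
from .ensemble_model import Ensemble
from .thermo_stats import FreeEnergySurface, _fes_from_hist, \
    _histogram_nd, blocking

HYDROPHOBIC_CUTOFF = 4.0       # angstrom, C-C / C-Cl
HBOND_DISTANCE_CUTOFF = 3.5    # angstrom, H...acceptor
HBOND_ANGLE_CUTOFF = 150.0     # degrees, donor-H-acceptor


@dataclass
class StackingGeometry:
    """Per-frame ring-pair geometry; angles already folded into [0, 90]."""

    R: np.ndarray        # ring-center distance, angstrom
    theta: np.ndarray    # interplane normal angle, deg
    phi: np.ndarray      # protein-normal vs center-vector angle, deg

    def __post_init__(self):
        for arr in (self.R, self.theta, self.phi):
            if np.asarray(arr).shape != np.asarray(self.R).shape:
                raise ValueError("R, theta, phi must be aligned")


@dataclass
class StackingCutoffs:
    parallel_r: float = 6.5
    parallel_theta: float = 60.0
    parallel_phi: float = 45.0
    t_r: float = 7.5
    t_theta: float = 75.0
    t_phi: float = 45.0

    def __post_init__(self):
        if self.parallel_theta > self.t_theta:
            raise ValueError("parallel and T theta bands must be disjoint")


#: Cutoffs as stated in the analysis conventions (default).
METHODS_CUTOFFS = StackingCutoffs()
#: Alternative preset with the tighter parallel theta / looser phi bands.
FIGURE_CUTOFFS = StackingCutoffs(parallel_theta=45.0, parallel_phi=60.0,
                                 t_phi=60.0)

STACKING_PRESETS = {"methods": METHODS_CUTOFFS, "figure": FIGURE_CUTOFFS}


# ---------------------------------------------------------------------------
# hydrophobic contacts
# ---------------------------------------------------------------------------

def hydrophobic_contacts(ensemble: Ensemble,
                         cutoff: float = HYDROPHOBIC_CUTOFF):
    """Per-residue hydrophobic contact populations and interaction records.

    Contact: any protein carbon within ``cutoff`` of any ligand carbon or
    chlorine (the annotated hydrophobic atom sets).  Returns (table,
    records) where records maps author residue number -> InteractionRecord
    and includes an "any" record over all residues.
    """
    top = ensemble.topology
    lig_set = set(top.ligand_atoms)
    lig_hydro = np.array([i for i in top.hydrophobic_atoms if i in lig_set],
                         dtype=int)
    if lig_hydro.size == 0:
        raise ValueError("no ligand hydrophobic atoms annotated")
    atom_res = top.atom_residue_indices()
    records, rows = {}, []
    any_mask = np.zeros(ensemble.n_frames, dtype=bool)
    for ri in top.protein_residue_indices():
        res = top.residues[ri]
        atoms = np.array([i for i in top.hydrophobic_atoms
                          if i not in lig_set and atom_res[i] == ri],
                         dtype=int)
        if atoms.size == 0:
            mask = np.zeros(ensemble.n_frames, dtype=bool)
        else:
            mask = _pairwise_within(ensemble.coordinates, atoms, lig_hydro,
                                    cutoff)
        rec = InteractionRecord(name=f"hydrophobic:{res.name}{res.author_index}",
                                mask=mask)
        records[res.author_index] = rec
        any_mask |= mask
        b = blocking(mask.astype(float), weights=ensemble.frame_weights)
        rows.append({"residue": res.author_index, "name": res.name,
                     "population": b.mean, "se": b.se,
                     "block_size": b.optimal_block_size})
    records["any"] = InteractionRecord(name="hydrophobic:any", mask=any_mask)
    return pd.DataFrame(rows), records


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _hbond_mask(coords: np.ndarray, donor: tuple[int, int], acceptor: int,
                dist_cutoff: float, angle_cutoff: float) -> np.ndarray:
    d_idx, h_idx = donor
    h = coords[:, h_idx, :]
    a = coords[:, acceptor, :]
    d = coords[:, d_idx, :]
    ha = np.linalg.norm(a - h, axis=-1)
    v1 = d - h
    v2 = a - h
    cosang = np.einsum("fi,fi->f", v1, v2) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return (ha < dist_cutoff) & (angle > angle_cutoff)


def hydrogen_bonds(ensemble: Ensemble,
                   dist_cutoff: float = HBOND_DISTANCE_CUTOFF,
                   angle_cutoff: float = HBOND_ANGLE_CUTOFF):
    """Intermolecular hydrogen bonds in both donor directions.

    Returns (per_residue_table, per_pair_table, records) where records maps
    author residue number -> InteractionRecord of any hydrogen bond
    involving that residue, plus an "any" record.
    """
    top = ensemble.topology
    lig_set = set(top.ligand_atoms)
    prot_donors = [d for d in top.donors if d[0] not in lig_set]
    lig_donors = [d for d in top.donors if d[0] in lig_set]
    prot_acceptors = [a for a in top.acceptors if a not in lig_set]
    lig_acceptors = [a for a in top.acceptors if a in lig_set]
    for d_idx, h_idx in top.donors:
        if h_idx >= ensemble.n_atoms:
            raise ValueError("donor hydrogen lacks coordinates")

    atom_res = top.atom_residue_indices()
    pair_rows = []
    res_masks: dict[int, np.ndarray] = {
        top.residues[ri].author_index: np.zeros(ensemble.n_frames, dtype=bool)
        for ri in top.protein_residue_indices()}
    any_mask = np.zeros(ensemble.n_frames, dtype=bool)

    def scan(donors, acceptors, direction):
        nonlocal any_mask
        for d_idx, h_idx in donors:
            for acc in acceptors:
                if acc == d_idx:
                    continue
                mask = _hbond_mask(ensemble.coordinates, (d_idx, h_idx), acc,
                                   dist_cutoff, angle_cutoff)
                if not mask.any():
                    continue
                prot_atom = d_idx if direction == "protein-donor" else acc
                res = top.residues[atom_res[prot_atom]]
                if res.is_cap or res.is_ligand:
                    continue
                b = blocking(mask.astype(float),
                             weights=ensemble.frame_weights)
                pair_rows.append({
                    "direction": direction,
                    "residue": res.author_index, "res_name": res.name,
                    "donor_atom": top.atoms[d_idx].name,
                    "acceptor_atom": top.atoms[acc].name,
                    "population": b.mean, "se": b.se,
                    "block_size": b.optimal_block_size})
                res_masks[res.author_index] |= mask
                any_mask |= mask

    scan(prot_donors, lig_acceptors, "protein-donor")
    scan(lig_donors, prot_acceptors, "ligand-donor")

    res_rows = []
    records = {}
    for ri in top.protein_residue_indices():
        res = top.residues[ri]
        mask = res_masks[res.author_index]
        records[res.author_index] = InteractionRecord(
            name=f"hbond:{res.name}{res.author_index}", mask=mask)
        b = blocking(mask.astype(float), weights=ensemble.frame_weights)
        res_rows.append({"residue": res.author_index, "name": res.name,
                         "population": b.mean, "se": b.se,
                         "block_size": b.optimal_block_size})
    records["any"] = InteractionRecord(name="hbond:any", mask=any_mask)
    return pd.DataFrame(res_rows), pd.DataFrame(pair_rows), records


# ---------------------------------------------------------------------------
# aromatic stacking
# ---------------------------------------------------------------------------

def _ring_centers_normals(coords: np.ndarray, ring: list[int]):
    """Least-squares ring plane per frame: centers (F,3), unit normals (F,3).

    A least-squares plane is robust to slight ring non-planarity; degenerate
    (collinear) ring atoms raise an error.
    """
    pts = coords[:, ring, :]
    centers = pts.mean(axis=1)
    dev = pts - centers[:, None, :]
    _, s, vt = np.linalg.svd(dev)
    if np.any(s[:, 1] < 1e-8):
        raise ValueError("collinear ring atoms; ring plane is undefined")
    normals = vt[:, 2, :]
    return centers, normals / np.linalg.norm(normals, axis=-1, keepdims=True)


def stacking_geometry(ensemble: Ensemble, protein_ring: str,
                      ligand_ring: str) -> StackingGeometry:
    """Per-frame (R, theta, phi) between two annotated rings.

    theta = arccos|n_p . n_l|, phi = arccos|n_p . R_hat|; both therefore in
    [0, 90] degrees.
    """
    top = ensemble.topology
    cp, np_ = _ring_centers_normals(ensemble.coordinates,
                                    top.ring_groups[protein_ring])
    cl, nl = _ring_centers_normals(ensemble.coordinates,
                                   top.ring_groups[ligand_ring])
    vec = cl - cp
    r = np.linalg.norm(vec, axis=-1)
    r_hat = vec / r[:, None]
    theta = np.degrees(np.arccos(np.clip(
        np.abs(np.einsum("fi,fi->f", np_, nl)), 0.0, 1.0)))
    phi = np.degrees(np.arccos(np.clip(
        np.abs(np.einsum("fi,fi->f", np_, r_hat)), 0.0, 1.0)))
    return StackingGeometry(R=r, theta=theta, phi=phi)


def classify_stacking(geometry: StackingGeometry,
                      cutoffs: StackingCutoffs | str = "methods") -> np.ndarray:
    """Per-frame label array: "parallel", "t_stacked" or "none"."""
    if isinstance(cutoffs, str):
        cutoffs = STACKING_PRESETS[cutoffs]
    labels = np.full(len(geometry.R), "none", dtype=object)
    par = ((geometry.R < cutoffs.parallel_r)
           & (geometry.theta < cutoffs.parallel_theta)
           & (geometry.phi < cutoffs.parallel_phi))
    tst = ((geometry.R < cutoffs.t_r)
           & (geometry.theta > cutoffs.t_theta)
           & (geometry.phi < cutoffs.t_phi))
    labels[par] = "parallel"
    labels[tst] = "t_stacked"
    return labels.astype(str)


def stacking_populations(ensemble: Ensemble,
                         cutoffs: StackingCutoffs | str = "methods"):
    """Stacking census over every protein ring x ligand ring pair.

    Returns (table, records): one table row per ring pair with parallel/T/
    either populations and blocking errors; records maps author residue
    number -> InteractionRecord of any stacking by that residue's rings
    (rings of one residue combined by OR), plus an "any" record.
    """
    top = ensemble.topology
    lig_set = set(top.ligand_atoms)
    prot_rings = {k: v for k, v in top.ring_groups.items()
                  if not set(v) <= lig_set}
    lig_rings = {k: v for k, v in top.ring_groups.items()
                 if set(v) <= lig_set}
    if not lig_rings:
        raise ValueError("no ligand rings annotated")
    atom_res = top.atom_residue_indices()
    rows = []
    res_masks: dict[int, np.ndarray] = {}
    any_mask = np.zeros(ensemble.n_frames, dtype=bool)
    for pname, pring in prot_rings.items():
        author = top.residues[atom_res[pring[0]]].author_index
        for lname in lig_rings:
            geom = stacking_geometry(ensemble, pname, lname)
            labels = classify_stacking(geom, cutoffs)
            either = labels != "none"
            row = {"protein_ring": pname, "ligand_ring": lname,
                   "residue": author}
            for kind, mask in (("parallel", labels == "parallel"),
                               ("t_stacked", labels == "t_stacked"),
                               ("stacked", either)):
                b = blocking(mask.astype(float),
                             weights=ensemble.frame_weights)
                row[f"{kind}_population"] = b.mean
                row[f"{kind}_se"] = b.se
            rows.append(row)
            res_masks.setdefault(author,
                                 np.zeros(ensemble.n_frames, dtype=bool))
            res_masks[author] |= either
            any_mask |= either
    records = {author: InteractionRecord(name=f"stacking:{author}", mask=m)
               for author, m in res_masks.items()}
    records["any"] = InteractionRecord(name="stacking:any", mask=any_mask)
    return pd.DataFrame(rows), records


def stacking_fes(geometry: StackingGeometry,
                 bins_r=24, bins_theta=18,
                 r_range: tuple[float, float] = (2.0, 10.0),
                 temperature: float = 300.0,
                 weights: np.ndarray | None = None) -> FreeEnergySurface:
    """Jacobian-normalized free-energy surface over (R, theta).

    The weighted (R, theta) histogram is divided by R^2 sin(theta) at the
    bin centers before taking F = -k_B T ln, so an isotropic, uniform-in-
    volume reference is flat.  Empty bins are undefined (NaN), not zero.
    """
    n = len(geometry.R)
    w = np.full(n, 1.0 / n) if weights is None else \
        np.asarray(weights, dtype=float)
    edges_spec = [np.linspace(r_range[0], r_range[1], bins_r + 1)
                  if np.isscalar(bins_r) else np.asarray(bins_r),
                  np.linspace(0.0, 90.0, bins_theta + 1)
                  if np.isscalar(bins_theta) else np.asarray(bins_theta)]
    hist, edges = _histogram_nd([geometry.R, geometry.theta], edges_spec, w)
    if (hist > 0).sum() <= 1:
        import warnings as _w
        _w.warn("all stacking geometries fall in one bin; "
                "the surface is degenerate")
    rc = 0.5 * (edges[0][1:] + edges[0][:-1])
    tc = 0.5 * (edges[1][1:] + edges[1][:-1])
    jac = np.outer(rc**2, np.sin(np.deg2rad(tc)))
    norm = hist / jac
    f, occ = _fes_from_hist(norm, temperature)
    # block errors on the Jacobian-normalized surface
    n_frames = len(geometry.R)
    bounds = np.linspace(0, n_frames, 6).astype(int)
    per_block = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        h, _ = _histogram_nd([geometry.R[b0:b1], geometry.theta[b0:b1]],
                             edges, w[b0:b1])
        fb, ob = _fes_from_hist(h / jac, temperature)
        per_block.append(np.where(ob, fb, np.nan))
    stack = np.stack(per_block)
    counts = np.sum(~np.isnan(stack), axis=0)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(stack, axis=0, ddof=1)
    se = sd / np.sqrt(np.maximum(counts, 1))
    se[counts < 2] = np.nan
    return FreeEnergySurface(edges=edges, free_energy=f, se=se, occupied=occ,
                             temperature=temperature,
                             axis_names=["R_A", "theta_deg"])
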