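"""Synthetic ensemble generators with known ground truth.

Everything the analysis operators consume can be generated here: ideal
helices and coils built by internal-coordinate (NeRF-style) chain extension,
two-state helical-globule/coil mixtures with retained state labels, a rigid
two-ring toy ligand placed at prescribed stacking geometries, autocorrelated
AR(1) scalar series for blocking tests, and reweighting test sets with a
known generating weight vector.

The generators emulate the statistical structure of the real study system (a
56-residue disordered chain whose collapsed state is partially helical and
compact) without any physical energetics: dihedral-space sampling only, no
sterics, no solvent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ensemble_model import (
    Atom,
    Ensemble,
    ObservableSeries,
    Residue,
    Topology,
    annotate_topology,
)

# Standard backbone internal geometry (angstrom / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5

#: Ideal alpha-helix backbone dihedrals (degrees).
HELIX_PHI = -57.0
HELIX_PSI = -47.0

# Turn dihedrals used between helical segments of the synthetic globule
# state; a three-residue extended kink that folds the three helical segments
# back on themselves into a compact antiparallel bundle.
TURN_PHI = 10.0
TURN_PSI = 180.0
TURN_LENGTH = 3


def _extend(a: np.ndarray, b: np.ndarray, c: np.ndarray,
            bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given A, B, C with |CD|, angle(BCD) and torsion(ABCD)."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(ang),
                               np.sin(ang) * np.cos(tor),
                               np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class HelixSpec:
    """Backbone build specification: one (phi, psi, omega) triple per residue.

    Scalars broadcast to all residues.  Defaults build an ideal alpha helix.
    """

    n_residues: int = 56
    phi: float | np.ndarray = HELIX_PHI
    psi: float | np.ndarray = HELIX_PSI
    omega: float | np.ndarray = 180.0
    residue_name: str = "ALA"
    author_start: int = 391
    aromatic_residues: tuple[int, ...] = ()   # 0-based residues given a ring

    def dihedral_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = self.n_residues
        phi = np.broadcast_to(np.asarray(self.phi, dtype=float), (n,)).copy()
        psi = np.broadcast_to(np.asarray(self.psi, dtype=float), (n,)).copy()
        omg = np.broadcast_to(np.asarray(self.omega, dtype=float), (n,)).copy()
        return phi, psi, omg


def _build_backbone(phi: np.ndarray, psi: np.ndarray,
                    omega: np.ndarray) -> np.ndarray:
    """Coordinates (n_residues, 4, 3) for N, CA, C, O by chain extension."""
    n = len(phi)
    xyz = np.zeros((n, 4, 3))
    # first residue: N at origin, CA on x, C in the xy plane
    xyz[0, 0] = (0.0, 0.0, 0.0)
    xyz[0, 1] = (BOND_N_CA, 0.0, 0.0)
    ang = np.deg2rad(180.0 - ANGLE_N_CA_C)
    xyz[0, 2] = xyz[0, 1] + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        xyz[i, 0] = _extend(xyz[i - 1, 0], xyz[i - 1, 1], xyz[i - 1, 2],
                            BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        xyz[i, 1] = _extend(xyz[i - 1, 1], xyz[i - 1, 2], xyz[i, 0],
                            BOND_N_CA, ANGLE_C_N_CA, omega[i - 1])
        xyz[i, 2] = _extend(xyz[i - 1, 2], xyz[i, 0], xyz[i, 1],
                            BOND_CA_C, ANGLE_N_CA_C, phi[i])
    # carbonyl oxygens: anti to the next amide nitrogen (trans peptide)
    for i in range(n):
        xyz[i, 3] = _extend(xyz[i, 0], xyz[i, 1], xyz[i, 2],
                            BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0)
    return xyz


_RING_RADIUS = 1.39  # aromatic C-C ring radius, angstrom


def _hexagon(center: np.ndarray, normal: np.ndarray,
             reference: np.ndarray) -> np.ndarray:
    """Six ring-atom coordinates in the plane through center with normal."""
    normal = normal / np.linalg.norm(normal)
    e1 = reference - np.dot(reference, normal) * normal
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    angles = np.deg2rad(np.arange(6) * 60.0)
    return center + _RING_RADIUS * (np.outer(np.cos(angles), e1)
                                    + np.outer(np.sin(angles), e2))


def build_chain(spec: HelixSpec) -> Ensemble:
    """Build a one-frame backbone-only (N/CA/C/O) chain from dihedrals.

    With every residue at (phi, psi) = (-57, -47) the result is an ideal
    alpha helix (rise ~1.5 A/residue, ~3.6 residues/turn).  Deterministic:
    repeated calls are bit-identical.
    """
    phi, psi, omega = spec.dihedral_arrays()
    bb = _build_backbone(phi, psi, omega)
    residues, atoms, coords = [], [], []
    ring_registry = {}
    for i in range(spec.n_residues):
        residues.append(Residue(author_index=spec.author_start + i,
                                name=spec.residue_name, code="A"))
        for name, k in (("N", 0), ("CA", 1), ("C", 2), ("O", 3)):
            atoms.append(Atom(name=name, element=name[0], residue_index=i))
            coords.append(bb[i, k])
        if i in spec.aromatic_residues:
            # rigid hexagonal ring standing in for an aromatic sidechain,
            # hung off CA in the local backbone frame
            n_vec, ca, c_vec = bb[i, 0], bb[i, 1], bb[i, 2]
            out = ca - 0.5 * (n_vec + c_vec)
            out = out / np.linalg.norm(out)
            center = ca + 2.4 * out
            plane_normal = np.cross(c_vec - n_vec, out)
            ring = _hexagon(center, plane_normal, out)
            start = len(atoms)
            for k in range(6):
                atoms.append(Atom(name=f"CR{k + 1}", element="C",
                                  residue_index=i))
                coords.append(ring[k])
            ring_registry[
                f"{spec.residue_name}{spec.author_start + i}:ring"] = list(
                    range(start, start + 6))
    top = Topology(residues=residues, atoms=atoms)
    coords = np.asarray(coords)[None, :, :]
    annotate_topology(top, coords[0])
    top.ring_groups.update(ring_registry)
    return Ensemble(topology=top, coordinates=coords)


# ---------------------------------------------------------------------------
# two-state helical-globule / coil mixture
# ---------------------------------------------------------------------------

@dataclass
class MixtureSpec:
    """Two-state ensemble: helical-globule fraction p, the rest random coil."""

    p: float = 0.4
    n_frames: int = 1000
    seed: int = 0
    n_residues: int = 56
    helix_noise_deg: float = 7.0      # dihedral jitter inside helical runs
    turn_noise_deg: float = 7.0
    coil_noise_deg: float = 18.0
    author_start: int = 391
    aromatic_residues: tuple[int, ...] = ()

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("mixture fraction p must be in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


# coil basins: (phi, psi, weight) for PPII, beta and alpha_R
_COIL_BASINS = np.array([[-75.0, 145.0], [-120.0, 130.0], [-60.0, -45.0]])
_COIL_PROBS = np.array([0.40, 0.35, 0.25])


def _globule_dihedrals(n_res: int, rng: np.random.Generator,
                       helix_noise: float, turn_noise: float):
    """Helix-turn-helix-turn-helix dihedral pattern that folds back on
    itself into a compact, highly helical bundle."""
    seg = n_res // 3
    phi = np.full(n_res, HELIX_PHI)
    psi = np.full(n_res, HELIX_PSI)
    noise = np.full(n_res, helix_noise)
    for t0 in (seg - 2, 2 * seg - 2):
        phi[t0:t0 + TURN_LENGTH] = TURN_PHI
        psi[t0:t0 + TURN_LENGTH] = TURN_PSI
        noise[t0:t0 + TURN_LENGTH] = turn_noise
    phi = phi + rng.normal(0.0, noise)
    psi = psi + rng.normal(0.0, noise)
    return phi, psi


def _coil_dihedrals(n_res: int, rng: np.random.Generator, noise: float):
    basins = rng.choice(len(_COIL_BASINS), size=n_res, p=_COIL_PROBS)
    phi = _COIL_BASINS[basins, 0] + rng.normal(0.0, noise, n_res)
    psi = _COIL_BASINS[basins, 1] + rng.normal(0.0, noise, n_res)
    return phi, psi


def sample_two_state_ensemble(spec: MixtureSpec) -> Ensemble:
    """Draw frames from a helical-globule state (high Sa, low R_g) and a
    coil state with mixing fraction ``p``.

    The generating state labels (1 = globule, 0 = coil) are retained on the
    returned ensemble as ``state_labels`` for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    labels = (rng.random(spec.n_frames) < spec.p).astype(int)
    frames = []
    template = None
    for lab in labels:
        if lab == 1:
            phi, psi = _globule_dihedrals(spec.n_residues, rng,
                                          spec.helix_noise_deg,
                                          spec.turn_noise_deg)
        else:
            phi, psi = _coil_dihedrals(spec.n_residues, rng,
                                       spec.coil_noise_deg)
        chain = build_chain(HelixSpec(n_residues=spec.n_residues, phi=phi,
                                      psi=psi,
                                      author_start=spec.author_start,
                                      aromatic_residues=spec.aromatic_residues))
        if template is None:
            template = chain
        frames.append(chain.coordinates[0])
    ensemble = Ensemble(topology=template.topology,
                        coordinates=np.asarray(frames))
    ensemble.state_labels = labels
    return ensemble


# ---------------------------------------------------------------------------
# toy ligand
# ---------------------------------------------------------------------------

def _ligand_template() -> tuple[list[tuple[str, str]], np.ndarray]:
    """Rigid two-ring toy ligand: biphenyl-like core, one hydroxyl, one
    chlorine.  Ring 1 (C1-C6) is centered at the origin in the xy plane."""
    names = [(f"C{i + 1}", "C") for i in range(6)]
    ring1 = _hexagon(np.zeros(3), np.array([0.0, 0.0, 1.0]),
                     np.array([1.0, 0.0, 0.0]))
    ring2_center = np.array([2 * _RING_RADIUS + 1.5, 0.0, 0.0])
    ring2 = _hexagon(ring2_center, np.array([0.0, 0.0, 1.0]),
                     np.array([1.0, 0.0, 0.0]))
    names += [(f"C{i + 7}", "C") for i in range(6)]
    o_pos = ring2_center + np.array([_RING_RADIUS + 1.36, 0.0, 0.0])
    h_pos = o_pos + np.array([0.64, 0.72, 0.0])
    cl_pos = np.array([-_RING_RADIUS - 1.72, 0.0, 0.0])
    names += [("O1", "O"), ("HO1", "H"), ("CL1", "Cl")]
    coords = np.vstack([ring1, ring2, o_pos, h_pos, cl_pos])
    return names, coords


TOY_LIGAND_ANNOTATION = {
    "residue_name": "LIG",
    "rings": {"ring1": [f"C{i + 1}" for i in range(6)],
              "ring2": [f"C{i + 7}" for i in range(6)]},
    "donors": [["O1", "HO1"]],
    "acceptors": ["O1"],
    "hydrophobic": [f"C{i + 1}" for i in range(12)] + ["CL1"],
    "special": {"chlorohydrin_Cl": "CL1", "hydroxyl_O": "O1"},
}


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _ring_frame(coords: np.ndarray, ring: list[int]):
    pts = coords[ring]
    center = pts.mean(axis=0)
    dev = pts - center
    _, _, vt = np.linalg.svd(dev)
    return center, vt[2] / np.linalg.norm(vt[2])


def place_ligand(ensemble: Ensemble,
                 R: float | np.ndarray,
                 theta: float | np.ndarray = 0.0,
                 phi: float | np.ndarray = 0.0,
                 target_ring: str | None = None,
                 target_atom: str | int | None = None,
                 clash_tolerance: float = 1.0,
                 box_edge: float | None = None) -> Ensemble:
    """Attach the rigid toy ligand at a prescribed stacking geometry.

    The first ligand ring center is placed at distance ``R`` (angstrom) from
    the target ring center (or tagged atom), with interplane normal angle
    ``theta`` and center-vector angle ``phi`` (degrees).  R/theta/phi may be
    per-frame arrays, which is how bound/unbound mixtures are generated.
    Frames where the placement clashes with the protein (any heavy-heavy
    pair closer than ``clash_tolerance`` angstrom) are skipped with a
    warning.
    """
    top = ensemble.topology
    if target_ring is not None:
        ring = top.ring_groups[target_ring]
        anchor = ("ring", ring)
    elif target_atom is not None:
        if isinstance(target_atom, str):
            target_atom = top.special_atoms[target_atom]
        anchor = ("atom", int(target_atom))
    else:
        raise ValueError("a target ring or atom is required")

    n = ensemble.n_frames
    R = np.broadcast_to(np.asarray(R, dtype=float), (n,))
    theta = np.broadcast_to(np.asarray(theta, dtype=float), (n,))
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (n,))

    lig_names, lig_template = _ligand_template()
    lig_heavy = np.array([e.upper() != "H" for _, e in lig_names])
    prot_heavy = np.where(top.heavy_mask)[0]

    new_frames, kept = [], []
    for f in range(ensemble.n_frames):
        coords = ensemble.coordinates[f]
        if anchor[0] == "ring":
            center, normal = _ring_frame(coords, anchor[1])
        else:
            center = coords[anchor[1]]
            normal = np.array([0.0, 0.0, 1.0])
        base_perp = np.cross(normal, [1.0, 0.0, 0.0])
        if np.linalg.norm(base_perp) < 1e-8:
            base_perp = np.cross(normal, [0.0, 1.0, 0.0])
        base_perp = base_perp / np.linalg.norm(base_perp)
        # (R, theta, phi) leave the azimuth about the target normal free, so
        # clashes are first resolved by scanning azimuthal positions
        placed = None
        for azimuth in range(0, 360, 30):
            perp = _rotation_about(normal, float(azimuth)) @ base_perp
            r_hat = _rotation_about(perp, phi[f]) @ normal
            lig_normal = _rotation_about(perp, theta[f]) @ normal
            lig_center = center + R[f] * r_hat
            # map the template (ring1 in xy plane, normal +z) onto lig_normal
            e1 = perp - np.dot(perp, lig_normal) * lig_normal
            e1 = e1 / np.linalg.norm(e1)
            e2 = np.cross(lig_normal, e1)
            rot = np.column_stack([e1, e2, lig_normal])
            lig_xyz = lig_template @ rot.T + lig_center
            d = np.linalg.norm(coords[prot_heavy][:, None, :]
                               - lig_xyz[lig_heavy][None, :, :], axis=-1)
            if d.min() >= clash_tolerance:
                placed = lig_xyz
                break
        if placed is None:
            warnings.warn(f"frame {f}: infeasible ligand geometry "
                          f"(clash at every azimuth); frame skipped")
            continue
        new_frames.append(np.vstack([coords, placed]))
        kept.append(f)

    residues = [Residue(r.author_index, r.name, r.code, r.is_cap, r.is_ligand)
                for r in top.residues]
    lig_res_index = len(residues)
    residues.append(Residue(author_index=residues[-1].author_index + 1,
                            name="LIG", is_ligand=True))
    atoms = [Atom(a.name, a.element, a.residue_index, a.heavy)
             for a in top.atoms]
    n_prot = len(atoms)
    for name, elem in lig_names:
        atoms.append(Atom(name=name, element=elem,
                          residue_index=lig_res_index,
                          heavy=elem.upper() != "H"))
    new_top = Topology(residues=residues, atoms=atoms,
                       ligand_atoms=list(range(n_prot, len(atoms))))
    coords = np.asarray(new_frames)
    annotate_topology(new_top, coords[0], TOY_LIGAND_ANNOTATION)
    new_top.ring_groups.update(
        {k: list(v) for k, v in top.ring_groups.items()})
    out = Ensemble(topology=new_top, coordinates=coords,
                   box_edge=box_edge if box_edge is not None else ensemble.box_edge,
                   temperature=ensemble.temperature)
    out.kept_frames = np.array(kept, dtype=int)
    if hasattr(ensemble, "state_labels"):
        out.state_labels = np.asarray(ensemble.state_labels)[out.kept_frames]
    return out


def make_binding_ensemble(p_globule: float = 0.4, bound_rate: float = 0.5,
                          n_frames: int = 400, seed: int = 0,
                          near_r: float = 4.5, far_r: float = 60.0,
                          box_edge: float = 7.5) -> Ensemble:
    """Two-state protein ensemble with the toy ligand placed near (in
    contact) or far (out of contact) at a prescribed Bernoulli rate.

    The returned ensemble carries ``state_labels`` (globule/coil) and
    ``placed_bound`` (the generating bound indicator) for recovery tests.
    """
    spec = MixtureSpec(p=p_globule, n_frames=n_frames, seed=seed,
                       aromatic_residues=(6, 42))
    protein = sample_two_state_ensemble(spec)
    rng = np.random.default_rng(seed + 1)
    bound = rng.random(n_frames) < bound_rate
    ring = next(iter(protein.topology.ring_groups))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = place_ligand(protein, R=np.where(bound, near_r, far_r),
                           target_ring=ring, box_edge=box_edge)
    out.placed_bound = bound[out.kept_frames]
    return out


# ---------------------------------------------------------------------------
# scalar series and reweighting test sets
# ---------------------------------------------------------------------------

def ar1_series(n: int, mean: float = 0.0, sigma: float = 1.0,
               rho: float = 0.0, seed: int = 0,
               name: str = "ar1") -> ObservableSeries:
    """Gaussian AR(1) series with stationary standard deviation ``sigma``.

    x_{t+1} = mean + rho (x_t - mean) + sigma sqrt(1 - rho^2) eps_t, so the
    marginal variance is sigma^2 for any |rho| < 1 and the integrated
    autocorrelation factor is (1 + rho)/(1 - rho).
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1 for a stationary AR(1) series")
    rng = np.random.default_rng(seed)
    innov = sigma * np.sqrt(1.0 - rho**2)
    x = np.empty(n)
    x[0] = mean + sigma * rng.standard_normal()
    eps = rng.standard_normal(n - 1)
    for t in range(1, n):
        x[t] = mean + rho * (x[t - 1] - mean) + innov * eps[t - 1]
    return ObservableSeries(name=name, values=x)


def make_reweight_testset(n_frames: int, n_restraints: int,
                          true_weights: np.ndarray, noise_sd: float = 0.0,
                          seed: int = 0):
    """Observable matrix + target vector + uncertainties with known truth.

    Per-frame observables are standard-normal draws; targets are the
    true-weighted averages plus Gaussian noise of sd ``noise_sd``;
    uncertainties are set to ``noise_sd`` (floored at 1e-6 so a Gaussian
    error model is always defined).
    """
    w = np.asarray(true_weights, dtype=float)
    if w.shape != (n_frames,) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("true_weights must be normalized, one per frame")
    rng = np.random.default_rng(seed)
    s = rng.standard_normal((n_frames, n_restraints))
    targets = s.T @ w
    if noise_sd > 0:
        targets = targets + rng.normal(0.0, noise_sd, n_restraints)
    sigma = np.full(n_restraints, max(noise_sd, 1e-6))
    return s, targets, sigma
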