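# Methods

This note documents the models, conventions and numerical choices behind
each analysis operator, what the synthetic generators do and do not emulate,
and the design decisions taken where more than one convention exists.

## Units and conventions

Internal length unit is the ångström.  Radii of gyration, box edges and the
globule compaction cutoff are reported in nanometers, with conversions
centralized in `units.py`.  Thermal energy uses
k_B = 0.0019872 kcal/(mol·K), so k_B·T = 0.5962 kcal/mol at the default
300 K.  Author residue numbering (391–446 for the androgen-receptor Tau-5
R2–R3 fragment this package was built around) is preserved in all outputs;
internal indexing is 0-based; ACE/NH2 caps are recognized and excluded from
per-residue tables and Sα windows.  Analyses assume the solute is whole: no
minimum-image handling is applied, which is valid whenever the box edge
exceeds every cutoff by a wide margin (7.5 nm versus ≤ 10 Å here).

## Sα helical order parameter

Sα sums the rational switching function f(x) = (1 − x⁸)/(1 − x¹²) over all
L − 5 consecutive six-residue windows, with x the window's Cα RMSD to a
six-residue ideal-helix reference divided by r₀ = 1.0 Å.  The removable
singularity at x = 1 is evaluated as 2/3.  The window RMSD uses optimal
(Kabsch) superposition: without superposition a rigidly rotated ideal helix
would not score L − 5, so best-fit RMSD is the only reading under which a
fully helical 56-mer scores 51.  The reference fragment is built once by
the internal chain builder at (φ, ψ) = (−57°, −47°).  Kabsch RMSDs are
evaluated in a single batched SVD over all frames × windows.

Per-residue helicity is delegated to mdtraj's DSSP implementation and
counts class "H" (α-helix) only by default; 3₁₀/π classes can be included
via the `classes` argument since "helical propensity" conventions differ.

## Backbone builder

Chains are built by sequential internal-coordinate (NeRF-style) extension
with standard geometry (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å; angles
N–Cα–C 111.2°, Cα–C–N 116.2°, C–N–Cα 121.7°; ω = 180°), backbone atoms
N/Cα/C/O only, carbonyl oxygens placed trans to the next amide nitrogen.
The builder is deterministic and bit-reproducible.  Only Sα/RMSD properties
of built structures are asserted in tests, never absolute coordinates:
different builders produce different Cartesian frames for the same
dihedrals.

## Synthetic generators: what they emulate

The two-state generator draws each frame from either a "helical globule"
state or a coil state with mixing fraction p (Bernoulli per frame, one
seeded generator for all randomness, labels retained).  The globule state
is a helix–turn–helix–turn–helix dihedral pattern: three helical segments
at (−57, −47) with 7° Gaussian jitter, folded back on themselves by
three-residue kinks at (φ, ψ) = (10°, 180°), chosen once so that the built
bundle is compact (mean Cα R_g ≈ 0.95 nm) and highly helical (Sα ≈ 38) —
comfortably inside the Sα > 6, R_g < 1.3 nm globule definition while the
coil state (dihedrals from PPII/β/α_R basins at 40/35/25%, 18° jitter,
mean R_g ≈ 2.2 nm, Sα ≲ 4) is comfortably outside, so generating labels and
(Sα, R_g) classification agree for ≥ 95% of frames.  The generator emulates
the *statistical* structure of a disordered ensemble with a collapsed
helical substate — controllable populations, realistic order-parameter
separations — but none of the physics: no sterics beyond a clash check at
ligand placement, no solvent, no energetics, and frames are independent
draws rather than a correlated trajectory.  Passing recovery tests
therefore demonstrates correctness of the estimators, not force-field
realism.

The toy ligand is a rigid two-ring construct (two hexagonal "phenyl" rings,
one hydroxyl donor, one chlorine) — a minimal proxy carrying every
annotation class the analysis operators consume, not a real compound
topology; real ligands enter through the YAML annotation file.  Placement
at a prescribed stacking geometry fixes (R, θ, ϕ) exactly; the azimuth
about the target ring normal, which the geometry leaves free, is scanned in
30° steps to resolve steric clashes before a frame is skipped.

AR(1) series use x_{t+1} = μ + ρ(x_t − μ) + σ√(1−ρ²)ε, giving stationary
variance σ² and an exactly known SE of the mean,
σ√((1+ρ)/(1−ρ))/√n, used to validate blocking.

## Contacts, K_D and interaction censuses

Contacts are heavy-atom/heavy-atom at 6.0 Å; the laxer variant including
protein hydrogens exists behind a flag (default off).  K_D is computed from
the box geometry: v = edge³, C_box = (v·N_A)⁻¹ mol/L = 3.936 mM at 7.5 nm,
K_D = (1−P_b)/P_b · C_box.  "R_g versus minimum contacts" strata use
"≥ k" (a minimum), not "= k".  Hydrogen-bond donors are inferred
geometrically (H within 1.25 Å of N/O/S in the first frame) on the protein
side and declared in the annotation file on the ligand side; acceptors are
all N/O/S heavy atoms.

Stacking geometry uses least-squares ring planes (robust to slight
non-planarity), θ = arccos|n̂_p·n̂_l| and ϕ = arccos|n̂_p·R̂|, folding both
angles into [0°, 90°].  Two cutoff presets ship, because two conventions
are in circulation: the default "methods" preset (parallel: R < 6.5 Å,
θ < 60°, ϕ < 45°; T: R < 7.5 Å, θ > 75°, ϕ < 45°) and a "figure" preset
(θ < 45° / ϕ < 60° parallel band, ϕ < 60° T band).  The θ bands are
disjoint by construction, so a frame is never both parallel and T-stacked.
Tryptophan contributes its five- and six-membered rings as separate ring
groups; per-residue stacking populations combine a residue's rings by OR.
Orientation surfaces over (R, θ) divide bin probabilities by R² sin θ at
bin centers so an isotropic, uniform-in-volume reference is flat.

## Blocking and free-energy surfaces

Blocking applies recursive pair-averaging; at each level the SE over block
means is recorded, and the optimal level is the first whose block size b
satisfies b³ ≥ 2n(SE_b/SE_0)⁴ (the automated optimal-block criterion of
Lee et al. 2011).  If no level satisfies it the last level's SE is returned
with a warning.  For weighted series both w·x and w are block-averaged and
the SE is taken over per-block weighted means, so a constant observable has
zero SE under any weighting.  Series shorter than 8 frames fall back to the
naive SE with a warning.

Free-energy surfaces are weighted histograms with F = −k_B T ln P, shifted
so the occupied minimum is zero; empty bins are undefined (NaN), never
zero.  Per-bin errors come from splitting the frame sequence into five
contiguous equal blocks (each block's F min-shifted before taking the
standard error over blocks), independent of the automated blocking used
for scalars.  Default binning for the (R_g, Sα) surface: Sα width 1.0 over
[0, 51], R_g width 0.05 nm.

## Globule thermodynamics

The helical-globule state is Sα > 6.0 and R_g < 1.3 nm (both
configurable).  Its formation free energy is the two-state log-odds
ΔG = −k_B T ln(p/(1−p)) at the ensemble temperature — this form reproduces
every published (population, ΔG) pairing this package was validated
against (40.4% → +0.23, 48.5% → +0.04, 61.1% → −0.27 kcal/mol at 300 K) —
with the SE of p propagated by the delta method,
SE(ΔG) = k_B T·SE(p)/(p(1−p)).  Saturated populations (p ∈ {0, 1}) yield a
signed-infinite ΔG with a warning.  A cutoff scan reports the population as
a function of the Sα threshold (monotone non-increasing).

## Maximum-entropy reweighting

Posterior weights w_i ∝ w0_i·exp(−λ·s_i) with λ minimizing the convex dual
Γ(λ) = ln Σᵢ w0ᵢ e^{−λ·sᵢ} + λ·s_exp + ½Σ_k σ_k²λ_k².  The optimizer is
deterministic L-BFGS with the analytic gradient, started from λ = 0
(convexity makes the optimum start-independent; tested from multiple
starts), gradient tolerance 1e-10, at most 10⁴ iterations, log-sum-exp
stabilized.  At the optimum ⟨s_k⟩_w = s_exp,k + σ_k²λ_k; the residual of
this identity is reported as a convergence diagnostic.  One global σ per
restraint class is the default (1.73 ppm for Cα shifts); per-restraint σ is
supported.  The Kish ratio is reported in percent, 100/(N·Σw²) for
normalized weights.  Chemical-shift prediction is consumed from file; the
predictor itself is out of scope.

## Pipeline and problem sizes

`run_full_analysis` composes the stages in a fixed order with stage-level
logging and full parameter echo into provenance; report scalars equal the
values of the corresponding standalone module calls, and reruns on
identical inputs are byte-identical.  The test-suite exercises the
pipeline on synthetic ensembles of 300–500 frames of a 56-residue chain and
scalar series of 10⁴–10⁵ points, sizes at which every binomial 3-SE
recovery band is a few percent wide and the suite completes in well under a
minute per module.

## Known limitations

* The synthetic coil is a dihedral-basin caricature; it has no excluded
  volume, so its R_g distribution is broader than a real disordered chain's.
* Frames are i.i.d. draws, so blocking on synthetic ensembles plateaus at
  level 0; autocorrelation handling is validated on the AR(1) series
  instead.
* DSSP on backbone-only chains relies on mdtraj's internal amide-hydrogen
  reconstruction; ensembles lacking carbonyl oxygens cannot be assigned.
* No π–cation or halogen-bond detection, no residence-time kinetics, no
  reweighting across temperature rungs (WHAM/MBAR) — all outside the
  analysis this package defines.
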