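# globulebind

Ensemble analysis of small-molecule binding to intrinsically disordered
protein (IDP) regions.

IDPs do not fold into a single structure; a ligand that "binds" one does so
through a dynamic cloud of interconverting contacts, and its effect shows up
as a shift in the conformational ensemble — for example the stabilization of
collapsed, partially helical ("helical globule") states in the
transactivation domain of the androgen receptor by bisphenol-A-derived
inhibitors.  This package implements the complete analysis pipeline for
quantifying such effects from a conformational ensemble (topology +
trajectory frames), together with synthetic-ensemble generators that make
every operator testable against known ground truth.

## What it computes

* **Helical order.**  The Sα order parameter
  `Sα = Σᵢ (1 − xᵢ⁸)/(1 − xᵢ¹²)`, `xᵢ = RMSDαᵢ / r₀`, summed over all
  N = L − 5 consecutive six-residue windows, where RMSDαᵢ is the best-fit
  Cα RMSD of window *i* to an ideal α-helix (φ = −57°, ψ = −47°) and
  r₀ = 1.0 Å.  A fully helical 56-residue chain scores 51.  Per-residue
  helicity by DSSP (delegated to mdtraj).
* **Binding statistics.**  Heavy-atom residue–ligand contacts at 6.0 Å, the
  bound fraction P_b, and the dissociation constant
  `K_D = (P_u / P_b) · (v c° N_A)⁻¹` with v the cubic box volume
  (3.93 mM for one molecule in a 7.5 nm box); pairwise simultaneous-contact
  maps, conditional interaction probabilities, R_g versus the minimum number
  of distinct residue contacts, and tagged-atom proximity distributions.
* **Interaction censuses.**  Hydrophobic contacts (C–C/C–Cl < 4 Å), hydrogen
  bonds (H···A < 3.5 Å, ∠D–H–A > 150°, both donor directions), and aromatic
  stacking classified from the ring-pair geometry (R, θ, ϕ) into parallel
  and T-shaped bands, with free-energy surfaces over (R, θ) normalized by
  the R² sin θ Jacobian.
* **Thermodynamics and errors.**  Blocking (recursive pair-averaging) error
  analysis with automated optimal block selection; 1-D/2-D free-energy
  surfaces with five-block errors; the helical-globule population
  (Sα > 6, R_g < 1.3 nm) and its formation free energy
  `ΔG = −k_B T ln(p/(1−p))`.
* **Maximum-entropy reweighting.**  Frame weights minimally perturbed to
  match experimental observables (e.g. Cα chemical shifts, σ = 1.73 ppm)
  under a Gaussian error model, with the Kish effective-sample ratio.

## Worked example

Generate a synthetic two-state ensemble (40% helical-globule, 60% coil) of a
56-residue chain with a toy two-ring ligand placed in contact in half the
frames, then run the full pipeline:

```bash
globulebind simulate --preset two-state --p 0.4 --n 300 --seed 1 \
    --ligand --out fixtures
globulebind run config.yaml      # points at fixtures/, box_edge: 7.5
```

Scalars from `analysis/report.json` (all errors from blocking):

```
globule_population   0.405 ± 0.024
delta_g_globule     +0.230 ± 0.059  kcal/mol
bound_fraction       0.547 ± 0.039
kd                   3.26  ± 0.52   mM
c_box                3.936          mM
salpha_mean          16.9  ± 0.9
rg_mean              1.687 ± 0.036  nm
fraction_helix       0.335
```

The globule population recovers the generator's 40% mixing fraction; its
free energy of formation (+0.23 kcal/mol) is the two-state log-odds at
300 K; the bound fraction matches the 50% placement rate and maps to a
K_D just below the 3.94 mM single-molecule box concentration.  Per-residue
tables (contact probabilities, helicity, interaction populations, pair
maps, FES grids) are written alongside as CSV.

The same operations are available as library calls (`globulebind.helicity.
salpha`, `globulebind.binding.kd_from_bound_fraction`, …) and as focused
subcommands (`globulebind salpha`, `bind`, `interactions`, `thermo`,
`reweight`).

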