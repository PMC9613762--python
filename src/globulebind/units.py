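"""Centralized unit conversions and physical constants.

Internal length unit is the angstrom; radii of gyration, box edges and the
globule compaction cutoff are reported in nanometers.
"""

ANGSTROM_PER_NM = 10.0

#: Boltzmann constant, kcal/(mol K)
KB_KCAL = 0.0019872

#: Avogadro's number, 1/mol
N_AVOGADRO = 6.02214076e23


def nm_to_angstrom(x):
    return x * ANGSTROM_PER_NM


def angstrom_to_nm(x):
    return x / ANGSTROM_PER_NM


def kt_kcal(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol at the given temperature (K)."""
    return KB_KCAL * temperature


def box_volume_liters(box_edge_nm: float) -> float:
    """Volume of a cubic box with the given edge (nm), in liters."""
    edge_dm = box_edge_nm * 1e-8  # 1 nm = 1e-8 dm
    return edge_dm**3


def single_molecule_concentration(box_edge_nm: float) -> float:
    """Concentration (mol/L) of one molecule in a cubic box of edge (nm).

    C_box = (v * N_A)^-1 with v the box volume in liters.  For a 7.5 nm box
    this evaluates to 3.93 mM, the concentration of one protein and one
    ligand copy in the simulation cell.
    """
    return 1.0 / (box_volume_liters(box_edge_nm) * N_AVOGADRO)
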