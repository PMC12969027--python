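"""Physical constants and default model parameters.

All distances are in nm, energies in kJ/mol, angles in degrees unless a
name says otherwise. Force constants follow GROMACS conventions:
kJ mol^-1 nm^-2 for bonds and kJ mol^-1 rad^-2 for angles/dihedrals.
"""

# Boltzmann constant in kJ mol^-1 K^-1 (CODATA)
KB = 0.008314462618

#: default simulation temperature (K)
DEFAULT_TEMPERATURE = 300.0

#: gas constant in kJ mol^-1 K^-1 (identical to KB in molar units)
R_GAS = KB

#: 1 kJ mol^-1 nm^-1 expressed in piconewton
PN_PER_KJ_MOL_NM = 1.66054

# ---------------------------------------------------------------------------
# Collagen backbone bonded defaults (harmonic terms between BB beads).
# Two bond classes implement the sequence rule: bonds whose *first* residue
# is proline-like (PRO or HYP) are shorter and stiffer than general bonds.
# ---------------------------------------------------------------------------

#: general BB(i)-BB(i+1) bond: equilibrium length (nm) and force constant
BOND_GENERAL_R0 = 0.356
BOND_GENERAL_K = 18000.0

#: PRO/HYP-X BB(i)-BB(i+1) bond: equilibrium length (nm) and force constant
BOND_SHORT_R0 = 0.320
BOND_SHORT_K = 34000.0

#: BB-BB-BB angle: equilibrium (deg) and force constant (kJ mol^-1 rad^-2,
#: the printed Martini convention value)
ANGLE_THETA0 = 138.0
ANGLE_K = 152.0

#: BB-BB-BB-BB proper dihedral: equilibrium (deg) and force constant (kJ/mol)
DIHEDRAL_PHI0 = 76.0
DIHEDRAL_K = 17.0

#: bond-length threshold separating the two backbone bond populations (nm);
#: the density crossing point of the two fitted Gaussian components
BOND_CLASS_THRESHOLD = 0.329

#: AA backbone bond-length mixture components (nm): (mean, sd)
BACKBONE_BOND_LOWER = (0.318, 0.010)
BACKBONE_BOND_UPPER = (0.354, 0.013)

# ---------------------------------------------------------------------------
# Go model defaults (intrahelical structure-based contacts)
# ---------------------------------------------------------------------------

#: Lennard-Jones well depth of a native contact (kJ/mol)
GO_EPSILON = 9.414
GO_CUTOFF_LOW = 0.3
GO_CUTOFF_HIGH = 1.1
GO_MIN_SEQ_SEP = 3

# ---------------------------------------------------------------------------
# Bead masses (amu) and van der Waals radii (nm) by Martini size class
# ---------------------------------------------------------------------------

BEAD_MASS = {"regular": 72.0, "small": 54.0, "tiny": 36.0}
BEAD_RADIUS = {"regular": 0.264, "small": 0.230, "tiny": 0.191}
DEFAULT_PROBE_RADIUS = 0.191

#: residues recognized by the backbone machinery
STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HYP",
}

#: residues triggering the short bond class when first in a bond
PROLINE_LIKE = {"PRO", "HYP"}

#: default backbone atom selection for center-of-geometry mapping
DEFAULT_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

# experimental triple-helix geometry used as validation target
EXPERIMENTAL_RISE_PER_RESIDUE = 0.290  # nm
EXPERIMENTAL_RESIDUES_PER_TURN = 3.28
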