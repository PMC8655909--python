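"""Model constants: coarse-grained geometry, force-field parameters, units.

Energies are in units of kBT (temperature is fixed at 1 kBT), distances in
nanometres, angles in radians, throughout the package.

The five-site nucleotide consists of a phosphate bead (P), a sugar bead (S)
and a rigid planar base triangle (B1, B2, B3).  The bonded parameters below
are chosen so that an unrestrained chain has an inter-phosphate spacing of
about 0.6 nm and a persistence length of roughly 1 nm, which is the
single-stranded-RNA-like regime the model targets.
"""

import numpy as np

KBT = 1.0

# --- site indexing within a nucleotide -------------------------------------
SITE_P = 0
SITE_S = 1
SITE_B1 = 2
SITE_B2 = 3
SITE_B3 = 4
N_SITES = 5

# --- bonded terms ----------------------------------------------------------
# backbone phosphate-phosphate connectivity
BOND_PP = 0.60          # nm, rest length P(i)-P(i+1)
K_BOND_PP = 200.0       # kBT/nm^2
# intra-nucleotide bonds (constant under rigid-nucleotide moves, but part of
# the energy function so that non-rigid deformations would be penalised)
BOND_PS = 0.48          # nm, phosphate-sugar
K_BOND_PS = 200.0
BOND_SB = 0.33          # nm, sugar to base-triangle centroid
K_BOND_SB = 200.0
# backbone bending P(i-1)-P(i)-P(i+1)
ANGLE_PPP = np.pi       # rad, straight rest angle
K_ANGLE = 1.7           # kBT/rad^2; gives persistence length ~ 1 nm

# --- excluded volume (hard spheres; pairs between nucleotides |i-j| >= 2) ---
# The phosphate size (diameter) is 0.3 nm, consistent with the wall
# potential whose minimum sits ~0.15 nm above the plane (a touching
# sphere).  The sugar bead is a virtual site locating the nucleoside
# attachment and carries no excluded volume of its own; the base triangle
# provides the nucleoside sterics.
PHOSPHATE_SIZE = 0.30   # nm, diameter
RADIUS_P = PHOSPHATE_SIZE / 2.0
RADIUS_S = 0.0
RADIUS_B = 0.16
SITE_RADII = np.array([RADIUS_P, RADIUS_S, RADIUS_B, RADIUS_B, RADIUS_B])

# --- base triangle ----------------------------------------------------------
BASE_EDGE = 0.40                        # nm, equilateral edge
BASE_CIRCUMRADIUS = BASE_EDGE / np.sqrt(3.0)

# --- secondary-structure restraint (harmonic in the eRMSD metric) -----------
K_SS = 400.0            # kBT per (eRMSD)^2, per stem; keeps the rms stem
                        # eRMSD near 0.23 (equipartition over ~40 modes),
                        # i.e. well below the melting of the imposed pairs
ERMSD_SCALE_XY = 0.5    # nm, in-base-plane anisotropic scaling
ERMSD_SCALE_Z = 0.3     # nm, base-normal scaling
ERMSD_CUTOFF = 2.4      # in scaled units
ERMSD_GAMMA = np.pi / ERMSD_CUTOFF
# A stem whose instantaneous eRMSD stays below this value is considered to
# retain its secondary structure ("below the melting temperature" regime).
ERMSD_RESTRAINT_MAX = 0.6

# --- ideal A-form helix used for templates and initial coordinates ----------
AFORM_RISE = 0.28                       # nm per base pair
AFORM_TWIST = np.deg2rad(32.7)          # rad per base pair
AFORM_R_P = 0.90                        # nm, phosphate radius from axis
AFORM_R_B = 0.45                        # nm, base-centroid radius from axis
AFORM_PAIR_PHASE = 2.9                  # rad, angular offset of paired strand
AFORM_P_PHASE = -0.6                    # rad, phosphate angular lead
AFORM_P_DROP = 0.18                     # nm, phosphate height offset
AFORM_PAIR_RISE = 0.05                  # nm, paired-residue height offset

# --- simulation box ----------------------------------------------------------
WALL_Z = 0.0            # adsorbing wall plane
Z_TOP = 8.0             # nm, hard upper boundary bounding the desorbed state

# --- umbrella-sampling defaults ---------------------------------------------
WINDOW_SPRING = 50.0    # kBT/nm^2
# The PMF is referenced to its plateau over the outermost nanometre of
# this range.  A flexible chain can still dangle a tail onto the wall a
# few nm out, so this finite-range reference is a convention: absolute
# adsorption free energies carry a small convention offset, and wiss/noss
# comparisons always use the same convention on both sides.
WINDOW_CENTERS = np.arange(0.5, 4.01, 0.25)   # nm
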