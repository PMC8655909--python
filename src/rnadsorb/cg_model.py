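"""Coarse-grained RNA representation, intramolecular energies and restraints.

Each nucleotide is a rigid body of five interaction sites: a phosphate bead
(P), a sugar bead (S) and a planar equilateral base triangle (B1-B3) whose
orientation defines the nucleotide frame.  Chains are connected through
harmonic P(i)-P(i+1) bonds and P-P-P bending angles; non-adjacent
nucleotides interact through hard-sphere excluded volume.  Secondary
structure is enforced per stem by a harmonic restraint on the eRMSD metric
(anisotropically scaled base-base G-vectors) measured against an ideal
A-form template, so that stems stay formed while their relative placement
and the unpaired regions remain fully flexible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from . import _kernels, constants, geometry

__all__ = [
    "FragmentTopology",
    "ForceFieldParams",
    "NucleotideGeometry",
    "Conformation",
    "AFormTemplate",
    "build_topology",
    "ermsd",
    "ermsd_between",
    "restraint_energy",
    "intra_energy",
]

_VALID_BASES = set("ACGUN")


@dataclass(frozen=True)
class FragmentTopology:
    """Connectivity and secondary structure of one RNA fragment."""

    n_nucleotides: int
    base_pairs: tuple  # ((i, j), ...) with i < j, 0-based
    stems: tuple       # per stem, a tuple of stacked pairs
    structured: bool
    sequence: str = ""
    dotbracket: str = ""

    def __post_init__(self):
        if self.n_nucleotides < 1:
            raise ValueError("fragment must contain at least one nucleotide")
        seen = set()
        for i, j in self.base_pairs:
            if not (0 <= i < j < self.n_nucleotides):
                raise ValueError(f"invalid pair ({i}, {j})")
            if j - i < 4:
                raise ValueError(
                    f"pair ({i}, {j}) closes a loop shorter than 3 nucleotides"
                )
            if i in seen or j in seen:
                raise ValueError(f"index in pair ({i}, {j}) is already paired")
            seen.update((i, j))
        if not self.structured and self.base_pairs:
            raise ValueError("unstructured topology must have no base pairs")

    @property
    def paired_fraction(self) -> float:
        return 2.0 * len(self.base_pairs) / self.n_nucleotides

    def unstructured(self) -> "FragmentTopology":
        """The same chain with all base pairs removed (the 'noss' variant)."""
        return replace(self, base_pairs=(), stems=(), structured=False,
                       dotbracket="." * self.n_nucleotides)


@dataclass(frozen=True)
class ForceFieldParams:
    """Bonded, excluded-volume and restraint parameters (kBT, nm, rad)."""

    k_bond_pp: float = constants.K_BOND_PP
    bond_pp: float = constants.BOND_PP
    k_bond_ps: float = constants.K_BOND_PS
    bond_ps: float = constants.BOND_PS
    k_bond_sb: float = constants.K_BOND_SB
    bond_sb: float = constants.BOND_SB
    k_angle: float = constants.K_ANGLE
    angle0: float = constants.ANGLE_PPP
    k_ss: float = constants.K_SS
    z_top: float = constants.Z_TOP
    radii: tuple = tuple(constants.SITE_RADII)
    temperature: float = constants.KBT  # fixed at 1 kBT

    def __post_init__(self):
        for name in ("k_bond_pp", "k_bond_ps", "k_bond_sb", "k_angle", "k_ss"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(2 * self.radii[constants.SITE_P] - constants.PHOSPHATE_SIZE) > 1e-12:
            raise ValueError("phosphate excluded-volume size is fixed at 0.3 nm")

    def vector(self) -> np.ndarray:
        return np.array([
            self.k_bond_pp, self.bond_pp, self.k_bond_ps, self.bond_ps,
            self.k_bond_sb, self.bond_sb, self.k_angle, self.angle0,
            self.k_ss, self.z_top,
        ])

    def radii_array(self) -> np.ndarray:
        return np.asarray(self.radii, dtype=float)


class NucleotideGeometry:
    """View of one nucleotide's five sites with its orthonormal frame.

    The frame is derived from the base triangle: x toward the first base
    site, z along the triangle normal, y completing a right-handed triad.
    """

    def __init__(self, sites: np.ndarray):
        sites = np.asarray(sites, dtype=float)
        if sites.shape != (5, 3):
            raise ValueError("a nucleotide has five 3D sites")
        self.sites = sites

    @property
    def phosphate_position(self) -> np.ndarray:
        return self.sites[constants.SITE_P]

    @property
    def sugar_position(self) -> np.ndarray:
        return self.sites[constants.SITE_S]

    @property
    def base_sites(self) -> np.ndarray:
        return self.sites[constants.SITE_B1:constants.SITE_B3 + 1]

    @property
    def nucleotide_frame(self) -> np.ndarray:
        """Rows are the x, y, z unit vectors of the base frame."""
        tri = self.base_sites
        c = tri.mean(axis=0)
        x = geometry.normalize(tri[0] - c)
        z = geometry.normalize(np.cross(x, tri[1] - c))
        return np.vstack([x, np.cross(z, x), z])


class Conformation:
    """Per-nucleotide rigid-body coordinates above the wall at z = 0.

    ``pos`` has shape (n_nucleotides, 5, 3) in nm with site order
    P, S, B1, B2, B3.
    """

    def __init__(self, pos: np.ndarray):
        pos = np.asarray(pos, dtype=float)
        if pos.ndim != 3 or pos.shape[1:] != (5, 3):
            raise ValueError("conformation must have shape (n, 5, 3)")
        self.pos = pos

    @property
    def n_nucleotides(self) -> int:
        return self.pos.shape[0]

    @property
    def phosphates(self) -> np.ndarray:
        return self.pos[:, constants.SITE_P]

    @property
    def bases(self) -> np.ndarray:
        """Base-site coordinates, shape (n, 3, 3)."""
        return self.pos[:, constants.SITE_B1:constants.SITE_B3 + 1]

    def copy(self) -> "Conformation":
        return Conformation(self.pos.copy())

    def com(self) -> np.ndarray:
        return self.pos.reshape(-1, 3).mean(axis=0)

    @property
    def com_z(self) -> float:
        return float(self.pos[..., 2].mean())

    def translated(self, shift) -> "Conformation":
        return Conformation(self.pos + np.asarray(shift, dtype=float))

    def at_height(self, z_com: float, z_floor: float = 0.05) -> "Conformation":
        """Rigidly shift so the centre of mass sits at ``z_com``, but never
        push any site below ``z_floor`` above the wall."""
        dz = z_com - self.com_z
        min_z = self.pos[..., 2].min()
        if min_z + dz < z_floor:
            dz = z_floor - min_z
        return self.translated([0.0, 0.0, dz])

    # --- CG-PDB I/O (one residue per nucleotide; atoms P, S, B1, B2, B3) ---

    def to_pdb(self, path) -> None:
        n = self.n_nucleotides
        atoms = bst.AtomArray(n * 5)
        names = ["P", "S", "B1", "B2", "B3"]
        atoms.coord = self.pos.reshape(-1, 3) * 10.0  # nm -> Angstrom
        atoms.atom_name = np.array(names * n)
        atoms.res_id = np.repeat(np.arange(1, n + 1), 5)
        atoms.res_name = np.full(n * 5, "RN")
        atoms.chain_id = np.full(n * 5, "A")
        atoms.element = np.array(["P", "C", "N", "N", "N"] * n)
        atoms.hetero = np.full(n * 5, True)
        pdb = PDBFile()
        pdb.set_structure(atoms)
        pdb.write(path)

    @classmethod
    def from_pdb(cls, path) -> "Conformation":
        atoms = PDBFile.read(path).get_structure(model=1)
        if len(atoms) % 5 != 0:
            raise ValueError("CG-PDB must contain five sites per nucleotide")
        return cls(atoms.coord.reshape(-1, 5, 3) / 10.0)


def build_topology(dotbracket: str, sequence: str | None = None) -> FragmentTopology:
    """Parse a dot-bracket string into a :class:`FragmentTopology`.

    Raises ``ValueError`` for unbalanced strings, invalid characters,
    hairpin loops shorter than three nucleotides, or a sequence of
    mismatched length.
    """
    if not dotbracket:
        raise ValueError("empty dot-bracket string")
    stack = []
    pairs = []
    for k, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {k}")
            pairs.append((stack.pop(), k))
        elif ch != ".":
            raise ValueError(f"invalid character {ch!r} at position {k}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    if sequence is not None:
        if len(sequence) != len(dotbracket):
            raise ValueError("sequence length does not match structure length")
        bad = set(sequence.upper()) - _VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
    pairs.sort()
    stems = _find_stems(pairs)
    return FragmentTopology(
        n_nucleotides=len(dotbracket),
        base_pairs=tuple(pairs),
        stems=tuple(stems),
        structured=bool(pairs),
        sequence=(sequence or "").upper(),
        dotbracket=dotbracket,
    )


def _find_stems(pairs):
    """Group base pairs into maximal runs of stacked pairs (i+1, j-1)."""
    stems = []
    current = []
    for p in pairs:
        if current and p == (current[-1][0] + 1, current[-1][1] - 1):
            current.append(p)
        else:
            if current:
                stems.append(tuple(current))
            current = [p]
    if current:
        stems.append(tuple(current))
    return stems


class AFormTemplate:
    """Ideal A-form base-site coordinates for every stem of a topology.

    Each stem is referenced to its own helix (helical rise 0.28 nm, twist
    32.7 degrees per base pair), so the restraint fixes the internal stem
    geometry but not the relative placement of different stems.
    """

    def __init__(self, topology: FragmentTopology):
        self.topology = topology
        self.stem_residues: list[np.ndarray] = []
        self.stem_bases: list[np.ndarray] = []
        coords: dict[int, np.ndarray] = {}
        for stem in topology.stems:
            res = sorted([i for i, _ in stem] + [j for _, j in stem])
            step_of = {}
            for t, (i, j) in enumerate(stem):
                step_of[i] = (t, "A")
                step_of[j] = (t, "B")
            bases = np.empty((len(res), 3, 3))
            for a, r in enumerate(res):
                t, strand = step_of[r]
                full = geometry.helix_residue(t, strand)
                bases[a] = full[2:5]
                coords[r] = full
            self.stem_residues.append(np.asarray(res, dtype=np.int64))
            self.stem_bases.append(bases)
        self._coords = coords
        self._encoded = None

    def base_coords(self, residues) -> np.ndarray:
        """Template base triangles (m, 3, 3) for the given residues."""
        out = np.empty((len(residues), 3, 3))
        for a, r in enumerate(residues):
            if r not in self._coords:
                raise KeyError(f"residue {r} is not covered by the template")
            out[a] = self._coords[r][2:5]
        return out

    def kernel_arrays(self):
        """Stem encoding consumed by the numba kernels (cached)."""
        if self._encoded is None:
            self._encoded = _encode_stems(self.stem_residues, self.stem_bases)
        return self._encoded


def empty_stem_arrays():
    return (
        np.zeros(1, dtype=np.int64),
        np.zeros(0, dtype=np.int64),
        np.zeros(0),
        np.zeros(1, dtype=np.int64),
    )


def _encode_stems(stem_residues, stem_bases):
    if not stem_residues:
        return empty_stem_arrays()
    stem_off = [0]
    gt_off = [0]
    res_cat = []
    gt_cat = []
    for res, bases in zip(stem_residues, stem_bases):
        m = len(res)
        res_cat.append(res)
        g = _kernels.base_gmat(np.ascontiguousarray(bases))
        gt_cat.append(g.ravel())
        stem_off.append(stem_off[-1] + m)
        gt_off.append(gt_off[-1] + m * m * 4)
    return (
        np.asarray(stem_off, dtype=np.int64),
        np.concatenate(res_cat).astype(np.int64),
        np.concatenate(gt_cat),
        np.asarray(gt_off, dtype=np.int64),
    )


def stem_arrays_for(topology: FragmentTopology, template: AFormTemplate | None):
    """Kernel stem encoding for a (topology, template) pair; empty for noss."""
    if not topology.structured or template is None:
        return empty_stem_arrays()
    return template.kernel_arrays()


def ermsd_between(bases_a: np.ndarray, bases_b: np.ndarray) -> float:
    """eRMSD between two base-coordinate sets of shape (m, 3, 3).

    The metric is built from relative base positions expressed in local
    base frames, so it is invariant under global rigid motions of either
    structure, symmetric in its arguments, and zero iff all G-vectors
    coincide.
    """
    a = np.ascontiguousarray(bases_a, dtype=float)
    b = np.ascontiguousarray(bases_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3 or a.shape[1:] != (3, 3):
        raise ValueError("expected matching (m, 3, 3) base-coordinate arrays")
    g1 = _kernels.base_gmat(a)
    g2 = _kernels.base_gmat(b)
    return float(np.sqrt(_kernels.ermsd_sq_between(g1, g2)))


def ermsd(conf: Conformation, template: AFormTemplate, residues) -> float:
    """eRMSD between a conformation and the template, over ``residues``."""
    residues = list(residues)
    if not residues:
        raise ValueError("residue list is empty")
    if max(residues) >= conf.n_nucleotides or min(residues) < 0:
        raise IndexError("residue index out of range")
    conf_bases = conf.bases[residues]
    tmpl_bases = template.base_coords(residues)
    return ermsd_between(conf_bases, tmpl_bases)


def restraint_energy(conf: Conformation, topology: FragmentTopology,
                     template: AFormTemplate | None,
                     k_ss: float = constants.K_SS) -> float:
    """Harmonic secondary-structure restraint: k_ss * eRMSD^2 per stem.

    Zero for unstructured (noss) fragments.
    """
    if not topology.structured:
        return 0.0
    if template is None:
        raise ValueError("structured topology requires an A-form template")
    e = 0.0
    for res, bases in zip(template.stem_residues, template.stem_bases):
        e += k_ss * ermsd_between(conf.bases[res], bases) ** 2
    return e


def intra_energy(conf: Conformation, topology: FragmentTopology,
                 params: ForceFieldParams | None = None,
                 template: AFormTemplate | None = None) -> float:
    """Total intramolecular energy: bonds + angles + excluded volume +
    restraints, in kBT.  Returns ``inf`` on hard-core overlap or when any
    site leaves the slab 0 < z < z_top (move-rejection sentinel)."""
    params = params or ForceFieldParams()
    stem_off, stem_res, gt_flat, gt_off = stem_arrays_for(topology, template)
    return float(_kernels.intra_energy_kernel(
        np.ascontiguousarray(conf.pos), params.vector(), params.radii_array(),
        stem_off, stem_res, gt_flat, gt_off,
    ))
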