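"""Steric descriptors from 3D molecular structures.

This module holds the geometric half of the per-site descriptor block:

* **Percent buried volume (%Vbur)** — the fraction of a probe sphere centered
  on an atom that is occupied by the (scaled) van der Waals spheres of the
  surrounding atoms.  Computed by regular-grid point counting, which is
  deterministic for a fixed grid spacing.
* **Sterimol L, B1, B5** — Verloop's substituent steric parameters: the length
  of a substituent along its attachment axis (L) and its minimal (B1) and
  maximal (B5) perpendicular half-widths.  B1 is found by scanning in-plane
  directions at a configurable angular resolution.

Structures are taken as given (no conformer generation, no optimization) and
read from plain XYZ or MDL SDF/MOL V2000 files.  Bonds, when absent, are
inferred from covalent-radius distance cutoffs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "BONDI_VDW_RADII",
    "COVALENT_RADII",
    "GeometryError",
    "Molecule3D",
    "RadiiSet",
    "StericDescriptors",
    "compute_buried_volume",
    "compute_sterimol",
    "infer_bonds",
    "read_xyz",
    "read_sdf",
    "read_structure",
    "write_xyz",
]

# Bondi (1964) van der Waals radii in angstrom, with common extensions for
# elements Bondi did not tabulate (B, heavier metalloids).
BONDI_VDW_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40,
    "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "Ne": 1.54,
    "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Ar": 1.88,
    "As": 1.85, "Se": 1.90, "Br": 1.85, "Kr": 2.02,
    "Te": 2.06, "I": 1.98, "Xe": 2.16,
    "Li": 1.82, "Na": 2.27, "K": 2.75, "Mg": 1.73, "Zn": 1.39,
}

# Cordero et al. (2008) single-bond covalent radii in angstrom (C is the sp3
# value; adequate for distance-cutoff bond perception).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Zn": 1.22,
    "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Te": 1.38, "I": 1.39, "Xe": 1.40,
}

_MIN_ATOM_SEPARATION = 0.5  # angstrom; closer pairs indicate a broken structure


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent geometric input."""


@dataclass(frozen=True)
class RadiiSet:
    """A van der Waals radius table with a global scale factor.

    Parameters
    ----------
    radii
        Mapping element symbol -> radius in angstrom.
    scale
        Dimensionless multiplier applied to every radius.  The buried-volume
        convention (SambVca) scales Bondi radii by 1.17; classic Verloop
        Sterimol uses unscaled radii.
    """

    radii: Mapping[str, float]
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"radius scale must be positive, got {self.scale}")
        bad = {el: r for el, r in self.radii.items() if r <= 0}
        if bad:
            raise ValueError(f"non-positive radii: {bad}")

    def radius(self, element: str) -> float:
        """Scaled radius for *element*; KeyError for unknown elements."""
        try:
            return self.radii[element] * self.scale
        except KeyError:
            raise KeyError(f"no van der Waals radius tabulated for element {element!r}")

    @classmethod
    def bondi(cls, scale: float = 1.0) -> "RadiiSet":
        return cls(radii=BONDI_VDW_RADII, scale=scale)


# Package defaults: SambVca-style buried volume, classic Verloop Sterimol.
DEFAULT_BV_RADII = RadiiSet.bondi(scale=1.17)
DEFAULT_STERIMOL_RADII = RadiiSet.bondi(scale=1.0)
DEFAULT_SPHERE_RADIUS = 3.5       # angstrom
DEFAULT_GRID_SPACING = 0.05       # angstrom
DEFAULT_ANGLE_RESOLUTION = 1.0    # degrees
DEFAULT_BOND_TOLERANCE = 1.2      # dimensionless, on summed covalent radii


@dataclass
class Molecule3D:
    """A molecule as element symbols + Cartesian coordinates in angstrom.

    ``bonds`` is optional; :func:`infer_bonds` derives it from covalent-radius
    cutoffs when needed.
    """

    elements: list[str]
    coordinates: np.ndarray  # (n_atoms, 3), angstrom
    bonds: list[tuple[int, int]] | None = None
    identifier: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = len(self.elements)
        if self.coordinates.shape != (n, 3):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{n} elements"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        unknown = [el for el in self.elements if el not in COVALENT_RADII]
        if unknown:
            raise ValueError(f"unknown element symbols: {sorted(set(unknown))}")
        if n >= 2:
            d = np.linalg.norm(
                self.coordinates[:, None, :] - self.coordinates[None, :, :], axis=-1
            )
            np.fill_diagonal(d, np.inf)
            if d.min() < _MIN_ATOM_SEPARATION:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise ValueError(
                    f"atoms {i} and {j} are {d[i, j]:.3f} A apart "
                    f"(< {_MIN_ATOM_SEPARATION} A)"
                )
        if self.bonds is not None:
            clean: list[tuple[int, int]] = []
            for i, j in self.bonds:
                if not (0 <= i < n and 0 <= j < n):
                    raise IndexError(f"bond ({i}, {j}) out of range for {n} atoms")
                if i == j:
                    raise ValueError(f"self-bond on atom {i}")
                clean.append((min(i, j), max(i, j)))
            self.bonds = sorted(set(clean))

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def bond_list(self, tolerance: float = DEFAULT_BOND_TOLERANCE) -> list[tuple[int, int]]:
        """Stored bonds, or bonds inferred from covalent radii."""
        if self.bonds is not None:
            return self.bonds
        return infer_bonds(self, tolerance)


@dataclass
class StericDescriptors:
    """Per-site steric block: %Vbur plus the Sterimol triple.

    Fields not yet populated are ``None``; populated fields are validated
    (0 <= %Vbur <= 100, 0 < B1 <= B5, L > 0).
    """

    percent_buried_volume: float | None = None
    sterimol_L: float | None = None
    sterimol_B1: float | None = None
    sterimol_B5: float | None = None

    def __post_init__(self) -> None:
        pbv = self.percent_buried_volume
        if pbv is not None and not (0.0 <= pbv <= 100.0):
            raise ValueError(f"percent buried volume {pbv} outside [0, 100]")
        if self.sterimol_L is not None and self.sterimol_L <= 0:
            raise ValueError("Sterimol L must be positive")
        if self.sterimol_B1 is not None and self.sterimol_B5 is not None:
            if not (0 < self.sterimol_B1 <= self.sterimol_B5 + 1e-9):
                raise ValueError(
                    f"require 0 < B1 <= B5, got B1={self.sterimol_B1}, "
                    f"B5={self.sterimol_B5}"
                )


# ---------------------------------------------------------------------------
# bond perception
# ---------------------------------------------------------------------------

def infer_bonds(mol: Molecule3D, tolerance: float = DEFAULT_BOND_TOLERANCE) -> list[tuple[int, int]]:
    """Distance-cutoff bond perception.

    Atoms i, j are bonded iff ``d(i, j) <= tolerance * (r_cov_i + r_cov_j)``.
    ``tolerance`` must lie in [1.0, 1.5]; 1.2 comfortably separates aromatic
    C-C/C-H contacts from non-bonded ring distances.
    """
    if not 1.0 <= tolerance <= 1.5:
        raise ValueError(f"tolerance {tolerance} outside [1.0, 1.5]")
    rc = np.array([COVALENT_RADII[el] for el in mol.elements])
    xyz = mol.coordinates
    bonds: list[tuple[int, int]] = []
    for i in range(mol.n_atoms):
        d = np.linalg.norm(xyz[i + 1:] - xyz[i], axis=1)
        cutoff = tolerance * (rc[i] + rc[i + 1:])
        for off in np.nonzero(d <= cutoff)[0]:
            bonds.append((i, i + 1 + int(off)))
    return bonds


# ---------------------------------------------------------------------------
# percent buried volume
# ---------------------------------------------------------------------------

def compute_buried_volume(
    mol: Molecule3D,
    center_atom: int,
    sphere_radius: float = DEFAULT_SPHERE_RADIUS,
    radii: RadiiSet = DEFAULT_BV_RADII,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    exclude_atoms: Iterable[int] | None = None,
) -> float:
    """Percent of a probe sphere occupied by neighboring vdW spheres.

    The probe sphere of ``sphere_radius`` is centered on ``center_atom``.  A
    regular Cartesian grid of pitch ``grid_spacing`` is laid over the sphere
    and each grid point inside the sphere is tested against the scaled vdW
    sphere of every atom not in ``exclude_atoms``.  By default only the center
    atom itself is excluded and hydrogens are included.

    Returns the occupied percentage in [0, 100]; deterministic for a fixed
    grid.
    """
    n = mol.n_atoms
    if not 0 <= center_atom < n:
        raise IndexError(f"center atom {center_atom} out of range for {n} atoms")
    if sphere_radius <= 0:
        raise ValueError("sphere_radius must be positive")
    if not 0 < grid_spacing <= sphere_radius / 5:
        raise ValueError(
            f"grid_spacing must lie in (0, sphere_radius/5]; got {grid_spacing} "
            f"for sphere_radius {sphere_radius}"
        )
    excluded = {center_atom} if exclude_atoms is None else set(exclude_atoms)
    for idx in excluded:
        if not 0 <= idx < n:
            raise IndexError(f"excluded atom {idx} out of range")

    center = mol.coordinates[center_atom]
    # Atoms whose scaled vdW sphere can intersect the probe sphere at all.
    contributors: list[tuple[np.ndarray, float]] = []
    for i in range(n):
        if i in excluded:
            continue
        r = radii.radius(mol.elements[i])
        if np.linalg.norm(mol.coordinates[i] - center) <= sphere_radius + r:
            contributors.append((mol.coordinates[i] - center, r))
    if not contributors:
        warnings.warn(
            f"no atoms occupy the probe sphere at atom {center_atom}; "
            "buried volume is 0",
            stacklevel=2,
        )
        return 0.0

    half = int(math.floor(sphere_radius / grid_spacing))
    axis = np.arange(-half, half + 1, dtype=float) * grid_spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    in_sphere = np.einsum("ij,ij->i", pts, pts) <= sphere_radius**2
    pts = pts[in_sphere]

    occupied = np.zeros(len(pts), dtype=bool)
    for pos, r in contributors:
        free = ~occupied
        if not free.any():
            break
        d2 = np.einsum("ij,ij->i", pts[free] - pos, pts[free] - pos)
        occupied[np.nonzero(free)[0][d2 <= r * r]] = True
    return float(100.0 * occupied.sum() / len(pts))


# ---------------------------------------------------------------------------
# Sterimol
# ---------------------------------------------------------------------------

def compute_sterimol(
    mol: Molecule3D,
    base_atom: int,
    attached_atom: int,
    substituent_atoms: Iterable[int],
    radii: RadiiSet = DEFAULT_STERIMOL_RADII,
    angle_resolution: float = DEFAULT_ANGLE_RESOLUTION,
) -> StericDescriptors:
    """Verloop Sterimol L, B1, B5 of a substituent.

    The attachment axis is the unit vector from ``base_atom`` (the atom the
    substituent hangs from, e.g. the ipso carbon) to ``attached_atom`` (the
    substituent's first atom).  With projections measured from ``base_atom``:

    * ``L``  = max over substituent atoms of (axial projection + vdW radius)
    * ``B5`` = max over substituent atoms of (distance from axis + vdW radius)
    * ``B1`` = min over in-plane directions *u*, scanned every
      ``angle_resolution`` degrees, of max over atoms of (signed projection
      onto *u* + vdW radius)

    Deterministic; B1 <= B5 by construction (up to scan resolution).
    """
    n = mol.n_atoms
    sub = sorted(set(int(i) for i in substituent_atoms))
    for idx in (base_atom, attached_atom, *sub):
        if not 0 <= idx < n:
            raise IndexError(f"atom index {idx} out of range for {n} atoms")
    if not sub:
        raise ValueError("substituent_atoms must be nonempty")
    if attached_atom not in sub:
        raise ValueError("substituent_atoms must contain attached_atom")
    if angle_resolution <= 0:
        raise ValueError("angle_resolution must be positive")

    base = mol.coordinates[base_atom]
    axis = mol.coordinates[attached_atom] - base
    norm = np.linalg.norm(axis)
    if norm < 1e-8:
        raise GeometryError("base and attached atoms coincide; axis undefined")
    if norm > 2.0:
        raise GeometryError(
            f"base and attached atoms are {norm:.2f} A apart (> 2.0 A); "
            "not an attachment bond"
        )
    axis = axis / norm

    rel = mol.coordinates[sub] - base
    rads = np.array([radii.radius(mol.elements[i]) for i in sub])
    axial = rel @ axis
    perp_vec = rel - np.outer(axial, axis)
    perp = np.linalg.norm(perp_vec, axis=1)

    L = float(np.max(axial + rads))
    B5 = float(np.max(perp + rads))

    # Orthonormal in-plane frame for the B1 direction scan.
    seed = np.array([1.0, 0.0, 0.0])
    if abs(axis @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u1 = seed - (seed @ axis) * axis
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(axis, u1)

    angles = np.deg2rad(np.arange(0.0, 360.0, angle_resolution))
    dirs = np.outer(np.cos(angles), u1) + np.outer(np.sin(angles), u2)  # (m, 3)
    # widths[m] = max over atoms of signed projection onto dir m + radius
    widths = (perp_vec @ dirs.T + rads[:, None]).max(axis=0)
    B1 = float(min(widths.min(), B5))

    return StericDescriptors(sterimol_L=L, sterimol_B1=B1, sterimol_B5=B5)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path) -> Molecule3D:
    """Read a plain XYZ file (counts line, comment line, then atoms, in A)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: first line of an XYZ file must be the atom count")
    body = lines[2:2 + count]
    if len(body) < count:
        raise ValueError(f"{path}: expected {count} atom lines, found {len(body)}")
    elements, coords = [], []
    for ln in body:
        parts = ln.split()
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    name = lines[1].strip() or path.stem
    return Molecule3D(elements=elements, coordinates=np.array(coords), identifier=name)


def write_xyz(mol: Molecule3D, path: str | Path, comment: str | None = None) -> None:
    path = Path(path)
    lines = [str(mol.n_atoms), comment if comment is not None else mol.identifier]
    for el, (x, y, z) in zip(mol.elements, mol.coordinates):
        lines.append(f"{el:<3s} {x:15.8f} {y:15.8f} {z:15.8f}")
    path.write_text("\n".join(lines) + "\n")


def read_sdf(path: str | Path) -> Molecule3D:
    """Read the first record of an SDF/MOL V2000 file, hydrogens retained."""
    from rdkit import Chem

    path = Path(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    rdmol = next((m for m in supplier if m is not None), None)
    if rdmol is None:
        raise ValueError(f"{path}: no parseable molecule record")
    conf = rdmol.GetConformer()
    elements = [a.GetSymbol() for a in rdmol.GetAtoms()]
    coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                        conf.GetAtomPosition(i).z] for i in range(rdmol.GetNumAtoms())])
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in rdmol.GetBonds()]
    name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else path.stem
    return Molecule3D(elements=elements, coordinates=coords, bonds=bonds,
                      identifier=name or path.stem)


def read_structure(path: str | Path) -> Molecule3D:
    """Dispatch on extension: .xyz -> XYZ, .sdf/.mol -> SDF V2000."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".xyz":
        return read_xyz(path)
    if ext in (".sdf", ".mol"):
        return read_sdf(path)
    raise ValueError(f"unsupported structure format: {path}")
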