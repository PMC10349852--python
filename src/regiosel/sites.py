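"""Symmetry-distinct C-H sites and the pairwise competing-site encoding.

A regioselectivity measurement compares symmetry-distinct aromatic C-H
positions of one arene (e.g. the ortho/meta/para positions of anisole).
This module:

* enumerates aromatic C-H sites and groups them into symmetry classes by
  iterative neighborhood refinement over the molecular graph (topology only,
  so conformational noise cannot split a class); the class size is the
  statistical multiplicity of the position;
* ingests externally computed per-site QM descriptors (Fukui indices,
  partial charge, C-H bond dissociation energy) and per-molecule descriptors
  (computed oxidation potential) from CSV tables;
* assembles, for every ordered pair of competing sites, a fixed-width
  feature vector ``[site A block | site B block | molecule block |
  temperature]``.  The default schema is 13 per-site descriptors x 2 sites
  + redox potential + temperature = 28 features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from . import geometry
from .geometry import Molecule3D

__all__ = [
    "DescriptorSchema",
    "FormatError",
    "MoleculeDescriptors",
    "PairFeatureVector",
    "PairingError",
    "SchemaError",
    "SiteClass",
    "SiteDescriptors",
    "DEFAULT_SCHEMA",
    "build_pair_vector",
    "canonical_pair_order",
    "enumerate_sites",
    "load_molecule_table",
    "load_qm_table",
    "molecular_graph",
    "symmetry_classes",
]


class PairingError(ValueError):
    """Sites that cannot legally form a competing pair."""


class SchemaError(ValueError):
    """Descriptor block does not satisfy the declared schema."""


class FormatError(ValueError):
    """Malformed descriptor/measurement table."""


# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------

DEFAULT_PER_SITE_DESCRIPTORS: tuple[str, ...] = (
    # steric block (geometry module)
    "percent_buried_volume",
    "sterimol_L",
    "sterimol_B1",
    "sterimol_B5",
    # electronic block (ingested QM)
    "fukui_plus",
    "fukui_minus",
    "fukui_zero",
    "dual_descriptor",
    "partial_charge",
    "ch_bde",
    # extension slots for user-supplied descriptors
    "ext_1",
    "ext_2",
    "ext_3",
)
DEFAULT_MOLECULE_DESCRIPTORS: tuple[str, ...] = ("redox_potential",)

# Physical sanity bounds on ingested electronic descriptors (units: e for
# Fukui/charge, kcal/mol for BDE).  Wide on purpose; they catch unit mixups,
# not chemistry.
DESCRIPTOR_BOUNDS: dict[str, tuple[float, float]] = {
    "fukui_plus": (-1.0, 1.0),
    "fukui_minus": (-1.0, 1.0),
    "fukui_zero": (-1.0, 1.0),
    "dual_descriptor": (-2.0, 2.0),
    "partial_charge": (-3.0, 3.0),
    "ch_bde": (50.0, 200.0),
}


@dataclass(frozen=True)
class DescriptorSchema:
    """Ordered feature layout of a competing-site pair vector."""

    per_site: tuple[str, ...] = DEFAULT_PER_SITE_DESCRIPTORS
    molecule: tuple[str, ...] = DEFAULT_MOLECULE_DESCRIPTORS
    include_temperature: bool = True

    def __post_init__(self) -> None:
        if len(set(self.per_site)) != len(self.per_site):
            raise SchemaError("duplicate per-site descriptor names")
        if len(set(self.molecule)) != len(self.molecule):
            raise SchemaError("duplicate molecule descriptor names")

    @property
    def width(self) -> int:
        return 2 * len(self.per_site) + len(self.molecule) + int(self.include_temperature)

    @property
    def feature_names(self) -> tuple[str, ...]:
        names = [f"site_a__{d}" for d in self.per_site]
        names += [f"site_b__{d}" for d in self.per_site]
        names += [f"mol__{d}" for d in self.molecule]
        if self.include_temperature:
            names.append("temperature_K")
        return tuple(names)


DEFAULT_SCHEMA = DescriptorSchema()
assert DEFAULT_SCHEMA.width == 28


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SiteClass:
    """One symmetry class of aromatic C-H positions."""

    label: str                    # deterministic class label, e.g. "a", "b"
    atom_indices: tuple[int, ...]  # ring-carbon indices, sorted
    multiplicity: int

    @property
    def representative(self) -> int:
        return self.atom_indices[0]


@dataclass
class SiteDescriptors:
    """Per-site descriptor block keyed by (arene id, atom index)."""

    arene_id: str
    atom_index: int
    values: dict[str, float] = field(default_factory=dict)
    class_label: str | None = None

    def validate(self, schema: DescriptorSchema) -> None:
        missing = [d for d in schema.per_site if d not in self.values]
        if missing:
            raise SchemaError(
                f"site ({self.arene_id}, atom {self.atom_index}) missing "
                f"descriptors {missing}"
            )
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise SchemaError(
                    f"non-finite descriptor {name!r} at "
                    f"({self.arene_id}, atom {self.atom_index})"
                )
            lo, hi = DESCRIPTOR_BOUNDS.get(name, (-np.inf, np.inf))
            if not lo <= v <= hi:
                raise SchemaError(
                    f"descriptor {name!r}={v} outside physical bounds "
                    f"[{lo}, {hi}] at ({self.arene_id}, atom {self.atom_index})"
                )


@dataclass
class MoleculeDescriptors:
    """Per-molecule descriptor block (computed oxidation potential, V)."""

    arene_id: str
    values: dict[str, float] = field(default_factory=dict)

    def validate(self, schema: DescriptorSchema) -> None:
        missing = [d for d in schema.molecule if d not in self.values]
        if missing:
            raise SchemaError(f"arene {self.arene_id} missing molecule descriptors {missing}")
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise SchemaError(f"non-finite molecule descriptor {name!r} for {self.arene_id}")


@dataclass
class PairFeatureVector:
    """Named feature vector for one ordered pair of competing sites."""

    names: tuple[str, ...]
    values: np.ndarray
    arene_id: str
    site_a: int
    site_b: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise SchemaError("feature names and values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise SchemaError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError("missing/non-finite feature values")


# ---------------------------------------------------------------------------
# site enumeration
# ---------------------------------------------------------------------------

def molecular_graph(mol: Molecule3D) -> nx.Graph:
    """Element-labelled bond graph (bonds inferred if absent)."""
    g = nx.Graph()
    for i, el in enumerate(mol.elements):
        g.add_node(i, element=el)
    g.add_edges_from(mol.bond_list())
    return g


def _aromatic_carbons(mol: Molecule3D, g: nx.Graph) -> set[int]:
    """Carbons in 5-/6-membered rings whose ring carbons are all sp2-like.

    Ring perception runs on the bond graph; a ring is eligible when every
    member is C/N/O/S and every ring carbon has exactly three neighbors
    (planar trigonal coordination).  This covers benzene/naphthalene and
    thiophene/furan/pyrrole-type heteroarenes without electronic structure.
    """
    aromatic: set[int] = set()
    for ring in nx.cycle_basis(g):
        if len(ring) not in (5, 6):
            continue
        ok = True
        for idx in ring:
            el = mol.elements[idx]
            if el not in ("C", "N", "O", "S"):
                ok = False
                break
            if el == "C" and g.degree(idx) != 3:
                ok = False
                break
        if ok:
            aromatic.update(i for i in ring if mol.elements[i] == "C")
    return aromatic


def symmetry_classes(g: nx.Graph, nodes: Iterable[int]) -> list[tuple[int, ...]]:
    """Partition *nodes* by iterative neighborhood (Morgan/WL) refinement.

    Initial colors are element symbols; each round replaces a node's color
    with (color, sorted multiset of neighbor colors) until the partition is
    stable.  Topologically equivalent atoms end with equal colors.
    """
    colors: dict[int, int] = {}
    table: dict[object, int] = {}
    for v in g.nodes:
        key = g.nodes[v]["element"]
        colors[v] = table.setdefault(key, len(table))
    while True:
        table = {}
        new: dict[int, int] = {}
        for v in g.nodes:
            key = (colors[v], tuple(sorted(colors[u] for u in g.neighbors(v))))
            new[v] = table.setdefault(key, len(table))
        if len(set(new.values())) == len(set(colors.values())):
            colors = new
            break
        colors = new
    groups: dict[int, list[int]] = {}
    for v in sorted(nodes):
        groups.setdefault(colors[v], []).append(v)
    return sorted((tuple(sorted(vs)) for vs in groups.values()), key=lambda t: t[0])


_CLASS_LABELS = "abcdefghijklmnopqrstuvwxyz"


def enumerate_sites(mol: Molecule3D) -> list[SiteClass]:
    """Symmetry-distinct aromatic C-H sites with multiplicities.

    Every aromatic carbon bearing exactly one hydrogen is a site; sites are
    grouped into symmetry classes by canonical atom ranking on the molecular
    graph.  Classes are labelled ``a``, ``b``, ... in order of their lowest
    atom index, so the ordering is deterministic for a given atom numbering.
    Returns an empty list (with a warning) when the molecule has no aromatic
    C-H.
    """
    g = molecular_graph(mol)
    ch_sites = [
        c for c in _aromatic_carbons(mol, g)
        if sum(1 for u in g.neighbors(c) if mol.elements[u] == "H") == 1
    ]
    if not ch_sites:
        warnings.warn(
            f"molecule {mol.identifier or '<unnamed>'} has no aromatic C-H site",
            stacklevel=2,
        )
        return []
    classes = symmetry_classes(g, ch_sites)
    if len(classes) > len(_CLASS_LABELS):
        raise ValueError("more than 26 symmetry classes are not supported")
    return [
        SiteClass(label=_CLASS_LABELS[k], atom_indices=members, multiplicity=len(members))
        for k, members in enumerate(classes)
    ]


def site_hydrogen(mol: Molecule3D, carbon: int) -> int:
    """Index of the single H bonded to an aromatic carbon site."""
    g = molecular_graph(mol)
    hs = [u for u in g.neighbors(carbon) if mol.elements[u] == "H"]
    if len(hs) != 1:
        raise ValueError(f"atom {carbon} bears {len(hs)} hydrogens, expected 1")
    return hs[0]


# ---------------------------------------------------------------------------
# QM descriptor tables
# ---------------------------------------------------------------------------

_REQUIRED_SITE_COLUMNS = ("fukui_plus", "fukui_minus", "fukui_zero",
                          "partial_charge", "ch_bde")


def load_qm_table(path: str | Path, index_base: int = 0) -> dict[tuple[str, int], SiteDescriptors]:
    """Load per-site QM descriptors from CSV.

    Expected columns: ``arene_id, atom_index, fukui_plus, fukui_minus,
    fukui_zero, partial_charge, ch_bde`` plus any number of extension
    columns, which are preserved under their own names.  The dual descriptor
    (f+ - f-) is derived when not supplied.  ``index_base=1`` converts
    1-based atom indices from external tables to the package's 0-based
    convention.
    """
    df = pd.read_csv(path)
    for col in ("arene_id", "atom_index", *_REQUIRED_SITE_COLUMNS):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    dup = df.duplicated(subset=["arene_id", "atom_index"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate row for (arene {row['arene_id']!r}, "
            f"atom {row['atom_index']})"
        )
    out: dict[tuple[str, int], SiteDescriptors] = {}
    extra = [c for c in df.columns if c not in ("arene_id", "atom_index")]
    for _, row in df.iterrows():
        atom = int(row["atom_index"]) - index_base
        values = {c: float(row[c]) for c in extra}
        if "dual_descriptor" not in values:
            values["dual_descriptor"] = values["fukui_plus"] - values["fukui_minus"]
        out[(str(row["arene_id"]), atom)] = SiteDescriptors(
            arene_id=str(row["arene_id"]), atom_index=atom, values=values
        )
    return out


def load_molecule_table(path: str | Path) -> dict[str, MoleculeDescriptors]:
    """Load per-molecule descriptors (``arene_id, redox_potential, ...``)."""
    df = pd.read_csv(path)
    for col in ("arene_id", "redox_potential"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df["arene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate arene_id rows")
    cols = [c for c in df.columns if c != "arene_id"]
    return {
        str(row["arene_id"]): MoleculeDescriptors(
            arene_id=str(row["arene_id"]),
            values={c: float(row[c]) for c in cols},
        )
        for _, row in df.iterrows()
    }


# ---------------------------------------------------------------------------
# pair encoding
# ---------------------------------------------------------------------------

def build_pair_vector(
    a: SiteDescriptors,
    b: SiteDescriptors,
    mol: MoleculeDescriptors,
    temperature: float,
    schema: DescriptorSchema = DEFAULT_SCHEMA,
) -> PairFeatureVector:
    """Assemble the fixed-width encoding of one competing-site pair.

    Layout: ``[site A block | site B block | molecule block | temperature]``
    with the descriptor order fixed by *schema*.  Both sites must belong to
    the same arene as the molecule block.
    """
    if not (a.arene_id == b.arene_id == mol.arene_id):
        raise PairingError(
            f"sites/molecule from different arenes: {a.arene_id!r}, "
            f"{b.arene_id!r}, {mol.arene_id!r}"
        )
    if a.atom_index == b.atom_index:
        raise PairingError(f"site paired with itself (atom {a.atom_index})")
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    a.validate(schema)
    b.validate(schema)
    mol.validate(schema)
    values = [a.values[d] for d in schema.per_site]
    values += [b.values[d] for d in schema.per_site]
    values += [mol.values[d] for d in schema.molecule]
    if schema.include_temperature:
        values.append(float(temperature))
    return PairFeatureVector(
        names=schema.feature_names,
        values=np.array(values, dtype=float),
        arene_id=a.arene_id,
        site_a=a.atom_index,
        site_b=b.atom_index,
    )


def site_steric_block(
    mol: Molecule3D,
    site_carbon: int,
    mode: str = "flanking",
    shell: int = 3,
    bv_radii: geometry.RadiiSet = geometry.DEFAULT_BV_RADII,
    sterimol_radii: geometry.RadiiSet = geometry.DEFAULT_STERIMOL_RADII,
    sphere_radius: float = geometry.DEFAULT_SPHERE_RADIUS,
    grid_spacing: float = geometry.DEFAULT_GRID_SPACING,
    angle_resolution: float = geometry.DEFAULT_ANGLE_RESOLUTION,
) -> dict[str, float]:
    """Geometric descriptor block for one aromatic C-H site.

    ``percent_buried_volume`` is evaluated at the site carbon.  The Sterimol
    triple describes the congestion *around* the site:

    * ``mode="flanking"`` (default): for each ring neighbor of the site
      carbon, the Sterimol of its exocyclic substituent is measured from
      that neighbor (the substituent's ipso carbon); the block is the
      elementwise maximum over the flanking substituents, i.e. the worst
      flanking bulk.  The substituent branch is truncated at graph radius
      ``shell`` from its first atom, which keeps the measure local in fused
      polycyclics.  Sites with only bare (H) flanks get the H Sterimol.
    * ``mode="h_shell"``: Sterimol of the site's own H plus ring atoms
      within graph distance ``shell`` of the site carbon, measured along
      the C-H axis.
    """
    g = molecular_graph(mol)
    h = site_hydrogen(mol, site_carbon)
    pbv = geometry.compute_buried_volume(
        mol, site_carbon, sphere_radius=sphere_radius, radii=bv_radii,
        grid_spacing=grid_spacing,
    )

    def _sterimol(base: int, attached: int, atoms: set[int]):
        return geometry.compute_sterimol(
            mol, base, attached, atoms, radii=sterimol_radii,
            angle_resolution=angle_resolution,
        )

    if mode == "h_shell":
        lengths = nx.single_source_shortest_path_length(g, site_carbon, cutoff=shell)
        atoms = {h} | {v for v, d in lengths.items()
                       if v != site_carbon and mol.elements[v] != "H"}
        st = _sterimol(site_carbon, h, atoms)
    elif mode == "flanking":
        ring_neighbors = [u for u in g.neighbors(site_carbon)
                          if mol.elements[u] != "H"]
        measured: list = []
        for nb in ring_neighbors:
            exo = [u for u in g.neighbors(nb)
                   if u != site_carbon and not _shares_ring(g, nb, u)]
            for first in exo:
                lengths = nx.single_source_shortest_path_length(
                    g.subgraph(set(g.nodes) - {nb}), first, cutoff=shell)
                measured.append(_sterimol(nb, first, set(lengths)))
        if not measured:
            measured.append(_sterimol(site_carbon, h, {h}))
        st_L = max(s.sterimol_L for s in measured)
        st_B5 = max(s.sterimol_B5 for s in measured)
        st_B1 = max(s.sterimol_B1 for s in measured)
        st = geometry.StericDescriptors(
            sterimol_L=st_L, sterimol_B1=min(st_B1, st_B5), sterimol_B5=st_B5)
    else:
        raise ValueError(f"unknown Sterimol site mode {mode!r}")
    return {
        "percent_buried_volume": pbv,
        "sterimol_L": st.sterimol_L,
        "sterimol_B1": st.sterimol_B1,
        "sterimol_B5": st.sterimol_B5,
    }


def _shares_ring(g: nx.Graph, u: int, v: int) -> bool:
    """True when edge (u, v) lies on any cycle (i.e. both atoms share a ring)."""
    if not g.has_edge(u, v):
        return False
    h = g.copy()
    h.remove_edge(u, v)
    return nx.has_path(h, u, v)


def canonical_pair_order(a: SiteClass, b: SiteClass) -> tuple[SiteClass, SiteClass, int]:
    """Deterministic ordering of a competing-site pair.

    Orders by (class label lexicographic, then lowest atom index) and returns
    ``(first, second, sign)`` where ``sign`` is -1 if the inputs were swapped
    (pairwise targets must then be negated) and +1 otherwise.  Idempotent.
    """
    if a.label == b.label and a.atom_indices == b.atom_indices:
        raise PairingError(f"cannot pair symmetry class {a.label!r} with itself")
    key_a = (a.label, a.atom_indices[0])
    key_b = (b.label, b.atom_indices[0])
    if key_a == key_b:
        raise PairingError(f"indistinguishable site classes {a.label!r}")
    if key_a <= key_b:
        return a, b, +1
    return b, a, -1
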