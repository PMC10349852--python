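"""Shared fixtures and independent oracles.

The oracles deliberately use different algorithms from the package:
Monte-Carlo integration for buried volume, a fine brute-force angle scan
for Sterimol widths, and explicit graph-automorphism enumeration for
symmetry classes.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from regiosel import Molecule3D, RadiiSet, make_ring_fixture
from regiosel.sites import molecular_graph


# ---------------------------------------------------------------------------
# molecule fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def benzene() -> Molecule3D:
    return make_ring_fixture("benzene")


@pytest.fixture(scope="session")
def anisole() -> Molecule3D:
    return make_ring_fixture({1: "OMe"}, identifier="anisole")


@pytest.fixture(scope="session")
def o_xylene() -> Molecule3D:
    return make_ring_fixture({1: "Me", 2: "Me"}, identifier="o_xylene")


@pytest.fixture(scope="session")
def naphthalene() -> Molecule3D:
    return make_ring_fixture("naphthalene")


@pytest.fixture(scope="session")
def thiophene() -> Molecule3D:
    return make_ring_fixture("thiophene")


@pytest.fixture(scope="session")
def water() -> Molecule3D:
    # equilibrium geometry: r(OH) = 0.9572 A, angle 104.52 deg
    ang = math.radians(104.52)
    return Molecule3D(
        elements=["O", "H", "H"],
        coordinates=np.array([
            [0.0, 0.0, 0.0],
            [0.9572, 0.0, 0.0],
            [0.9572 * math.cos(ang), 0.9572 * math.sin(ang), 0.0],
        ]),
        identifier="water",
    )


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def mc_buried_volume(
    mol: Molecule3D,
    center_atom: int,
    sphere_radius: float,
    radii: RadiiSet,
    exclude_atoms: set[int] | None = None,
    n_points: int = 1_000_000,
    seed: int = 1234,
) -> float:
    """Monte-Carlo %Vbur: uniform points in the probe sphere vs vdW spheres."""
    rng = np.random.default_rng(seed)
    excluded = {center_atom} if exclude_atoms is None else set(exclude_atoms)
    center = mol.coordinates[center_atom]
    # uniform sampling in a ball by rejection from the bounding cube
    pts = np.empty((0, 3))
    while len(pts) < n_points:
        cand = rng.uniform(-sphere_radius, sphere_radius, size=(n_points, 3))
        cand = cand[np.einsum("ij,ij->i", cand, cand) <= sphere_radius**2]
        pts = np.vstack([pts, cand])
    pts = pts[:n_points]
    occupied = np.zeros(n_points, dtype=bool)
    for i in range(mol.n_atoms):
        if i in excluded:
            continue
        r = radii.radius(mol.elements[i])
        rel = mol.coordinates[i] - center
        occupied |= np.einsum("ij,ij->i", pts - rel, pts - rel) <= r * r
    return 100.0 * occupied.mean()


def scan_sterimol(
    mol: Molecule3D,
    base_atom: int,
    attached_atom: int,
    substituent_atoms: set[int],
    radii: RadiiSet,
    resolution_deg: float = 0.1,
) -> tuple[float, float, float]:
    """Brute-force Sterimol (L, B1, B5) via an explicit fine angle scan."""
    base = mol.coordinates[base_atom]
    axis = mol.coordinates[attached_atom] - base
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 1.0, 0.0]) if abs(axis[0]) > 0.9 else np.array([1.0, 0.0, 0.0])
    u1 = ref - np.dot(ref, axis) * axis
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(axis, u1)
    L = -np.inf
    B5 = -np.inf
    B1 = np.inf
    atoms = [(mol.coordinates[i] - base, radii.radius(mol.elements[i]))
             for i in sorted(substituent_atoms)]
    for rel, r in atoms:
        proj = float(np.dot(rel, axis))
        L = max(L, proj + r)
        perp = rel - proj * axis
        B5 = max(B5, float(np.linalg.norm(perp)) + r)
    n_steps = int(round(360.0 / resolution_deg))
    for k in range(n_steps):
        theta = math.radians(k * resolution_deg)
        u = math.cos(theta) * u1 + math.sin(theta) * u2
        width = max(float(np.dot(rel - np.dot(rel, axis) * axis, u)) + r
                    for rel, r in atoms)
        B1 = min(B1, width)
    return L, min(B1, B5), B5


def automorphism_orbits(mol: Molecule3D, nodes: list[int]) -> list[tuple[int, ...]]:
    """Orbits of *nodes* under the element-preserving graph automorphism group."""
    g = molecular_graph(mol)
    gm = nx.algorithms.isomorphism.GraphMatcher(
        g, g, node_match=lambda a, b: a["element"] == b["element"])
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for mapping in gm.isomorphisms_iter():
        for v in nodes:
            a, b = find(v), find(mapping[v])
            if a != b:
                parent[a] = b
    orbits: dict[int, list[int]] = {}
    for v in nodes:
        orbits.setdefault(find(v), []).append(v)
    return sorted((tuple(sorted(vs)) for vs in orbits.values()), key=lambda t: t[0])
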