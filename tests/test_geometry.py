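"""Steric descriptors: buried volume, Sterimol, bond perception, file I/O."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from regiosel import (
    Molecule3D,
    RadiiSet,
    compute_buried_volume,
    compute_sterimol,
    infer_bonds,
    make_ring_fixture,
    read_sdf,
    read_xyz,
    write_xyz,
)
from regiosel.geometry import GeometryError

from conftest import mc_buried_volume, scan_sterimol

BONDI = RadiiSet.bondi()
BONDI_117 = RadiiSet.bondi(scale=1.17)


class TestMolecule3D:
    def test_rejects_overlapping_atoms(self):
        with pytest.raises(ValueError, match="apart"):
            Molecule3D(["C", "C"], [[0, 0, 0], [0.2, 0, 0]])

    def test_rejects_unknown_element(self):
        with pytest.raises(ValueError, match="unknown element"):
            Molecule3D(["Xq"], [[0, 0, 0]])

    def test_rejects_nonfinite_coordinates(self):
        with pytest.raises(ValueError, match="finite"):
            Molecule3D(["C"], [[np.nan, 0, 0]])

    def test_rejects_out_of_range_bond(self):
        with pytest.raises(IndexError):
            Molecule3D(["C", "H"], [[0, 0, 0], [0, 0, 1.09]], bonds=[(0, 5)])


class TestInferBonds:
    def test_distant_hydrogens_unbonded(self):
        mol = Molecule3D(["H", "H"], [[0, 0, 0], [10, 0, 0]])
        assert infer_bonds(mol, 1.2) == []

    def test_benzene_ring_bond_count(self, benzene):
        bonds = infer_bonds(benzene, 1.2)
        cc = [b for b in bonds if benzene.elements[b[0]] == benzene.elements[b[1]] == "C"]
        ch = [b for b in bonds if "H" in (benzene.elements[b[0]], benzene.elements[b[1]])]
        assert len(cc) == 6 and len(ch) == 6 and len(bonds) == 12

    def test_water_two_oh_bonds(self, water):
        assert infer_bonds(water, 1.2) == [(0, 1), (0, 2)]

    def test_tolerance_bounds_enforced(self, water):
        with pytest.raises(ValueError):
            infer_bonds(water, 0.8)


class TestBuriedVolume:
    def test_isolated_atom_zero(self):
        mol = Molecule3D(["C"], [[0, 0, 0]])
        with pytest.warns(UserWarning, match="buried volume is 0"):
            assert compute_buried_volume(mol, 0) == 0.0

    def test_fully_enclosed_center_is_100(self):
        # six large spheres on the axes engulf a 1.5 A probe sphere entirely
        coords = [[0, 0, 0]] + [
            [s * 1.0 if ax == 0 else 0,
             s * 1.0 if ax == 1 else 0,
             s * 1.0 if ax == 2 else 0]
            for ax in range(3) for s in (+1, -1)
        ]
        mol = Molecule3D(["C"] + ["I"] * 6, coords)
        pbv = compute_buried_volume(mol, 0, sphere_radius=1.5,
                                    radii=RadiiSet.bondi(scale=1.3),
                                    grid_spacing=0.1)
        assert pbv == pytest.approx(100.0, abs=0.5)

    def test_single_neighbor_matches_monte_carlo(self):
        """One carbon 2.0 A from the center, vs a 10^6-point MC oracle."""
        mol = Molecule3D(["C", "C"], [[0, 0, 0], [2.0, 0, 0]])
        grid = compute_buried_volume(mol, 0, sphere_radius=3.5,
                                     radii=BONDI_117, grid_spacing=0.05)
        mc = mc_buried_volume(mol, 0, 3.5, BONDI_117)
        assert grid == pytest.approx(mc, abs=0.5)

    def test_monotone_in_added_atoms(self, benzene):
        partial = Molecule3D(benzene.elements[:8],
                             benzene.coordinates[:8])
        full = benzene
        assert compute_buried_volume(full, 0) >= compute_buried_volume(partial, 0)

    def test_larger_sphere_dilutes_close_occupancy(self):
        mol = Molecule3D(["C", "C"], [[0, 0, 0], [1.5, 0, 0]])
        small = compute_buried_volume(mol, 0, sphere_radius=3.0)
        large = compute_buried_volume(mol, 0, sphere_radius=5.0, grid_spacing=0.05)
        assert 0 <= large <= small <= 100

    def test_permutation_invariance(self, o_xylene):
        rng = np.random.default_rng(7)
        perm = rng.permutation(o_xylene.n_atoms)
        shuffled = Molecule3D([o_xylene.elements[i] for i in perm],
                              o_xylene.coordinates[perm])
        center = int(np.nonzero(perm == 3)[0][0])
        assert compute_buried_volume(o_xylene, 3) == pytest.approx(
            compute_buried_volume(shuffled, center), abs=1e-9)

    def test_invalid_center_raises(self, benzene):
        with pytest.raises(IndexError):
            compute_buried_volume(benzene, 99)

    def test_grid_spacing_bound(self, benzene):
        with pytest.raises(ValueError):
            compute_buried_volume(benzene, 0, sphere_radius=3.5, grid_spacing=1.0)


class TestSterimol:
    def test_single_hydrogen_closed_form(self):
        """H substituent at 1.09 A with r_H = 1.20: L = 2.29, B1 = B5 = 1.20."""
        mol = Molecule3D(["C", "H"], [[0, 0, 0], [0, 0, 1.09]])
        st = compute_sterimol(mol, 0, 1, {1}, radii=BONDI)
        assert st.sterimol_L == pytest.approx(2.29, abs=1e-9)
        assert st.sterimol_B1 == pytest.approx(1.20, abs=1e-9)
        assert st.sterimol_B5 == pytest.approx(1.20, abs=1e-9)

    def test_axially_symmetric_substituent_b1_equals_b5(self):
        """Collinear C#N along the axis: rotational symmetry forces B1 = B5."""
        mol = Molecule3D(["C", "C", "N"],
                         [[0, 0, 0], [0, 0, 1.43], [0, 0, 2.59]])
        st = compute_sterimol(mol, 0, 1, {1, 2}, radii=BONDI)
        assert st.sterimol_B1 == pytest.approx(st.sterimol_B5, abs=1e-6)

    @pytest.mark.parametrize("token", ["H", "Me", "Et", "OMe"])
    def test_matches_fine_angle_scan_oracle(self, token):
        mol = make_ring_fixture({1: token})
        # substituent branch = atoms bonded through the ipso carbon (index 0)
        import networkx as nx
        from regiosel.sites import molecular_graph
        g = molecular_graph(mol)
        g.remove_node(0)
        comp = next(c for c in nx.connected_components(g)
                    if not any(v in range(1, 6) for v in c))
        first = min(comp, key=lambda v: np.linalg.norm(
            mol.coordinates[v] - mol.coordinates[0]))
        st = compute_sterimol(mol, 0, first, comp, radii=BONDI)
        L, B1, B5 = scan_sterimol(mol, 0, first, comp, BONDI, resolution_deg=0.1)
        assert st.sterimol_L == pytest.approx(L, abs=1e-9)
        assert st.sterimol_B5 == pytest.approx(B5, abs=1e-9)
        assert st.sterimol_B1 == pytest.approx(B1, abs=0.01)

    def test_b1_not_larger_than_b5_and_rotation_invariance(self):
        rng = np.random.default_rng(3)
        mol = make_ring_fixture({1: "Et"})
        rot = Rotation.random(random_state=11).as_matrix()
        moved = Molecule3D(mol.elements, mol.coordinates @ rot.T + rng.normal(size=3))
        sub = set(range(6, mol.n_atoms))
        # drop ring hydrogens, keep the ethyl branch (atoms beyond index 5
        # bonded through position 1); branch atoms were appended first
        branch = {6, 7, 8, 9, 10, 11, 12}
        a = compute_sterimol(mol, 0, 6, branch, radii=BONDI)
        b = compute_sterimol(moved, 0, 6, branch, radii=BONDI)
        assert a.sterimol_B1 <= a.sterimol_B5 + 1e-12
        assert a.sterimol_L == pytest.approx(b.sterimol_L, abs=1e-9)
        assert a.sterimol_B5 == pytest.approx(b.sterimol_B5, abs=1e-9)
        assert a.sterimol_B1 == pytest.approx(b.sterimol_B1, abs=2e-3)

    def test_finer_angle_scan_never_increases_b1(self):
        mol = make_ring_fixture({1: "OMe"})
        branch = {6, 7, 8, 9, 10}
        coarse = compute_sterimol(mol, 0, 6, branch, radii=BONDI,
                                  angle_resolution=2.0)
        fine = compute_sterimol(mol, 0, 6, branch, radii=BONDI,
                                angle_resolution=1.0)
        assert fine.sterimol_B1 <= coarse.sterimol_B1 + 1e-12

    def test_degenerate_axis_raises(self):
        mol = Molecule3D(["C", "H", "H"],
                         [[0, 0, 0], [0, 0, 1.09], [0, 1.09, 0]])
        with pytest.raises(GeometryError):
            compute_sterimol(mol, 1, 1, {1})

    def test_substituent_must_contain_attached(self):
        mol = Molecule3D(["C", "H", "H"],
                         [[0, 0, 0], [0, 0, 1.09], [0, 1.09, 0]])
        with pytest.raises(ValueError, match="contain attached"):
            compute_sterimol(mol, 0, 1, {2})


class TestFileIO:
    def test_xyz_round_trip(self, tmp_path, anisole):
        path = tmp_path / "anisole.xyz"
        write_xyz(anisole, path)
        back = read_xyz(path)
        assert back.elements == anisole.elements
        np.testing.assert_allclose(back.coordinates, anisole.coordinates,
                                   atol=1e-7)
        assert back.identifier == "anisole"

    def test_sdf_v2000_read(self, tmp_path, water):
        # hand-rolled V2000 record for water
        lines = ["water", "  test", "", "  3  2  0  0  0  0  0  0  0  0999 V2000"]
        for el, (x, y, z) in zip(water.elements, water.coordinates):
            lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {el:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
        lines += ["  1  2  1  0", "  1  3  1  0", "M  END", "$$$$", ""]
        path = tmp_path / "water.sdf"
        path.write_text("\n".join(lines))
        mol = read_sdf(path)
        assert mol.elements == ["O", "H", "H"]
        assert mol.bonds == [(0, 1), (0, 2)]

    def test_malformed_xyz_raises(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("not-a-count\nhello\n")
        with pytest.raises(ValueError, match="atom count"):
            read_xyz(path)
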