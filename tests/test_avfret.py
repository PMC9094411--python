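import numpy as np
import pytest

from kissfret.avfret import (AVCloud, BuriedAttachmentError, DyeParams,
                             Structure, compute_av, fret_from_clouds,
                             read_structure, select_atom, snapshot_fret,
                             write_structure)

MINIMAL_PDB = """\
ATOM      1  P     G A   1       1.000   2.000   3.000  1.00  0.00           P
ATOM      2  C4'   G A   1       2.500   3.500   4.500  1.00  0.00           C
ATOM      3  N1    G A   1       4.000   5.000   6.000  1.00  0.00           N
HETATM    4  C1  GAI B   9      10.000  10.000  10.000  1.00  0.00           C
END
"""


def point_structure(coords, elements=None):
    coords = np.asarray(coords, float)
    n = len(coords)
    return Structure(
        atom_name=np.array([f"X{i}" for i in range(n)]),
        res_id=np.arange(1, n + 1),
        res_name=np.array(["DUM"] * n),
        chain_id=np.array(["A"] * n),
        element=np.array(elements or ["C"] * n),
        coord=coords,
        hetero=np.zeros(n, dtype=bool),
    )


def point_cloud(xyz):
    return AVCloud(points=np.array([xyz], float), weights=np.array([1.0]),
                   attachment=np.array(xyz, float), grid_spacing=1.0)


class TestStructureIO:
    def test_minimal_pdb_parsed_exactly(self):
        s = read_structure(MINIMAL_PDB)
        assert len(s) == 4
        assert np.allclose(s.coord[0], [1.0, 2.0, 3.0])
        assert s.element[0] == "P"

    def test_hetatm_ligand_included_and_tagged(self):
        s = read_structure(MINIMAL_PDB)
        assert s.hetero[3] and not s.hetero[0]
        assert s.res_name[3] == "GAI"

    def test_malformed_line_skipped_with_warning(self):
        bad = MINIMAL_PDB.replace("   1.000   2.000   3.000",
                                  "   x.xxx   2.000   3.000")
        with pytest.warns(UserWarning, match="malformed"):
            s = read_structure(bad)
        assert len(s) == 3

    def test_round_trip_preserves_coordinates(self, tmp_path):
        s = read_structure(MINIMAL_PDB)
        path = tmp_path / "out.pdb"
        write_structure(s, path)
        again = read_structure(path)
        assert np.allclose(again.coord, s.coord, atol=1e-3)

    def test_no_atoms_raises(self):
        with pytest.raises(Exception):
            read_structure("REMARK nothing here\nEND\n")


class TestComputeAv:
    def test_free_dye_cloud_matches_sphere_volume_oracle(self):
        s = point_structure([[0.0, 0.0, 0.0]])
        dye = DyeParams(10.0, 2.0, (1.0, 1.0, 1.0))
        cloud = compute_av(s, 0, dye, grid_spacing=1.0)
        expected = 4 / 3 * np.pi * 10.0 ** 3
        assert len(cloud) == pytest.approx(expected, rel=0.05)
        assert abs(cloud.weights.sum() - 1.0) < 1e-9

    def test_fully_enclosed_attachment_raises_buried(self):
        # dense shell of atoms at 3 A around the attachment, dye radius 6.8
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(600, 3))
        pts = 3.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        coords = np.vstack([[0.0, 0.0, 0.0], pts])
        s = point_structure(coords)
        dye = DyeParams(12.0, 4.5, (6.8, 6.8, 6.8))
        with pytest.raises(BuriedAttachmentError):
            compute_av(s, 0, dye, grid_spacing=1.0, seed_radius=0.0)

    def test_blocking_wall_strictly_shrinks_cloud(self):
        dye = DyeParams(10.0, 2.0, (2.0, 2.0, 2.0))
        free = compute_av(point_structure([[0.0, 0.0, 0.0]]), 0, dye,
                          grid_spacing=1.0)
        xs, ys = np.meshgrid(np.arange(-12, 13, 1.5), np.arange(-12, 13, 1.5))
        wall = np.column_stack([xs.ravel(), ys.ravel(),
                                np.full(xs.size, 4.0)])
        blocked = compute_av(point_structure(
            np.vstack([[0.0, 0.0, 0.0], wall])), 0, dye, grid_spacing=1.0)
        assert len(blocked) < len(free)

    def test_cloud_volume_rotation_invariant(self, hairpin):
        structure, _ = hairpin
        dye = DyeParams(12.0, 4.5, (5.0, 3.0, 1.5))
        idx = select_atom(structure, "A", 1, "C4'")
        base = compute_av(structure, idx, dye, grid_spacing=1.0)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        rotated = Structure(structure.atom_name, structure.res_id,
                            structure.res_name, structure.chain_id,
                            structure.element, structure.coord @ rot.T,
                            structure.hetero)
        other = compute_av(rotated, idx, dye, grid_spacing=1.0)
        assert len(other) == pytest.approx(len(base), rel=0.02)


class TestFretFromClouds:
    def test_single_points_at_forster_radius_give_half(self):
        e, r = fret_from_clouds(point_cloud([0, 0, 0]),
                                point_cloud([60.0, 0, 0]), 60.0)
        assert e == pytest.approx(0.5, abs=1e-12)
        assert r == pytest.approx(60.0)

    def test_coincident_and_distant_limits(self):
        e0, _ = fret_from_clouds(point_cloud([0, 0, 0]),
                                 point_cloud([0, 0, 0]), 60.0)
        assert e0 == 1.0
        einf, _ = fret_from_clouds(point_cloud([0, 0, 0]),
                                   point_cloud([600.0, 0, 0]), 60.0)
        assert einf < 1e-5

    def test_efficiency_monotone_in_separation(self):
        s = point_structure([[0.0, 0.0, 0.0]])
        dye = DyeParams(8.0, 2.0, (1.5, 1.5, 1.5))
        cloud = compute_av(s, 0, dye, grid_spacing=1.0)
        prev = 1.1
        for shift in np.linspace(20, 110, 10):
            moved = AVCloud(cloud.points + [shift, 0, 0], cloud.weights,
                            cloud.attachment + [shift, 0, 0], 1.0)
            e, _ = fret_from_clouds(cloud, moved, 60.0)
            assert e < prev
            prev = e

    def test_grid_halving_converges(self):
        # toy dumbbell: two attachment atoms 40 A apart
        s = point_structure([[0.0, 0.0, 0.0], [40.0, 0.0, 0.0]])
        dye = DyeParams(8.0, 2.0, (2.0, 2.0, 2.0))
        results = []
        for spacing in (1.2, 0.6):
            a = compute_av(s, 0, dye, grid_spacing=spacing)
            b = compute_av(s, 1, dye, grid_spacing=spacing)
            e, _ = fret_from_clouds(a, b, 60.0)
            results.append(e)
        assert abs(results[0] - results[1]) < 0.02


class TestSnapshotFret:
    def test_compact_geometry_beats_extended(self):
        n = 12
        radii = np.full(n, 0.25)
        extended = np.column_stack([np.arange(n) * 0.6,
                                    np.zeros(n), np.zeros(n)])
        theta = np.linspace(0, 1.5 * np.pi, n)
        compact = np.column_stack([1.0 * np.cos(theta), 1.0 * np.sin(theta),
                                   np.linspace(0, 1.0, n)])
        e_ext = snapshot_fret(extended, radii, (0, n - 1), grid_spacing=1.2)
        e_cmp = snapshot_fret(compact, radii, (0, n - 1), grid_spacing=1.2)
        assert e_cmp > e_ext

    def test_sites_at_forster_distance_give_half(self):
        # compact clouds (short linkers) so the pair distance stays ~R0;
        # long-linker clouds average E over +/-25 A and sit below E(R0)
        coords = np.array([[0.0, 0.0, 0.0], [6.0, 0.0, 0.0]])  # nm
        radii = np.array([0.2, 0.2])
        small = DyeParams(3.0, 2.0, (1.5, 1.5, 1.5))
        e = snapshot_fret(coords, radii, (0, 1), grid_spacing=1.0,
                          dye_a=small, dye_b=small)
        assert e == pytest.approx(0.5, abs=0.05)

    def test_sampling_stable_across_seeds(self):
        coords = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        radii = np.array([0.25, 0.25])
        e1 = snapshot_fret(coords, radii, (0, 1), grid_spacing=1.2, seed=1)
        e2 = snapshot_fret(coords, radii, (0, 1), grid_spacing=1.2, seed=2)
        assert abs(e1 - e2) < 0.01
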