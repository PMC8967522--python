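"""Marching-tetrahedra reconstruction: cell math, combinatorics, meshes."""

import math
import struct
from fractions import Fraction
from itertools import product

import numpy as np
import pytest

from wmh3d.phantom import sphere_field
from wmh3d.reconstruction import (
    CUBE_CORNERS,
    TET_DECOMPOSITIONS,
    TriangleMesh,
    Voxel,
    classify_vertex,
    decompose_cube,
    enumerate_cube_cases,
    evaluate_trilinear_corners,
    extract_isosurface,
    fit_trilinear,
    read_mesh,
    triangulate_tetrahedron,
    write_mesh,
)

RNG = np.random.default_rng(11)


# ---------------------------------------------------------------------------
# Trilinear cells
# ---------------------------------------------------------------------------

class TestTrilinear:
    def test_constant_field(self):
        cell = fit_trilinear(Voxel(np.full(8, 3.25)))
        assert cell.coefficients[0] == 3.25
        assert np.all(cell.coefficients[1:] == 0.0)
        assert cell.evaluate(0.3, 0.7, 0.1) == 3.25

    def test_corner_reproduction_exact(self):
        values = RNG.normal(size=8)
        cell = fit_trilinear(Voxel(values))
        for c in range(8):
            x, y, z = CUBE_CORNERS[c]
            assert cell.evaluate(x, y, z) == pytest.approx(values[c], abs=1e-12)

    def test_center_is_mean_of_corners(self):
        values = RNG.normal(size=8)
        cell = fit_trilinear(Voxel(values))
        assert cell.evaluate(0.5, 0.5, 0.5) == pytest.approx(values.mean(), abs=1e-12)

    def test_matches_weighted_corner_oracle(self):
        for _ in range(20):
            values = RNG.normal(size=8)
            x, y, z = RNG.random(3)
            cell = fit_trilinear(Voxel(values))
            expected = evaluate_trilinear_corners(values, x, y, z)
            assert cell.evaluate(x, y, z) == pytest.approx(expected, abs=1e-12)


def test_classify_vertex_tie_is_inside():
    assert classify_vertex(0.5, 0.5) == "inside"
    assert classify_vertex(0.5 - 1e-12, 0.5) == "outside"
    assert classify_vertex(0.5 + 1e-12, 0.5) == "inside"


# ---------------------------------------------------------------------------
# Case combinatorics
# ---------------------------------------------------------------------------

class TestCubeCases:
    def test_reported_counts(self):
        report = enumerate_cube_cases()
        assert report["total"] == 256
        assert report["complement_classes"] == 128
        assert report["rotation_complement_classes"] == 15

    def test_rotation_classes_match_burnside(self):
        """Orbit count under the rotation group via Burnside's lemma:
        (1/|G|) sum over g of 2^(number of corner-permutation cycles)."""
        from wmh3d.reconstruction import _rotation_permutations

        perms = _rotation_permutations()
        assert len(perms) == 24
        total_fixed = 0
        for perm in perms:
            seen = set()
            cycles = 0
            for start in range(8):
                if start in seen:
                    continue
                cycles += 1
                c = start
                while c not in seen:
                    seen.add(c)
                    c = perm[c]
            total_fixed += 2**cycles
        burnside = total_fixed // 24
        assert enumerate_cube_cases()["rotation_classes"] == burnside == 23


# ---------------------------------------------------------------------------
# Cube decomposition
# ---------------------------------------------------------------------------

class TestDecomposeCube:
    @pytest.mark.parametrize("parity", ["even", "odd"])
    def test_five_tetrahedra_volumes_sum_exactly(self, parity):
        tets = decompose_cube(Voxel(RNG.normal(size=8)), parity)
        assert len(tets) == 5
        # exact rational volume sum: corners are 0/1, so determinants are ints
        total = Fraction(0)
        for tet in tets:
            p = [[Fraction(int(x)) for x in row] for row in tet.vertex_positions]
            d = [[p[i][j] - p[0][j] for j in range(3)] for i in (1, 2, 3)]
            det = (
                d[0][0] * (d[1][1] * d[2][2] - d[1][2] * d[2][1])
                - d[0][1] * (d[1][0] * d[2][2] - d[1][2] * d[2][0])
                + d[0][2] * (d[1][0] * d[2][1] - d[1][1] * d[2][0])
            )
            assert det != 0
            total += abs(det)
        assert total / 6 == Fraction(1)

    def test_interiors_disjoint_by_point_sampling(self):
        """Random interior points fall in exactly one tetrahedron."""
        tets = decompose_cube(Voxel(np.zeros(8)), "even")

        def contains(tet, q, tol=-1e-9):
            p = tet.vertex_positions
            # barycentric coordinates via linear solve
            mat = np.column_stack([p[1] - p[0], p[2] - p[0], p[3] - p[0]])
            lam = np.linalg.solve(mat, q - p[0])
            return lam.min() > tol and lam.sum() < 1 - tol

        for q in RNG.random((200, 3)):
            hits = sum(contains(t, q) for t in tets)
            assert hits == 1

    def test_adjacent_parities_share_face_diagonals(self):
        """Face-adjacent cubes with alternating parity must induce the same
        diagonal on their shared face (the crack-free condition)."""
        even = decompose_cube(Voxel(np.zeros(8)), "even")
        odd = decompose_cube(Voxel(np.zeros(8)), "odd")

        def face_diagonals(tets, axis, value, offset):
            """Diagonal edges lying on the cube face {axis == value},
            expressed in global coordinates after shifting by offset."""
            diags = set()
            for tet in tets:
                p = tet.vertex_positions + offset
                for i, j in [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]:
                    a, b = p[i], p[j]
                    on_face = a[axis] == value + offset[axis] and \
                        b[axis] == value + offset[axis]
                    if on_face and np.abs(a - b).sum() == 2:  # a diagonal
                        diags.add(tuple(sorted([tuple(a), tuple(b)])))
            return diags

        for axis in range(3):
            offset = np.zeros(3)
            offset[axis] = 1.0
            # even cube's far face vs the odd neighbour's near face
            d_even = face_diagonals(even, axis, 1, np.zeros(3))
            d_odd = face_diagonals(odd, axis, 0, offset)
            assert len(d_even) == 1
            assert d_even == d_odd


# ---------------------------------------------------------------------------
# Per-tetrahedron triangulation
# ---------------------------------------------------------------------------

def _tet(values):
    ids = (0, 3, 5, 6)
    return __import__("wmh3d.reconstruction", fromlist=["Tetrahedron"]).Tetrahedron(
        vertex_indices=ids,
        vertex_values=np.asarray(values, dtype=float),
        vertex_positions=CUBE_CORNERS[list(ids)],
    )


class TestTriangulateTetrahedron:
    def test_all_inside_or_outside_yields_nothing(self):
        assert triangulate_tetrahedron(_tet([1, 1, 1, 1]), 0.5) == []
        assert triangulate_tetrahedron(_tet([0, 0, 0, 0]), 0.5) == []

    def test_sixteen_sign_cases_triangle_counts(self):
        """All 2^4 sign cases: 0/4 inside -> 0, 1/3 inside -> 1, 2 -> 2."""
        counted = 0
        for case in range(16):
            values = [1.0 if (case >> i) & 1 else 0.0 for i in range(4)]
            tris = triangulate_tetrahedron(_tet(values), 0.5)
            n_in = bin(case).count("1")
            expected = {0: 0, 1: 1, 2: 2, 3: 1, 4: 0}[n_in]
            assert len(tris) == expected
            counted += 1
        assert counted == 16

    def test_single_inside_vertex_gives_midpoint_triangle(self):
        tris = triangulate_tetrahedron(_tet([1, 0, 0, 0]), 0.5)
        assert len(tris) == 1
        pos = CUBE_CORNERS[[0, 3, 5, 6]]
        midpoints = {tuple((pos[0] + pos[j]) / 2.0) for j in (1, 2, 3)}
        assert {tuple(p) for p in tris[0]} == midpoints

    def test_two_inside_vertices_give_planar_quadrilateral(self):
        tris = triangulate_tetrahedron(_tet([1, 1, 0, 0]), 0.5)
        assert len(tris) == 2
        pts = np.unique(np.concatenate(tris).round(12), axis=0)
        assert len(pts) == 4
        # coplanarity of the 4 quad corners
        n = np.cross(pts[1] - pts[0], pts[2] - pts[0])
        assert abs(n @ (pts[3] - pts[0])) < 1e-12

    def test_normals_point_toward_outside(self):
        tet = _tet([1, 0, 0, 0])
        (tri,) = triangulate_tetrahedron(tet, 0.5)
        normal = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        inside_vertex = tet.vertex_positions[0]
        outward = tri.mean(axis=0) - inside_vertex
        assert normal @ outward > 0


# ---------------------------------------------------------------------------
# Volume-level extraction
# ---------------------------------------------------------------------------

def _sphere_mesh(n, r):
    c = (n - 1) / 2.0
    return extract_isosurface(sphere_field((n, n, n), (c, c, c), r), iso=0.0)


class TestExtractIsosurface:
    def test_empty_mask_gives_empty_mesh(self):
        mesh = extract_isosurface(np.zeros((4, 8, 8)), iso=0.5)
        assert mesh.n_triangles == 0

    def test_sphere_watertight_euler_two(self):
        mesh = _sphere_mesh(64, 20.0)
        assert mesh.is_watertight()
        assert mesh.euler_characteristic() == 2

    def test_sphere_area_and_volume_match_analytic(self):
        r = 20.0
        mesh = _sphere_mesh(64, r)
        assert mesh.area() == pytest.approx(4 * math.pi * r**2, rel=0.03)
        assert mesh.enclosed_volume() == pytest.approx(
            4.0 / 3.0 * math.pi * r**3, rel=0.02
        )

    def test_error_decreases_with_resolution(self):
        """Halving the voxel size (32^3 -> 64^3 at proportional radius)
        shrinks the relative area and volume errors."""
        errs = {}
        for n, r in ((32, 10.0), (64, 20.0)):
            mesh = _sphere_mesh(n, r)
            errs[n] = (
                abs(mesh.area() / (4 * math.pi * r**2) - 1),
                abs(mesh.enclosed_volume() / (4 / 3 * math.pi * r**3) - 1),
            )
        assert errs[64][0] < errs[32][0]
        assert errs[64][1] < errs[32][1]

    def test_vertices_lie_on_cell_edges_at_iso_level(self):
        """Each weld vertex sits on a tetra edge (a segment between two
        grid corners, possibly a cell diagonal) where the linear
        interpolant between the corner values equals the iso value."""
        field = sphere_field((16, 16, 16), (7.5, 7.5, 7.5), 5.0)
        mesh = extract_isosurface(field, iso=0.0)
        data = field.voxels
        for v in mesh.vertices[::17]:  # sample
            x, y, z = v  # mm == voxel units here (unit spacing)
            lo = np.floor([x, y, z]).astype(int)
            matched = False
            for ca, cb in product(product((0, 1), repeat=3), repeat=2):
                a = lo + np.minimum(ca, 1)
                b = lo + np.minimum(cb, 1)
                d = b - a
                if not d.any():
                    continue
                # collinearity: v = a + t (b - a) with a single t in [0, 1]
                ts = [(v[k] - a[k]) / d[k] for k in range(3) if d[k] != 0]
                t = ts[0]
                if any(abs(tk - t) > 1e-9 for tk in ts):
                    continue
                if not (0.0 - 1e-9 <= t <= 1.0 + 1e-9):
                    continue
                off = [abs(v[k] - a[k]) > 1e-9 for k in range(3) if d[k] == 0]
                if any(off):
                    continue
                va = data[a[2], a[1], a[0]]
                vb = data[b[2], b[1], b[0]]
                if abs((1 - t) * va + t * vb - 0.0) < 1e-9:
                    matched = True
                    break
            assert matched

    def test_complement_invariance_flips_normals(self):
        """Inverting the field around the iso level keeps the geometry and
        reverses orientation."""
        field = sphere_field((16, 16, 16), (7.5, 7.5, 7.5), 5.0)
        mesh = extract_isosurface(field.voxels, iso=0.0)
        flipped = extract_isosurface(-field.voxels, iso=0.0)
        assert mesh.area() == pytest.approx(flipped.area(), rel=1e-9)
        assert mesh.enclosed_volume() == pytest.approx(
            -flipped.enclosed_volume(), rel=1e-6
        )

    def test_spacings_scale_coordinates(self):
        from wmh3d.volume import SliceStack

        field = sphere_field((16, 16, 16), (7.5, 7.5, 7.5), 5.0)
        stack = SliceStack(field.voxels, pixel_spacing=(1.0, 1.0),
                           slice_spacing=2.0)
        iso_mesh = extract_isosurface(stack, iso=0.0)
        unit_mesh = extract_isosurface(field.voxels, iso=0.0)
        # z (third mm coordinate) doubles, x/y unchanged
        assert iso_mesh.vertices[:, 2] == pytest.approx(
            2.0 * unit_mesh.vertices[:, 2]
        )
        assert iso_mesh.vertices[:, :2] == pytest.approx(unit_mesh.vertices[:, :2])

    def test_binary_lesion_mask_is_watertight(self):
        mask = np.zeros((10, 16, 16))
        mask[3:7, 5:11, 4:12] = 1.0
        mesh = extract_isosurface(mask, iso=0.5)
        assert mesh.n_triangles > 0
        assert mesh.is_watertight()
        assert mesh.enclosed_volume() > 0


# ---------------------------------------------------------------------------
# Mesh I/O
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def mesh():
    return _sphere_mesh(16, 5.0)


class TestMeshIO:
    @pytest.mark.parametrize("fmt", ["obj", "ply"])
    def test_indexed_round_trip_preserves_topology(self, tmp_path, mesh, fmt):
        path = write_mesh(mesh, tmp_path / f"m.{fmt}", fmt)
        back = read_mesh(path)
        assert back.n_triangles == mesh.n_triangles
        assert back.n_vertices == mesh.n_vertices
        assert back.vertices == pytest.approx(mesh.vertices, abs=1e-5)
        assert np.array_equal(back.triangles, mesh.triangles)

    def test_stl_round_trip_preserves_triangles(self, tmp_path, mesh):
        """Binary STL is a triangle soup: triangle count and per-triangle
        geometry survive, shared-vertex indexing does not."""
        path = write_mesh(mesh, tmp_path / "m.stl", "stl")
        back = read_mesh(path)
        assert back.n_triangles == mesh.n_triangles
        assert back.area() == pytest.approx(mesh.area(), rel=1e-6)
        got = np.sort(back.vertices[back.triangles].reshape(-1, 9), axis=0)
        want = np.sort(mesh.vertices[mesh.triangles].reshape(-1, 9), axis=0)
        assert got == pytest.approx(want, abs=1e-5)

    def test_stl_facet_count_by_independent_parse(self, tmp_path, mesh):
        path = write_mesh(mesh, tmp_path / "m.stl", "stl")
        raw = path.read_bytes()
        (count,) = struct.unpack("<I", raw[80:84])
        assert count == mesh.n_triangles
        assert len(raw) == 84 + 50 * count

    def test_empty_mesh_round_trip(self, tmp_path):
        empty = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
        path = write_mesh(empty, tmp_path / "e.stl", "stl")
        assert read_mesh(path).n_triangles == 0

    def test_unknown_format_rejected(self, tmp_path, mesh):
        with pytest.raises(ValueError, match="unknown mesh format"):
            write_mesh(mesh, tmp_path / "m.xyz", "xyz")
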