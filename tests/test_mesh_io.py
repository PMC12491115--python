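"""STL read/write, label sidecars, and surface sampling."""

import json
import struct

import numpy as np
import pytest

import odontomatch as om
from odontomatch.mesh_io import (STLParseError, Tissue, read_stl, sample_surface,
                                 sidecar_path, write_stl)

ASCII_TRIANGLE = """solid test
facet normal 0 0 1
outer loop
vertex 0 0 0
vertex 1 0 0
vertex 0 1 0
endloop
endfacet
endsolid test
"""


def small_mesh():
    """Two-triangle labeled mesh near the origin (binary STL keeps 1e-6)."""
    v = np.array([[0, 0, 0], [2, 0, 0], [0, 1, 0], [0, 0, 1.5]], float)
    f = np.array([[0, 1, 2], [0, 1, 3]])
    tissue = np.array([Tissue.TOOTH, Tissue.TOOTH, Tissue.GINGIVA, Tissue.OTHER],
                      np.int8)
    tooth = np.array([11, 11, 0, 0], np.int16)
    return om.LabeledMesh(v, f, tissue, tooth, frame_id="unit")


class TestReadWrite:
    def test_ascii_single_triangle(self, tmp_path):
        p = tmp_path / "tri.stl"
        p.write_text(ASCII_TRIANGLE)
        mesh = read_stl(p)
        assert mesh.n_vertices == 3
        assert mesh.n_faces == 1
        assert np.all(mesh.tissue == int(Tissue.OTHER))

    @pytest.mark.parametrize("dialect", ["ascii", "binary"])
    def test_roundtrip_small_mesh(self, tmp_path, dialect):
        m = small_mesh()
        p = tmp_path / f"m.{dialect}.stl"
        write_stl(m, p, dialect)
        back = read_stl(p)
        assert back.n_faces == m.n_faces
        # same vertex set within 1e-6 mm (order is canonical on both sides)
        a = m.vertices[np.lexsort(np.round(m.vertices, 9).T[::-1])]
        assert np.abs(np.sort(a, axis=0) - np.sort(back.vertices, axis=0)).max() < 1e-6

    @pytest.mark.parametrize("dialect,tol", [("ascii", 1e-12), ("binary", 5e-6)])
    def test_roundtrip_full_arch(self, tmp_path, default_arch, dialect, tol):
        # binary STL stores float32: ulp at ~35 mm coordinates is ~4e-6 mm
        p = tmp_path / "arch.stl"
        write_stl(default_arch, p, dialect)
        back = read_stl(p)
        assert back.n_faces == default_arch.n_faces
        assert back.n_vertices == default_arch.n_vertices
        a = np.sort(default_arch.vertices, axis=0)
        b = np.sort(back.vertices, axis=0)
        assert np.abs(a - b).max() < tol

    def test_sidecar_roundtrips_bit_exactly(self, tmp_path, default_arch):
        p = tmp_path / "arch.stl"
        write_stl(default_arch, p, "ascii")
        assert sidecar_path(p).exists()
        back = read_stl(p)
        # vertex order is canonical, so labels must align without reordering
        assert np.array_equal(np.sort(back.tooth_id), np.sort(default_arch.tooth_id))
        assert np.array_equal(np.sort(back.tissue), np.sort(default_arch.tissue))
        # tooth labels must sit on the same coordinates
        key_orig = {tuple(np.round(v, 6)): (int(t), int(d)) for v, t, d in
                    zip(default_arch.vertices, default_arch.tissue, default_arch.tooth_id)}
        for v, t, d in zip(back.vertices, back.tissue, back.tooth_id):
            assert key_orig[tuple(np.round(v, 6))] == (int(t), int(d))

    def test_no_sidecar_written_for_unlabeled(self, tmp_path):
        m = small_mesh()
        m.tissue[:] = int(Tissue.OTHER)
        m.tooth_id[:] = 0
        p = tmp_path / "plain.stl"
        write_stl(m, p, "binary")
        assert not sidecar_path(p).exists()

    def test_binary_layout_exact_size(self, tmp_path):
        m = om.LabeledMesh(np.eye(3), np.array([[0, 1, 2]]))
        p = tmp_path / "one.stl"
        write_stl(m, p, "binary")
        assert p.stat().st_size == 84 + 50

    def test_ascii_starts_with_solid(self, tmp_path):
        m = om.LabeledMesh(np.eye(3), np.array([[0, 1, 2]]))
        p = tmp_path / "one.stl"
        write_stl(m, p, "ascii")
        assert p.read_bytes().startswith(b"solid")

    def test_write_empty_mesh_rejected(self, tmp_path):
        m = om.LabeledMesh(np.empty((0, 3)), np.empty((0, 3), int))
        with pytest.raises(ValueError):
            write_stl(m, tmp_path / "e.stl", "ascii")

    def test_binary_triangle_count_mismatch(self, tmp_path):
        m = om.LabeledMesh(np.eye(3), np.array([[0, 1, 2]]))
        p = tmp_path / "bad.stl"
        write_stl(m, p, "binary")
        raw = bytearray(p.read_bytes())
        raw[80:84] = struct.pack("<I", 7)  # lie about the triangle count
        p.write_bytes(bytes(raw))
        with pytest.raises(STLParseError, match="7 triangles"):
            read_stl(p)

    def test_empty_solid_rejected(self, tmp_path):
        p = tmp_path / "empty.stl"
        p.write_text("solid nothing\nendsolid nothing\n")
        with pytest.raises(STLParseError):
            read_stl(p)

    def test_duplicate_soup_vertices_merged(self, tmp_path):
        # two triangles sharing an edge, written as disconnected soup
        body = ASCII_TRIANGLE.replace(
            "endsolid test", """facet normal 0 0 1
outer loop
vertex 1 0 0
vertex 0 1 0
vertex 1 1 0
endloop
endfacet
endsolid test""")
        p = tmp_path / "soup.stl"
        p.write_text(body)
        mesh = read_stl(p)
        assert mesh.n_vertices == 4  # 6 soup corners merge to 4
        assert mesh.n_faces == 2


class TestLabeledMeshInvariants:
    def test_face_index_out_of_range(self):
        with pytest.raises(ValueError):
            om.LabeledMesh(np.eye(3), np.array([[0, 1, 5]]))

    def test_face_repeating_vertex(self):
        with pytest.raises(ValueError):
            om.LabeledMesh(np.eye(3), np.array([[0, 1, 1]]))

    def test_tooth_id_requires_tooth_tissue(self):
        with pytest.raises(ValueError):
            om.LabeledMesh(np.eye(3), np.array([[0, 1, 2]]),
                           tissue=np.array([0, 0, 0]),
                           tooth_id=np.array([11, 0, 0]))

    def test_nonfinite_coordinates_rejected(self):
        v = np.eye(3)
        v[0, 0] = np.nan
        with pytest.raises(ValueError):
            om.LabeledMesh(v, np.array([[0, 1, 2]]))


class TestSampleSurface:
    def two_triangle_mesh(self):
        # areas 1 and 3 in the z=0 plane, distinct labels per triangle
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0],
                      [5, 0, 0], [7, 0, 0], [5, 3, 0]], float)
        f = np.array([[0, 1, 2], [3, 4, 5]])
        tissue = np.array([Tissue.GINGIVA] * 3 + [Tissue.TOOTH] * 3, np.int8)
        tooth = np.array([0, 0, 0, 11, 11, 11], np.int16)
        return om.LabeledMesh(v, f, tissue, tooth)

    def test_area_uniform_fractions(self):
        mesh = self.two_triangle_mesh()
        n = 40000
        cloud = sample_surface(mesh, n, seed=2)
        frac_large = np.mean(cloud.tissue == int(Tissue.TOOTH))
        sigma = np.sqrt(0.75 * 0.25 / n)
        assert abs(frac_large - 0.75) < 3 * sigma

    def test_points_lie_in_their_faces(self):
        mesh = self.two_triangle_mesh()
        cloud = sample_surface(mesh, 500, seed=4)
        v, f = mesh.vertices, mesh.faces
        for p in cloud.points:
            inside_any = False
            for tri in f:
                a, b, c = v[tri]
                # barycentric solve in the triangle plane
                M = np.column_stack([b - a, c - a])
                coef, res, *_ = np.linalg.lstsq(M, p - a, rcond=None)
                recon = a + M @ coef
                if (np.linalg.norm(recon - p) < 1e-9
                        and coef.min() > -1e-12 and coef.sum() < 1 + 1e-12):
                    inside_any = True
                    break
            assert inside_any

    def test_label_inheritance_majority_and_tie(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        f = np.array([[0, 1, 2]])
        two_tooth = om.LabeledMesh(v, f, np.array([1, 1, 2], np.int8),
                                   np.array([11, 11, 0], np.int16))
        cloud = sample_surface(two_tooth, 50, seed=0)
        assert np.all(cloud.tissue == int(Tissue.TOOTH))
        assert np.all(cloud.tooth_id == 11)
        all_distinct = om.LabeledMesh(v, f, np.array([0, 1, 2], np.int8),
                                      np.array([0, 11, 0], np.int16))
        cloud = sample_surface(all_distinct, 50, seed=0)
        assert np.all(cloud.tissue == int(Tissue.OTHER))  # tie -> OTHER
        assert np.all(cloud.tooth_id == 0)

    def test_zero_points_and_determinism(self, default_arch):
        assert len(sample_surface(default_arch, 0, seed=1)) == 0
        c1 = sample_surface(default_arch, 200, seed=9)
        c2 = sample_surface(default_arch, 200, seed=9)
        assert np.array_equal(c1.points, c2.points)
        assert np.array_equal(c1.tissue, c2.tissue)

    def test_all_degenerate_faces_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        mesh = om.LabeledMesh(v, np.array([[0, 1, 2]]))
        with pytest.raises(ValueError):
            sample_surface(mesh, 10, seed=0)
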