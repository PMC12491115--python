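"""STL mesh input/output with tissue-label sidecars, and surface point sampling.

Dental scans travel as STL triangle soup, which carries no attributes: tissue
labels (tooth vs gingiva) and FDI tooth identifiers therefore live in a JSON
sidecar file next to the STL (same stem, ``.labels.json`` extension), keyed by
vertex index.  All coordinates are millimetres — the intra-oral scanner
convention; STL has no unit metadata so the convention is documented, not
detected.

On read, duplicated soup vertices are merged (tolerance 1e-9 mm) into a
canonical, lexicographically ordered vertex array so that faces share indices
and sidecar labels align deterministically with the merged ordering.
"""

from __future__ import annotations

import io
import json
import struct
from dataclasses import dataclass, replace
from enum import IntEnum
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "Tissue",
    "LabeledMesh",
    "PointCloud",
    "STLParseError",
    "read_stl",
    "write_stl",
    "sample_surface",
    "sidecar_path",
]

#: vertices closer than 1e-9 mm are merged into one
MERGE_DECIMALS = 9


class Tissue(IntEnum):
    """Per-vertex tissue class."""

    OTHER = 0
    TOOTH = 1
    GINGIVA = 2


class STLParseError(ValueError):
    """Raised when an STL file cannot be parsed."""


def _as_float_array(x, name: str, shape_tail: tuple) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != len(shape_tail) + 1 or a.shape[1:] != shape_tail:
        raise ValueError(f"{name} must have shape (n, {shape_tail}), got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return a


@dataclass
class LabeledMesh:
    """Triangle surface mesh (mm) with per-vertex tissue labels.

    Parameters
    ----------
    vertices : (n, 3) float array, millimetres.
    faces : (m, 3) int array of vertex indices; no face repeats a vertex.
    tissue : (n,) array of :class:`Tissue` codes; defaults to all OTHER.
    tooth_id : (n,) int array of FDI two-digit tooth codes, 0 where the vertex
        is not part of a tooth.  Must be 0 wherever ``tissue != TOOTH``.
    frame_id : free-text coordinate-frame tag.
    """

    vertices: np.ndarray
    faces: np.ndarray
    tissue: np.ndarray | None = None
    tooth_id: np.ndarray | None = None
    frame_id: str = ""

    def __post_init__(self):
        self.vertices = _as_float_array(self.vertices, "vertices", (3,))
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError(f"faces must have shape (m, 3), got {self.faces.shape}")
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError("face index out of range")
        if self.faces.size:
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise ValueError("degenerate face repeats a vertex")
        if self.tissue is None:
            self.tissue = np.full(n, int(Tissue.OTHER), dtype=np.int8)
        else:
            self.tissue = np.asarray(self.tissue, dtype=np.int8)
            if self.tissue.shape != (n,):
                raise ValueError("tissue must have one entry per vertex")
        if self.tooth_id is None:
            self.tooth_id = np.zeros(n, dtype=np.int16)
        else:
            self.tooth_id = np.asarray(self.tooth_id, dtype=np.int16)
            if self.tooth_id.shape != (n,):
                raise ValueError("tooth_id must have one entry per vertex")
        if np.any((self.tissue != int(Tissue.TOOTH)) & (self.tooth_id != 0)):
            raise ValueError("tooth_id must be 0 wherever tissue != TOOTH")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def distinct_tooth_ids(self) -> np.ndarray:
        """Sorted array of FDI codes present on the mesh."""
        ids = np.unique(self.tooth_id)
        return ids[ids != 0]

    def transformed(self, transform) -> "LabeledMesh":
        """Mesh with vertices mapped through a rigid transform; labels kept."""
        return replace(self, vertices=transform.apply(self.vertices))

    def copy(self) -> "LabeledMesh":
        return LabeledMesh(
            self.vertices.copy(), self.faces.copy(),
            self.tissue.copy(), self.tooth_id.copy(), self.frame_id,
        )


@dataclass
class PointCloud:
    """Unstructured 3D points (mm) with optional tissue labels and tooth ids."""

    points: np.ndarray
    tissue: np.ndarray | None = None
    tooth_id: np.ndarray | None = None
    frame_id: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points contain non-finite coordinates")
        n = len(self.points)
        for name in ("tissue", "tooth_id"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != (n,):
                    raise ValueError(f"{name} must have one entry per point")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def has_labels(self) -> bool:
        return self.tissue is not None

    def select(self, index) -> "PointCloud":
        """Sub-cloud at the given indices/boolean mask, order preserved."""
        return PointCloud(
            self.points[index],
            None if self.tissue is None else self.tissue[index],
            None if self.tooth_id is None else self.tooth_id[index],
            self.frame_id,
        )

    def distinct_tooth_ids(self) -> np.ndarray:
        if self.tooth_id is None:
            return np.array([], dtype=int)
        ids = np.unique(self.tooth_id)
        return ids[ids != 0]


# ---------------------------------------------------------------------------
# canonical vertex merging
# ---------------------------------------------------------------------------

def _canonicalize(soup_vertices: np.ndarray, soup_faces: np.ndarray):
    """Merge near-duplicate vertices and order them deterministically.

    Vertices whose coordinates agree after rounding to ``MERGE_DECIMALS``
    decimals collapse to one, represented by the first occurrence's full
    precision coordinates; the merged array is sorted lexicographically by the
    rounded key so the ordering is reproducible across write/read cycles.
    Degenerate faces created by the merge are dropped.
    """
    key = np.round(soup_vertices, MERGE_DECIMALS)
    # np.unique sorts rows lexicographically -> deterministic canonical order
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    vertices = soup_vertices[first]
    faces = inverse[np.asarray(soup_faces, dtype=np.int64)]
    ok = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    return vertices, faces[ok], inverse


def sidecar_path(stl_path) -> Path:
    """Label sidecar path for an STL file (same stem, ``.labels.json``)."""
    p = Path(stl_path)
    return p.with_name(p.stem + ".labels.json")


_TISSUE_NAMES = {t.name: int(t) for t in Tissue}


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

def read_stl(path) -> LabeledMesh:
    """Read a binary or ASCII STL file into a :class:`LabeledMesh`.

    Labels default to all OTHER unless a sidecar label file (see
    :func:`sidecar_path`) sits next to the STL, in which case tissue labels
    and tooth ids are attached to the merged vertex ordering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = path.read_bytes()
    _validate_stl_bytes(raw, path)
    try:
        mesh = trimesh.load(io.BytesIO(raw), file_type="stl", process=False)
    except Exception as exc:  # pragma: no cover - trimesh message varies
        raise STLParseError(f"{path}: cannot parse STL ({exc})") from exc
    if mesh.is_empty or len(mesh.faces) == 0:
        raise STLParseError(f"{path}: STL contains no triangles (empty solid)")
    vertices, faces, _ = _canonicalize(np.asarray(mesh.vertices, float),
                                       np.asarray(mesh.faces))
    if len(faces) == 0:
        raise STLParseError(f"{path}: all triangles degenerate after vertex merge")
    tissue = tooth_id = None
    frame_id = ""
    sc = sidecar_path(path)
    if sc.exists():
        data = json.loads(sc.read_text())
        tissue_raw = data["tissue"]
        if len(tissue_raw) != len(vertices):
            raise ValueError(
                f"{sc}: sidecar has {len(tissue_raw)} labels for "
                f"{len(vertices)} merged vertices")
        tissue = np.array([_TISSUE_NAMES[t] if isinstance(t, str) else int(t)
                           for t in tissue_raw], dtype=np.int8)
        tooth_id = np.asarray(data.get("tooth_id", np.zeros(len(vertices))), dtype=np.int16)
        frame_id = data.get("frame_id", "")
    return LabeledMesh(vertices, faces, tissue, tooth_id, frame_id)


def _validate_stl_bytes(raw: bytes, path) -> None:
    """Cheap structural validation before handing the bytes to the parser."""
    if len(raw) == 0:
        raise STLParseError(f"{path}: empty file")
    head = raw[:5].lower()
    if len(raw) >= 84:
        (count,) = struct.unpack("<I", raw[80:84])
        expected = 84 + 50 * count
        if expected == len(raw):
            return  # well-formed binary layout
        if head != b"solid":
            raise STLParseError(
                f"{path}: binary STL declares {count} triangles "
                f"(expects {expected} bytes) but file is {len(raw)} bytes; "
                "mismatch at byte 80")
    if head != b"solid":
        raise STLParseError(f"{path}: not an STL file (no 'solid' header, "
                            "no valid binary layout)")


def write_stl(mesh: LabeledMesh, path, dialect: str = "binary") -> None:
    """Write a mesh as STL plus, when any label is set, a JSON label sidecar.

    The mesh is canonicalized (vertex merge + deterministic ordering) before
    export so that sidecar labels match the vertex order :func:`read_stl`
    reconstructs.  ``dialect`` is ``"binary"`` (84 + 50·m bytes) or
    ``"ascii"``.
    """
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"dialect must be 'binary' or 'ascii', got {dialect!r}")
    if mesh.n_faces == 0 or mesh.n_vertices == 0:
        raise ValueError("refusing to write an empty mesh")
    path = Path(path)
    vertices, faces, inverse = _canonicalize(mesh.vertices, mesh.faces)
    # carry labels over to the canonical ordering (first occurrence wins)
    tissue = np.full(len(vertices), int(Tissue.OTHER), dtype=np.int8)
    tooth = np.zeros(len(vertices), dtype=np.int16)
    tissue[inverse] = mesh.tissue
    tooth[inverse] = mesh.tooth_id
    tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    data = tm.export(file_type="stl" if dialect == "binary" else "stl_ascii")
    if isinstance(data, str):
        data = data.encode()
    path.write_bytes(data)
    if np.any(tissue != int(Tissue.OTHER)) or np.any(tooth != 0):
        payload = {
            "tissue": [Tissue(int(t)).name for t in tissue],
            "tooth_id": [int(t) for t in tooth],
            "frame_id": mesh.frame_id,
        }
        sidecar_path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# surface sampling
# ---------------------------------------------------------------------------

def sample_surface(mesh: LabeledMesh, n_points: int, seed: int) -> PointCloud:
    """Draw ``n_points`` area-uniform samples from the mesh surface.

    Each sample inherits the tissue label held by the majority of its face's
    vertices (three-way ties resolve to OTHER — never invent TOOTH), and the
    tooth id shared by at least two of the face's vertices (else 0).
    Deterministic for a fixed seed.
    """
    if n_points < 0:
        raise ValueError("n_points must be >= 0")
    v, f = mesh.vertices, mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    total = areas.sum()
    if total <= 0:
        raise ValueError("all faces are degenerate (zero area)")
    if n_points == 0:
        return PointCloud(np.empty((0, 3)), np.empty(0, np.int8),
                          np.empty(0, np.int16), mesh.frame_id)
    rng = np.random.default_rng(seed)
    face_idx = rng.choice(len(f), size=n_points, p=areas / total)
    r1 = np.sqrt(rng.random(n_points))
    r2 = rng.random(n_points)
    a, b, c = v[f[face_idx, 0]], v[f[face_idx, 1]], v[f[face_idx, 2]]
    pts = (1 - r1)[:, None] * a + (r1 * (1 - r2))[:, None] * b + (r1 * r2)[:, None] * c

    tri_tissue = mesh.tissue[f[face_idx]]          # (n, 3)
    tri_tooth = mesh.tooth_id[f[face_idx]]
    tissue = np.full(n_points, int(Tissue.OTHER), dtype=np.int8)
    tooth = np.zeros(n_points, dtype=np.int16)
    for col_a, col_b in ((0, 1), (0, 2), (1, 2)):
        agree = tri_tissue[:, col_a] == tri_tissue[:, col_b]
        tissue[agree] = tri_tissue[agree, col_a]
        t_agree = agree & (tri_tooth[:, col_a] == tri_tooth[:, col_b])
        tooth[t_agree] = tri_tooth[t_agree, col_a]
    tooth[tissue != int(Tissue.TOOTH)] = 0
    return PointCloud(pts, tissue, tooth, mesh.frame_id)
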