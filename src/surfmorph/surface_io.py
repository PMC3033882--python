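"""Reading and writing surfaces, overlays, labels and volumes.

Binary surface and overlay files use the FreeSurfer dialects (big-endian
triangle-file and new-format "curv"), read and written through
``nibabel.freesurfer``; labels use the FreeSurfer ASCII label layout.
A plain-text OFF reader/writer is provided as a fixture-friendly fallback.
"""
from __future__ import annotations

import struct
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
from nibabel.freesurfer import io as fsio
from scipy.spatial import cKDTree

from .errors import ConsistencyError, FormatError, ParseError
from .mesh import IntensityVolume, LesionLabel, TriangleMesh

__all__ = [
    "read_surface",
    "write_surface",
    "read_overlay",
    "write_overlay",
    "read_label",
    "write_label",
    "read_off",
    "write_off",
    "load_volume",
    "save_volume",
    "project_voxel_mask_to_label",
    "close_label",
]

PathLike = Union[str, Path]

_TRIANGLE_MAGIC = b"\xff\xff\xfe"


def read_surface(path: PathLike) -> TriangleMesh:
    """Read a surface mesh (FreeSurfer binary triangle file, or OFF text)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as f:
        head = f.read(3)
    if head.startswith(b"OFF"):
        return read_off(path)
    if head != _TRIANGLE_MAGIC:
        raise FormatError(
            f"{path}: magic bytes {head!r} do not match the binary "
            "triangle-surface format"
        )
    try:
        coords, faces = fsio.read_geometry(str(path))
    except (ValueError, struct.error, EOFError, OSError) as exc:
        raise ParseError(f"{path}: truncated or malformed surface file: {exc}")
    return TriangleMesh(coords, faces)


def write_surface(path: PathLike, mesh: TriangleMesh) -> None:
    """Write a mesh as a binary triangle-format surface (geometry-stable)."""
    fsio.write_geometry(str(path), mesh.vertices, mesh.faces)


def read_off(path: PathLike) -> TriangleMesh:
    """Read the plain-text OFF fallback format."""
    tokens: list[str] = []
    with open(path) as f:
        for line in f:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if not tokens or tokens[0] != "OFF":
        raise FormatError(f"{path}: not an OFF file")
    try:
        nv, nf = int(tokens[1]), int(tokens[2])
        pos = 4  # skip edge count
        flat = [float(t) for t in tokens[pos:pos + 3 * nv]]
        vertices = np.array(flat, float).reshape(nv, 3)
        pos += 3 * nv
        faces = []
        for _ in range(nf):
            k = int(tokens[pos])
            if k != 3:
                raise ParseError(f"{path}: only triangular faces supported")
            faces.append([int(t) for t in tokens[pos + 1:pos + 4]])
            pos += 1 + k
        return TriangleMesh(vertices, np.array(faces, int).reshape(nf, 3))
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}: malformed OFF file: {exc}")


def write_off(path: PathLike, mesh: TriangleMesh) -> None:
    with open(path, "w") as f:
        f.write("OFF\n")
        f.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for v in mesh.vertices:
            f.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for face in mesh.faces:
            f.write(f"3 {face[0]} {face[1]} {face[2]}\n")


def read_overlay(path: PathLike, n_vertices: int,
                 measure_name: str = "other", units: str = ""):
    """Read a per-vertex overlay (new-format binary "curv" dialect)."""
    from .mesh import VertexOverlay

    try:
        values = fsio.read_morph_data(str(path))
    except (ValueError, struct.error, EOFError) as exc:
        raise ParseError(f"{path}: malformed overlay file: {exc}")
    if len(values) != n_vertices:
        raise ConsistencyError(
            f"{path}: overlay has {len(values)} values but the mesh has "
            f"{n_vertices} vertices"
        )
    return VertexOverlay(measure_name, np.asarray(values, float), units)


def write_overlay(path: PathLike, overlay) -> None:
    fsio.write_morph_data(str(path), overlay.values.astype(np.float32))


def read_label(path: PathLike, n_vertices: int,
               source: str = "manual_tracing") -> LesionLabel:
    """Read an ASCII label: one comment line, a count line, then
    ``index x y z value`` rows."""
    with open(path) as f:
        lines = [ln.rstrip("\n") for ln in f]
    body = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    if not body:
        raise ParseError(f"{path}: empty label file")
    try:
        count = int(body[0].split()[0])
    except ValueError:
        raise ParseError(f"{path}: missing vertex-count line")
    rows = body[1:]
    if len(rows) != count:
        raise ParseError(
            f"{path}: header declares {count} vertices, found {len(rows)} rows"
        )
    indices = []
    for ln in rows:
        parts = ln.split()
        if len(parts) < 5:
            raise ParseError(f"{path}: malformed label row: {ln!r}")
        try:
            idx = int(parts[0])
            [float(p) for p in parts[1:5]]
        except ValueError:
            raise ParseError(f"{path}: malformed label row: {ln!r}")
        indices.append(idx)
    arr = np.asarray(indices, dtype=np.int64)
    if len(np.unique(arr)) != len(arr):
        raise ConsistencyError(f"{path}: duplicate vertex indices in label")
    if arr.size and (arr.min() < 0 or arr.max() >= n_vertices):
        raise ConsistencyError(
            f"{path}: label vertex index out of range for a mesh of "
            f"{n_vertices} vertices"
        )
    return LesionLabel(arr, source=source)


def write_label(path: PathLike, label: LesionLabel,
                mesh: TriangleMesh | None = None) -> None:
    """Write an ASCII label; vertex coordinates come from ``mesh`` if given."""
    idx = label.vertex_indices
    coords = (mesh.vertices[idx] if mesh is not None
              else np.zeros((len(idx), 3)))
    with open(path, "w") as f:
        f.write("#!ascii label, surfmorph\n")
        f.write(f"{len(idx)}\n")
        for i, (x, y, z) in zip(idx, coords):
            f.write(f"{i}  {x:.6f}  {y:.6f}  {z:.6f} 0.000000\n")


def load_volume(path: PathLike) -> IntensityVolume:
    img = nib.load(str(path))
    return IntensityVolume(np.asarray(img.dataobj, dtype=np.float64),
                           img.affine)


def save_volume(path: PathLike, volume: IntensityVolume) -> None:
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), volume.affine),
             str(path))


def project_voxel_mask_to_label(mesh: TriangleMesh, mask: IntensityVolume,
                                rings: int = 1) -> LesionLabel:
    """Project a binary voxel mask onto the surface.

    Each nonzero voxel is assigned to its nearest vertex (Euclidean distance
    of the voxel center, ties broken by lowest vertex index), and the
    resulting label is morphologically closed to fill sub-voxel gaps.
    """
    ijk = np.argwhere(mask.data != 0)
    if ijk.size == 0:
        return LesionLabel(np.empty(0, dtype=np.int64), source="projected")
    centers = mask.voxel_to_mm(ijk.astype(float))
    tree = cKDTree(mesh.vertices)
    k = min(8, mesh.n_vertices)
    dists, idx = tree.query(centers, k=k)
    dists = np.atleast_2d(dists)
    idx = np.atleast_2d(idx)
    tol = 1e-9
    nearest = np.empty(len(centers), dtype=np.int64)
    for row in range(len(centers)):
        tie = idx[row][dists[row] <= dists[row, 0] + tol]
        nearest[row] = tie.min()
    label = LesionLabel(np.unique(nearest), source="projected")
    if rings >= 1:
        label = close_label(mesh, label, rings=rings)
        label.source = "projected"
    return label


def close_label(mesh: TriangleMesh, label: LesionLabel,
                rings: int = 1) -> LesionLabel:
    """Morphological closing on the vertex graph: dilate then erode by
    ``rings`` one-ring steps. Extensive (result contains the input) and
    idempotent at fixed ``rings``."""
    if rings < 1:
        raise ValueError("rings must be >= 1")
    if len(label) == 0:
        return LesionLabel(np.empty(0, dtype=np.int64), source=label.source)
    adj = mesh.adjacency
    m = label.mask(mesh.n_vertices)
    for _ in range(rings):
        m = m | (adj @ m > 0)
    for _ in range(rings):
        m = m & ~(adj @ (~m) > 0)
    closed = np.flatnonzero(m | label.mask(mesh.n_vertices))
    return LesionLabel(closed, source=label.source)
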