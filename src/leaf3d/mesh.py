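"""Triangle meshing of leaf grids and Sqrt3 subdivision.

Adjacent points in each row and column are joined into quadrilaterals, each
split into two triangles along a fixed diagonal (row r, col c) -> (row r+1,
col c+1); the last full row is fanned to the tip point with four triangles.
An n-row grid therefore yields 5n + 1 vertices and 8(n - 1) + 4 faces, a
topological disk.

The raw mesh carries the trait computations (3D leaf area in particular).
For display a Kobbelt Sqrt3 subdivision refines it: each step inserts a
vertex at every face centroid, splits each face 1 -> 3, flips the original
interior edges, and relaxes old interior vertices; boundary vertices are held
fixed so the digitized margin — the signal — never shrinks.  Each step
triples the face count and adds one vertex per previous face.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import Leaf3DError, TopologyError
from .grid import LeafPointGrid, growth_direction


@dataclass
class LeafMesh:
    vertices: np.ndarray
    faces: np.ndarray
    subdivision_level: int = 0

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def edges(self) -> set[tuple[int, int]]:
        es: set[tuple[int, int]] = set()
        for a, b, c in self.faces:
            for u, v in ((a, b), (b, c), (c, a)):
                es.add((min(u, v), max(u, v)))
        return es

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces


def triangle_areas(mesh: LeafMesh) -> np.ndarray:
    """Unsigned area of every facet (half cross-product magnitude)."""
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def mesh_area(mesh: LeafMesh) -> float:
    return float(triangle_areas(mesh).sum())


def build_triangle_mesh(grid: LeafPointGrid) -> LeafMesh:
    """Quad-split triangle mesh of a leaf grid, wound adaxial-side-out.

    Vertex r*5 + c is grid row r column c; the tip is the last vertex.  The
    winding of all faces is flipped together if the basal band's mean facet
    normal opposes the plant growth direction, so face normals agree with the
    oriented adaxial side at the base.
    """
    n = grid.n_rows
    vertices = np.vstack([grid.rows.reshape(-1, 3), grid.tip[None, :]])
    faces = []
    for r in range(n - 1):
        for c in range(4):
            a = r * 5 + c
            b = r * 5 + c + 1
            d = (r + 1) * 5 + c + 1
            e = (r + 1) * 5 + c
            faces.append((a, b, d))  # diagonal a -> d, fixed for all quads
            faces.append((a, d, e))
    tip = 5 * n
    base = (n - 1) * 5
    for c in range(4):
        faces.append((base + c, base + c + 1, tip))
    faces = np.asarray(faces, dtype=np.int64)
    mesh = LeafMesh(vertices=vertices, faces=faces, subdivision_level=0)
    # orient winding toward the adaxial side at the base
    basal = triangle_normals(mesh, np.arange(8))
    g = growth_direction(grid)
    if float(basal.sum(axis=0) @ g) < 0:
        mesh.faces = faces[:, (0, 2, 1)]
    return mesh


def triangle_normals(mesh: LeafMesh, idx: np.ndarray | None = None) -> np.ndarray:
    faces = mesh.faces if idx is None else mesh.faces[idx]
    v = mesh.vertices
    nrm = np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]])
    return nrm


def _edge_faces(faces: np.ndarray) -> dict[tuple[int, int], list[int]]:
    ef: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            ef.setdefault((min(u, v), max(u, v)), []).append(fi)
    return ef


def sqrt3_subdivide(mesh: LeafMesh, steps: int = 1) -> LeafMesh:
    """Kobbelt Sqrt3 subdivision with fixed boundary, ``steps`` times.

    Deterministic: identical input gives bit-identical output.  Raises
    :class:`TopologyError` on non-manifold input (an edge shared by more than
    two faces).
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    out = LeafMesh(mesh.vertices.copy(), mesh.faces.copy(), mesh.subdivision_level)
    for _ in range(steps):
        out = _sqrt3_once(out)
    return out


def _sqrt3_once(mesh: LeafMesh) -> LeafMesh:
    verts, faces = mesh.vertices, mesh.faces
    nv, nf = len(verts), len(faces)
    ef = _edge_faces(faces)
    if any(len(fs) > 2 for fs in ef.values()):
        raise TopologyError("non-manifold edge: shared by more than two faces")

    boundary_vertices: set[int] = set()
    neighbors: dict[int, set[int]] = {i: set() for i in range(nv)}
    for (u, v), fs in ef.items():
        neighbors[u].add(v)
        neighbors[v].add(u)
        if len(fs) == 1:
            boundary_vertices.update((u, v))

    centroids = verts[faces].mean(axis=1)

    # relax old interior vertices with the valence-dependent Sqrt3 weights
    new_old = verts.copy()
    for i in range(nv):
        if i in boundary_vertices or not neighbors[i]:
            continue
        k = len(neighbors[i])
        alpha = (4.0 - 2.0 * math.cos(2.0 * math.pi / k)) / 9.0
        ring = verts[sorted(neighbors[i])].mean(axis=0)
        new_old[i] = (1.0 - alpha) * verts[i] + alpha * ring

    new_vertices = np.vstack([new_old, centroids])

    # directed-edge bookkeeping: which face owns edge (a, b) in that order
    directed: dict[tuple[int, int], int] = {}
    for fi, (a, b, c) in enumerate(faces):
        directed[(a, b)] = fi
        directed[(b, c)] = fi
        directed[(c, a)] = fi

    new_faces: list[tuple[int, int, int]] = []
    for (u, v), fs in ef.items():
        if len(fs) == 1:
            fi = fs[0]
            a, b = (u, v) if (u, v) in directed and directed[(u, v)] == fi else (v, u)
            new_faces.append((a, b, nv + fi))  # boundary: plain 1->3 corner
        else:
            f1 = directed.get((u, v))
            if f1 is None or f1 not in fs:
                u, v = v, u
                f1 = directed[(u, v)]
            f2 = fs[0] if fs[1] == f1 else fs[1]
            z1, z2 = nv + f1, nv + f2
            # flipped pair across the old edge (u, v)
            new_faces.append((z1, u, z2))
            new_faces.append((z2, v, z1))
    return LeafMesh(vertices=new_vertices,
                    faces=np.asarray(new_faces, dtype=np.int64),
                    subdivision_level=mesh.subdivision_level + 1)


def to_trimesh(mesh: LeafMesh) -> trimesh.Trimesh:
    return trimesh.Trimesh(vertices=mesh.vertices.copy(),
                           faces=mesh.faces.copy(), process=False)


def export_mesh(mesh: LeafMesh, path, fmt: str | None = None) -> None:
    """Write ASCII OBJ (1-based indices) or ASCII PLY (0-based indices)."""
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower() if "." in path else ""
    fmt = fmt.lower()
    tm = to_trimesh(mesh)
    if fmt == "obj":
        tm.export(path, file_type="obj", include_normals=False)
    elif fmt == "ply":
        tm.export(path, file_type="ply", encoding="ascii")
    else:
        raise Leaf3DError(f"unknown mesh format {fmt!r}: use 'obj' or 'ply'")
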