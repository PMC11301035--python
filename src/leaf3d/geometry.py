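"""Local surface decomposition, plane fitting and normal orientation.

Three consecutive acquisition rows (15 points) form one *local leaf surface*
(patch); an n-row blade yields n - 2 patches, the first and last rows serving
only as patch members.  Each patch gets a total-least-squares plane whose
normal stands in for the local surface normal.  Normals are then given a
consistent sign: the basal normal points along the plant's growth direction
(adaxial side up) and each subsequent normal is flipped if it turns more than
90 degrees from its predecessor, so the oriented normal field is continuous
from base to tip.

Strongly rolled or twisted blades can defeat the 15-point fit.  A per-leaf
gate on the first-pass traits (BST > r1, |OBIA_avg - 180| > r2 or
OBIA_sd > r3, defaults 1.5 / 50.0 / 65.0) switches the whole leaf to a
fallback in which every patch plane is refit from its six bilateral edge
points only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateGeometryError, ValidationError
from .grid import COL_EDGE_LEFT, COL_EDGE_RIGHT, COL_VEIN, LeafPointGrid, validate_grid

#: eigenvalue-ratio below which a point set is treated as collinear
DEGENERACY_EIGEN_RATIO = 1e-12


@dataclass(frozen=True)
class Plane:
    """Oriented plane: a point on it plus a unit normal."""

    origin: np.ndarray
    normal: np.ndarray

    def flipped(self) -> "Plane":
        return Plane(self.origin, -self.normal)


@dataclass(frozen=True)
class FallbackThresholds:
    """Eq.-style gate thresholds: r1 on BST, r2 on |OBIA_avg - 180| (deg),
    r3 on OBIA_sd (deg)."""

    r1: float = 1.5
    r2: float = 50.0
    r3: float = 65.0

    def __post_init__(self):
        if min(self.r1, self.r2, self.r3) <= 0:
            raise ValueError("fallback thresholds must be positive")


DEFAULT_THRESHOLDS = FallbackThresholds()


@dataclass
class LocalPatch:
    """A 3-row, 15-point local leaf surface.

    ``points`` has shape (3, 5, 3): rows i..i+2 of the grid.  ``center`` is
    the middle row's vein point, which anchors the plane origin.  ``plane``
    is None until fitted.
    """

    index: int
    points: np.ndarray
    center: np.ndarray
    plane: Plane | None = None
    fallback: bool = False

    @property
    def edge_points(self) -> np.ndarray:
        """The six bilateral margin points (columns 0 and 4 of the 3 rows)."""
        return self.points[:, (COL_EDGE_LEFT, COL_EDGE_RIGHT), :].reshape(6, 3)


def decompose_patches(grid: LeafPointGrid) -> list[LocalPatch]:
    """Split an n-row grid into its n - 2 overlapping local patches (planes unset)."""
    violations = validate_grid(grid)
    if violations:
        raise ValidationError(grid.leaf_id, violations)
    n = grid.n_rows
    patches = []
    for i in range(n - 2):
        pts = grid.rows[i:i + 3].copy()
        patches.append(LocalPatch(index=i, points=pts,
                                  center=pts[1, COL_VEIN].copy()))
    return patches


def fit_plane_tls(points: np.ndarray, anchor: np.ndarray | None = None,
                  what: str = "point set") -> Plane:
    """Total-least-squares plane of a point set.

    Minimizes the sum of squared orthogonal distances (SVD of the centered
    coordinates; the normal is the right singular vector of least singular
    value).  The returned origin is the orthogonal projection of ``anchor``
    (default: the centroid) onto the plane, so the anchor's residual is
    absorbed into the origin, not the normal.  Normal sign is unspecified.
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    # scatter eigenvalues are s**2; collinear = two vanishing plane directions
    if s[0] == 0.0 or (s[1] / s[0]) ** 2 < DEGENERACY_EIGEN_RATIO:
        raise DegenerateGeometryError(f"{what}: points are collinear or coincident")
    normal = vt[2] / np.linalg.norm(vt[2])
    if anchor is None:
        origin = centroid
    else:
        anchor = np.asarray(anchor, dtype=float)
        origin = anchor - np.dot(anchor - centroid, normal) * normal
    return Plane(origin=origin, normal=normal)


def fit_patch_plane(patch: LocalPatch) -> Plane:
    """TLS plane of the patch's 15 points, origin anchored at the patch center."""
    return fit_plane_tls(patch.points.reshape(15, 3), anchor=patch.center,
                         what=f"patch {patch.index}")


def fit_all_planes(patches: list[LocalPatch]) -> list[LocalPatch]:
    return [replace(p, plane=fit_patch_plane(p)) for p in patches]


def orient_normals(patches: list[LocalPatch], growth: np.ndarray) -> list[LocalPatch]:
    """Give all patch normals a consistent adaxial sign.

    The basal normal is flipped to have a non-negative component along the
    growth direction (tie at exactly zero broken by the mean edge-point offset
    along the candidate normal); then, walking base to tip, each normal is
    flipped if its dot product with the previous oriented normal is negative,
    limiting the turn between neighbours to 90 degrees.  Idempotent.
    """
    if not patches or any(p.plane is None for p in patches):
        raise ValueError("all patch planes must be fitted before orientation")
    growth = np.asarray(growth, dtype=float)
    out: list[LocalPatch] = []
    first = patches[0]
    n0 = first.plane.normal
    d = float(np.dot(n0, growth))
    if d == 0.0:
        offset = float(np.mean((first.edge_points - first.plane.origin) @ n0))
        if offset == 0.0:
            raise DegenerateGeometryError(
                f"patch {first.index}: normal orientation is ambiguous")
        d = offset
    plane0 = first.plane if d > 0 else first.plane.flipped()
    out.append(replace(first, plane=plane0))
    for p in patches[1:]:
        prev = out[-1].plane.normal
        pl = p.plane if float(np.dot(prev, p.plane.normal)) >= 0 else p.plane.flipped()
        out.append(replace(p, plane=pl))
    return out


def needs_fallback(record, thresholds: FallbackThresholds = DEFAULT_THRESHOLDS) -> bool:
    """Per-leaf gate on first-pass traits deciding the edge-point refit.

    ``record`` is any object with BST, OBIA_avg and OBIA_sd attributes.
    """
    return (record.BST > thresholds.r1
            or abs(record.OBIA_avg - 180.0) > thresholds.r2
            or record.OBIA_sd > thresholds.r3)


def fallback_normals(patches: list[LocalPatch], growth: np.ndarray) -> list[LocalPatch]:
    """Refit every patch plane from its six bilateral edge points and re-orient.

    The patch center stays the origin anchor, so downstream distances remain
    referenced to the vein.  Idempotent (the edge points do not change).
    """
    refit = []
    for p in patches:
        plane = fit_plane_tls(p.edge_points, anchor=p.center,
                              what=f"patch {p.index} (edge fallback)")
        refit.append(replace(p, plane=plane, fallback=True))
    return orient_normals(refit, growth)


def project_to_plane(p: np.ndarray, plane: Plane) -> np.ndarray:
    """Orthogonal projection of a point onto a plane."""
    p = np.asarray(p, dtype=float)
    return p - np.dot(p - plane.origin, plane.normal) * plane.normal


def project_vector(v: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Component of ``v`` perpendicular to ``normal`` (unit normal assumed)."""
    v = np.asarray(v, dtype=float)
    return v - np.dot(v, normal) * np.asarray(normal, dtype=float)
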