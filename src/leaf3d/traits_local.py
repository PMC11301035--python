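"""Per-patch local geometry and the ten local-feature traits.

For each local patch (center P_i on the vein, oriented unit normal N_i) the
local vein tangent T_i runs to the next row's vein point; its in-plane part
T_i' defines the cross-section plane F_i^T through P_i.  Within F_i^T:

* the blade-included angle theta_i is the angle between the projected margin
  points of the middle row as seen from P_i, mapped to (0, 360) by which side
  of the patch plane the margins sit on (adaxial => inner rolling, < 180);
* the local self-twisting angle phi_i is the signed in-plane angle from N_i
  to the projection of the next patch's normal, counterclockwise (right-hand
  rule about T_i', looking base to tip) positive.

Margin-to-plane signed distances d feed blade planarity (mean |d|) and margin
amplitude (mean absolute difference of consecutive same-side d).  Aggregation
over the blade yields BIA_avg / OBIA_avg / OBIA_sd, OBST / BST / OBST_sd,
BP / BP_sd and MA_avg / MA_sd; all *_sd are sample (n-1) standard deviations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, InsufficientDataError
from .geometry import (
    DEFAULT_THRESHOLDS,
    FallbackThresholds,
    LocalPatch,
    Plane,
    decompose_patches,
    fallback_normals,
    fit_all_planes,
    needs_fallback,
    orient_normals,
    project_to_plane,
)
from .grid import (
    COL_EDGE_LEFT,
    COL_EDGE_RIGHT,
    COL_VEIN,
    LeafPointGrid,
    TraitRecord,
    growth_direction,
)
from .traits_global import DEFAULT_IA_ROWS, inclination_angle, leaf_area_3d, leaf_length

log = logging.getLogger(__name__)

_EPS = 1e-9


def _sample_sd(values) -> float:
    return float(np.std(np.asarray(values, dtype=float), ddof=1))


@dataclass(frozen=True)
class CrossSectionFrame:
    """In-plane vein tangent T' and the cross-section plane F^T it defines."""

    tangent: np.ndarray       # T', unit, lies in the patch plane
    section_plane: Plane      # through the patch center, normal = T'


def cross_section_frame(patch: LocalPatch, next_vein_point: np.ndarray) -> CrossSectionFrame:
    """Project the local vein tangent into the patch plane; build F^T from it."""
    normal = patch.plane.normal
    t = np.asarray(next_vein_point, dtype=float) - patch.center
    t_in = t - np.dot(t, normal) * normal
    nt = float(np.linalg.norm(t_in))
    if nt < _EPS * max(float(np.linalg.norm(t)), _EPS):
        raise DegenerateGeometryError(
            f"patch {patch.index}: vein tangent parallel to the patch normal")
    t_unit = t_in / nt
    return CrossSectionFrame(tangent=t_unit,
                             section_plane=Plane(origin=patch.center.copy(),
                                                 normal=t_unit))


def local_bia(patch: LocalPatch, frame: CrossSectionFrame) -> float:
    """Oriented blade-included angle theta_i in degrees, in (0, 360).

    The middle row's two margin points are projected into the cross-section
    plane; the unsigned angle they subtend at the patch center is kept as-is
    when the margins sit on (or straddle symmetrically) the adaxial side of
    the patch plane (inner rolling) and reflected to 360 - gamma otherwise.
    """
    p_left = patch.points[1, COL_EDGE_LEFT]
    p_right = patch.points[1, COL_EDGE_RIGHT]
    a = project_to_plane(p_left, frame.section_plane) - patch.center
    b = project_to_plane(p_right, frame.section_plane) - patch.center
    na, nb = float(np.linalg.norm(a)), float(np.linalg.norm(b))
    if na < _EPS or nb < _EPS:
        raise DegenerateGeometryError(
            f"patch {patch.index}: margin projection coincides with the vein point")
    gamma = math.degrees(math.atan2(float(np.linalg.norm(np.cross(a, b))),
                                    float(np.dot(a, b))))
    # side test is vein-centered, like the angle itself: the blade is inner
    # rolling when the margins rise from the vein toward the adaxial normal
    n = patch.plane.normal
    side = 0.5 * (float(np.dot(p_left - patch.center, n))
                  + float(np.dot(p_right - patch.center, n)))
    return gamma if side >= 0.0 else 360.0 - gamma


def bia_traits(thetas) -> tuple[float, float, float]:
    """(OBIA_avg, BIA_avg, OBIA_sd) from the per-patch oriented angles."""
    thetas = np.asarray(thetas, dtype=float)
    if thetas.size < 2:
        raise InsufficientDataError("need at least 2 local blade angles")
    folded = np.where(thetas > 180.0, 360.0 - thetas, thetas)
    return float(thetas.mean()), float(folded.mean()), _sample_sd(thetas)


def local_twist(patch: LocalPatch, patch_next: LocalPatch,
                frame: CrossSectionFrame) -> float:
    """Signed local self-twisting angle phi_i (deg), |phi| < 180."""
    n_i = patch.plane.normal
    n_next = patch_next.plane.normal
    t = frame.tangent
    n_proj = n_next - np.dot(n_next, t) * t
    if float(np.linalg.norm(n_proj)) < _EPS:
        raise DegenerateGeometryError(
            f"patch {patch.index}: next normal parallel to the vein tangent")
    return math.degrees(math.atan2(float(np.dot(np.cross(n_i, n_proj), t)),
                                   float(np.dot(n_i, n_proj))))


def twist_traits(phis) -> tuple[float, float, float]:
    """(OBST, BST, OBST_sd): OBST = sum(phi)/180, BST = |OBST|."""
    phis = np.asarray(phis, dtype=float)
    if phis.size < 2:
        raise InsufficientDataError("need at least 2 local twist angles")
    obst = float(phis.sum()) / 180.0
    return obst, abs(obst), _sample_sd(phis)


def edge_distances(patch: LocalPatch) -> tuple[float, float]:
    """Signed distances (cm) of the middle row's margin points to the patch
    plane; positive on the adaxial (+N) side."""
    n = patch.plane.normal
    o = patch.plane.origin
    d_left = float(np.dot(patch.points[1, COL_EDGE_LEFT] - o, n))
    d_right = float(np.dot(patch.points[1, COL_EDGE_RIGHT] - o, n))
    return d_left, d_right


def planarity_traits(d_all, signed_mean: bool = False) -> tuple[float, float]:
    """(BP, BP_sd) over the 2(n-2) margin distances.

    BP is the mean absolute distance (the trait is a magnitude); BP_sd is
    always the sample sd of the absolute values.  ``signed_mean`` preserves
    the literal signed mean for comparison.
    """
    d_all = np.asarray(d_all, dtype=float)
    if d_all.size < 4:
        raise InsufficientDataError("need at least 4 margin distances")
    mags = np.abs(d_all)
    bp = float(d_all.mean()) if signed_mean else float(mags.mean())
    return bp, _sample_sd(mags)


def margin_traits(d_left, d_right) -> tuple[float, float]:
    """(MA_avg, MA_sd): mean and sample sd of the 2(n-3) local margin
    amplitudes |d_{i+1} - d_i|, taken side by side on the signed distances."""
    d_left = np.asarray(d_left, dtype=float)
    d_right = np.asarray(d_right, dtype=float)
    if d_left.size < 2 or d_right.size < 2:
        raise InsufficientDataError("need at least 2 margin distances per side")
    amps = np.concatenate([np.abs(np.diff(d_left)), np.abs(np.diff(d_right))])
    return float(amps.mean()), _sample_sd(amps)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class _LocalSeries:
    thetas: np.ndarray
    phis: np.ndarray
    d_left: np.ndarray
    d_right: np.ndarray


def _compute_local_series(grid: LeafPointGrid, patches: list[LocalPatch]) -> _LocalSeries:
    thetas, phis, d_left, d_right = [], [], [], []
    for k, patch in enumerate(patches):
        next_vein = grid.rows[patch.index + 2, COL_VEIN]
        frame = cross_section_frame(patch, next_vein)
        thetas.append(local_bia(patch, frame))
        dl, dr = edge_distances(patch)
        d_left.append(dl)
        d_right.append(dr)
        if k + 1 < len(patches):
            phis.append(local_twist(patch, patches[k + 1], frame))
    return _LocalSeries(np.asarray(thetas), np.asarray(phis),
                        np.asarray(d_left), np.asarray(d_right))


def _aggregate(grid: LeafPointGrid, series: _LocalSeries, *, ia_rows: int,
               bp_signed: bool, fallback_used: bool) -> TraitRecord:
    obia_avg, bia_avg, obia_sd = bia_traits(series.thetas)
    obst, bst, obst_sd = twist_traits(series.phis)
    bp, bp_sd = planarity_traits(np.concatenate([series.d_left, series.d_right]),
                                 signed_mean=bp_signed)
    ma_avg, ma_sd = margin_traits(series.d_left, series.d_right)
    return TraitRecord(
        leaf_id=grid.leaf_id,
        LL=leaf_length(grid),
        LA=leaf_area_3d(grid),
        IA=inclination_angle(grid, ia_rows=ia_rows),
        BIA_avg=bia_avg, OBIA_avg=obia_avg, OBIA_sd=obia_sd,
        BST=bst, OBST=obst, OBST_sd=obst_sd,
        BP=bp, BP_sd=bp_sd,
        MA_avg=ma_avg, MA_sd=ma_sd,
        fallback_used=fallback_used,
    )


def extract_all_traits(grid: LeafPointGrid,
                       thresholds: FallbackThresholds = DEFAULT_THRESHOLDS,
                       ia_rows: int = DEFAULT_IA_ROWS,
                       bp_signed: bool = False) -> TraitRecord:
    """Full per-leaf pipeline: decompose, fit, orient, first-pass traits,
    fallback gate, optional edge-point refit and recomputation.

    Deterministic for fixed input.  Raises on invalid grids and degenerate
    geometry, always naming the leaf and stage through the error message.
    """
    growth = growth_direction(grid)
    patches = orient_normals(fit_all_planes(decompose_patches(grid)), growth)
    series = _compute_local_series(grid, patches)
    record = _aggregate(grid, series, ia_rows=ia_rows, bp_signed=bp_signed,
                        fallback_used=False)
    if needs_fallback(record, thresholds):
        log.warning("leaf %s: first-pass traits exceed the thresholds "
                    "(BST=%.3f, OBIA_avg=%.1f, OBIA_sd=%.1f); refitting normals "
                    "from bilateral edge points", grid.leaf_id, record.BST,
                    record.OBIA_avg, record.OBIA_sd)
        patches = fallback_normals(patches, growth)
        series = _compute_local_series(grid, patches)
        record = _aggregate(grid, series, ia_rows=ia_rows, bp_signed=bp_signed,
                            fallback_used=True)
    return record
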