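"""Whole-leaf traits: leaf length, 3D leaf area and inclination angle."""

from __future__ import annotations

import logging
import math

import numpy as np

from .errors import DegenerateGeometryError
from .grid import COL_EDGE_LEFT, COL_EDGE_RIGHT, LeafPointGrid
from .mesh import build_triangle_mesh, triangle_areas

log = logging.getLogger(__name__)

#: number of basal vein segments spanned by the inclination chord
DEFAULT_IA_ROWS = 2


def leaf_length(grid: LeafPointGrid) -> float:
    """LL (cm): summed Euclidean length of the vein polyline, tip included."""
    vein = grid.vein_points
    return float(np.linalg.norm(np.diff(vein, axis=0), axis=1).sum())


def leaf_area_3d(grid: LeafPointGrid) -> float:
    """LA (cm^2): total facet area of the raw (unsubdivided) triangle mesh.

    Zero-area facets (e.g. the tip fan of a leaf digitized to its very tip)
    contribute nothing; their presence is logged, not raised.
    """
    areas = triangle_areas(build_triangle_mesh(grid))
    n_zero = int((areas == 0.0).sum())
    if n_zero:
        log.warning("leaf %s: %d zero-area facet(s) in LA sum", grid.leaf_id, n_zero)
    return float(areas.sum())


def inclination_angle(grid: LeafPointGrid, ia_rows: int = DEFAULT_IA_ROWS) -> float:
    """IA (deg, 0..90): elevation of the basal vein chord above the horizontal.

    The chord runs from the row-0 vein point to the vein point ``ia_rows``
    rows up (default 2, damping single-point digitizing noise); world +Z is
    taken as vertical — the stem reference points only disambiguate the
    adaxial side, they do not redefine the vertical.
    """
    vein = grid.vein_points
    ia_rows = min(int(ia_rows), len(vein) - 1)
    if ia_rows < 1:
        raise DegenerateGeometryError(f"leaf {grid.leaf_id!r}: no basal chord")
    chord = vein[ia_rows] - vein[0]
    norm = float(np.linalg.norm(chord))
    if norm == 0.0:
        raise DegenerateGeometryError(
            f"leaf {grid.leaf_id!r}: basal vein chord has zero length")
    return math.degrees(math.asin(min(1.0, abs(float(chord[2])) / norm)))


def leaf_area_1d(grid: LeafPointGrid) -> float:
    """Reference 1D estimate 0.75 * LL * max width (cm^2); not a TraitRecord field.

    The classical ruler-based approximation kept for comparison only.
    """
    widths = np.linalg.norm(
        grid.rows[:, COL_EDGE_RIGHT, :] - grid.rows[:, COL_EDGE_LEFT, :], axis=1)
    return 0.75 * leaf_length(grid) * float(widths.max())
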