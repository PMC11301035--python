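"""Shared fixtures: handcrafted grids and transform helpers."""

from __future__ import annotations

import numpy as np
import pytest

from leaf3d import LeafPointGrid, SyntheticLeafParams


def make_flat_grid(n_rows: int = 11, row_spacing: float = 5.0,
                   half_width: float = 5.0, tip_overhang: float = 0.0,
                   leaf_id: str = "flat") -> LeafPointGrid:
    """Planar horizontal leaf in z=0: vein along +y, columns along x.

    With ``tip_overhang=0`` the tip coincides with the last row's vein point
    (a blade digitized to its very tip), so LL = (n-1)*spacing and
    LA = 2*half_width*(n-1)*spacing exactly.
    """
    rows = np.zeros((n_rows, 5, 3))
    xs = np.array([-half_width, -half_width / 2, 0.0, half_width / 2, half_width])
    for r in range(n_rows):
        rows[r, :, 0] = xs
        rows[r, :, 1] = r * row_spacing
    tip = np.array([0.0, (n_rows - 1) * row_spacing + tip_overhang, 0.0])
    return LeafPointGrid(leaf_id, rows, tip,
                         stem_upper=np.array([0.0, -2.0, 5.0]),
                         stem_lower=np.array([0.0, -2.0, -5.0]))


def rotation_matrix(axis, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def transform_grid(grid: LeafPointGrid, R: np.ndarray | None = None,
                   t: np.ndarray | None = None, scale: float = 1.0) -> LeafPointGrid:
    """Apply scale, then rotation, then translation to every point incl. stems."""
    R = np.eye(3) if R is None else np.asarray(R, dtype=float)
    t = np.zeros(3) if t is None else np.asarray(t, dtype=float)

    def f(p):
        return (scale * np.asarray(p)) @ R.T + t

    return LeafPointGrid(grid.leaf_id, f(grid.rows), f(grid.tip),
                         f(grid.stem_upper), f(grid.stem_lower))


def mirror_grid_adaxial(grid: LeafPointGrid) -> LeafPointGrid:
    """Reflect the blade through the horizontal plane, keeping the stem
    reference (world up) fixed: inner rolling becomes outer and twist
    handedness flips."""
    M = np.diag([1.0, 1.0, -1.0])
    return LeafPointGrid(grid.leaf_id, grid.rows @ M, grid.tip @ M,
                         grid.stem_upper.copy(), grid.stem_lower.copy())


@pytest.fixture
def flat_grid() -> LeafPointGrid:
    return make_flat_grid()


@pytest.fixture
def clean_params() -> SyntheticLeafParams:
    """Noise-free defaults used when a test needs an exactly known surface."""
    return SyntheticLeafParams(noise_sd=0.0)


@pytest.fixture(autouse=True)
def _quiet_fallback_logging(caplog):
    # fallback warnings are expected all over the synthetic suites
    import logging
    logging.getLogger("leaf3d.traits_local").setLevel(logging.ERROR)
    yield
    logging.getLogger("leaf3d.traits_local").setLevel(logging.NOTSET)
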