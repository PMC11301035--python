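"""Structured leaf point grids and their on-disk representation.

The digitizing protocol records a maize blade as *n* full rows of five points
each — ordered ``edge_left, mid_left, vein, mid_right, edge_right`` from base
to tip — plus a single tip point, for ``5n + 1`` points per leaf, of which
``n + 1`` lie on the vein and ``2n`` on the margins.  Two extra stem points,
one above and one below the leaf insertion, give the plant's growth direction
so the adaxial (upper) surface can be identified.

On disk a leaf table is long-format delimited text (comma by default, tab
accepted) with columns ``leaf_id, row_index, column_index, role, x, y, z``;
coordinates are centimetres.  ``role`` is one of ``leaf``, ``tip``,
``stem_upper``, ``stem_lower``.  Rows must appear base-to-tip; the reader
rejects non-monotone row indices rather than sorting silently, so acquisition
mistakes surface early.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, ParseError, ValidationError

#: column identifiers of a full acquisition row, base frame of the whole package
COL_EDGE_LEFT, COL_MID_LEFT, COL_VEIN, COL_MID_RIGHT, COL_EDGE_RIGHT = range(5)

ROLE_LEAF = "leaf"
ROLE_TIP = "tip"
ROLE_STEM_UPPER = "stem_upper"
ROLE_STEM_LOWER = "stem_lower"

TABLE_COLUMNS = ["leaf_id", "row_index", "column_index", "role", "x", "y", "z"]

#: trait identifiers in canonical output order
TRAIT_NAMES = [
    "LL", "LA", "IA",
    "BIA_avg", "OBIA_avg", "OBIA_sd",
    "BST", "OBST", "OBST_sd",
    "BP", "BP_sd",
    "MA_avg", "MA_sd",
]

MIN_ROWS = 4


def expected_point_count(n_rows: float) -> float:
    """Points acquired for a leaf with ``n_rows`` full rows: ``5 n + 1``.

    Accepts fractional row counts so population averages can be converted
    (e.g. an average of 15.6 full rows corresponds to 79 points per leaf).
    """
    return 5.0 * n_rows + 1.0


@dataclass
class LeafPointGrid:
    """One digitized leaf: ``(n, 5, 3)`` row array, tip and stem references.

    Coordinates are centimetres.  ``rows[r, c]`` is the point in row ``r``
    (base first) and column ``c`` (see ``COL_*`` constants; column 2 is the
    vein, columns 0 and 4 the margins).
    """

    leaf_id: str
    rows: np.ndarray
    tip: np.ndarray
    stem_upper: np.ndarray
    stem_lower: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        self.tip = np.asarray(self.tip, dtype=float).reshape(3)
        self.stem_upper = np.asarray(self.stem_upper, dtype=float).reshape(3)
        self.stem_lower = np.asarray(self.stem_lower, dtype=float).reshape(3)

    @property
    def n_rows(self) -> int:
        return int(self.rows.shape[0])

    @property
    def n_points(self) -> int:
        """Leaf points only (rows + tip), excluding the stem references."""
        return 5 * self.n_rows + 1

    @property
    def vein_points(self) -> np.ndarray:
        """The ``n + 1`` vein points, base to tip (tip included)."""
        return np.vstack([self.rows[:, COL_VEIN, :], self.tip])

    def edge_points(self, side: str) -> np.ndarray:
        col = COL_EDGE_LEFT if side == "left" else COL_EDGE_RIGHT
        return self.rows[:, col, :]


def validate_grid(grid: LeafPointGrid) -> list[str]:
    """Check the acquisition-grid invariants; violations are data, not errors.

    Returns an empty list iff the grid is valid.  Each violation names the
    rule and the offending index.  Never raises on finite input.
    """
    out: list[str] = []
    rows = np.asarray(grid.rows, dtype=float)
    if rows.ndim != 3 or rows.shape[1:] != (5, 3):
        out.append(f"row_shape: expected (n, 5, 3), got {rows.shape}")
        return out
    n = rows.shape[0]
    if n < MIN_ROWS:
        out.append(f"row_count: n={n} < {MIN_ROWS}")
    if not np.isfinite(rows).all():
        bad = int(np.argwhere(~np.isfinite(rows).all(axis=(1, 2)))[0, 0])
        out.append(f"finite_coordinates: row {bad} has non-finite values")
    if not (np.isfinite(grid.tip).all() and np.isfinite(grid.stem_upper).all()
            and np.isfinite(grid.stem_lower).all()):
        out.append("finite_coordinates: tip or stem point non-finite")
    if np.array_equal(grid.stem_upper, grid.stem_lower):
        out.append("stem_points_distinct: stem_upper == stem_lower")
    vein = rows[:, COL_VEIN, :]
    seg = np.linalg.norm(np.diff(vein, axis=0), axis=1)
    for i in np.nonzero(seg == 0.0)[0]:
        out.append(f"vein_points_distinct: rows {i} and {i + 1} share a vein point")
    # The tip may coincide with the last full row's vein point (a leaf digitized
    # to its very tip); its segment then contributes zero length to LL.
    return out


def growth_direction(grid: LeafPointGrid) -> np.ndarray:
    """Unit vector from the lower to the upper stem reference point."""
    d = grid.stem_upper - grid.stem_lower
    norm = float(np.linalg.norm(d))
    if norm == 0.0:
        raise DegenerateGeometryError(
            f"leaf {grid.leaf_id!r}: coincident stem reference points")
    return d / norm


# ---------------------------------------------------------------------------
# leaf table I/O


def _grid_from_records(leaf_id: str, df: pd.DataFrame) -> LeafPointGrid:
    for role, label in [(ROLE_TIP, "tip"), (ROLE_STEM_UPPER, "stem_upper"),
                        (ROLE_STEM_LOWER, "stem_lower")]:
        k = int((df["role"] == role).sum())
        if k != 1:
            raise ValidationError(leaf_id, [f"{label}_count: expected 1, found {k}"])
    leaf = df[df["role"] == ROLE_LEAF]
    if leaf.empty:
        raise ValidationError(leaf_id, ["leaf_rows: no leaf points"])
    ridx = leaf["row_index"].to_numpy()
    if np.any(np.diff(ridx) < 0):
        where = int(np.nonzero(np.diff(ridx) < 0)[0][0])
        raise ValidationError(
            leaf_id, [f"row_order: row_index not monotone at record {where + 1} "
                      f"({ridx[where]} -> {ridx[where + 1]})"])
    n = int(ridx.max()) + 1
    if int(ridx.min()) != 0:
        raise ValidationError(leaf_id, [f"row_index: must start at 0, starts at {ridx.min()}"])
    rows = np.full((n, 5, 3), np.nan)
    for _, rec in leaf.iterrows():
        r, c = int(rec["row_index"]), int(rec["column_index"])
        if not 0 <= c <= 4:
            raise ValidationError(leaf_id, [f"column_index: row {r} has column {c} outside 0..4"])
        if np.isfinite(rows[r, c]).any():
            raise ValidationError(leaf_id, [f"duplicate_point: row {r} column {c} appears twice"])
        rows[r, c] = (rec["x"], rec["y"], rec["z"])
    incomplete = np.nonzero(~np.isfinite(rows).all(axis=(1, 2)))[0]
    if incomplete.size:
        r = int(incomplete[0])
        k = int(np.isfinite(rows[r]).all(axis=1).sum())
        raise ValidationError(leaf_id, [f"row_width: row {r} has {k} points, expected 5"])

    def one(role: str) -> np.ndarray:
        rec = df[df["role"] == role].iloc[0]
        return np.array([rec["x"], rec["y"], rec["z"]], dtype=float)

    grid = LeafPointGrid(leaf_id, rows, one(ROLE_TIP),
                         one(ROLE_STEM_UPPER), one(ROLE_STEM_LOWER))
    violations = validate_grid(grid)
    if violations:
        raise ValidationError(leaf_id, violations)
    return grid


def read_leaf_table(path, delimiter: str | None = None) -> list[LeafPointGrid]:
    """Read a long-format leaf table into validated :class:`LeafPointGrid` s.

    ``delimiter=None`` sniffs comma vs tab.  Raises :class:`ParseError` for a
    malformed file and :class:`ValidationError` (naming leaf and rule) for a
    structurally broken leaf.
    """
    try:
        if delimiter is None:
            with open(path, "r", encoding="utf-8") as fh:
                first = fh.readline()
            delimiter = "\t" if "\t" in first else ","
        # round_trip parsing keeps coordinates bit-exact through write/read
        df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    bad_role = set(df["role"].unique()) - {ROLE_LEAF, ROLE_TIP, ROLE_STEM_UPPER, ROLE_STEM_LOWER}
    if bad_role:
        raise ParseError(f"{path}: unknown role values {sorted(bad_role)}")
    grids = []
    for leaf_id, sub in df.groupby("leaf_id", sort=False):
        grids.append(_grid_from_records(str(leaf_id), sub))
    return grids


def write_leaf_table(grids: Iterable[LeafPointGrid], path, delimiter: str = ",") -> None:
    """Inverse of :func:`read_leaf_table`; round-trips coordinates bit-exactly."""
    recs = []
    for g in grids:
        n = g.n_rows
        for r in range(n):
            for c in range(5):
                x, y, z = g.rows[r, c]
                recs.append((g.leaf_id, r, c, ROLE_LEAF, x, y, z))
        recs.append((g.leaf_id, n, COL_VEIN, ROLE_TIP, *g.tip))
        recs.append((g.leaf_id, -1, -1, ROLE_STEM_UPPER, *g.stem_upper))
        recs.append((g.leaf_id, -1, -1, ROLE_STEM_LOWER, *g.stem_lower))
    pd.DataFrame.from_records(recs, columns=TABLE_COLUMNS).to_csv(
        path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# trait records


@dataclass
class TraitRecord:
    """The 13 extracted shape traits of one leaf.

    Units: LL, BP, BP_sd, MA_avg, MA_sd in cm; LA in cm^2; IA, BIA_avg,
    OBIA_avg, OBIA_sd, OBST_sd in degrees; BST and OBST dimensionless
    (multiples of 180 degrees of accumulated twist, OBST signed).
    """

    leaf_id: str
    LL: float
    LA: float
    IA: float
    BIA_avg: float
    OBIA_avg: float
    OBIA_sd: float
    BST: float
    OBST: float
    OBST_sd: float
    BP: float
    BP_sd: float
    MA_avg: float
    MA_sd: float
    fallback_used: bool = False

    def as_dict(self) -> dict:
        d = {"leaf_id": self.leaf_id}
        d.update({k: getattr(self, k) for k in TRAIT_NAMES})
        d["fallback_used"] = self.fallback_used
        return d


def write_trait_table(records: Sequence[TraitRecord], path, delimiter: str = ",") -> None:
    """Write one row per leaf with the canonical trait header, 7 significant
    digits (the least fixed precision that re-reads within 1e-6 relative)."""
    df = pd.DataFrame.from_records([r.as_dict() for r in records],
                                   columns=["leaf_id", *TRAIT_NAMES, "fallback_used"])
    df.to_csv(path, sep=delimiter, index=False, float_format="%.7g")


def read_trait_table(path, delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in TRAIT_NAMES if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing trait columns {missing}")
    return df
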