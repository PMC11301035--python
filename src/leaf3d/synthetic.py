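"""Parametric maize-leaf surfaces sampled into the acquisition grid format.

The generator builds a unit-speed vein curve in the vertical plane x = 0 from
a basal inclination and a droop rate (the tangent's elevation falls linearly
along the blade), transports a cross-section frame along it, twists the frame
about the local tangent by a cumulative twist profile, and folds the blade
into two straight half-blades meeting at the vein with a prescribed dihedral
(180 deg = flat, < 180 folded toward the adaxial side = inner rolling,
> 180 outer).  Five points per row are placed at transverse offsets
{-1, -1/2, 0, 1/2, 1} x half-width; the two margin columns are additionally
displaced along the local adaxial normal by a sinusoidal margin wave, and
optional iid Gaussian digitizing noise (seeded) is added last.  Stem
reference points encode world +Z as the growth direction.

Rows sit at arc positions u_r = r / n_rows, the tip at u = 1, so the tip is a
genuine extra vein point.  The labelled total twist is applied between the
second and the third-from-last row with flat tails at both ends: the discrete
estimator only sees normals at patch centers (rows 1 .. n-2), and confining
the twist to that span makes the label the physically correct base-to-tip
twist *and* recoverable from the samples.

Every leaf ships with a :class:`GroundTruth` carrying analytically known
trait values (quadrature where closed forms are unwieldy) and per-trait
recovery tolerances valid for noise-free leaves with >= 25 rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .grid import LeafPointGrid

Profile = Callable[[float], float]


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1.0 - c)


@dataclass(frozen=True)
class SyntheticLeafParams:
    """Generative parameters; defaults follow the population means of field
    ear leaves at grain filling (length 69.2 cm, inclination 49.5 deg,
    near-flat fold 174 deg, total twist 35.3 deg, ~500 cm^2 area).

    ``fold_deg``/``twist_deg``/``margin_wave_amplitude`` are scalar shortcuts
    expanded into profiles over arc position u in [0, 1]; pass explicit
    profile callables to override.  ``noise_sd`` is the iid Gaussian
    digitizing noise (cm, ~half-millimetre stylus precision by default).
    """

    n_rows: int = 25
    length: float = 69.2
    max_half_width: float = 5.4
    half_width_profile: Profile | None = None   # default parabolic, zero at tip
    inclination: float = 49.5
    droop_curvature: float = 30.0               # deg of tangent elevation lost per unit u
    fold_deg: float = 174.0
    fold_profile: Profile | None = None
    twist_deg: float = 35.3
    twist_profile: Profile | None = None
    margin_wave_amplitude: float = 1.0
    margin_wave_cycles: float = 2.5
    noise_sd: float = 0.05
    seed: int = 0
    leaf_id: str = "synthetic"

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.n_rows < 4:
            raise ValueError("n_rows must be >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.fold_profile is None and not (0.0 < self.fold_deg < 360.0):
            raise ValueError("fold_deg must lie in (0, 360)")

    # --- resolved profiles -------------------------------------------------

    def half_width(self, u: float) -> float:
        if self.half_width_profile is not None:
            return float(self.half_width_profile(u))
        return self.max_half_width * (1.0 - u * u)

    def fold(self, u: float) -> float:
        if self.fold_profile is not None:
            return float(self.fold_profile(u))
        return self.fold_deg

    def twist(self, u: float) -> float:
        """Cumulative twist (deg) at arc position u."""
        if self.twist_profile is not None:
            return float(self.twist_profile(u))
        n = self.n_rows
        lo, hi = 2.0 / n, (n - 3.0) / n
        if u <= lo:
            return 0.0
        if u >= hi:
            return self.twist_deg
        return self.twist_deg * (u - lo) / (hi - lo)

    def wave(self, u: float) -> float:
        return self.margin_wave_amplitude * math.sin(
            2.0 * math.pi * self.margin_wave_cycles * u)


@dataclass
class GroundTruth:
    """Expected trait values where the surface makes them analytic, with the
    tolerances inside which a noise-free >= 25-row leaf recovers them."""

    LL: float
    LA: float
    IA: float
    BIA_avg: float
    OBIA_avg: float
    OBST: float
    BST: float
    tolerances: dict = field(default_factory=lambda: {
        "LL": 0.5, "LA": 10.0, "IA": 1.0,
        "BIA_avg": 2.0, "OBIA_avg": 2.0, "OBST": 0.05, "BST": 0.05,
    })


class _LeafSurface:
    """Continuous surface a parameter set describes; shared by the row
    sampler and the ground-truth quadrature."""

    def __init__(self, params: SyntheticLeafParams):
        self.p = params
        self.incl = math.radians(params.inclination)
        self.droop = math.radians(params.droop_curvature)

    def elevation(self, u: float) -> float:
        return self.incl - self.droop * u

    def vein(self, u: float) -> np.ndarray:
        """Unit-speed vein point at arc position u (arc length = u * length)."""
        L, e0, d = self.p.length, self.incl, self.droop
        if d == 0.0:
            return np.array([0.0, L * u * math.cos(e0), L * u * math.sin(e0)])
        # integral of (cos e(t), sin e(t)) dt with e linear in t
        y = L * (math.sin(e0) - math.sin(e0 - d * u)) / d
        z = L * (math.cos(e0 - d * u) - math.cos(e0)) / d
        return np.array([0.0, y, z])

    def frame(self, u: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(tangent, transverse, adaxial-normal) after twisting about the tangent."""
        e = self.elevation(u)
        t = np.array([0.0, math.cos(e), math.sin(e)])
        w = np.array([1.0, 0.0, 0.0])
        n = np.cross(w, t)
        theta = math.radians(self.p.twist(u))
        if theta != 0.0:
            w = _rotate_about(w, t, theta)
            n = _rotate_about(n, t, theta)
        return t, w, n

    def cross_section(self, u: float) -> np.ndarray:
        """The 5 column points of the row at arc position u, shape (5, 3)."""
        p = self.p
        vein = self.vein(u)
        _, w, n = self.frame(u)
        beta = math.radians(180.0 - p.fold(u)) / 2.0
        d_left = -math.cos(beta) * w + math.sin(beta) * n
        d_right = math.cos(beta) * w + math.sin(beta) * n
        hw = p.half_width(u)
        pts = np.vstack([
            vein + hw * d_left,
            vein + 0.5 * hw * d_left,
            vein,
            vein + 0.5 * hw * d_right,
            vein + hw * d_right,
        ])
        wave = p.wave(u)
        if wave != 0.0:
            pts[0] += wave * n
            pts[4] += wave * n
        return pts

    # --- ground truth ------------------------------------------------------

    def area_quadrature(self, n_u: int = 1200) -> float:
        """Facet-area quadrature of the surface over the digitized span.

        Dense strips between u = 0 and the last full row, plus the exact tip
        fan (four triangles from the last row to the tip point) — matching
        the region the mesh of a sampled grid covers, at the resolution limit.
        """
        p = self.p
        u_last = (p.n_rows - 1) / p.n_rows
        us = np.linspace(0.0, u_last, n_u + 1)
        secs = np.stack([self.cross_section(u) for u in us])  # (n_u+1, 5, 3)
        total = 0.0
        a = secs[:-1, :-1]
        b = secs[:-1, 1:]
        c = secs[1:, 1:]
        d = secs[1:, :-1]
        total += 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=-1).sum()
        total += 0.5 * np.linalg.norm(np.cross(c - a, d - a), axis=-1).sum()
        last = secs[-1]
        tip = self.vein(1.0)
        for c0 in range(4):
            total += 0.5 * np.linalg.norm(
                np.cross(last[c0 + 1] - last[c0], tip - last[c0]))
        return float(total)

    def local_blade_angle(self, u: float) -> float:
        """Exact oriented included angle of the cross-section at u (deg).

        Equals the fold dihedral when the margin wave is off; with a wave the
        margins leave the fold planes and the true angle differs — the label
        tracks the surface actually generated, not the nominal dihedral.
        """
        p = self.p
        _, w, n = self.frame(u)
        beta = math.radians(180.0 - p.fold(u)) / 2.0
        hw = p.half_width(u)
        wave = p.wave(u)
        a = hw * (-math.cos(beta) * w + math.sin(beta) * n) + wave * n
        b = hw * (math.cos(beta) * w + math.sin(beta) * n) + wave * n
        gamma = math.degrees(math.atan2(float(np.linalg.norm(np.cross(a, b))),
                                        float(np.dot(a, b))))
        side = float((0.5 * (a + b)) @ n)
        return gamma if side >= 0.0 else 360.0 - gamma

    def ground_truth(self) -> GroundTruth:
        p = self.p
        n = p.n_rows
        # IA from the same basal chord the estimator uses (rows 0 -> 2)
        chord = self.vein(2.0 / n) - self.vein(0.0)
        ia = math.degrees(math.asin(abs(chord[2]) / np.linalg.norm(chord)))
        centers = [(r / n) for r in range(1, n - 1)]   # patch-center rows 1..n-2
        folds = np.array([self.local_blade_angle(u) for u in centers])
        obia = float(folds.mean())
        bia = float(np.where(folds > 180.0, 360.0 - folds, folds).mean())
        obst = (p.twist(centers[-1]) - p.twist(centers[0])) / 180.0
        return GroundTruth(LL=p.length, LA=self.area_quadrature(), IA=ia,
                           BIA_avg=bia, OBIA_avg=obia,
                           OBST=obst, BST=abs(obst))


def generate_leaf(params: SyntheticLeafParams) -> tuple[LeafPointGrid, GroundTruth]:
    """Sample one parametric leaf into the acquisition grid, with its labels.

    Self-intersecting parameter combinations (extreme folds plus large waves)
    are not detected; the grid is returned as sampled.
    """
    surf = _LeafSurface(params)
    n = params.n_rows
    rows = np.stack([surf.cross_section(r / n) for r in range(n)])
    tip = surf.vein(1.0)
    if params.noise_sd > 0.0:
        rng = np.random.default_rng(params.seed)
        rows = rows + rng.normal(0.0, params.noise_sd, size=rows.shape)
        tip = tip + rng.normal(0.0, params.noise_sd, size=3)
    base = surf.vein(0.0)
    stem_lower = base + np.array([0.0, -1.0, -10.0])
    stem_upper = base + np.array([0.0, -1.0, 10.0])
    grid = LeafPointGrid(params.leaf_id, rows, tip, stem_upper, stem_lower)
    return grid, surf.ground_truth()


#: parameter ranges spanning the population variation reported for field ear
#: leaves (lengths 41-101 cm, inclinations up to ~89 deg, inner to outer
#: rolling, twists to +-1.2 turns-of-180)
DEFAULT_PARAM_RANGES: dict = {
    "n_rows": (12, 30),
    "length": (41.0, 101.0),
    "max_half_width": (3.0, 7.5),
    "inclination": (1.0, 89.0),
    "droop_curvature": (0.0, 60.0),
    "fold_deg": (60.0, 300.0),
    "twist_deg": (-210.0, 250.0),
    "margin_wave_amplitude": (0.0, 2.0),
    "margin_wave_cycles": (1.0, 4.0),
}


def generate_population(n_leaves: int, param_ranges: dict | None = None,
                        seed: int = 0,
                        base_params: SyntheticLeafParams | None = None
                        ) -> list[tuple[LeafPointGrid, GroundTruth]]:
    """Seeded population of synthetic leaves with distinct leaf ids.

    ``param_ranges`` maps parameter names to (lo, hi) uniform ranges (ints
    sampled inclusively for ``n_rows``) or to fixed values.  Unlisted
    parameters keep their ``base_params`` value.
    """
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    ranges = DEFAULT_PARAM_RANGES if param_ranges is None else param_ranges
    if not ranges:
        raise ValueError("param_ranges must not be empty")
    base = base_params if base_params is not None else SyntheticLeafParams()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_leaves):
        sampled = {}
        for name, rng_spec in ranges.items():
            if isinstance(rng_spec, (tuple, list)) and len(rng_spec) == 2:
                lo, hi = rng_spec
                if name == "n_rows":
                    sampled[name] = int(rng.integers(int(lo), int(hi) + 1))
                else:
                    sampled[name] = float(rng.uniform(float(lo), float(hi)))
            else:
                sampled[name] = rng_spec
        leaf_seed = int(rng.integers(0, 2**31 - 1))
        params = replace(base, leaf_id=f"leaf_{i:04d}", seed=leaf_seed, **sampled)
        out.append(generate_leaf(params))
    return out
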