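"""Per-patch angles/distances and their leaf-level aggregation."""

import math
import statistics

import numpy as np
import pytest

from leaf3d import (
    DegenerateGeometryError,
    InsufficientDataError,
    SyntheticLeafParams,
    decompose_patches,
    extract_all_traits,
    generate_leaf,
    growth_direction,
    orient_normals,
)
from leaf3d.geometry import fit_all_planes
from leaf3d.traits_local import (
    bia_traits,
    cross_section_frame,
    edge_distances,
    local_bia,
    local_twist,
    margin_traits,
    planarity_traits,
    twist_traits,
)

from conftest import make_flat_grid, rotation_matrix


def _oriented_patches(grid):
    return orient_normals(fit_all_planes(decompose_patches(grid)),
                          growth_direction(grid))


class TestCrossSectionFrame:
    def test_flat_leaf_frame(self, flat_grid):
        patches = _oriented_patches(flat_grid)
        p = patches[0]
        frame = cross_section_frame(p, flat_grid.rows[p.index + 2, 2])
        np.testing.assert_allclose(frame.tangent, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(frame.section_plane.normal, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(frame.section_plane.origin, p.center, atol=1e-12)

    def test_tangent_component_along_normal_removed(self, flat_grid):
        patches = _oriented_patches(flat_grid)
        p = patches[0]
        # next vein point lifted: T = (0, 1, 1) against N = (0, 0, 1)
        frame = cross_section_frame(p, p.center + np.array([0.0, 1.0, 1.0]))
        np.testing.assert_allclose(frame.tangent, [0, 1, 0], atol=1e-12)

    def test_tangent_always_perpendicular_to_normal(self):
        grid, _ = generate_leaf(SyntheticLeafParams(noise_sd=0.03, seed=9))
        patches = _oriented_patches(grid)
        for p in patches:
            frame = cross_section_frame(p, grid.rows[p.index + 2, 2])
            assert abs(frame.tangent @ p.plane.normal) < 1e-12

    def test_tangent_parallel_to_normal_degenerate(self, flat_grid):
        p = _oriented_patches(flat_grid)[0]
        with pytest.raises(DegenerateGeometryError):
            cross_section_frame(p, p.center + np.array([0.0, 0.0, 2.0]))


class TestLocalBIA:
    def test_flat_leaf_is_180(self, flat_grid):
        patches = _oriented_patches(flat_grid)
        p = patches[3]
        frame = cross_section_frame(p, flat_grid.rows[p.index + 2, 2])
        assert local_bia(p, frame) == pytest.approx(180.0, abs=1e-9)

    @pytest.mark.parametrize("fold, expected", [(120.0, 120.0), (240.0, 240.0)])
    def test_v_fold_dihedral_recovered(self, fold, expected):
        grid, _ = generate_leaf(SyntheticLeafParams(
            noise_sd=0.0, fold_deg=fold, twist_deg=0.0, margin_wave_amplitude=0.0))
        patches = _oriented_patches(grid)
        p = patches[len(patches) // 2]
        frame = cross_section_frame(p, grid.rows[p.index + 2, 2])
        assert local_bia(p, frame) == pytest.approx(expected, abs=0.5)


class TestAggregation:
    def test_constant_180(self):
        obia, bia, sd = bia_traits([180.0] * 8)
        assert (obia, bia, sd) == (180.0, 180.0, 0.0)

    def test_inner_outer_pair(self):
        obia, bia, sd = bia_traits([120.0, 240.0])
        assert obia == pytest.approx(180.0)
        assert bia == pytest.approx(120.0)
        assert sd == pytest.approx(60.0 * math.sqrt(2.0))
        assert sd == pytest.approx(statistics.stdev([120.0, 240.0]))

    def test_bia_invariant_under_folding_any_subset(self):
        thetas = [100.0, 150.0, 210.0, 300.0]
        reflected = [360.0 - t for t in thetas]
        assert bia_traits(thetas)[1] == pytest.approx(bia_traits(reflected)[1])

    def test_insufficient_angles(self):
        with pytest.raises(InsufficientDataError):
            bia_traits([180.0])

    def test_twist_scaling_216_degrees(self):
        phis = np.full(22, 216.0 / 22.0)
        obst, bst, _ = twist_traits(phis)
        assert obst == pytest.approx(1.2, abs=1e-12)
        assert bst == pytest.approx(1.2, abs=1e-12)

    def test_twist_cancellation_vs_variability(self):
        obst, bst, sd = twist_traits([90.0, -90.0])
        assert obst == 0.0 and bst == 0.0
        assert sd == pytest.approx(90.0 * math.sqrt(2.0))
        assert sd == pytest.approx(statistics.stdev([90.0, -90.0]))

    def test_planarity(self):
        bp, sd = planarity_traits([1.0, -1.0, 1.0, -1.0])
        assert (bp, sd) == (1.0, 0.0)
        bp, sd = planarity_traits([0.0, 2.0, 0.0, 2.0])
        assert bp == pytest.approx(1.0)
        assert sd == pytest.approx(statistics.stdev([0.0, 2.0, 0.0, 2.0]))

    def test_planarity_signed_switch(self):
        bp, _ = planarity_traits([1.0, -1.0, 1.0, -1.0], signed_mean=True)
        assert bp == 0.0

    def test_margin_alternating(self):
        a = 0.7
        d_one = [a, -a, a, -a, a]
        d_flat = [0.0] * 5
        ma, _ = margin_traits(d_one, d_flat)
        assert ma == pytest.approx(a)

    def test_margin_offset_invariance(self):
        rng = np.random.default_rng(1)
        d1, d2 = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
        base = margin_traits(d1, d2)
        shifted = margin_traits(d1 + 5.0, d2 - 3.0)
        assert base == pytest.approx(shifted)


class TestLocalTwist:
    def test_identical_normals_zero(self, flat_grid):
        patches = _oriented_patches(flat_grid)
        frame = cross_section_frame(patches[0], flat_grid.rows[2, 2])
        assert local_twist(patches[0], patches[1], frame) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_oracle_plus_30(self, flat_grid):
        patches = _oriented_patches(flat_grid)
        p0, p1 = patches[0], patches[1]
        frame = cross_section_frame(p0, flat_grid.rows[2, 2])
        R = rotation_matrix(frame.tangent, math.radians(30.0))
        from dataclasses import replace
        from leaf3d.geometry import Plane
        p1r = replace(p1, plane=Plane(p1.plane.origin, R @ p1.plane.normal))
        assert local_twist(p0, p1r, frame) == pytest.approx(30.0, abs=1e-9)
        p1l = replace(p1, plane=Plane(p1.plane.origin, R.T @ p1.plane.normal))
        assert local_twist(p0, p1l, frame) == pytest.approx(-30.0, abs=1e-9)


class TestEdgeDistances:
    def test_flat_leaf_zero(self, flat_grid):
        patches = _oriented_patches(flat_grid)
        dl, dr = edge_distances(patches[2])
        assert dl == pytest.approx(0.0, abs=1e-12)
        assert dr == pytest.approx(0.0, abs=1e-12)

    def test_signed_sides_against_exact_plane(self, flat_grid):
        from dataclasses import replace
        from leaf3d.geometry import Plane
        flat_grid.rows[3, 0, 2] = 1.0    # left margin of row 3 lifted 1 cm
        flat_grid.rows[3, 4, 2] = -0.5   # right margin dropped 0.5 cm
        patches = _oriented_patches(flat_grid)
        p = patches[2]  # middle row is grid row 3
        # against the exact plane of the unperturbed blade the signed
        # distances are the imposed displacements
        exact = replace(p, plane=Plane(origin=np.array([0.0, 15.0, 0.0]),
                                       normal=np.array([0.0, 0.0, 1.0])))
        dl, dr = edge_distances(exact)
        assert dl == pytest.approx(1.0, abs=1e-12)
        assert dr == pytest.approx(-0.5, abs=1e-12)
        # the TLS plane tilts toward the perturbation but keeps the signs
        dl_fit, dr_fit = edge_distances(p)
        assert dl_fit > 0 > dr_fit


class TestExtractAllTraits:
    def test_flat_leaf_fixed_point(self, flat_grid):
        r = extract_all_traits(flat_grid)
        assert r.LL == pytest.approx(50.0, abs=1e-9)
        assert r.LA == pytest.approx(500.0, abs=1e-9)
        assert r.IA == pytest.approx(0.0, abs=1e-9)
        assert r.BIA_avg == pytest.approx(180.0, abs=1e-6)
        assert r.OBIA_avg == pytest.approx(180.0, abs=1e-6)
        for trait in ("OBIA_sd", "BST", "OBST", "OBST_sd", "BP", "BP_sd",
                      "MA_avg", "MA_sd"):
            assert getattr(r, trait) == pytest.approx(0.0, abs=1e-6), trait
        assert not r.fallback_used

    def test_twist_recovery(self):
        grid, truth = generate_leaf(SyntheticLeafParams(
            noise_sd=0.0, fold_deg=180.0, twist_deg=216.0,
            margin_wave_amplitude=0.0))
        r = extract_all_traits(grid)
        assert truth.OBST == pytest.approx(1.2, abs=1e-12)
        assert r.OBST == pytest.approx(1.2, abs=0.05)
        assert r.BST == pytest.approx(abs(r.OBST), abs=1e-12)

    def test_fallback_trigger_sets_flag(self):
        grid, _ = generate_leaf(SyntheticLeafParams(
            noise_sd=0.0, fold_deg=180.0, twist_deg=290.0,
            margin_wave_amplitude=0.0))
        r = extract_all_traits(grid)
        assert r.fallback_used
        assert np.isfinite([r.OBST, r.BIA_avg, r.BP, r.MA_avg]).all()

    def test_deterministic(self):
        grid, _ = generate_leaf(SyntheticLeafParams(seed=33))
        a = extract_all_traits(grid)
        b = extract_all_traits(grid)
        assert a == b
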