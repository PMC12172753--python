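"""Excitability maps: interpolation, centroid, weighted area, overlap, pairs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tmsmap.mapping import (
    EmptyMapError,
    ExcitabilityMap,
    MapError,
    UndefinedMetricError,
    area_size,
    centroid,
    interpolate_to_vertices,
    overlap,
    pair_grouping,
)
from tmsmap.surface import TriSurface
from tmsmap.synthetic import GroundTruthField, make_flat_patch_mesh


def _single_triangle(verts):
    v = np.asarray(verts, float)
    return TriSurface(v, [[0, 1, 2]], np.zeros(3), np.array(["m"] * 3))


class TestInterpolation:
    def test_isolated_stimulation(self, patch):
        emap = interpolate_to_vertices([50], [300.0], patch, radius_mm=0.5)
        assert list(emap.vertex_ids) == [50]
        assert emap.mep[0] == pytest.approx(300.0)

    def test_constant_field_reproduced_between_stims(self, patch):
        # two equal-amplitude stims: everything in range gets that amplitude
        emap = interpolate_to_vertices([100, 104], [250.0, 250.0], patch, radius_mm=4.0)
        np.testing.assert_allclose(emap.mep, 250.0, rtol=1e-12)

    def test_stim_vertices_keep_exact_amplitude(self, patch, rng):
        sv = rng.choice(patch.n_vertices, size=30, replace=False)
        amps = rng.uniform(100, 900, size=30)
        emap = interpolate_to_vertices(sv, amps, patch, radius_mm=5.0)
        lookup = dict(zip(emap.vertex_ids.tolist(), emap.mep))
        for v, a in zip(sv, amps):
            assert lookup[v] == pytest.approx(a, rel=1e-12)

    def test_duplicate_stim_vertices_average(self, patch):
        emap = interpolate_to_vertices([10, 10], [100.0, 300.0], patch, radius_mm=0.5)
        assert emap.mep[list(emap.vertex_ids).index(10)] == pytest.approx(200.0)

    def test_gaussian_field_recovered_off_sample(self, rng):
        # sigma = 6 mm >= 3 x edge length (1 mm): off-sample IDW within 15%
        grid = make_flat_patch_mesh(31, 31, 1.0)
        field = GroundTruthField("FDI", np.array([0.0, 0.0, 0.0]), 6.0, 500.0)
        sv = rng.choice(grid.n_vertices, size=120, replace=False)
        amps = field.noiseless(grid.vertices[sv])
        emap = interpolate_to_vertices(sv, amps, grid, radius_mm=5.0)
        truth = field.noiseless(grid.vertices[emap.vertex_ids])
        # map-level accuracy, normalised by the field peak: the bulk of
        # off-sample vertices reproduce the analytic field within 15%
        err = np.abs(emap.mep - truth) / 500.0
        assert np.percentile(err, 95) < 0.15
        assert np.median(err) < 0.05

    def test_empty_stimulation_set_rejected(self, patch):
        with pytest.raises(EmptyMapError):
            interpolate_to_vertices([], [], patch, radius_mm=5.0)


class TestCentroid:
    def test_single_vertex(self):
        surf = _single_triangle([[1, 2, 3], [4, 5, 6], [7, 8, 9.5]])
        emap = ExcitabilityMap(surf, [0], [42.0])
        np.testing.assert_allclose(centroid(emap), [1, 2, 3])

    def test_two_point_weighted_mean(self):
        surf = _single_triangle([[0, 0, 0], [2, 0, 0], [0, 1, 0]])
        emap = ExcitabilityMap(surf, [0, 1], [1.0, 3.0])
        np.testing.assert_allclose(centroid(emap), [1.5, 0, 0])

    def test_fine_grid_gaussian_centroid_near_center(self):
        grid = make_flat_patch_mesh(41, 41, 0.5)
        field = GroundTruthField("FDI", np.array([1.2, -0.7, 0.0]), 3.0, 400.0)
        w = field.noiseless(grid.vertices)
        emap = ExcitabilityMap(grid, np.arange(grid.n_vertices), w)
        err = np.linalg.norm(centroid(emap) - field.center)
        assert err < 0.5 * grid.mean_edge_length()

    @given(
        d=st.tuples(*[st.floats(-50, 50, allow_nan=False)] * 3),
        c=st.floats(0.01, 100.0, allow_nan=False),
    )
    def test_translation_equivariance_and_weight_scale_invariance(self, d, c):
        surf = _single_triangle([[0, 0, 0], [2, 0, 0], [0, 1, 0]])
        w = np.array([1.0, 2.0, 3.5])
        emap = ExcitabilityMap(surf, [0, 1, 2], w)
        c0 = centroid(emap)
        shifted = TriSurface(
            surf.vertices + np.asarray(d), surf.faces, surf.curvature, surf.atlas_labels
        )
        c_shift = centroid(ExcitabilityMap(shifted, [0, 1, 2], w))
        np.testing.assert_allclose(c_shift, c0 + np.asarray(d), atol=1e-9)
        c_scaled = centroid(ExcitabilityMap(surf, [0, 1, 2], w * c))
        np.testing.assert_allclose(c_scaled, c0, atol=1e-9)

    def test_zero_weights_rejected(self):
        surf = _single_triangle([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        with pytest.raises(UndefinedMetricError):
            centroid(ExcitabilityMap(surf, [0, 1], [0.0, 0.0]))


class TestAreaSize:
    def test_unit_right_triangle(self):
        surf = _single_triangle([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        assert area_size(ExcitabilityMap(surf, [0, 1, 2], [1.0, 1.0, 1.0])) == pytest.approx(0.5)

    def test_mean_weight_scales_area(self):
        surf = _single_triangle([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        emap = ExcitabilityMap(surf, [0, 1, 2], [1.0, 2.0, 3.0])
        assert area_size(emap) == pytest.approx(1.0)  # mean weight 2 x area 0.5

    def test_unit_weights_match_cross_product_oracle(self, rng):
        for _ in range(50):
            nx, ny = rng.integers(2, 7, size=2)
            surf = make_flat_patch_mesh(int(nx), int(ny), float(rng.uniform(0.3, 3.0)))
            # random out-of-plane warp keeps triangles non-degenerate
            verts = surf.vertices.copy()
            verts[:, 2] = rng.normal(0, 0.2, size=len(verts))
            warped = TriSurface(verts, surf.faces, surf.curvature, surf.atlas_labels)
            emap = ExcitabilityMap(warped, np.arange(warped.n_vertices), np.ones(warped.n_vertices))
            assert area_size(emap) == pytest.approx(warped.total_area(), rel=1e-9)

    def test_incomplete_map_has_zero_size_with_warning(self):
        surf = _single_triangle([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        with pytest.warns(UserWarning, match="no complete triangle"):
            assert area_size(ExcitabilityMap(surf, [0, 1], [1.0, 1.0])) == 0.0


def _strip_surface():
    """Four vertices, three triangles in a row: A, B, C from left to right."""
    verts = np.array(
        [[0, 0, 0], [1, 0, 0], [0.5, 1, 0], [1.5, 1, 0], [2, 0, 0]], dtype=float
    )
    faces = np.array([[0, 1, 2], [1, 3, 2], [1, 4, 3]])
    return TriSurface(verts, faces, np.zeros(5), np.array(["m"] * 5))


class TestOverlap:
    def test_identical_maps(self, patch):
        ids = np.arange(60)
        emap = ExcitabilityMap(patch, ids, np.linspace(1, 5, 60))
        assert overlap(emap, emap) == pytest.approx(1.0)
        assert overlap(emap, emap, mode="weighted") == pytest.approx(1.0)

    def test_disjoint_maps(self, patch):
        a = ExcitabilityMap(patch, np.arange(0, 30), np.ones(30))
        b = ExcitabilityMap(patch, np.arange(200, 230), np.ones(30))
        assert overlap(a, b) == 0.0

    def test_one_shared_triangle_of_three(self):
        surf = _strip_surface()
        # map K covers triangles {0, 1}; map L covers {1, 2}; all equal area
        k = ExcitabilityMap(surf, [0, 1, 2, 3], np.ones(4))
        l = ExcitabilityMap(surf, [1, 2, 3, 4], np.ones(4))
        assert overlap(k, l) == pytest.approx(1.0 / 3.0)

    @pytest.mark.parametrize("mode", ["geometric", "weighted"])
    def test_symmetry(self, patch, rng, mode):
        a_ids = rng.choice(patch.n_vertices, size=80, replace=False)
        b_ids = rng.choice(patch.n_vertices, size=80, replace=False)
        a = ExcitabilityMap(patch, a_ids, rng.uniform(1, 9, 80))
        b = ExcitabilityMap(patch, b_ids, rng.uniform(1, 9, 80))
        try:
            o_ab = overlap(a, b, mode=mode)
            o_ba = overlap(b, a, mode=mode)
        except UndefinedMetricError:
            pytest.skip("degenerate random draw with empty union")
        assert o_ab == pytest.approx(o_ba, rel=1e-12)
        assert 0.0 <= o_ab <= 1.0

    def test_growing_intersection_never_decreases(self):
        surf = _strip_surface()
        union_map = ExcitabilityMap(surf, [0, 1, 2, 3, 4], np.ones(5))
        small = ExcitabilityMap(surf, [0, 1, 2], np.ones(3))  # triangle 0 only
        bigger = ExcitabilityMap(surf, [0, 1, 2, 3], np.ones(4))  # triangles 0, 1
        assert overlap(small, union_map) <= overlap(bigger, union_map)

    def test_different_surfaces_rejected(self, patch, hemisphere):
        a = ExcitabilityMap(patch, [0, 1, 2], np.ones(3))
        b = ExcitabilityMap(hemisphere, [0, 1, 2], np.ones(3))
        with pytest.raises(MapError):
            overlap(a, b)

    def test_empty_union_rejected(self, patch):
        a = ExcitabilityMap(patch, [0], [1.0])  # no complete triangle
        with pytest.raises(UndefinedMetricError):
            overlap(a, a)

    def test_disc_overlap_matches_analytic_ratio(self):
        from tmsmap.synthetic import disc_iou

        grid = make_flat_patch_mesh(81, 81, 0.5)
        r, d = 10.0, 8.0
        c1, c2 = np.array([-d / 2, 0, 0]), np.array([d / 2, 0, 0])
        maps = []
        for c in (c1, c2):
            ids = np.flatnonzero(np.linalg.norm(grid.vertices - c, axis=1) <= r)
            maps.append(ExcitabilityMap(grid, ids, np.ones(len(ids))))
        o = overlap(maps[0], maps[1])
        analytic = disc_iou(c1, r, c2, r)
        assert o == pytest.approx(analytic, rel=0.05)


class TestPairGrouping:
    def test_28_pairs_partitioned_6_16_6(self):
        tab = pair_grouping()
        assert len(tab) == 28
        counts = tab.pair_group.value_counts()
        assert counts["hand-hand"] == 6
        assert counts["hand-forearm"] == 16
        assert counts["forearm-forearm"] == 6

    def test_synergistic_sets(self):
        tab = pair_grouping()
        syn = tab[tab.synergistic]
        by_group = syn.pair_group.value_counts()
        assert by_group["hand-hand"] == 3  # FDI-APB, FDI-FPB, APB-FPB
        assert by_group["forearm-forearm"] == 2  # EDC-ECR, FDS-FCR
        assert by_group["hand-forearm"] == 8  # {EDC, FDS} x {FDI, APB, FPB, ADM}
        hh = {frozenset((r.muscle_k, r.muscle_l)) for r in syn.itertuples() if r.pair_group == "hand-hand"}
        assert hh == {
            frozenset(("FDI", "APB")),
            frozenset(("FDI", "FPB")),
            frozenset(("APB", "FPB")),
        }

    def test_unknown_muscle_rejected(self):
        with pytest.raises(MapError, match="unknown"):
            pair_grouping(("FDI", "biceps"))
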