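import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wristcompact import (
    BoneMask,
    CentroidSet,
    Point2D,
    WristMaskSet,
    bbox_diagonal,
    centroid,
    centroid_set,
    compactness_vector,
    mpd,
    overlap_metrics,
    pairwise_overlap_sizes,
    radial_quantile,
    rmsr,
)
from wristcompact.compactness import METRIC_ORDER, OverlapTable
from wristcompact.errors import DegenerateConfigurationError, EmptyMaskError

import oracles
from conftest import random_mask_set


def mask_from_pixels(pixels, shape=(30, 30), label="a"):
    g = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        g[r, c] = True
    return BoneMask(label, g)


class TestCentroid:
    def test_2x2_block_centroid_is_at_block_center(self):
        m = mask_from_pixels([(10, 20), (10, 21), (11, 20), (11, 21)])
        assert centroid(m) == Point2D(20.5, 10.5)

    def test_single_pixel(self):
        assert centroid(mask_from_pixels([(7, 5)])) == Point2D(5.0, 7.0)

    def test_random_blob_matches_pixel_list_oracle(self):
        rng = np.random.default_rng(42)
        pixels = {(int(r), int(c)) for r, c in rng.integers(0, 30, size=(50, 2))}
        m = mask_from_pixels(pixels)
        x, y = oracles.bf_centroid(oracles.pixel_list(m.grid))
        got = centroid(m)
        assert got.x == pytest.approx(x, abs=1e-12)
        assert got.y == pytest.approx(y, abs=1e-12)

    def test_empty_mask_is_an_error(self):
        with pytest.raises(EmptyMaskError, match="empty"):
            centroid(BoneMask("a", np.zeros((5, 5), dtype=bool)))


class TestOverlaps:
    def test_known_shared_pixels(self):
        a = mask_from_pixels([(0, 0), (0, 1), (0, 2), (5, 5)], label="A")
        b = mask_from_pixels([(0, 0), (0, 1), (0, 2), (9, 9)], label="B")
        c = mask_from_pixels([(20, 20)], label="C")
        ms = WristMaskSet("s", "left", "BL", (a, b, c))
        table = pairwise_overlap_sizes(ms)
        assert dict(((i, j), s) for i, j, s in table.pairs) == {
            ("A", "B"): 3, ("A", "C"): 0, ("B", "C"): 0,
        }

    def test_identical_masks_attain_min_area(self):
        pix = [(i, i) for i in range(10)]
        ms = WristMaskSet("s", "left", "BL",
                          (mask_from_pixels(pix, label="A"),
                           mask_from_pixels(pix, label="B")))
        assert pairwise_overlap_sizes(ms).pairs[0][2] == 10

    def test_random_masks_match_set_intersection_oracle(self):
        ms = random_mask_set(seed=7)
        got = [s for _, _, s in pairwise_overlap_sizes(ms).pairs]
        want = oracles.bf_overlaps([oracles.pixel_list(m.grid) for m in ms.masks])
        assert got == want

    @pytest.mark.parametrize(
        "sizes, oss, ossd",
        [
            ((3, 0, 0), 3, math.sqrt(2)),
            ((0, 0, 0), 0, 0.0),
            ((5, 5, 5, 5, 5, 5), 30, 0.0),
        ],
    )
    def test_overlap_summaries(self, sizes, oss, ossd):
        table = OverlapTable(
            pairs=tuple(("a", "b", s) for s in sizes),
            n_bones={3: 3, 6: 4}[len(sizes)],
        )
        got_oss, got_ossd = overlap_metrics(table)
        assert got_oss == oss
        assert got_ossd == pytest.approx(ossd, abs=1e-12)

    def test_sample_divisor_convention_available(self):
        table = OverlapTable(pairs=(("a", "b", 3), ("a", "c", 0), ("b", "c", 0)),
                             n_bones=3)
        _, ossd = overlap_metrics(table, ddof=1)
        assert ossd == pytest.approx(math.sqrt(3), abs=1e-12)


class TestCentroidGeometry:
    def test_square_corner_centroids(self):
        cs = CentroidSet.from_points([(0, 0), (2, 0), (0, 2), (2, 2)])
        assert cs.mu == Point2D(1.0, 1.0)
        np.testing.assert_allclose(cs.radii, math.sqrt(2), atol=1e-12)
        assert rmsr(cs) == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_two_points(self):
        cs = CentroidSet.from_points([(0, 0), (4, 0)])
        assert cs.mu == Point2D(2.0, 0.0)
        np.testing.assert_allclose(cs.radii, [2.0, 2.0], atol=1e-12)
        assert mpd(cs) == pytest.approx(4.0, abs=1e-12)  # distance d between two points

    def test_mu_matches_composed_pixel_oracles(self):
        ms = random_mask_set(seed=9)
        cs = centroid_set(ms)
        cents = [oracles.bf_centroid(oracles.pixel_list(m.grid)) for m in ms.masks]
        assert cs.mu.x == pytest.approx(sum(x for x, _ in cents) / 7, abs=1e-12)
        assert cs.mu.y == pytest.approx(sum(y for _, y in cents) / 7, abs=1e-12)

    def test_unit_square_mpd_closed_form(self):
        cs = CentroidSet.from_points([(0, 0), (1, 0), (0, 1), (1, 1)])
        assert mpd(cs) == pytest.approx((4 + 2 * math.sqrt(2)) / 6, abs=1e-12)

    def test_rmsr_zero_for_coincident_points(self):
        cs = CentroidSet.from_points([(3, 3), (3, 3), (3, 3)])
        assert rmsr(cs) == 0.0

    def test_rmsr_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, size=(7, 2))
        cs = CentroidSet.from_points(pts)
        mu = pts.mean(axis=0)
        want = math.sqrt(sum((p - mu) @ (p - mu) for p in pts) / 7)
        assert rmsr(cs) == pytest.approx(want, rel=1e-12)

    def test_mpd_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, size=(7, 2))
        cs = CentroidSet.from_points(pts)
        total = sum(
            math.dist(pts[i], pts[j])
            for i in range(7) for j in range(7) if i != j
        )
        assert mpd(cs) == pytest.approx(total / 42, rel=1e-12)


class TestRadialQuantilesAndBBox:
    def _cs_with_radii(self, radii):
        # collinear points at +radii from origin plus mirrored mass are hard
        # to construct exactly; patch the radii field directly instead
        cs = CentroidSet.from_points([(0, 0), (1, 1)])
        object.__setattr__(cs, "radii", np.asarray(radii, dtype=float))
        return cs

    def test_median_of_three(self):
        assert radial_quantile(self._cs_with_radii([1, 2, 3]), 0.5) == 2.0

    def test_type7_interpolation_at_q90(self):
        # h = 0.9 * 4 = 3.6 -> 4 + 0.6 * (5 - 4)
        assert radial_quantile(self._cs_with_radii([1, 2, 3, 4, 5]), 0.9) == pytest.approx(4.6)

    def test_constant_radii_for_any_q(self):
        cs = self._cs_with_radii([2.5] * 6)
        for q in (0.0, 0.3, 0.5, 0.9, 1.0):
            assert radial_quantile(cs, q) == 2.5

    def test_q_outside_unit_interval_rejected(self):
        cs = self._cs_with_radii([1, 2])
        with pytest.raises(ValueError):
            radial_quantile(cs, 1.5)

    @pytest.mark.parametrize(
        "points, want",
        [([(0, 0), (3, 4)], 5.0),
         ([(0, 0), (1, 0), (0, 1), (1, 1)], math.sqrt(2)),
         ([(2, 2), (2, 2), (2, 2)], 0.0)],
    )
    def test_bbox_diagonal(self, points, want):
        assert bbox_diagonal(CentroidSet.from_points(points)) == pytest.approx(want, abs=1e-12)


class TestCompactnessVector:
    def test_full_vector_matches_pixel_list_oracle(self):
        ms = random_mask_set(seed=13)
        vec = compactness_vector(ms).as_dict()
        want = oracles.bf_metrics([oracles.pixel_list(m.grid) for m in ms.masks])
        for name, value in want.items():
            assert vec[name] == pytest.approx(value, rel=1e-9), name

    def test_seven_one_pixel_bones_end_to_end(self):
        coords = [(5, 5), (5, 15), (5, 25), (15, 5), (15, 25), (25, 10), (25, 20)]
        masks = tuple(mask_from_pixels([rc], label=f"b{i}") for i, rc in enumerate(coords))
        ms = WristMaskSet("s", "left", "BL", masks)
        vec = compactness_vector(ms).as_dict()
        want = oracles.bf_metrics([[rc] for rc in coords])
        for name, value in want.items():
            assert vec[name] == pytest.approx(value, rel=1e-12), name
        assert vec["OSS"] == 0

    def test_coincident_bones_raise_with_raw_metrics_payload(self):
        m = [(3, 3)]
        masks = tuple(mask_from_pixels(m, label=f"b{i}") for i in range(3))
        ms = WristMaskSet("s", "left", "BL", masks)
        with pytest.raises(DegenerateConfigurationError) as exc:
            compactness_vector(ms)
        assert exc.value.raw_metrics["RMSR"] == 0.0
        assert exc.value.raw_metrics["OSS"] == 3  # three fully coincident pairs of 1 px

    def test_normalization_identity(self):
        ms = random_mask_set(seed=21)
        vec = compactness_vector(ms)
        for raw, norm in [("RMSR", "RMSRn"), ("MPD", "MPDn"), ("R50", "R50n"), ("R90", "R90n")]:
            assert getattr(vec, norm) * vec.Lbbox == pytest.approx(getattr(vec, raw), abs=1e-9)


# ---------------------------------------------------------------------------
# geometric invariance properties on centroid sets

finite = st.floats(min_value=-500.0, max_value=500.0, allow_nan=False)
point_sets = st.lists(st.tuples(finite, finite), min_size=3, max_size=10).filter(
    lambda pts: max(x for x, _ in pts) - min(x for x, _ in pts) > 1e-3
    or max(y for _, y in pts) - min(y for _, y in pts) > 1e-3
)

RAW = (rmsr, mpd, lambda cs: radial_quantile(cs, 0.5), lambda cs: radial_quantile(cs, 0.9))


def _metrics(points):
    cs = CentroidSet.from_points(points)
    return np.array([f(cs) for f in RAW] + [bbox_diagonal(cs)])


@given(point_sets, finite, finite)
def test_translation_invariance(pts, dx, dy):
    base = _metrics(pts)
    moved = _metrics([(x + dx, y + dy) for x, y in pts])
    np.testing.assert_allclose(moved, base, rtol=1e-9, atol=1e-9)


@given(point_sets, st.floats(min_value=0.01, max_value=100.0))
def test_scale_equivariance_and_normalized_invariance(pts, s):
    base = _metrics(pts)
    scaled = _metrics([(x * s, y * s) for x, y in pts])
    np.testing.assert_allclose(scaled, s * base, rtol=1e-9)
    np.testing.assert_allclose(scaled / scaled[-1], base / base[-1], rtol=1e-9)


@given(point_sets, st.floats(min_value=-math.pi, max_value=math.pi))
def test_rotation_invariance_of_raw_distance_metrics(pts, theta):
    # Lbbox is axis-aligned and intentionally NOT rotation invariant, so only
    # the four raw distance metrics are compared
    c, s = math.cos(theta), math.sin(theta)
    rotated = [(x * c - y * s, x * s + y * c) for x, y in pts]
    np.testing.assert_allclose(_metrics(rotated)[:4], _metrics(pts)[:4], rtol=1e-9, atol=1e-9)


@given(point_sets, st.randoms(use_true_random=False))
def test_permutation_invariance(pts, rnd):
    shuffled = list(pts)
    rnd.shuffle(shuffled)
    np.testing.assert_allclose(_metrics(shuffled), _metrics(pts), rtol=1e-12)


@given(point_sets, st.floats(min_value=0.0, max_value=1.0))
def test_contraction_law_scales_all_raw_metrics(pts, lam):
    from wristcompact import apply_contraction

    base = _metrics(pts)
    contracted = _metrics(apply_contraction([Point2D(*p) for p in pts], lam))
    np.testing.assert_allclose(contracted, (1 - lam) * base, rtol=1e-9, atol=1e-9)


@given(point_sets)
def test_metric_bounds(pts):
    cs = CentroidSet.from_points(pts)
    r50, r90 = radial_quantile(cs, 0.5), radial_quantile(cs, 0.9)
    lbbox = bbox_diagonal(cs)
    assert r50 <= r90 + 1e-12
    assert cs.radii.max() <= lbbox + 1e-9
    assert rmsr(cs) <= lbbox + 1e-9
    assert mpd(cs) <= lbbox + 1e-9
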