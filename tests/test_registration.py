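import math

import numpy as np
import pytest
from skimage.transform import ProjectiveTransform

from lizardtherm.errors import MappingError, OutOfPanelError, SingularQuadError
from lizardtherm.mask_pixel import PixelCoord
from lizardtherm.registration import (
    Homography,
    QuadCorrespondence,
    fit_homography,
    map_point,
    rect_quad,
)

UNIT_SQUARE = tuple(rect_quad(0, 0, 1, 1))


def random_rect_corr(rng, span=200):
    """Random axis-aligned rectangle-to-rectangle correspondence.

    Panel scales are kept within [0.6, 2] of each other, matching the two
    similarly sized camera views; below a 0.5 axis scale the forward
    rounding error alone can exceed 1 src pixel under the inverse map, so
    the round-trip bound would not be a fair property to demand.
    """
    x1, y1 = rng.uniform(0, span, 2)
    w, h = rng.uniform(20, span, 2)
    fx, fy = rng.uniform(0.6, 2.0, 2)
    x2, y2 = rng.uniform(0, span, 2)
    return QuadCorrespondence(
        tuple(rect_quad(x1, y1, x1 + w, y1 + h)),
        tuple(rect_quad(x2, y2, x2 + w * fx, y2 + h * fy)),
    )


def random_general_corr(rng, span=200):
    """Random non-degenerate convex quads (perturbed rectangles)."""
    while True:
        def quad():
            base = np.array(rect_quad(*sorted(rng.uniform(0, span, 2)),
                                      *sorted(rng.uniform(span, 2 * span, 2))))
            return [tuple(p) for p in base + rng.uniform(-5, 5, (4, 2))]

        try:
            return QuadCorrespondence(tuple(quad()), tuple(quad()))
        except SingularQuadError:
            continue


class TestFitHomography:
    def test_identity(self):
        h = fit_homography(QuadCorrespondence(UNIT_SQUARE, UNIT_SQUARE))
        np.testing.assert_allclose(h.m, np.eye(3), atol=1e-12)

    def test_pure_scaling(self):
        dst = tuple((2 * x, 2 * y) for x, y in UNIT_SQUARE)
        h = fit_homography(QuadCorrespondence(UNIT_SQUARE, dst))
        np.testing.assert_allclose(h.m, np.diag([2.0, 2.0, 1.0]), atol=1e-12)

    def test_corners_reproduce_vs_independent_estimator(self):
        """Corner reprojection within 1e-6 and agreement with skimage's
        ProjectiveTransform fit on the same correspondences."""
        rng = np.random.default_rng(101)
        for _ in range(50):
            corr = random_general_corr(rng)
            h = fit_homography(corr)
            for (x, y), (u, v) in zip(corr.src, corr.dst):
                vec = h.m @ [x, y, 1.0]
                assert abs(vec[0] / vec[2] - u) < 1e-6
                assert abs(vec[1] / vec[2] - v) < 1e-6
            oracle = ProjectiveTransform.from_estimate(
                np.array(corr.src), np.array(corr.dst)
            )
            np.testing.assert_allclose(
                h.m, oracle.params / oracle.params[2, 2], rtol=1e-6, atol=1e-8
            )

    def test_collinear_quad_rejected(self):
        degenerate = ((0, 0), (1, 1), (2, 2), (0, 1))
        with pytest.raises(SingularQuadError):
            QuadCorrespondence(degenerate, UNIT_SQUARE)


class TestMapPoint:
    def test_identity_matrix(self):
        h = Homography(np.eye(3))
        assert map_point(h, PixelCoord(5, 7)) == PixelCoord(5, 7)

    def test_half_integer_rounds_up(self):
        # 5 * 0.5 = 2.5 -> floor(2.5 + 0.5) = 3
        h = Homography(np.diag([0.5, 0.5, 1.0]))
        assert map_point(h, PixelCoord(5, 0)) == PixelCoord(3, 0)

    def test_matches_symbolic_oracle(self):
        """Full homogeneous product computed independently, per formula."""
        rng = np.random.default_rng(202)
        for _ in range(100):
            corr = random_general_corr(rng)
            h = fit_homography(corr)
            p = PixelCoord(int(rng.integers(0, 400)), int(rng.integers(0, 400)))
            m = h.m
            w = m[2, 0] * p.x + m[2, 1] * p.y + m[2, 2]
            xr = (m[0, 0] * p.x + m[0, 1] * p.y + m[0, 2]) / w
            yr = (m[1, 0] * p.x + m[1, 1] * p.y + m[1, 2]) / w
            expected_x = math.floor(xr + 0.5)
            expected_y = math.floor(yr + 0.5)
            if expected_x < 0 or expected_y < 0:
                with pytest.raises(OutOfPanelError):
                    map_point(h, p)
            else:
                assert map_point(h, p) == PixelCoord(expected_x, expected_y)

    def test_point_at_infinity(self):
        m = np.array([[1.0, 0, 0], [0, 1.0, 0], [-1.0, 0, 1.0]])
        with pytest.raises(MappingError):
            map_point(Homography(m), PixelCoord(1, 0))

    def test_out_of_panel_carries_raw_coordinates(self):
        h = Homography(np.diag([2.0, 2.0, 1.0]))
        with pytest.raises(OutOfPanelError) as exc:
            map_point(h, PixelCoord(30, 2), panel_shape=(10, 10))
        assert exc.value.raw_x == pytest.approx(60.0)

    def test_negative_result_is_out_of_panel_not_rounded(self):
        m = np.eye(3)
        m[0, 2] = -10
        with pytest.raises(OutOfPanelError):
            map_point(Homography(m), PixelCoord(3, 3))


class TestProperties:
    def test_round_trip_within_one_pixel(self):
        """Forward then inverse homography returns interior points to
        within 1 px after rounding."""
        rng = np.random.default_rng(303)
        for _ in range(200):
            corr = random_rect_corr(rng)
            fwd = fit_homography(corr)
            rev = fit_homography(QuadCorrespondence(corr.dst, corr.src))
            xs = [p[0] for p in corr.src]
            ys = [p[1] for p in corr.src]
            p = PixelCoord(
                int(rng.uniform(min(xs) + 1, max(xs) - 1)),
                int(rng.uniform(min(ys) + 1, max(ys) - 1)),
            )
            q = map_point(fwd, p)
            back = map_point(rev, q)
            assert abs(back.x - p.x) <= 1 and abs(back.y - p.y) <= 1

    def test_rectangle_case_equals_per_axis_interpolation(self):
        """For axis-aligned rectangle correspondences the projective map
        degenerates to independent linear interpolation per axis."""
        rng = np.random.default_rng(404)
        for _ in range(100):
            corr = random_rect_corr(rng)
            h = fit_homography(corr)
            (sx1, sy1), _, (sx2, sy2), _ = corr.src
            (dx1, dy1), _, (dx2, dy2), _ = corr.dst
            p = PixelCoord(
                int(rng.uniform(sx1, sx2)), int(rng.uniform(sy1, sy2))
            )
            lx = dx1 + (p.x - sx1) / (sx2 - sx1) * (dx2 - dx1)
            ly = dy1 + (p.y - sy1) / (sy2 - sy1) * (dy2 - dy1)
            got = map_point(h, p)
            assert got == PixelCoord(math.floor(lx + 0.5), math.floor(ly + 0.5))


class TestHomographyText:
    def test_cached_matrix_round_trip(self):
        rng = np.random.default_rng(505)
        h = fit_homography(random_general_corr(rng))
        np.testing.assert_array_equal(Homography.from_text(h.to_text()).m, h.m)
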