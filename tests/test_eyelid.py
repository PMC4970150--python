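import numpy as np
import pytest

from eyeseg.eyelid import (
    EyeShape,
    Hypothesis,
    MatchParams,
    band_pixels,
    eye_corners,
    generate_hypotheses,
    parabola_from_points,
    score_hypothesis,
    segment_eye,
    shape_mask,
    shape_to_parabolas,
    vote_shape,
)
from eyeseg.synthetic import default_eye_shape


def symmetric_shape(cx=50.0, cy=50.0, R=12.0):
    return default_eye_shape(cx, cy, R)


class TestParabolaFromPoints:
    def test_unit_parabola(self):
        p = parabola_from_points((-1, 1), (0, 0), (1, 1))
        assert (p.a, p.b, p.c) == pytest.approx((1, 0, 0))

    def test_collinear_degenerates_to_line(self):
        p = parabola_from_points((0, 0), (1, 1), (2, 2))
        assert (p.a, p.b, p.c) == pytest.approx((0, 1, 0), abs=1e-12)

    def test_matches_linear_solve_oracle(self):
        pts = [(0, 2), (3, 0), (5, 4)]
        p = parabola_from_points(*pts)
        # independent 3x3 solve
        A = np.array([[x * x, x, 1.0] for x, _ in pts])
        coeffs = np.linalg.solve(A, np.array([y for _, y in pts], float))
        assert (p.a, p.b, p.c) == pytest.approx(tuple(coeffs))

    def test_duplicate_x_rejected(self):
        with pytest.raises(ValueError):
            parabola_from_points((1, 0), (1, 5), (2, 2))


class TestShapeToParabolas:
    def test_symmetric_shape_has_zero_linear_term(self):
        top, bottom = shape_to_parabolas(symmetric_shape(cx=0.0, cy=0.0))
        assert top.b == pytest.approx(0.0, abs=1e-9)
        assert bottom.b == pytest.approx(0.0, abs=1e-9)

    def test_zero_offsets_collapse_to_single_curve(self):
        s = EyeShape(
            cx=0, cy=0, tx=0, ty=-10, bx=0, by=-10,
            tlx=-20, tly=-3, trx=20, try_=-3, bly=0, bry=0,
        )
        top, bottom = shape_to_parabolas(s)
        assert (top.a, top.b, top.c) == pytest.approx((bottom.a, bottom.b, bottom.c))

    def test_parabolas_interpolate_control_points(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            R = rng.uniform(8, 16)
            s = symmetric_shape(rng.uniform(30, 70), rng.uniform(30, 70), R)
            top, bottom = shape_to_parabolas(s)
            assert top(s.cx + s.tx) == pytest.approx(s.cy + s.ty, abs=1e-9)
            assert top(s.cx + s.tlx) == pytest.approx(s.cy + s.tly, abs=1e-9)
            assert bottom(s.cx + s.bx) == pytest.approx(s.cy + s.by, abs=1e-9)
            assert bottom(s.cx + s.trx) == pytest.approx(s.cy + s.try_ + s.bry, abs=1e-9)


class TestBandPixels:
    def test_delta_one_single_row_per_x(self):
        p = parabola_from_points((0, 10), (5, 8), (10, 10))
        pts = band_pixels(p, "inner", 1, (0, 10))
        assert len(pts) == 11

    def test_inner_outer_same_size_interior(self):
        p = parabola_from_points((0, 20), (10, 15), (20, 20))
        inner = band_pixels(p, "inner", 4, (0, 20), (60, 60))
        outer = band_pixels(p, "outer", 4, (0, 20), (60, 60))
        assert len(inner) == len(outer)

    def test_matches_enumeration_oracle(self):
        p = parabola_from_points((0, 12), (6, 9), (12, 12))
        pts = set(map(tuple, band_pixels(p, "inner", 3, (0, 12), (40, 40))))
        expected = set()
        for x in range(0, 13):
            y0 = int(np.rint(p(x)))
            for d in range(1, 4):
                if 0 <= y0 + d < 40:
                    expected.add((x, y0 + d))
        assert pts == expected

    def test_bottom_eyelid_inner_goes_up(self):
        p = parabola_from_points((0, 10), (5, 14), (10, 10))
        pts = band_pixels(p, "inner", 2, (5, 5), eyelid="bottom")
        assert set(pts[:, 1]) == {13, 12}  # above the curve at x=5 (y=14)


class TestScoreHypothesis:
    def test_uniform_map_scores_zero(self):
        s = symmetric_shape()
        m = np.full((100, 100), 0.7)
        assert score_hypothesis(m, s, MatchParams()) == pytest.approx(0.0)

    def test_truth_on_binary_map_scores_half(self):
        s = symmetric_shape(cx=50.0, cy=50.0, R=12.0)
        m = shape_mask(s, (100, 100)).astype(float)
        # central x-range: bands stay fully inside/outside the eye region
        omega = score_hypothesis(m, s, MatchParams(), x_range=(38, 62))
        assert omega == pytest.approx(0.5)

    def test_displaced_hypothesis_nonpositive(self):
        s = symmetric_shape(cx=50.0, cy=50.0)
        m = shape_mask(s, (120, 120)).astype(float)
        displaced = s.translated(0, 55)  # fully outside the true eye
        assert score_hypothesis(m, displaced, MatchParams()) <= 0.0


class TestGenerateHypotheses:
    def test_degenerate_bounds_reproduce_exact_shape(self):
        bounds = {
            "tx": (0, 0), "ty": (-1.5, -1.5), "bx": (0, 0), "by": (1.5, 1.5),
            "tlx": (-2, -2), "tly": (-0.4, -0.4), "trx": (2, 2), "try_": (-0.4, -0.4),
            "bly": (1, 1), "bry": (1, 1),
        }
        params = MatchParams(n_hypotheses=1)
        (h,) = generate_hypotheses((10, 10), 10.0, params, bounds)
        assert h.shape.tx == 0 and h.shape.ty == -15.0 and h.shape.tlx == -20.0

    def test_ordering_invariant_enforced(self):
        params = MatchParams(n_hypotheses=500, seed=3)
        hyps = generate_hypotheses((0, 0), 10.0, params)
        for h in hyps:
            assert h.shape.tlx < h.shape.tx < h.shape.trx

    def test_samples_fill_bounds(self):
        params = MatchParams(n_hypotheses=10_000, seed=1)
        hyps = generate_hypotheses((0, 0), 10.0, params)
        tys = np.array([h.shape.ty for h in hyps])
        assert tys.min() < -21.0 and tys.max() > -9.0  # bounds are [-22, -8]

    def test_deterministic_given_seed(self):
        params = MatchParams(n_hypotheses=50, seed=7)
        a = generate_hypotheses((5, 5), 12.0, params)
        b = generate_hypotheses((5, 5), 12.0, params)
        assert all(
            np.array_equal(x.shape.as_vector(), y.shape.as_vector())
            for x, y in zip(a, b)
        )


class TestVoteShape:
    def test_identical_hypotheses_exact(self):
        s = symmetric_shape()
        hyps = [Hypothesis(s, 0.3) for _ in range(10)]
        voted = vote_shape(hyps, MatchParams())
        np.testing.assert_allclose(voted.as_vector(), s.as_vector())

    def test_equal_weights_give_midpoint(self):
        s1 = symmetric_shape(cx=40.0)
        s2 = symmetric_shape(cx=60.0)
        voted = vote_shape([Hypothesis(s1, 0.4), Hypothesis(s2, 0.4)], MatchParams(top_fraction=1.0))
        np.testing.assert_allclose(
            voted.as_vector(), (s1.as_vector() + s2.as_vector()) / 2
        )

    def test_result_in_convex_hull_of_selected(self):
        rng = np.random.default_rng(2)
        params = MatchParams(n_hypotheses=60, seed=11)
        hyps = generate_hypotheses((50, 50), 10.0, params)
        for h in hyps:
            h.omega = float(rng.uniform(-0.2, 0.6))
        voted = vote_shape(hyps, params)
        ranked = sorted(hyps, key=lambda h: -h.omega)[:18]
        vecs = np.stack([h.shape.as_vector() for h in ranked])
        assert np.all(voted.as_vector() >= vecs.min(axis=0) - 1e-9)
        assert np.all(voted.as_vector() <= vecs.max(axis=0) + 1e-9)


class TestEyeCorners:
    def test_symmetric_intersection(self):
        p1 = parabola_from_points((-2, 4), (0, 0), (2, 4))  # y = x^2
        p2 = parabola_from_points((-2, -2), (0, 2), (2, -2))  # y = 2 - x^2
        left, right = eye_corners(p1, p2)
        assert left == pytest.approx((-1.0, 1.0))
        assert right == pytest.approx((1.0, 1.0))

    def test_identical_parabolas_error(self):
        p = parabola_from_points((-1, 1), (0, 0), (1, 1))
        with pytest.raises(ValueError):
            eye_corners(p, p)

    def test_corners_satisfy_both_curves(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            s = symmetric_shape(rng.uniform(40, 60), rng.uniform(40, 60), rng.uniform(9, 15))
            top, bottom = shape_to_parabolas(s)
            for x, y in eye_corners(top, bottom):
                assert top(x) == pytest.approx(y, abs=1e-9)
                assert bottom(x) == pytest.approx(y, abs=1e-9)


class TestSegmentEye:
    def test_deterministic_under_seed(self):
        truth = symmetric_shape(60.0, 60.0, 12.0)
        m = shape_mask(truth, (120, 120)).astype(float)
        params = MatchParams(seed=5)
        out1 = segment_eye(m, (60.0, 60.0), 12.0, params, rng=np.random.default_rng(5))
        out2 = segment_eye(m, (60.0, 60.0), 12.0, params, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(out1[0].as_vector(), out2[0].as_vector())
        np.testing.assert_array_equal(out1[2], out2[2])

    def test_recovers_truth_within_band_width(self):
        truth = symmetric_shape(60.0, 60.0, 12.0)
        m = shape_mask(truth, (120, 120)).astype(float)
        shape, corners, mask = segment_eye(
            m, (60.0, 60.0), 12.0, MatchParams(seed=0), rng=np.random.default_rng(0)
        )
        assert np.max(np.abs(shape.as_vector() - truth.as_vector())) <= 5.0
        assert mask.sum() > 0

    def test_translation_equivariance(self):
        truth = symmetric_shape(50.0, 50.0, 10.0)
        m = shape_mask(truth, (140, 140)).astype(float)
        dx, dy = 17, 9
        m2 = np.roll(np.roll(m, dy, axis=0), dx, axis=1)
        s1, _, _ = segment_eye(m, (50.0, 50.0), 10.0, MatchParams(seed=3),
                               rng=np.random.default_rng(3))
        s2, _, _ = segment_eye(m2, (50.0 + dx, 50.0 + dy), 10.0, MatchParams(seed=3),
                               rng=np.random.default_rng(3))
        # band rows are rounded to integer pixels; float noise in the
        # parabola solve can flip a borderline row, so equivariance holds to
        # a small fraction of a pixel rather than exactly
        np.testing.assert_allclose(
            s2.as_vector() - s1.as_vector(),
            [dx, dy] + [0.0] * 10,
            atol=0.1,
        )

    def test_voted_omega_at_least_median_of_selected(self):
        truth = symmetric_shape(60.0, 60.0, 12.0)
        m = shape_mask(truth, (120, 120)).astype(float)
        params = MatchParams(seed=8)
        hyps = generate_hypotheses((60.0, 60.0), 12.0, params, rng=np.random.default_rng(8))
        x_range = (60 - 36, 60 + 36)
        for h in hyps:
            h.omega = score_hypothesis(m, h.shape, params, x_range)
        voted = vote_shape(hyps, params)
        sel = sorted(h.omega for h in hyps)[-60:]
        voted_omega = score_hypothesis(m, voted, params, x_range)
        assert voted_omega >= np.median(sel)

    def test_mask_bounded_by_corner_x_range(self):
        truth = symmetric_shape(60.0, 60.0, 12.0)
        m = shape_mask(truth, (120, 120)).astype(float)
        shape, ((lx, _), (rx, _)), mask = segment_eye(
            m, (60.0, 60.0), 12.0, MatchParams(seed=1), rng=np.random.default_rng(1)
        )
        xs = np.nonzero(mask.any(axis=0))[0]
        assert xs.min() >= np.floor(lx) and xs.max() <= np.ceil(rx)
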