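"""Angle measurement: thresholding, segmentation, landmarks, lines, angles."""

import numpy as np
import pytest

from grafhip import (
    BoundingBox,
    Detection,
    DetectionSet,
    Line,
    MeasurementError,
    PhantomSpec,
    StructureClass,
    angle_between,
    classify_graf,
    fit_baseline,
    locate_landmarks,
    max_entropy_threshold,
    measure,
    render_frame,
    segment_structure,
    tangent_point_from,
)


def kapur_oracle(hist):
    """Independent exhaustive Kapur maximizer with the smallest-t tie-break."""
    hist = np.asarray(hist, dtype=float)
    p = hist / hist.sum()

    def entropy(q):
        q = q[q > 0]
        q = q / q.sum()
        return float(-(q * np.log(q)).sum())

    best, best_value = None, -np.inf
    for t in range(hist.size - 1):
        pb, pf = p[: t + 1].sum(), p[t + 1 :].sum()
        if pb <= 0 or pf <= 0:
            continue
        value = entropy(p[: t + 1]) + entropy(p[t + 1 :])
        if value > best_value + 1e-12:
            best_value, best = value, t
    return best


class TestMaxEntropyThreshold:
    def test_uniform_histogram_splits_in_half(self):
        assert max_entropy_threshold(np.ones(256)) == 127

    def test_two_spikes_tie_resolves_to_smallest(self):
        hist = np.zeros(256)
        hist[10] = hist[240] = 7
        t = max_entropy_threshold(hist)
        assert t == 10
        levels = np.array([10] * 7 + [240] * 7)
        assert np.array_equal(np.nonzero(levels > t)[0], np.arange(7, 14))

    def test_single_level_rejected(self):
        hist = np.zeros(256)
        hist[40] = 100
        with pytest.raises(MeasurementError):
            max_entropy_threshold(hist)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            hist = rng.integers(0, 60, 256)
            hist[rng.integers(0, 256, 200)] = 0
            if np.count_nonzero(hist) < 2:
                continue
            assert max_entropy_threshold(hist) == kapur_oracle(hist)


class TestSegmentStructure:
    def test_phantom_ilium_coverage(self, default_frame):
        box = default_frame.true_boxes.box(StructureClass.ILIUM)
        mask = segment_structure(default_frame.image, box)
        x0, y0 = int(np.floor(box.x_min)), int(np.floor(box.y_min))
        region = default_frame.image[y0 : y0 + mask.shape[0], x0 : x0 + mask.shape[1]]
        core = region >= 150  # solidly rendered ilium pixels
        background = region <= 30  # pure background in the box
        assert (mask & core).sum() / core.sum() >= 0.8
        assert not (mask & background).any()

    def test_constant_region_rejected(self):
        img = np.full((50, 50), 90, dtype=np.uint8)
        with pytest.raises(MeasurementError):
            segment_structure(img, BoundingBox(5, 5, 30, 30))

    def test_keeps_only_largest_blob(self):
        img = np.zeros((40, 60), dtype=np.uint8)
        img[10:30, 5:25] = 200  # large blob
        img[15:20, 40:45] = 200  # small blob
        mask = segment_structure(img, BoundingBox(0, 0, 60, 40))
        assert mask[15, 10] and not mask[17, 42]


class TestFitBaseline:
    def test_straight_vertical_edge(self):
        mask = np.zeros((60, 30), dtype=bool)
        mask[0:51, 10:13] = True
        line = fit_baseline(mask, BoundingBox(0, 0, 30, 60))
        assert abs(line.direction[0]) < 1e-9  # vertical
        assert line.point[0] == pytest.approx(10.0, abs=1e-6)

    def test_phantom_band_direction(self):
        frame = render_frame(PhantomSpec(ilium_tilt=4.0, seed=6))
        box = frame.true_boxes.box(StructureClass.ILIUM)
        mask = segment_structure(frame.image, box)
        line = fit_baseline(mask, box)
        assert angle_between(line, frame.true_baseline) < 1.0

    def test_tangent_condition(self, default_frame):
        box = default_frame.true_boxes.box(StructureClass.ILIUM)
        mask = segment_structure(default_frame.image, box)
        line = fit_baseline(mask, box)
        rows = np.nonzero(mask.any(axis=1))[0]
        x0, y0 = int(np.floor(box.x_min)), int(np.floor(box.y_min))
        dx, dy = line.direction
        touched = False
        for r in rows:
            c = np.nonzero(mask[r])[0][0]
            # signed offset toward the superficial side
            off = -dy * (c + x0 - line.point[0]) + dx * (r + y0 - line.point[1])
            assert off <= 1e-6  # on or deep to the line
            touched = touched or abs(off) <= 0.5
        assert touched

    def test_short_mask_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0:3, 4] = True
        with pytest.raises(MeasurementError):
            fit_baseline(mask, BoundingBox(0, 0, 10, 10))


def one_sided_oracle(pivot, contour):
    """O(n^2) check: the supporting point with all cross products >= 0."""
    pts = np.unique(np.asarray(contour, dtype=float), axis=0)
    v = pts - np.asarray(pivot, dtype=float)
    tol = 1e-9 * max(1.0, float((np.abs(v) ** 2).max()))
    best, best_norm = None, -1.0
    for i in range(len(v)):
        cross = v[i, 0] * v[:, 1] - v[i, 1] * v[:, 0]
        if cross.min() >= -tol:
            norm = float(np.hypot(*v[i]))
            if norm > best_norm:
                best_norm, best = norm, tuple(pts[i])
    return best


class TestTangentPointFrom:
    def test_spec_toy_example(self):
        assert tangent_point_from((0, 0), [(5, 1), (5, 2), (5, 3)]) == (5.0, 1.0)

    def test_single_point_contour(self):
        assert tangent_point_from((0, 0), [(3, 4)]) == (3.0, 4.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_contours(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            n = int(rng.integers(4, 80))
            ang = rng.uniform(0, 2 * np.pi, n)
            radius = rng.uniform(3, 30, n)  # non-convex star-shaped contours
            pts = np.column_stack(
                [60 + radius * np.cos(ang), 60 + radius * np.sin(ang)]
            )
            pivot = (float(rng.uniform(100, 150)), float(rng.uniform(100, 150)))
            assert tangent_point_from(pivot, pts) == one_sided_oracle(pivot, pts)

    def test_circle_contour_satisfies_one_sided_property(self):
        ang = np.linspace(0, 2 * np.pi, 180, endpoint=False)
        pts = np.column_stack([50 + 20 * np.cos(ang), 50 + 20 * np.sin(ang)])
        pivot = (120.0, 90.0)
        p = tangent_point_from(pivot, pts)
        v = pts - np.asarray(pivot)
        d = np.asarray(p) - np.asarray(pivot)
        cross = d[0] * v[:, 1] - d[1] * v[:, 0]
        assert cross.min() >= -1e-6


class TestAngleBetween:
    def test_identical_and_perpendicular(self):
        v = Line((0, 0), (0, 1))
        assert angle_between(v, v) == 0.0
        assert angle_between(v, Line((0, 0), (1, 0))) == pytest.approx(90.0)

    def test_sixty_degree_construction(self):
        v = Line((0, 0), (0, 1))
        d = Line((0, 0), (np.sin(np.radians(60)), np.cos(np.radians(60))))
        assert angle_between(v, d) == pytest.approx(60.0)


class TestLocateLandmarks:
    def test_landmarks_within_3px_of_truth(self, default_frame):
        lm = locate_landmarks(default_frame.image, default_frame.true_boxes)
        truth = default_frame.true_landmarks
        for name in ("bony_roof_point", "bony_rim_point", "lower_limb_point", "labrum_center"):
            est = np.asarray(getattr(lm, name))
            ref = np.asarray(getattr(truth, name))
            assert np.hypot(*(est - ref)) <= 3.0, name

    def test_missing_structure_is_named(self, default_frame):
        partial = DetectionSet(
            [d for s, d in default_frame.true_boxes.items() if s != StructureClass.LOWER_LIMB]
        )
        with pytest.raises(MeasurementError, match="lower_limb"):
            locate_landmarks(default_frame.image, partial)

    def test_symmetric_labrum_centroid(self, default_frame):
        lm = locate_landmarks(default_frame.image, default_frame.true_boxes)
        true_center = default_frame.true_landmarks.labrum_center
        assert np.hypot(
            lm.labrum_center[0] - true_center[0], lm.labrum_center[1] - true_center[1]
        ) <= 1.0


class TestClassifyGraf:
    @pytest.mark.parametrize("alpha,expected", [(61.0, "I"), (60.0, "I"), (59.0, "II")])
    def test_boundary_inclusive_to_type_one(self, alpha, expected):
        assert classify_graf(alpha) == expected

    def test_flip_exactly_at_configured_boundary(self):
        alphas = np.arange(50.0, 70.0, 0.5)
        labels = [classify_graf(a, boundary=62.0) for a in alphas]
        flips = [i for i in range(1, len(labels)) if labels[i] != labels[i - 1]]
        assert len(flips) == 1 and alphas[flips[0]] == 62.0


class TestMeasure:
    def test_recovery_and_type(self, grid_frames):
        frame = grid_frames[(65.0, 55.0)]
        res = measure(frame.image, frame.true_boxes)
        assert abs(res.alpha - 65.0) <= 2.0
        assert abs(res.beta - 55.0) <= 2.0
        assert res.graf_type == "I"
        assert res.lines.bony_roof_line.distance_to(res.landmarks.lower_limb_point) < 0.5
        assert res.lines.cartilage_roof_line.distance_to(res.landmarks.labrum_center) < 0.5
        assert res.lines.cartilage_roof_line.distance_to(res.landmarks.bony_rim_point) < 0.5

    def test_dysplastic_alpha_is_type_two(self, grid_frames):
        frame = grid_frames[(55.0, 55.0)]
        assert measure(frame.image, frame.true_boxes).graf_type == "II"

    def test_deterministic(self, default_frame):
        r1 = measure(default_frame.image, default_frame.true_boxes)
        r2 = measure(default_frame.image, default_frame.true_boxes)
        assert r1 == r2
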