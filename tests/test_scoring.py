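"""Standard-plane scoring: moments, orientation, sub-scores, frame selection."""

import numpy as np
import pytest

from grafhip import (
    BoundingBox,
    Detection,
    DetectionSet,
    PhantomSpec,
    ScoringError,
    ScoringWeights,
    StructureClass,
    angle_score,
    compute_moments,
    expand_box,
    frame_score,
    height_width_ratio,
    ilium_score,
    orientation_theta,
    oracle_detector,
    render_frame,
    render_video,
    select_standard_frame,
)
from conftest import bar_image


class TestExpandBox:
    def test_zero_margin_is_identity(self):
        box = BoundingBox(10, 10, 20, 30)
        assert expand_box(box, (100, 100), 0.0) == box

    def test_fractional_margin(self):
        out = expand_box(BoundingBox(10, 10, 20, 30), (100, 100), 0.1)
        assert out == BoundingBox(9, 8, 21, 32)

    def test_clipped_at_image_edge(self):
        out = expand_box(BoundingBox(0, 0, 10, 10), (100, 100), 0.5)
        assert out == BoundingBox(0, 0, 15, 15)


class TestComputeMoments:
    def test_uniform_3x3(self):
        m = compute_moments(np.ones((3, 3)))
        assert m.m00 == 9 and (m.xc, m.yc) == (1.0, 1.0)
        assert m.a == pytest.approx(2 / 3) and m.c == pytest.approx(2 / 3)
        assert m.b == 0.0

    def test_single_pixel(self):
        v = np.zeros((8, 8))
        v[5, 2] = 3.0  # row j=5, column i=2
        m = compute_moments(v)
        assert (m.xc, m.yc) == (2.0, 5.0)
        assert m.a == m.b == m.c == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 255, (8, 8))
        m = compute_moments(v)
        oracle = {}
        for p in range(3):
            for q in range(3):
                if p + q > 2:
                    continue
                total = 0.0
                for j in range(8):
                    for i in range(8):
                        total += (i**p) * (j**q) * v[j, i]
                oracle[(p, q)] = total
        for key, attr in [((0, 0), m.m00), ((1, 0), m.m10), ((0, 1), m.m01),
                          ((1, 1), m.m11), ((2, 0), m.m20), ((0, 2), m.m02)]:
            assert attr == pytest.approx(oracle[key], rel=1e-9)

    def test_zero_region_rejected(self):
        with pytest.raises(ValueError):
            compute_moments(np.zeros((4, 4)))


class TestOrientation:
    def test_vertical_bar_is_zero(self):
        v = np.zeros((6, 3))
        v[0:5, 1] = 1.0
        assert orientation_theta(compute_moments(v)) == 0.0

    def test_horizontal_bar_is_ninety(self):
        v = np.zeros((3, 6))
        v[1, 0:5] = 1.0
        assert orientation_theta(compute_moments(v)) == pytest.approx(90.0)

    def test_isotropic_region_is_zero(self):
        assert orientation_theta(compute_moments(np.ones((9, 9)))) == 0.0

    @pytest.mark.parametrize("tilt", [-30, -15, -7, 0, 7, 15, 30])
    def test_recovers_rendered_bar_tilt(self, tilt):
        theta = orientation_theta(compute_moments(bar_image(tilt)))
        assert abs(theta - tilt) < 1.0


class TestAngleScore:
    @pytest.mark.parametrize(
        "theta,expected", [(0.0, 1.0), (10.0, 0.0), (5.0, 0.5), (15.0, -0.5), (-5.0, 0.5)]
    )
    def test_values(self, theta, expected):
        assert angle_score(theta) == pytest.approx(expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            angle_score(float("nan"))


class TestHeightWidthRatio:
    def test_examples(self):
        assert height_width_ratio(BoundingBox(10, 10, 20, 40)) == 3.0
        assert height_width_ratio(BoundingBox(0, 0, 7, 7)) == 1.0

    def test_true_ilium_ratio_peaks_at_zero_tilt(self):
        video = render_video(PhantomSpec(seed=1), [-10.0, -5.0, 0.0, 5.0, 10.0])
        ratios = [
            height_width_ratio(f.true_boxes.box(StructureClass.ILIUM))
            for f in video.frames
        ]
        assert int(np.argmax(ratios)) == 2


def vertical_bar_scene():
    """Image + ilium box with height/width exactly 2 and a vertical bar inside."""
    img = np.zeros((100, 100), dtype=np.uint8)
    img[22:58, 48:53] = 200
    box = BoundingBox(40, 20, 60, 60)  # w 20, h 40 -> Shw = 2
    return img, box


class TestIliumScore:
    def test_printed_weight_substitution(self):
        img, box = vertical_bar_scene()
        ish = ilium_score(1.0, box, img)
        assert ish.theta == pytest.approx(0.0, abs=1e-6)
        assert ish.s_hw == 2.0
        assert ish.s_ilium == pytest.approx(0.2 * 1.0 + 0.3 * 2.0 + 0.5 * 1.0)

    def test_sub_score_identity_holds(self, default_frame):
        box = default_frame.true_boxes.box(StructureClass.ILIUM)
        ish = ilium_score(0.7, box, default_frame.image)
        w = ScoringWeights()
        assert ish.s_ilium == pytest.approx(
            w.lam5 * ish.s_conf + w.lam6 * ish.s_hw + w.lam7 * ish.s_angle, abs=1e-9
        )
        assert ish.s_angle == pytest.approx(1 - abs(ish.theta) / 10, abs=1e-9)

    def test_tilt_strictly_degrades_score(self):
        scores = []
        for tilt in (0.0, 4.0, 8.0):
            frame = render_frame(PhantomSpec(ilium_tilt=tilt, seed=4))
            box = frame.true_boxes.box(StructureClass.ILIUM)
            scores.append(ilium_score(1.0, box, frame.image).s_ilium)
        assert scores[0] > scores[1] > scores[2]


class TestFrameScore:
    def test_full_confidence_example(self):
        img, box = vertical_bar_scene()
        # blobs laid out to satisfy R1-R4 around the bar
        ds = DetectionSet(
            [
                Detection(StructureClass.ILIUM, box, 1.0),
                Detection(StructureClass.LOWER_LIMB, BoundingBox(75, 70, 85, 80), 1.0),
                Detection(StructureClass.BONY_RIM, BoundingBox(58, 62, 66, 70), 1.0),
                Detection(StructureClass.LABRUM, BoundingBox(30, 70, 40, 80), 1.0),
            ]
        )
        fs = frame_score(img, ds)
        assert fs.position_valid
        assert fs.s == pytest.approx(3 + 1 + 1 + 1.3)
        # dropping the lower limb zeroes the heaviest term
        ds2 = DetectionSet([d for s, d in ds.items() if s != StructureClass.LOWER_LIMB])
        assert frame_score(img, ds2).s == pytest.approx(3.3)

    def test_invalid_layout_scores_zero(self):
        img, box = vertical_bar_scene()
        ds = DetectionSet(
            [
                Detection(StructureClass.ILIUM, box, 1.0),
                Detection(StructureClass.BONY_RIM, BoundingBox(58, 62, 66, 70), 1.0),
                Detection(StructureClass.LABRUM, BoundingBox(80, 70, 90, 80), 1.0),
            ]
        )
        fs = frame_score(img, ds)
        assert not fs.position_valid and fs.s == 0.0

    def test_score_increasesing_in_each_confidence(self, default_frame):
        base = dict(default_frame.true_boxes)
        for target in (StructureClass.LOWER_LIMB, StructureClass.LABRUM,
                       StructureClass.BONY_RIM, StructureClass.ILIUM):
            lowered = {
                s: (Detection(s, d.box, 0.4) if s is target else d)
                for s, d in base.items()
            }
            high = frame_score(default_frame.image, DetectionSet(base.values()))
            low = frame_score(default_frame.image, DetectionSet(lowered.values()))
            assert high.s > low.s, target

    def test_eq_consistency_on_phantom(self, default_frame):
        fs = frame_score(default_frame.image, default_frame.true_boxes)
        w = ScoringWeights()
        assert fs.s == pytest.approx(
            w.lam1 * fs.s_lower_limb
            + w.lam2 * fs.s_labrum
            + w.lam3 * fs.s_bony_rim
            + w.lam4 * fs.s_ilium.s_ilium,
            abs=1e-9,
        )


class TestSelectStandardFrame:
    def test_earliest_exact_tie_wins(self, default_frame):
        frames = [default_frame.image, default_frame.image.copy()]
        idx, scores = select_standard_frame(frames, oracle_detector([default_frame]))
        assert idx == 0 and scores[0].s == scores[1].s

    def test_sweep_selects_best_frame(self):
        video = render_video(PhantomSpec(seed=9), [-10.0, -5.0, 0.0, 5.0, 10.0])
        idx, scores = select_standard_frame(
            [f.image for f in video.frames], oracle_detector(video)
        )
        assert idx == video.best_frame_index == 2
        assert scores[2].s == max(fs.s for fs in scores)

    def test_single_good_frame(self, default_frame):
        idx, _ = select_standard_frame([default_frame.image], oracle_detector([default_frame]))
        assert idx == 0

    def test_blank_video_has_no_usable_plane(self):
        blanks = [np.zeros((256, 256), dtype=np.uint8)] * 3
        with pytest.raises(ScoringError, match="no usable plane"):
            select_standard_frame(blanks, lambda img: [])
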