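"""Standard-plane scoring for dynamic (video) measurement.

Each video frame is scored by how well it meets Graf's standard-plane
criteria, and the highest-scoring frame is selected for angle measurement.
The frame score combines the detector confidences of the four structures with
a shape term for the ilium:

    S = lam1*S_lower_limb + lam2*S_labrum + lam3*S_bony_rim + lam4*S_ilium

    S_ilium = lam5*S_conf + lam6*S_hw + lam7*S_angle,   S_angle = 1 - |theta|/10

where S_hw is the height-width ratio of the ilium bounding box (a straight,
vertical ilium occupies little width) and theta is the tilt of the ilium from
the image vertical in degrees, estimated from second-order image moments of
the expanded ilium region.  S_angle peaks at 1 for a perfectly vertical ilium
and goes negative beyond 10 degrees of tilt — the negativity is a deliberate
penalty and is never clamped.  Default weights: lam1=3, lam2=lam3=lam4=1,
lam5=0.2, lam6=0.3, lam7=0.5; the lower limb is weighted highest because no
diagnosis may be made when it is not seen.

Frames whose detected boxes violate the clinical layout check score 0.
Scores are comparable only within one video; S_hw is intentionally not
normalized across videos.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detection import (
    BoundingBox,
    DetectionSet,
    Detector,
    PositionCheck,
    StructureClass,
    check_relative_positions,
    select_best_per_class,
)


class ScoringError(ValueError):
    """Raised when no usable plane exists in a frame sequence."""


@dataclass(frozen=True)
class ScoringWeights:
    """Frame-level (lam1-lam4) and ilium-level (lam5-lam7) score weights."""

    lam1: float = 3.0  # lower limb of the os ilium
    lam2: float = 1.0  # labrum
    lam3: float = 1.0  # bony rim
    lam4: float = 1.0  # ilium shape score
    lam5: float = 0.2  # ilium confidence
    lam6: float = 0.3  # ilium height-width ratio
    lam7: float = 0.5  # ilium angle score

    def __post_init__(self) -> None:
        for name in ("lam1", "lam2", "lam3", "lam4", "lam5", "lam6", "lam7"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


DEFAULT_WEIGHTS = ScoringWeights()


# ---------------------------------------------------------------------------
# Image moments and orientation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MomentSet:
    """Raw and central image moments of a pixel region.

    Moments are ``M_pq = sum_i sum_j i^p j^q V(i, j)`` with ``i`` over the
    region's columns and ``j`` over its rows; ``(xc, yc)`` is the intensity
    centroid and ``a``, ``b``, ``c`` are the normalized second-order central
    terms (variances along columns/rows and their covariance).
    """

    m00: float
    m10: float
    m01: float
    m11: float
    m20: float
    m02: float
    xc: float
    yc: float
    a: float
    b: float
    c: float


def compute_moments(region: np.ndarray) -> MomentSet:
    """Moments up to order 2 of an intensity region (rows x columns array)."""
    v = np.asarray(region, dtype=float)
    if v.ndim != 2 or v.size == 0:
        raise ValueError("region must be a non-empty 2-D array")
    j, i = np.mgrid[0 : v.shape[0], 0 : v.shape[1]]  # j rows, i columns
    m00 = float(v.sum())
    if m00 <= 0:
        raise ValueError("region has zero total intensity (M00 = 0)")
    m10 = float((i * v).sum())
    m01 = float((j * v).sum())
    m11 = float((i * j * v).sum())
    m20 = float((i * i * v).sum())
    m02 = float((j * j * v).sum())
    xc = m10 / m00
    yc = m01 / m00
    return MomentSet(
        m00=m00,
        m10=m10,
        m01=m01,
        m11=m11,
        m20=m20,
        m02=m02,
        xc=xc,
        yc=yc,
        a=m20 / m00 - xc * xc,
        b=m11 / m00 - xc * yc,
        c=m02 / m00 - yc * yc,
    )


def orientation_theta(m: MomentSet) -> float:
    """Tilt of the region's major axis from the image vertical, in degrees.

    Uses the half-angle principal-axis relation evaluated with a two-argument
    arctangent, ``theta_axis = 0.5 * atan2(2b, a - c)`` (measured from the
    column axis), then reports the deviation from the vertical wrapped to
    (-90, 90].  Positive when the top of the axis leans toward larger column
    index; isotropic regions return 0.
    """
    if abs(m.a - m.c) < 1e-12 and abs(m.b) < 1e-12:
        return 0.0
    theta_axis = 0.5 * np.degrees(np.arctan2(2.0 * m.b, m.a - m.c))
    dev = theta_axis + 90.0  # deviation of the major axis from vertical
    if dev > 90.0:
        dev -= 180.0
    return float(dev)


def angle_score(theta: float) -> float:
    """Ilium angle score ``1 - |theta| / 10``; negative beyond 10 degrees."""
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    return 1.0 - abs(theta) / 10.0


def height_width_ratio(box: BoundingBox) -> float:
    """Height-width ratio of a bounding box (larger for a vertical ilium)."""
    if box.width <= 0:
        raise ValueError("box has zero width")
    return box.height / box.width


def expand_box(
    box: BoundingBox, image_shape: tuple[int, int], margin_fraction: float
) -> BoundingBox:
    """Grow each side by ``margin_fraction`` of the box dimension, clipped.

    ``image_shape`` is (rows, cols).  Used to make sure the scored region
    contains the entire ilium even when the detector box is tight.
    """
    if margin_fraction < 0:
        raise ValueError("margin_fraction must be non-negative")
    rows, cols = image_shape
    dx = margin_fraction * box.width
    dy = margin_fraction * box.height
    return BoundingBox(
        x_min=max(0.0, box.x_min - dx),
        y_min=max(0.0, box.y_min - dy),
        x_max=min(float(cols), box.x_max + dx),
        y_max=min(float(rows), box.y_max + dy),
    )


# ---------------------------------------------------------------------------
# Frame scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IliumShapeScore:
    """The ilium sub-score and its parts: S_ilium = lam5*Sconf + lam6*Shw + lam7*Sangle."""

    s_conf: float
    s_hw: float
    s_angle: float
    theta: float
    s_ilium: float


@dataclass(frozen=True)
class FrameScore:
    """Total frame score S and its sub-scores (Eq. S definition above)."""

    s: float
    s_lower_limb: float
    s_labrum: float
    s_bony_rim: float
    s_ilium: IliumShapeScore | None
    position_valid: bool
    position_reasons: tuple[str, ...] = ()


def ilium_score(
    conf: float,
    box: BoundingBox,
    image: np.ndarray,
    weights: ScoringWeights = DEFAULT_WEIGHTS,
    margin_fraction: float = 0.1,
) -> IliumShapeScore:
    """Shape-aware ilium sub-score from confidence, box ratio, and tilt.

    The box is expanded by ``margin_fraction`` per side, the region median is
    subtracted as a background estimate (clipped at zero), and theta is the
    moment-based tilt of the remaining intensity from the vertical.
    """
    if conf <= 0:
        raise ValueError("ilium_score requires a present ilium (conf > 0)")
    image = np.asarray(image)
    roi_box = expand_box(box, image.shape, margin_fraction)
    x0, y0 = int(np.floor(roi_box.x_min)), int(np.floor(roi_box.y_min))
    x1, y1 = int(np.ceil(roi_box.x_max)), int(np.ceil(roi_box.y_max))
    roi = image[y0:y1, x0:x1].astype(float)
    roi = np.clip(roi - np.median(roi), 0.0, None)
    if roi.sum() <= 0:
        theta = 0.0
    else:
        theta = orientation_theta(compute_moments(roi))
    s_angle = angle_score(theta)
    s_hw = height_width_ratio(box)
    s_ilium = weights.lam5 * conf + weights.lam6 * s_hw + weights.lam7 * s_angle
    return IliumShapeScore(
        s_conf=conf, s_hw=s_hw, s_angle=s_angle, theta=theta, s_ilium=s_ilium
    )


def frame_score(
    image: np.ndarray,
    ds: DetectionSet,
    weights: ScoringWeights = DEFAULT_WEIGHTS,
    margin_fraction: float = 0.1,
) -> FrameScore:
    """Score one frame from its detections.

    Absent structures contribute 0 (their confidence); frames failing the
    relative-position check score 0 outright, since such detections cannot be
    trusted for measurement.
    """
    image = np.asarray(image)
    check = check_relative_positions(ds, image.shape)
    s_ll = ds.confidence(StructureClass.LOWER_LIMB)
    s_lab = ds.confidence(StructureClass.LABRUM)
    s_rim = ds.confidence(StructureClass.BONY_RIM)
    ish: IliumShapeScore | None = None
    if ds.present(StructureClass.ILIUM):
        ish = ilium_score(
            ds.confidence(StructureClass.ILIUM),
            ds.box(StructureClass.ILIUM),
            image,
            weights,
            margin_fraction,
        )
    if not check.valid:
        return FrameScore(
            s=0.0,
            s_lower_limb=s_ll,
            s_labrum=s_lab,
            s_bony_rim=s_rim,
            s_ilium=ish,
            position_valid=False,
            position_reasons=check.reasons,
        )
    s_il = ish.s_ilium if ish is not None else 0.0
    s = (
        weights.lam1 * s_ll
        + weights.lam2 * s_lab
        + weights.lam3 * s_rim
        + weights.lam4 * s_il
    )
    return FrameScore(
        s=s,
        s_lower_limb=s_ll,
        s_labrum=s_lab,
        s_bony_rim=s_rim,
        s_ilium=ish,
        position_valid=True,
    )


def confidence_sum_score(ds: DetectionSet) -> float:
    """Ablation baseline: the plain sum of the four raw confidences."""
    return sum(ds.confidence(s) for s in StructureClass)


def select_standard_frame(
    frames: Sequence[np.ndarray],
    detector: Detector,
    weights: ScoringWeights = DEFAULT_WEIGHTS,
    margin_fraction: float = 0.1,
) -> tuple[int, list[FrameScore]]:
    """Score every frame and return (argmax index, all frame scores).

    Exact ties go to the earliest frame.  If no frame attains a positive
    score there is no usable plane in the sequence and a
    :class:`ScoringError` is raised — in that situation no diagnosis should
    be made.
    """
    if len(frames) == 0:
        raise ValueError("at least one frame is required")
    scores: list[FrameScore] = []
    for img in frames:
        ds = select_best_per_class(detector(np.asarray(img)))
        scores.append(frame_score(img, ds, weights, margin_fraction))
    s_values = [fs.s for fs in scores]
    best = int(np.argmax(s_values))
    if s_values[best] <= 0:
        raise ScoringError("no usable plane: every frame scored zero or below")
    return best, scores
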