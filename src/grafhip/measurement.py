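"""Angle measurement on a Graf standard plane.

Given a grayscale hip image and one bounding box per anatomical structure,
this module segments each structure with maximum-entropy (Kapur) thresholding,
localizes the four Graf landmarks (bony roof point, bony rim point, lower
limb point, labrum center), constructs the three measurement lines, and
reports the alpha and beta angles plus the binary Graf type:

* baseline — tangent along the superficial (uppermost) edge of the ilium echo;
* bony roof line — through the lower limb point, tangent to the bony roof;
  alpha = angle(baseline, bony roof line);
* cartilage roof line — through the bony rim point and the labrum center;
  beta = angle(baseline, cartilage roof line).

Type I is reported when alpha >= 60 deg (boundary inclusive and configurable);
everything else in scope is type II.  Decentered morphologies (Graf D/III/IV)
are out of scope.

Landmark operationalizations (mask centroids, the minimum-column rim pixel,
and an exact tangent-from-pivot construction) are this package's geometric
concretization of clinical practice; each is deliberately simple, deterministic
and testable against the phantom's analytic ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .detection import BoundingBox, DetectionSet, StructureClass


class MeasurementError(ValueError):
    """Raised when a measurement cannot be made (missing/degenerate input)."""


# ---------------------------------------------------------------------------
# Maximum-entropy (Kapur) thresholding
# ---------------------------------------------------------------------------

def max_entropy_threshold(histogram: np.ndarray | Iterable[int]) -> int:
    """Kapur maximum-entropy threshold of a gray-level histogram.

    Searches exhaustively over every threshold ``t`` that leaves both classes
    non-empty and returns the ``t`` maximizing the sum of Shannon entropies of
    the normalized background (levels <= t) and foreground (levels > t)
    distributions.  The smallest ``t`` wins ties.  Foreground pixels are those
    strictly above the returned level.

    Raises
    ------
    MeasurementError
        If the histogram is empty or concentrated on a single gray level.
    """
    hist = np.asarray(list(histogram) if not isinstance(histogram, np.ndarray) else histogram, dtype=float)
    if hist.ndim != 1 or hist.size < 2:
        raise MeasurementError("histogram must be a 1-D array of level counts")
    if (hist < 0).any():
        raise MeasurementError("histogram counts must be non-negative")
    total = hist.sum()
    if total <= 0 or np.count_nonzero(hist) < 2:
        raise MeasurementError("histogram must occupy at least two gray levels")

    p = hist / total
    cum_p = np.cumsum(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    cum_plogp = np.cumsum(plogp)

    t = np.arange(hist.size - 1)  # threshold candidates; foreground is > t
    pb = cum_p[t]
    pf = 1.0 - pb
    valid = (pb > 0) & (pf > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        hb = -cum_plogp[t] / pb + np.log(pb)
        hf = -(cum_plogp[-1] - cum_plogp[t]) / pf + np.log(pf)
    psi = np.where(valid, hb + hf, -np.inf)
    best = int(np.argmax(psi))  # argmax returns the first (smallest) maximizer
    if not valid[best]:
        raise MeasurementError("no threshold leaves both classes non-empty")
    return best


def segment_structure(image: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Binary mask (box-local) of the structure inside ``box``.

    The threshold is computed from the box-local histogram with
    :func:`max_entropy_threshold`; the mask is the largest 8-connected
    foreground component, which suppresses small bright speckle islands.
    """
    image = np.asarray(image)
    x0, y0 = int(np.floor(box.x_min)), int(np.floor(box.y_min))
    x1, y1 = int(np.ceil(box.x_max)), int(np.ceil(box.y_max))
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, image.shape[1]), min(y1, image.shape[0])
    if x1 - x0 < 1 or y1 - y0 < 1:
        raise MeasurementError("box lies outside the image")
    region = image[y0:y1, x0:x1].astype(np.uint8)
    hist = np.bincount(region.ravel(), minlength=256)
    t = max_entropy_threshold(hist)  # raises on constant content
    fg = region > t
    if not fg.any():
        raise MeasurementError("empty foreground after thresholding")
    labels = skmeasure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = int(np.argmax(counts))
    return labels == keep


# ---------------------------------------------------------------------------
# Lines and landmark geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Line:
    """Undirected line through ``point`` with unit ``direction`` (column, row)."""

    point: tuple[float, float]
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        norm = float(np.hypot(*self.direction))
        if not np.isclose(norm, 1.0, atol=1e-9):
            if norm == 0:
                raise ValueError("line direction must be nonzero")
            object.__setattr__(
                self, "direction", (self.direction[0] / norm, self.direction[1] / norm)
            )

    @classmethod
    def through(cls, p: tuple[float, float], q: tuple[float, float]) -> "Line":
        d = (q[0] - p[0], q[1] - p[1])
        return cls(point=(float(p[0]), float(p[1])), direction=d)

    def distance_to(self, q: tuple[float, float]) -> float:
        dx, dy = self.direction
        vx, vy = q[0] - self.point[0], q[1] - self.point[1]
        return abs(dx * vy - dy * vx)


def angle_between(l1: Line, l2: Line) -> float:
    """Acute angle between two undirected lines, in degrees, range [0, 90]."""
    dot = abs(l1.direction[0] * l2.direction[0] + l1.direction[1] * l2.direction[1])
    return float(np.degrees(np.arccos(np.clip(dot, 0.0, 1.0))))


def fit_baseline(ilium_mask: np.ndarray, box: BoundingBox) -> Line:
    """Tangent along the superficial edge of the ilium.

    For each row spanned by the (box-local) mask the superficial edge pixel
    (minimum column) is taken; a total-least-squares line is fit to those edge
    points and then translated perpendicular toward the superficial side until
    every edge point lies on or deep to it.
    """
    mask = np.asarray(ilium_mask, dtype=bool)
    rows = np.nonzero(mask.any(axis=1))[0]
    if rows.size < 5:
        raise MeasurementError("ilium mask must span at least 5 rows")
    cols = np.array([np.nonzero(mask[r])[0][0] for r in rows], dtype=float)
    x0, y0 = float(np.floor(box.x_min)), float(np.floor(box.y_min))
    pts = np.column_stack([cols + x0, rows.astype(float) + y0])  # (col,row) global

    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    d = vt[0]
    if d[1] < 0:  # orient caudally (row increasing)
        d = -d
    # Unit normal pointing superficial (toward smaller column); with d
    # oriented caudally, (-d_row, d_col) has a non-positive column component.
    n = np.array([-d[1], d[0]])
    offsets = (pts - center) @ n
    shift = float(offsets.max())
    anchor = center + shift * n
    return Line(point=(float(anchor[0]), float(anchor[1])), direction=(float(d[0]), float(d[1])))


def tangent_point_from(
    pivot: tuple[float, float], contour: np.ndarray | Iterable[tuple[float, float]]
) -> tuple[float, float]:
    """Contour point ``p`` whose line through ``pivot`` supports the contour.

    Returns the point such that every contour point lies on one fixed side of
    the directed line pivot -> p — the side with ``cross(p - pivot, q - pivot)
    >= 0`` in image coordinates, which for the bony-roof geometry is the deep
    (larger-column) half-plane.  Collinear ties are broken by the point
    farthest from the pivot.
    """
    pts = np.asarray(list(contour) if not isinstance(contour, np.ndarray) else contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValueError("contour must be a non-empty list of (col, row) points")
    pts = np.unique(pts, axis=0)
    if pts.shape[0] == 1:
        return (float(pts[0, 0]), float(pts[0, 1]))
    v = pts - np.asarray(pivot, dtype=float)

    # The supporting point is a convex-hull vertex; reduce when profitable.
    idx = np.arange(v.shape[0])
    if v.shape[0] > 64:
        try:
            from scipy.spatial import ConvexHull, QhullError

            idx = np.asarray(ConvexHull(v).vertices)
        except QhullError:
            pass  # degenerate (collinear) contours: brute force
    cand = v[idx]
    # One-sided check of every candidate against the hull/contour points.
    cross = cand[:, 0:1] * cand[:, 1].T[None, :] - cand[:, 1:2] * cand[:, 0].T[None, :]
    scale = max(float(np.abs(v).max()) ** 2, 1.0)
    tol = 1e-9 * scale
    ok = cross.min(axis=1) >= -tol
    if not ok.any():  # numerical fallback: least-violating candidate
        ok = cross.min(axis=1) == cross.min(axis=1).max()
    norms = np.hypot(cand[:, 0], cand[:, 1])
    norms = np.where(ok, norms, -np.inf)
    best = pts[idx[int(np.argmax(norms))]]
    return (float(best[0]), float(best[1]))


# ---------------------------------------------------------------------------
# Landmarks, lines, and the measurement itself
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandmarkSet:
    """The four Graf landmarks in global (column, row) pixel coordinates."""

    bony_roof_point: tuple[float, float]
    bony_rim_point: tuple[float, float]
    lower_limb_point: tuple[float, float]
    labrum_center: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "bony_roof_point": list(self.bony_roof_point),
            "bony_rim_point": list(self.bony_rim_point),
            "lower_limb_point": list(self.lower_limb_point),
            "labrum_center": list(self.labrum_center),
        }


@dataclass(frozen=True)
class MeasurementLines:
    baseline: Line
    bony_roof_line: Line
    cartilage_roof_line: Line

    def as_dict(self) -> dict:
        def line(l: Line) -> dict:
            return {"point": list(l.point), "direction": list(l.direction)}

        return {
            "baseline": line(self.baseline),
            "bony_roof_line": line(self.bony_roof_line),
            "cartilage_roof_line": line(self.cartilage_roof_line),
        }


@dataclass(frozen=True)
class AngleResult:
    alpha: float
    beta: float
    graf_type: str  # "I" or "II"
    landmarks: LandmarkSet
    lines: MeasurementLines
    frame_index: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 90.0 and 0.0 <= self.beta <= 90.0):
            raise ValueError("alpha and beta must lie in [0, 90] degrees")

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "graf_type": self.graf_type,
            "landmarks": self.landmarks.as_dict(),
            "lines": self.lines.as_dict(),
            "frame_index": self.frame_index,
        }

    def with_frame_index(self, idx: int) -> "AngleResult":
        return replace(self, frame_index=idx)


def classify_graf(alpha: float, boundary: float = 60.0) -> str:
    """Binary Graf type from alpha: type I iff alpha >= boundary (inclusive)."""
    if not (0.0 <= alpha <= 90.0):
        raise ValueError("alpha must lie in [0, 90] degrees")
    return "I" if alpha >= boundary else "II"


def _global_mask(image: np.ndarray, box: BoundingBox) -> np.ndarray:
    local = segment_structure(image, box)
    out = np.zeros(image.shape, dtype=bool)
    y0, x0 = int(np.floor(box.y_min)), int(np.floor(box.x_min))
    y0, x0 = max(y0, 0), max(x0, 0)
    out[y0 : y0 + local.shape[0], x0 : x0 + local.shape[1]] = local
    return out


def _centroid(mask: np.ndarray) -> tuple[float, float]:
    r, c = np.nonzero(mask)
    return (float(c.mean()), float(r.mean()))


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    interior = ndimage.binary_erosion(mask, border_value=0)
    r, c = np.nonzero(mask & ~interior)
    return np.column_stack([c.astype(float), r.astype(float)])


def _require_all_structures(ds: DetectionSet) -> None:
    missing = ds.missing()
    if missing:
        names = ", ".join(s.value for s in missing)
        raise MeasurementError(
            f"cannot measure: structure(s) not detected: {names}; "
            "no diagnosis should be made without them"
        )


def locate_landmarks(image: np.ndarray, ds: DetectionSet) -> LandmarkSet:
    """Identify the four Graf landmarks from segmented structures.

    * lower limb point — centroid of the lower-limb mask;
    * labrum center — centroid of the labrum mask;
    * bony rim point — most superficial (minimum-column) pixel of the bony-rim
      mask, most cranial on ties;
    * bony roof point — tangent point from the lower limb point to the contour
      of the caudal half of the ilium mask united with the bony-rim mask.
    """
    _require_all_structures(ds)
    image = np.asarray(image)

    lower_mask = _global_mask(image, ds.box(StructureClass.LOWER_LIMB))
    labrum_mask = _global_mask(image, ds.box(StructureClass.LABRUM))
    rim_mask = _global_mask(image, ds.box(StructureClass.BONY_RIM))
    ilium_mask = _global_mask(image, ds.box(StructureClass.ILIUM))

    lower_limb_point = _centroid(lower_mask)
    labrum_center = _centroid(labrum_mask)

    rr, cc = np.nonzero(rim_mask)
    min_col = cc.min()
    rows_at = rr[cc == min_col]
    bony_rim_point = (float(min_col), float(rows_at.min()))

    il_rows = np.nonzero(ilium_mask.any(axis=1))[0]
    mid = (il_rows.min() + il_rows.max()) / 2.0
    caudal_half = ilium_mask.copy()
    caudal_half[: int(np.ceil(mid)), :] = False
    union = caudal_half | rim_mask
    contour = _boundary_points(union)
    bony_roof_point = tangent_point_from(lower_limb_point, contour)

    return LandmarkSet(
        bony_roof_point=bony_roof_point,
        bony_rim_point=bony_rim_point,
        lower_limb_point=lower_limb_point,
        labrum_center=labrum_center,
    )


def measure(
    image: np.ndarray,
    ds: DetectionSet,
    boundary: float = 60.0,
    frame_index: int | None = None,
) -> AngleResult:
    """Full Graf measurement on one standard plane.

    Composes segmentation, baseline fitting and landmark localization, builds
    the three measurement lines, and reports alpha, beta and the Graf type.
    Deterministic: identical inputs yield identical outputs.
    """
    _require_all_structures(ds)
    image = np.asarray(image)

    ilium_box = ds.box(StructureClass.ILIUM)
    ilium_local = segment_structure(image, ilium_box)
    baseline = fit_baseline(ilium_local, ilium_box)

    lm = locate_landmarks(image, ds)
    bony_roof_line = Line.through(lm.lower_limb_point, lm.bony_roof_point)
    cartilage_roof_line = Line.through(lm.bony_rim_point, lm.labrum_center)
    lines = MeasurementLines(
        baseline=baseline,
        bony_roof_line=bony_roof_line,
        cartilage_roof_line=cartilage_roof_line,
    )
    alpha = angle_between(baseline, bony_roof_line)
    beta = angle_between(baseline, cartilage_roof_line)
    return AngleResult(
        alpha=alpha,
        beta=beta,
        graf_type=classify_graf(alpha, boundary),
        landmarks=lm,
        lines=lines,
        frame_index=frame_index,
    )


# ---------------------------------------------------------------------------
# Overlay rendering (optional visual output)
# ---------------------------------------------------------------------------

def draw_overlay(image: np.ndarray, result: AngleResult) -> np.ndarray:
    """RGB copy of ``image`` with the three lines and four landmarks drawn."""
    from PIL import Image, ImageDraw

    img = Image.fromarray(np.asarray(image).astype(np.uint8)).convert("RGB")
    draw = ImageDraw.Draw(img)
    h, w = np.asarray(image).shape

    def endpoints(line: Line) -> tuple[tuple[float, float], tuple[float, float]]:
        px, py = line.point
        dx, dy = line.direction
        span = float(np.hypot(h, w))
        return (px - span * dx, py - span * dy), (px + span * dx, py + span * dy)

    for line, color in (
        (result.lines.baseline, (255, 255, 0)),
        (result.lines.bony_roof_line, (255, 64, 64)),
        (result.lines.cartilage_roof_line, (64, 128, 255)),
    ):
        (x0, y0), (x1, y1) = endpoints(line)
        draw.line([(x0, y0), (x1, y1)], fill=color, width=1)
    for pt, color in (
        (result.landmarks.bony_roof_point, (255, 64, 64)),
        (result.landmarks.bony_rim_point, (255, 255, 0)),
        (result.landmarks.lower_limb_point, (64, 255, 64)),
        (result.landmarks.labrum_center, (64, 128, 255)),
    ):
        x, y = pt
        draw.ellipse([x - 2, y - 2, x + 2, y + 2], outline=color, width=1)
    return np.asarray(img)
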