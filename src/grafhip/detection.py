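"""Detector contract and detection post-processing.

The measurement pipeline is detector-agnostic: any callable mapping an 8-bit
grayscale image to a list of :class:`Detection` objects can drive it (a neural
detector, the bundled heuristic :func:`reference_detect`, or phantom ground
truth).  This module defines the interchange schema — one axis-aligned
bounding box plus a confidence in [0, 1] per anatomical structure — and the
two post-processing steps applied to raw detector output before scoring and
measurement:

* :func:`select_best_per_class` keeps the single highest-confidence box per
  structure; structures with no detection are reported absent with
  confidence 0.
* :func:`check_relative_positions` validates that the surviving boxes are laid
  out like a coronal Graf plane (ilium superficial and near-vertical, lower
  limb deep and caudal, bony rim between them, labrum superficial to the rim).

Coordinate convention (shared package-wide): origin at the top-left pixel,
columns (x) increase with depth into the tissue, rows (y) increase caudally.
Boxes are 0-based half-open ``[x_min, x_max) x [y_min, y_max)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure


class StructureClass(str, Enum):
    """The four anatomical structures required for Graf measurement."""

    ILIUM = "ilium"
    LABRUM = "labrum"
    BONY_RIM = "bony_rim"
    LOWER_LIMB = "lower_limb"


#: Stable iteration order used for reports and JSON output.
STRUCTURES: tuple[StructureClass, ...] = (
    StructureClass.ILIUM,
    StructureClass.LABRUM,
    StructureClass.BONY_RIM,
    StructureClass.LOWER_LIMB,
)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based, half-open in both axes."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"degenerate box {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        """(column, row) center."""
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def iou(self, other: "BoundingBox") -> float:
        """Intersection over union with ``other``."""
        ix = max(0.0, min(self.x_max, other.x_max) - max(self.x_min, other.x_min))
        iy = max(0.0, min(self.y_max, other.y_max) - max(self.y_min, other.y_min))
        inter = ix * iy
        union = self.area + other.area - inter
        return inter / union if union > 0 else 0.0

    def as_list(self) -> list[float]:
        return [self.x_min, self.y_min, self.x_max, self.y_max]


@dataclass(frozen=True)
class Detection:
    """One localized structure with detector confidence in [0, 1]."""

    structure: StructureClass
    box: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


class DetectionSet(Mapping[StructureClass, Detection]):
    """At most one detection per structure; absent structures have confidence 0.

    Behaves as a read-only mapping from :class:`StructureClass` to
    :class:`Detection`.  ``confidence(structure)`` returns 0 for absent
    structures, mirroring how a detector reports an unrecognized structure.
    """

    def __init__(self, detections: Iterable[Detection] = ()) -> None:
        self._by_class: dict[StructureClass, Detection] = {}
        for det in detections:
            if det.structure in self._by_class:
                raise ValueError(f"duplicate structure {det.structure.value}")
            self._by_class[det.structure] = det

    def __getitem__(self, structure: StructureClass) -> Detection:
        return self._by_class[structure]

    def __iter__(self) -> Iterator[StructureClass]:
        return iter(self._by_class)

    def __len__(self) -> int:
        return len(self._by_class)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        parts = ", ".join(
            f"{s.value}:{d.confidence:.2f}" for s, d in self._by_class.items()
        )
        return f"DetectionSet({parts})"

    def present(self, structure: StructureClass) -> bool:
        return structure in self._by_class

    def confidence(self, structure: StructureClass) -> float:
        det = self._by_class.get(structure)
        return det.confidence if det is not None else 0.0

    def box(self, structure: StructureClass) -> BoundingBox | None:
        det = self._by_class.get(structure)
        return det.box if det is not None else None

    def all_present(self) -> bool:
        return all(s in self._by_class for s in STRUCTURES)

    def missing(self) -> list[StructureClass]:
        return [s for s in STRUCTURES if s not in self._by_class]


def select_best_per_class(raw: Iterable[Detection]) -> DetectionSet:
    """Keep the single highest-confidence detection per structure.

    Ties on confidence are broken by larger box area, then first occurrence.
    Structures with no detection are absent from the result (confidence 0).
    Idempotent: applying it to its own output is the identity.
    """
    best: dict[StructureClass, Detection] = {}
    for det in raw:
        cur = best.get(det.structure)
        if cur is None:
            best[det.structure] = det
        elif det.confidence > cur.confidence or (
            det.confidence == cur.confidence and det.box.area > cur.box.area
        ):
            best[det.structure] = det
    return DetectionSet(best.values())


@dataclass(frozen=True)
class PositionCheck:
    """Result of the clinical-layout check; invalidity is a state, not an error."""

    valid: bool
    reasons: tuple[str, ...] = ()


def check_relative_positions(
    ds: DetectionSet, image_shape: tuple[int, int] | None = None
) -> PositionCheck:
    """Validate the coronal-plane layout of the detected boxes.

    Rules (absent structures skip the rules that involve them):

    * R1 — the lower-limb center is deeper (larger column) than the ilium
      center and caudal to the ilium box's vertical midpoint.
    * R2 — the bony-rim center is caudal to the ilium box's cranial edge and
      superficial to the lower-limb center.
    * R3 — the labrum center is superficial (smaller column) to the bony-rim
      center.
    * R4 — no box center lies outside the image (checked only when
      ``image_shape`` = (rows, cols) is given).
    """
    reasons: list[str] = []
    ilium = ds.box(StructureClass.ILIUM)
    labrum = ds.box(StructureClass.LABRUM)
    rim = ds.box(StructureClass.BONY_RIM)
    lower = ds.box(StructureClass.LOWER_LIMB)

    if ilium is not None and lower is not None:
        lx, ly = lower.center
        ix, _ = ilium.center
        mid_row = (ilium.y_min + ilium.y_max) / 2.0
        if not (lx > ix and ly > mid_row):
            reasons.append(
                "R1: lower-limb center must be deeper than the ilium center "
                "and caudal to the ilium midpoint"
            )
    if ilium is not None and rim is not None:
        rx, ry = rim.center
        ok = ry > ilium.y_min
        if lower is not None:
            ok = ok and rx < lower.center[0]
        if not ok:
            reasons.append(
                "R2: bony-rim center must be caudal to the ilium cranial edge "
                "and superficial to the lower-limb center"
            )
    if labrum is not None and rim is not None:
        if not labrum.center[0] < rim.center[0]:
            reasons.append(
                "R3: labrum center must be superficial to the bony-rim center"
            )
    if image_shape is not None:
        rows, cols = image_shape
        for s in STRUCTURES:
            b = ds.box(s)
            if b is None:
                continue
            cx, cy = b.center
            if not (0 <= cx < cols and 0 <= cy < rows):
                reasons.append(f"R4: {s.value} box center lies outside the image")
    return PositionCheck(valid=not reasons, reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# Reference heuristic detector
# ---------------------------------------------------------------------------

def _entropy_threshold_or_none(image: np.ndarray) -> int | None:
    from .measurement import max_entropy_threshold

    hist = np.bincount(image.ravel().astype(np.uint8), minlength=256)
    if np.count_nonzero(hist) < 2:
        return None
    return max_entropy_threshold(hist)


def reference_detect(image: np.ndarray) -> list[Detection]:
    """Heuristic detector for phantom-like Graf-plane images.

    Thresholds the image at the maximum-entropy gray level, labels 8-connected
    bright components, and assigns the four structure roles by layout: the
    ilium is the most elongated near-vertical component; the remaining blobs
    are classified by their column offset from the caudal ilium tip (labrum
    superficial, lower limb deep, bony rim near the tip).  Confidence is the
    component's mean intensity normalized to [0, 1] times its bounding-box
    fill fraction.  Blank images yield no detections.

    This stands in for a trained object detector and honors the same output
    contract; it is a geometric heuristic, not a learned model.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    img = image.astype(np.uint8)
    t = _entropy_threshold_or_none(img)
    if t is None:
        return []
    mask = img > t
    # Opening removes isolated speckle pixels and 1-px noise bridges that
    # would otherwise merge neighboring structures into one component.
    mask = ndimage.binary_opening(mask)
    if not mask.any():
        return []
    rows, cols = img.shape
    scale = min(rows, cols) / 256.0
    labels = skmeasure.label(mask, connectivity=2)
    props = skmeasure.regionprops(labels, intensity_image=img)
    props = [p for p in props if p.area >= max(8, 12 * scale * scale)]
    if not props:
        return []

    def theta_dev_from_vertical(p) -> float:
        # regionprops orientation: angle (rad) between the row axis and the
        # major axis; 0 means vertical in our convention.
        return abs(np.degrees(p.orientation))

    # Ilium: elongated, near-vertical, reasonably long.
    candidates = [
        p
        for p in props
        if p.axis_major_length >= 0.12 * rows
        and theta_dev_from_vertical(p) <= 40.0
        and p.axis_minor_length > 0
    ]
    detections: list[Detection] = []
    ilium_prop = None
    if candidates:
        ilium_prop = max(
            candidates, key=lambda p: p.axis_major_length / max(p.axis_minor_length, 1e-9)
        )
        detections.append(_prop_to_detection(ilium_prop, StructureClass.ILIUM, img))
    if ilium_prop is None:
        # Without an ilium there is no anatomical frame of reference to
        # classify the remaining blobs; report nothing.
        return detections

    # Caudal tip of the ilium: most caudal rows, most superficial column there.
    r_idx, c_idx = np.nonzero(labels == ilium_prop.label)
    max_row = r_idx.max()
    near_tip = r_idx >= max_row - 2
    tip_col = c_idx[near_tip].min()
    tip = (float(tip_col), float(max_row))

    blobs = [p for p in props if p is not ilium_prop]
    assigned: dict[StructureClass, Detection] = {}
    for p in blobs:
        cy, cx = p.centroid
        dx = cx - tip[0]
        if dx <= -0.04 * cols:
            role = StructureClass.LABRUM
        elif dx >= 0.08 * cols:
            role = StructureClass.LOWER_LIMB
        else:
            role = StructureClass.BONY_RIM
        det = _prop_to_detection(p, role, img)
        cur = assigned.get(role)
        if cur is None or det.confidence > cur.confidence:
            assigned[role] = det
    detections.extend(assigned.values())
    return detections


def _prop_to_detection(p, structure: StructureClass, img: np.ndarray) -> Detection:
    min_row, min_col, max_row, max_col = p.bbox
    box = BoundingBox(float(min_col), float(min_row), float(max_col), float(max_row))
    fill = p.area / max(box.area, 1.0)
    conf = float(np.clip((p.intensity_mean / 255.0) * fill, 0.0, 1.0))
    return Detection(structure=structure, box=box, confidence=conf)


# ---------------------------------------------------------------------------
# Annotation JSON I/O
# ---------------------------------------------------------------------------

def detections_to_json(
    detections: Iterable[Detection], image_name: str = ""
) -> dict:
    """Serialize detections to the annotation schema (shared with phantoms)."""
    return {
        "image": image_name,
        "detections": [
            {
                "structure": d.structure.value,
                "box": d.box.as_list(),
                "confidence": d.confidence,
            }
            for d in detections
        ],
    }


def detections_from_json(obj: dict) -> list[Detection]:
    """Parse the annotation schema back into detections."""
    out = []
    for entry in obj.get("detections", []):
        x0, y0, x1, y1 = entry["box"]
        out.append(
            Detection(
                structure=StructureClass(entry["structure"]),
                box=BoundingBox(x0, y0, x1, y1),
                confidence=float(entry["confidence"]),
            )
        )
    return out


def write_annotation(path: str | Path, detections: Iterable[Detection], image_name: str = "") -> None:
    Path(path).write_text(json.dumps(detections_to_json(detections, image_name), indent=1))


def read_annotation(path: str | Path) -> list[Detection]:
    return detections_from_json(json.loads(Path(path).read_text()))


#: A detector is any callable image -> list of Detection.
Detector = Callable[[np.ndarray], list[Detection]]
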