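"""Synthetic Graf-plane hip phantom with exact analytic ground truth.

Real infant-hip ultrasound with expert annotations is not publicly
distributable, so every downstream stage of this package is exercised on a
parametric phantom that mimics the geometry of a coronal Graf standard plane:

* a bright, near-vertical ilium band (tilt and curvature controllable) whose
  superficial edge defines the baseline;
* a lower-limb blob placed deep and caudal of the band's caudal tip so that
  the line from the blob center to the tip makes exactly ``alpha_true``
  degrees with the baseline;
* a bony-rim blob just deep of the tip (strictly on the deep side of the bony
  roof line, so the roof tangent touches the tip);
* a labrum blob positioned so the bony-rim-point-to-labrum-center line makes
  exactly ``beta_true`` degrees with the baseline.

All landmarks, the baseline, the per-structure boxes, and the true angles are
computed analytically before any pixel is drawn, which makes angle-recovery
errors of the measurement pipeline attributable to the pipeline alone.

Coordinates follow the package convention: origin top-left, columns = depth
(rightward), rows = caudal (downward); the near field is the left edge.
Speckle is approximated by additive Gaussian noise only; physically realistic
ultrasound simulation is a non-goal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .detection import (
    BoundingBox,
    Detection,
    DetectionSet,
    Detector,
    STRUCTURES,
    StructureClass,
)
from .measurement import Line

BACKGROUND_LEVEL = 25.0
_EDGE_SOFTNESS = 1.0  # px over which structure edges fade


class PhantomGeometryError(ValueError):
    """Raised when a spec would place a landmark or structure off-image."""


def _normalize_visibility(
    vis: Mapping[StructureClass | str, float] | None,
) -> dict[StructureClass, float]:
    out = {s: 1.0 for s in STRUCTURES}
    if vis:
        for key, value in vis.items():
            s = StructureClass(key)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"visibility for {s.value} outside [0, 1]")
            out[s] = float(value)
    return out


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic standard-plane image.

    ``ilium_tilt`` is the tilt of the ilium from the image vertical in
    degrees, positive when the cranial end leans toward larger column
    (deeper).  ``ilium_curvature`` bows the band toward the deep side
    (0 = straight).  ``visibility`` scales each structure's brightness;
    0 removes the structure entirely.  ``contrast`` is the peak brightness of
    structures above the background, in gray levels.
    """

    image_height: int = 256
    image_width: int = 256
    ilium_tilt: float = 0.0
    ilium_curvature: float = 0.0
    alpha_true: float = 60.0
    beta_true: float = 55.0
    visibility: Mapping[StructureClass, float] = field(default_factory=dict)
    noise_sigma: float = 0.0
    contrast: float = 170.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 128 or self.image_width < 128:
            raise ValueError("image dimensions must be at least 128 px")
        if not (40.0 <= self.alpha_true <= 80.0):
            raise ValueError("alpha_true must lie in [40, 80] degrees")
        if not (30.0 <= self.beta_true <= 90.0):
            raise ValueError("beta_true must lie in [30, 90] degrees")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")
        object.__setattr__(
            self, "visibility", _normalize_visibility(self.visibility)
        )

    def with_(self, **kwargs) -> "PhantomSpec":
        """Functional update; ``visibility`` entries are merged, not replaced."""
        if "visibility" in kwargs:
            merged = dict(self.visibility)
            merged.update(_normalize_visibility(kwargs["visibility"]))
            kwargs["visibility"] = merged
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PhantomFrame:
    """A rendered phantom image plus its exact ground truth."""

    image: np.ndarray
    true_boxes: DetectionSet
    true_landmarks: "object"  # LandmarkSet; typed loosely to avoid cycle
    true_baseline: Line
    true_alpha: float
    true_beta: float
    true_tilt: float
    spec: PhantomSpec


@dataclass(frozen=True)
class PhantomVideo:
    """An ordered probe-sweep sequence of phantom frames.

    ``best_frame_index`` is the earliest frame minimizing the absolute tilt
    among frames in which all four structures are visible.  ``alpha_video`` /
    ``beta_video`` are the subject's angles at the standard plane (tilt 0);
    frames rendered off-plane carry obliquity-distorted apparent angles.
    """

    frames: tuple[PhantomFrame, ...]
    best_frame_index: int
    alpha_video: float
    beta_video: float


# ---------------------------------------------------------------------------
# Analytic geometry
# ---------------------------------------------------------------------------

def _geometry(spec: PhantomSpec) -> dict:
    """Analytic layout: landmarks, baseline, band polygon, blob placement."""
    from .measurement import LandmarkSet  # local import avoids module cycle

    h, w = spec.image_height, spec.image_width
    m = min(h, w)
    s = m / 256.0
    t = np.radians(spec.ilium_tilt)
    u = np.array([-np.sin(t), np.cos(t)])  # caudal, along the band axis
    v = np.array([np.cos(t), np.sin(t)])  # deep, perpendicular to the band

    tip = np.array([0.30 * w, 0.55 * h])  # caudal end of the superficial edge
    band_len = 0.45 * h
    band_w = 8.0 * s
    bow_amp = 6.0 * s * spec.ilium_curvature

    r_roof = 0.22 * m
    alpha = np.radians(spec.alpha_true)
    lower_limb = tip + r_roof * (np.sin(alpha) * v + np.cos(alpha) * u)

    rim_radius = 4.0 * s
    rim_center = tip + 16.0 * s * v - 4.0 * s * u
    rim_point = rim_center - np.array([rim_radius, 0.0])

    rho = 0.20 * m
    beta = np.radians(spec.beta_true)
    labrum_center = rim_point + rho * (np.cos(beta) * u - np.sin(beta) * v)

    landmarks = LandmarkSet(
        bony_roof_point=(float(tip[0]), float(tip[1])),
        bony_rim_point=(float(rim_point[0]), float(rim_point[1])),
        lower_limb_point=(float(lower_limb[0]), float(lower_limb[1])),
        labrum_center=(float(labrum_center[0]), float(labrum_center[1])),
    )
    baseline = Line(point=(float(tip[0]), float(tip[1])), direction=(float(u[0]), float(u[1])))

    # Band support polygon, sampled along its axis (includes the deep bow).
    ss = np.linspace(0.0, 1.0, 65)
    bow = bow_amp * 4.0 * ss * (1.0 - ss)
    sup = tip[None, :] - (ss * band_len)[:, None] * u[None, :] + bow[:, None] * v[None, :]
    deep = sup + band_w * v[None, :]
    band_pts = np.vstack([sup, deep])

    blobs = {
        StructureClass.LOWER_LIMB: (lower_limb, 6.0 * s),
        StructureClass.BONY_RIM: (rim_center, rim_radius),
        StructureClass.LABRUM: (labrum_center, 5.0 * s),
    }
    return {
        "u": u,
        "v": v,
        "tip": tip,
        "band_len": band_len,
        "band_w": band_w,
        "bow_amp": bow_amp,
        "band_pts": band_pts,
        "blobs": blobs,
        "landmarks": landmarks,
        "baseline": baseline,
        "scale": s,
    }


def _validate_inside(spec: PhantomSpec, geo: dict) -> None:
    h, w = spec.image_height, spec.image_width
    pts = [np.asarray(p) for p in (
        geo["landmarks"].bony_roof_point,
        geo["landmarks"].bony_rim_point,
        geo["landmarks"].lower_limb_point,
        geo["landmarks"].labrum_center,
    )]
    pts.extend(geo["band_pts"])
    for center, radius in geo["blobs"].values():
        pts.append(center - radius)
        pts.append(center + radius)
    arr = np.vstack(pts)
    if (arr[:, 0] < 0).any() or (arr[:, 0] > w - 1).any() or (arr[:, 1] < 0).any() or (arr[:, 1] > h - 1).any():
        raise PhantomGeometryError(
            "spec places a structure or landmark outside the image"
        )


def _soft(d: np.ndarray) -> np.ndarray:
    """Edge profile: 0 outside, 1 inside, linear ramp over the softness width."""
    return np.clip(d / _EDGE_SOFTNESS + 0.5, 0.0, 1.0)


def true_boxes(spec: PhantomSpec) -> DetectionSet:
    """Ground-truth boxes for the visible structures; confidence = visibility."""
    geo = _geometry(spec)
    dets = []
    vis = spec.visibility
    if vis[StructureClass.ILIUM] > 0:
        pts = geo["band_pts"]
        dets.append(
            Detection(
                StructureClass.ILIUM,
                BoundingBox(
                    float(pts[:, 0].min() - 0.5),
                    float(pts[:, 1].min() - 0.5),
                    float(pts[:, 0].max() + 0.5),
                    float(pts[:, 1].max() + 0.5),
                ),
                vis[StructureClass.ILIUM],
            )
        )
    for s, (center, radius) in geo["blobs"].items():
        if vis[s] > 0:
            dets.append(
                Detection(
                    s,
                    BoundingBox(
                        float(center[0] - radius - 0.5),
                        float(center[1] - radius - 0.5),
                        float(center[0] + radius + 0.5),
                        float(center[1] + radius + 0.5),
                    ),
                    vis[s],
                )
            )
    return DetectionSet(dets)


def add_noise(image: np.ndarray, noise_sigma: float, seed: int) -> np.ndarray:
    """Additive zero-mean Gaussian noise, clipped to [0, 255]; seed-deterministic."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    img = np.asarray(image)
    if noise_sigma == 0:
        return img.astype(np.uint8, copy=True)
    rng = np.random.default_rng(seed)
    noisy = img.astype(float) + rng.normal(0.0, noise_sigma, img.shape)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def render_frame(spec: PhantomSpec) -> PhantomFrame:
    """Render one phantom image with its exact ground truth.

    Deterministic for a fixed spec (including seed).  Structures with
    visibility 0 are omitted from both the image and the ground-truth boxes.
    """
    geo = _geometry(spec)
    _validate_inside(spec, geo)
    h, w = spec.image_height, spec.image_width
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.stack([xx, yy], axis=-1).astype(float)
    rel = pts - geo["tip"]
    img = np.full((h, w), BACKGROUND_LEVEL, dtype=float)
    vis = spec.visibility

    if vis[StructureClass.ILIUM] > 0:
        pu = -(rel @ geo["u"])  # distance cranially from the tip
        pv = rel @ geo["v"]  # depth offset from the superficial edge
        with np.errstate(invalid="ignore"):
            ss = np.clip(pu / geo["band_len"], 0.0, 1.0)
        bow = geo["bow_amp"] * 4.0 * ss * (1.0 - ss)
        inside = np.minimum.reduce(
            [pv - bow, geo["band_w"] - (pv - bow), pu, geo["band_len"] - pu]
        )
        img += spec.contrast * vis[StructureClass.ILIUM] * _soft(inside)

    for s, (center, radius) in geo["blobs"].items():
        if vis[s] > 0:
            dist = np.hypot(pts[..., 0] - center[0], pts[..., 1] - center[1])
            img += spec.contrast * vis[s] * _soft(radius - dist)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    img = add_noise(img, spec.noise_sigma, spec.seed)
    return PhantomFrame(
        image=img,
        true_boxes=true_boxes(spec),
        true_landmarks=geo["landmarks"],
        true_baseline=geo["baseline"],
        true_alpha=spec.alpha_true,
        true_beta=spec.beta_true,
        true_tilt=spec.ilium_tilt,
        spec=spec,
    )


def render_video(
    base_spec: PhantomSpec,
    tilt_trajectory: Sequence[float],
    dropout_schedule: Sequence[Mapping[StructureClass | str, float]] | None = None,
    alpha_drift: float = 0.4,
    beta_drift: float = 0.3,
) -> PhantomVideo:
    """Render a probe sweep: one frame per tilt-trajectory entry.

    Off-plane frames are rendered with obliquity-distorted apparent angles
    ``alpha + alpha_drift * tilt`` and ``beta + beta_drift * tilt`` (clipped
    to the valid ranges), so measuring a tilted frame incurs a real angle
    error — the phantom's analogue of measuring off the standard plane.
    ``dropout_schedule`` optionally overrides per-frame structure visibility.
    """
    if len(tilt_trajectory) == 0:
        raise ValueError("tilt trajectory must be non-empty")
    if dropout_schedule is not None and len(dropout_schedule) != len(tilt_trajectory):
        raise ValueError("dropout schedule length must match the trajectory")
    frames = []
    for i, tilt in enumerate(tilt_trajectory):
        overrides = dropout_schedule[i] if dropout_schedule is not None else {}
        spec_i = base_spec.with_(
            ilium_tilt=float(tilt),
            alpha_true=float(np.clip(base_spec.alpha_true + alpha_drift * tilt, 40.0, 80.0)),
            beta_true=float(np.clip(base_spec.beta_true + beta_drift * tilt, 30.0, 90.0)),
            seed=int((base_spec.seed + 7919 * (i + 1)) % (2**31)),
            visibility=overrides,
        )
        frames.append(render_frame(spec_i))

    usable = [
        i
        for i, f in enumerate(frames)
        if all(f.spec.visibility[s] > 0 for s in STRUCTURES)
    ]
    if not usable:
        raise ValueError("no frame has all four structures visible")
    best = min(usable, key=lambda i: (abs(frames[i].true_tilt), i))
    return PhantomVideo(
        frames=tuple(frames),
        best_frame_index=best,
        alpha_video=base_spec.alpha_true,
        beta_video=base_spec.beta_true,
    )


def make_sweep_video(
    base_spec: PhantomSpec,
    n_frames: int = 9,
    tilt_step: float = 3.0,
    seed: int = 0,
    visibility_jitter: float = 0.1,
    conspicuity_gradient: float = 0.25,
) -> PhantomVideo:
    """A randomized probe sweep crossing the standard plane once.

    The frame nearest tilt 0 lands at a random position in the sweep.  Blob
    conspicuity is lowest at the standard plane and increases toward the
    sweep ends (``conspicuity_gradient``), with uniform jitter subtracted —
    emulating that detector confidence tracks structure visibility, not plane
    quality.  The ilium stays fully visible throughout.
    """
    if n_frames < 3:
        raise ValueError("a sweep needs at least 3 frames")
    rng = np.random.default_rng(seed)
    center = int(rng.integers(1, n_frames - 1))
    jitters = rng.uniform(-0.4, 0.4, n_frames)
    tilts = (np.arange(n_frames) - center) * tilt_step + jitters
    tilts[center] = jitters[center]  # keep the center frame nearest vertical
    span = max(abs(tilts).max(), 1.0)

    schedule = []
    for tilt in tilts:
        frame_vis = {}
        for s in (StructureClass.LABRUM, StructureClass.BONY_RIM, StructureClass.LOWER_LIMB):
            vis = 0.7 + conspicuity_gradient * abs(tilt) / span
            vis -= rng.uniform(0.0, visibility_jitter)
            frame_vis[s] = float(np.clip(vis, 0.3, 1.0))
        schedule.append(frame_vis)
    return render_video(
        base_spec.with_(seed=int(seed % (2**31))), list(tilts), schedule
    )


# ---------------------------------------------------------------------------
# Oracle detector and disk I/O
# ---------------------------------------------------------------------------

def oracle_detector(frames: Sequence[PhantomFrame] | PhantomVideo | PhantomFrame) -> Detector:
    """Detector returning the ground-truth boxes of known phantom frames.

    Looks frames up by pixel content, so it can be handed to any pipeline
    entry point that expects an ``image -> detections`` callable.
    """
    if isinstance(frames, PhantomVideo):
        frame_list = list(frames.frames)
    elif isinstance(frames, PhantomFrame):
        frame_list = [frames]
    else:
        frame_list = list(frames)
    table = {f.image.tobytes(): f for f in frame_list}

    def detect(image: np.ndarray) -> list[Detection]:
        key = np.ascontiguousarray(np.asarray(image, dtype=np.uint8)).tobytes()
        frame = table.get(key)
        if frame is None:
            raise KeyError("image is not one of the known phantom frames")
        return list(frame.true_boxes.values())

    return detect


def save_frame(frame: PhantomFrame, image_path: str | Path, annotation_path: str | Path | None = None) -> None:
    """Write the frame as 8-bit PNG plus a ground-truth JSON sidecar."""
    import imageio.v3 as iio

    image_path = Path(image_path)
    iio.imwrite(image_path, frame.image)
    if annotation_path is None:
        annotation_path = image_path.with_suffix(".json")
    from .detection import detections_to_json

    payload = detections_to_json(frame.true_boxes.values(), image_path.name)
    payload["true_alpha"] = frame.true_alpha
    payload["true_beta"] = frame.true_beta
    payload["true_tilt"] = frame.true_tilt
    payload["true_landmarks"] = frame.true_landmarks.as_dict()
    Path(annotation_path).write_text(json.dumps(payload, indent=1))


def save_video(video: PhantomVideo, out_dir: str | Path) -> None:
    """Write a sweep as frame_0000.png ... plus per-frame sidecars and metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(video.frames):
        save_frame(frame, out_dir / f"frame_{i:04d}.png")
    meta = {
        "n_frames": len(video.frames),
        "best_frame_index": video.best_frame_index,
        "alpha_video": video.alpha_video,
        "beta_video": video.beta_video,
        "tilts": [f.true_tilt for f in video.frames],
    }
    (out_dir / "video.json").write_text(json.dumps(meta, indent=1))
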