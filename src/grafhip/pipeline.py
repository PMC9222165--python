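"""End-to-end static and dynamic measurement pipelines.

Two clinical workflows are wired from the library modules:

* **Static mode** (:func:`run_static`) — the sonographer supplies a standard
  plane (plus detections from an annotation file or a detector); measurement
  is performed directly on it.  A failed layout check only warns, since the
  operator vouches for the plane.
* **Dynamic mode** (:func:`run_dynamic`) — every frame of a sweep is detected
  and scored, the highest-scoring frame becomes the standard plane, and
  measurement runs on it.  Frames failing the layout check score 0.

Both modes are deterministic for fixed inputs and configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import agreement
from .detection import (
    Detection,
    DetectionSet,
    Detector,
    check_relative_positions,
    read_annotation,
    reference_detect,
    select_best_per_class,
)
from .measurement import AngleResult, MeasurementError, measure
from .scoring import (
    DEFAULT_WEIGHTS,
    FrameScore,
    ScoringWeights,
    select_standard_frame,
)

logger = logging.getLogger("grafhip")


@dataclass(frozen=True)
class PipelineConfig:
    """Framework parameters; defaults are the published operating point."""

    weights: ScoringWeights = DEFAULT_WEIGHTS
    margin_fraction: float = 0.1
    boundary: float = 60.0
    detector: str = "reference"
    seed: int = 0
    verbose: bool = False

    def resolve_detector(self, override: Detector | None = None) -> Detector:
        if override is not None:
            return override
        if callable(self.detector):
            return self.detector  # type: ignore[return-value]
        if self.detector == "reference":
            return reference_detect
        raise ValueError(
            f"unknown detector {self.detector!r}; pass a callable for external detectors"
        )


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from an optional TOML/key=value file plus overrides.

    Recognized keys: lam1..lam7, margin_fraction, boundary, detector, seed,
    verbose.  Flags given as ``overrides`` win over the file.
    """
    values: dict = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            import tomllib

            values = tomllib.loads(text)
        except Exception:
            for line in text.splitlines():
                line = line.strip()
                if line and not line.startswith("#") and "=" in line:
                    k, v = (s.strip() for s in line.split("=", 1))
                    values[k] = v
    values.update({k: v for k, v in overrides.items() if v is not None})
    lam_kwargs = {}
    for i in range(1, 8):
        key = f"lam{i}"
        if key in values:
            lam_kwargs[key] = float(values.pop(key))
    weights = ScoringWeights(**lam_kwargs) if lam_kwargs else DEFAULT_WEIGHTS
    cfg_kwargs = {}
    for key, conv in (
        ("margin_fraction", float),
        ("boundary", float),
        ("detector", str),
        ("seed", int),
        ("verbose", lambda v: str(v).lower() in ("1", "true", "yes")),
    ):
        if key in values:
            cfg_kwargs[key] = conv(values[key])
    return PipelineConfig(weights=weights, **cfg_kwargs)


# ---------------------------------------------------------------------------
# Frame loading
# ---------------------------------------------------------------------------

def load_image(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def load_frames(source: str | Path) -> list[np.ndarray]:
    """Frames from a directory of images (lexicographic) or a multi-page TIFF."""
    source = Path(source)
    if source.is_dir():
        paths = sorted(
            p
            for p in source.iterdir()
            if p.suffix.lower() in (".png", ".tif", ".tiff", ".jpg", ".jpeg")
        )
        if not paths:
            raise ValueError(f"no frames found in {source}")
        return [load_image(p) for p in paths]
    if source.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        stack = tifffile.imread(source)
        if stack.ndim == 2:
            stack = stack[None]
        return [np.clip(np.rint(f), 0, 255).astype(np.uint8) for f in stack]
    return [load_image(source)]


# ---------------------------------------------------------------------------
# Static mode
# ---------------------------------------------------------------------------

def _resolve_detections(
    image: np.ndarray,
    detections_source,
    config: PipelineConfig,
    detector: Detector | None,
) -> DetectionSet:
    if detections_source is None:
        raw = config.resolve_detector(detector)(image)
    elif isinstance(detections_source, DetectionSet):
        return detections_source
    elif callable(detections_source):
        raw = detections_source(image)
    elif isinstance(detections_source, (str, Path)):
        raw = read_annotation(detections_source)
    else:
        raw = list(detections_source)
    return select_best_per_class(raw)


def run_static(
    image: np.ndarray,
    detections_source=None,
    config: PipelineConfig = PipelineConfig(),
    detector: Detector | None = None,
) -> AngleResult:
    """Measure a given standard plane.

    ``detections_source`` may be an annotation JSON path, a list of raw
    detections, a ready DetectionSet, or a detector callable; when omitted the
    configured detector runs on the image.  Layout violations are warnings
    here — the plane was vouched for by the operator.
    """
    image = np.asarray(image)
    ds = _resolve_detections(image, detections_source, config, detector)
    check = check_relative_positions(ds, image.shape)
    if not check.valid:
        for reason in check.reasons:
            logger.warning("position check: %s", reason)
    return measure(image, ds, boundary=config.boundary)


# ---------------------------------------------------------------------------
# Dynamic mode
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DynamicResult:
    frame_index: int
    result: AngleResult
    frame_scores: tuple[FrameScore, ...]

    def scores_frame(self) -> pd.DataFrame:
        rows = []
        for i, fs in enumerate(self.frame_scores):
            ish = fs.s_ilium
            rows.append(
                {
                    "frame_index": i,
                    "S": fs.s,
                    "S_lower_limb": fs.s_lower_limb,
                    "S_labrum": fs.s_labrum,
                    "S_bony_rim": fs.s_bony_rim,
                    "S_ilium": ish.s_ilium if ish else 0.0,
                    "S_conf": ish.s_conf if ish else 0.0,
                    "S_hw": ish.s_hw if ish else float("nan"),
                    "S_angle": ish.s_angle if ish else float("nan"),
                    "theta": ish.theta if ish else float("nan"),
                    "position_valid": fs.position_valid,
                }
            )
        return pd.DataFrame(rows)


def run_dynamic(
    frame_source: Sequence[np.ndarray] | str | Path,
    config: PipelineConfig = PipelineConfig(),
    detector: Detector | None = None,
) -> DynamicResult:
    """Select the standard plane of a sweep and measure it.

    Raises :class:`grafhip.scoring.ScoringError` ("no usable plane") when
    every frame scores zero — no diagnosis should be made from such a video.
    """
    if isinstance(frame_source, (str, Path)):
        frames = load_frames(frame_source)
    else:
        frames = [np.asarray(f) for f in frame_source]
    det = config.resolve_detector(detector)
    best, scores = select_standard_frame(
        frames, det, config.weights, config.margin_fraction
    )
    ds = select_best_per_class(det(frames[best]))
    result = measure(frames[best], ds, boundary=config.boundary, frame_index=best)
    return DynamicResult(frame_index=best, result=result, frame_scores=tuple(scores))


# ---------------------------------------------------------------------------
# Batch evaluation
# ---------------------------------------------------------------------------

def run_evaluate(
    predictions: str | Path | pd.DataFrame,
    references: str | Path | pd.DataFrame,
    out_dir: str | Path | None = None,
    plots: bool = False,
) -> dict:
    """Agreement report between prediction and reference measurement tables.

    Tables need columns id, alpha, beta, graf_type; ids must match one-to-one.
    Writes report.csv / report.txt (and optional Bland-Altman PNGs) when
    ``out_dir`` is given; returns the report dict either way.
    """
    pred = predictions if isinstance(predictions, pd.DataFrame) else agreement.read_measurements_csv(predictions)
    ref = references if isinstance(references, pd.DataFrame) else agreement.read_measurements_csv(references)
    report = agreement.evaluate_tables(pred, ref)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        agreement.report_to_frame(report).to_csv(out_dir / "report.csv", index=False)
        (out_dir / "report.txt").write_text(agreement.format_report(report) + "\n")
        if plots:
            merged = pred.merge(ref, on="id", suffixes=("_method", "_ref"))
            for angle in ("alpha", "beta"):
                agreement.bland_altman_plot(
                    agreement.PairedAngles.from_arrays(
                        merged[f"{angle}_method"], merged[f"{angle}_ref"]
                    ),
                    out_dir / f"bland_altman_{angle}.png",
                    title=angle,
                )
    return report


def write_result_json(result: AngleResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.as_dict(), indent=1, sort_keys=True))
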