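"""View and exposure segmentation plus Dice / mIoU evaluation.

Two segmentation roles, each an sklearn-style estimator with a deterministic
photometric baseline standing in for the trained networks used clinically:

* :class:`ViewSegmenter` — the endoscopy *view* region within the frame
  (the CMEA denominator; normalizing by it removes bias from different
  endoscope manufacturers cropping the optical field differently);
* :class:`ExposureSegmenter` — the *clearly exposed mucosa* inside the view
  (the CMEA numerator; specular reflections, fecal residue / occlusion,
  instrument shafts and excessively dark regions do not count as exposed).

Evaluation: ``dice`` (2|A∩B| / (|A|+|B|)), per-pair ``iou`` and ``miou``
(mean IoU over images by default, with a class-averaged switch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage
from skimage import color, measure, morphology
from sklearn.base import BaseEstimator

from ccmea.types import Frame, ProcedureFrame, mask_area, validate_mask_pair

__all__ = [
    "SegConfig",
    "SegEvalReport",
    "EmptyViewError",
    "ViewSegmenter",
    "ExposureSegmenter",
    "OracleViewSegmenter",
    "OracleExposureSegmenter",
    "segment_view",
    "segment_exposure",
    "dice",
    "iou",
    "miou",
    "evaluate_segmentation",
]

logger = logging.getLogger(__name__)

FrameLike = Union[Frame, ProcedureFrame, np.ndarray]


class EmptyViewError(ValueError):
    """Raised when no endoscopy view can be found (caller should treat the
    frame as unqualified)."""


@dataclass(frozen=True)
class SegConfig:
    """Photometric thresholds of the baseline segmenters.

    Luminance/saturation/hue are in [0, 1] (HSV hue as a fraction of the
    color circle).  Calibrated once on the synthetic phantom fixtures at
    fixed seed; config values, never constants buried in logic.
    """

    view_lum_min: float = 0.05
    specular_lum_min: float = 0.90
    specular_sat_max: float = 0.15
    dark_lum_max: float = 0.10
    fecal_hue_band: tuple[float, float] = (0.04, 0.14)
    fecal_sat_min: float = 0.30
    fecal_val_max: float = 0.65
    instrument_sat_max: float = 0.12
    min_object_px: int = 16

    def validate(self) -> None:
        if not (0 <= self.view_lum_min < 1):
            raise ValueError("view_lum_min must lie in [0, 1)")
        lo, hi = self.fecal_hue_band
        if not (0 <= lo < hi <= 1):
            raise ValueError("fecal_hue_band must be an increasing interval within [0, 1]")
        if self.min_object_px < 0:
            raise ValueError("min_object_px must be >= 0")


def _image_of(frame: FrameLike) -> np.ndarray:
    if isinstance(frame, ProcedureFrame):
        frame = frame.frame
    if isinstance(frame, Frame):
        img = frame.image
    else:
        img = np.asarray(frame)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] == 0 or img.shape[1] == 0:
        raise ValueError(f"expected non-empty (H, W, 3) image, got shape {img.shape}")
    return img


class ViewSegmenter(BaseEstimator):
    """Baseline endoscopy-view segmenter.

    Luminance threshold above near-black, hole filling, largest connected
    component, then convex closure — the view is a single convex-ish bright
    region by optical construction.
    """

    def __init__(self, lum_min: float = SegConfig.view_lum_min, convex_closure: bool = True):
        self.lum_min = lum_min
        self.convex_closure = convex_closure

    def fit(self, X=None, y=None) -> "ViewSegmenter":
        logger.info("view segmenter baseline lum_min=%s", self.lum_min)
        return self

    def predict(self, frame: FrameLike) -> np.ndarray:
        img = _image_of(frame)
        gray = color.rgb2gray(img)
        raw = gray > self.lum_min
        if not raw.any():
            raise EmptyViewError("frame contains no endoscopy view (all pixels near black)")
        filled = ndimage.binary_fill_holes(raw)
        labels = measure.label(filled, connectivity=2)
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        mask = labels == largest
        if self.convex_closure:
            # offset_coordinates would pad the hull by half-pixel corners and
            # systematically overshoot a discretized disk boundary
            mask = morphology.convex_hull_image(mask, offset_coordinates=False)
        return mask


class ExposureSegmenter(BaseEstimator):
    """Baseline clearly-exposed-mucosa segmenter.

    Inside the view, removes specular pixels (high luminance, low
    saturation), dark pixels, fecal/occlusion pixels (brown hue band) and
    desaturated instrument-gray pixels, then applies small-object
    morphological cleanup.  The result is always a subset of the view.
    """

    def __init__(
        self,
        specular_lum_min: float = SegConfig.specular_lum_min,
        specular_sat_max: float = SegConfig.specular_sat_max,
        dark_lum_max: float = SegConfig.dark_lum_max,
        fecal_hue_band: tuple[float, float] = SegConfig.fecal_hue_band,
        fecal_sat_min: float = SegConfig.fecal_sat_min,
        fecal_val_max: float = SegConfig.fecal_val_max,
        instrument_sat_max: float = SegConfig.instrument_sat_max,
        min_object_px: int = SegConfig.min_object_px,
    ):
        self.specular_lum_min = specular_lum_min
        self.specular_sat_max = specular_sat_max
        self.dark_lum_max = dark_lum_max
        self.fecal_hue_band = fecal_hue_band
        self.fecal_sat_min = fecal_sat_min
        self.fecal_val_max = fecal_val_max
        self.instrument_sat_max = instrument_sat_max
        self.min_object_px = min_object_px

    def fit(self, X=None, y=None) -> "ExposureSegmenter":
        logger.info("exposure segmenter baseline params=%s", self.get_params())
        return self

    def predict(self, frame: FrameLike, view: np.ndarray) -> np.ndarray:
        img = _image_of(frame)
        view = np.asarray(view)
        if view.dtype != bool or view.shape != img.shape[:2]:
            raise ValueError("view mask must be boolean with the frame's spatial shape")
        if not view.any():
            raise EmptyViewError("view mask is empty")

        gray = color.rgb2gray(img)
        hsv = color.rgb2hsv(img)
        hue, sat, val = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        lo, hi = self.fecal_hue_band
        specular = (gray >= self.specular_lum_min) & (sat <= self.specular_sat_max)
        dark = gray <= self.dark_lum_max
        fecal = (hue >= lo) & (hue <= hi) & (sat >= self.fecal_sat_min) & (val <= self.fecal_val_max)
        instrument = (sat <= self.instrument_sat_max) & (val >= 0.2) & (gray < self.specular_lum_min)

        exposure = view & ~(specular | dark | fecal | instrument)
        if self.min_object_px > 0:
            exposure = morphology.remove_small_objects(exposure, max_size=self.min_object_px)
            exposure = morphology.remove_small_holes(exposure, max_size=self.min_object_px)
        return exposure & view


class OracleViewSegmenter(BaseEstimator):
    """Returns the synthetic generator's ground-truth view mask."""

    def fit(self, X=None, y=None):
        return self

    def predict(self, frame: FrameLike) -> np.ndarray:
        if not isinstance(frame, ProcedureFrame) or frame.view_truth is None:
            raise ValueError("oracle segmenter requires frames carrying ground truth")
        if not frame.view_truth.any():
            raise EmptyViewError("ground-truth view is empty")
        return frame.view_truth


class OracleExposureSegmenter(BaseEstimator):
    """Returns the synthetic generator's ground-truth exposure mask."""

    def fit(self, X=None, y=None):
        return self

    def predict(self, frame: FrameLike, view: np.ndarray) -> np.ndarray:
        if not isinstance(frame, ProcedureFrame) or frame.exposure_truth is None:
            raise ValueError("oracle segmenter requires frames carrying ground truth")
        return frame.exposure_truth


def segment_view(frame: FrameLike, config: Optional[SegConfig] = None) -> np.ndarray:
    """Functional wrapper over :class:`ViewSegmenter`."""
    cfg = config or SegConfig()
    cfg.validate()
    return ViewSegmenter(lum_min=cfg.view_lum_min).predict(frame)


def segment_exposure(
    frame: FrameLike, view: np.ndarray, config: Optional[SegConfig] = None
) -> np.ndarray:
    """Functional wrapper over :class:`ExposureSegmenter`."""
    cfg = config or SegConfig()
    cfg.validate()
    seg = ExposureSegmenter(
        specular_lum_min=cfg.specular_lum_min,
        specular_sat_max=cfg.specular_sat_max,
        dark_lum_max=cfg.dark_lum_max,
        fecal_hue_band=cfg.fecal_hue_band,
        fecal_sat_min=cfg.fecal_sat_min,
        fecal_val_max=cfg.fecal_val_max,
        instrument_sat_max=cfg.instrument_sat_max,
        min_object_px=cfg.min_object_px,
    )
    return seg.predict(frame, view)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|); 1.0 when both masks are empty
    (agreement on absence; each occurrence is logged)."""
    a, b = validate_mask_pair(a, b)
    total = mask_area(a) + mask_area(b)
    if total == 0:
        logger.debug("dice of two empty masks defined as 1.0")
        return 1.0
    inter = int((a & b).sum())
    return 2.0 * inter / total


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union |A∩B| / |A∪B|; 1.0 when both masks are empty."""
    a, b = validate_mask_pair(a, b)
    union = int((a | b).sum())
    if union == 0:
        logger.debug("iou of two empty masks defined as 1.0")
        return 1.0
    return int((a & b).sum()) / union


def miou(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]], average: str = "image"
) -> float:
    """Mean IoU over (prediction, truth) pairs.

    ``average='image'`` (default): mean of the foreground IoU across pairs.
    ``average='class'``: for each pair, mean of foreground and background
    IoU, then averaged across pairs.
    """
    if len(pairs) == 0:
        raise ValueError("miou requires at least one (prediction, truth) pair")
    if average not in ("image", "class"):
        raise ValueError("average must be 'image' or 'class'")
    vals = []
    for pred, truth in pairs:
        fg = iou(pred, truth)
        if average == "class":
            bg = iou(~np.asarray(pred), ~np.asarray(truth))
            vals.append((fg + bg) / 2.0)
        else:
            vals.append(fg)
    return float(np.mean(vals))


@dataclass
class SegEvalReport:
    """Aggregate segmentation evaluation: Dice, mIoU, per-image records."""

    dice: float
    miou: float
    per_image_records: list

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.per_image_records)


def evaluate_segmentation(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]], average: str = "image"
) -> SegEvalReport:
    """Evaluate predicted masks against truth with mean Dice and mIoU."""
    if len(pairs) == 0:
        raise ValueError("evaluation requires at least one (prediction, truth) pair")
    records = []
    for i, (pred, truth) in enumerate(pairs):
        records.append({"image": i, "dice": dice(pred, truth), "iou": iou(pred, truth)})
    return SegEvalReport(
        dice=float(np.mean([r["dice"] for r in records])),
        miou=miou(pairs, average=average),
        per_image_records=records,
    )
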