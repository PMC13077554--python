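"""Per-frame quality control: qualified vs. unqualified frame classification.

The production systems this package models use a trained CNN for this stage;
here the classifier is a pluggable *backend* contract with two shipped
implementations:

* :class:`HeuristicFrameClassifier` — a deterministic photometric baseline
  (luminance for in-vitro/black frames, blue-hue coverage for
  chromoendoscopy, Laplacian-energy sharpness for blur);
* :class:`OracleFrameClassifier` — returns the generator's ground-truth
  label, for pipeline tests that must isolate downstream stages.

Classification is stateless: the class of frame *i* never depends on any
other frame.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy import ndimage
from skimage import color
from sklearn.base import BaseEstimator

from ccmea.types import Frame, FrameClass, ProcedureFrame

__all__ = [
    "QcConfig",
    "Classification",
    "sharpness_score",
    "classify_frame",
    "classify_stream",
    "HeuristicFrameClassifier",
    "OracleFrameClassifier",
    "get_backend",
]

logger = logging.getLogger(__name__)

FrameLike = Union[Frame, ProcedureFrame, np.ndarray]


@dataclass(frozen=True)
class QcConfig:
    """Decision thresholds of the heuristic frame-QC baseline.

    Defaults were calibrated once on the synthetic phantom fixture set at its
    default 128x128 rendering size (see the methods note); they are plain
    config values, never hard-coded in the decision logic.
    """

    sharpness_min: float = 8e-5
    dark_frame_max: float = 0.08
    chromo_hue_band: tuple[float, float] = (0.50, 0.78)
    chromo_sat_min: float = 0.25
    chromo_coverage_min: float = 0.40
    backend: str = "heuristic"

    def validate(self) -> None:
        for name in ("sharpness_min", "dark_frame_max", "chromo_sat_min", "chromo_coverage_min"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        lo, hi = self.chromo_hue_band
        if not (0 <= lo < hi <= 1):
            raise ValueError("chromo_hue_band must be an increasing interval within [0, 1]")


@dataclass(frozen=True)
class Classification:
    """One frame's class plus a confidence in [0, 1]."""

    label: FrameClass
    score: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")


def _image_of(frame: FrameLike) -> np.ndarray:
    if isinstance(frame, ProcedureFrame):
        frame = frame.frame
    if isinstance(frame, Frame):
        img = frame.image
    else:
        img = np.asarray(frame)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] == 0 or img.shape[1] == 0:
        raise ValueError(f"undecodable frame: expected non-empty (H, W, 3) image, got {img.shape}")
    return img


def sharpness_score(frame: FrameLike) -> float:
    """Laplacian-energy sharpness: variance of the discrete Laplacian.

    Zero for constant images; for a fixed scene, Gaussian blur removes
    high-frequency energy, so increasing the blur sigma never increases the
    score.
    """
    img = _image_of(frame)
    gray = color.rgb2gray(img)
    lap = ndimage.laplace(gray)
    return float(lap.var())


def classify_frame(frame: FrameLike, config: Optional[QcConfig] = None) -> Classification:
    """Classify one frame with the heuristic baseline.

    Decision order: in-vitro (dark) -> chromoendoscopy (blue-hue coverage)
    -> blurred (low sharpness) -> qualified.  The confidence score is the
    margin of the deciding statistic mapped into [0, 1].
    """
    config = config or QcConfig()
    config.validate()
    img = _image_of(frame)
    gray = color.rgb2gray(img)

    mean_lum = float(gray.mean())
    if mean_lum < config.dark_frame_max:
        return Classification(
            FrameClass.IN_VITRO, min(1.0, (config.dark_frame_max - mean_lum) / config.dark_frame_max)
        )

    hsv = color.rgb2hsv(img)
    in_body = hsv[..., 2] > 0.15
    if in_body.any():
        hue, sat = hsv[..., 0][in_body], hsv[..., 1][in_body]
        lo, hi = config.chromo_hue_band
        coverage = float(np.mean((hue >= lo) & (hue <= hi) & (sat >= config.chromo_sat_min)))
    else:
        coverage = 0.0
    if coverage >= config.chromo_coverage_min:
        return Classification(FrameClass.CHROMOENDOSCOPY, min(1.0, coverage))

    sharp = float(ndimage.laplace(gray).var())
    if sharp < config.sharpness_min:
        return Classification(
            FrameClass.BLURRED, min(1.0, (config.sharpness_min - sharp) / config.sharpness_min)
        )
    return Classification(FrameClass.QUALIFIED, min(1.0, sharp / (2 * config.sharpness_min)))


def classify_stream(
    frames: Iterable[FrameLike], config: Optional[QcConfig] = None
) -> tuple[list[Classification], Counter]:
    """Classify an ordered frame stream; order-preserving and stateless."""
    results = [classify_frame(f, config) for f in frames]
    counts = Counter(r.label for r in results)
    return results, counts


class HeuristicFrameClassifier(BaseEstimator):
    """Photometric frame-QC baseline as an sklearn-style classifier.

    Stateless at prediction time; ``fit`` only records the class inventory.
    The three unqualified classes the baseline cannot construct from
    photometry alone (flushing, instrument, operation) are never emitted.
    """

    def __init__(
        self,
        sharpness_min: float = QcConfig.sharpness_min,
        dark_frame_max: float = QcConfig.dark_frame_max,
        chromo_hue_band: tuple[float, float] = QcConfig.chromo_hue_band,
        chromo_sat_min: float = QcConfig.chromo_sat_min,
        chromo_coverage_min: float = QcConfig.chromo_coverage_min,
    ):
        self.sharpness_min = sharpness_min
        self.dark_frame_max = dark_frame_max
        self.chromo_hue_band = chromo_hue_band
        self.chromo_sat_min = chromo_sat_min
        self.chromo_coverage_min = chromo_coverage_min

    def _config(self) -> QcConfig:
        return QcConfig(
            sharpness_min=self.sharpness_min,
            dark_frame_max=self.dark_frame_max,
            chromo_hue_band=tuple(self.chromo_hue_band),
            chromo_sat_min=self.chromo_sat_min,
            chromo_coverage_min=self.chromo_coverage_min,
        )

    def fit(self, X=None, y=None) -> "HeuristicFrameClassifier":
        cfg = self._config()
        cfg.validate()
        logger.info("frame-QC backend=heuristic config=%s", cfg)
        self.classes_ = np.array([c.value for c in FrameClass])
        return self

    def classify(self, frame: FrameLike) -> Classification:
        return classify_frame(frame, self._config())

    def predict(self, X: Sequence[FrameLike]) -> np.ndarray:
        return np.array([self.classify(f).label.value for f in X])


class OracleFrameClassifier(BaseEstimator):
    """Backend that returns the synthetic generator's ground-truth label.

    Only usable on :class:`~ccmea.types.ProcedureFrame` inputs; it exists so
    pipeline tests can isolate stages downstream of frame QC.
    """

    def fit(self, X=None, y=None) -> "OracleFrameClassifier":
        self.classes_ = np.array([c.value for c in FrameClass])
        return self

    def classify(self, frame: FrameLike) -> Classification:
        if not isinstance(frame, ProcedureFrame) or frame.label is None:
            raise ValueError("oracle backend requires frames carrying ground-truth labels")
        return Classification(frame.label, 1.0)

    def predict(self, X: Sequence[FrameLike]) -> np.ndarray:
        return np.array([self.classify(f).label.value for f in X])


_BACKENDS = {"heuristic": HeuristicFrameClassifier, "oracle": OracleFrameClassifier}


def get_backend(name: str) -> BaseEstimator:
    """Instantiate a frame-QC backend by its registry name."""
    try:
        return _BACKENDS[name]()
    except KeyError:
        raise ValueError(f"unknown frame-QC backend {name!r}; known: {sorted(_BACKENDS)}") from None
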