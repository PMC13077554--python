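"""Core domain types shared across the CCMEA pipeline.

Images are ``float`` RGB arrays in [0, 1] of shape ``(H, W, 3)``; masks are
2-D boolean arrays of the same spatial shape, row-major, 0-based ``(row, col)``
indexing.  Areas are pixel counts — CMEA is a dimensionless ratio, so the
pixel scale cancels and no physical units are attached.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "FrameClass",
    "Frame",
    "ProcedureFrame",
    "FrameMetric",
    "ProcedureRecord",
    "mask_area",
    "validate_mask_pair",
]


class FrameClass(str, enum.Enum):
    """Per-frame quality class.

    ``QUALIFIED`` frames contribute to CCMEA.  ``CHROMOENDOSCOPY`` is tracked
    separately from the other unqualified classes because it *suspends*
    accumulation (dye-spray imaging is diagnostic, not inspectional), while
    the remaining classes mark frames that carry no usable mucosal view.
    The heuristic baseline classifier never emits FLUSHING / INSTRUMENT /
    OPERATION (they are visually unconstructable without real data) but the
    taxonomy keeps them distinct for backends that can.
    """

    QUALIFIED = "qualified"
    IN_VITRO = "in_vitro"
    BLURRED = "blurred"
    FLUSHING = "flushing"
    INSTRUMENT = "instrument"
    OPERATION = "operation"
    CHROMOENDOSCOPY = "chromoendoscopy"

    @property
    def is_qualified(self) -> bool:
        return self is FrameClass.QUALIFIED

    @property
    def is_chromo(self) -> bool:
        return self is FrameClass.CHROMOENDOSCOPY


@dataclass
class Frame:
    """One decoded video frame plus its acquisition index."""

    image: np.ndarray  # (H, W, 3) float in [0, 1]
    index: int = 0
    timestamp: Optional[float] = None

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] < 1 or img.shape[1] < 1:
            raise ValueError(f"frame image must be (H, W, 3) with H, W >= 1, got {img.shape}")
        self.image = img

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass
class ProcedureFrame:
    """A synthetic frame bundled with its ground truth.

    ``cmea_truth`` is the analytic exposure ratio computed from the truth
    masks; it is ``None`` when the frame has no endoscopy view (in-vitro).
    Downstream code treats truth fields as optional — real frames carry none.
    """

    frame: Frame
    view_truth: Optional[np.ndarray] = None
    exposure_truth: Optional[np.ndarray] = None
    label: Optional[FrameClass] = None
    cmea_truth: Optional[float] = None


@dataclass
class FrameMetric:
    """Per-frame scoring outcome: class plus CMEA when qualified."""

    frame_index: int
    frame_class: FrameClass
    cmea: Optional[float] = None

    def __post_init__(self) -> None:
        if self.frame_class.is_qualified:
            if self.cmea is None or not (0.0 <= self.cmea <= 1.0):
                raise ValueError("qualified frames must carry a CMEA in [0, 1]")
        elif self.cmea is not None:
            raise ValueError("unqualified frames must not carry a CMEA")


@dataclass
class ProcedureRecord:
    """Accumulated per-procedure state: the CCMEA score and frame bookkeeping.

    ``ccmea`` is the sum of per-frame CMEA ratios over qualified frames only,
    hence dimensionless and bounded by ``n_qualified``.  ``sampling_rate`` is
    the frame rate (frames/s) at which accumulation ran; the qualification
    threshold is only meaningful at the rate it was calibrated at, so every
    record carries it.
    """

    patient_id: str = ""
    ccmea: float = 0.0
    n_frames_total: int = 0
    n_qualified: int = 0
    n_chromo: int = 0
    n_other_unqualified: int = 0
    sampling_rate: float = 25.0
    threshold: float = 2000.0
    qualified_flag: bool = False
    class_counts: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.ccmea < -1e-9:
            raise ValueError("CCMEA must be non-negative")
        if self.ccmea > self.n_qualified + 1e-9:
            raise ValueError("CCMEA cannot exceed the number of qualified frames")
        if self.n_qualified + self.n_chromo + self.n_other_unqualified != self.n_frames_total:
            raise ValueError("frame class counts must sum to the total frame count")

    def to_json(self, **kwargs) -> str:
        d = asdict(self)
        d["class_counts"] = {str(k): int(v) for k, v in self.class_counts.items()}
        return json.dumps(d, **kwargs)


def mask_area(mask: np.ndarray) -> int:
    """Pixel count of a boolean mask."""
    m = np.asarray(mask)
    if m.dtype != bool:
        raise TypeError("mask must be a boolean array")
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    return int(m.sum())


def validate_mask_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Validate two masks as boolean 2-D arrays of identical shape."""
    a = np.asarray(a)
    b = np.asarray(b)
    for m in (a, b):
        if m.ndim != 2:
            raise ValueError("masks must be 2-D")
        if m.dtype != bool:
            raise TypeError("masks must be boolean arrays")
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b
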