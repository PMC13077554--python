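"""CMEA and CCMEA: the per-frame exposure ratio and its per-procedure sum.

``CMEA = exposed-mucosa area / endoscopy-view area`` for a single qualified
frame (dimensionless, in [0, 1]).  ``CCMEA`` is the sum of CMEA over all
*qualified* frames of a withdrawal: chromoendoscopy frames suspend
accumulation (contribute exactly 0, accumulation resumes when white-light
imaging resumes) and every other unqualified frame also contributes 0.

Because CCMEA is a plain sum over frames, its magnitude scales with the
frame rate at which a withdrawal is sampled; a qualification threshold is
only meaningful at the rate it was calibrated at, so every record carries
``sampling_rate`` and the accumulator takes it explicitly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Callable, Iterable, Optional, Union

import numpy as np
import pandas as pd

from ccmea.frame_qc import HeuristicFrameClassifier, OracleFrameClassifier
from ccmea.segmentation import (
    EmptyViewError,
    ExposureSegmenter,
    OracleExposureSegmenter,
    OracleViewSegmenter,
    ViewSegmenter,
)
from ccmea.types import Frame, FrameClass, FrameMetric, ProcedureFrame, mask_area

__all__ = [
    "cmea",
    "accumulate",
    "score_frames",
    "score_directory",
    "score_video",
    "oracle_pipeline",
    "baseline_pipeline",
    "DEFAULT_THRESHOLD",
    "DEFAULT_SAMPLING_RATE",
]

logger = logging.getLogger(__name__)

#: Calibrated qualification threshold (CCMEA units) at the calibration frame rate.
DEFAULT_THRESHOLD = 2000.0
#: Frame rate (frames/s) assumed for synthetic fixtures.
DEFAULT_SAMPLING_RATE = 25.0


def cmea(exposure: np.ndarray, view: np.ndarray) -> float:
    """Per-frame mucosal exposure ratio ``|exposure ∩ view| / |view|``.

    Raises on an empty view (such a frame should have been filtered out as
    unqualified before ever reaching the metric).
    """
    exposure = np.asarray(exposure)
    view = np.asarray(view)
    if exposure.shape != view.shape:
        raise ValueError(f"mask shapes differ: {exposure.shape} vs {view.shape}")
    va = mask_area(view)
    if va == 0:
        raise ZeroDivisionError("CMEA is undefined for an empty endoscopy view")
    return float((exposure & view).sum()) / va


def baseline_pipeline() -> dict:
    """Default component set: heuristic QC + photometric segmenters."""
    return {
        "classifier": HeuristicFrameClassifier().fit(),
        "view_segmenter": ViewSegmenter().fit(),
        "exposure_segmenter": ExposureSegmenter().fit(),
    }


def oracle_pipeline() -> dict:
    """Ground-truth component set, for isolating the accumulation stage."""
    return {
        "classifier": OracleFrameClassifier().fit(),
        "view_segmenter": OracleViewSegmenter().fit(),
        "exposure_segmenter": OracleExposureSegmenter().fit(),
    }


def accumulate(
    frame_stream: Iterable[Union[Frame, ProcedureFrame, np.ndarray]],
    classifier=None,
    view_segmenter=None,
    exposure_segmenter=None,
    threshold: float = DEFAULT_THRESHOLD,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    patient_id: str = "",
    on_frame: Optional[Callable[[FrameMetric], None]] = None,
):
    """Stream frames through QC + segmentation and accumulate CCMEA.

    Only frames classified qualified contribute to the sum; chromoendoscopy
    frames are counted separately (they suspend accumulation) and all other
    unqualified classes contribute exactly 0.  Memory use is independent of
    stream length.  An empty stream yields a zero record with
    ``qualified_flag = False``; a CCMEA exactly at ``threshold`` counts as
    qualified.
    """
    from ccmea.types import ProcedureRecord  # local to keep module import light

    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    classifier = classifier if classifier is not None else HeuristicFrameClassifier().fit()
    view_segmenter = view_segmenter if view_segmenter is not None else ViewSegmenter().fit()
    exposure_segmenter = (
        exposure_segmenter if exposure_segmenter is not None else ExposureSegmenter().fit()
    )

    total = 0.0
    n_total = n_qual = n_chromo = n_other = 0
    class_counts: dict[str, int] = {}
    for i, item in enumerate(frame_stream):
        cls = classifier.classify(item)
        label = cls.label
        value: Optional[float] = None
        if label.is_qualified:
            try:
                view = view_segmenter.predict(item)
                exposure = exposure_segmenter.predict(item, view)
                value = cmea(exposure, view)
            except EmptyViewError:
                # no usable view: demote to in-vitro rather than scoring
                label = FrameClass.IN_VITRO
        if label.is_qualified:
            n_qual += 1
            total += value
        elif label.is_chromo:
            n_chromo += 1
        else:
            n_other += 1
        n_total += 1
        class_counts[label.value] = class_counts.get(label.value, 0) + 1
        if on_frame is not None:
            on_frame(FrameMetric(frame_index=i, frame_class=label, cmea=value))

    record = ProcedureRecord(
        patient_id=patient_id,
        ccmea=total,
        n_frames_total=n_total,
        n_qualified=n_qual,
        n_chromo=n_chromo,
        n_other_unqualified=n_other,
        sampling_rate=sampling_rate,
        threshold=threshold,
        qualified_flag=bool(total >= threshold),
        class_counts=class_counts,
    )
    record.validate()
    return record


def score_frames(
    frame_stream,
    classifier=None,
    view_segmenter=None,
    exposure_segmenter=None,
    threshold: float = DEFAULT_THRESHOLD,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    patient_id: str = "",
):
    """Like :func:`accumulate` but also returns the per-frame metric log."""
    rows: list[dict] = []

    def collect(m: FrameMetric) -> None:
        rows.append(
            {"frame_index": m.frame_index, "frame_class": m.frame_class.value, "cmea": m.cmea}
        )

    record = accumulate(
        frame_stream,
        classifier=classifier,
        view_segmenter=view_segmenter,
        exposure_segmenter=exposure_segmenter,
        threshold=threshold,
        sampling_rate=sampling_rate,
        patient_id=patient_id,
        on_frame=collect,
    )
    log = pd.DataFrame(rows, columns=["frame_index", "frame_class", "cmea"])
    return record, log


_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff")


def _load_image(path: Path) -> Frame:
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.float32 and arr.dtype != np.float64:
        arr = arr.astype(np.float32) / np.iinfo(arr.dtype).max
    return Frame(image=arr.astype(np.float32))


def _iter_directory(directory: Path, start: Optional[int], end: Optional[int]):
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
    if not files:
        raise FileNotFoundError(f"no decodable frames in {directory}")
    for p in files[start:end]:
        yield _load_image(p)


def score_directory(
    directory: Union[str, Path],
    start: Optional[int] = None,
    end: Optional[int] = None,
    **kwargs,
):
    """Score an image-directory 'procedure' (frames in sorted filename order).

    ``start``/``end`` optionally restrict scoring to a frame window (the
    withdrawal phase is assumed to be what was recorded; no phase detection
    is attempted).
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    return score_frames(_iter_directory(directory, start, end), **kwargs)


def score_video(
    path: Union[str, Path],
    start: Optional[int] = None,
    end: Optional[int] = None,
    **kwargs,
):
    """Score a video container (or, if given a directory, delegate to
    :func:`score_directory`).  Requires an imageio plugin able to decode the
    container; failures raise an error naming the file."""
    path = Path(path)
    if path.is_dir():
        return score_directory(path, start=start, end=end, **kwargs)
    if not path.exists():
        raise FileNotFoundError(f"no such input: {path}")
    import imageio.v3 as iio

    def frames():
        n = 0
        try:
            for i, arr in enumerate(iio.imiter(path)):
                if start is not None and i < start:
                    continue
                if end is not None and i >= end:
                    break
                if arr.ndim == 2:
                    arr = np.stack([arr] * 3, axis=-1)
                if arr.dtype != np.float32 and arr.dtype != np.float64:
                    arr = arr.astype(np.float32) / np.iinfo(arr.dtype).max
                n += 1
                yield Frame(image=arr.astype(np.float32)[..., :3], index=i)
        except Exception as exc:  # decoding failure names the file
            raise IOError(f"cannot decode video container {path}: {exc}") from exc
        if n == 0:
            raise IOError(f"zero decodable frames in {path}")

    return score_frames(frames(), **kwargs)
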