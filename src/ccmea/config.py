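"""Run configuration: a single YAML file for all thresholds and seeds.

Sections map onto the dataclass configs of each stage (``frame_qc`` ->
:class:`~ccmea.frame_qc.QcConfig`, ``segmentation`` ->
:class:`~ccmea.segmentation.SegConfig`) plus scalar pipeline settings
(``threshold``, ``sampling_rate``, ``bin_width``, ``adr_target``, ``alpha``,
``n_tests``, ``seed``).  Every run logs the configuration hash, seed and
backend identifiers so results can be traced to the exact settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from ccmea.frame_qc import QcConfig
from ccmea.segmentation import SegConfig

__all__ = ["RunConfig", "load_config", "config_hash"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on, in one place."""

    qc: QcConfig = dataclasses.field(default_factory=QcConfig)
    seg: SegConfig = dataclasses.field(default_factory=SegConfig)
    threshold: float = 2000.0
    sampling_rate: float = 25.0
    bin_width: float = 1000.0
    adr_target: float = 0.25
    alpha: float = 0.05
    n_tests: int = 11
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


def config_hash(cfg: RunConfig) -> str:
    """Short deterministic digest of a configuration, for run logs."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: Optional[Union[str, Path]] = None) -> RunConfig:
    """Load a YAML run configuration; missing keys keep their defaults."""
    if path is None:
        cfg = RunConfig()
    else:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc_kwargs = raw.pop("frame_qc", {}) or {}
        seg_kwargs = raw.pop("segmentation", {}) or {}
        if "chromo_hue_band" in qc_kwargs:
            qc_kwargs["chromo_hue_band"] = tuple(qc_kwargs["chromo_hue_band"])
        if "fecal_hue_band" in seg_kwargs:
            seg_kwargs["fecal_hue_band"] = tuple(seg_kwargs["fecal_hue_band"])
        known = {f.name for f in dataclasses.fields(RunConfig)} - {"qc", "seg"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = RunConfig(qc=QcConfig(**qc_kwargs), seg=SegConfig(**seg_kwargs), **raw)
    cfg.qc.validate()
    cfg.seg.validate()
    logger.info(
        "run config hash=%s seed=%d backend=%s sampling_rate=%.3g",
        config_hash(cfg),
        cfg.seed,
        cfg.qc.backend,
        cfg.sampling_rate,
    )
    return cfg
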