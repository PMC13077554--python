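"""Endoscopy-like phantom frames with exact ground-truth masks.

A phantom frame mimics the gross photometric structure of a colonoscopy
frame: a bright, textured, pink-red mucosal disk (the endoscopy view) on a
near-black background, optionally carrying the artifact classes that make
mucosa *not* clearly exposed — specular reflections (bright, desaturated),
fecal residue (brown), excessively dark patches, and instrument shafts
(gray, desaturated).  A global blue tint emulates dye-spray chromoendoscopy
and Gaussian blur emulates motion blur.

The ground-truth exposure mask is, by construction, the view mask minus the
union of artifact masks — the generator renders exactly what it reports.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from skimage import filters, transform

from ccmea.types import Frame, FrameClass, ProcedureFrame

__all__ = ["FramePhantomSpec", "generate_frame", "generate_procedure", "phase_plan_total"]

ARTIFACT_CLASSES = ("specular", "fecal", "dark", "instrument")

#: Blur sigma (pixels) above which a rendered frame is labeled BLURRED.
BLUR_LABEL_BOUND = 2.0

# Photometric palette (RGB in [0, 1]).  Chosen so that the artifact classes are
# separable in HSV space from the mucosa base color: mucosa hue ~0.02 (pink-red,
# saturated), fecal hue ~0.09 (brown, mid-value), specular value ~0.98 at near-zero
# saturation, instrument desaturated mid-gray, dark patches value < 0.05.
_MUCOSA_RGB = np.array([0.80, 0.44, 0.40])
_FECAL_RGB = np.array([0.45, 0.28, 0.10])
_SPECULAR_RGB = np.array([0.98, 0.98, 0.96])
_INSTRUMENT_RGB = np.array([0.55, 0.57, 0.60])
_CHROMO_RGB = np.array([0.18, 0.35, 0.80])
_CHROMO_BLEND = 0.55
_BACKGROUND_LEVEL = 0.015


@dataclass(frozen=True)
class FramePhantomSpec:
    """Parameters of one rendered phantom frame.

    ``view_fraction`` is the fraction of the frame area occupied by the
    endoscopy view; ``artifact_budget`` maps artifact class name to the
    fraction of the *view* area it should cover (union of all budgets must
    not exceed 1).  ``blur_sigma`` is the Gaussian blur in pixels applied to
    the composed frame.  ``in_vitro_flag`` renders an out-of-body frame
    (dim gray noise, no endoscopy view at all).
    """

    image_height: int = 128
    image_width: int = 128
    view_shape: str = "circle"  # or "rounded-rectangle"
    view_fraction: float = 0.62
    artifact_budget: Mapping[str, float] = field(
        default_factory=lambda: {"specular": 0.05, "fecal": 0.03, "dark": 0.03}
    )
    blur_sigma: float = 0.0
    chromo_flag: bool = False
    in_vitro_flag: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.image_height < 1 or self.image_width < 1:
            raise ValueError("image dimensions must be positive")
        if self.view_shape not in ("circle", "rounded-rectangle"):
            raise ValueError(f"unknown view shape {self.view_shape!r}")
        if not (0.4 <= self.view_fraction <= 0.95):
            raise ValueError("view_fraction must lie in [0.4, 0.95]")
        total = 0.0
        for name, frac in self.artifact_budget.items():
            if name not in ARTIFACT_CLASSES:
                raise ValueError(f"unknown artifact class {name!r}")
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"artifact budget for {name!r} must lie in [0, 1]")
            total += frac
        if total > 1.0 + 1e-9:
            raise ValueError(f"artifact budgets sum to {total:.3f} > 1")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")

    def replace(self, **changes) -> "FramePhantomSpec":
        return dataclasses.replace(self, **changes)


def _view_mask(spec: FramePhantomSpec) -> np.ndarray:
    """Boolean view mask whose area matches ``view_fraction`` to ~0.5%."""
    H, W = spec.image_height, spec.image_width
    target = spec.view_fraction * H * W
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0

    if spec.view_shape == "circle":
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2

        def mask_at(r: float) -> np.ndarray:
            return d2 <= r * r

        lo, hi = 0.0, float(np.hypot(H, W))
    else:  # rounded-rectangle: grow a half-extent, fixed relative corner radius
        rho = 0.15 * min(H, W)

        def mask_at(t: float) -> np.ndarray:
            hy, hx = t * H / 2.0, t * W / 2.0
            dy = np.maximum(np.abs(yy - cy) - (hy - rho), 0.0)
            dx = np.maximum(np.abs(xx - cx) - (hx - rho), 0.0)
            return dy * dy + dx * dx <= rho * rho

        lo, hi = 0.0, 1.0

    for _ in range(48):  # bisect on the size parameter to hit the target area
        mid = (lo + hi) / 2.0
        if mask_at(mid).sum() < target:
            lo = mid
        else:
            hi = mid
    return mask_at(hi)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], coarse: int = 8) -> np.ndarray:
    """Smooth zero-mean noise field in roughly [-1, 1] for mucosal texture."""
    h = max(2, shape[0] // coarse)
    w = max(2, shape[1] // coarse)
    noise = rng.normal(size=(h, w))
    fieldimg = transform.resize(noise, shape, order=3, mode="reflect", anti_aliasing=False)
    scale = max(np.abs(fieldimg).max(), 1e-12)
    return fieldimg / scale


def _place_blobs(
    rng: np.random.Generator,
    view: np.ndarray,
    occupied: np.ndarray,
    target_area: float,
) -> np.ndarray:
    """Random disks inside the view until ``target_area`` pixels are covered."""
    H, W = view.shape
    mask = np.zeros_like(view)
    if target_area <= 0:
        return mask
    coords = np.argwhere(view)
    rmin, rmax = 0.03 * min(H, W), 0.12 * min(H, W)
    yy, xx = np.mgrid[0:H, 0:W]
    for _ in range(300):
        if mask.sum() >= target_area:
            break
        cy, cx = coords[rng.integers(len(coords))]
        r = rng.uniform(rmin, rmax)
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        mask |= disk & view & ~occupied
    return mask


def generate_frame(
    spec: FramePhantomSpec, index: int = 0
) -> tuple[Frame, np.ndarray, np.ndarray, FrameClass]:
    """Render one phantom frame.

    Returns ``(frame, view_truth, exposure_truth, label)`` where
    ``exposure_truth == view_truth & ~artifacts`` by construction and the
    label follows the spec flags (in-vitro > chromoendoscopy > blurred >
    qualified).
    """
    spec.validate()
    H, W = spec.image_height, spec.image_width
    rng = np.random.default_rng(spec.seed)

    if spec.in_vitro_flag:
        img = np.clip(0.03 + 0.012 * rng.normal(size=(H, W, 1)), 0, 1) * np.ones((1, 1, 3))
        empty = np.zeros((H, W), dtype=bool)
        frame = Frame(image=img.astype(np.float32), index=index)
        return frame, empty, empty, FrameClass.IN_VITRO

    view = _view_mask(spec)
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0

    # Mucosa: textured pink-red with a mild radial falloff toward the view edge.
    texture = 1.0 + 0.12 * _smooth_field(rng, (H, W))
    r_norm = np.sqrt(((yy - cy) / (H / 2)) ** 2 + ((xx - cx) / (W / 2)) ** 2)
    vignette = 1.0 - 0.15 * np.clip(r_norm, 0, 1) ** 2
    shading = (texture * vignette)[..., None]
    img = np.empty((H, W, 3))
    img[:] = _BACKGROUND_LEVEL + 0.008 * np.abs(rng.normal(size=(H, W, 1)))
    img[view] = (_MUCOSA_RGB[None, :] * shading[view]).clip(0.05, 1.0)

    # Artifact placement with class precedence: each class is carved out of the
    # still-unoccupied view so the union area ~= the budget sum.
    view_area = float(view.sum())
    artifact_union = np.zeros((H, W), dtype=bool)
    artifact_masks: dict[str, np.ndarray] = {}
    budget = dict(spec.artifact_budget)
    for name in ARTIFACT_CLASSES:
        frac = float(budget.get(name, 0.0))
        m = _place_blobs(rng, view, artifact_union, frac * view_area)
        artifact_masks[name] = m
        artifact_union |= m
    if sum(budget.values()) >= 0.999:
        # Full occlusion requested: random disks cannot tile the last pixels,
        # so sweep the remainder into the largest-budget class.
        biggest = max(budget, key=lambda k: budget[k])
        rest = view & ~artifact_union
        artifact_masks[biggest] |= rest
        artifact_union |= rest

    spec_noise = 0.01 * rng.normal(size=(H, W, 1))
    for name, color in (
        ("instrument", _INSTRUMENT_RGB),
        ("fecal", _FECAL_RGB),
        ("specular", _SPECULAR_RGB),
    ):
        m = artifact_masks[name]
        if m.any():
            img[m] = np.clip(color[None, :] + spec_noise[m], 0, 1)
    if artifact_masks["dark"].any():
        img[artifact_masks["dark"]] *= 0.04

    if spec.chromo_flag:
        img[view] = (1 - _CHROMO_BLEND) * img[view] + _CHROMO_BLEND * _CHROMO_RGB[None, :]

    if spec.blur_sigma > 0:
        img = filters.gaussian(img, sigma=spec.blur_sigma, channel_axis=-1, preserve_range=True)

    exposure = view & ~artifact_union
    if spec.chromo_flag:
        label = FrameClass.CHROMOENDOSCOPY
    elif spec.blur_sigma > BLUR_LABEL_BOUND:
        label = FrameClass.BLURRED
    else:
        label = FrameClass.QUALIFIED
    frame = Frame(image=np.clip(img, 0, 1).astype(np.float32), index=index)
    return frame, view, exposure, label


def phase_plan_total(phase_plan: Sequence[tuple[FrameClass, int]]) -> int:
    """Total frame count of a phase plan."""
    return sum(int(n) for _, n in phase_plan)


#: Frame classes the phantom renderer can produce.
RENDERABLE_CLASSES = frozenset(
    {FrameClass.QUALIFIED, FrameClass.BLURRED, FrameClass.CHROMOENDOSCOPY, FrameClass.IN_VITRO}
)


def generate_procedure(
    n_frames: int,
    phase_plan: Sequence[tuple[FrameClass, int]],
    spec_defaults: Optional[FramePhantomSpec] = None,
) -> list[ProcedureFrame]:
    """Render a whole withdrawal 'procedure' as an ordered frame sequence.

    ``phase_plan`` is a run-length encoding of frame classes, e.g.
    ``[(QUALIFIED, 50), (CHROMOENDOSCOPY, 10), (QUALIFIED, 40)]``; run
    lengths must sum to ``n_frames``.  Each frame gets its own child seed
    derived from ``spec_defaults.seed`` so the sequence is reproducible yet
    per-frame varied.  Ground-truth CMEA is recorded alongside every frame
    that has an endoscopy view (blurred and chromo frames included, although
    downstream accumulation excludes them).
    """
    if not phase_plan:
        raise ValueError("phase_plan must not be empty")
    plan = [(FrameClass(lbl), int(n)) for lbl, n in phase_plan]
    if any(n < 0 for _, n in plan):
        raise ValueError("run lengths must be non-negative")
    if phase_plan_total(plan) != n_frames:
        raise ValueError(
            f"phase plan run lengths sum to {phase_plan_total(plan)}, expected {n_frames}"
        )
    unsupported = {lbl for lbl, _ in plan} - RENDERABLE_CLASSES
    if unsupported:
        raise ValueError(
            f"phantom renderer cannot produce classes: {sorted(c.value for c in unsupported)}"
        )
    spec = spec_defaults if spec_defaults is not None else FramePhantomSpec()
    spec.validate()

    child_seeds = np.random.SeedSequence(spec.seed).generate_state(max(n_frames, 1)) % (2**31)
    frames: list[ProcedureFrame] = []
    i = 0
    for label, run in plan:
        for _ in range(run):
            s = int(child_seeds[i])
            if label is FrameClass.QUALIFIED:
                fspec = spec.replace(seed=s, chromo_flag=False, in_vitro_flag=False)
            elif label is FrameClass.BLURRED:
                fspec = spec.replace(
                    seed=s,
                    chromo_flag=False,
                    in_vitro_flag=False,
                    blur_sigma=max(spec.blur_sigma, 4.0),
                )
            elif label is FrameClass.CHROMOENDOSCOPY:
                fspec = spec.replace(seed=s, chromo_flag=True, in_vitro_flag=False)
            else:  # IN_VITRO
                fspec = spec.replace(seed=s, in_vitro_flag=True)
            frame, view, exposure, got = generate_frame(fspec, index=i)
            assert got is label, f"renderer produced {got} for planned {label}"
            va = int(view.sum())
            cmea_truth = float(exposure.sum()) / va if va else None
            frames.append(
                ProcedureFrame(
                    frame=frame,
                    view_truth=view,
                    exposure_truth=exposure,
                    label=label,
                    cmea_truth=cmea_truth,
                )
            )
            i += 1
    return frames
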