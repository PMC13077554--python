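"""Qualification-threshold calibration from a cohort's CCMEA / adenoma data.

Procedure: group patients by CCMEA in fixed-width bins (1000 units wide by
default), compute the per-bin adenoma detection rate (ADR), fit a monotone
saturating logistic dose-response ``ADR(c) = L / (1 + exp(-k (c - c0)))`` to
the bin midpoints weighted by bin size, and select the smallest bin-edge
multiple at which the fitted ADR — and everything above it — exceeds the
screening target (25% by default).

The logistic family is the minimal bounded increasing dose-response; when
the weighted fit fails to converge the fit falls back to isotonic
regression (flagged in the result), and a cohort whose bins all share one
ADR yields a flagged constant "curve".  Applying the criterion to the
*fitted* curve (rather than raw bin ADRs, which can be non-monotone from
sampling noise) is the default; a raw-bin mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "BinSummary",
    "CurveParams",
    "ThresholdResult",
    "bin_by_ccmea",
    "fit_adr_curve",
    "predict_adr",
    "select_threshold",
    "curve_table",
    "AdrThresholdCalibrator",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_ADR_TARGET",
]

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 1000.0
DEFAULT_ADR_TARGET = 0.25


@dataclass(frozen=True)
class BinSummary:
    """One half-open CCMEA bin [lower, upper) with its ADR."""

    bin_lower: float
    bin_upper: float
    n_patients: int
    n_adenoma_positive: int

    @property
    def adr(self) -> float:
        return self.n_adenoma_positive / self.n_patients if self.n_patients else float("nan")

    @property
    def midpoint(self) -> float:
        return (self.bin_lower + self.bin_upper) / 2.0


@dataclass(frozen=True)
class CurveParams:
    """Fitted ADR-vs-CCMEA curve.

    ``method`` is ``"logistic"`` for the primary parametric fit
    (``L, k, c0``), ``"isotonic"`` for the non-parametric fallback and
    ``"constant"`` for the degenerate equal-ADR case.
    """

    method: str
    L: float = float("nan")
    k: float = float("nan")
    c0: float = float("nan")
    constant: float = float("nan")
    iso_x: Optional[np.ndarray] = None
    iso_y: Optional[np.ndarray] = None
    residuals: tuple = ()
    converged: bool = True


def _logistic(c, L, k, c0):
    return L / (1.0 + np.exp(-k * (np.asarray(c, dtype=float) - c0)))


def bin_by_ccmea(
    cohort: pd.DataFrame,
    width: float = DEFAULT_BIN_WIDTH,
    ccmea_col: str = "ccmea",
    adenoma_col: str = "adenoma",
) -> list[BinSummary]:
    """Group a cohort into half-open CCMEA bins of the given width.

    Bins partition [0, max) — interior empty bins are kept (they carry
    ``n_patients == 0``), trailing empty bins cannot occur because the top
    bin contains the cohort maximum.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    if len(cohort) == 0:
        raise ValueError("cannot bin an empty cohort")
    for col in (ccmea_col, adenoma_col):
        if col not in cohort.columns:
            raise KeyError(f"cohort table lacks required column {col!r}")
    c = cohort[ccmea_col].to_numpy(dtype=float)
    y = cohort[adenoma_col].to_numpy(dtype=int)
    if (c < 0).any():
        raise ValueError("CCMEA values must be non-negative")
    idx = np.floor(c / width).astype(int)
    n_bins = int(idx.max()) + 1
    bins = []
    for b in range(n_bins):
        sel = idx == b
        bins.append(
            BinSummary(
                bin_lower=b * width,
                bin_upper=(b + 1) * width,
                n_patients=int(sel.sum()),
                n_adenoma_positive=int(y[sel].sum()),
            )
        )
    return bins


def fit_adr_curve(bins: Sequence[BinSummary]) -> CurveParams:
    """Fit the saturating logistic ADR curve to non-empty bins.

    Weighted by bin size (sigma ∝ 1/sqrt(n)).  Falls back to isotonic
    regression when the parametric fit fails; returns a flagged constant
    curve when every bin shares the same ADR.
    """
    occupied = [b for b in bins if b.n_patients > 0]
    if len(occupied) < 3:
        raise ValueError(f"need >= 3 non-empty bins to fit a curve, got {len(occupied)}")
    x = np.array([b.midpoint for b in occupied])
    adr = np.array([b.adr for b in occupied])
    n = np.array([b.n_patients for b in occupied], dtype=float)

    if np.allclose(adr, adr[0]):
        logger.warning("degenerate fit: all bins share ADR %.4f; returning constant curve", adr[0])
        return CurveParams(method="constant", constant=float(adr[0]), converged=False)

    width = occupied[0].bin_upper - occupied[0].bin_lower
    p0 = (min(max(adr.max(), 0.05), 1.0), 2.0 / max(x.max() - x.min(), width), float(np.median(x)))
    try:
        popt, _ = curve_fit(
            _logistic,
            x,
            adr,
            p0=p0,
            sigma=1.0 / np.sqrt(n),
            bounds=([1e-6, 1e-9, -np.inf], [1.0, np.inf, np.inf]),
            maxfev=20000,
        )
        resid = tuple(adr - _logistic(x, *popt))
        return CurveParams(
            method="logistic",
            L=float(popt[0]),
            k=float(popt[1]),
            c0=float(popt[2]),
            residuals=resid,
            converged=True,
        )
    except (RuntimeError, ValueError) as exc:
        logger.warning("logistic ADR fit failed (%s); falling back to isotonic regression", exc)
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
        iso.fit(x, adr, sample_weight=n)
        yhat = iso.predict(x)
        return CurveParams(
            method="isotonic",
            iso_x=x.copy(),
            iso_y=yhat.copy(),
            residuals=tuple(adr - yhat),
            converged=False,
        )


def predict_adr(params: CurveParams, c) -> np.ndarray:
    """Evaluate a fitted ADR curve at CCMEA value(s) ``c``."""
    c = np.asarray(c, dtype=float)
    if params.method == "logistic":
        return _logistic(c, params.L, params.k, params.c0)
    if params.method == "constant":
        return np.full_like(c, params.constant, dtype=float)
    if params.method == "isotonic":
        return np.interp(c, params.iso_x, params.iso_y)
    raise ValueError(f"unknown curve method {params.method!r}")


@dataclass(frozen=True)
class ThresholdResult:
    """Selected qualification threshold (a bin-width multiple), or a flagged
    "no qualifying threshold" outcome when the curve never reaches target."""

    threshold: Optional[float]
    adr_target: float
    curve_params: CurveParams
    diagnostics: dict = field(default_factory=dict)

    @property
    def reached(self) -> bool:
        return self.threshold is not None


def select_threshold(
    curve_params: CurveParams,
    bins: Sequence[BinSummary],
    adr_target: float = DEFAULT_ADR_TARGET,
    width: float = DEFAULT_BIN_WIDTH,
    raw_bins: bool = False,
) -> ThresholdResult:
    """Smallest bin-edge multiple above which ADR always exceeds the target.

    Default: the criterion is applied to the *fitted* curve, evaluated on a
    fine grid from each candidate edge to the top of the binned range.  With
    ``raw_bins=True`` the raw bin ADRs are used instead.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if not bins:
        raise ValueError("no bins provided")
    max_edge = max(b.bin_upper for b in bins)
    candidates = np.arange(0.0, max_edge, width)

    diagnostics = {
        "residuals": curve_params.residuals,
        "method": curve_params.method,
        "max_edge": max_edge,
    }
    for t in candidates:
        if raw_bins:
            above = [b for b in bins if b.bin_lower >= t and b.n_patients > 0]
            ok = len(above) > 0 and all(b.adr > adr_target for b in above)
        else:
            grid = np.linspace(t, max_edge, 256)
            ok = bool(np.all(predict_adr(curve_params, grid) > adr_target))
        if ok:
            return ThresholdResult(
                threshold=float(t),
                adr_target=adr_target,
                curve_params=curve_params,
                diagnostics=diagnostics,
            )
    logger.warning("fitted ADR curve never exceeds target %.3f: no qualifying threshold", adr_target)
    return ThresholdResult(
        threshold=None, adr_target=adr_target, curve_params=curve_params, diagnostics=diagnostics
    )


def curve_table(
    bins: Sequence[BinSummary], params: CurveParams, n_grid: int = 200
) -> pd.DataFrame:
    """Plot-ready table: bin midpoints, raw ADR, and the fitted curve."""
    rows = [
        {
            "ccmea": b.midpoint,
            "kind": "bin",
            "adr": b.adr,
            "n": b.n_patients,
        }
        for b in bins
        if b.n_patients > 0
    ]
    grid = np.linspace(0, max(b.bin_upper for b in bins), n_grid)
    fitted = predict_adr(params, grid)
    rows += [{"ccmea": float(c), "kind": "fit", "adr": float(a), "n": 0} for c, a in zip(grid, fitted)]
    return pd.DataFrame(rows)


class AdrThresholdCalibrator(BaseEstimator):
    """Sklearn-style calibrator: fit on (CCMEA, adenoma) data, then classify
    procedures as qualified/unqualified.

    Parameters mirror the calibration procedure: bin ``width``,
    ``adr_target``, and whether the criterion applies to the fitted curve or
    the raw bins.  Fitted attributes: ``bins_``, ``curve_params_``,
    ``threshold_`` (None when the target is unreachable) and ``result_``.
    """

    def __init__(
        self,
        width: float = DEFAULT_BIN_WIDTH,
        adr_target: float = DEFAULT_ADR_TARGET,
        raw_bins: bool = False,
    ):
        self.width = width
        self.adr_target = adr_target
        self.raw_bins = raw_bins

    def fit(self, X, y=None) -> "AdrThresholdCalibrator":
        """``X`` is either a cohort DataFrame with ``ccmea``/``adenoma``
        columns, or an array of CCMEA values with ``y`` the 0/1 adenoma
        indicators."""
        if isinstance(X, pd.DataFrame):
            cohort = X
        else:
            if y is None:
                raise ValueError("array input requires y (adenoma indicators)")
            cohort = pd.DataFrame({"ccmea": np.asarray(X, dtype=float).ravel(), "adenoma": y})
        self.bins_ = bin_by_ccmea(cohort, width=self.width)
        self.curve_params_ = fit_adr_curve(self.bins_)
        self.result_ = select_threshold(
            self.curve_params_,
            self.bins_,
            adr_target=self.adr_target,
            width=self.width,
            raw_bins=self.raw_bins,
        )
        self.threshold_ = self.result_.threshold
        logger.info(
            "calibrated threshold=%s (target ADR %.3f, curve=%s)",
            self.threshold_,
            self.adr_target,
            self.curve_params_.method,
        )
        return self

    def predict(self, ccmea) -> np.ndarray:
        """Qualified flag per procedure (CCMEA >= threshold; ties qualify)."""
        if not hasattr(self, "threshold_"):
            raise RuntimeError("calibrator is not fitted")
        if self.threshold_ is None:
            raise RuntimeError("no qualifying threshold was reachable on the training cohort")
        return np.asarray(ccmea, dtype=float) >= self.threshold_
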