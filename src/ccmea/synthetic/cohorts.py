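"""Synthetic multi-center colonoscopy cohorts with a known CCMEA→outcome model.

Each patient gets a CCMEA drawn from a right-skewed (gamma) per-center
distribution, covariates (sex, colonoscopy indication) matching the marginal
frequencies of a screening-age population, and lesion outcomes generated
from an explicit model:

* adenoma presence is Bernoulli with logit probability
  ``beta0 + beta_ccmea * (ccmea - half_point) + beta_sex * male +
  beta_indication[ind] + u_center``, ``u_center ~ N(0, center_sd)`` —
  a saturating logistic dose-response in CCMEA with a center random
  intercept, the structure assumed by the downstream mixed-model analysis;
* the adenoma *count* is 0 when the indicator is 0, else 1 plus a Poisson
  overcount whose mean grows with CCMEA;
* non-adenomatous polyps are an independent Poisson count, so
  ``polyp count >= adenoma count >= 0`` always holds;
* lesion size classes (diminutive <=5 mm, small 5-10 mm, large >=10 mm) and
  advanced histology are sampled per lesion.

Defaults place the baseline 25% adenoma-probability point at CCMEA = 2000
(``half_point``); with the default covariate mix, the *marginal* ADR curve
crosses 25% near CCMEA ~1600, i.e. inside the [1000, 2000) bin, so the
1000-wide-bin threshold-selection procedure should recover 2000.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "CohortGenSpec",
    "generate_cohort",
    "generate_two_group_cohort",
    "adenoma_probability",
]

_SIZE_CLASSES = ("diminutive", "small", "large")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class CohortGenSpec:
    """Generative parameters for one synthetic cohort.

    ``beta0`` is the logit adenoma probability at ``ccmea == half_point`` for
    the reference covariates (female, health-examination indication, average
    center); ``beta_ccmea`` is the log-odds slope per CCMEA unit.
    ``ccmea_center_log_sd`` adds per-center log-normal jitter to the gamma
    scale of the CCMEA distribution (0 = identical distribution in every
    center).  ``poisson_rate_fn`` optionally overrides the default
    non-adenomatous polyp rate as a function of CCMEA.
    """

    n_patients: int = 510
    n_centers: int = 3
    center_sd: float = 0.3
    beta0: float = float(np.log(0.25 / 0.75))  # logit(0.25)
    beta_ccmea: float = 8e-4
    half_point: float = 2000.0
    beta_sex: float = 0.35
    beta_indication: Mapping[str, float] = field(
        default_factory=lambda: {"health examination": 0.0, "diagnostic": 0.15, "surveillance": 0.40}
    )
    sex_p_male: float = 0.467
    indication_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "health examination": 0.218,
            "diagnostic": 0.619,
            "surveillance": 0.163,
        }
    )
    ccmea_gamma_shape: float = 2.4
    ccmea_gamma_scale: float = 1000.0
    ccmea_center_log_sd: float = 0.0
    # mean extra adenomas (beyond the first) among adenoma-positive patients
    adenoma_overcount_base: float = 0.4
    adenoma_overcount_slope: float = 2.5e-4
    # mean non-adenomatous polyp count; the gamma frailty (shape
    # polyp_dispersion, mean 1) makes counts overdispersed like real lesion
    # counts (SD > mean), which a marginal Poisson cannot produce; set
    # polyp_dispersion = 0 for pure Poisson counts
    polyp_rate_base: float = 0.5
    polyp_rate_slope: float = 5.5e-4
    polyp_dispersion: float = 0.6
    poisson_rate_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None
    adenoma_size_probs: tuple[float, float, float] = (0.78, 0.17, 0.05)
    polyp_size_probs: tuple[float, float, float] = (0.88, 0.10, 0.02)
    # probability a non-large adenoma is advanced via high-grade/villous histology
    advanced_histology_p: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_centers < 1:
            raise ValueError("n_centers must be >= 1")
        if self.center_sd < 0:
            raise ValueError("center_sd must be >= 0")
        if not 0 <= self.sex_p_male <= 1:
            raise ValueError("sex_p_male must be a probability")
        for probs in (self.adenoma_size_probs, self.polyp_size_probs):
            if len(probs) != 3 or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("size-class probabilities must be three values summing to 1")
        if abs(sum(self.indication_probs.values()) - 1.0) > 1e-9:
            raise ValueError("indication probabilities must sum to 1")
        if self.polyp_dispersion < 0:
            raise ValueError("polyp_dispersion must be >= 0")


def adenoma_probability(
    spec: CohortGenSpec,
    ccmea,
    male: bool = False,
    indication: str = "health examination",
    center_effect: float = 0.0,
):
    """Generating adenoma probability for given CCMEA and covariates."""
    c = np.asarray(ccmea, dtype=float)
    lp = (
        spec.beta0
        + spec.beta_ccmea * (c - spec.half_point)
        + (spec.beta_sex if male else 0.0)
        + spec.beta_indication.get(indication, 0.0)
        + center_effect
    )
    return _sigmoid(lp)


def _nonadenoma_rate(spec: CohortGenSpec, ccmea: np.ndarray) -> np.ndarray:
    if spec.poisson_rate_fn is not None:
        return np.clip(np.asarray(spec.poisson_rate_fn(ccmea), dtype=float), 0.0, 50.0)
    return np.clip(spec.polyp_rate_base * np.exp(spec.polyp_rate_slope * ccmea), 0.0, 20.0)


def generate_cohort(spec: CohortGenSpec) -> pd.DataFrame:
    """Draw one synthetic cohort as a per-patient table.

    Columns: ``patient_id``, ``center``, ``sex``, ``indication``, ``ccmea``,
    ``p_adenoma`` (the generating probability, kept for calibration checks),
    ``adenoma`` (0/1), ``n_adenomas``, ``n_polyps``, per-size detection
    indicators ``det_adenoma_{diminutive,small,large}`` /
    ``det_polyp_{...}``, ``det_advanced``, ``det_polyp`` and
    ``max_polyp_size_class``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    center_idx = rng.integers(0, spec.n_centers, size=n)
    center_u = rng.normal(0.0, spec.center_sd, size=spec.n_centers) if spec.center_sd > 0 else np.zeros(spec.n_centers)
    scale_jitter = (
        np.exp(rng.normal(0.0, spec.ccmea_center_log_sd, size=spec.n_centers))
        if spec.ccmea_center_log_sd > 0
        else np.ones(spec.n_centers)
    )

    male = rng.random(n) < spec.sex_p_male
    ind_names = list(spec.indication_probs)
    ind_p = np.array([spec.indication_probs[k] for k in ind_names])
    indication = np.array(ind_names, dtype=object)[rng.choice(len(ind_names), size=n, p=ind_p)]

    ccmea = rng.gamma(spec.ccmea_gamma_shape, spec.ccmea_gamma_scale * scale_jitter[center_idx])

    ind_beta = np.array([spec.beta_indication.get(k, 0.0) for k in indication])
    lp = (
        spec.beta0
        + spec.beta_ccmea * (ccmea - spec.half_point)
        + spec.beta_sex * male
        + ind_beta
        + center_u[center_idx]
    )
    p = _sigmoid(lp)
    adenoma = rng.random(n) < p

    n_adenomas = np.where(
        adenoma,
        1
        + rng.poisson(
            np.clip(
                spec.adenoma_overcount_base * np.exp(spec.adenoma_overcount_slope * ccmea), 0, 5.0
            )
        ),
        0,
    )
    lam_np = _nonadenoma_rate(spec, ccmea)
    if spec.polyp_dispersion > 0:
        lam_np = lam_np * rng.gamma(spec.polyp_dispersion, 1.0 / spec.polyp_dispersion, size=n)
    n_nonadenoma = rng.poisson(lam_np)
    n_polyps = n_adenomas + n_nonadenoma

    # Per-lesion size classes, summarized as per-size detection indicators.
    det = {
        f"det_{kind}_{sz}": np.zeros(n, dtype=bool)
        for kind in ("adenoma", "polyp")
        for sz in _SIZE_CLASSES
    }
    det_advanced = np.zeros(n, dtype=bool)
    max_size_idx = np.full(n, -1)
    a_probs = np.asarray(spec.adenoma_size_probs)
    p_probs = np.asarray(spec.polyp_size_probs)
    for i in range(n):
        a_sizes = rng.choice(3, size=int(n_adenomas[i]), p=a_probs)
        np_sizes = rng.choice(3, size=int(n_nonadenoma[i]), p=p_probs)
        for s in a_sizes:
            det[f"det_adenoma_{_SIZE_CLASSES[s]}"][i] = True
            det[f"det_polyp_{_SIZE_CLASSES[s]}"][i] = True
            if s == 2 or rng.random() < spec.advanced_histology_p:
                det_advanced[i] = True
        for s in np_sizes:
            det[f"det_polyp_{_SIZE_CLASSES[s]}"][i] = True
        sizes = np.concatenate([a_sizes, np_sizes])
        if sizes.size:
            max_size_idx[i] = sizes.max()

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "center": [f"C{c + 1}" for c in center_idx],
            "sex": np.where(male, "male", "female"),
            "indication": indication,
            "ccmea": ccmea,
            "p_adenoma": p,
            "adenoma": adenoma.astype(int),
            "n_adenomas": n_adenomas.astype(int),
            "n_polyps": n_polyps.astype(int),
            "det_polyp": (n_polyps > 0).astype(int),
            "det_advanced": det_advanced.astype(int),
            "max_polyp_size_class": [
                "none" if k < 0 else _SIZE_CLASSES[k] for k in max_size_idx
            ],
        }
    )
    for name, col in det.items():
        df[name] = col.astype(int)
    return df


def generate_two_group_cohort(
    n_patients: int = 510,
    n_centers: int = 3,
    center_sd: float = 0.3,
    log_or: float = float(np.log(8)),
    log_irr: float = float(np.log(4)),
    baseline_logit: float = -1.8,  # unqualified-group ADR ~14%
    baseline_log_rate: float = float(np.log(1.3)),  # unqualified mean polyp count
    beta_sex: float = 0.3,
    p_group: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-group cohort with explicit group effects, for estimator recovery.

    The binary outcome follows a logit model with group log-odds ``log_or``
    and the count outcome a log-linear Poisson model with group log-rate
    ``log_irr``; both share a ``N(0, center_sd)`` center random intercept and
    a sex effect, mirroring the structure the mixed-model fitters assume.
    """
    rng = np.random.default_rng(seed)
    n = n_patients
    center_idx = rng.integers(0, n_centers, size=n)
    u_b = rng.normal(0.0, center_sd, size=n_centers) if center_sd > 0 else np.zeros(n_centers)
    u_p = rng.normal(0.0, center_sd, size=n_centers) if center_sd > 0 else np.zeros(n_centers)
    group = (rng.random(n) < p_group).astype(int)
    male = rng.random(n) < 0.47
    indication = np.array(["health examination", "diagnostic", "surveillance"], dtype=object)[
        rng.choice(3, size=n, p=[0.22, 0.62, 0.16])
    ]
    ind_beta = np.select(
        [indication == "diagnostic", indication == "surveillance"], [0.1, 0.2], 0.0
    )

    lp = baseline_logit + log_or * group + beta_sex * male + ind_beta + u_b[center_idx]
    y = (rng.random(n) < _sigmoid(lp)).astype(int)
    lam = np.exp(baseline_log_rate + log_irr * group + 0.1 * male + 0.5 * ind_beta + u_p[center_idx])
    count = rng.poisson(lam)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "center": [f"C{c + 1}" for c in center_idx],
            "sex": np.where(male, "male", "female"),
            "indication": indication,
            "group": group,
            "adenoma": y,
            "n_polyps": count,
        }
    )
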