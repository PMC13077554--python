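"""Bundled reference tables from the multicenter prospective validation study.

These are the *published aggregate* numbers (per-outcome event counts by
group, and the screening/exclusion flow); per-patient covariate data were
never released, which is why the mixed-model machinery is validated by
parameter recovery on synthetic cohorts instead of by reproducing the
study's adjusted ratios.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_prospective_outcomes", "load_exclusion_accounting"]


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("ccmea.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_prospective_outcomes() -> pd.DataFrame:
    """Outcome table of the prospective study: per-outcome event counts and
    group sizes (qualified n=270, unqualified n=240), plus group means/SDs
    for the two lesion-count outcomes."""
    return _read_csv("prospective_outcomes.csv")


def load_exclusion_accounting() -> tuple[int, dict[str, int]]:
    """Screening flow of the prospective study.

    Returns ``(n_screened, reasons)`` where ``reasons`` maps each exclusion
    reason to its patient count.
    """
    df = _read_csv("exclusion_accounting.csv")
    counts = dict(zip(df["item"], df["count"].astype(int)))
    screened = counts.pop("screened")
    return screened, counts
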