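"""Accessors for the packaged published association tables.

Raw cohort data are not deposited, so the joint analysis can only be rerun
from the printed per-study hazard ratios and confidence intervals. These
loaders return the per-study rows (input to published-table mode) and the
printed joint columns (used as expected values when checking the pooling).
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_burden_per_study", "load_burden_joint",
           "load_regions_per_study", "load_regions_joint"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("cnvsurv.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh, sep="\t")


def load_burden_per_study() -> pd.DataFrame:
    """Per-study CNV-burden HR/CI/P rows (two studies per burden metric)."""
    return _load("burden_per_study.tsv")


def load_burden_joint() -> pd.DataFrame:
    """Printed joint-analysis columns for the burden metrics."""
    return _load("burden_joint.tsv")


def load_regions_per_study() -> pd.DataFrame:
    """Per-study HR/CI/P rows for the 20 suggestive regions (NA = not testable)."""
    return _load("regions_per_study.tsv")


def load_regions_joint() -> pd.DataFrame:
    """Printed joint-analysis columns for the replicated regions."""
    return _load("regions_joint.tsv")
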