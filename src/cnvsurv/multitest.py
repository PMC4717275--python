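"""Significance thresholds and result flagging.

Bonferroni thresholds are alpha/m; rounding to significant digits is for
display only and never feeds back into flagging decisions. Result flags:
``significant`` (at or below the family threshold), ``suggestive`` (p <=
0.05, closed inequality), ``replicated_consistent`` (joint p <= 0.05 with
the same direction of effect in discovery and replication), and
``not_testable`` (replication carrier frequency below 1%, or replication
absent).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ThresholdPolicy", "bonferroni", "round_sig", "flag_results"]


def round_sig(x: float, sig_digits: int) -> float:
    """Round to ``sig_digits`` significant digits."""
    if sig_digits < 1:
        raise ValueError("sig_digits must be >= 1")
    if x == 0:
        return 0.0
    d = sig_digits - 1 - math.floor(math.log10(abs(x)))
    return round(x, d)


def bonferroni(alpha: float, m: int, sig_digits: int | None = None) -> float:
    """Bonferroni cutoff alpha/m, optionally rounded for reporting."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    t = alpha / m
    return round_sig(t, sig_digits) if sig_digits is not None else t


@dataclass(frozen=True)
class ThresholdPolicy:
    """A named testing family with its Bonferroni cutoff.

    ``threshold`` (exact alpha/m) drives decisions; ``display_threshold``
    is the rounded value for reports.
    """

    family: str
    alpha: float
    m: int
    sig_digits: int | None = None

    def __post_init__(self):
        bonferroni(self.alpha, self.m)  # validate

    @property
    def threshold(self) -> float:
        return bonferroni(self.alpha, self.m)

    @property
    def display_threshold(self) -> float:
        return bonferroni(self.alpha, self.m, self.sig_digits)


def flag_results(
    results: pd.DataFrame,
    policy: ThresholdPolicy,
    p_col: str = "p",
    suggestive_alpha: float = 0.05,
    joint_p_col: str | None = None,
    discovery_dir_col: str | None = None,
    replication_dir_col: str | None = None,
    replication_freq_col: str | None = None,
    min_replication_freq: float = 0.01,
) -> pd.DataFrame:
    """Annotate association results with significance flags.

    Replication-aware flags (``replicated_consistent``, ``not_testable``)
    are only produced when the joint p and per-study direction columns are
    supplied; requesting a joint p without directions is an error.
    """
    out = results.copy()
    p = out[p_col].to_numpy(float)
    out["significant"] = p <= policy.threshold
    out["suggestive"] = p <= suggestive_alpha
    if joint_p_col is not None:
        if discovery_dir_col is None or replication_dir_col is None:
            raise ValueError(
                "per-study direction columns are required for replication flagging"
            )
        jp = out[joint_p_col].to_numpy(float)
        d1 = out[discovery_dir_col].to_numpy(float)
        d2 = out[replication_dir_col].to_numpy(float)
        if replication_freq_col is not None:
            rf = out[replication_freq_col].to_numpy(float)
            not_testable = np.isnan(rf) | (rf < min_replication_freq)
        else:
            not_testable = np.isnan(d2)
        same_dir = np.sign(d1) == np.sign(d2)
        out["not_testable"] = not_testable
        out["replicated_consistent"] = (
            ~not_testable & ~np.isnan(jp) & (jp <= suggestive_alpha) & same_dir
        )
    return out
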