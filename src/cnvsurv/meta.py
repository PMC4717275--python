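"""Fixed-effect inverse-variance meta-analysis of hazard ratios.

Per-study log hazard ratios are pooled with weights 1/se^2. Standard errors
can be reconstructed from published 95% confidence intervals via the Wald
identity se = (ln U - ln L) / (2 * 1.959964), which makes CI round-trips
exact at the printed precision. The pooled p-value is a two-sided normal z
test. Heterogeneity statistics (Cochran's Q, I^2) are available behind a
flag but off by default.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Z95

__all__ = ["StudyEstimate", "MetaResult", "se_from_ci", "fixed_effect_meta",
           "pool_published"]


def _z_for_level(level: float) -> float:
    if level == 0.95:
        return Z95
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    return float(stats.norm.ppf(0.5 + level / 2.0))


def se_from_ci(hr: float, ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Standard error of log HR implied by a symmetric-on-log-scale CI."""
    if ci_low <= 0 or ci_high <= 0 or hr <= 0:
        raise ValueError("hr and CI bounds must be > 0")
    if not ci_low <= hr <= ci_high:
        raise ValueError("CI bounds must bracket the HR")
    if ci_high == ci_low:
        raise ValueError("zero-width confidence interval")
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * _z_for_level(level))


@dataclass(frozen=True)
class StudyEstimate:
    study_id: str
    log_hr: float
    se_log_hr: float

    def __post_init__(self):
        if not self.se_log_hr > 0:
            raise ValueError("se_log_hr must be > 0")

    @classmethod
    def from_ci(cls, study_id: str, hr: float, ci_low: float, ci_high: float,
                level: float = 0.95) -> "StudyEstimate":
        return cls(study_id=study_id, log_hr=math.log(hr),
                   se_log_hr=se_from_ci(hr, ci_low, ci_high, level))


@dataclass(frozen=True)
class MetaResult:
    log_hr: float
    se_log_hr: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    study_weights: tuple  # normalized, ordered as the input estimates
    q: float | None = None
    i2: float | None = None


def fixed_effect_meta(estimates, heterogeneity: bool = False) -> MetaResult:
    """Inverse-variance fixed-effect pooling of per-study log hazard ratios."""
    estimates = list(estimates)
    if not estimates:
        raise ValueError("at least one study estimate is required")
    b = np.array([e.log_hr for e in estimates])
    w = np.array([e.se_log_hr for e in estimates]) ** -2.0
    # canonical summation order -> results are bit-identical under input
    # permutation despite float non-associativity
    order = np.lexsort((b, w))
    wsum = float(w[order].sum())
    pooled = float(np.sum(w[order] * b[order]) / wsum)
    se = float(wsum ** -0.5)
    z = pooled / se
    q = i2 = None
    if heterogeneity:
        q = float(np.sum(w * (b - pooled) ** 2))
        dof = len(estimates) - 1
        i2 = float(max(0.0, (q - dof) / q)) if q > 0 else 0.0
    return MetaResult(
        log_hr=pooled, se_log_hr=se, hr=float(np.exp(pooled)),
        ci_low=float(np.exp(pooled - Z95 * se)),
        ci_high=float(np.exp(pooled + Z95 * se)),
        p=float(2.0 * stats.norm.sf(abs(z))),
        study_weights=tuple(w / wsum),
        q=q, i2=i2,
    )


def pool_published(
    table: pd.DataFrame,
    label_col: str = "label",
    study_col: str = "study",
    hr_col: str = "hr",
    ci_low_col: str = "ci_low",
    ci_high_col: str = "ci_high",
) -> pd.DataFrame:
    """Pool per-study HR/CI rows grouped by label (published-table mode).

    Rows with missing HR or CI (not-testable studies) are dropped before
    pooling; labels left with no rows are omitted. Returns one row per label
    with the pooled hr, ci_low, ci_high, p and the number of studies pooled.
    """
    rows = []
    for label, grp in table.groupby(label_col, sort=False):
        grp = grp.dropna(subset=[hr_col, ci_low_col, ci_high_col])
        if grp.empty:
            continue
        ests = [
            StudyEstimate.from_ci(str(r[study_col]), float(r[hr_col]),
                                  float(r[ci_low_col]), float(r[ci_high_col]))
            for _, r in grp.iterrows()
        ]
        m = fixed_effect_meta(ests)
        rows.append({
            label_col: label, "n_studies": len(ests), "hr": m.hr,
            "ci_low": m.ci_low, "ci_high": m.ci_high, "p": m.p,
            "log_hr": m.log_hr, "se_log_hr": m.se_log_hr,
        })
    return pd.DataFrame(rows)
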