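"""Per-sample quality metrics and exclusion rules.

A sample fails if its autosomal LRR standard deviation exceeds 0.30, if more
than 100 CNVs were called for it, or if the magnitude of its GC wave factor
exceeds 0.05. All comparisons are strict, so boundary values pass. The GC
wave factor is operationalized as the least-squares slope of LRR on the
standardized local GC track (users can substitute another definition by
filling QCMetrics themselves).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MarkerMap, SampleSignal

__all__ = ["QCMetrics", "QCThresholds", "QCDecision", "compute_qc_metrics",
           "apply_sample_qc", "qc_report"]


@dataclass(frozen=True)
class QCMetrics:
    sample_id: str
    lrr_sd: float
    n_cnvs_called: int
    gc_wave_factor: float  # NaN when undefined (constant GC track)

    def __post_init__(self):
        if self.lrr_sd < 0:
            raise ValueError("lrr_sd must be >= 0")
        if self.n_cnvs_called < 0:
            raise ValueError("n_cnvs_called must be >= 0")


@dataclass(frozen=True)
class QCThresholds:
    lrr_sd: float = 0.30
    max_cnvs: int = 100
    gcwf: float = 0.05


@dataclass(frozen=True)
class QCDecision:
    sample_id: str
    passed: bool
    reasons: tuple


def compute_qc_metrics(
    signal: SampleSignal, marker_map: MarkerMap, calls
) -> QCMetrics:
    """Metrics over all autosomal markers of one sample.

    ``calls`` is the sample's filtered call list (the CNV count is taken
    after the size/SNP filters; pass pre-filter candidates to count those
    instead).
    """
    if len(signal) != len(marker_map):
        raise ValueError("signal length does not match marker map")
    lrr = signal.lrr
    lrr_sd = float(np.std(lrr))
    gc = marker_map.gc
    gc_sd = float(np.std(gc))
    if gc_sd == 0.0:
        gcwf = math.nan  # undefined slope; sample will fail closed
    else:
        z = (gc - gc.mean()) / gc_sd
        gcwf = float(np.sum(z * (lrr - lrr.mean())) / np.sum(z * z))
    return QCMetrics(
        sample_id=signal.sample_id,
        lrr_sd=lrr_sd,
        n_cnvs_called=len(calls),
        gc_wave_factor=gcwf,
    )


def apply_sample_qc(
    metrics: QCMetrics, thresholds: QCThresholds = QCThresholds()
) -> QCDecision:
    """Pass/fail decision with every triggered reason, in rule order."""
    reasons = []
    vals = (metrics.lrr_sd, metrics.n_cnvs_called, metrics.gc_wave_factor)
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals):
        return QCDecision(metrics.sample_id, False, ("incomplete",))
    if metrics.lrr_sd > thresholds.lrr_sd:
        reasons.append(f"lrr_sd>{thresholds.lrr_sd}")
    if metrics.n_cnvs_called > thresholds.max_cnvs:
        reasons.append(f"n_cnvs>{thresholds.max_cnvs}")
    if abs(metrics.gc_wave_factor) > thresholds.gcwf:
        reasons.append(f"|gcwf|>{thresholds.gcwf}")
    return QCDecision(metrics.sample_id, not reasons, tuple(reasons))


def qc_report(
    metrics_list, thresholds: QCThresholds = QCThresholds()
) -> pd.DataFrame:
    """Tabular QC report: one row per sample with metrics, pass flag, reasons."""
    rows = []
    for m in metrics_list:
        d = apply_sample_qc(m, thresholds)
        rows.append({
            "sample_id": m.sample_id,
            "lrr_sd": m.lrr_sd,
            "n_cnvs_called": m.n_cnvs_called,
            "gc_wave_factor": m.gc_wave_factor,
            "pass": d.passed,
            "reasons": ";".join(d.reasons),
        })
    return pd.DataFrame(rows)
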