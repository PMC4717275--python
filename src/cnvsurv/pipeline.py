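"""End-to-end orchestration: simulate -> call -> QC -> regions/burden -> Cox -> flags.

A run is driven by a :class:`RunConfig` whose threshold defaults match the
analysis defaults used throughout the package (caller filters 3 SNPs / 1 kb,
QC cutoffs 0.30 / 100 / 0.05, 50% merge fraction, 1% frequency floor,
burden family alpha 0.05 over 8 tests). Each run writes every intermediate
table plus a manifest of row counts at every filter, and serializes the
config verbatim, so reruns with the same seed are byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .burden import compute_burden
from .cnvr import carrier_matrix, filter_regions, match_regions, merge_calls
from .hmm_caller import HMMParams, call_sample
from .meta import StudyEstimate, fixed_effect_meta, pool_published
from .multitest import ThresholdPolicy, bonferroni, flag_results
from .qc import QCThresholds, apply_sample_qc, compute_qc_metrics, qc_report
from .survival import fit_cox, test_regions
from .synthetic_data import (
    CohortConfig,
    simulate_cohort_truth,
    simulate_marker_map,
    simulate_signals,
    simulate_survival,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "run_discovery", "run_joint"]


class ConfigError(ValueError):
    """Invalid run configuration (raised before any compute)."""


@dataclass
class RunConfig:
    """Everything needed for one reproducible discovery-style run."""

    study_id: str = "SIM"
    seed: int = 0
    # simulation
    n_samples: int = 20
    n_markers: int = 2000
    chrom_lengths: dict = field(default_factory=lambda: {"1": 8_000_000, "2": 8_000_000})
    target_median_spacing: float = 2100.0
    n_planted_regions: int = 3
    planted_freq_range: tuple = (0.10, 0.30)
    planted_size_range_markers: tuple = (10, 30)
    lrr_sd: float = 0.12
    baf_sd: float = 0.03
    gc_wave_coef: float = 0.0
    # caller filters
    min_snps: int = 3
    min_length_bp: int = 1000
    # QC cutoffs
    qc_lrr_sd: float = 0.30
    qc_max_cnvs: int = 100
    qc_gcwf: float = 0.05
    # region construction
    merge_min_frac: float = 0.5
    min_freq: float = 0.01
    exclusion_bed: str | None = None
    # survival
    adjustments: tuple = ("sex", "entry_age", "birth_cohort")
    cluster: str | None = None
    planted_log_hrs: dict = field(default_factory=dict)
    gompertz_a: float = 2e-5
    gompertz_b: float = 0.10
    entry_age_mean: float = 96.9
    entry_age_sd: float = 1.5
    censor_date_offset: float = 13.0
    # multiple testing
    burden_alpha: float = 0.05
    burden_m: int = 8

    def validate(self) -> None:
        checks = [
            (self.n_samples > 0, "n_samples must be > 0"),
            (self.n_markers >= 2, "n_markers must be >= 2"),
            (self.target_median_spacing > 0, "target_median_spacing must be > 0"),
            (self.lrr_sd >= 0 and self.baf_sd >= 0, "noise sds must be >= 0"),
            (self.min_snps >= 1, "min_snps must be >= 1"),
            (self.min_length_bp >= 1, "min_length_bp must be >= 1"),
            (0 < self.merge_min_frac <= 1, "merge_min_frac must lie in (0, 1]"),
            (0 < self.min_freq <= 1, "min_freq must lie in (0, 1]"),
            (0 < self.burden_alpha < 1, "burden_alpha must lie in (0, 1)"),
            (self.burden_m >= 1, "burden_m must be >= 1"),
            (self.gompertz_a > 0 and self.gompertz_b > 0, "Gompertz parameters must be > 0"),
            (self.censor_date_offset > 0, "censor_date_offset must be > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["chrom_lengths"] = {str(k): int(v) for k, v in d["chrom_lengths"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("planted_freq_range", "planted_size_range_markers", "adjustments"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


_BURDEN_EXPOSURES = [
    (f"{cls}_{suffix}", f"{cls}_{label}")
    for cls in ("all", "deletion", "duplication")
    for suffix, label in (("n_per10", "n_per10"),
                          ("avg_per10kb", "avg_per10kb"),
                          ("total_per100kb", "total_per100kb"))
]


def run_discovery(config: RunConfig, outdir) -> dict:
    """Execute the full simulated discovery pipeline into ``outdir``.

    Returns the manifest (also written as ``manifest.json``): row counts at
    every stage and filter, so the records surviving each rule are auditable.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"study_id": config.study_id, "config_hash": config.config_hash()}

    # stage 1: marker map
    marker_map = simulate_marker_map(
        config.n_markers, config.chrom_lengths,
        config.target_median_spacing, seed=config.seed,
    )
    marker_map.to_tsv(out / "marker_map.tsv")
    manifest["n_markers"] = len(marker_map)

    # stage 2: cohort truth + signals
    sample_ids, truth, region_truth = simulate_cohort_truth(
        marker_map, config.n_samples, n_regions=config.n_planted_regions,
        freq_range=config.planted_freq_range,
        size_range_markers=config.planted_size_range_markers,
        seed=config.seed + 1,
    )
    region_truth.to_csv(out / "truth_regions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(t.sample_id, t.chrom, t.start_pos, t.end_pos, t.copy_number) for t in truth],
        columns=["sample_id", "chrom", "start_pos", "end_pos", "copy_number"],
    ).to_csv(out / "truth_cnvs.tsv", sep="\t", index=False)
    signals = simulate_signals(
        marker_map, truth, noise=(config.lrr_sd, config.baf_sd, config.gc_wave_coef),
        seed=config.seed + 2, sample_ids=sample_ids,
    )
    cio.write_signals(signals, marker_map, out / "signals.tsv")
    manifest["n_samples_simulated"] = len(sample_ids)

    # stage 3: CNV calling
    params = HMMParams()
    calls_by_sample = {
        sid: call_sample(signals[sid], marker_map, params,
                         min_snps=config.min_snps, min_length_bp=config.min_length_bp)
        for sid in sample_ids
    }
    all_calls = [c for sid in sample_ids for c in calls_by_sample[sid]]
    cio.write_calls_tsv(all_calls, out / "calls.tsv")
    cio.write_rawcnv(all_calls, out / "calls.rawcnv")
    manifest["n_calls"] = len(all_calls)

    # stage 4: sample QC
    thresholds = QCThresholds(config.qc_lrr_sd, config.qc_max_cnvs, config.qc_gcwf)
    metrics = [compute_qc_metrics(signals[sid], marker_map, calls_by_sample[sid])
               for sid in sample_ids]
    report = qc_report(metrics, thresholds)
    report.to_csv(out / "qc_report.tsv", sep="\t", index=False, float_format="%.6g")
    passing = [m.sample_id for m in metrics if apply_sample_qc(m, thresholds).passed]
    manifest["qc"] = {
        "input": len(sample_ids), "kept": len(passing),
        "dropped": len(sample_ids) - len(passing),
    }

    # stage 5: regions
    passing_calls = [c for c in all_calls if c.sample_id in set(passing)]
    regions = merge_calls(passing_calls, min_frac=config.merge_min_frac,
                          n_passing_samples=len(passing))
    exclusion = cio.read_bed(config.exclusion_bed) if config.exclusion_bed else []
    kept_regions = filter_regions(regions, exclusion, min_freq=config.min_freq)
    cio.write_regions_tsv(kept_regions, out / "regions.tsv")
    manifest["regions"] = {
        "input": len(regions), "kept": len(kept_regions),
        "dropped": len(regions) - len(kept_regions),
        "n_deletions": sum(r.cnv_type == "deletion" for r in kept_regions),
        "n_duplications": sum(r.cnv_type == "duplication" for r in kept_regions),
    }
    carriers = carrier_matrix(kept_regions, passing)
    carriers.to_csv(out / "carrier_matrix.tsv", sep="\t")

    # stage 6: burden
    burden = compute_burden(passing_calls, passing)
    burden.to_csv(out / "burden.tsv", sep="\t", float_format="%.8g")

    # stage 7: survival outcomes (planted effects on burden covariates)
    cohort = CohortConfig(
        n_samples=len(passing),
        entry_age_mean=config.entry_age_mean, entry_age_sd=config.entry_age_sd,
        gompertz_a=config.gompertz_a, gompertz_b=config.gompertz_b,
        log_hr_per_covariate=dict(config.planted_log_hrs),
        censor_date_offset=config.censor_date_offset,
        seed=config.seed + 3,
    )
    pheno = simulate_survival(cohort, burden_covariates=burden)
    pheno.to_csv(out / "phenotype.tsv", sep="\t", index=False, float_format="%.8g")
    manifest["n_events"] = int(pheno["event"].sum())

    # stage 8: burden and region associations
    data = pheno.merge(burden.reset_index(), on="sample_id")
    burden_rows = []
    for name, column in _BURDEN_EXPOSURES:
        try:
            res = fit_cox(data, column, adjustments=list(config.adjustments),
                          cluster=config.cluster)
        except ValueError as e:
            logger.warning("burden model %s skipped: %s", name, e)
            continue
        burden_rows.append({
            "exposure": name, "hr": res.hr, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "log_hr": res.log_hr,
            "se_log_hr": res.se_log_hr, "p": res.p,
            "n": res.n, "n_events": res.n_events,
        })
    burden_assoc = pd.DataFrame(burden_rows)
    burden_policy = ThresholdPolicy("burden", config.burden_alpha, config.burden_m,
                                    sig_digits=1)
    if not burden_assoc.empty:
        burden_assoc = flag_results(burden_assoc, burden_policy)
    burden_assoc.to_csv(out / "assoc_burden.tsv", sep="\t", index=False,
                        float_format="%.8g")

    region_assoc = test_regions(carriers, pheno,
                                adjustments=list(config.adjustments),
                                cluster=config.cluster)
    if not region_assoc.empty:
        region_policy = ThresholdPolicy("regionwise", 0.05, len(region_assoc),
                                        sig_digits=2)
        region_assoc = flag_results(region_assoc, region_policy)
        manifest["region_threshold"] = region_policy.threshold
    region_assoc.to_csv(out / "assoc_regions.tsv", sep="\t", index=False,
                        float_format="%.8g")
    manifest["n_burden_models"] = len(burden_assoc)
    manifest["n_region_models"] = len(region_assoc)
    manifest["burden_threshold"] = burden_policy.threshold

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def run_joint(discovery_dir, replication_dir, outdir,
              suggestive_alpha: float = 0.05, min_overlap_bp: int = 1,
              min_freq: float = 0.01) -> pd.DataFrame:
    """Joint analysis of two completed run bundles.

    Suggestive discovery regions are matched into the replication bundle
    (same type, >= ``min_overlap_bp`` overlap); matched pairs are pooled by
    fixed-effect meta-analysis, unmatched or sub-frequency regions are
    emitted as NA rows excluded from pooling.
    """
    ddir, rdir = Path(discovery_dir), Path(replication_dir)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    d_assoc = pd.read_csv(ddir / "assoc_regions.tsv", sep="\t")
    d_regions = {r.region_id: r for r in cio.read_regions_tsv(ddir / "regions.tsv")}
    r_regions = cio.read_regions_tsv(rdir / "regions.tsv")
    r_assoc = pd.read_csv(rdir / "assoc_regions.tsv", sep="\t").set_index("region_id")

    suggestive = d_assoc[d_assoc["p"] <= suggestive_alpha]
    matches = match_regions([d_regions[i] for i in suggestive["region_id"]],
                            r_regions, min_overlap_bp=min_overlap_bp)
    rows = []
    for _, drow in suggestive.iterrows():
        rid = drow["region_id"]
        row = {
            "region_id": rid,
            "discovery_hr": drow["hr"], "discovery_ci_low": drow["ci_low"],
            "discovery_ci_high": drow["ci_high"], "discovery_p": drow["p"],
            "discovery_freq": drow["frequency"],
        }
        hits = [h for h in matches[rid] if h.frequency >= min_freq
                and h.region_id in r_assoc.index]
        if hits:
            best = max(hits, key=lambda h: h.frequency)
            rrow = r_assoc.loc[best.region_id]
            ests = [
                StudyEstimate("discovery", float(drow["log_hr"]), float(drow["se_log_hr"])),
                StudyEstimate("replication", float(rrow["log_hr"]), float(rrow["se_log_hr"])),
            ]
            m = fixed_effect_meta(ests)
            row.update({
                "replication_region_id": best.region_id,
                "replication_hr": rrow["hr"], "replication_ci_low": rrow["ci_low"],
                "replication_ci_high": rrow["ci_high"], "replication_p": rrow["p"],
                "replication_freq": best.frequency,
                "joint_hr": m.hr, "joint_ci_low": m.ci_low,
                "joint_ci_high": m.ci_high, "joint_p": m.p,
                "log_hr_discovery": drow["log_hr"], "log_hr_replication": rrow["log_hr"],
            })
        else:
            row.update({k: np.nan for k in (
                "replication_hr", "replication_ci_low", "replication_ci_high",
                "replication_p", "replication_freq", "joint_hr", "joint_ci_low",
                "joint_ci_high", "joint_p", "log_hr_discovery", "log_hr_replication")})
            row["log_hr_discovery"] = drow["log_hr"]
        rows.append(row)
    joint = pd.DataFrame(rows)
    if not joint.empty:
        policy = ThresholdPolicy("regionwise", 0.05, max(len(d_assoc), 1), sig_digits=2)
        joint = flag_results(
            joint, policy, p_col="discovery_p", joint_p_col="joint_p",
            discovery_dir_col="log_hr_discovery",
            replication_dir_col="log_hr_replication",
            replication_freq_col="replication_freq", min_replication_freq=min_freq,
        )
    joint.to_csv(out / "joint_regions.tsv", sep="\t", index=False, float_format="%.8g")
    return joint
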