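"""Synthetic cohort generator.

Produces marker maps emulating a dense SNP array (~2.1 kb median spacing),
per-sample LRR/BAF signal tracks with implanted copy-number segments, and
left-truncated proportional-hazards survival outcomes with known planted
effect sizes. Every downstream stage of the pipeline is testable against the
ground truth produced here.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    LRR_MEANS,
    MarkerMap,
    SampleSignal,
    normalize_chrom,
    chrom_sort_key,
)

__all__ = [
    "TruthCNV",
    "CohortConfig",
    "simulate_marker_map",
    "simulate_signals",
    "simulate_cohort_truth",
    "simulate_survival",
]


@dataclass(frozen=True)
class TruthCNV:
    """Simulation ground truth: one implanted CNV in one sample."""

    sample_id: str
    chrom: str
    start_pos: int
    end_pos: int
    copy_number: int

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start_pos > self.end_pos:
            raise ValueError("start_pos must be <= end_pos")
        if self.copy_number not in (0, 1, 3, 4):
            raise ValueError("copy_number must be in {0, 1, 3, 4}")


@dataclass
class CohortConfig:
    """Knobs for the survival and signal generators.

    The hazard is Gompertz, h(t) = a * exp(b * t) * exp(beta' x), on the age
    timescale; individuals enter the risk set at their baseline age (left
    truncation) and are administratively censored ``censor_date_offset``
    years after entry.
    """

    n_samples: int
    sex_fraction_female: float = 0.75
    entry_age_mean: float = 96.9
    entry_age_sd: float = 1.5
    gompertz_a: float = 2e-5
    gompertz_b: float = 0.10
    log_hr_per_covariate: dict = field(default_factory=dict)
    censor_date_offset: float = 13.0
    lrr_sd: float = 0.15
    baf_sd: float = 0.03
    gc_wave_coef: float = 0.0
    baseline_year: int = 2001
    family_size: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be > 0")
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise ValueError("sex_fraction_female must lie in [0, 1]")
        if self.gompertz_a <= 0 or self.gompertz_b <= 0:
            raise ValueError("gompertz_a and gompertz_b must be > 0")
        if self.censor_date_offset <= 0:
            raise ValueError("censor_date_offset must be > 0")
        if self.lrr_sd < 0 or self.baf_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.family_size < 1:
            raise ValueError("family_size must be >= 1")


def simulate_marker_map(
    n_markers: int,
    chrom_lengths: dict,
    target_median_spacing: float = 2100.0,
    seed: int = 0,
) -> MarkerMap:
    """Simulate an ordered marker map with exponential inter-marker gaps.

    Markers are allocated to chromosomes proportionally to length. Gaps are
    exponential with median equal to ``target_median_spacing``; PFB is a
    mixture of near-monomorphic (near 0 / near 1) and uniform components and
    the GC track is a smooth sinusoidal process inside [0.3, 0.7].
    """
    if target_median_spacing <= 0:
        raise ValueError("target_median_spacing must be > 0")
    if not chrom_lengths:
        raise ValueError("chrom_lengths must not be empty")
    chroms = sorted((normalize_chrom(c) for c in chrom_lengths), key=chrom_sort_key)
    lengths = {normalize_chrom(c): int(l) for c, l in chrom_lengths.items()}
    total = sum(lengths.values())
    alloc = {c: max(2, int(round(n_markers * lengths[c] / total))) for c in chroms}
    if n_markers < 2 * len(chroms):
        raise ValueError("need at least 2 markers per requested chromosome")

    rng = np.random.default_rng(seed)
    scale = target_median_spacing / math.log(2.0)
    frames = []
    for c in chroms:
        n = alloc[c]
        gaps = np.maximum(1, np.round(rng.exponential(scale, size=n)).astype(np.int64))
        pos = np.cumsum(gaps)
        if pos[-1] > lengths[c]:
            raise ValueError(
                f"chromosome {c}: {n} markers at ~{target_median_spacing} bp spacing "
                f"do not fit in length {lengths[c]}"
            )
        u = rng.random(n)
        pfb = rng.uniform(0.0, 1.0, size=n)
        pfb[u < 0.10] = rng.uniform(0.0, 0.005, size=int((u < 0.10).sum()))
        pfb[u > 0.90] = rng.uniform(0.995, 1.0, size=int((u > 0.90).sum()))
        # smooth GC: two long-wavelength sinusoids, range within [0.3, 0.7]
        p1 = rng.uniform(1e6, 5e6)
        p2 = rng.uniform(2e5, 1e6)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        gc = 0.5 + 0.12 * np.sin(2 * np.pi * pos / p1 + ph1) \
                 + 0.07 * np.sin(2 * np.pi * pos / p2 + ph2)
        gc = np.clip(gc, 0.3, 0.7)
        frames.append(pd.DataFrame({
            "marker_id": [f"m{c}_{i:06d}" for i in range(n)],
            "chrom": c,
            "pos": pos,
            "pfb": pfb,
            "gc": gc,
        }))
    return MarkerMap(pd.concat(frames, ignore_index=True))


def _copy_number_track(marker_map: MarkerMap, cnvs: list[TruthCNV]) -> np.ndarray:
    cn = np.full(len(marker_map), 2, dtype=np.int64)
    chrom = marker_map.chrom
    pos = marker_map.pos
    for t in cnvs:
        if t.chrom not in marker_map.chromosomes:
            raise ValueError(f"truth CNV on chromosome {t.chrom!r} absent from marker map")
        mask = (chrom == t.chrom) & (pos >= t.start_pos) & (pos <= t.end_pos)
        if not mask.any():
            raise ValueError(
                f"truth CNV {t.chrom}:{t.start_pos}-{t.end_pos} spans no marker"
            )
        cn[mask] = t.copy_number
    return cn


def simulate_signals(
    marker_map: MarkerMap,
    truth: list[TruthCNV],
    noise: tuple[float, float, float] = (0.15, 0.03, 0.0),
    seed: int = 0,
    sample_ids: list[str] | None = None,
    emission_means: tuple = LRR_MEANS,
) -> dict[str, SampleSignal]:
    """Simulate LRR/BAF tracks for each sample with implanted CNVs.

    ``noise`` is ``(lrr_sd, baf_sd, gc_wave_coef)``. LRR is the state
    emission mean plus ``gc_wave_coef`` times the standardized local GC plus
    Gaussian noise. BAF is generated by drawing the B-allele count from a
    binomial at the marker PFB (Hardy-Weinberg) at the local copy number and
    adding truncated Gaussian noise inside [0, 1]; copy-number-0 markers emit
    uniform noise.
    """
    lrr_sd, baf_sd, gc_wave_coef = noise
    if lrr_sd < 0 or baf_sd < 0:
        raise ValueError("noise standard deviations must be >= 0")
    by_sample: dict[str, list[TruthCNV]] = {}
    for t in truth:
        by_sample.setdefault(t.sample_id, []).append(t)
    if sample_ids is None:
        sample_ids = sorted(by_sample)
    means = np.asarray(emission_means, float)

    gc = marker_map.gc
    gc_sd = gc.std()
    zgc = (gc - gc.mean()) / gc_sd if gc_sd > 0 else np.zeros_like(gc)
    pfb = marker_map.pfb

    children = np.random.SeedSequence(seed).spawn(len(sample_ids))
    out: dict[str, SampleSignal] = {}
    for sid, child in zip(sample_ids, children):
        rng = np.random.default_rng(child)
        cn = _copy_number_track(marker_map, by_sample.get(sid, []))
        lrr = means[cn] + gc_wave_coef * zgc
        if lrr_sd > 0:
            lrr = lrr + rng.normal(0.0, lrr_sd, size=cn.size)
        baf0 = np.empty(cn.size)
        zero = cn == 0
        baf0[zero] = rng.uniform(0.0, 1.0, size=int(zero.sum()))
        for c in np.unique(cn[~zero]):
            m = cn == c
            b = rng.binomial(int(c), pfb[m])
            baf0[m] = b / float(c)
        if baf_sd > 0:
            nz = ~zero
            lo = (0.0 - baf0[nz]) / baf_sd
            hi = (1.0 - baf0[nz]) / baf_sd
            baf0[nz] = stats.truncnorm.rvs(
                lo, hi, loc=baf0[nz], scale=baf_sd, random_state=rng
            )
        out[sid] = SampleSignal(sample_id=sid, lrr=lrr, baf=np.clip(baf0, 0.0, 1.0))
    return out


def simulate_cohort_truth(
    marker_map: MarkerMap,
    n_samples: int,
    n_regions: int = 3,
    freq_range: tuple[float, float] = (0.05, 0.20),
    size_range_markers: tuple[int, int] = (10, 30),
    copy_numbers: tuple[int, ...] = (1, 3),
    seed: int = 0,
) -> tuple[list[str], list[TruthCNV], pd.DataFrame]:
    """Plant shared CNV regions across a cohort.

    Returns sample ids, the flat list of per-sample truth CNVs, and a table
    describing each planted region (span, copy number, carrier count).
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    chrom = marker_map.chrom
    pos = marker_map.pos
    taken: list[tuple[str, int, int]] = []
    truth: list[TruthCNV] = []
    rows = []
    for r in range(n_regions):
        for _ in range(200):
            c = marker_map.chromosomes[rng.integers(len(marker_map.chromosomes))]
            sl = marker_map.chrom_slice(c)
            n_block = sl.stop - sl.start
            n_mk = int(rng.integers(size_range_markers[0], size_range_markers[1] + 1))
            if n_mk >= n_block:
                continue
            i0 = sl.start + int(rng.integers(0, n_block - n_mk))
            start, end = int(pos[i0]), int(pos[i0 + n_mk - 1])
            if all(not (c == tc and start <= te and end >= ts) for tc, ts, te in taken):
                break
        else:  # pragma: no cover - pathological map
            raise RuntimeError("could not place a non-overlapping region")
        taken.append((c, start, end))
        freq = rng.uniform(*freq_range)
        n_carriers = max(1, int(round(freq * n_samples)))
        carriers = rng.choice(sample_ids, size=n_carriers, replace=False)
        cn = int(copy_numbers[rng.integers(len(copy_numbers))])
        for s in sorted(carriers):
            truth.append(TruthCNV(s, c, start, end, cn))
        rows.append({
            "region_id": f"planted_{r + 1}", "chrom": c, "start_pos": start,
            "end_pos": end, "copy_number": cn, "n_markers": n_mk,
            "n_carriers": n_carriers,
        })
    return sample_ids, truth, pd.DataFrame(rows)


def _gompertz_death_age(rng, entry, a, b, eta):
    """Death age conditional on survival to `entry` under Gompertz PH."""
    e1 = np.random.default_rng() if rng is None else rng
    E = e1.exponential(1.0, size=np.shape(entry))
    return np.log(np.exp(b * entry) + b * E / (a * np.exp(eta))) / b


def simulate_survival(
    config: CohortConfig,
    burden_covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw left-truncated survival outcomes with planted hazard ratios.

    ``burden_covariates`` (indexed by sample id, or carrying a ``sample_id``
    column) supplies per-sample covariate values; keys of
    ``config.log_hr_per_covariate`` must each match a covariate column or the
    built-in ``sex_female`` indicator. Returns a phenotype table with columns
    sample_id, sex, entry_age, exit_age, event, birth_cohort, family_id.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    if burden_covariates is not None:
        cov = burden_covariates.copy()
        if "sample_id" in cov.columns:
            cov = cov.set_index("sample_id")
        sample_ids = [str(s) for s in cov.index]
        if len(sample_ids) != n:
            raise ValueError("burden_covariates rows must match n_samples")
    else:
        cov = None
        sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]

    female = rng.random(n) < config.sex_fraction_female
    entry = rng.normal(config.entry_age_mean, config.entry_age_sd, size=n)
    entry = np.maximum(entry, 60.0)

    eta = np.zeros(n)
    for name, beta in config.log_hr_per_covariate.items():
        if name == "sex_female":
            x = female.astype(float)
        elif cov is not None and name in cov.columns:
            x = cov[name].to_numpy(float)
            if np.any(~np.isfinite(x)):
                raise ValueError(f"covariate {name!r} has non-finite values")
        else:
            raise ValueError(f"planted covariate {name!r} not available")
        eta += beta * x

    death = _gompertz_death_age(rng, entry, config.gompertz_a, config.gompertz_b, eta)
    censor = entry + config.censor_date_offset
    event = (death <= censor).astype(int)
    exit_age = np.minimum(death, censor)

    birth_year = np.round(config.baseline_year - entry).astype(int)
    cohort = [f"{(y // 10) * 10}s" for y in birth_year]
    fam = [f"F{(i // config.family_size) + 1:04d}" for i in range(n)]

    return pd.DataFrame({
        "sample_id": sample_ids,
        "sex": np.where(female, "F", "M"),
        "entry_age": entry,
        "exit_age": exit_age,
        "event": event,
        "birth_cohort": cohort,
        "family_id": fam,
    })
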