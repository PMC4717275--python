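"""Copy-number HMM: emissions, distance-modulated Viterbi decoding, call extraction.

Five hidden states correspond directly to copy numbers 0-4 (no separate
LOH state; only states 0/1/3/4 are used downstream). Emissions combine a
Gaussian LRR density with a BAF mixture whose component locations are the
allelic ratios attainable at the state's copy number, weighted by
Hardy-Weinberg genotype probabilities at the marker's PFB. Transitions decay
toward a near-diagonal base matrix with the inter-marker distance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import CNVCall, LRR_MEANS, MarkerMap, SampleSignal

__all__ = [
    "HMMParams",
    "emission_loglik",
    "emission_matrix",
    "transition_matrix",
    "viterbi_decode",
    "extract_calls",
    "call_sample",
    "compute_pfb",
]

N_STATES = 5
_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class HMMParams:
    """Emission and transition parameters for the 5-state copy-number HMM."""

    lrr_means: tuple = LRR_MEANS
    lrr_sds: tuple = (0.30, 0.25, 0.20, 0.22, 0.24)
    baf_noise_sd: float = 0.04
    transition_offdiag: float = 1e-4
    distance_scale: float = 100_000.0  # bp constant D

    def __post_init__(self):
        if len(self.lrr_means) != N_STATES or len(self.lrr_sds) != N_STATES:
            raise ValueError("lrr_means and lrr_sds must have 5 entries")
        if any(s <= 0 for s in self.lrr_sds) or self.baf_noise_sd <= 0:
            raise ValueError("standard deviations must be > 0")
        if not 0 < self.transition_offdiag < 1 / (N_STATES - 1):
            raise ValueError("transition_offdiag out of range")
        if self.distance_scale <= 0:
            raise ValueError("distance_scale must be > 0")

    @property
    def base_matrix(self) -> np.ndarray:
        off = self.transition_offdiag
        A = np.full((N_STATES, N_STATES), off)
        np.fill_diagonal(A, 1.0 - (N_STATES - 1) * off)
        return A


def _baf_density(baf, pfb, state: int, sd: float):
    """BAF mixture density; broadcasts over numpy arrays.

    State 0 has no allelic signal and emits uniform noise on [0, 1]. For
    copy number c >= 1 the mixture has components at b/c (b = 0..c) with
    binomial Hardy-Weinberg weights, each a [0, 1]-truncated Gaussian.
    """
    baf = np.asarray(baf, float)
    pfb = np.asarray(pfb, float)
    if state == 0:
        return np.ones(np.broadcast(baf, pfb).shape)
    c = state
    dens = np.zeros(np.broadcast(baf, pfb).shape)
    for b in range(c + 1):
        w = stats.binom.pmf(b, c, pfb)
        loc = b / c
        comp = stats.truncnorm.pdf(
            baf, (0.0 - loc) / sd, (1.0 - loc) / sd, loc=loc, scale=sd
        )
        dens = dens + w * comp
    return dens


def emission_loglik(lrr_value, baf_value, pfb, state: int, params: HMMParams) -> float:
    """Log emission density of one marker observation under one state."""
    if state not in range(N_STATES):
        raise ValueError(f"state must be in 0..4, got {state}")
    if not (np.isfinite(lrr_value) and np.isfinite(baf_value) and np.isfinite(pfb)):
        raise ValueError("non-finite input")
    if not 0.0 <= pfb <= 1.0:
        raise ValueError("pfb must lie in [0, 1]")
    ll_lrr = stats.norm.logpdf(lrr_value, params.lrr_means[state], params.lrr_sds[state])
    dens = _baf_density(baf_value, pfb, state, params.baf_noise_sd)
    return float(ll_lrr + np.log(np.maximum(dens, _LOG_FLOOR)))


def emission_matrix(
    signal: SampleSignal, marker_map: MarkerMap, params: HMMParams
) -> np.ndarray:
    """(n_markers, 5) log emission densities for one sample."""
    if len(signal) != len(marker_map):
        raise ValueError("signal length does not match marker map")
    lrr, baf, pfb = signal.lrr, signal.baf, marker_map.pfb
    out = np.empty((len(marker_map), N_STATES))
    for s in range(N_STATES):
        ll_lrr = stats.norm.logpdf(lrr, params.lrr_means[s], params.lrr_sds[s])
        dens = _baf_density(baf, pfb, s, params.baf_noise_sd)
        out[:, s] = ll_lrr + np.log(np.maximum(dens, _LOG_FLOOR))
    return out


def transition_matrix(distance_bp: float, params: HMMParams) -> np.ndarray:
    """Distance-modulated transitions: A(d) = w*I + (1-w)*A_base, w = exp(-d/D).

    Rows sum to 1 at every distance; adjacent markers barely transition,
    distant markers approach the base matrix.
    """
    w = np.exp(-float(distance_bp) / params.distance_scale)
    return w * np.eye(N_STATES) + (1.0 - w) * params.base_matrix


def _viterbi_chrom(emis: np.ndarray, pos: np.ndarray, params: HMMParams) -> np.ndarray:
    n = emis.shape[0]
    delta = np.log(1.0 / N_STATES) + emis[0]
    back = np.zeros((n, N_STATES), dtype=np.int64)
    for i in range(1, n):
        logA = np.log(transition_matrix(pos[i] - pos[i - 1], params))
        scores = delta[:, None] + logA  # (from, to)
        # np.argmax returns the first (lowest copy number) maximizer
        back[i] = np.argmax(scores, axis=0)
        delta = scores[back[i], np.arange(N_STATES)] + emis[i]
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def viterbi_decode(
    signal: SampleSignal, marker_map: MarkerMap, params: HMMParams | None = None
) -> np.ndarray:
    """Most likely per-marker state path, decoded per chromosome.

    Ties are broken toward the lower copy number. Chromosomes are decoded
    independently, so the result does not depend on their block order.
    """
    params = params or HMMParams()
    if len(signal) != len(marker_map):
        raise ValueError("signal length does not match marker map")
    emis = emission_matrix(signal, marker_map, params)
    pos = marker_map.pos
    path = np.empty(len(marker_map), dtype=np.int64)
    for chrom, sl in marker_map.iter_chrom_slices():
        if sl.stop - sl.start < 2:
            raise ValueError(f"chromosome {chrom} has < 2 markers")
        path[sl] = _viterbi_chrom(emis[sl], pos[sl], params)
    return path


def extract_calls(
    path: np.ndarray,
    marker_map: MarkerMap,
    sample_id: str,
    min_snps: int = 3,
    min_length_bp: int = 1000,
) -> list[CNVCall]:
    """Turn a decoded state path into filtered CNV calls.

    Maximal runs of a constant non-diploid state become candidates;
    candidates with fewer than ``min_snps`` markers or shorter than
    ``min_length_bp`` (outermost marker positions, inclusive) are dropped.
    """
    path = np.asarray(path)
    if path.shape[0] != len(marker_map):
        raise ValueError("path length does not match marker map")
    pos = marker_map.pos
    calls: list[CNVCall] = []
    for chrom, sl in marker_map.iter_chrom_slices():
        sub = path[sl]
        i = 0
        n = sub.shape[0]
        while i < n:
            s = int(sub[i])
            j = i
            while j + 1 < n and sub[j + 1] == s:
                j += 1
            if s != 2:
                start = int(pos[sl.start + i])
                end = int(pos[sl.start + j])
                n_snps = j - i + 1
                if n_snps >= min_snps and end - start + 1 >= min_length_bp:
                    calls.append(CNVCall(
                        sample_id=sample_id, chrom=chrom,
                        start_pos=start, end_pos=end, state=s, n_snps=n_snps,
                    ))
            i = j + 1
    return calls


def call_sample(
    signal: SampleSignal,
    marker_map: MarkerMap,
    params: HMMParams | None = None,
    min_snps: int = 3,
    min_length_bp: int = 1000,
) -> list[CNVCall]:
    """Decode one sample and extract its filtered CNV calls."""
    path = viterbi_decode(signal, marker_map, params)
    return extract_calls(path, marker_map, signal.sample_id, min_snps, min_length_bp)


def compute_pfb(signals, marker_map: MarkerMap) -> np.ndarray:
    """Per-marker median BAF across samples (PFB compiled from a cohort)."""
    mat = np.stack([s.baf for s in signals])
    if mat.shape[1] != len(marker_map):
        raise ValueError("signal length does not match marker map")
    return np.median(mat, axis=0)
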