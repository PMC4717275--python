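"""Cross-sample CNV region construction.

Calls of the same type (deletion: states 0/1; duplication: states 3/4) on
the same chromosome are merged when they overlap by at least 50% of the
shorter call; merging takes the transitive closure of that pairwise
relation, so the result does not depend on input order. Region boundaries
are the outermost boundaries of the merged component. Regions hitting
exclusion intervals (centromeres/telomeres) or with carrier frequency below
1% are then dropped.
"""
from __future__ import annotations

import pandas as pd

from .core import CNVRegion, chrom_sort_key, normalize_chrom

__all__ = [
    "overlap_fraction_shorter",
    "merge_calls",
    "filter_regions",
    "carrier_matrix",
    "match_regions",
]


def _overlap_bp(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def overlap_fraction_shorter(a, b) -> float:
    """Overlap length divided by the length of the shorter interval.

    ``a`` and ``b`` need ``chrom``, ``start_pos`` and ``end_pos`` attributes
    (calls or regions). Intervals on different chromosomes overlap by 0 by
    contract.
    """
    if normalize_chrom(a.chrom) != normalize_chrom(b.chrom):
        return 0.0
    ov = _overlap_bp(a.start_pos, a.end_pos, b.start_pos, b.end_pos)
    shorter = min(a.end_pos - a.start_pos + 1, b.end_pos - b.start_pos + 1)
    return ov / shorter


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_calls(calls, min_frac: float = 0.5, n_passing_samples: int | None = None):
    """Merge same-type overlapping calls into :class:`CNVRegion` objects.

    Within each (chromosome, type) group, regions are the connected
    components of the graph joining call pairs whose overlap is at least
    ``min_frac`` of the shorter call. Carrier counts are distinct samples; a
    sample contributing both state-0 and state-1 calls to one deletion
    region counts once. Frequencies use ``n_passing_samples`` as the
    denominator (defaults to the number of distinct samples in ``calls``).
    """
    calls = list(calls)
    if not 0.0 < min_frac <= 1.0:
        raise ValueError("min_frac must lie in (0, 1]")
    if n_passing_samples is None:
        n_passing_samples = len({c.sample_id for c in calls})
    if calls and n_passing_samples <= 0:
        raise ValueError("n_passing_samples must be > 0")

    groups: dict[tuple[str, str], list] = {}
    for c in calls:
        groups.setdefault((c.chrom, c.cnv_type), []).append(c)

    regions = []
    for (chrom, cnv_type), group in groups.items():
        # sorting makes component membership independent of input order
        group = sorted(group, key=lambda c: (c.start_pos, c.end_pos, c.sample_id, c.state))
        uf = _UnionFind(len(group))
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if group[j].start_pos > group[i].end_pos:
                    break  # sorted by start: no later call overlaps i
                if overlap_fraction_shorter(group[i], group[j]) >= min_frac:
                    uf.union(i, j)
        comps: dict[int, list] = {}
        for i in range(len(group)):
            comps.setdefault(uf.find(i), []).append(group[i])
        for comp in comps.values():
            start = min(c.start_pos for c in comp)
            end = max(c.end_pos for c in comp)
            carriers = frozenset(c.sample_id for c in comp)
            regions.append(CNVRegion(
                region_id="",  # assigned below after global ordering
                chrom=chrom, start_pos=start, end_pos=end, cnv_type=cnv_type,
                carriers=carriers,
                frequency=len(carriers) / n_passing_samples,
            ))

    regions.sort(key=lambda r: (chrom_sort_key(r.chrom), r.start_pos, r.end_pos, r.cnv_type))
    out = []
    for i, r in enumerate(regions, start=1):
        tag = "DEL" if r.cnv_type == "deletion" else "DUP"
        out.append(CNVRegion(
            region_id=f"{tag}_chr{r.chrom}_{r.start_pos}_{r.end_pos}",
            chrom=r.chrom, start_pos=r.start_pos, end_pos=r.end_pos,
            cnv_type=r.cnv_type, carriers=r.carriers, frequency=r.frequency,
        ))
    return out


def filter_regions(regions, exclusion_intervals=(), min_freq: float = 0.01):
    """Drop regions touching an exclusion interval or below the frequency floor.

    ``exclusion_intervals`` are (chrom, start, end) triples in 1-based
    inclusive coordinates (see :func:`cnvsurv.io.read_bed` for BED input);
    one shared base pair suffices for exclusion. The frequency rule drops
    regions with frequency strictly below ``min_freq``.
    """
    if not 0.0 < min_freq <= 1.0:
        raise ValueError("min_freq must lie in (0, 1]")
    excl = [(normalize_chrom(c), int(s), int(e)) for c, s, e in exclusion_intervals]
    kept = []
    for r in regions:
        hit = any(
            c == r.chrom and _overlap_bp(r.start_pos, r.end_pos, s, e) >= 1
            for c, s, e in excl
        )
        if hit or r.frequency < min_freq:
            continue
        kept.append(r)
    return kept


def carrier_matrix(regions, samples) -> pd.DataFrame:
    """Binary samples x regions carrier matrix.

    Every carrier must appear in ``samples`` (the QC-passing set); unknown
    carriers raise with the offending ids listed.
    """
    samples = [str(s) for s in samples]
    sset = set(samples)
    unknown = sorted({s for r in regions for s in r.carriers} - sset)
    if unknown:
        raise ValueError(f"carriers absent from sample list: {unknown}")
    mat = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"),
                       columns=[r.region_id for r in regions], dtype=int)
    for r in regions:
        mat.loc[sorted(r.carriers), r.region_id] = 1
    return mat


def match_regions(discovery, replication, min_overlap_bp: int = 1):
    """Match discovery regions into a replication region set.

    A replication region counts as "the same" CNV when it has the same type
    and overlaps the discovery region by at least ``min_overlap_bp`` bases.
    Returns ``{discovery_region_id: [replication regions...]}`` with
    unmatched regions mapping to an empty list.
    """
    out = {}
    for d in discovery:
        hits = [
            r for r in replication
            if r.cnv_type == d.cnv_type and r.chrom == d.chrom
            and _overlap_bp(d.start_pos, d.end_pos, r.start_pos, r.end_pos) >= min_overlap_bp
        ]
        out[d.region_id] = hits
    return out
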