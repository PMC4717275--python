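"""Shared domain types and constants.

Coordinates are 1-based and inclusive throughout the package (BED input is
converted on read). Chromosome labels are plain autosome strings (``"1"`` ..
``"22"``); a leading ``chr`` prefix is stripped on input and re-added by
writers that mimic external formats.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: z quantile backing every 95% Wald interval. 1.959964 (not 1.96) so that
#: CI -> SE -> CI round-trips are exact to the printed precision.
Z95 = 1.959964

#: Default LRR emission means by copy number.
LRR_MEANS = (-3.5, -0.66, 0.0, 0.40, 0.68)

DELETION_STATES = (0, 1)
DUPLICATION_STATES = (3, 4)
CNV_STATES = DELETION_STATES + DUPLICATION_STATES


def normalize_chrom(chrom) -> str:
    """Return the canonical chromosome label (``"chr7"`` -> ``"7"``)."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


def chrom_sort_key(chrom: str):
    """Natural ordering: numeric autosomes first, other labels after."""
    c = normalize_chrom(chrom)
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


def state_to_type(state: int) -> str:
    if state in DELETION_STATES:
        return "deletion"
    if state in DUPLICATION_STATES:
        return "duplication"
    raise ValueError(f"state {state} is not a CNV state (copy number 2 is normal)")


MARKER_COLUMNS = ("marker_id", "chrom", "pos", "pfb", "gc")


@dataclass(frozen=True)
class MarkerMap:
    """Ordered genomic markers with PFB and GC covariates.

    The backing table has columns ``marker_id, chrom, pos, pfb, gc`` with
    positions strictly increasing within each chromosome and chromosomes
    stored as contiguous blocks.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        missing = [c for c in MARKER_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"marker map missing columns: {missing}")
        t = t.reset_index(drop=True)
        t["chrom"] = t["chrom"].map(normalize_chrom)
        if t["marker_id"].duplicated().any():
            dups = t.loc[t["marker_id"].duplicated(), "marker_id"].head().tolist()
            raise ValueError(f"duplicate marker_id values, e.g. {dups}")
        for col in ("pfb", "gc"):
            v = t[col].to_numpy(float)
            if np.any(~np.isfinite(v)) or v.min() < 0 or v.max() > 1:
                raise ValueError(f"{col} values must be finite and within [0, 1]")
        # contiguous chromosome blocks, strictly increasing positions inside
        chroms = t["chrom"].to_numpy()
        seen: dict[str, int] = {}
        for i, c in enumerate(chroms):
            if c in seen and chroms[i - 1] != c:
                raise ValueError(f"chromosome {c} is not a contiguous block")
            seen.setdefault(c, i)
        pos = t["pos"].to_numpy(np.int64)
        same = chroms[1:] == chroms[:-1]
        if np.any(pos[1:][same] <= pos[:-1][same]):
            raise ValueError("positions must be strictly increasing within a chromosome")
        object.__setattr__(self, "table", t)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def marker_id(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.table["pos"].to_numpy(np.int64)

    @property
    def pfb(self) -> np.ndarray:
        return self.table["pfb"].to_numpy(float)

    @property
    def gc(self) -> np.ndarray:
        return self.table["gc"].to_numpy(float)

    def chrom_slice(self, chrom: str) -> slice:
        """Positional slice of the (contiguous) block for one chromosome."""
        idx = np.flatnonzero(self.chrom == normalize_chrom(chrom))
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in marker map")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def iter_chrom_slices(self) -> Iterator[tuple[str, slice]]:
        for c in self.chromosomes:
            yield c, self.chrom_slice(c)

    @classmethod
    def from_arrays(cls, marker_id, chrom, pos, pfb, gc) -> "MarkerMap":
        return cls(pd.DataFrame({
            "marker_id": marker_id, "chrom": chrom, "pos": pos,
            "pfb": pfb, "gc": gc,
        }))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path) -> "MarkerMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


@dataclass(frozen=True)
class SampleSignal:
    """Per-sample LRR/BAF vectors aligned to a :class:`MarkerMap`."""

    sample_id: str
    lrr: np.ndarray
    baf: np.ndarray

    def __post_init__(self):
        lrr = np.asarray(self.lrr, float)
        baf = np.asarray(self.baf, float)
        if lrr.shape != baf.shape or lrr.ndim != 1:
            raise ValueError("lrr and baf must be 1-D arrays of equal length")
        if baf.size and (np.nanmin(baf) < 0 or np.nanmax(baf) > 1):
            raise ValueError("baf values must lie in [0, 1]")
        object.__setattr__(self, "lrr", lrr)
        object.__setattr__(self, "baf", baf)

    def __len__(self) -> int:
        return self.lrr.size


@dataclass(frozen=True, order=True)
class CNVCall:
    """One called deletion/duplication segment in one sample.

    Boundaries are the outermost marker positions of the decoded run,
    1-based inclusive.
    """

    sample_id: str
    chrom: str
    start_pos: int
    end_pos: int
    state: int
    n_snps: int

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.state not in CNV_STATES:
            raise ValueError(f"state must be one of {CNV_STATES}, got {self.state}")
        if self.start_pos > self.end_pos:
            raise ValueError("start_pos must be <= end_pos")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")

    @property
    def cnv_type(self) -> str:
        return state_to_type(self.state)

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1


@dataclass(frozen=True)
class CNVRegion:
    """A merged cross-sample CNV region with its carrier set."""

    region_id: str
    chrom: str
    start_pos: int
    end_pos: int
    cnv_type: str
    carriers: frozenset
    frequency: float

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "carriers", frozenset(self.carriers))
        if self.cnv_type not in ("deletion", "duplication"):
            raise ValueError(f"cnv_type must be deletion/duplication, got {self.cnv_type}")
        if not self.carriers:
            raise ValueError("a region must have at least one carrier")
        if not (0.0 < self.frequency <= 1.0):
            raise ValueError(f"frequency must lie in (0, 1], got {self.frequency}")
        if self.start_pos > self.end_pos:
            raise ValueError("start_pos must be <= end_pos")

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


@dataclass(frozen=True)
class SurvivalRecord:
    """Delayed-entry survival data for one individual (age timescale)."""

    sample_id: str
    sex: str
    entry_age: float
    exit_age: float
    event: int
    birth_cohort: str = ""
    family_id: str | None = None

    def __post_init__(self):
        if not self.entry_age < self.exit_age:
            raise ValueError(f"entry_age must be < exit_age ({self.sample_id})")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


PHENOTYPE_COLUMNS = (
    "sample_id", "sex", "entry_age", "exit_age", "event", "birth_cohort", "family_id",
)


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample_id, r.sex, r.entry_age, r.exit_age, r.event, r.birth_cohort,
          "" if r.family_id is None else r.family_id) for r in records],
        columns=PHENOTYPE_COLUMNS,
    )


def frame_to_records(df: pd.DataFrame) -> list[SurvivalRecord]:
    recs = []
    for row in df.itertuples(index=False):
        fam = getattr(row, "family_id", None)
        if fam is not None and (pd.isna(fam) or fam == ""):
            fam = None
        recs.append(SurvivalRecord(
            sample_id=str(row.sample_id), sex=str(row.sex),
            entry_age=float(row.entry_age), exit_age=float(row.exit_age),
            event=int(row.event), birth_cohort=str(getattr(row, "birth_cohort", "")),
            family_id=None if fam is None else str(fam),
        ))
    return recs
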