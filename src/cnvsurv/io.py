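"""Plain-text file formats: signal TSV, call TSV, rawcnv lines, BED, PFB.

All package-native tables are tab-separated with a header row and 1-based
inclusive coordinates. BED input is 0-based half-open and converted on
read. The rawcnv dialect is one call per line,

    chr1:1000-5000 numsnp=5 length=4001 state2,cn=1 SAMPLE

with the PennCNV state labels (state1=CN0, state2=CN1, state5=CN3,
state6=CN4); the ``cn=`` field is authoritative when parsing.
"""
from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CNVCall, CNVRegion, MarkerMap, SampleSignal, normalize_chrom

__all__ = [
    "write_signals", "read_signals", "write_calls_tsv", "read_calls_tsv",
    "write_rawcnv", "read_rawcnv", "read_bed", "write_pfb", "read_pfb",
    "write_regions_tsv", "read_regions_tsv",
]

_CN_TO_STATELABEL = {0: "state1", 1: "state2", 3: "state5", 4: "state6"}

CALL_COLUMNS = ("sample_id", "chrom", "start_pos", "end_pos", "state",
                "cnv_type", "n_snps", "length_bp")


def write_signals(signals: dict[str, SampleSignal], marker_map: MarkerMap, path) -> None:
    """Wide TSV: marker_id then ``<sample>.lrr`` / ``<sample>.baf`` columns."""
    data = {"marker_id": marker_map.marker_id}
    for sid in sorted(signals):
        s = signals[sid]
        if len(s) != len(marker_map):
            raise ValueError(f"signal {sid} length does not match marker map")
        data[f"{sid}.lrr"] = s.lrr
        data[f"{sid}.baf"] = s.baf
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_signals(path, marker_map: MarkerMap) -> dict[str, SampleSignal]:
    df = pd.read_csv(path, sep="\t")
    if not np.array_equal(df["marker_id"].to_numpy(), marker_map.marker_id):
        raise ValueError("signal file markers do not match the marker map")
    sids = sorted({c.rsplit(".", 1)[0] for c in df.columns if c.endswith(".lrr")})
    return {
        sid: SampleSignal(sample_id=sid,
                          lrr=df[f"{sid}.lrr"].to_numpy(float),
                          baf=df[f"{sid}.baf"].to_numpy(float))
        for sid in sids
    }


def calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.sample_id, c.chrom, c.start_pos, c.end_pos, c.state, c.cnv_type,
          c.n_snps, c.length_bp) for c in calls],
        columns=CALL_COLUMNS,
    )


def write_calls_tsv(calls, path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> list[CNVCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CNVCall(sample_id=str(r.sample_id), chrom=str(r.chrom),
                start_pos=int(r.start_pos), end_pos=int(r.end_pos),
                state=int(r.state), n_snps=int(r.n_snps))
        for r in df.itertuples(index=False)
    ]


def write_rawcnv(calls, path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"chr{c.chrom}:{c.start_pos}-{c.end_pos} numsnp={c.n_snps} "
                f"length={c.length_bp} {_CN_TO_STATELABEL[c.state]},cn={c.state} "
                f"{c.sample_id}\n"
            )


_RAWCNV_RE = re.compile(
    r"^(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)\s+numsnp=(?P<numsnp>[\d,]+)\s+"
    r"length=(?P<length>[\d,]+)\s+state\d+,cn=(?P<cn>\d)\s+(?P<sample>\S+)"
)


def read_rawcnv(path) -> list[CNVCall]:
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            m = _RAWCNV_RE.match(line)
            if not m:
                raise ValueError(f"{path}: malformed rawcnv line {lineno}: {line.strip()!r}")
            calls.append(CNVCall(
                sample_id=m["sample"], chrom=normalize_chrom(m["chrom"]),
                start_pos=int(m["start"]), end_pos=int(m["end"]),
                state=int(m["cn"]), n_snps=int(m["numsnp"].replace(",", "")),
            ))
    return calls


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read 3+-column BED; returns (chrom, start, end) 1-based inclusive."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            fields = s.split("\t") if "\t" in s else s.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}: {s!r}")
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as e:
                raise ValueError(f"{path}: malformed BED line {lineno}: {s!r}") from e
            if end0 <= start0:
                raise ValueError(f"{path}: empty/negative BED interval at line {lineno}")
            out.append((normalize_chrom(fields[0]), start0 + 1, end0))
    return out


def write_pfb(marker_map: MarkerMap, pfb, path) -> None:
    """PennCNV-style .pfb table: marker_id, chrom, pos, pfb."""
    pd.DataFrame({
        "marker_id": marker_map.marker_id, "chrom": marker_map.chrom,
        "pos": marker_map.pos, "pfb": np.asarray(pfb, float),
    }).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_pfb(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


REGION_COLUMNS = ("region_id", "chrom", "start_pos", "end_pos", "cnv_type",
                  "n_carriers", "frequency", "carriers")


def write_regions_tsv(regions, path) -> None:
    pd.DataFrame(
        [(r.region_id, r.chrom, r.start_pos, r.end_pos, r.cnv_type,
          r.n_carriers, r.frequency, ",".join(sorted(r.carriers)))
         for r in regions],
        columns=REGION_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_regions_tsv(path) -> list[CNVRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CNVRegion(region_id=str(r.region_id), chrom=str(r.chrom),
                  start_pos=int(r.start_pos), end_pos=int(r.end_pos),
                  cnv_type=str(r.cnv_type),
                  carriers=frozenset(str(r.carriers).split(",")),
                  frequency=float(r.frequency))
        for r in df.itertuples(index=False)
    ]
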