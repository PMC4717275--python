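"""Per-individual CNV burden: call count, average length and total length.

Burden is computed from filtered calls (not merged regions), overall and
separately for deletions and duplications. Alongside the raw kb metrics the
table carries pre-scaled covariate columns -- count per 10 CNVs, average
length per 10 kb, total length per 100 kb -- so fitted hazard ratios come
out in the units the association tables report.
"""
from __future__ import annotations

import pandas as pd

__all__ = ["BURDEN_CLASSES", "compute_burden"]

BURDEN_CLASSES = ("all", "deletion", "duplication")


def compute_burden(calls, samples, drop_zero_burden: bool = False) -> pd.DataFrame:
    """Burden table indexed by sample id.

    Columns per class ``{all,deletion,duplication}``: ``<cls>_n``,
    ``<cls>_avg_kb``, ``<cls>_total_kb`` plus scaled covariates
    ``<cls>_n_per10``, ``<cls>_avg_per10kb``, ``<cls>_total_per100kb``.
    Samples with no calls get all-zero rows (kept in models by default;
    ``drop_zero_burden`` removes samples with zero calls overall).
    """
    samples = [str(s) for s in samples]
    sset = set(samples)
    per_sample: dict[str, dict[str, list[int]]] = {
        s: {c: [] for c in BURDEN_CLASSES} for s in samples
    }
    for call in calls:
        if call.sample_id not in sset:
            raise ValueError(
                f"call for sample {call.sample_id!r} not in the passing sample list"
            )
        per_sample[call.sample_id]["all"].append(call.length_bp)
        per_sample[call.sample_id][call.cnv_type].append(call.length_bp)

    rows = []
    for s in samples:
        row: dict[str, float] = {"sample_id": s}
        for cls in BURDEN_CLASSES:
            lengths = per_sample[s][cls]
            n = len(lengths)
            total_kb = sum(lengths) / 1000.0
            avg_kb = total_kb / n if n else 0.0
            row[f"{cls}_n"] = n
            row[f"{cls}_avg_kb"] = avg_kb
            row[f"{cls}_total_kb"] = total_kb
            row[f"{cls}_n_per10"] = n / 10.0
            row[f"{cls}_avg_per10kb"] = avg_kb / 10.0
            row[f"{cls}_total_per100kb"] = total_kb / 100.0
        rows.append(row)
    df = pd.DataFrame(rows).set_index("sample_id")
    if drop_zero_burden:
        df = df[df["all_n"] > 0]
    return df
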