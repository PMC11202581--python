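"""Simple structural-variant signature binning.

Deletions and tandem duplications are binned by size — half-open intervals
(0, 1 Mb] small, (1 Mb, 10 Mb] mid, (10 Mb, inf) large by default —
while inversions and translocations carry their reciprocal/fold-back or
reciprocal/unbalanced subtypes as input annotations (determining those
requires breakpoint-cluster context that upstream clustering provides).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .subtype_classify import SubtypeCall

DEFAULT_SIZE_BINS = (1_000_000, 10_000_000)

SV_CATEGORIES = [
    "DEL_small", "DEL_mid", "DEL_large",
    "DUP_small", "DUP_mid", "DUP_large",
    "reciprocal_inv", "fold_back_inv",
    "reciprocal_tra", "unbalanced_tra",
    "unresolved",
]


@dataclass(frozen=True)
class SVRecord:
    sample_id: str
    sv_type: str  # {"DEL", "DUP", "INV", "TRA"}
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    inv_subtype: Optional[str] = None  # {"reciprocal", "fold_back"}
    tra_subtype: Optional[str] = None  # {"reciprocal", "unbalanced"}

    def __post_init__(self):
        if self.sv_type not in ("DEL", "DUP", "INV", "TRA"):
            raise ValueError(f"bad sv_type {self.sv_type!r}")
        if self.sv_type == "TRA":
            if self.chrom1 == self.chrom2:
                raise ValueError("TRA requires different chromosomes")
        else:
            if self.chrom1 != self.chrom2 or self.pos2 <= self.pos1:
                raise ValueError("intra-chromosomal SV requires chrom1=chrom2, pos2>pos1")

    @property
    def size(self) -> int:
        return self.pos2 - self.pos1


def classify_simple_sv(record: SVRecord, size_bins=DEFAULT_SIZE_BINS) -> str:
    """Category label for one simple SV."""
    bin1, bin2 = size_bins
    if record.sv_type in ("DEL", "DUP"):
        if record.size <= bin1:
            size_label = "small"
        elif record.size <= bin2:
            size_label = "mid"
        else:
            size_label = "large"
        return f"{record.sv_type}_{size_label}"
    if record.sv_type == "INV":
        if record.inv_subtype == "reciprocal":
            return "reciprocal_inv"
        if record.inv_subtype == "fold_back":
            return "fold_back_inv"
        return "unresolved"
    if record.tra_subtype == "reciprocal":
        return "reciprocal_tra"
    if record.tra_subtype == "unbalanced":
        return "unbalanced_tra"
    return "unresolved"


def _wilcoxon_rank_sum(x, y, exact_max: int = 25) -> float:
    """Two-sided Wilcoxon rank-sum p; exact for small groups, else normal
    approximation with continuity correction."""
    method = "exact" if max(len(x), len(y)) <= exact_max else "asymptotic"
    try:
        return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    except ValueError:  # exact method refuses ties; fall back
        return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                        method="asymptotic").pvalue)


def sv_signature_counts(records: Iterable[SVRecord], calls: Iterable[SubtypeCall],
                        size_bins=DEFAULT_SIZE_BINS) -> tuple:
    """Per-sample SV category counts plus pairwise subtype comparisons.

    Returns ``(counts, comparisons)``: a samples x categories count matrix
    (with the sample's subtype attached) and, per category and subtype
    pair, a two-sided Wilcoxon rank-sum p-value on the per-sample counts.
    """
    subtype_of = {c.sample_id: c.subtype for c in calls}
    counts = pd.DataFrame(0, index=sorted(subtype_of), columns=SV_CATEGORIES, dtype=int)
    counts.index.name = "sample_id"
    for r in records:
        if r.sample_id not in subtype_of:
            continue
        counts.loc[r.sample_id, classify_simple_sv(r, size_bins)] += 1
    counts["subtype"] = [subtype_of[s] for s in counts.index]

    subtypes = [s for s in counts["subtype"].unique() if s != "excluded"]
    rows = []
    for st_a, st_b in combinations(sorted(subtypes), 2):
        xa = counts[counts["subtype"] == st_a]
        xb = counts[counts["subtype"] == st_b]
        for cat in SV_CATEGORIES:
            a, b = xa[cat].to_numpy(), xb[cat].to_numpy()
            if len(a) == 0 or len(b) == 0:
                continue
            rows.append(dict(category=cat, group_a=st_a, group_b=st_b,
                             mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
                             p=_wilcoxon_rank_sum(a, b)))
    comparisons = pd.DataFrame(rows)
    return counts, comparisons


def read_sv_table(path) -> list:
    """Read a BEDPE-like SV TSV (sample, type, chrom1, pos1, chrom2, pos2,
    optional inv_subtype / tra_subtype columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(SVRecord(
            sample_id=row.sample, sv_type=row.type,
            chrom1=row.chrom1, pos1=int(row.pos1),
            chrom2=row.chrom2, pos2=int(row.pos2),
            inv_subtype=getattr(row, "inv_subtype", "") or None,
            tra_subtype=getattr(row, "tra_subtype", "") or None))
    return records


def write_sv_table(records: Iterable[SVRecord], path) -> None:
    pd.DataFrame([
        dict(sample=r.sample_id, type=r.sv_type, chrom1=r.chrom1, pos1=r.pos1,
             chrom2=r.chrom2, pos2=r.pos2, inv_subtype=r.inv_subtype or "",
             tra_subtype=r.tra_subtype or "") for r in records
    ]).to_csv(path, sep="\t", index=False)
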