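"""Subtype-conditioned downstream statistics.

Three families: per-gene truncating-indel enrichment between two sample
groups (two-sided Fisher exact test, no multiple-testing correction by
default, mirroring a plain p < 0.05 gate), differential expression by
Welch's t-test with a joint p < 0.05 and |log2FC| > 1 gate, and
neoantigen-burden summaries counting predicted binders with IC50 strictly
below 50 nM in expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mutation_io import MutationRecord
from .subtype_classify import SubtypeCall

TRUNCATING_CONSEQUENCES = {"frameshift", "nonsense"}


@dataclass(frozen=True)
class NeoantigenRecord:
    """One predicted HLA-binding peptide from a somatic mutation."""

    sample_id: str
    gene: str
    mutation_class: str  # {"SNV", "INS", "DEL", "SV"}
    ic50_nm: float
    expressed: bool

    def __post_init__(self):
        if not np.isfinite(self.ic50_nm) or self.ic50_nm <= 0:
            raise ValueError("ic50_nm must be finite and positive")
        if self.mutation_class not in ("SNV", "INS", "DEL", "SV"):
            raise ValueError(f"bad mutation_class {self.mutation_class!r}")


def truncating_indel_matrix(records: Iterable[MutationRecord],
                            kind: Optional[str] = None) -> pd.DataFrame:
    """Binary gene x sample indicator of truncating indels.

    ``kind`` restricts to ``"INS"`` or ``"DEL"``; by default both count.
    Only records with a gene and a truncating consequence contribute.
    """
    cells = set()
    genes, samples = set(), set()
    for r in records:
        if r.variant_class not in ("INS", "DEL") or r.gene is None:
            continue
        if r.consequence not in TRUNCATING_CONSEQUENCES:
            continue
        samples.add(r.sample_id)
        if kind is not None and r.variant_class != kind:
            continue
        genes.add(r.gene)
        cells.add((r.gene, r.sample_id))
    mat = pd.DataFrame(0, index=sorted(genes), columns=sorted(samples), dtype=int)
    for g, s in cells:
        mat.loc[g, s] = 1
    return mat


def gene_enrichment(matrix: pd.DataFrame, group_a: Sequence, group_b: Sequence,
                    alpha: float = 0.05, correction: Optional[str] = None) -> pd.DataFrame:
    """Per-gene 2x2 Fisher exact tests between two disjoint sample groups.

    The table is mutated/unmutated x group; ``p`` is the two-sided exact
    p-value (point-probability rule).  ``correction="bh"`` adds a
    Benjamini-Hochberg q-value column; the default applies none.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    cols_a = [s for s in group_a if s in matrix.columns]
    cols_b = [s for s in group_b if s in matrix.columns]
    rows = []
    for gene in matrix.index:
        a = int(matrix.loc[gene, cols_a].sum())          # mutated in A
        b = len(group_a) - a                             # unmutated in A
        c = int(matrix.loc[gene, cols_b].sum())          # mutated in B
        d = len(group_b) - c
        if a + c == 0:
            p, odds = 1.0, np.nan
            flagged = True
        else:
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            flagged = False
        frac_a = a / len(group_a)
        frac_b = c / len(group_b)
        rows.append(dict(gene=gene, a=a, b=b, c=c, d=d, p=p,
                         direction="A" if frac_a >= frac_b else "B",
                         absent_in_both=flagged))
    out = pd.DataFrame(rows).set_index("gene")
    if correction == "bh":
        out["q"] = _benjamini_hochberg(out["p"].to_numpy())
        out["significant"] = out["q"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def select_degs(expression: pd.DataFrame, group_a: Sequence, group_b: Sequence,
                p_threshold: float = 0.05, lfc_threshold: float = 1.0) -> pd.DataFrame:
    """Differential expression between two groups of log2-scale profiles.

    Per gene: Welch's two-sample t-test and the mean difference (group A
    minus group B, i.e. the log2 fold change since the input is log-scale).
    Selected iff ``p < p_threshold`` and ``|log2FC| > lfc_threshold``.
    Zero-variance genes: p = 1 when the group means agree, else p = 0 and
    the gene is flagged degenerate.
    """
    cols_a = [s for s in group_a if s in expression.columns]
    cols_b = [s for s in group_b if s in expression.columns]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 samples with expression")
    xa = expression[cols_a].to_numpy(dtype=float)
    xb = expression[cols_b].to_numpy(dtype=float)
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    var_a = xa.var(axis=1, ddof=1)
    var_b = xb.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    lfc = mean_a - mean_b
    degenerate = (var_a == 0) & (var_b == 0)
    p = np.where(degenerate, np.where(mean_a == mean_b, 1.0, 0.0), p)
    out = pd.DataFrame(dict(log2fc=lfc, p=p, degenerate=degenerate),
                       index=expression.index)
    out["selected"] = (out["p"] < p_threshold) & (out["log2fc"].abs() > lfc_threshold)
    out["direction"] = np.where(lfc >= 0, "up_in_A", "up_in_B")
    return out


def _subtype_of(calls: Iterable[SubtypeCall]) -> Mapping:
    return {c.sample_id: c.subtype for c in calls}


def neoantigen_burden(records: Iterable[NeoantigenRecord], calls: Iterable[SubtypeCall],
                      affinity_cutoff: float = 50.0) -> tuple:
    """Counts of strong, expressed neoantigens per sample and subtype.

    A record qualifies iff ``ic50_nm < affinity_cutoff`` (strictly below)
    and the gene is expressed.  Returns ``(per_sample, per_subtype)``:
    per-sample counts stratified by mutation class, and per-subtype
    mean/median of the totals.
    """
    subtype_of = _subtype_of(calls)
    classes = ("SNV", "INS", "DEL", "SV")
    counts: dict = {sid: dict.fromkeys(classes, 0) for sid in subtype_of}
    for r in records:
        if r.sample_id not in counts:
            continue
        if r.expressed and r.ic50_nm < affinity_cutoff:
            counts[r.sample_id][r.mutation_class] += 1
    per_sample = pd.DataFrame.from_dict(counts, orient="index").sort_index()
    per_sample.index.name = "sample_id"
    per_sample["total"] = per_sample.sum(axis=1)
    per_sample["subtype"] = [subtype_of[s] for s in per_sample.index]
    per_subtype = per_sample.groupby("subtype")["total"].agg(["mean", "median", "count"])
    return per_sample, per_subtype


def recurrent_neoantigen_genes(records: Iterable[NeoantigenRecord],
                               calls: Iterable[SubtypeCall], subtype: str,
                               min_fraction: float = 0.40,
                               affinity_cutoff: float = 50.0) -> pd.DataFrame:
    """Genes with qualifying neoantigens in more than ``min_fraction`` of the
    target subtype's samples (strict); fractions reported for all subtypes."""
    subtype_of = _subtype_of(calls)
    members: dict = {}
    for sid, st in subtype_of.items():
        members.setdefault(st, set()).add(sid)
    if subtype not in members or not members[subtype]:
        raise ValueError(f"subtype {subtype!r} has no samples")
    carriers: dict = {}
    for r in records:
        st = subtype_of.get(r.sample_id)
        if st is None:
            continue
        if r.expressed and r.ic50_nm < affinity_cutoff:
            carriers.setdefault(r.gene, {}).setdefault(st, set()).add(r.sample_id)
    rows = []
    for gene, by_subtype in carriers.items():
        row = dict(gene=gene)
        for st, samples in members.items():
            row[f"frac_{st}"] = len(by_subtype.get(st, ())) / len(samples)
        row["listed"] = row.get(f"frac_{subtype}", 0.0) > min_fraction
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["gene", "listed"]).set_index("gene")
    return pd.DataFrame(rows).set_index("gene").fillna(0.0).sort_values(
        f"frac_{subtype}", ascending=False)
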