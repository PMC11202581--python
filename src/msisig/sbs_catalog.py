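"""96-channel single-base-substitution catalogs in trinucleotide context.

Channels are the 6 pyrimidine-referenced substitution classes (C>A, C>G,
C>T, T>A, T>C, T>G) crossed with the 16 flanking base combinations, in the
canonical COSMIC block ordering.  Substitutions recorded on the purine
strand are reverse-complemented before assignment.
"""

from __future__ import annotations

import logging
from typing import Iterable, NamedTuple, Optional

import numpy as np
import pandas as pd

from .indel_catalog import MutationalCatalog
from .mutation_io import COMPLEMENT, MutationRecord, as_reference, fetch_window

logger = logging.getLogger("msisig")

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

SBS96_LABELS = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in "ACGT"
    for three in "ACGT"
]
SBS96_INDEX = {label: i for i, label in enumerate(SBS96_LABELS)}
assert len(SBS96_LABELS) == 96


class Sbs96Channel(NamedTuple):
    index: int
    label: str


class ReferenceMismatchError(ValueError):
    """The reference base at a site does not match the record's ref allele."""


def _revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def assign_sbs96_channel(record: MutationRecord, reference) -> Optional[Sbs96Channel]:
    """Assign an SNV to its trinucleotide channel; ``None`` when the triplet
    contains an N or the site has no complete triplet (contig edge)."""
    if record.variant_class != "SNV":
        raise ValueError("assign_sbs96_channel requires an SNV record")
    ref = as_reference(reference)
    window = fetch_window(ref, record.chrom, record.pos, 1)
    if window.end - window.start != 2:  # clipped at a contig end
        return None
    triplet = window.sequence
    if triplet[1] != record.ref:
        raise ReferenceMismatchError(
            f"reference base at {record.chrom}:{record.pos} is {triplet[1]!r}, "
            f"record says {record.ref!r}")
    if "N" in triplet:
        return None
    ref_base, alt_base = record.ref, record.alt
    if ref_base in "GA":
        triplet = _revcomp(triplet)
        ref_base = ref_base.translate(COMPLEMENT)
        alt_base = alt_base.translate(COMPLEMENT)
    label = f"{triplet[0]}[{ref_base}>{alt_base}]{triplet[2]}"
    return Sbs96Channel(SBS96_INDEX[label], label)


def build_sbs_catalog(records: Iterable[MutationRecord], reference,
                      sample_ids=None) -> MutationalCatalog:
    """Per-sample 96-channel catalog; full channel axis even when zero."""
    ref = as_reference(reference)
    records = [r for r in records if r.variant_class == "SNV"]
    if sample_ids is None:
        sample_ids = sorted({r.sample_id for r in records})
    index = {s: i for i, s in enumerate(sample_ids)}
    counts = np.zeros((len(sample_ids), 96), dtype=int)
    dropped: dict = {}
    for r in records:
        if r.sample_id not in index:
            continue
        channel = assign_sbs96_channel(r, ref)
        if channel is None:
            dropped[r.sample_id] = dropped.get(r.sample_id, 0) + 1
            continue
        counts[index[r.sample_id], channel.index] += 1
    if dropped:
        logger.info("SBS96: %d records unclassifiable", sum(dropped.values()))
    return MutationalCatalog(list(sample_ids), list(SBS96_LABELS), counts, dropped)


def substitution_class_fractions(catalog: MutationalCatalog) -> pd.DataFrame:
    """Collapse 96 channels to the 6 substitution classes, as proportions.

    Samples with an all-zero catalog row are reported as missing (NaN).
    """
    if list(catalog.channel_labels) != SBS96_LABELS:
        raise ValueError("catalog does not carry the 96 SBS channels")
    frame = catalog.to_frame()
    collapsed = pd.DataFrame(
        {cls: frame.loc[:, [l for l in SBS96_LABELS if f"[{cls}]" in l]].sum(axis=1)
         for cls in SUBSTITUTION_CLASSES})
    totals = collapsed.sum(axis=1)
    out = collapsed.div(totals, axis=0)
    out[totals == 0] = np.nan
    return out
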