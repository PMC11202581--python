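"""COSMIC-style 83-channel indel classification and per-sample catalogs.

The 83 channels decompose as 12 (1 bp deletions) + 12 (1 bp insertions) +
24 (repeat-mediated deletions of length >= 2) + 24 (repeat-mediated
insertions) + 11 (microhomology deletions).  Labels follow the canonical
scheme used by COSMIC signature files, e.g. ``1:Del:T:5`` (1 bp T deletion
in a homopolymer of length 6+), ``3:Ins:R:0`` (3 bp insertion with no
pre-existing tandem copy), ``4:Del:M:2`` (4 bp deletion with 2 bp of
flanking microhomology).

Numeric suffix conventions (COSMIC):

* 1 bp deletions: suffix = homopolymer length - 1, capped at 5 ("6+").
* 1 bp insertions: suffix = pre-existing homopolymer length, capped at 5.
* Longer deletions: suffix = tandem repeat count including the deleted
  copy, minus 1, capped at 5.
* Longer insertions: suffix = pre-existing tandem copies, capped at 5.
* Microhomology deletions: suffix = microhomology length, capped at 5.

Single-base events are pyrimidine-normalised (A -> T, G -> C); sequences of
length >= 2 are never strand-normalised, matching the COSMIC convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np
import pandas as pd

from .mutation_io import (
    COMPLEMENT,
    MutationRecord,
    ReferenceWindow,
    as_reference,
    fetch_window,
    left_align,
)

logger = logging.getLogger("msisig")

#: exact repeat/run counting is performed up to this cap before binning
COUNT_CAP = 20


def _build_id83_labels() -> list:
    labels = []
    for base in ("C", "T"):
        labels += [f"1:Del:{base}:{k}" for k in range(6)]
    for base in ("C", "T"):
        labels += [f"1:Ins:{base}:{k}" for k in range(6)]
    for size in ("2", "3", "4", "5"):
        labels += [f"{size}:Del:R:{k}" for k in range(6)]
    for size in ("2", "3", "4", "5"):
        labels += [f"{size}:Ins:R:{k}" for k in range(6)]
    labels += ["2:Del:M:1"]
    labels += [f"3:Del:M:{k}" for k in (1, 2)]
    labels += [f"4:Del:M:{k}" for k in (1, 2, 3)]
    labels += [f"5:Del:M:{k}" for k in (1, 2, 3, 4, 5)]
    return labels


ID83_LABELS = _build_id83_labels()
ID83_INDEX = {label: i for i, label in enumerate(ID83_LABELS)}

# the 12+12+24+24+11 decomposition is structural; fail loudly at import
assert len(ID83_LABELS) == 83 and len(ID83_INDEX) == 83
assert sum(1 for l in ID83_LABELS if l.startswith("1:Del")) == 12
assert sum(1 for l in ID83_LABELS if l.startswith("1:Ins")) == 12
assert sum(1 for l in ID83_LABELS if ":Del:R" in l) == 24
assert sum(1 for l in ID83_LABELS if ":Ins:R" in l and not l.startswith("1:")) == 24
assert sum(1 for l in ID83_LABELS if ":Del:M" in l) == 11


class Id83Channel(NamedTuple):
    index: int
    label: str


@dataclass
class MutationalCatalog:
    """Non-negative integer count matrix, samples x channels."""

    sample_ids: list
    channel_labels: list
    counts: np.ndarray
    dropped: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.channel_labels)):
            raise ValueError("counts shape does not match axes")
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.channel_labels)

    def row(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_ids.index(sample_id)]

    def to_tsv(self, path) -> None:
        """COSMIC layout: first column the channel label, one column per sample."""
        df = self.to_frame().T
        df.index.name = "Type"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "MutationalCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(sample_ids=list(df.columns), channel_labels=list(df.index),
                   counts=df.T.to_numpy())


def homopolymer_run(window: ReferenceWindow, site: int, base: str, kind: str = "DEL") -> int:
    """Length of the homopolymer run of ``base`` at an indel locus.

    For a deletion, ``site`` is the position of the deleted base and the run
    containing it is returned.  For an insertion, ``site`` is the anchor base
    5' of the insertion point and the longer of the two runs adjacent to the
    insertion point is returned (0 if neither neighbour matches).  Counting
    is exact up to :data:`COUNT_CAP`.
    """
    seq = window.sequence
    i = site - window.start
    if not 0 <= i < len(seq):
        raise ValueError("site outside window")

    def run_left(j):  # run of `base` ending at index j (inclusive)
        n = 0
        while j >= 0 and seq[j] == base and n < COUNT_CAP:
            n += 1
            j -= 1
        return n

    def run_right(j):  # run of `base` starting at index j
        n = 0
        while j < len(seq) and seq[j] == base and n < COUNT_CAP:
            n += 1
            j += 1
        return n

    if kind == "DEL":
        if seq[i] != base:
            raise ValueError(f"window base {seq[i]!r} at site {site} is not {base!r}")
        return min(run_left(i - 1) + 1 + run_right(i + 1), COUNT_CAP)
    if kind == "INS":
        return min(max(run_left(i), run_right(i + 1)), COUNT_CAP)
    raise ValueError(f"kind must be DEL or INS, got {kind!r}")


def repeat_unit_count(indel_seq: str, left_flank: str, right_flank: str, kind: str) -> int:
    """Number of exact tandem copies of ``indel_seq`` at the locus.

    Copies are counted scanning rightward from the indel site; for a
    deletion the deleted copy itself is included.  ``left_flank`` is part of
    the signature for interface symmetry but does not contribute: input
    indels are left-aligned, so the event sits at the leftmost copy.
    """
    del left_flank
    unit = indel_seq
    n = 0
    pos = 0
    while right_flank.startswith(unit, pos) and n < COUNT_CAP:
        n += 1
        pos += len(unit)
    if kind == "DEL":
        n += 1
    return min(n, COUNT_CAP)


def microhomology_length(deleted_seq: str, left_flank: str, right_flank: str) -> int:
    """Longest homology between a deletion's boundary and its flanks.

    Maximum over the longest proper prefix of ``deleted_seq`` matching the
    start of the right flank and the longest proper suffix matching the end
    of the left flank; always strictly less than the deletion length.
    """
    best = 0
    for j in range(1, len(deleted_seq)):
        if right_flank.startswith(deleted_seq[:j]):
            best = max(best, j)
        if left_flank.endswith(deleted_seq[-j:]):
            best = max(best, j)
    return best


def _pyrimidine(base: str) -> str:
    return base if base in "CT" else base.translate(COMPLEMENT)


def assign_id83_channel(record: MutationRecord, reference) -> Optional[Id83Channel]:
    """Assign an indel to one of the 83 channels, or ``None`` if the decisive
    sequence context contains an N (unclassifiable)."""
    if record.variant_class not in ("INS", "DEL"):
        raise ValueError("assign_id83_channel requires an indel record")
    ref = as_reference(reference)
    record = left_align(record, ref)
    length = record.indel_length
    flank = COUNT_CAP * max(1, length) + length + 5
    center = max(1, record.pos)
    window = fetch_window(ref, record.chrom, center, flank)
    seq = window.sequence

    if record.variant_class == "DEL":
        i = record.pos - window.start
        deleted = seq[i : i + length]
        if deleted != record.ref:
            raise ValueError(
                f"reference mismatch at {record.chrom}:{record.pos}: "
                f"expected {record.ref!r}, found {deleted!r}")
        left, right = seq[:i], seq[i + length :]
        if length == 1:
            if "N" in (left[-COUNT_CAP:] + deleted + right[:COUNT_CAP]):
                return None
            run = homopolymer_run(window, record.pos, deleted, "DEL")
            label = f"1:Del:{_pyrimidine(deleted)}:{min(run, 6) - 1}"
            return Id83Channel(ID83_INDEX[label], label)
        if "N" in deleted or "N" in right[: COUNT_CAP * length] or "N" in left[-length:]:
            return None
        size = min(length, 5)
        count = repeat_unit_count(deleted, left, right, "DEL")
        if count >= 2:
            label = f"{size}:Del:R:{min(count, 6) - 1}"
        else:
            mh = microhomology_length(deleted, left, right)
            if mh >= 1:
                label = f"{size}:Del:M:{min(mh, 5)}"
            else:
                label = f"{size}:Del:R:0"
        return Id83Channel(ID83_INDEX[label], label)

    # insertion: pos anchors the base 5' of the inserted sequence
    inserted = record.alt
    i = record.pos - window.start  # anchor index; insertion point after it
    left, right = seq[: i + 1], seq[i + 1 :]
    if record.pos < window.start:  # insertion left-aligned to contig start
        left, right = "", seq
    if length == 1:
        if "N" in (left[-COUNT_CAP:] + right[:COUNT_CAP]):
            return None
        run = homopolymer_run(window, record.pos, inserted, "INS") if record.pos >= window.start \
            else min(len(right) - len(right.lstrip(inserted)), COUNT_CAP)
        label = f"1:Ins:{_pyrimidine(inserted)}:{min(run, 5)}"
        return Id83Channel(ID83_INDEX[label], label)
    if "N" in right[: COUNT_CAP * length]:
        return None
    size = min(length, 5)
    count = repeat_unit_count(inserted, left, right, "INS")
    label = f"{size}:Ins:R:{min(count, 5)}"
    return Id83Channel(ID83_INDEX[label], label)


def build_id_catalog(records: Iterable[MutationRecord], reference,
                     sample_ids: Optional[list] = None) -> MutationalCatalog:
    """Classify every indel record and accumulate per-sample channel counts.

    The channel axis is always the full 83 labels; samples with no
    classifiable indel get a zero row.  Unclassifiable records (N context,
    or SNVs passed in by accident are rejected upstream) are counted in
    ``catalog.dropped``.
    """
    ref = as_reference(reference)
    records = [r for r in records if r.variant_class in ("INS", "DEL")]
    if sample_ids is None:
        sample_ids = sorted({r.sample_id for r in records})
    index = {s: i for i, s in enumerate(sample_ids)}
    counts = np.zeros((len(sample_ids), 83), dtype=int)
    dropped: dict = {}
    for r in records:
        if r.sample_id not in index:
            continue
        channel = assign_id83_channel(r, ref)
        if channel is None:
            dropped[r.sample_id] = dropped.get(r.sample_id, 0) + 1
            continue
        counts[index[r.sample_id], channel.index] += 1
    if dropped:
        logger.info("ID83: %d records unclassifiable", sum(dropped.values()))
    return MutationalCatalog(list(sample_ids), list(ID83_LABELS), counts, dropped)
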