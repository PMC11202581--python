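"""Reading/writing somatic mutation tables and reference sequence access.

Coordinate convention is 1-based inclusive throughout, following the MAF
convention: for an SNV ``pos`` is the substituted base, for a deletion the
first deleted base, and for an insertion the base immediately 5' of the
inserted sequence.  Pure insertions carry ``ref == "-"`` and pure deletions
``alt == "-"``.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

logger = logging.getLogger("msisig")

VALID_BASES = set("ACGT")
COMPLEMENT = str.maketrans("ACGT", "TGCA")

VARIANT_CLASSES = ("SNV", "INS", "DEL")
CONSEQUENCES = ("silent", "missense", "nonsense", "frameshift", "splice", "other")

#: MAF Variant_Classification values mapped onto the compact consequence set.
MAF_CONSEQUENCE = {
    "Silent": "silent",
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Nonstop_Mutation": "nonsense",
    "Frame_Shift_Ins": "frameshift",
    "Frame_Shift_Del": "frameshift",
    "In_Frame_Ins": "other",
    "In_Frame_Del": "other",
    "Splice_Site": "splice",
    "Splice_Region": "splice",
    "Translation_Start_Site": "other",
}

MAF_COLUMNS = {
    "sample_id": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "gene": "Hugo_Symbol",
    "consequence": "Variant_Classification",
}

SIMPLE_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "gene", "consequence"]


class FormatError(ValueError):
    """A required column is missing or a table cannot be parsed."""


class ReferenceLookupError(KeyError):
    """A chromosome is absent from the reference."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant (SNV, insertion or deletion)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    gene: Optional[str] = None
    consequence: Optional[str] = None

    def __post_init__(self):
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.variant_class == "INS" and (self.ref != "-" or len(self.alt) < 1):
            raise ValueError("INS requires ref='-' and non-empty alt")
        if self.variant_class == "DEL" and (self.alt != "-" or len(self.ref) < 1):
            raise ValueError("DEL requires alt='-' and non-empty ref")
        if self.variant_class == "SNV" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("SNV requires single-base ref and alt")

    @property
    def indel_length(self) -> int:
        if self.variant_class == "INS":
            return len(self.alt)
        if self.variant_class == "DEL":
            return len(self.ref)
        return 0


@dataclass(frozen=True)
class CohortAnnotation:
    """Per-sample clinical/technical annotation used by the classifier."""

    sample_id: str
    tumor_type: str = "NA"
    msi_status: str = "unknown"  # {"MSI-H", "MSS", "unknown"}
    ppd_hotspot: bool = False
    platform: str = "exome"  # {"exome", "genome"}
    callable_mb: float = 38.0

    def __post_init__(self):
        if self.msi_status not in ("MSI-H", "MSS", "unknown"):
            raise ValueError(f"bad msi_status {self.msi_status!r}")
        if self.platform not in ("exome", "genome"):
            raise ValueError(f"bad platform {self.platform!r}")
        if not self.callable_mb > 0:
            raise ValueError("callable_mb must be positive")


@dataclass(frozen=True)
class ReferenceWindow:
    """A 1-based inclusive slice of reference sequence."""

    chrom: str
    start: int
    end: int
    sequence: str

    def __post_init__(self):
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length does not match coordinates")


class ReferenceGenome:
    """Uniform access to a reference, backed by an indexed FASTA or a dict.

    A :class:`dict` mapping contig name to sequence is accepted so that
    simulated cohorts never need to touch the filesystem; a path is opened
    through :mod:`pyfaidx`.
    """

    def __init__(self, source: Union[str, Path, Mapping]):
        if isinstance(source, (str, Path)):
            import pyfaidx

            self._fasta = pyfaidx.Fasta(str(source), sequence_always_upper=True)
            self._dict = None
        elif isinstance(source, Mapping):
            self._dict = {str(k): str(v).upper() for k, v in source.items()}
            self._fasta = None
        else:
            raise TypeError("reference source must be a path or a mapping")

    @property
    def contigs(self) -> list:
        if self._dict is not None:
            return list(self._dict)
        return list(self._fasta.keys())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.contigs

    def length(self, chrom: str) -> int:
        if self._dict is not None:
            try:
                return len(self._dict[chrom])
            except KeyError as exc:
                raise ReferenceLookupError(chrom) from exc
        try:
            return len(self._fasta[chrom])
        except KeyError as exc:
            raise ReferenceLookupError(chrom) from exc

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the sequence for [start, end], 1-based inclusive."""
        if start < 1 or end < start:
            raise ValueError(f"bad window [{start}, {end}]")
        if self._dict is not None:
            try:
                seq = self._dict[chrom]
            except KeyError as exc:
                raise ReferenceLookupError(chrom) from exc
            return seq[start - 1 : end]
        try:
            return str(self._fasta[chrom][start - 1 : end]).upper()
        except KeyError as exc:
            raise ReferenceLookupError(chrom) from exc


def as_reference(reference) -> ReferenceGenome:
    if isinstance(reference, ReferenceGenome):
        return reference
    return ReferenceGenome(reference)


def fetch_window(reference, chrom: str, center_pos: int, flank: int) -> ReferenceWindow:
    """Fetch ``center_pos`` ± ``flank``, clipped at the contig ends."""
    ref = as_reference(reference)
    if chrom not in ref:
        raise ReferenceLookupError(chrom)
    n = ref.length(chrom)
    start = max(1, center_pos - flank)
    end = min(n, center_pos + flank)
    return ReferenceWindow(chrom, start, end, ref.fetch(chrom, start, end))


def _classify_alleles(ref: str, alt: str) -> Optional[str]:
    if ref == "-" and len(alt) >= 1:
        return "INS"
    if alt == "-" and len(ref) >= 1:
        return "DEL"
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    return None  # delins / length-mismatch without dash: unsupported


def _alleles_clean(ref: str, alt: str) -> bool:
    for allele in (ref, alt):
        if allele == "-":
            continue
        if not allele or not set(allele) <= VALID_BASES:
            return False
    return True


def read_mutations(path, dialect: str = "simple_tsv") -> list:
    """Read a mutation table into :class:`MutationRecord` objects.

    ``dialect`` is ``"maf"`` (MAF-like TSV with standard column names) or
    ``"simple_tsv"`` (7 columns: sample, chrom, pos, ref, alt, gene,
    consequence).  Rows with ambiguity codes, equal alleles or unsupported
    allele shapes (delins) are dropped with a logged count.
    """
    if dialect not in ("maf", "simple_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    if df.empty and df.columns.size == 0:
        logger.warning("empty mutation file %s", path)
        return []
    if dialect == "maf":
        colmap = MAF_COLUMNS
    else:
        colmap = {k: v for k, v in zip(
            ["sample_id", "chrom", "pos", "ref", "alt", "gene", "consequence"],
            SIMPLE_COLUMNS)}
    for col in colmap.values():
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} for dialect {dialect!r}")

    records = []
    dropped = 0
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(row)
        ref = str(row[colmap["ref"]]).upper().strip()
        alt = str(row[colmap["alt"]]).upper().strip()
        # normalise the common empty-allele spellings to "-"
        ref = ref if ref not in ("", ".", "NA") else "-"
        alt = alt if alt not in ("", ".", "NA") else "-"
        vclass = _classify_alleles(ref, alt)
        if vclass is None or not _alleles_clean(ref, alt) or ref == alt:
            dropped += 1
            continue
        raw_cons = str(row[colmap["consequence"]]).strip()
        if dialect == "maf":
            consequence = MAF_CONSEQUENCE.get(raw_cons, "other") if raw_cons else None
        else:
            consequence = raw_cons if raw_cons in CONSEQUENCES else None
        try:
            pos = int(float(row[colmap["pos"]]))
        except ValueError:
            dropped += 1
            continue
        gene = str(row[colmap["gene"]]).strip() or None
        records.append(
            MutationRecord(
                sample_id=str(row[colmap["sample_id"]]),
                chrom=str(row[colmap["chrom"]]),
                pos=pos,
                ref=ref,
                alt=alt,
                variant_class=vclass,
                gene=gene,
                consequence=consequence,
            )
        )
    if dropped:
        logger.info("dropped %d malformed/ambiguous rows from %s", dropped, path)
    if not records:
        logger.warning("no usable mutation rows in %s", path)
    return records


def write_mutations(records: Iterable[MutationRecord], path, dialect: str = "simple_tsv") -> None:
    """Write records as a TSV in the given dialect (round-trips with read)."""
    rows = []
    for r in records:
        if dialect == "simple_tsv":
            rows.append(
                dict(sample=r.sample_id, chrom=r.chrom, pos=r.pos, ref=r.ref,
                     alt=r.alt, gene=r.gene or "", consequence=r.consequence or ""))
        elif dialect == "maf":
            inverse = {v: k for k, v in MAF_CONSEQUENCE.items()}
            rows.append({
                "Tumor_Sample_Barcode": r.sample_id,
                "Chromosome": r.chrom,
                "Start_Position": r.pos,
                "Reference_Allele": r.ref,
                "Tumor_Seq_Allele2": r.alt,
                "Hugo_Symbol": r.gene or "",
                "Variant_Classification": inverse.get(r.consequence, "") if r.consequence else "",
            })
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> dict:
    """Read a cohort annotation TSV into {sample_id: CohortAnnotation}."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "msi_status", "ppd_hotspot", "platform", "callable_mb"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in annotation table")
    out = {}
    for row in df.itertuples(index=False):
        out[row.sample_id] = CohortAnnotation(
            sample_id=row.sample_id,
            tumor_type=getattr(row, "tumor_type", "NA") or "NA",
            msi_status=row.msi_status,
            ppd_hotspot=str(row.ppd_hotspot).lower() in ("1", "true", "yes"),
            platform=row.platform,
            callable_mb=float(row.callable_mb),
        )
    return out


def write_annotations(annotations: Mapping, path) -> None:
    rows = [
        dict(sample_id=a.sample_id, tumor_type=a.tumor_type, msi_status=a.msi_status,
             ppd_hotspot=a.ppd_hotspot, platform=a.platform, callable_mb=a.callable_mb)
        for a in annotations.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def left_align(record: MutationRecord, reference) -> MutationRecord:
    """Shift an indel to its leftmost equivalent position (slippage class).

    Input indels are assumed left-aligned already; this pass is defensive so
    that channel assignment never depends on the caller's normalisation.
    SNVs are returned unchanged.
    """
    if record.variant_class == "SNV":
        return record
    ref = as_reference(reference)

    if record.variant_class == "DEL":
        pos, allele = record.pos, record.ref
        # shift while the base before the deletion equals its last base
        while pos > 1:
            prev = ref.fetch(record.chrom, pos - 1, pos - 1)
            if prev != allele[-1]:
                break
            allele = prev + allele[:-1]
            pos -= 1
        if pos == record.pos:
            return record
        return replace(record, pos=pos, ref=allele)

    # INS: anchor at the base 5' of the insertion; pos may reach 0 when the
    # insertion left-aligns to the very start of the contig.
    pos, allele = record.pos, record.alt
    while pos >= 1:
        anchor = ref.fetch(record.chrom, pos, pos)
        if anchor != allele[-1]:
            break
        allele = allele[-1] + allele[:-1]
        pos -= 1
    if pos == record.pos:
        return record
    return replace(record, pos=pos, alt=allele)


def compute_tmb(records: Iterable[MutationRecord], annotations: Mapping) -> pd.DataFrame:
    """Per-sample mutation burdens.

    ``tmb_count`` counts all non-silent mutations (records with missing
    consequence count as non-silent), ``indel_count`` counts insertions plus
    deletions, and ``indels_per_mb`` divides by the sample's callable
    megabases from its annotation.
    """
    per_sample: dict = {}
    for r in records:
        d = per_sample.setdefault(r.sample_id, dict(tmb_count=0, snv_count=0, indel_count=0))
        if r.consequence != "silent":
            d["tmb_count"] += 1
        if r.variant_class == "SNV":
            d["snv_count"] += 1
        else:
            d["indel_count"] += 1
    for sid, ann in annotations.items():
        per_sample.setdefault(sid, dict(tmb_count=0, snv_count=0, indel_count=0))
    rows = []
    for sid in sorted(per_sample):
        d = per_sample[sid]
        ann = annotations.get(sid)
        callable_mb = ann.callable_mb if ann is not None else float("nan")
        rows.append(dict(sample_id=sid, **d,
                         indels_per_mb=d["indel_count"] / callable_mb))
    return pd.DataFrame(rows).set_index("sample_id")
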