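"""Routing of hypermutated genomes into MMRd-del, MMRd-ins and PPd.

The workflow: (1) drop samples below the platform's indel-burden threshold
(>= 10 indels per exome; > 1000 indels per genome); (2) score each retained
sample by the dominance = raw ID1 exposure minus raw ID2 exposure (ID1 is
the 1 bp-insertion slippage signature, ID2 the 1 bp-deletion one); (3) route
by MSI status and POLE/POLD1 exonuclease-hotspot annotation:

* microsatellite-stable samples are excluded outright;
* hotspot carriers with insertion-dominant indels are PPd;
* hotspot carriers that are deletion-dominant *and* MSI-H are MMRd-del
  (deletion-dominant POLE genomes ride with the MMRd-del group);
* MSI-H samples go to MMRd-del or MMRd-ins by the dominance sign, with
  MMRd-ins additionally requiring the absence of a hotspot;
* anything else is excluded as unknown status.

A sample with zero exposure for both ID signatures carries no usable indel
signal and is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .mutation_io import CohortAnnotation
from .signature_fit import ExposureTable

SUBTYPES = ("MMRd-del", "MMRd-ins", "PPd", "excluded")
EXCLUSION_REASONS = ("low_indel_burden", "zero_id_signal",
                     "microsatellite_stable", "unknown_status")


@dataclass(frozen=True)
class SubtypeCall:
    sample_id: str
    dominance: float
    subtype: str
    exclusion_reason: Optional[str] = None

    def __post_init__(self):
        if self.subtype not in SUBTYPES:
            raise ValueError(f"bad subtype {self.subtype!r}")
        if (self.subtype == "excluded") != (self.exclusion_reason is not None):
            raise ValueError("exclusion_reason must be set iff subtype is excluded")


def filter_by_indel_burden(burden: pd.DataFrame, annotations: Mapping,
                           exome_min_indels: int = 10,
                           genome_min_indels: int = 1000) -> tuple:
    """Split samples into (retained ids, {excluded id: reason}).

    Exome samples are retained iff ``indel_count >= exome_min_indels``;
    genome samples iff ``indel_count > genome_min_indels`` (strict).
    """
    retained, excluded = [], {}
    for sid, row in burden.iterrows():
        ann = annotations.get(sid)
        if ann is None:
            raise KeyError(f"sample {sid!r} missing from annotations")
        if ann.platform == "exome":
            keep = row["indel_count"] >= exome_min_indels
        elif ann.platform == "genome":
            keep = row["indel_count"] > genome_min_indels
        else:  # pragma: no cover - CohortAnnotation already validates
            raise ValueError(f"unknown platform {ann.platform!r}")
        if keep:
            retained.append(sid)
        else:
            excluded[sid] = "low_indel_burden"
    return retained, excluded


def dominance_score(exposures: ExposureTable, ins_signature: str = "ID1",
                    del_signature: str = "ID2") -> pd.Series:
    """Raw insertion-signature exposure minus raw deletion-signature exposure."""
    ins = exposures.raw_series(ins_signature)
    dele = exposures.raw_series(del_signature)
    return (ins - dele).rename("dominance")


def zero_id_signal(exposures: ExposureTable, ins_signature: str = "ID1",
                   del_signature: str = "ID2") -> pd.Series:
    """Boolean series: neither ID signature has any exposure in the sample."""
    ins = exposures.raw_series(ins_signature)
    dele = exposures.raw_series(del_signature)
    return ((ins == 0) & (dele == 0)).rename("zero_id_signal")


def assign_subtype(sample_id: str, dominance: float, annotation: CohortAnnotation,
                   no_id_signal: bool = False) -> SubtypeCall:
    """Apply the decision tree to one burden-filtered sample."""
    if no_id_signal:
        return SubtypeCall(sample_id, dominance, "excluded", "zero_id_signal")
    if annotation.msi_status == "MSS":
        return SubtypeCall(sample_id, dominance, "excluded", "microsatellite_stable")
    if annotation.ppd_hotspot and dominance > 0:
        return SubtypeCall(sample_id, dominance, "PPd")
    if annotation.ppd_hotspot and dominance <= 0 and annotation.msi_status == "MSI-H":
        return SubtypeCall(sample_id, dominance, "MMRd-del")
    if annotation.msi_status == "MSI-H":
        if dominance > 0:  # MMRd-ins requires no hotspot, enforced above
            return SubtypeCall(sample_id, dominance, "MMRd-ins")
        return SubtypeCall(sample_id, dominance, "MMRd-del")
    return SubtypeCall(sample_id, dominance, "excluded", "unknown_status")


def classify_cohort(burden: pd.DataFrame, exposures: ExposureTable,
                    annotations: Mapping, ins_signature: str = "ID1",
                    del_signature: str = "ID2", exome_min_indels: int = 10,
                    genome_min_indels: int = 1000) -> list:
    """Run the full workflow; every input sample gets exactly one call."""
    retained, low = filter_by_indel_burden(burden, annotations,
                                           exome_min_indels, genome_min_indels)
    dom = dominance_score(exposures, ins_signature, del_signature)
    nosig = zero_id_signal(exposures, ins_signature, del_signature)
    calls = []
    for sid in burden.index:
        if sid in low:
            calls.append(SubtypeCall(sid, float(dom.get(sid, 0.0)),
                                     "excluded", "low_indel_burden"))
            continue
        calls.append(assign_subtype(sid, float(dom[sid]), annotations[sid],
                                    bool(nosig[sid])))
    return calls


def order_cohort(calls: Iterable[SubtypeCall]) -> list:
    """Samples by descending dominance; ties broken lexicographically."""
    return [c.sample_id for c in sorted(calls, key=lambda c: (-c.dominance, c.sample_id))]


def calls_to_frame(calls: Iterable[SubtypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(sample_id=c.sample_id, dominance=c.dominance, subtype=c.subtype,
              exclusion_reason=c.exclusion_reason or "") for c in calls]
    ).set_index("sample_id")
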