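"""Synthetic cohorts with known ground truth for every pipeline stage.

Two layers:

* **Sequence planting.**  Catalog sampling alone cannot exercise the
  context classifiers, so for every ID83 or SBS96 channel a locus is
  synthesised whose local sequence *forces* that channel: a minimal witness
  (homopolymer run, exact tandem copies, exact microhomology) flanked by
  guard bases chosen so that no run, repeat copy or homology extends past
  the witness, with random spacer sequence between loci.  The emitted
  truth label is therefore correct by construction.

* **Cohort simulation.**  Samples are drawn from subtype archetypes
  (signature-exposure profiles plus burden ranges, MSI status and
  POLE/POLD1 hotspot flags); channel counts are multinomial draws from
  ``signatures @ profile``; mutations are planted on per-sample contigs;
  expression, neoantigen and SV tables carry planted effects with recorded
  truth.  Everything is reproducible from a single integer seed.

The module also generates the bundled *synthetic* reference signature
matrices (stand-ins for the COSMIC v3 ID/SBS references, with the
field-standard structure: ID1 = 1 bp insertions at T homopolymers, ID2 =
1 bp deletions, an SBS10-like column spiking T[C>A]T and T[C>T]C, etc.).
These are fixtures, not biological claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort_stats import NeoantigenRecord
from .indel_catalog import ID83_LABELS
from .mutation_io import (
    COMPLEMENT,
    CohortAnnotation,
    MutationRecord,
    write_annotations,
    write_mutations,
)
from .sbs_catalog import SBS96_LABELS
from .signature_fit import SignatureMatrix
from .sv_classify import SVRecord, write_sv_table

_BASES = "ACGT"
_SIGNATURE_NOISE_SEED = 774001  # fixed: the reference matrices are constants


# ---------------------------------------------------------------------------
# synthetic reference signature matrices
# ---------------------------------------------------------------------------

_ID_CHARACTERISTIC = {
    "ID1": {"1:Ins:T:5": 0.50, "1:Ins:T:4": 0.30, "1:Ins:C:5": 0.10, "1:Ins:T:3": 0.10},
    "ID2": {"1:Del:T:5": 0.55, "1:Del:T:4": 0.25, "1:Del:C:5": 0.10, "1:Del:T:3": 0.10},
    "ID3": {"1:Del:C:0": 0.40, "1:Del:C:1": 0.30, "1:Del:T:0": 0.15, "2:Del:R:0": 0.15},
    "ID4": {"2:Del:R:2": 0.30, "3:Del:R:1": 0.25, "2:Del:M:1": 0.25, "3:Del:M:1": 0.20},
    "ID5": {"1:Del:T:1": 0.35, "1:Del:T:2": 0.35, "1:Del:C:2": 0.30},
    "ID6": {"5:Del:M:2": 0.30, "5:Del:M:3": 0.25, "4:Del:M:2": 0.25, "5:Del:M:4": 0.20},
    "ID7": {"1:Del:T:3": 0.50, "1:Del:C:3": 0.30, "1:Del:T:2": 0.20},
    "ID8": {"5:Del:R:0": 0.30, "4:Del:R:0": 0.30, "3:Del:R:0": 0.20, "5:Del:M:1": 0.20},
    "ID9": {"1:Ins:C:0": 0.35, "5:Del:R:1": 0.35, "1:Ins:C:1": 0.30},
    "ID10": {"5:Ins:R:0": 0.40, "4:Ins:R:0": 0.30, "5:Ins:R:1": 0.30},
    "ID11": {"1:Ins:C:2": 0.40, "1:Ins:C:3": 0.30, "1:Ins:T:0": 0.30},
    "ID12": {"2:Ins:R:1": 0.40, "2:Ins:R:2": 0.30, "3:Ins:R:1": 0.30},
    "ID13": {"1:Del:T:0": 0.60, "1:Ins:T:1": 0.40},
    "ID14": {"4:Ins:R:1": 0.40, "4:Ins:R:2": 0.35, "3:Ins:R:2": 0.25},
    "ID15": {"2:Del:R:1": 0.55, "2:Del:R:3": 0.45},
    "ID16": {"3:Ins:R:0": 0.50, "2:Ins:R:0": 0.50},
    "ID17": {"4:Del:R:1": 0.50, "4:Del:R:2": 0.50},
    "ID18": {"3:Del:R:2": 0.50, "2:Ins:R:5": 0.50},
}

_SBS_CHARACTERISTIC = {
    "SBS1": {f"{x}[C>T]G": 0.25 for x in _BASES},
    "SBS5": {},  # flat, noise-dominated background
    "SBS6": {"G[C>T]A": 0.2, "G[C>T]C": 0.2, "G[C>T]G": 0.2, "G[C>T]T": 0.2,
             "C[C>T]A": 0.2},
    "SBS10a": {"T[C>A]T": 0.70, "T[C>A]A": 0.20, "C[C>A]T": 0.10},
    "SBS10b": {"T[C>T]C": 0.60, "T[C>T]T": 0.25, "C[C>T]C": 0.15},
    "SBS14": {"A[C>A]A": 0.35, "T[C>T]A": 0.35, "A[C>A]T": 0.30},
    "SBS15": {"A[C>T]A": 0.30, "A[C>T]T": 0.30, "T[C>T]G": 0.40},
    "SBS20": {"C[C>A]C": 0.40, "C[C>T]T": 0.35, "G[C>A]G": 0.25},
    "SBS21": {"G[T>C]C": 0.40, "A[T>C]C": 0.35, "C[T>C]C": 0.25},
    "SBS26": {"A[T>C]T": 0.40, "C[T>C]T": 0.35, "T[T>C]T": 0.25},
    "SBS44": {"A[C>T]C": 0.40, "G[C>T]T": 0.35, "C[C>T]G": 0.25},
}


def _build_signature_matrix(channel_labels, characteristic, noise_weight=0.15):
    rng = np.random.default_rng(_SIGNATURE_NOISE_SEED)
    index = {l: i for i, l in enumerate(channel_labels)}
    columns = {}
    for name, channels in characteristic.items():
        core = np.zeros(len(channel_labels))
        for label, w in channels.items():
            core[index[label]] = w
        noise = rng.dirichlet(np.ones(len(channel_labels)))
        if core.sum() == 0:  # flat signature
            col = noise
        else:
            col = (1 - noise_weight) * core / core.sum() + noise_weight * noise
        columns[name] = col / col.sum()
    names = list(characteristic)
    weights = np.column_stack([columns[n] for n in names])
    return SignatureMatrix(list(channel_labels), names, weights)


def synthetic_id83_signatures() -> SignatureMatrix:
    """The bundled 18-column synthetic ID83 reference matrix (deterministic)."""
    return _build_signature_matrix(ID83_LABELS, _ID_CHARACTERISTIC)


def synthetic_sbs96_signatures() -> SignatureMatrix:
    """The bundled synthetic SBS96 reference matrix (deterministic)."""
    return _build_signature_matrix(SBS96_LABELS, _SBS_CHARACTERISTIC)


# ---------------------------------------------------------------------------
# channel -> forcing sequence context
# ---------------------------------------------------------------------------

def _random_seq(rng, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _base_not(rng, *excluded) -> str:
    choices = [b for b in _BASES if b not in excluded]
    return choices[rng.integers(0, len(choices))]


def _random_unit(rng, length: int) -> str:
    """Random DNA word of the given length with at least two distinct bases."""
    while True:
        unit = _random_seq(rng, length)
        if len(set(unit)) >= 2:
            return unit


def _id83_locus(label: str, rng) -> tuple:
    """Construct ``(sequence, event_offset, ref, alt)`` forcing ``label``.

    ``event_offset`` is the 0-based index within ``sequence`` of the first
    deleted base (DEL) or of the anchor base 5' of the insertion (INS).
    Guard bases at both ends stop any run/repeat/homology from leaking into
    neighbouring sequence.
    """
    size_s, kind, cls, suffix_s = label.split(":")
    suffix = int(suffix_s)

    if size_s == "1":
        pyr = cls  # C or T
        base = pyr if rng.integers(0, 2) == 0 else pyr.translate(COMPLEMENT)
        if kind == "Del":
            run = suffix + 1 if suffix < 5 else 6 + int(rng.integers(0, 3))
            g1 = _base_not(rng, base)
            g2 = _base_not(rng, base)
            return g1 + base * run + g2, 1, base, "-"
        run = suffix if suffix < 5 else 5 + int(rng.integers(0, 3))
        anchor = _base_not(rng, base)
        g2 = _base_not(rng, base)
        return anchor + base * run + g2, 0, "-", base

    length = int(size_s)
    if length == 5:
        length = 5 + int(rng.integers(0, 2))

    if cls == "R" and kind == "Del":
        copies = suffix + 1 if suffix < 5 else 6 + int(rng.integers(0, 2))
        unit = _random_unit(rng, length)
        g1 = _base_not(rng, unit[-1])
        g2 = _base_not(rng, unit[0])
        return g1 + unit * copies + g2, 1, unit, "-"

    if cls == "R" and kind == "Ins":
        copies = suffix if suffix < 5 else 5 + int(rng.integers(0, 2))
        unit = _random_unit(rng, length)
        anchor = _base_not(rng, unit[-1])
        g2 = _base_not(rng, unit[0])
        return anchor + unit * copies + g2, 0, "-", unit

    # microhomology deletion: exact m bases of prefix homology on the right
    m = suffix
    if size_s == "5" and m >= 5:
        length = 6 + int(rng.integers(0, 2))
    deleted = _random_unit(rng, length)
    g1 = _base_not(rng, deleted[-1])
    g2 = _base_not(rng, deleted[m])
    return g1 + deleted + deleted[:m] + g2, 1, deleted, "-"


def _sbs96_locus(label: str, rng) -> tuple:
    """``(sequence, event_offset, ref, alt)`` forcing an SBS96 channel;
    half the loci are written on the purine strand."""
    five, mid, three = label[0], label[2:5], label[6]
    ref_base, alt_base = mid[0], mid[2]
    triplet = five + ref_base + three
    if rng.integers(0, 2) == 1:
        triplet = triplet.translate(COMPLEMENT)[::-1]
        ref_base = ref_base.translate(COMPLEMENT)
        alt_base = alt_base.translate(COMPLEMENT)
    g1 = _random_seq(rng, 1)
    g2 = _random_seq(rng, 1)
    return g1 + triplet + g2, 2, ref_base, alt_base


@dataclass
class PlantedMutations:
    """A synthetic contig plus the records planted on it, with truth labels."""

    contig: str
    sequence: str
    records: list
    truth_labels: list  # parallel to records: the intended channel label


def plant_mutations(id_targets, sbs_targets, seed_or_rng=0, sample_id: str = "SIM",
                    contig: str = "ctg_sim", spacing: int = 100) -> PlantedMutations:
    """Plant indel and/or SNV channel witnesses along one contig.

    Loci are separated by at least ``spacing`` bases of random spacer so
    planted contexts cannot interact.
    """
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    parts, records, truth = [], [], []
    pos = 0
    jobs = [("ID", l) for l in id_targets] + [("SBS", l) for l in sbs_targets]
    for family, label in jobs:
        spacer = _random_seq(rng, spacing)
        parts.append(spacer)
        pos += len(spacer)
        seq, offset, ref, alt = (_id83_locus if family == "ID" else _sbs96_locus)(label, rng)
        parts.append(seq)
        if ref == "-":
            vclass = "INS"
        elif alt == "-":
            vclass = "DEL"
        else:
            vclass = "SNV"
        records.append(MutationRecord(
            sample_id=sample_id, chrom=contig, pos=pos + offset + 1,
            ref=ref, alt=alt, variant_class=vclass))
        truth.append(label)
        pos += len(seq)
    parts.append(_random_seq(rng, spacing))
    return PlantedMutations(contig, "".join(parts), records, truth)


def plant_indels(channel_targets, seed_or_rng=0, sample_id: str = "SIM",
                 contig: str = "ctg_sim", spacing: int = 100) -> PlantedMutations:
    """Plant one indel per requested ID83 label (see :func:`plant_mutations`)."""
    for label in channel_targets:
        if label not in ID83_LABELS:
            raise ValueError(f"unknown ID83 label {label!r}")
    return plant_mutations(channel_targets, [], seed_or_rng, sample_id, contig, spacing)


# ---------------------------------------------------------------------------
# archetypes and cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubtypeArchetype:
    """The generative caricature of one subtype; fixtures, not biology."""

    name: str
    id_profile: dict
    sbs_profile: dict
    indel_count_range: tuple
    snv_count_range: tuple
    msi_status: str
    ppd_hotspot: bool
    neoantigen_rate: float
    sv_rates: dict


def default_archetypes() -> dict:
    """Archetypes for an exome-scale cohort.

    MMRd archetypes carry the bulk of their indel mass on the deletion
    (ID2-type) or insertion (ID1-type) slippage signature; the PPd
    archetype is insertion-dominant with a much higher substitution burden
    dominated by the SBS10-like column; MSS samples sit above the burden
    filter but are excluded by annotation.
    """
    return {
        "MMRd-del": SubtypeArchetype(
            name="MMRd-del",
            id_profile={"ID2": 0.65, "ID1": 0.05, "ID5": 0.15, "ID4": 0.15},
            sbs_profile={"SBS6": 0.35, "SBS15": 0.20, "SBS1": 0.25, "SBS5": 0.20},
            indel_count_range=(50, 300), snv_count_range=(100, 400),
            msi_status="MSI-H", ppd_hotspot=False, neoantigen_rate=8.0,
            sv_rates={"DEL_small": 0.8, "DEL_mid": 0.8, "DEL_large": 0.3,
                      "DUP_small": 0.5, "DUP_mid": 0.5, "reciprocal_inv": 0.4,
                      "fold_back_inv": 0.2, "reciprocal_tra": 0.4,
                      "unbalanced_tra": 0.3}),
        "MMRd-ins": SubtypeArchetype(
            name="MMRd-ins",
            id_profile={"ID1": 0.60, "ID2": 0.10, "ID5": 0.15, "ID9": 0.15},
            sbs_profile={"SBS6": 0.20, "SBS15": 0.20, "SBS26": 0.40, "SBS5": 0.20},
            indel_count_range=(50, 300), snv_count_range=(100, 400),
            msi_status="MSI-H", ppd_hotspot=False, neoantigen_rate=25.0,
            sv_rates={"DEL_small": 4.0, "DEL_mid": 1.0, "DEL_large": 0.2,
                      "DUP_small": 3.0, "DUP_mid": 0.5, "reciprocal_inv": 0.4,
                      "fold_back_inv": 0.2, "reciprocal_tra": 0.4,
                      "unbalanced_tra": 0.3}),
        "PPd": SubtypeArchetype(
            name="PPd",
            id_profile={"ID1": 0.55, "ID2": 0.05, "ID12": 0.20, "ID10": 0.20},
            sbs_profile={"SBS10a": 0.35, "SBS10b": 0.25, "SBS5": 0.25, "SBS1": 0.15},
            indel_count_range=(30, 120), snv_count_range=(600, 2000),
            msi_status="unknown", ppd_hotspot=True, neoantigen_rate=30.0,
            sv_rates={"DEL_small": 0.5, "DEL_mid": 0.3, "DUP_small": 0.3,
                      "reciprocal_inv": 0.2, "reciprocal_tra": 0.2}),
        "MSS": SubtypeArchetype(
            name="MSS",
            id_profile={"ID5": 0.40, "ID8": 0.30, "ID3": 0.30},
            sbs_profile={"SBS5": 0.60, "SBS1": 0.40},
            indel_count_range=(12, 40), snv_count_range=(50, 200),
            msi_status="MSS", ppd_hotspot=False, neoantigen_rate=2.0,
            sv_rates={"DEL_small": 0.3, "DEL_mid": 0.3, "DUP_small": 0.2,
                      "reciprocal_inv": 0.1, "reciprocal_tra": 0.1}),
    }


def _profile_vector(profile: dict, signatures: SignatureMatrix) -> np.ndarray:
    vec = np.zeros(len(signatures.signature_names))
    for name, w in profile.items():
        vec[signatures.signature_names.index(name)] = w
    total = vec.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError("archetype profile must sum to 1")
    return vec


def simulate_catalog(profile, signatures: SignatureMatrix, n_mutations: int,
                     seed_or_rng=0) -> tuple:
    """Multinomial channel counts from a signature mixture.

    ``profile`` is a {signature: weight} dict (weights summing to 1) or a
    vector over ``signatures.signature_names``.  Returns ``(counts,
    true_exposures)`` where the exposures are on the count scale
    (``n_mutations`` times the profile).
    """
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) \
        else np.random.default_rng(seed_or_rng)
    if isinstance(profile, dict):
        profile = _profile_vector(profile, signatures)
    probs = signatures.weights @ np.asarray(profile, dtype=float)
    probs = probs / probs.sum()
    counts = rng.multinomial(int(n_mutations), probs)
    return counts, n_mutations * np.asarray(profile, dtype=float)


@dataclass
class CohortConfig:
    """Study conditions for the default synthetic cohort (exome scale)."""

    n_per_subtype: dict = field(default_factory=lambda: {
        "MMRd-del": 40, "MMRd-ins": 8, "PPd": 10, "MSS": 20})
    platform: str = "exome"
    callable_mb: Optional[float] = None  # 38 (exome) / 2800 (genome)
    tumor_type: str = "SYNTH"
    n_genes: int = 300
    n_deg: int = 25
    deg_lfc: float = 2.0
    deg_sigma: float = 0.5
    expression_baseline: tuple = (4.0, 9.0)
    n_enriched_genes: int = 4       # per indel kind
    enrichment_p_high: float = 0.8
    enrichment_p_low: float = 0.05
    n_recurrent_neo_genes: int = 5
    recurrent_neo_p_target: float = 0.75
    recurrent_neo_p_other: float = 0.10
    spacing: int = 100

    def resolved_callable_mb(self) -> float:
        if self.callable_mb is not None:
            return self.callable_mb
        return 38.0 if self.platform == "exome" else 2800.0


@dataclass
class SyntheticTruth:
    subtype: dict
    id_exposures: pd.DataFrame
    sbs_exposures: pd.DataFrame
    record_channels: list
    deg_genes: list
    deg_lfc: float
    enriched_del_genes: list
    enriched_ins_genes: list
    recurrent_neo_genes: list


@dataclass
class SimulatedCohort:
    """Everything the pipeline reads, plus the generating truth."""

    records: list
    reference: dict
    annotations: dict
    expression: pd.DataFrame
    neoantigens: list
    svs: list
    truth: SyntheticTruth
    config: CohortConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_mutations(self.records, outdir / "mutations.tsv")
        write_annotations(self.annotations, outdir / "annotations.tsv")
        self.expression.to_csv(outdir / "expression.tsv", sep="\t")
        pd.DataFrame([
            dict(sample=r.sample_id, gene=r.gene, mutation_class=r.mutation_class,
                 ic50_nm=r.ic50_nm, expressed=r.expressed) for r in self.neoantigens
        ]).to_csv(outdir / "neoantigens.tsv", sep="\t", index=False)
        write_sv_table(self.svs, outdir / "svs.tsv")
        with open(outdir / "reference.fa", "w") as fh:
            for name, seq in self.reference.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")


_SV_SIZE_RANGES = {"small": (1_000, 1_000_000), "mid": (1_000_001, 10_000_000),
                   "large": (10_000_001, 50_000_000)}


def _make_sv(rng, sample_id: str, category: str) -> SVRecord:
    if category.startswith(("DEL", "DUP")):
        sv_type, size_label = category.split("_")
        lo, hi = _SV_SIZE_RANGES[size_label]
        size = int(rng.integers(lo, hi + 1))
        pos1 = int(rng.integers(1, 100_000_000))
        return SVRecord(sample_id, sv_type, "chr1", pos1, "chr1", pos1 + size)
    pos1 = int(rng.integers(1, 100_000_000))
    if category.endswith("_inv"):
        size = int(rng.integers(1_000, 5_000_000))
        return SVRecord(sample_id, "INV", "chr1", pos1, "chr1", pos1 + size,
                        inv_subtype=category.replace("_inv", ""))
    return SVRecord(sample_id, "TRA", "chr1", pos1, "chr2",
                    int(rng.integers(1, 100_000_000)),
                    tra_subtype=category.replace("_tra", ""))


def simulate_cohort(config: Optional[CohortConfig] = None, seed: int = 0,
                    archetypes: Optional[dict] = None) -> SimulatedCohort:
    """Simulate a full input bundle with ground truth.

    Every mutation's sequence context is planted so that the classifiers'
    output can be checked record by record against the drawn channel.
    """
    config = config or CohortConfig()
    archetypes = archetypes or default_archetypes()
    for name in config.n_per_subtype:
        if name not in archetypes:
            raise ValueError(f"no archetype named {name!r}")
    if config.n_deg + 2 * config.n_enriched_genes + config.n_recurrent_neo_genes \
            > config.n_genes:
        raise ValueError("planted gene sets exceed the gene pool")
    rng = np.random.default_rng(seed)
    id_sig = synthetic_id83_signatures()
    sbs_sig = synthetic_sbs96_signatures()

    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    deg_genes = genes[: config.n_deg]
    k = config.n_deg
    enr_del = genes[k : k + config.n_enriched_genes]
    enr_ins = genes[k + config.n_enriched_genes : k + 2 * config.n_enriched_genes]
    k += 2 * config.n_enriched_genes
    neo_genes = genes[k : k + config.n_recurrent_neo_genes]

    records: list = []
    record_channels: list = []
    reference: dict = {}
    annotations: dict = {}
    neoantigens: list = []
    svs: list = []
    truth_subtype: dict = {}
    id_expo_rows, sbs_expo_rows, sample_order = [], [], []
    callable_mb = config.resolved_callable_mb()

    for subtype in sorted(config.n_per_subtype):
        arch = archetypes[subtype]
        for i in range(config.n_per_subtype[subtype]):
            sid = f"{subtype.replace('-', '')}_{i:03d}"
            sample_order.append(sid)
            truth_subtype[sid] = subtype
            annotations[sid] = CohortAnnotation(
                sample_id=sid, tumor_type=config.tumor_type,
                msi_status=arch.msi_status, ppd_hotspot=arch.ppd_hotspot,
                platform=config.platform, callable_mb=callable_mb)

            lo, hi = arch.indel_count_range
            n_ind = int(rng.integers(lo, hi + 1))
            lo, hi = arch.snv_count_range
            n_snv = int(rng.integers(lo, hi + 1))
            id_counts, id_expo = simulate_catalog(arch.id_profile, id_sig, n_ind, rng)
            sbs_counts, sbs_expo = simulate_catalog(arch.sbs_profile, sbs_sig, n_snv, rng)
            id_expo_rows.append(id_expo)
            sbs_expo_rows.append(sbs_expo)

            id_targets = list(np.repeat(ID83_LABELS, id_counts))
            sbs_targets = list(np.repeat(SBS96_LABELS, sbs_counts))
            planted = plant_mutations(id_targets, sbs_targets, rng, sample_id=sid,
                                      contig=f"ctg_{sid}", spacing=config.spacing)
            reference[planted.contig] = planted.sequence

            # attach genes and consequences; then relabel a few indels onto
            # the planted enrichment genes with subtype-dependent probability
            sample_records = []
            for rec in planted.records:
                if rec.variant_class == "SNV":
                    cons = ["missense", "silent", "nonsense"][
                        rng.choice(3, p=[0.6, 0.25, 0.15])]
                else:
                    cons = "frameshift" if rng.random() < 0.8 else "other"
                sample_records.append(MutationRecord(
                    sample_id=rec.sample_id, chrom=rec.chrom, pos=rec.pos,
                    ref=rec.ref, alt=rec.alt, variant_class=rec.variant_class,
                    gene=genes[rng.integers(0, len(genes))], consequence=cons))
            for gene_set, kind, target_subtype in (
                    (enr_del, "DEL", "MMRd-del"), (enr_ins, "INS", "MMRd-ins")):
                p = config.enrichment_p_high if subtype == target_subtype \
                    else config.enrichment_p_low
                idx = [j for j, r in enumerate(sample_records)
                       if r.variant_class == kind]
                rng.shuffle(idx)
                for gene in gene_set:
                    if rng.random() < p and idx:
                        j = idx.pop()
                        r = sample_records[j]
                        sample_records[j] = MutationRecord(
                            sample_id=r.sample_id, chrom=r.chrom, pos=r.pos,
                            ref=r.ref, alt=r.alt, variant_class=r.variant_class,
                            gene=gene, consequence="frameshift")
            records.extend(sample_records)
            record_channels.extend(planted.truth_labels)

            # neoantigens: background rate plus planted recurrent genes
            n_neo = rng.poisson(arch.neoantigen_rate)
            for _ in range(n_neo):
                neoantigens.append(NeoantigenRecord(
                    sample_id=sid, gene=genes[rng.integers(0, len(genes))],
                    mutation_class=["SNV", "INS", "DEL"][rng.choice(3)],
                    ic50_nm=float(np.exp(rng.normal(np.log(60.0), 1.2))),
                    expressed=bool(rng.random() < 0.7)))
            p_neo = config.recurrent_neo_p_target if subtype == "MMRd-ins" \
                else config.recurrent_neo_p_other
            for gene in neo_genes:
                if rng.random() < p_neo:
                    neoantigens.append(NeoantigenRecord(
                        sample_id=sid, gene=gene, mutation_class="INS",
                        ic50_nm=float(rng.uniform(5.0, 45.0)), expressed=True))

            for category, rate in arch.sv_rates.items():
                for _ in range(rng.poisson(rate)):
                    svs.append(_make_sv(rng, sid, category))

    # expression: log2-scale baselines with a planted shift in MMRd-ins
    baseline = rng.uniform(*config.expression_baseline, size=config.n_genes)
    expr = rng.normal(baseline[:, None], config.deg_sigma,
                      size=(config.n_genes, len(sample_order)))
    expression = pd.DataFrame(expr, index=genes, columns=sample_order)
    ins_cols = [s for s in sample_order if truth_subtype[s] == "MMRd-ins"]
    expression.loc[deg_genes, ins_cols] += config.deg_lfc

    truth = SyntheticTruth(
        subtype=truth_subtype,
        id_exposures=pd.DataFrame(id_expo_rows, index=sample_order,
                                  columns=id_sig.signature_names),
        sbs_exposures=pd.DataFrame(sbs_expo_rows, index=sample_order,
                                   columns=sbs_sig.signature_names),
        record_channels=record_channels,
        deg_genes=list(deg_genes), deg_lfc=config.deg_lfc,
        enriched_del_genes=list(enr_del), enriched_ins_genes=list(enr_ins),
        recurrent_neo_genes=list(neo_genes))
    return SimulatedCohort(records, reference, annotations, expression,
                           neoantigens, svs, truth, config)
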