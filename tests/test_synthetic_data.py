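import numpy as np
import pandas as pd
import pytest

from msisig import (
    ID83_LABELS,
    SBS96_LABELS,
    assign_id83_channel,
    assign_sbs96_channel,
    cosine_similarity,
    load_reference,
    plant_indels,
    plant_mutations,
    refit_exposures,
    simulate_catalog,
    simulate_cohort,
    synthetic_id83_signatures,
    synthetic_sbs96_signatures,
)
from msisig.indel_catalog import MutationalCatalog
from msisig.synthetic_data import CohortConfig


class TestSignatureGenerators:
    def test_generators_match_bundled_files(self):
        for generator, kind in ((synthetic_id83_signatures, "ID83"),
                                (synthetic_sbs96_signatures, "SBS96")):
            generated = generator()
            bundled = load_reference(kind)
            assert generated.signature_names == bundled.signature_names
            np.testing.assert_allclose(generated.weights, bundled.weights, atol=1e-12)

    def test_id_matrix_full_column_rank(self):
        sig = synthetic_id83_signatures()
        assert np.linalg.matrix_rank(sig.weights) == 18


class TestSimulateCatalog:
    def test_zero_mutations_gives_zero_vector(self, id_signatures):
        counts, expo = simulate_catalog({"ID1": 1.0}, id_signatures, 0, 1)
        assert counts.sum() == 0 and expo.sum() == 0

    def test_identical_seeds_identical_draws(self, id_signatures):
        c1, _ = simulate_catalog({"ID1": 0.5, "ID2": 0.5}, id_signatures, 500, 42)
        c2, _ = simulate_catalog({"ID1": 0.5, "ID2": 0.5}, id_signatures, 500, 42)
        assert np.array_equal(c1, c2)

    def test_large_sample_converges_to_signature_column(self, id_signatures):
        counts, _ = simulate_catalog({"ID2": 1.0}, id_signatures, 1_000_000, 7)
        empirical = counts / counts.sum()
        l1 = np.abs(empirical - id_signatures.column("ID2")).sum()
        assert l1 < 0.01


class TestPlanting:
    def test_all_83_channels_constructible_and_recovered(self):
        planted = plant_indels(list(ID83_LABELS), seed_or_rng=1)
        ref = {planted.contig: planted.sequence}
        assert len(planted.records) == 83
        for rec, truth in zip(planted.records, planted.truth_labels):
            assert assign_id83_channel(rec, ref).label == truth

    def test_all_96_snv_channels_recovered(self):
        planted = plant_mutations([], list(SBS96_LABELS), seed_or_rng=1)
        ref = {planted.contig: planted.sequence}
        for rec, truth in zip(planted.records, planted.truth_labels):
            assert assign_sbs96_channel(rec, ref).label == truth

    def test_microhomology_witness_structure(self):
        planted = plant_indels(["4:Del:M:2"], seed_or_rng=8)
        rec = planted.records[0]
        seq = planted.sequence
        deleted = seq[rec.pos - 1 : rec.pos + 3]
        right = seq[rec.pos + 3 :]
        assert rec.ref == deleted and len(deleted) == 4
        assert right.startswith(deleted[:2]) and not right.startswith(deleted[:3])
        assert not right.startswith(deleted)  # no tandem copy

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown ID83 label"):
            plant_indels(["9:Del:Z:9"])

    def test_seed_stability(self):
        a = plant_indels(["1:Del:T:5", "3:Ins:R:2"], seed_or_rng=13)
        b = plant_indels(["1:Del:T:5", "3:Ins:R:2"], seed_or_rng=13)
        assert a.sequence == b.sequence and a.records == b.records


class TestCohort:
    def test_truth_covers_every_record(self, cohort):
        assert len(cohort.truth.record_channels) == len(cohort.records)
        for rec, label in zip(cohort.records, cohort.truth.record_channels):
            family = "SBS" if rec.variant_class == "SNV" else "ID"
            assert label in (SBS96_LABELS if family == "SBS" else ID83_LABELS)

    def test_generator_and_classifiers_agree_on_every_mutation(self, cohort):
        subset = list(zip(cohort.records, cohort.truth.record_channels))[::7]
        for rec, truth in subset:
            if rec.variant_class == "SNV":
                got = assign_sbs96_channel(rec, cohort.reference)
            else:
                got = assign_id83_channel(rec, cohort.reference)
            assert got.label == truth

    def test_exposure_refit_converges_to_archetype(self, id_signatures):
        profile = {"ID1": 0.60, "ID2": 0.10, "ID5": 0.15, "ID9": 0.15}
        counts, e_star = simulate_catalog(profile, id_signatures, 10_000, 3)
        catalog = MutationalCatalog(["S"], list(ID83_LABELS), np.atleast_2d(counts))
        table = refit_exposures(catalog, id_signatures)
        assert cosine_similarity(table.raw[0], e_star) >= 0.99

    def test_full_determinism_byte_identical(self, tmp_path):
        a = simulate_cohort(CohortConfig(n_per_subtype={"MMRd-del": 2, "MSS": 2}),
                            seed=5)
        b = simulate_cohort(CohortConfig(n_per_subtype={"MMRd-del": 2, "MSS": 2}),
                            seed=5)
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        for name in ("mutations.tsv", "annotations.tsv", "expression.tsv",
                     "neoantigens.tsv", "svs.tsv", "reference.fa"):
            assert (tmp_path / "a" / name).read_bytes() \
                == (tmp_path / "b" / name).read_bytes()

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError, match="gene pool"):
            simulate_cohort(CohortConfig(n_genes=10, n_deg=20), seed=0)

    def test_planted_degs_recovered(self, cohort):
        from msisig import select_degs

        truth = cohort.truth
        ins = [s for s, t in truth.subtype.items() if t == "MMRd-ins"]
        dele = [s for s, t in truth.subtype.items() if t == "MMRd-del"]
        out = select_degs(cohort.expression, ins, dele)
        sensitivity = out.loc[truth.deg_genes, "selected"].mean()
        assert sensitivity >= 0.95

    def test_planted_enrichment_genes_significant(self, cohort):
        from msisig import gene_enrichment, truncating_indel_matrix

        truth = cohort.truth
        ins = [s for s, t in truth.subtype.items() if t == "MMRd-ins"]
        dele = [s for s, t in truth.subtype.items() if t == "MMRd-del"]
        mat = truncating_indel_matrix(cohort.records, kind="DEL")
        out = gene_enrichment(mat, dele, ins)
        present = [g for g in truth.enriched_del_genes if g in out.index]
        assert present and out.loc[present, "significant"].mean() >= 0.5
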