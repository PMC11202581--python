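import numpy as np
import pytest

from msisig import (
    ID83_LABELS,
    MutationRecord,
    ReferenceWindow,
    assign_id83_channel,
    build_id_catalog,
    homopolymer_run,
    left_align,
    microhomology_length,
    plant_indels,
    repeat_unit_count,
)
from oracle_id83 import oracle_id83


class TestChannelSpace:
    def test_decomposition(self):
        assert len(ID83_LABELS) == len(set(ID83_LABELS)) == 83
        groups = {
            "1bp_del": [l for l in ID83_LABELS if l.startswith("1:Del")],
            "1bp_ins": [l for l in ID83_LABELS if l.startswith("1:Ins")],
            "rep_del": [l for l in ID83_LABELS if ":Del:R" in l],
            "rep_ins": [l for l in ID83_LABELS
                        if ":Ins:R" in l and not l.startswith("1:")],
            "mh_del": [l for l in ID83_LABELS if ":Del:M" in l],
        }
        assert [len(groups[k]) for k in
                ("1bp_del", "1bp_ins", "rep_del", "rep_ins", "mh_del")] \
            == [12, 12, 24, 24, 11]


class TestContextPrimitives:
    def test_deletion_run_counts_deleted_base(self):
        w = ReferenceWindow("c", 1, 10, "AATTTTTGGC")
        assert homopolymer_run(w, 5, "T", "DEL") == 5

    def test_insertion_with_no_adjacent_copy_is_zero(self):
        w = ReferenceWindow("c", 1, 4, "AGGA")
        assert homopolymer_run(w, 1, "T", "INS") == 0

    def test_run_matches_linear_scan_on_random_sequences(self, rng):
        for _ in range(200):
            seq = "".join(rng.choice(list("AT"), size=30))
            site = int(rng.integers(1, 31))
            base = seq[site - 1]
            w = ReferenceWindow("c", 1, 30, seq)
            # oracle: expand left/right from the site
            j = k = site - 1
            while j > 0 and seq[j - 1] == base:
                j -= 1
            while k < 29 and seq[k + 1] == base:
                k += 1
            assert homopolymer_run(w, site, base, "DEL") == k - j + 1

    def test_tandem_copies_counted_rightward(self):
        assert repeat_unit_count("AC", "GG", "ACACGGTT", "DEL") == 3
        assert repeat_unit_count("CAG", "GG", "TTTTTT", "INS") == 0

    def test_copies_unaffected_by_far_flank(self):
        assert repeat_unit_count("AC", "GG", "ACACGG" + "AC" * 5, "DEL") == 3

    def test_microhomology_prefix_and_suffix_sides(self):
        assert microhomology_length("ACGT", "GGGG", "ACTT") == 2
        assert microhomology_length("ACGT", "GGAT", "TTTT") == 1   # suffix side
        assert microhomology_length("ACGT", "GGAT", "ACTT") == 2   # max of both

    def test_microhomology_vs_enumeration(self, rng):
        for _ in range(300):
            d = "".join(rng.choice(list("ACGT"), size=int(rng.integers(2, 7))))
            left = "".join(rng.choice(list("ACGT"), size=8))
            right = "".join(rng.choice(list("ACGT"), size=8))
            best = 0
            for j in range(1, len(d)):
                if right[:j] == d[:j]:
                    best = max(best, j)
                if left[-j:] == d[-j:]:
                    best = max(best, j)
            assert microhomology_length(d, left, right) == best


class TestChannelAssignment:
    @pytest.mark.parametrize("seq,pos,ref,alt,expected", [
        # delete one A inside a 7-A run: pyrimidine-normalised to T, bin 6+
        ("TTAAAAAAACC", 3, "A", "-", "1:Del:T:5"),
        # insert TA where TA does not occur adjacently
        ("GGGGG", 2, "-", "TA", "2:Ins:R:0"),
        # 4 bp deletion, no tandem copy, 2 bp right homology
        ("GACGTACTTGG", 2, "ACGT", "-", "4:Del:M:2"),
        # single T deletion from a lone T
        ("GATGC", 3, "T", "-", "1:Del:T:0"),
        # 2 bp deletion of one of three tandem copies
        ("GACACACTT", 2, "AC", "-", "2:Del:R:2"),
    ])
    def test_forced_contexts(self, seq, pos, ref, alt, expected):
        vclass = "INS" if ref == "-" else "DEL"
        rec = MutationRecord("S", "c", pos, ref, alt, vclass)
        channel = assign_id83_channel(rec, {"c": seq})
        assert channel.label == expected
        assert ID83_LABELS[channel.index] == expected

    def test_n_in_decisive_context_is_unclassifiable(self):
        rec = MutationRecord("S", "c", 3, "T", "-", "DEL")
        assert assign_id83_channel(rec, {"c": "GGTNTCC"}) is None

    def test_one_bp_events_are_strand_symmetric(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(50):
            run = int(rng.integers(1, 9))
            base = "ACGT"[rng.integers(0, 4)]
            other = [b for b in "ACGT" if b != base][rng.integers(0, 3)]
            seq = other + base * run + other
            rec = MutationRecord("S", "c", 2, base, "-", "DEL")
            fwd = assign_id83_channel(rec, {"c": seq})
            rc_seq = seq.translate(comp)[::-1]
            rc_pos = len(seq) - (2 + run - 1) + 1  # leftmost run base on rc
            rc = MutationRecord("S", "c", rc_pos, base.translate(comp), "-", "DEL")
            rev = assign_id83_channel(rc, {"c": rc_seq})
            assert fwd.label == rev.label

    def test_left_shift_never_changes_channel(self, rng):
        """Any position within a slippage equivalence class classifies alike."""
        planted = plant_indels(list(ID83_LABELS), seed_or_rng=3)
        ref = {planted.contig: planted.sequence}
        for rec, label in zip(planted.records, planted.truth_labels):
            if rec.variant_class != "DEL":
                continue
            # re-anchor at the rightmost equivalent position, if any
            seq = planted.sequence
            L = len(rec.ref)
            pos, allele = rec.pos, rec.ref
            while pos + L <= len(seq) and seq[pos + L - 1] == allele[0]:
                allele = allele[1:] + allele[0]
                pos += 1
            shifted = MutationRecord(rec.sample_id, rec.chrom, pos, allele, "-", "DEL")
            assert assign_id83_channel(shifted, ref).label == label


class TestOracleEquivalence:
    def test_planted_indels_match_brute_force(self):
        planted = plant_indels(list(ID83_LABELS) * 6, seed_or_rng=17)
        ref = {planted.contig: planted.sequence}
        for rec, truth in zip(planted.records, planted.truth_labels):
            mine = assign_id83_channel(rec, ref).label
            oracle = oracle_id83(planted.sequence, rec.pos, rec.ref, rec.alt)
            assert mine == oracle == truth


class TestCatalog:
    def test_zero_indels_gives_zero_row(self):
        catalog = build_id_catalog([], {"c": "ACGT"}, sample_ids=["S1"])
        assert catalog.counts.shape == (1, 83) and catalog.counts.sum() == 0

    def test_row_sum_equals_classifiable_count(self, cohort):
        catalog = build_id_catalog(cohort.records, cohort.reference)
        n_indels = sum(r.variant_class != "SNV" for r in cohort.records)
        assert catalog.counts.sum() + sum(catalog.dropped.values()) == n_indels

    def test_tsv_round_trip(self, tmp_path, cohort):
        catalog = build_id_catalog(cohort.records[:500], cohort.reference)
        path = tmp_path / "catalog.tsv"
        catalog.to_tsv(path)
        back = catalog.from_tsv(path)
        assert back.channel_labels == catalog.channel_labels
        assert np.array_equal(back.counts, catalog.counts)
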