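from math import comb

import numpy as np
import pandas as pd
import pytest

from msisig import (
    NeoantigenRecord,
    SubtypeCall,
    gene_enrichment,
    neoantigen_burden,
    recurrent_neoantigen_genes,
    select_degs,
    truncating_indel_matrix,
)
from msisig.cohort_stats import _benjamini_hochberg


def fisher_two_sided_oracle(a, b, c, d):
    """Hypergeometric enumeration: sum table probabilities <= observed."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(r1 + r2, c1)
    def pk(k):
        return comb(r1, k) * comb(r2, c1 - k) / denom
    p_obs = pk(a)
    return sum(pk(k) for k in range(max(0, c1 - r2), min(r1, c1) + 1)
               if pk(k) <= p_obs * (1 + 1e-7))


def _groups(n_a, n_b):
    return [f"A{i}" for i in range(n_a)], [f"B{i}" for i in range(n_b)]


def _matrix(mut_a, n_a, mut_b, n_b, gene="G"):
    ga, gb = _groups(n_a, n_b)
    mat = pd.DataFrame(0, index=[gene], columns=ga + gb, dtype=int)
    mat.loc[gene, ga[:mut_a]] = 1
    mat.loc[gene, gb[:mut_b]] = 1
    return mat, ga, gb


class TestGeneEnrichment:
    def test_perfect_separation_p_value(self):
        mat, ga, gb = _matrix(5, 5, 0, 5)
        out = gene_enrichment(mat, ga, gb)
        assert out.loc["G", "p"] == pytest.approx(2 / 252, abs=1e-12)
        assert out.loc["G", "significant"]

    def test_identical_proportions_give_p_one(self):
        mat, ga, gb = _matrix(3, 6, 3, 6)
        assert gene_enrichment(mat, ga, gb).loc["G", "p"] == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(300):
            a, b = rng.integers(0, 16, size=2)
            c, d = rng.integers(0, 16, size=2)
            if (a + c) == 0 or (a + b) == 0 or (c + d) == 0:
                continue
            mat, ga, gb = _matrix(int(a), int(a + b), int(c), int(c + d))
            p = gene_enrichment(mat, ga, gb).loc["G", "p"]
            assert p == pytest.approx(
                fisher_two_sided_oracle(int(a), int(b), int(c), int(d)), abs=1e-12)

    def test_gene_absent_in_both_flagged(self):
        mat, ga, gb = _matrix(0, 4, 0, 4)
        out = gene_enrichment(mat, ga, gb)
        assert out.loc["G", "p"] == 1.0 and out.loc["G", "absent_in_both"]

    def test_groups_must_be_disjoint(self):
        mat, ga, gb = _matrix(1, 3, 1, 3)
        with pytest.raises(ValueError, match="disjoint"):
            gene_enrichment(mat, ga, ga)

    def test_bh_option_is_monotone_in_p(self, rng):
        p = rng.uniform(size=40)
        q = _benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestTruncatingMatrix:
    def test_only_truncating_indels_count(self):
        from msisig import MutationRecord
        records = [
            MutationRecord("S1", "c", 1, "A", "-", "DEL", gene="G1",
                           consequence="frameshift"),
            MutationRecord("S1", "c", 9, "A", "-", "DEL", gene="G2",
                           consequence="other"),
            MutationRecord("S2", "c", 5, "-", "T", "INS", gene="G1",
                           consequence="frameshift"),
        ]
        mat = truncating_indel_matrix(records)
        assert mat.loc["G1"].tolist() == [1, 1]
        assert "G2" not in mat.index
        ins_only = truncating_indel_matrix(records, kind="INS")
        assert ins_only.loc["G1"].tolist() == [0, 1]


class TestDegSelection:
    def test_planted_shift_selected_and_fc_gate_enforced(self, rng):
        ga, gb = _groups(10, 10)
        base = rng.normal(5, 0.1, size=(3, 20))
        expr = pd.DataFrame(base, index=["big", "small", "null"], columns=ga + gb)
        expr.loc["big", ga] += 3.0     # past both gates
        expr.loc["small", ga] += 0.5   # significant but below the FC gate
        out = select_degs(expr, ga, gb)
        assert bool(out.loc["big", "selected"])
        assert out.loc["small", "p"] < 0.05 and not out.loc["small", "selected"]
        assert not out.loc["null", "selected"]

    def test_null_type_one_error_calibrated(self, rng):
        ga, gb = _groups(10, 10)
        expr = pd.DataFrame(rng.normal(5, 1, size=(1000, 20)), columns=ga + gb)
        out = select_degs(expr, ga, gb)
        assert (out["p"] < 0.05).mean() <= 0.06
        # the joint gate can only remove calls relative to the t-test alone
        assert out["selected"].sum() <= (out["p"] < 0.05).sum()

    def test_zero_variance_handling(self):
        ga, gb = _groups(2, 2)
        expr = pd.DataFrame([[5, 5, 5, 5], [7, 7, 5, 5]],
                            index=["flat", "split"], columns=ga + gb)
        out = select_degs(expr, ga, gb)
        assert out.loc["flat", "p"] == 1.0
        assert out.loc["split", "p"] == 0.0 and out.loc["split", "degenerate"]

    def test_sample_order_invariance(self, rng):
        ga, gb = _groups(5, 5)
        expr = pd.DataFrame(rng.normal(size=(50, 10)), columns=ga + gb)
        out1 = select_degs(expr, ga, gb)
        out2 = select_degs(expr[ga[::-1] + gb[::-1]], ga[::-1], gb[::-1])
        np.testing.assert_allclose(out1["p"], out2["p"])


def _neo_calls():
    return [SubtypeCall("I1", 5.0, "MMRd-ins"), SubtypeCall("I2", 4.0, "MMRd-ins"),
            SubtypeCall("I3", 3.0, "MMRd-ins"), SubtypeCall("D1", -5.0, "MMRd-del")]


class TestNeoantigens:
    def test_affinity_boundary_strictly_below(self):
        records = [NeoantigenRecord("I1", "G1", "INS", 50.0, True),
                   NeoantigenRecord("I1", "G1", "INS", 49.9, True),
                   NeoantigenRecord("I1", "G1", "INS", 10.0, False)]  # not expressed
        per_sample, _ = neoantigen_burden(records, _neo_calls())
        assert per_sample.loc["I1", "total"] == 1

    def test_per_subtype_summaries(self):
        records = ([NeoantigenRecord("I1", "G1", "INS", 10.0, True)] * 4
                   + [NeoantigenRecord("I2", "G1", "DEL", 10.0, True)] * 2
                   + [NeoantigenRecord("D1", "G1", "SNV", 10.0, True)])
        per_sample, per_subtype = neoantigen_burden(records, _neo_calls())
        assert per_subtype.loc["MMRd-ins", "mean"] == pytest.approx(2.0)
        assert per_subtype.loc["MMRd-del", "median"] == 1.0
        assert per_sample.loc["I1", "INS"] == 4

    def test_recurrence_strictly_above_fraction(self):
        # G1 in 2/3 MMRd-ins samples (0.667 > 0.40); G2 in 1/3 only
        records = [NeoantigenRecord("I1", "G1", "INS", 10.0, True),
                   NeoantigenRecord("I2", "G1", "INS", 10.0, True),
                   NeoantigenRecord("I3", "G2", "INS", 10.0, True)]
        out = recurrent_neoantigen_genes(records, _neo_calls(), "MMRd-ins")
        assert bool(out.loc["G1", "listed"]) and not bool(out.loc["G2", "listed"])
        assert out.loc["G1", "frac_MMRd-ins"] == pytest.approx(2 / 3)

    def test_fraction_exactly_at_threshold_not_listed(self):
        calls = [SubtypeCall(f"I{i}", 1.0, "MMRd-ins") for i in range(5)]
        records = [NeoantigenRecord(f"I{i}", "G1", "INS", 10.0, True)
                   for i in range(2)]  # exactly 2/5 = 0.40
        out = recurrent_neoantigen_genes(records, calls, "MMRd-ins")
        assert not bool(out.loc["G1", "listed"])
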