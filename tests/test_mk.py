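"""McDonald-Kreitman machinery: codon classification, tabulation, alpha,
Fisher's exact test (with an independent enumeration oracle)."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from condevol import (
    FormatError,
    MKCounts,
    SequenceRecord,
    alpha_from_counts,
    classify_codon_pair,
    mk_fisher,
    mk_from_counts_table,
    tabulate_mk,
)
from condevol.mk import _CODON_TABLE, mk_table_frame
import pandas as pd


def test_codon_table_matches_biopython():
    for codon, aa in _CODON_TABLE.items():
        assert str(Seq(codon).translate()) == aa


class TestClassifyCodonPair:
    def test_single_step_synonymous(self):
        assert classify_codon_pair("AAA", "AAG") == [("synonymous", 1.0)]

    def test_single_step_nonsynonymous(self):
        assert classify_codon_pair("AAA", "GAA") == [("nonsynonymous", 1.0)]

    def test_identical_codons(self):
        assert classify_codon_pair("ATG", "ATG") == []

    def test_two_step_pathway_average(self):
        """TTT->GTA: path via GTT is nonsyn+syn, via TTA nonsyn+nonsyn."""
        result = dict(classify_codon_pair("TTT", "GTA"))
        assert result["synonymous"] == pytest.approx(0.5)
        assert result["nonsynonymous"] == pytest.approx(1.5)
        assert sum(result.values()) == pytest.approx(2.0)

    def test_weights_always_sum_to_hamming_distance(self):
        rng = np.random.default_rng(3)
        codons = [c for c in _CODON_TABLE if _CODON_TABLE[c] != "*"]
        for _ in range(200):
            a, b = rng.choice(codons, size=2)
            out = classify_codon_pair(a, b)
            if out is None:
                continue
            k = sum(x != y for x, y in zip(a, b))
            assert sum(w for _, w in out) == pytest.approx(k)

    def test_stop_or_ambiguous_input_rejected(self):
        for bad in ("TAA", "AA-", "ANA"):
            with pytest.raises(FormatError):
                classify_codon_pair(bad, "AAA")


def seqs(alphabet_strings, prefix="h"):
    return [SequenceRecord(f"{prefix}{i}", "dna", s)
            for i, s in enumerate(alphabet_strings)]


class TestTabulate:
    def test_fixed_synonymous_difference(self):
        tab = tabulate_mk(seqs(["ATGAAA"] * 4), seqs(["ATGAAG"], "o"))
        assert (tab.counts.pS, tab.counts.pN, tab.counts.dS,
                tab.counts.dN) == (0, 0, 1, 0)

    def test_segregating_nonsynonymous(self):
        tab = tabulate_mk(seqs(["ATGAAA", "ATGGAA"]), seqs(["ATGAAA"], "o"))
        assert (tab.counts.pS, tab.counts.pN, tab.counts.dS,
                tab.counts.dN) == (0, 1, 0, 0)

    def test_all_identical_all_zero(self):
        tab = tabulate_mk(seqs(["ATGAAA"] * 3), seqs(["ATGAAA"], "o"))
        assert tab.counts == MKCounts(0, 0, 0, 0)

    def test_polymorphic_and_divergent_site(self):
        """Outgroup allele absent from a segregating site adds the fixed
        component on top of the polymorphism."""
        tab = tabulate_mk(seqs(["AAA", "AAA", "AAA", "AAG"]),
                          seqs(["GAA"], "o"))
        assert tab.counts.pS == 1     # AAA/AAG segregates (Lys/Lys)
        assert tab.counts.dN == 1     # major AAA vs outgroup GAA (Lys/Glu)

    def test_shared_allele_suppresses_fixed_component(self):
        tab = tabulate_mk(seqs(["AAA", "AAG"]), seqs(["AAG"], "o"))
        assert tab.counts.dS == 0 and tab.counts.dN == 0
        assert tab.counts.pS == 1

    def test_gap_and_stop_columns_skipped_and_reported(self):
        tab = tabulate_mk(seqs(["ATG---AAA", "ATGAAAAAA"]),
                          seqs(["ATGAAATAA"], "o"))
        assert tab.skipped_sites.get("gap_ambiguous_or_stop") == 2
        assert tab.counts == MKCounts(0, 0, 0, 0)

    def test_order_and_relabeling_invariance(self):
        a = ["ATGAAACCC", "ATGGAACCA", "ATGAAACCC", "ATGAAACCA"]
        out = ["ATGAAGCCG"]
        t1 = tabulate_mk(seqs(a), seqs(out, "o"))
        t2 = tabulate_mk(seqs(list(reversed(a)), prefix="z"),
                         seqs(out, "o"))
        assert t1.counts == t2.counts

    def test_outgroup_majority_rule(self):
        """Outgroup ties are skipped; a clear majority classifies."""
        tab = tabulate_mk(seqs(["AAA", "AAA"]), seqs(["AAG", "GAA"], "o"))
        assert tab.skipped_sites.get("outgroup_no_major_allele") == 1
        tab2 = tabulate_mk(seqs(["AAA", "AAA"]),
                           seqs(["AAG", "AAG", "GAA"], "o"))
        assert tab2.counts.dS == 1 and tab2.counts.dN == 0

    def test_unaligned_lengths_rejected(self):
        with pytest.raises(FormatError, match="aligned"):
            tabulate_mk(seqs(["ATGAAA", "ATG"]), seqs(["ATGAAA"], "o"))


class TestAlpha:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((544, 231, 25, 53), 0.7997),
            ((278, 119, 36, 30), 0.4863),
            ((100, 100, 10, 10), 0.0),
            ((150, 44, 24, 6), -0.1733),
        ],
    )
    def test_estimator(self, counts, expected):
        pS, pN, dS, dN = counts
        alpha = alpha_from_counts(MKCounts(pS, pN, dS, dN))
        assert alpha == pytest.approx(expected, abs=5e-5)

    def test_undefined_when_dn_or_ps_zero(self):
        assert alpha_from_counts(MKCounts(0, 5, 3, 2)) is None
        assert alpha_from_counts(MKCounts(10, 5, 3, 0)) is None


# ---------------------------------------------------------------------------
# enumeration oracle for the exact test on a 2x2 table [[dN, dS], [pN, pS]]
# ---------------------------------------------------------------------------

def fisher_oracle(table, tail):
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)

    def prob(k):
        return (math.comb(c1, k) * math.comb(n - c1, r1 - k)
                / math.comb(n, r1))

    p_obs = prob(a)
    if tail == "greater":
        return sum(prob(k) for k in range(a, hi + 1))
    if tail == "less":
        return sum(prob(k) for k in range(lo, a + 1))
    return sum(prob(k) for k in range(lo, hi + 1)
               if prob(k) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_cap_d3_table_two_sided(self):
        p = mk_fisher(MKCounts(pS=544, pN=231, dS=25, dN=53))
        assert p == pytest.approx(9.56e-11, rel=5e-3)
        assert p == pytest.approx(
            fisher_oracle([[53, 25], [231, 544]], "two-sided"))

    def test_small_table_one_sided_enumeration(self):
        """[[2,0],[0,2]] under 'greater' is 1/6 over the margin support."""
        p = mk_fisher(MKCounts(pS=2, pN=0, dS=0, dN=2), tail="greater")
        assert p == pytest.approx(1 / 6)

    def test_identical_proportions_near_one(self):
        p = mk_fisher(MKCounts(pS=300, pN=100, dS=30, dN=10))
        assert p > 0.9

    def test_all_zero_table_convention(self):
        assert mk_fisher(MKCounts(0, 0, 0, 0)) == 1.0

    @pytest.mark.parametrize("tail", ["two-sided", "greater", "less"])
    def test_matches_enumeration_oracle_small_tables(self, tail):
        rng = np.random.default_rng(11)
        for _ in range(120):
            pS, pN, dS, dN = (int(x) for x in rng.integers(0, 16, size=4))
            if pS + pN + dS + dN == 0 or pS + pN + dS + dN > 60:
                continue
            c = MKCounts(pS, pN, dS, dN)
            assert mk_fisher(c, tail) == pytest.approx(
                fisher_oracle(c.as_table(), tail), abs=1e-10)


class TestBatch:
    def test_counts_table_roundtrip(self):
        df = pd.DataFrame({"gene": ["a", "b"], "pS": [100, 10],
                           "pN": [50, 5], "dS": [10, 3], "dN": [20, 0]})
        results = mk_from_counts_table(df)
        assert len(results) == 2
        assert results[1].alpha is None          # dN = 0: alpha undefined
        assert 0 <= results[1].p_value <= 1      # p still computed
        frame = mk_table_frame(results)
        assert list(frame.columns)[:5] == ["gene", "pS", "pN", "dS", "dN"]

    def test_empty_table(self):
        df = pd.DataFrame(columns=["gene", "pS", "pN", "dS", "dN"])
        assert mk_from_counts_table(df) == []

    def test_negative_counts_rejected(self):
        df = pd.DataFrame({"gene": ["a"], "pS": [-1], "pN": [0],
                           "dS": [0], "dN": [0]})
        with pytest.raises(FormatError):
            mk_from_counts_table(df)
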