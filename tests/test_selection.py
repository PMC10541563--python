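import math

import numpy as np
import pytest

from phenolox.selection import (
    GenePair,
    classify_selection,
    codon_alignment_from_proteins,
    find_duplicate_pairs,
    kaks_for_pairs,
    ng86_pair,
    ng86_sites,
    pair_statistics,
    species_summary,
)
from phenolox.seqio import STANDARD_CODE, SequenceRecord

from oracles import ng86_pair_oracle, ng86_sites_oracle

SENSE = sorted(STANDARD_CODE.sense_codons)


class TestSites:
    def test_methionine_fully_nonsynonymous(self):
        assert ng86_sites("ATG") == (0.0, 3.0)

    def test_phenylalanine_third_position(self):
        s, n = ng86_sites("TTT")
        assert s == pytest.approx(1 / 3) and n == pytest.approx(8 / 3)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_sites("TAA")

    def test_site_conservation_and_oracle_on_all_sense_codons(self):
        for codon in SENSE:
            s, n = ng86_sites(codon)
            assert s + n == pytest.approx(3.0, abs=1e-12)
            os, on = ng86_sites_oracle(codon)
            assert s == pytest.approx(os, abs=1e-12)


class TestPair:
    def test_identical_sequences_ratio_na(self):
        cds = "ATGAAATTTGGG"
        res = ng86_pair(cds, cds)
        assert res.Ka == res.Ks == 0.0 and res.ratio is None
        assert res.selection_class == "NA"

    def test_single_synonymous_change_matches_closed_form(self):
        a = "".join(["ATG", "AAA", "TTT", "GGG", "CCC", "GAA", "GAT", "TGG", "TAT", "CAT"])
        b = a[:5] + "G" + a[6:]  # AAA -> AAG, synonymous
        res = ng86_pair(a, b)
        oracle = ng86_pair_oracle(a, b)
        assert res.Ka == 0.0
        assert res.Ks == pytest.approx(oracle["Ks"], abs=1e-12)
        assert res.Ks == pytest.approx(-0.75 * math.log(1 - 4 / (3 * res.Ns)), abs=1e-12)

    def test_two_difference_codon_pathway_average(self):
        # TTT (F) vs GTA (V): hand enumeration over both orderings
        a, b = "ATGTTT", "ATGGTA"
        res = ng86_pair(a, b)
        # path1 TTT->GTT(N)->GTA(S? GTT V, GTA V synonymous) => (1,1)
        # path2 TTT->TTA(L: N)->GTA(V: N) => (0,2); mean Sd=0.5, Nd=1.5
        assert res.Sd == pytest.approx(0.5)
        assert res.Nd == pytest.approx(1.5)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(SENSE, size=12))
        b = "".join(rng.choice(SENSE, size=12))
        ra, rb = ng86_pair(a, b), ng86_pair(b, a)
        assert ra.Ns == pytest.approx(rb.Ns) and ra.Sd == pytest.approx(rb.Sd)
        assert (ra.Ka, ra.Ks) == (rb.Ka, rb.Ks)

    def test_gapped_and_stop_codons_skipped_pairwise(self):
        a = "ATG" + "---" + "TAA" + "AAA"
        b = "ATG" + "CCC" + "AAA" + "AAA"
        res = ng86_pair(a, b)
        assert res.n_codons == 2  # ATG and final AAA only

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            ng86_pair("ATGAAA", "ATG")

    def test_jukes_cantor_correction_saturates(self):
        from phenolox.selection import jukes_cantor

        assert jukes_cantor(0.8) is None
        assert jukes_cantor(0.0) == 0.0


class TestClassifySelection:
    @pytest.mark.parametrize(
        "ratio, expected",
        [(1.32, "positive"), (0.91, "purifying"), (1.0, "neutral"), (None, "NA")],
    )
    def test_published_rule(self, ratio, expected):
        assert classify_selection(ratio) == expected

    def test_neutral_band_widens_neutral_class(self):
        assert classify_selection(1.05, neutral_band=0.1) == "neutral"
        assert classify_selection(1.05, neutral_band=0.0) == "positive"


def _prot(pid, seq, species="sp"):
    return SequenceRecord(id=pid, species=species, kind="protein", seq=seq)


BASE = "MKWVEHAGDFLNPQRSTYCI" * 3  # 60 residues


class TestDuplicatePairs:
    def test_identical_paralogs_retained(self):
        pairs = find_duplicate_pairs([_prot("a", BASE), _prot("b", BASE)])
        assert len(pairs) == 1
        assert pairs[0].fraction_identity == 1.0 and pairs[0].coverage == 1.0

    def test_identity_below_threshold_rejected(self):
        # 21 substitutions in 60 -> identity 0.65
        seq = list(BASE)
        for i in range(0, 42, 2):
            seq[i] = "A" if seq[i] != "A" else "G"
        assert find_duplicate_pairs([_prot("a", BASE), _prot("b", "".join(seq))]) == []

    def test_half_truncation_fails_coverage(self):
        pairs = find_duplicate_pairs([_prot("a", BASE), _prot("b", BASE[:30])])
        assert pairs == []
        identity, coverage, _ = pair_statistics(BASE, BASE[:30])
        assert identity == 1.0 and coverage == pytest.approx(0.5)

    def test_cross_species_pairs_never_formed(self):
        recs = [_prot("a", BASE, "sp1"), _prot("b", BASE, "sp2")]
        assert find_duplicate_pairs(recs) == []

    def test_singleton_species_empty(self):
        assert find_duplicate_pairs([_prot("a", BASE)]) == []


class TestCodonBackmap:
    def test_gaps_become_codon_gaps(self):
        aligned_a, aligned_b = codon_alignment_from_proteins(
            "MK-A", "MKWA", "ATGAAAGCT", "ATGAAATGGGCT"
        )
        assert aligned_a == "ATGAAA---GCT"
        assert aligned_b == "ATGAAATGGGCT"

    def test_terminal_stop_trimmed(self):
        aligned_a, _ = codon_alignment_from_proteins(
            "MK", "MK", "ATGAAATAA", "ATGAAA"
        )
        assert aligned_a == "ATGAAA"

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            codon_alignment_from_proteins("MKA", "MKA", "ATGAAA", "ATGAAAGCT")


class TestSpeciesSummary:
    def _result(self, ratio, cls, species="sp"):
        from phenolox.selection import KaKsResult

        pair = GenePair(species=species, id_a="a", id_b="b",
                        fraction_identity=1.0, coverage=1.0)
        return KaKsResult(pair=pair, Ns=10, Na=20, Sd=1, Nd=1, pS=0.1, pN=0.05,
                          Ks=0.1, Ka=0.05, ratio=ratio, selection_class=cls, n_codons=10)

    def test_arithmetic_on_stated_inputs(self):
        results = [
            self._result(0.5, "purifying"),
            self._result(0.7, "purifying"),
            self._result(1.4, "positive"),
        ]
        s = species_summary(results)
        assert (s.n_purifying, s.n_positive, s.n_neutral) == (2, 1, 0)
        assert s.mean_purifying == pytest.approx(0.6)
        assert s.mean_positive == pytest.approx(1.4)

    def test_all_na_gives_zero_counts(self):
        results = [self._result(None, "NA"), self._result(None, "NA")]
        s = species_summary(results)
        assert s.n_purifying == s.n_positive == s.n_neutral == 0
        assert s.n_na == 2 and s.mean_purifying is None

    def test_k_of_n_formatting(self):
        func = {f"p{i}": "functional" for i in range(33)}
        func["p0"] = func["p1"] = "non_functional"
        s = species_summary([self._result(0.5, "purifying")], functionality=func)
        assert s.nonfunctional_of_total == "2 of 33"

    def test_class_counts_sum_to_pairs_minus_na(self):
        results = [
            self._result(0.5, "purifying"),
            self._result(1.4, "positive"),
            self._result(None, "NA"),
        ]
        s = species_summary(results)
        assert s.n_purifying + s.n_positive + s.n_neutral == s.n_pairs - s.n_na
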