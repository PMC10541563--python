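from itertools import product

import numpy as np
import pytest

from phenolox import residues
from phenolox.residues import (
    SIX_HIS_ROLES,
    Alignment,
    ResidueReport,
    classify_functionality,
    extract_domain_columns,
    extract_domain_columns_aligned,
    global_align,
    map_positions,
    nnx_following_residues,
)
from phenolox.seqio import SequenceRecord

from oracles import global_score_oracle

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _self_alignment(profile):
    ref = profile.reference.seq
    return global_align(ref, ref)


class TestGlobalAlign:
    def test_identity_score_is_diagonal_sum(self):
        aln = global_align("AAA", "AAA")
        assert aln.query_row == aln.reference_row == "AAA"
        assert aln.score == 3 * 4  # BLOSUM62 A/A = 4

    def test_matches_bruteforce_enumeration_oracle(self):
        aln = global_align("MKHA", "MHA")
        assert aln.score == pytest.approx(global_score_oracle("MKHA", "MHA"))
        assert aln.reference_row.count("-") == 1 and aln.query_row.count("-") == 0

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            global_align("", "MK")

    def test_rows_ungap_to_inputs(self):
        aln = global_align("MKWWHA", "MHAAA")
        assert aln.query == "MKWWHA" and aln.reference == "MHAAA"


class TestExtractDomainColumns:
    def test_identity_reproduces_reference_domain_residues(self, co_profile):
        aln = _self_alignment(co_profile)
        expected = "".join(
            co_profile.reference.seq[s:e] for s, e in co_profile.domain_spans
        )
        assert extract_domain_columns(aln, co_profile) == expected

    def test_insertion_between_domains_invisible(self, co_profile):
        ref = co_profile.reference.seq
        tyr_end = co_profile.domain_spans[0][1]
        query = ref[:tyr_end] + "W" * 10 + ref[tyr_end:]
        aln = global_align(query, ref)
        base = extract_domain_columns(_self_alignment(co_profile), co_profile)
        assert extract_domain_columns(aln, co_profile) == base

    def test_deleting_whole_domain_shortens_by_span(self, co_profile):
        (s0, e0), (s1, e1), (s2, e2) = co_profile.domain_spans
        ref = co_profile.reference.seq
        query = ref[:s2]  # drop the whole third domain
        aln = global_align(query, ref)
        extracted = extract_domain_columns(aln, co_profile)
        assert len(extracted) == (e0 - s0) + (e1 - s1)

    def test_mismatched_reference_rejected(self, co_profile):
        aln = global_align("MKHAMKHA", "MKHAMKHA")
        with pytest.raises(ValueError):
            extract_domain_columns(aln, co_profile)

    def test_aligned_variant_is_constant_length(self, co_profile):
        span_total = sum(e - s for s, e in co_profile.domain_spans)
        ref = co_profile.reference.seq
        query = ref[: co_profile.domain_spans[1][0]]  # heavy C-terminal truncation
        aln = global_align(query, ref)
        padded = extract_domain_columns_aligned(aln, co_profile)
        assert len(padded) == span_total
        assert padded.endswith("-")


class TestMapPositions:
    def test_reference_maps_to_its_own_residues(self, co_profile):
        report = map_positions(_self_alignment(co_profile), co_profile)
        for role, pos in co_profile.named_positions.items():
            assert report.residues[role] == co_profile.reference.seq[pos - 1]
        assert report.residues["gatekeeper"] == "F"
        assert report.residues["waterkeeper"] == "E"

    def test_engineered_substitution_detected(self, co_profile):
        ref = co_profile.reference.seq
        pos = co_profile.named_positions["HisB2"] - 1
        query = ref[:pos] + "Y" + ref[pos + 1 :]
        report = map_positions(global_align(query, ref), co_profile)
        assert report.residues["HisB2"] == "Y"

    def test_deletion_across_cua_maps_to_gaps(self, co_profile):
        ref = co_profile.reference.seq
        a1 = co_profile.named_positions["HisA1"] - 1
        a3 = co_profile.named_positions["HisA3"]
        query = ref[:a1] + ref[a3:]
        report = map_positions(global_align(query, ref), co_profile)
        for role in ("HisA1", "HisA2", "HisA3"):
            assert report.residues[role] == "-"


class TestSixHisRule:
    def _report(self, residues_map):
        return ResidueReport(protein_id="p", residues=residues_map, extracted_domain_seq="")

    def test_all_his_functional(self):
        rep = classify_functionality(self._report({r: "H" for r in SIX_HIS_ROLES}))
        assert rep.functionality == "functional" and not rep.missing_his

    def test_single_substitution_non_functional(self):
        rmap = {r: "H" for r in SIX_HIS_ROLES}
        rmap["HisB2"] = "Y"
        rep = classify_functionality(self._report(rmap))
        assert rep.functionality == "non_functional"
        assert rep.missing_his == frozenset({"HisB2"})

    def test_gap_counts_as_absent(self):
        rmap = {r: "H" for r in SIX_HIS_ROLES}
        rmap["HisA1"] = "-"
        assert classify_functionality(self._report(rmap)).functionality == "non_functional"

    def test_agrees_with_conjunction_oracle_on_all_64_patterns(self):
        for pattern in product([True, False], repeat=6):
            rmap = {
                role: ("H" if present else "Q")
                for role, present in zip(SIX_HIS_ROLES, pattern)
            }
            rep = classify_functionality(self._report(rmap))
            expected = "functional" if all(pattern) else "non_functional"
            assert rep.functionality == expected

    def test_missing_role_is_error(self):
        with pytest.raises(ValueError):
            classify_functionality(self._report({"HisA1": "H"}))


class TestNnxFollowing:
    def test_reference_returns_own_four_residues(self, lacaao_profile):
        ref = lacaao_profile.reference.seq
        aln = global_align(ref, ref)
        anchor = lacaao_profile.named_positions["NNX_anchor"]
        assert nnx_following_residues(aln, lacaao_profile) == ref[anchor + 2 : anchor + 6]

    def test_deleted_columns_give_all_gaps(self, lacaao_profile):
        ref = lacaao_profile.reference.seq
        anchor = lacaao_profile.named_positions["NNX_anchor"]
        query = ref[: anchor + 2] + ref[anchor + 6 :]
        aln = global_align(query, ref)
        assert nnx_following_residues(aln, lacaao_profile) == "----"

    def test_substitution_at_position_two(self, lacaao_profile):
        ref = lacaao_profile.reference.seq
        anchor = lacaao_profile.named_positions["NNX_anchor"]
        idx = anchor + 3  # 0-based second of the four
        sub = "W" if ref[idx] != "W" else "Y"
        query = ref[:idx] + sub + ref[idx + 1 :]
        out = nnx_following_residues(global_align(query, ref), lacaao_profile)
        expected = ref[anchor + 2 : anchor + 6]
        assert out[1] == sub and out[0] == expected[0] and out[2:] == expected[2:]

    def test_requires_lacaao_family(self, co_profile):
        aln = _self_alignment(co_profile)
        with pytest.raises(ValueError):
            nnx_following_residues(aln, co_profile)


class TestRobustness:
    def test_mapping_survives_mutation_away_from_anchors(self, co_profile):
        """Substitutions and indels planted only outside +/-3 of every named
        position must leave all mapped role residues intact (500 trials)."""
        ref = co_profile.reference.seq
        protected = set()
        for pos in co_profile.named_positions.values():
            protected.update(range(pos - 4, pos + 3))  # 0-based +/-3 window
        free = sorted(set(range(len(ref))) - protected)
        planted = {
            role: ref[pos - 1] for role, pos in co_profile.named_positions.items()
        }
        rng = np.random.default_rng(20230516)
        failures = 0
        for _ in range(500):
            seq = list(ref)
            for pos in rng.choice(free, size=8, replace=False):
                seq[pos] = AA[rng.integers(20)]
            ins_at = int(rng.choice(free))
            ins = "".join(AA[i] for i in rng.integers(0, 20, size=rng.integers(1, 5)))
            del_at = int(rng.choice([p for p in free if p + 2 < len(ref) and
                                     p + 1 in free and p + 2 in free]))
            query = "".join(seq)
            query = query[:ins_at] + ins + query[ins_at:]
            shift = len(ins) if ins_at <= del_at else 0
            query = query[: del_at + shift] + query[del_at + shift + 2 :]
            report = map_positions(global_align(query, ref), co_profile)
            if any(report.residues[r] != planted[r] for r in planted):
                failures += 1
        assert failures == 0
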