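import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from phenolox.codonbias import (
    average_linkage,
    codon_counts,
    rscu,
    rscu_distance,
    vector_codons,
)
from phenolox.phylo import DistanceMatrix
from phenolox.seqio import BACTERIAL_CODE, STANDARD_CODE, SequenceRecord


def _cds(seq, pid="c1", species="sp"):
    return SequenceRecord(id=pid, species=species, kind="cds", seq=seq)


class TestCodonCounts:
    def test_direct_count(self):
        counts = codon_counts([_cds("ATGTTTTTT")])
        assert counts["ATG"] == 1 and counts["TTT"] == 2

    def test_empty_set_warns_all_zero(self, caplog):
        with caplog.at_level("WARNING"):
            counts = codon_counts([])
        assert sum(counts.values()) == 0 and "empty" in caplog.text

    def test_stops_and_n_codons_excluded(self):
        counts = codon_counts([_cds("ATGTAAANN")])
        assert counts["ATG"] == 1 and counts["TAA"] == 0
        assert sum(counts.values()) == 1

    def test_bad_length_names_record(self):
        rec = SequenceRecord.__new__(SequenceRecord)  # bypass validation
        object.__setattr__(rec, "id", "bad")
        object.__setattr__(rec, "species", "sp")
        object.__setattr__(rec, "kind", "cds")
        object.__setattr__(rec, "seq", "ATGAAAGG")
        with pytest.raises(ValueError, match="bad"):
            codon_counts([rec])


class TestRscu:
    def test_two_codon_family_formula(self):
        counts = {c: 0 for c in STANDARD_CODE.codon_to_aa}
        counts["TTT"], counts["TTC"] = 3, 1
        prof = rscu(counts)
        assert prof.rscu["TTT"] == pytest.approx(1.5)
        assert prof.rscu["TTC"] == pytest.approx(0.5)

    def test_unused_member_zero_and_used_gets_k(self):
        counts = {c: 0 for c in STANDARD_CODE.codon_to_aa}
        counts["TTT"] = 3
        prof = rscu(counts)
        assert prof.rscu["TTT"] == pytest.approx(2.0)
        assert prof.rscu["TTC"] == pytest.approx(0.0)

    def test_uniform_usage_gives_all_ones(self):
        counts = {c: 5 for c in STANDARD_CODE.codon_to_aa}
        prof = rscu(counts)
        observed = [v for v in prof.rscu.values() if v is not None]
        assert all(v == pytest.approx(1.0) for v in observed)

    def test_unobserved_family_is_na(self):
        counts = {c: 0 for c in STANDARD_CODE.codon_to_aa}
        prof = rscu(counts)
        assert all(v is None for v in prof.rscu.values())

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_family_sums_equal_degeneracy(self, seed):
        rng = np.random.default_rng(seed)
        counts = {c: int(rng.poisson(5)) for c in STANDARD_CODE.codon_to_aa}
        prof = rscu(counts)
        for aa, family in STANDARD_CODE.synonymous_families().items():
            if len(family) == 1:
                continue
            total = sum(counts[c] for c in family)
            if total == 0:
                continue
            assert sum(prof.rscu[c] for c in family) == pytest.approx(
                len(family), abs=1e-9
            )

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        counts = {c: int(rng.integers(1, 30)) for c in STANDARD_CODE.codon_to_aa}
        scaled = {c: 7 * v for c, v in counts.items()}
        p1, p2 = rscu(counts), rscu(scaled)
        for c in p1.rscu:
            assert p1.rscu[c] == pytest.approx(p2.rscu[c])

    def test_vector_has_59_codons_under_both_tables(self):
        assert len(vector_codons(STANDARD_CODE)) == 59
        assert vector_codons(STANDARD_CODE) == vector_codons(BACTERIAL_CODE)


def _profile_from_counts(counts, species):
    return rscu(counts, species=species)


class TestRscuDistance:
    def _uniform_counts(self):
        return {c: 10 for c in STANDARD_CODE.codon_to_aa}

    def test_identical_profiles_distance_zero(self):
        p1 = _profile_from_counts(self._uniform_counts(), "a")
        p2 = _profile_from_counts(self._uniform_counts(), "b")
        dm = rscu_distance([p1, p2])
        assert dm.value("a", "b") == pytest.approx(0.0)

    def test_single_coordinate_difference(self):
        c1 = self._uniform_counts()
        p1 = _profile_from_counts(c1, "a")
        c2 = dict(c1)
        c2["TTT"], c2["TTC"] = 15, 5  # RSCU 1.5/0.5 instead of 1/1
        p2 = _profile_from_counts(c2, "b")
        dm = rscu_distance([p1, p2])
        assert dm.value("a", "b") == pytest.approx(np.sqrt(0.5**2 + 0.5**2))

    def test_three_profiles_symmetric_zero_diagonal(self):
        ps = [_profile_from_counts(self._uniform_counts(), s) for s in "abc"]
        dm = rscu_distance(ps)
        assert dm.d.shape == (3, 3)

    def test_mixed_code_tables_rejected(self):
        p1 = rscu(self._uniform_counts(), STANDARD_CODE, species="a")
        p2 = rscu(self._uniform_counts(), BACTERIAL_CODE, species="b")
        with pytest.raises(ValueError):
            rscu_distance([p1, p2])


class TestAverageLinkage:
    def test_forced_merge_order(self):
        labels = ("a", "b", "c")
        d = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], dtype=float)
        dend = average_linkage(DistanceMatrix(labels, d))
        (l1, r1, h1), (l2, r2, h2) = dend.merges
        assert l1 | r1 == {"a", "b"} and h1 == 1.0
        assert h2 == 4.0

    def test_all_equal_distances_deterministic(self):
        labels = ("a", "b", "c", "d")
        d = np.ones((4, 4)) - np.eye(4)
        outs = {average_linkage(DistanceMatrix(labels, d)).newick for _ in range(5)}
        assert len(outs) == 1

    def test_heights_monotone_nondecreasing(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = 6
            m = rng.random((n, n)) + 0.1
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            dend = average_linkage(DistanceMatrix(tuple("abcdef"), d))
            heights = [h for _, _, h in dend.merges]
            assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_merge_heights_match_scipy_average_linkage(self):
        rng = np.random.default_rng(99)
        n = 7
        m = rng.random((n, n)) + 0.05
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        labels = tuple(f"s{i}" for i in range(n))
        dend = average_linkage(DistanceMatrix(labels, d))
        ours = sorted(h for _, _, h in dend.merges)
        scipy_heights = sorted(linkage(squareform(d), method="average")[:, 2])
        assert np.allclose(ours, scipy_heights)

    def test_single_label_rejected(self):
        dm = DistanceMatrix(("a",), np.zeros((1, 1)))
        with pytest.raises(ValueError):
            average_linkage(dm)

    def test_newick_parses_and_is_ultrametric(self):
        labels = ("a", "b", "c")
        d = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], dtype=float)
        dend = average_linkage(DistanceMatrix(labels, d))
        import dendropy

        tree = dendropy.Tree.get(data=dend.newick, schema="newick")
        depths = []
        for leaf in tree.leaf_node_iter():
            depth, node = 0.0, leaf
            while node.parent_node is not None:
                depth += node.edge.length or 0.0
                node = node.parent_node
            depths.append(depth)
        assert np.allclose(depths, depths[0])
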