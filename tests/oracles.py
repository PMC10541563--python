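"""Independent brute-force oracles used to validate the implementation.

Everything here is written against the problem definitions directly
(exhaustive enumeration, closed forms, Biopython translation) and shares
no code path with the package internals it checks.
"""

from __future__ import annotations

import math
from itertools import permutations, product

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
NUCS = "ACGT"


def bio_translate(codon: str, table_id: int = 1) -> str:
    tbl = CodonTable.unambiguous_dna_by_id[table_id]
    if codon in tbl.stop_codons:
        return "*"
    return str(Seq(codon).translate(table=table_id))


# ---------------------------------------------------------------------------
# NG86 brute force

def ng86_sites_oracle(codon: str, table_id: int = 1):
    """Per-position stop-excluded renormalized site counts."""
    aa = bio_translate(codon, table_id)
    assert aa != "*"
    syn = 0.0
    for pos in range(3):
        fates = []
        for alt in NUCS:
            if alt == codon[pos]:
                continue
            m = codon[:pos] + alt + codon[pos + 1 :]
            maa = bio_translate(m, table_id)
            if maa != "*":
                fates.append(maa == aa)
        if fates:
            syn += sum(fates) / len(fates)
    return syn, 3.0 - syn


def pathway_oracle(ca: str, cb: str, table_id: int = 1):
    """Mean (syn, nonsyn) difference counts over minimal pathways, stop
    pathways excluded (all pathways if every one is blocked)."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    if not diffs:
        return 0.0, 0.0

    def count(order, skip_stops):
        cur, s, n = ca, 0, 0
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if skip_stops and bio_translate(nxt, table_id) == "*":
                return None
            if bio_translate(nxt, table_id) == bio_translate(cur, table_id):
                s += 1
            else:
                n += 1
            cur = nxt
        return s, n

    paths = [r for r in (count(o, True) for o in permutations(diffs)) if r]
    if not paths:
        paths = [count(o, False) for o in permutations(diffs)]
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def ng86_pair_oracle(cds_a: str, cds_b: str, table_id: int = 1):
    """Full NG86 on two gap-free aligned coding sequences."""
    Ns = Na = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if "*" in (bio_translate(ca, table_id), bio_translate(cb, table_id)):
            continue
        sa, _ = ng86_sites_oracle(ca, table_id)
        sb, _ = ng86_sites_oracle(cb, table_id)
        Ns += (sa + sb) / 2
        Na += 3 - (sa + sb) / 2
        s, n = pathway_oracle(ca, cb, table_id)
        Sd += s
        Nd += n
    pS = Sd / Ns if Ns else 0.0
    pN = Nd / Na if Na else 0.0

    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return {"Ns": Ns, "Na": Na, "Sd": Sd, "Nd": Nd, "pS": pS, "pN": pN,
            "Ks": jc(pS), "Ka": jc(pN)}


# ---------------------------------------------------------------------------
# Fisher exact two-sided by direct combinatorial enumeration

def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-12):
            total += pk
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# alignment score brute force (tiny sequences, affine gaps)

def global_score_oracle(a: str, b: str, gap_open=10.0, gap_extend=1.0) -> float:
    """Max global alignment score by exhaustive enumeration of all
    alignments (op sequences), affine gap cost open+k*extend... the open
    penalty applies to the first gapped column of each run."""
    best = -math.inf

    def rec(i, j, score, last_op):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + _BLOSUM62[a[i], b[j]], "M")
        if i < len(a):
            cost = gap_extend if last_op == "A" else gap_open
            rec(i + 1, j, score - cost, "A")
        if j < len(b):
            cost = gap_extend if last_op == "B" else gap_open
            rec(i, j + 1, score - cost, "B")

    rec(0, 0, 0.0, None)
    return best


def local_score_oracle(a: str, b: str, gap_open=10.0, gap_extend=1.0) -> float:
    """Smith–Waterman optimal score by Gotoh dynamic programming."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            sub = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, sub + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]))
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


# ---------------------------------------------------------------------------
# additive distance matrices from planted trees

def additive_matrix_from_tree(newick: str):
    """Leaf labels and their path-length distance matrix (exact additive)."""
    import dendropy
    import numpy as np

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = tuple(t.label for t in taxa)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.path_edge_count(taxa[i], taxa[j]) and pdm.distance(
                taxa[i], taxa[j]
            )
    return labels, d


def tree_bipartitions_oracle(newick: str, labels):
    """Non-trivial bipartitions via dendropy, canonicalized like phylo."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    ref = min(labels)
    full = frozenset(labels)
    out = set()
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head.is_leaf() or head.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in head.leaf_iter())
        if ref in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            out.add(side)
    return out
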