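"""Relative synonymous codon usage (RSCU) and species clustering.

RSCU_i = n_i / ((1/k) * sum_j n_j) over the k synonymous codons of a
family: 1 means unbiased usage, >1 over-use. Profiles live on a 59-codon
vector — the 61 sense codons minus the two single-codon families (ATG,
TGG), whose RSCU is constant 1 whenever observed and carries no signal.
Under code table 11 the sense/stop partition is identical to table 1, so
the vector is the same; the table choice is honored for forward
compatibility.

Species profiles are compared by Euclidean distance (unobserved families
imputed as 0, with a logged count) and clustered by unweighted
average-linkage agglomeration, with lexicographic tie-breaks so the
dendrogram is deterministic even on exactly tied distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .phylo import DistanceMatrix
from .seqio import GeneticCode, STANDARD_CODE, SequenceRecord

log = logging.getLogger(__name__)

SINGLE_CODON_FAMILIES = ("ATG", "TGG")


def vector_codons(code: GeneticCode = STANDARD_CODE) -> Tuple[str, ...]:
    """The 59 degenerate sense codons, sorted, shared by tables 1 and 11."""
    return tuple(
        sorted(c for c in code.sense_codons if c not in SINGLE_CODON_FAMILIES)
    )


@dataclass(frozen=True)
class RSCUProfile:
    species: str
    code_table: int
    counts: Dict[str, int]  # all 64 codons
    rscu: Dict[str, Optional[float]]  # 59 degenerate sense codons; None = family unobserved

    def vector(self, impute: float = 0.0) -> np.ndarray:
        codons = vector_codons(GeneticCode.from_table(self.code_table))
        return np.array(
            [self.rscu[c] if self.rscu[c] is not None else impute for c in codons]
        )


def codon_counts(
    cds_set: Sequence[SequenceRecord], code: GeneticCode = STANDARD_CODE
) -> Dict[str, int]:
    """Codon usage summed over a species' coding sequences.

    Stop codons and codons containing N are excluded from counting.
    """
    counts = {codon: 0 for codon in code.codon_to_aa}
    if not cds_set:
        log.warning("codon_counts called on an empty CDS set")
        return counts
    for rec in cds_set:
        seq = rec.seq.upper()
        if len(seq) % 3 != 0:
            raise ValueError(f"CDS {rec.id!r}: length {len(seq)} not divisible by 3")
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if "N" in codon or code.is_stop(codon):
                continue
            counts[codon] += 1
    return counts


def rscu(
    counts: Dict[str, int], code: GeneticCode = STANDARD_CODE, species: str = ""
) -> RSCUProfile:
    """RSCU per degenerate sense codon; NA (None) where a family is unobserved."""
    values: Dict[str, Optional[float]] = {}
    for aa, family in code.synonymous_families().items():
        k = len(family)
        if k == 1:
            continue
        total = sum(counts.get(c, 0) for c in family)
        for c in family:
            values[c] = None if total == 0 else counts.get(c, 0) * k / total
    return RSCUProfile(
        species=species, code_table=code.table_id, counts=dict(counts), rscu=values
    )


def rscu_distance(profiles: Sequence[RSCUProfile]) -> DistanceMatrix:
    """Euclidean distance over the 59-codon RSCU vectors (NA imputed as 0)."""
    if len(profiles) < 2:
        raise ValueError("rscu_distance needs at least 2 profiles")
    tables = {p.code_table for p in profiles}
    if len(tables) > 1:
        raise ValueError(f"mixed genetic-code tables in profiles: {sorted(tables)}")
    n_imputed = sum(
        1 for p in profiles for v in p.rscu.values() if v is None
    )
    if n_imputed:
        log.info("rscu_distance imputed %d unobserved-family entries as 0", n_imputed)
    mat = np.stack([p.vector(impute=0.0) for p in profiles])
    labels = tuple(p.species for p in profiles)
    diff = mat[:, None, :] - mat[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(labels=labels, d=d)


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge sequence with an ultrametric Newick rendering."""

    labels: Tuple[str, ...]
    merges: Tuple[Tuple[frozenset, frozenset, float], ...]  # (left, right, height)
    newick: str

    def first_bipartition(self) -> Tuple[frozenset, frozenset]:
        """The two clusters joined by the final (root) merge."""
        left, right, _ = self.merges[-1]
        return left, right


def average_linkage(dm: DistanceMatrix) -> Dendrogram:
    """Unweighted average-linkage (UPGMA-style) agglomeration.

    Inter-cluster distance is the mean over all member pairs; ties are
    broken by the lexicographically smallest (min-label, min-label) pair
    of cluster representatives. Node height = merge distance / 2; Newick
    branch lengths are height differences, so heights are monotone.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("average_linkage needs at least 2 labels")
    clusters: Dict[int, frozenset] = {i: frozenset([dm.labels[i]]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    newicks = {i: dm.labels[i] for i in range(n)}
    reps = {i: dm.labels[i] for i in range(n)}
    D: Dict[Tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = float(dm.d[i, j])
    merges: List[Tuple[frozenset, frozenset, float]] = []
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        best = None
        for (i, j), dist in D.items():
            if i not in active or j not in active:
                continue
            key = (dist, tuple(sorted((reps[i], reps[j]))))
            if best is None or key < best[0]:
                best = (key, i, j)
        (dist, _), i, j = best
        if reps[i] > reps[j]:
            i, j = j, i
        height = dist / 2.0
        merges.append((clusters[i], clusters[j], dist))
        nid = next_id
        next_id += 1
        clusters[nid] = clusters[i] | clusters[j]
        sizes[nid] = sizes[i] + sizes[j]
        heights[nid] = height
        reps[nid] = min(reps[i], reps[j])
        newicks[nid] = (
            f"({newicks[i]}:{height - heights[i]:.10g},"
            f"{newicks[j]}:{height - heights[j]:.10g})"
        )
        for k in active:
            if k in (i, j):
                continue
            dik = D[tuple(sorted((i, k)))]
            djk = D[tuple(sorted((j, k)))]
            D[(k, nid) if k < nid else (nid, k)] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        active.discard(i)
        active.discard(j)
        active.add(nid)
    root = next(iter(active))
    return Dendrogram(
        labels=dm.labels, merges=tuple(merges), newick=newicks[root] + ";"
    )
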