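"""Desk-scale distance phylogeny: p-distances, neighbor-joining, bootstrap.

This stage exists so clade assignment is possible end-to-end (a TYR_LIKE
architecture call cannot separate a true tyrosinase from a catechol
oxidase that lost its shield domains; the tree can). It deliberately
trades model fidelity for determinism and testability: uncorrected
p-distances, classical neighbor-joining with a fixed lexicographic
tie-break, and column-resampling bootstrap supports on the point-estimate
tree's bipartitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: Tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("distance-matrix labels must be unique")
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < -1e-12):
            raise ValueError("negative distances")

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


class _Node:
    __slots__ = ("label", "children", "length")

    def __init__(self, label: Optional[str] = None):
        self.label = label
        self.children: List[Tuple["_Node", float]] = []
        self.length = 0.0


@dataclass
class Tree:
    """Unrooted tree, serialized as Newick with a basal multifurcation.

    ``supports`` maps canonical bipartitions (frozenset of labels on the
    side not containing the reference taxon) to integer bootstrap counts.
    """

    newick: str
    labels: Tuple[str, ...]
    supports: Dict[frozenset, int] = field(default_factory=dict)

    def bipartitions(self) -> set:
        return tree_bipartitions(self.newick, self.labels)

    def newick_with_supports(self) -> str:
        if not self.supports:
            return self.newick
        tree = dendropy.Tree.get(data=self.newick, schema="newick")
        ref = min(self.labels)
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if ref in side:
                side = frozenset(self.labels) - side
            if side in self.supports:
                node.label = str(self.supports[side])
        return tree.as_string(schema="newick", suppress_rooting=True).strip()


def p_distance(rows: Sequence[Tuple[str, str]]) -> DistanceMatrix:
    """Proportion of differing columns per pair, gap columns excluded pairwise.

    ``rows`` is a sequence of (label, gapped sequence); all sequences must
    share one length. A pair with no comparable columns is an error.
    """
    if len(rows) < 2:
        raise ValueError("p_distance needs at least 2 rows")
    labels = tuple(lbl for lbl, _ in rows)
    seqs = [s for _, s in rows]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("rows differ in length")
    arr = np.array([list(s) for s in seqs])
    gap = arr == "-"
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = ~(gap[i] | gap[j])
            m = int(usable.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            diff = int((arr[i][usable] != arr[j][usable]).sum())
            d[i, j] = d[j, i] = diff / m
    return DistanceMatrix(labels=labels, d=d)


def _newick_of(node: _Node) -> str:
    if not node.children:
        return f"{node.label}"
    inner = ",".join(f"{_newick_of(c)}:{l:.10g}" for c, l in node.children)
    return f"({inner})"


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Classical NJ (Q criterion). Ties on Q are broken by the
    lexicographically smallest label pair; negative branch lengths are
    clamped to 0 with a warning."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    nodes = [_Node(lbl) for lbl in dm.labels]
    # representative label per active cluster = min leaf label, for tie-breaks
    reps = list(dm.labels)
    D = dm.d.astype(float).copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            log.warning("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sums = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - sums[i] - sums[j]
                pair_key = tuple(sorted((reps[i], reps[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (sums[i] - sums[j]) / (2 * (m - 2))
        lj = dij - li
        parent = _Node()
        parent.children = [(nodes[i], clamp(li)), (nodes[j], clamp(lj))]
        # distances to the new node
        newrow = np.zeros(D.shape[0] + 1)
        D = np.pad(D, ((0, 1), (0, 1)))
        new = D.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            D[new, k] = D[k, new] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = _Node()
    root.children = [
        (nodes[i], clamp(li)),
        (nodes[j], clamp(lj)),
        (nodes[k], clamp(lk)),
    ]
    newick = _newick_of(root) + ";"
    return Tree(newick=newick, labels=dm.labels)


def tree_bipartitions(newick: str, labels: Sequence[str]) -> set:
    """Non-trivial bipartitions of an unrooted tree, canonicalized as the
    side not containing the lexicographically smallest label."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    all_labels = frozenset(labels)
    ref = min(labels)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_labels - side
        if 2 <= len(side) <= len(all_labels) - 2:
            out.add(side)
    return out


def bootstrap(
    rows: Sequence[Tuple[str, str]], n_replicates: int, seed: int
) -> Tree:
    """Column-resampling bootstrap supports on the point-estimate NJ tree.

    Support for each internal bipartition of the point tree = number of
    replicates whose NJ tree contains it. Fully seeded and reproducible.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    point = neighbor_joining(p_distance(rows))
    target = point.bipartitions()
    counts = {b: 0 for b in target}
    rng = np.random.default_rng(seed)
    labels = [lbl for lbl, _ in rows]
    seqs = [s for _, s in rows]
    length = len(seqs[0])
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        rep_rows = [
            (lbl, "".join(s[c] for c in cols)) for lbl, s in zip(labels, seqs)
        ]
        try:
            rep_tree = neighbor_joining(p_distance(rep_rows))
        except ValueError:
            continue  # replicate with an all-gap pair contributes no support
        rep_bips = rep_tree.bipartitions()
        for b in target:
            if b in rep_bips:
                counts[b] += 1
    return Tree(newick=point.newick, labels=point.labels, supports=counts)


def read_newick(path_or_string) -> dendropy.Tree:
    """Parse Newick (file path or literal string) into a dendropy tree."""
    text = str(path_or_string)
    if "(" in text:
        return dendropy.Tree.get(data=text, schema="newick")
    return dendropy.Tree.get(path=text, schema="newick")
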