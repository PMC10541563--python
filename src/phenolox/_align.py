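"""Pairwise alignment backend shared by domain detection and residue mapping.

BLOSUM62 with affine gaps (open 10, extend 1). Global mode anchors queries
to annotated references; local mode scores queries against domain templates.
Tracebacks are the aligner's canonical first alignment, so results are
deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

GAP_OPEN = 10.0
GAP_EXTEND = 1.0


@lru_cache(maxsize=None)
def _aligner(mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


@dataclass(frozen=True)
class PairwiseResult:
    """A single pairwise alignment with identity/coverage bookkeeping.

    ``query_row``/``target_row`` are the gapped strings (global mode only
    guarantees full-length rows). Spans are 0-based half-open on the
    ungapped inputs; ``aligned_columns`` counts columns where neither row
    has a gap, ``matches`` those that are also identical.
    """

    query_row: str
    target_row: str
    score: float
    query_span: tuple
    target_span: tuple
    aligned_columns: int
    matches: int

    @property
    def fraction_identity(self) -> float:
        return self.matches / self.aligned_columns if self.aligned_columns else 0.0

    @property
    def gapped_identity(self) -> float:
        """Matches over ALL columns of the aligned region, gap columns
        included — a gappy chance alignment cannot inflate this by
        cherry-picking matched residues between gaps."""
        qlen = self.query_span[1] - self.query_span[0]
        tlen = self.target_span[1] - self.target_span[0]
        total = qlen + tlen - self.aligned_columns
        return self.matches / total if total else 0.0

    def coverage_of(self, length: int) -> float:
        """Fraction of a sequence of given length covered by aligned columns."""
        return self.aligned_columns / length if length else 0.0


def _summarize(alignment, query: str, target: str) -> PairwiseResult:
    blocks_q, blocks_t = alignment.aligned
    matches = 0
    aligned_cols = 0
    for (qs, qe), (ts, te) in zip(blocks_q, blocks_t):
        aligned_cols += qe - qs
        matches += sum(1 for a, b in zip(query[qs:qe], target[ts:te]) if a == b)
    qspan = (int(blocks_q[0][0]), int(blocks_q[-1][1])) if len(blocks_q) else (0, 0)
    tspan = (int(blocks_t[0][0]), int(blocks_t[-1][1])) if len(blocks_t) else (0, 0)
    return PairwiseResult(
        query_row=alignment[0],
        target_row=alignment[1],
        score=float(alignment.score),
        query_span=qspan,
        target_span=tspan,
        aligned_columns=aligned_cols,
        matches=matches,
    )


def align_global(query: str, target: str) -> PairwiseResult:
    if not query or not target:
        raise ValueError("cannot align an empty sequence")
    alignment = next(iter(_aligner("global").align(query, target)))
    return _summarize(alignment, query, target)


def align_local(query: str, target: str) -> PairwiseResult:
    if not query or not target:
        raise ValueError("cannot align an empty sequence")
    alignment = next(iter(_aligner("local").align(query, target)))
    return _summarize(alignment, query, target)
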