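"""Domain detection and architecture classification of phenoloxidases.

Plant PPOs (tyrosinases and catechol oxidases) carry an N-terminal
tyrosinase domain; mature catechol oxidases add the PPO1_DWL linker and
often a C-terminal PPO1_KFDV shield domain. Laccases and ascorbate
oxidases instead carry three Cu-oxidase domains. The architecture class
is read directly off which of those domains are present:

========== ===========================================
TYR_LIKE   tyrosinase domain only
CO_DWL     tyrosinase + PPO1_DWL
CO_FULL    tyrosinase + PPO1_DWL + PPO1_KFDV
MCO        Cu-oxidase_3 + Cu-oxidase + Cu-oxidase_2
========== ===========================================

Anything else (no hits, partial multicopper sets, tyrosinase/Cu-oxidase
chimeras) is UNCLASSIFIED. A TYR_LIKE call cannot by itself separate a
true tyrosinase from a catechol oxidase that lost its shield domains —
that distinction is phylogenetic and belongs to a downstream join with
the tree stage.

Detection aligns the query locally against packaged per-domain consensus
templates (Smith–Waterman, BLOSUM62, affine gaps). Users who ran a real
profile-HMM scan can bypass the detector entirely by supplying its
per-domain table through :func:`phenolox.seqio.read_domtbl` and
:func:`hits_from_domtbl`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from . import _align
from .seqio import DOMAIN_VOCABULARY, RawDomainRow, SequenceRecord

log = logging.getLogger(__name__)

TYROSINASE_FAMILY = {"TYROSINASE", "PPO1_DWL", "PPO1_KFDV"}
CU_OXIDASE_FAMILY = {"CU_OXIDASE_3", "CU_OXIDASE", "CU_OXIDASE_2"}

MIN_QUERY_LENGTH = 30
DEFAULT_MIN_IDENTITY = 0.30
DEFAULT_MIN_COVERAGE = 0.60


@dataclass(frozen=True)
class DomainHit:
    """Located evidence for one diagnostic domain on one protein."""

    protein_id: str
    domain: str
    start: int  # 0-based half-open on the query
    end: int
    score: float
    fraction_identity: float = float("nan")
    coverage: float = float("nan")

    def __post_init__(self) -> None:
        if self.domain not in DOMAIN_VOCABULARY:
            raise ValueError(f"domain {self.domain!r} outside the closed vocabulary")
        if not self.start < self.end:
            raise ValueError(f"empty or inverted hit span [{self.start},{self.end})")


@dataclass(frozen=True)
class Architecture:
    """The family call derived from a protein's domain content."""

    protein_id: str
    cls: str  # TYR_LIKE | CO_DWL | CO_FULL | MCO | UNCLASSIFIED
    domains_present: frozenset
    kfdv_motif: Optional[bool] = None


def detect_domains(
    query: SequenceRecord,
    templates: Mapping[str, str],
    min_fraction_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list:
    """Scan a protein against per-domain consensus templates.

    Returns at most one (best-scoring) hit per domain, kept only when the
    local alignment reaches both the identity and the template-coverage
    threshold; hits are sorted by query start. Queries shorter than 30
    residues yield no hits (forcing UNCLASSIFIED downstream).
    """
    if len(query.seq) < MIN_QUERY_LENGTH:
        log.warning(
            "query %s shorter than %d residues; skipping domain detection",
            query.id,
            MIN_QUERY_LENGTH,
        )
        return []
    hits = []
    for domain in DOMAIN_VOCABULARY:
        if domain not in templates:
            continue
        template = templates[domain]
        res = _align.align_local(query.seq, template)
        if res.aligned_columns == 0:
            continue
        coverage = res.coverage_of(len(template))
        # identity counts gap columns in its denominator: a gappy chance
        # alignment that cherry-picks matches between gaps stays below
        # threshold, a real (near-gapless) domain match is unaffected
        identity = res.gapped_identity
        if identity >= min_fraction_identity and coverage >= min_coverage:
            hits.append(
                DomainHit(
                    protein_id=query.id,
                    domain=domain,
                    start=res.query_span[0],
                    end=res.query_span[1],
                    score=res.score,
                    fraction_identity=identity,
                    coverage=coverage,
                )
            )
    hits.sort(key=lambda h: (h.start, h.domain))
    return hits


def hits_from_domtbl(rows: Iterable[RawDomainRow]) -> dict:
    """Group precomputed domain-table rows into per-protein DomainHit lists.

    Keeps the best-scoring row per (protein, domain), mirroring the
    built-in detector's one-hit-per-domain contract.
    """
    best: dict = {}
    for row in rows:
        key = (row.protein_id, row.domain)
        if key not in best or row.score > best[key].score:
            best[key] = row
    grouped: dict = {}
    for (pid, domain), row in sorted(best.items()):
        grouped.setdefault(pid, []).append(
            DomainHit(
                protein_id=pid,
                domain=domain,
                start=row.start,
                end=row.end,
                score=row.score,
            )
        )
    for pid in grouped:
        grouped[pid].sort(key=lambda h: (h.start, h.domain))
    return grouped


def classify_architecture(hits: Sequence[DomainHit], protein_id: str = "") -> Architecture:
    """Call the architecture class from a protein's domain content."""
    ids = {h.protein_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(ids)}")
    pid = protein_id or (next(iter(ids)) if ids else "")
    present = frozenset(h.domain for h in hits)

    tyr_part = present & TYROSINASE_FAMILY
    cu_part = present & CU_OXIDASE_FAMILY
    if tyr_part and cu_part:
        log.warning("protein %s mixes tyrosinase and Cu-oxidase domains (chimera)", pid)
        cls = "UNCLASSIFIED"
    elif present == {"TYROSINASE"}:
        cls = "TYR_LIKE"
    elif present == {"TYROSINASE", "PPO1_DWL"}:
        cls = "CO_DWL"
    elif present == {"TYROSINASE", "PPO1_DWL", "PPO1_KFDV"}:
        cls = "CO_FULL"
    elif present == CU_OXIDASE_FAMILY:
        cls = "MCO"
    else:
        cls = "UNCLASSIFIED"
    return Architecture(protein_id=pid, cls=cls, domains_present=present)


def detect_kfdv_motif(
    query: SequenceRecord, kfdv_hit: Optional[DomainHit] = None
) -> tuple:
    """Locate the conserved KFDV tetrapeptide of the C-terminal shield domain.

    With a PPO1_KFDV hit supplied the motif must fall inside the hit span;
    without one the whole sequence is searched and the hit is flagged as
    unanchored. Returns ``(found, position, anchored)`` with the 0-based
    position of the leftmost K, or ``(False, None, anchored)``.
    """
    seq = query.seq
    if kfdv_hit is not None:
        window = seq[kfdv_hit.start : kfdv_hit.end]
        idx = window.find("KFDV")
        if idx == -1:
            return False, None, True
        return True, kfdv_hit.start + idx, True
    idx = seq.find("KFDV")
    if idx == -1:
        return False, None, False
    return True, idx, False
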