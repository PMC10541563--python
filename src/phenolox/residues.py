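"""Reference-anchored extraction of diagnostic active-site residues.

Catechol oxidases bind two copper ions (CuA, CuB) through six conserved
histidines (HisA1–HisA3, HisB1–HisB3); an enzyme missing any of the six
has a structurally defective center and is called non-functional here.
Around the pocket sit further diagnostic residues: the gatekeeper
phenylalanine controlling substrate access, the HB1+1 and HB2+1 activity
controllers immediately after the first and second CuB histidine, and the
waterkeeper glutamate. Laccases/ascorbate oxidases are profiled instead
by their three histidine regions (H-A, H-B, H-C) and the four residues
following a conserved NNX motif near the substrate pocket.

Each query is anchored to a single annotated reference by global
alignment; diagnostic positions are data (a packaged plain-text profile
keyed to the reference), not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import _align
from .seqio import SeqIOError, SequenceRecord, to_internal

SIX_HIS_ROLES = ("HisA1", "HisA2", "HisA3", "HisB1", "HisB2", "HisB3")
CO_ROLES = SIX_HIS_ROLES + ("gatekeeper", "HB1plus1", "HB2plus1", "waterkeeper")


@dataclass(frozen=True)
class Alignment:
    """A gapped pairwise alignment of a query against a reference."""

    query_row: str
    reference_row: str
    score: float

    def __post_init__(self) -> None:
        if len(self.query_row) != len(self.reference_row):
            raise ValueError("alignment rows differ in length")

    @property
    def query(self) -> str:
        return self.query_row.replace("-", "")

    @property
    def reference(self) -> str:
        return self.reference_row.replace("-", "")


@dataclass(frozen=True)
class AnchorProfile:
    """An annotated reference: domain spans plus named diagnostic positions.

    ``named_positions`` maps role names to 1-based positions on the
    ungapped reference. Profile construction checks that every HisX role
    sits on an 'H' and the waterkeeper on an 'E'.
    """

    family: str  # "CO" or "LAC_AAO"
    reference: SequenceRecord
    domain_spans: Tuple[Tuple[int, int], ...]  # internal 0-based half-open
    named_positions: Dict[str, int]

    def __post_init__(self) -> None:
        if self.family not in ("CO", "LAC_AAO"):
            raise ValueError(f"unknown profile family {self.family!r}")
        seq = self.reference.seq
        for start, end in self.domain_spans:
            if not (0 <= start < end <= len(seq)):
                raise ValueError(f"domain span [{start},{end}) outside reference")
        for role, pos in self.named_positions.items():
            if not (1 <= pos <= len(seq)):
                raise ValueError(f"role {role}: position {pos} outside reference")
            idx = pos - 1
            if not any(s <= idx < e for s, e in self.domain_spans):
                raise ValueError(f"role {role}: position {pos} outside domain spans")
            residue = seq[idx]
            if role.startswith("His") and residue != "H":
                raise ValueError(f"role {role}: reference residue {residue!r} is not H")
            if role == "waterkeeper" and residue != "E":
                raise ValueError(f"waterkeeper: reference residue {residue!r} is not E")
        if self.family == "CO":
            missing = [r for r in CO_ROLES if r not in self.named_positions]
            if missing:
                raise ValueError(f"CO profile missing roles: {missing}")
        if self.family == "LAC_AAO" and "NNX_anchor" not in self.named_positions:
            raise ValueError("LAC_AAO profile requires an NNX_anchor role")
        if "NNX_anchor" in self.named_positions:
            idx = self.named_positions["NNX_anchor"] - 1
            if seq[idx : idx + 2] != "NN":
                raise ValueError("NNX_anchor does not point at the first N of an NN pair")


@dataclass(frozen=True)
class ResidueReport:
    """Mapped diagnostic residues of one query, with the six-His verdict."""

    protein_id: str
    residues: Dict[str, str]  # role -> single AA or '-'
    extracted_domain_seq: str
    functionality: Optional[str] = None  # "functional" / "non_functional" (CO only)
    missing_his: frozenset = frozenset()


def global_align(a: str, b: str) -> Alignment:
    """Optimal global alignment (BLOSUM62, affine gaps open 10 / extend 1)."""
    res = _align.align_global(a, b)
    return Alignment(query_row=res.query_row, reference_row=res.target_row, score=res.score)


def read_profile(path, reference: SequenceRecord, family: str) -> AnchorProfile:
    """Parse a plain-text anchor profile.

    Format: '#' comments; ``reference<TAB>id`` naming the reference;
    ``domain<TAB>start<TAB>end`` spans (1-based inclusive); all other
    lines are ``role<TAB>position`` (1-based).
    """
    ref_id = None
    spans: List[Tuple[int, int]] = []
    roles: Dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "reference":
            ref_id = parts[1]
        elif parts[0] == "domain":
            spans.append(to_internal(int(parts[1]), int(parts[2])))
        else:
            if len(parts) != 2:
                raise SeqIOError(f"{path}:{lineno}: expected 'role<TAB>position'")
            roles[parts[0]] = int(parts[1])
    if ref_id is not None and ref_id != reference.id:
        raise SeqIOError(
            f"profile names reference {ref_id!r} but sequence {reference.id!r} was supplied"
        )
    return AnchorProfile(
        family=family,
        reference=reference,
        domain_spans=tuple(spans),
        named_positions=roles,
    )


def _reference_column_map(aln: Alignment, profile: AnchorProfile) -> List[int]:
    """Column index in the alignment for each reference position (0-based)."""
    if aln.reference != profile.reference.seq:
        raise ValueError("alignment reference row does not ungap to the profile reference")
    cols = []
    for col, ch in enumerate(aln.reference_row):
        if ch != "-":
            cols.append(col)
    return cols


def extract_domain_columns(aln: Alignment, profile: AnchorProfile) -> str:
    """Query residues aligned to reference domain columns, gaps dropped.

    Insertions relative to the reference (including whole inter-domain
    linkers) are invisible; a query deletion across a domain shortens the
    output by that span.
    """
    cols = _reference_column_map(aln, profile)
    out = []
    for start, end in profile.domain_spans:
        for refpos in range(start, end):
            ch = aln.query_row[cols[refpos]]
            if ch != "-":
                out.append(ch)
    return "".join(out)


def extract_domain_columns_aligned(aln: Alignment, profile: AnchorProfile) -> str:
    """Like :func:`extract_domain_columns` but gap-padded to the reference.

    Output length always equals the total domain-span length, so
    extractions of many queries against one profile are mutually aligned —
    the input the tree stage needs.
    """
    cols = _reference_column_map(aln, profile)
    out = []
    for start, end in profile.domain_spans:
        for refpos in range(start, end):
            out.append(aln.query_row[cols[refpos]])
    return "".join(out)


def map_positions(aln: Alignment, profile: AnchorProfile, protein_id: str = "") -> ResidueReport:
    """Report the query residue in each named reference column ('-' if gapped)."""
    cols = _reference_column_map(aln, profile)
    residues = {}
    for role, pos in profile.named_positions.items():
        residues[role] = aln.query_row[cols[pos - 1]]
    return ResidueReport(
        protein_id=protein_id,
        residues=residues,
        extracted_domain_seq=extract_domain_columns(aln, profile),
    )


def classify_functionality(report: ResidueReport) -> ResidueReport:
    """Apply the six-His rule: any of the six CuA/CuB histidines not an 'H'
    (substitution or gap alike) makes the enzyme center non-functional."""
    missing = [r for r in SIX_HIS_ROLES if r not in report.residues]
    if missing:
        raise ValueError(f"report lacks six-His roles: {missing}")
    absent = frozenset(r for r in SIX_HIS_ROLES if report.residues[r] != "H")
    verdict = "non_functional" if absent else "functional"
    return ResidueReport(
        protein_id=report.protein_id,
        residues=report.residues,
        extracted_domain_seq=report.extracted_domain_seq,
        functionality=verdict,
        missing_his=absent,
    )


def nnx_following_residues(aln: Alignment, profile: AnchorProfile) -> str:
    """The query residues in the four reference columns after the NNX motif.

    In land-plant ascorbate oxidases these four positions are frequently
    lost entirely, so an all-gap result is a valid observation.
    """
    if profile.family != "LAC_AAO":
        raise ValueError("NNX extraction requires a LAC_AAO profile")
    cols = _reference_column_map(aln, profile)
    anchor = profile.named_positions["NNX_anchor"]  # 1-based first N
    out = []
    for pos in range(anchor + 3, anchor + 7):  # four positions after N,N,X
        out.append(aln.query_row[cols[pos - 1]])
    return "".join(out)


def profile_report(
    query: SequenceRecord, profile: AnchorProfile
) -> Tuple[Alignment, ResidueReport]:
    """Anchor one query to the profile reference and map all roles.

    CO-family reports carry the six-His functionality verdict.
    """
    aln = global_align(query.seq, profile.reference.seq)
    report = map_positions(aln, profile, protein_id=query.id)
    if profile.family == "CO":
        report = classify_functionality(report)
    return aln, report
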