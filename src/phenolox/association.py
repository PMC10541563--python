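"""Chloroplast-targeting calls, the functionality x targeting contingency,
an exact two-sided Fisher test, and the per-species family census.

Targeting scores come from an external localization predictor and are
consumed, not computed: a protein is called chloroplast-targeted when its
score strictly exceeds the threshold (default 7). The association of
structural non-functionality with chloroplast targeting is then a single
2x2 Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from scipy.stats import hypergeom

from .classify import Architecture
from .seqio import SeqIOError

log = logging.getLogger(__name__)

DEFAULT_TARGETING_THRESHOLD = 7.0
_REL_SLACK = 1e-12  # float-tie tolerance in the probability-mass rule


@dataclass(frozen=True)
class TargetingCall:
    protein_id: str
    score: float
    targeted: bool


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: functional / non_functional; columns: targeted / not."""

    a: int  # functional, targeted
    b: int  # functional, not targeted
    c: int  # non_functional, targeted
    d: int  # non_functional, not targeted

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if not (isinstance(v, int) and v >= 0):
                raise ValueError("contingency counts must be non-negative integers")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def read_scores(path) -> Dict[str, float]:
    """Two-column TSV (protein_id, score); '#' lines are comments."""
    scores: Dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise SeqIOError(f"{path}:{lineno}: expected 'id<TAB>score'")
        try:
            scores[parts[0]] = float(parts[1])
        except ValueError:
            raise SeqIOError(f"{path}:{lineno}: non-numeric score {parts[1]!r}") from None
    return scores


def call_targeting(
    scores: Dict[str, float],
    threshold: float = DEFAULT_TARGETING_THRESHOLD,
    ids: Optional[Iterable[str]] = None,
) -> List[TargetingCall]:
    """Strict score > threshold calls; listed ids without a score are
    excluded with a warning."""
    if ids is None:
        ids = scores.keys()
    calls = []
    for pid in ids:
        if pid not in scores:
            log.warning("no targeting score for %s; excluded", pid)
            continue
        s = scores[pid]
        calls.append(TargetingCall(protein_id=pid, score=s, targeted=s > threshold))
    return calls


def targeting_summary(calls: Sequence[TargetingCall]) -> str:
    """'k of n' chloroplast-targeted summary string."""
    return f"{sum(1 for c in calls if c.targeted)} of {len(calls)}"


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by the probability-mass rule.

    p = sum of hypergeometric probabilities, at fixed margins, of all
    tables no more probable than the observed one (with 1e-12 relative
    slack on the comparison to avoid float-tie artifacts).
    """
    if table.total == 0:
        raise ValueError("all-zero contingency table")
    r1 = table.a + table.b
    c1 = table.a + table.c
    n = table.total
    dist = hypergeom(n, r1, c1)
    p_obs = dist.pmf(table.a)
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    p = 0.0
    for k in range(lo, hi + 1):
        pk = dist.pmf(k)
        if pk <= p_obs * (1.0 + _REL_SLACK):
            p += pk
    return min(p, 1.0)


def functionality_targeting_table(
    functionality: Dict[str, str],
    targeting: Sequence[TargetingCall],
) -> ContingencyTable2x2:
    """Cross-tabulate functionality and targeting over shared protein ids."""
    targeted = {c.protein_id: c.targeted for c in targeting}
    shared = set(functionality) & set(targeted)
    if not shared:
        raise ValueError("functionality and targeting inputs share no protein ids")
    dropped = (len(functionality) - len(shared)) + (len(targeted) - len(shared))
    if dropped:
        log.info("functionality/targeting join dropped %d unmatched ids", dropped)
    a = b = c = d = 0
    for pid in shared:
        functional = functionality[pid] == "functional"
        if functional and targeted[pid]:
            a += 1
        elif functional:
            b += 1
        elif targeted[pid]:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a=a, b=b, c=c, d=d)


@dataclass(frozen=True)
class CensusRow:
    """Per-species family counts in the style of the a/b census columns."""

    species: str
    n_tyr_like: int
    n_co: int  # CO_DWL + CO_FULL
    n_co_dwl: int
    n_co_full: int
    n_mco: int
    n_unclassified: int
    n_kfdv_motif: int
    nonfunctional_of_co: str  # "k of n" or "NA"


def census(
    architectures: Sequence[Tuple[str, Architecture]],
    functionality: Optional[Dict[str, str]] = None,
) -> List[CensusRow]:
    """Tally architecture classes per species.

    ``architectures`` is (species, Architecture) pairs. When functionality
    calls are joined, the CO column carries the 'k of n' non-functionality
    string the selection summary also uses.
    """
    by_species: Dict[str, List[Architecture]] = {}
    for species, arch in architectures:
        by_species.setdefault(species, []).append(arch)
    rows = []
    for species in sorted(by_species):
        archs = by_species[species]
        tally = {"TYR_LIKE": 0, "CO_DWL": 0, "CO_FULL": 0, "MCO": 0, "UNCLASSIFIED": 0}
        n_kfdv = 0
        co_ids = []
        for arch in archs:
            tally[arch.cls] += 1
            if arch.kfdv_motif:
                n_kfdv += 1
            if arch.cls in ("CO_DWL", "CO_FULL"):
                co_ids.append(arch.protein_id)
        if functionality is not None:
            co_with = [pid for pid in co_ids if pid in functionality]
            n_nf = sum(1 for pid in co_with if functionality[pid] == "non_functional")
            nf = f"{n_nf} of {len(co_with)}"
        else:
            nf = "NA"
        rows.append(
            CensusRow(
                species=species,
                n_tyr_like=tally["TYR_LIKE"],
                n_co=tally["CO_DWL"] + tally["CO_FULL"],
                n_co_dwl=tally["CO_DWL"],
                n_co_full=tally["CO_FULL"],
                n_mco=tally["MCO"],
                n_unclassified=tally["UNCLASSIFIED"],
                n_kfdv_motif=n_kfdv,
                nonfunctional_of_co=nf,
            )
        )
    return rows
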