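"""Duplicate-pair identification and Nei–Gojobori (NG86) Ka/Ks.

Within-species duplicate gene pairs are retained when the aligned regions
of the two proteins exceed 70% identity and cover more than 80% of the
shorter protein (both strict). For each retained pair the approximate
NG86 method estimates synonymous (Ks) and nonsynonymous (Ka)
substitutions per site:

* each codon position contributes a synonymous-site fraction equal to the
  proportion of its non-stop single-nucleotide changes that are
  synonymous (so sites per codon always sum to 3);
* codon pairs differing at k positions average the synonymous /
  nonsynonymous difference counts over all k! minimal mutational
  pathways, excluding pathways that pass through a stop codon;
* proportions pS = Sd/Ns, pN = Nd/Na are Jukes–Cantor corrected,
  d = -(3/4) ln(1 - 4p/3).

omega = Ka/Ks classifies selection: >1 positive, <1 purifying, =1 (within
an optional band) neutral. Pairs with Ks = 0 or a saturated correction
carry an NA ratio and are reported separately, never counted as neutral.

The codon alignment is induced from the protein alignment (align the
proteins, back-map gaps onto codons), the standard robust realization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Dict, List, Optional, Sequence, Tuple

from . import _align
from .seqio import GeneticCode, STANDARD_CODE, SequenceRecord

log = logging.getLogger(__name__)

NUCS = "ACGT"

DEFAULT_MIN_SIMILARITY = 0.70
DEFAULT_MIN_COVERAGE = 0.80


@dataclass(frozen=True)
class GenePair:
    """A within-species duplicate candidate with its alignment statistics."""

    species: str
    id_a: str
    id_b: str
    fraction_identity: float
    coverage: float

    def __post_init__(self) -> None:
        if not self.id_a < self.id_b:
            raise ValueError("GenePair ids must be lexicographically ordered")
        for name in ("fraction_identity", "coverage"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError(f"{name} {v} outside [0,1]")


@dataclass(frozen=True)
class KaKsResult:
    pair: GenePair
    Ns: float  # average synonymous sites
    Na: float  # average nonsynonymous sites
    Sd: float  # pathway-averaged synonymous differences
    Nd: float
    pS: float
    pN: float
    Ks: Optional[float]
    Ka: Optional[float]
    ratio: Optional[float]
    selection_class: str
    n_codons: int  # compared codons


def ng86_sites(codon: str, code: GeneticCode = STANDARD_CODE) -> Tuple[float, float]:
    """Synonymous/nonsynonymous site counts of one sense codon.

    Changes creating stop codons are dropped from both the numerator and
    the per-position denominator (position-wise renormalization), so the
    two counts always sum to exactly 3.
    """
    codon = codon.upper()
    if "N" in codon or len(codon) != 3:
        raise ValueError(f"cannot count sites for codon {codon!r}")
    aa = code.codon_to_aa[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no site counts")
    syn = 0.0
    for pos in range(3):
        n_valid = 0
        n_syn = 0
        for alt in NUCS:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            maa = code.codon_to_aa[mutant]
            if maa == "*":
                continue
            n_valid += 1
            if maa == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


def _pathway_differences(
    codon_a: str, codon_b: str, code: GeneticCode
) -> Tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts over all
    minimal mutational pathways between two codons, excluding pathways
    through stop codons. Falls back to all pathways if every one is
    blocked (both endpoints are sense codons, so counts stay defined)."""
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_positions)
    if k == 0:
        return 0.0, 0.0

    def walk(order, allow_stops: bool):
        syn = nsyn = 0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if code.codon_to_aa[nxt] == "*" and not allow_stops:
                return None
            if code.codon_to_aa[nxt] == code.codon_to_aa[current]:
                syn += 1
            else:
                nsyn += 1
            current = nxt
        return syn, nsyn

    results = [r for r in (walk(o, False) for o in permutations(diff_positions)) if r]
    if not results:
        results = [walk(o, True) for o in permutations(diff_positions)]
    s = sum(r[0] for r in results) / len(results)
    n = sum(r[1] for r in results) / len(results)
    return s, n


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 multiple-hit correction; undefined (None) at p >= 3/4."""
    if p < 0:
        raise ValueError("proportion below 0")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _usable_codon(codon: str, code: GeneticCode) -> bool:
    return (
        "-" not in codon
        and "N" not in codon
        and code.codon_to_aa.get(codon) not in (None, "*")
    )


def ng86_pair(
    cds_a: str, cds_b: str, code: GeneticCode = STANDARD_CODE,
    pair: Optional[GenePair] = None, neutral_band: float = 0.0,
) -> KaKsResult:
    """NG86 Ka/Ks on two aligned coding sequences of equal length.

    Codons containing a gap, an N, or a stop in either sequence are
    skipped pairwise. Site counts are averaged over the two sequences.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned coding sequences differ in length")
    if len(cds_a) % 3 != 0:
        raise ValueError("aligned CDS length not divisible by 3")
    Ns = Na = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if not (_usable_codon(ca, code) and _usable_codon(cb, code)):
            continue
        n_codons += 1
        sa, _ = ng86_sites(ca, code)
        sb, _ = ng86_sites(cb, code)
        s_sites = 0.5 * (sa + sb)
        Ns += s_sites
        Na += 3.0 - s_sites
        sd, nd = _pathway_differences(ca, cb, code)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise ValueError("no comparable codons between the two sequences")
    pS = Sd / Ns if Ns > 0 else 0.0
    pN = Nd / Na if Na > 0 else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    ratio = None
    if Ka is not None and Ks is not None and Ks > 0:
        ratio = Ka / Ks
    if pair is None:
        pair = GenePair(species="", id_a="a", id_b="b", fraction_identity=1.0, coverage=1.0)
    return KaKsResult(
        pair=pair,
        Ns=Ns,
        Na=Na,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        Ks=Ks,
        Ka=Ka,
        ratio=ratio,
        selection_class=classify_selection(ratio, neutral_band),
        n_codons=n_codons,
    )


def classify_selection(ratio: Optional[float], neutral_band: float = 0.0) -> str:
    """Positive (>1), purifying (<1), neutral (=1 within the band), or NA."""
    if ratio is None:
        return "NA"
    if ratio < 0:
        raise ValueError("omega cannot be negative")
    if abs(ratio - 1.0) <= neutral_band:
        return "neutral"
    return "positive" if ratio > 1.0 else "purifying"


# ---------------------------------------------------------------------------
# duplicate-pair identification

def pair_statistics(prot_a: str, prot_b: str) -> Tuple[float, float, object]:
    """Identity and coverage of a global protein alignment.

    Identity is over aligned (non-gap-pair) columns; coverage is aligned
    columns over the length of the longer protein, so a gene truncated to
    half its paralog's length scores coverage 0.5 however perfectly the
    remnant aligns.
    """
    res = _align.align_global(prot_a, prot_b)
    identity = res.fraction_identity
    coverage = res.aligned_columns / max(len(prot_a), len(prot_b))
    return identity, coverage, res


def find_duplicate_pairs(
    proteins: Sequence[SequenceRecord],
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> List[GenePair]:
    """All within-species protein pairs passing the strict >70% / >80% rule."""
    by_species: Dict[str, List[SequenceRecord]] = {}
    for rec in proteins:
        by_species.setdefault(rec.species, []).append(rec)
    pairs: List[GenePair] = []
    for species in sorted(by_species):
        members = sorted(by_species[species], key=lambda r: r.id)
        if len(members) < 2:
            continue
        for a, b in combinations(members, 2):
            identity, coverage, _ = pair_statistics(a.seq, b.seq)
            if identity > min_similarity and coverage > min_coverage:
                pairs.append(
                    GenePair(
                        species=species,
                        id_a=min(a.id, b.id),
                        id_b=max(a.id, b.id),
                        fraction_identity=identity,
                        coverage=coverage,
                    )
                )
    return pairs


def codon_alignment_from_proteins(
    prot_row_a: str, prot_row_b: str, cds_a: str, cds_b: str
) -> Tuple[str, str]:
    """Back-map a gapped protein alignment onto the two coding sequences.

    Each protein gap becomes a codon gap '---'; terminal stop codons on
    the CDS are tolerated and trimmed.
    """
    def trim(cds: str, n_aa: int) -> str:
        if len(cds) == 3 * (n_aa + 1):
            return cds[:-3]  # drop the stop codon
        if len(cds) != 3 * n_aa:
            raise ValueError(
                f"CDS length {len(cds)} does not match protein length {n_aa}"
            )
        return cds

    out_a, out_b = [], []
    ia = ib = 0
    na = len(prot_row_a.replace("-", ""))
    nb = len(prot_row_b.replace("-", ""))
    cds_a = trim(cds_a, na)
    cds_b = trim(cds_b, nb)
    for ca, cb in zip(prot_row_a, prot_row_b):
        if ca == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia : 3 * ia + 3])
            ia += 1
        if cb == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib : 3 * ib + 3])
            ib += 1
    return "".join(out_a), "".join(out_b)


def kaks_for_pairs(
    pairs: Sequence[GenePair],
    proteins: Dict[str, SequenceRecord],
    cds: Dict[str, SequenceRecord],
    code: GeneticCode = STANDARD_CODE,
    neutral_band: float = 0.0,
) -> List[KaKsResult]:
    """Run NG86 on each retained pair via protein-guided codon alignment."""
    results = []
    for pair in pairs:
        pa, pb = proteins[pair.id_a], proteins[pair.id_b]
        res = _align.align_global(pa.seq, pb.seq)
        row_a, row_b = res.query_row, res.target_row
        aln_a, aln_b = codon_alignment_from_proteins(
            row_a, row_b, cds[pair.id_a].seq, cds[pair.id_b].seq
        )
        results.append(ng86_pair(aln_a, aln_b, code, pair=pair, neutral_band=neutral_band))
    return results


# ---------------------------------------------------------------------------
# per-species summary (Table-1-like layout)

@dataclass(frozen=True)
class SpeciesSelectionSummary:
    species: str
    n_pairs: int
    n_purifying: int
    mean_purifying: Optional[float]
    n_positive: int
    mean_positive: Optional[float]
    n_neutral: int
    n_na: int
    nonfunctional_of_total: str  # "k of n", or "NA" when no functionality input


def species_summary(
    results: Sequence[KaKsResult],
    functionality: Optional[Dict[str, str]] = None,
    species: Optional[str] = None,
) -> SpeciesSelectionSummary:
    """Collapse one species' pair results into the per-species summary row."""
    if species is None:
        sps = {r.pair.species for r in results}
        if len(sps) > 1:
            raise ValueError(f"results span multiple species: {sorted(sps)}")
        species = next(iter(sps)) if sps else ""

    def bucket(cls):
        return [r.ratio for r in results if r.selection_class == cls]

    pur, pos, neu = bucket("purifying"), bucket("positive"), bucket("neutral")
    n_na = sum(1 for r in results if r.selection_class == "NA")
    if functionality:
        n_total = len(functionality)
        n_nf = sum(1 for v in functionality.values() if v == "non_functional")
        nf = f"{n_nf} of {n_total}"
    else:
        nf = "NA"
    mean = lambda xs: (sum(xs) / len(xs)) if xs else None
    return SpeciesSelectionSummary(
        species=species,
        n_pairs=len(results),
        n_purifying=len(pur),
        mean_purifying=mean(pur),
        n_positive=len(pos),
        mean_positive=mean(pos),
        n_neutral=len(neu),
        n_na=n_na,
        nonfunctional_of_total=nf,
    )
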