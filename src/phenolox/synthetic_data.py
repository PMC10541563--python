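"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes —
mixed domain architectures with a minority of His-defective catechol
oxidases, duplicate coding-sequence pairs fixed at a controlled dN/dS,
species groups with controlled codon-usage bias, targeting scores with a
planted association or independence, and alignments evolved on a planted
tree. They are deliberately simple: no indel model beyond inter-domain
linkers, no rate heterogeneity, no realistic amino-acid composition.
Every generator is a pure function of its config (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from . import resources
from .residues import AnchorProfile, SIX_HIS_ROLES
from .seqio import GeneticCode, STANDARD_CODE, SequenceRecord, write_fasta

AA20 = "ACDEFGHIKLMNPQRSTVWY"
NUCS = "ACGT"

DEFAULT_ARCHITECTURE_MIX = {
    "TYR_LIKE": 0.20,
    "CO_DWL": 0.25,
    "CO_FULL": 0.35,
    "MCO": 0.20,
}


@dataclass(frozen=True)
class SimConfig:
    """Shared knob set for the generators.

    Defaults reflect the conditions the analysis is designed around: a
    minority (~30%) of His-defective catechol oxidases, duplicate pairs
    of ~300 codons at moderate divergence, and a clearly detectable
    two-group codon bias.
    """

    seed: int = 0
    n_seqs: int = 100
    architecture_mix: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARCHITECTURE_MIX)
    )
    nonfunctional_rate: float = 0.3
    mutation_rate: float = 0.0  # per-residue substitution rate outside protected sites
    omega: float = 0.2
    n_codons: int = 300
    t: float = 0.3  # proposed changes per codon per lineage
    bias_strength: float = 0.8
    n_groups: int = 2
    species_per_group: int = 3

    def __post_init__(self) -> None:
        if abs(sum(self.architecture_mix.values()) - 1.0) > 1e-9:
            raise ValueError("architecture_mix proportions must sum to 1")
        for name in ("nonfunctional_rate", "mutation_rate", "bias_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0,1]")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if not 0.0 <= self.t <= 1.0:
            raise ValueError("divergence t outside [0,1]")


@dataclass(frozen=True)
class ProteinTruth:
    protein_id: str
    species: str
    cls: str
    missing_his: frozenset  # planted defect roles (subset of the six His)
    has_kfdv: bool


# ---------------------------------------------------------------------------
# architecture / residue simulator

def _linker(rng: np.random.Generator, lo: int = 8, hi: int = 20) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(AA20), size=length))


def simulate_proteins(
    cfg: SimConfig, species: Optional[Sequence[str]] = None
) -> Tuple[List[SequenceRecord], AnchorProfile, List[ProteinTruth]]:
    """Assemble proteins from the packaged synthetic domain templates.

    Tyrosinase-family records carry the full set of planted diagnostic
    residues (six His, gatekeeper F, waterkeeper E, HB+1 controllers);
    with probability ``nonfunctional_rate`` one uniformly chosen His is
    substituted by a random non-H residue. Point mutations at
    ``mutation_rate`` are applied only outside +/-3 of every named
    position (and outside the KFDV tetrapeptide), so planted residues
    survive mutation by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    templates = resources.load_templates()
    profile = resources.load_co_profile()
    offsets = resources.template_role_offsets()  # role -> 0-based offset in TYROSINASE
    kfdv_offset = resources.KFDV_MOTIF_OFFSET  # 0-based within PPO1_KFDV

    if species is None:
        species = ["simspecies"]
    classes = sorted(cfg.architecture_mix)
    probs = np.array([cfg.architecture_mix[c] for c in classes])

    records: List[SequenceRecord] = []
    truths: List[ProteinTruth] = []
    for idx in range(cfg.n_seqs):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        sp = species[idx % len(species)]
        if cls == "MCO":
            parts = ["CU_OXIDASE_3", "CU_OXIDASE", "CU_OXIDASE_2"]
        elif cls == "TYR_LIKE":
            parts = ["TYROSINASE"]
        elif cls == "CO_DWL":
            parts = ["TYROSINASE", "PPO1_DWL"]
        else:
            parts = ["TYROSINASE", "PPO1_DWL", "PPO1_KFDV"]

        chunks = [_linker(rng)]
        protected: set = set()
        named: Dict[str, int] = {}  # role -> 0-based position in assembly
        for part in parts:
            start = sum(len(c) for c in chunks)
            chunks.append(templates[part])
            if part == "TYROSINASE":
                for role, off in offsets.items():
                    named[role] = start + off
            if part == "PPO1_KFDV":
                protected.update(range(start + kfdv_offset, start + kfdv_offset + 4))
            chunks.append(_linker(rng))
        seq = list("".join(chunks))
        for pos in named.values():
            protected.update(range(pos - 3, pos + 4))

        missing: frozenset = frozenset()
        if named and rng.random() < cfg.nonfunctional_rate:
            role = SIX_HIS_ROLES[int(rng.integers(len(SIX_HIS_ROLES)))]
            pos = named[role]
            choices = [a for a in AA20 if a != "H"]
            seq[pos] = choices[int(rng.integers(len(choices)))]
            missing = frozenset([role])

        if cfg.mutation_rate > 0:
            hits = np.nonzero(rng.random(len(seq)) < cfg.mutation_rate)[0]
            for pos in hits:
                if int(pos) in protected:
                    continue
                choices = [a for a in AA20 if a != seq[pos]]
                seq[pos] = choices[int(rng.integers(len(choices)))]

        pid = f"syn{idx:04d}"
        records.append(
            SequenceRecord(id=pid, species=sp, kind="protein", seq="".join(seq))
        )
        truths.append(
            ProteinTruth(
                protein_id=pid,
                species=sp,
                cls=cls,
                missing_his=missing,
                has_kfdv="PPO1_KFDV" in parts,
            )
        )
    return records, profile, truths


# ---------------------------------------------------------------------------
# codon-pair simulator (controlled dN/dS)

@dataclass(frozen=True)
class CodonPairTruth:
    omega: float
    t: float
    fixed_synonymous: int
    fixed_nonsynonymous: int


def _random_sense_cds(
    rng: np.random.Generator, n_codons: int, code: GeneticCode
) -> List[str]:
    sense = sorted(code.sense_codons)
    return [sense[int(i)] for i in rng.integers(0, len(sense), size=n_codons)]


def _evolve_lineage(
    codons: List[str],
    n_proposals: int,
    omega: float,
    rng: np.random.Generator,
    code: GeneticCode,
) -> Tuple[List[str], int, int]:
    """Proposal–acceptance fixation: synonymous proposals accepted with
    probability 1 and nonsynonymous with omega (for omega > 1 the roles
    flip: nonsynonymous 1, synonymous 1/omega), so realized nonsyn/syn
    fixation odds equal omega. Proposals creating stops are redrawn."""
    codons = list(codons)
    p_syn = 1.0 if omega <= 1 else 1.0 / omega
    p_non = omega if omega <= 1 else 1.0
    n_syn = n_non = 0
    done = 0
    while done < n_proposals:
        ci = int(rng.integers(len(codons)))
        pos = int(rng.integers(3))
        alt = NUCS[int(rng.integers(4))]
        codon = codons[ci]
        if alt == codon[pos]:
            continue
        mutant = codon[:pos] + alt + codon[pos + 1 :]
        if code.codon_to_aa[mutant] == "*":
            continue  # rejected outright; redraw
        done += 1
        synonymous = code.codon_to_aa[mutant] == code.codon_to_aa[codon]
        p_accept = p_syn if synonymous else p_non
        if rng.random() < p_accept:
            codons[ci] = mutant
            if synonymous:
                n_syn += 1
            else:
                n_non += 1
    return codons, n_syn, n_non


def simulate_codon_pair(
    cfg: SimConfig, code: GeneticCode = STANDARD_CODE
) -> Tuple[str, str, CodonPairTruth]:
    """Two coding sequences diverged from a random sense-codon ancestor.

    Each lineage receives ``round(n_codons * t)`` proposed single-
    nucleotide changes.
    """
    rng = np.random.default_rng(cfg.seed)
    ancestor = _random_sense_cds(rng, cfg.n_codons, code)
    n_prop = int(round(cfg.n_codons * cfg.t))
    a, sa, na = _evolve_lineage(ancestor, n_prop, cfg.omega, rng, code)
    b, sb, nb = _evolve_lineage(ancestor, n_prop, cfg.omega, rng, code)
    truth = CodonPairTruth(
        omega=cfg.omega,
        t=cfg.t,
        fixed_synonymous=sa + sb,
        fixed_nonsynonymous=na + nb,
    )
    return "".join(a), "".join(b), truth


# ---------------------------------------------------------------------------
# codon-bias simulator

def _group_preferences(
    rng: np.random.Generator, code: GeneticCode, bias_strength: float
) -> Dict[str, np.ndarray]:
    """Per-family codon preference: uniform interpolated toward a spiky
    Dirichlet draw as bias_strength goes 0 -> 1."""
    prefs: Dict[str, np.ndarray] = {}
    for aa, family in sorted(code.synonymous_families().items()):
        k = len(family)
        if k == 1:
            prefs[aa] = np.array([1.0])
            continue
        spiky = rng.dirichlet(np.full(k, 0.3))
        prefs[aa] = (1.0 - bias_strength) / k + bias_strength * spiky
        prefs[aa] = prefs[aa] / prefs[aa].sum()
    return prefs


def simulate_codon_bias(
    cfg: SimConfig, code: GeneticCode = STANDARD_CODE, codons_per_species: int = 2000
) -> Tuple[List[SequenceRecord], Dict[str, int]]:
    """CDS sets for ``n_groups`` x ``species_per_group`` species.

    Species within a group share one Dirichlet-perturbed codon preference;
    amino acids are drawn uniformly over the degenerate families. Returns
    the records and the planted species -> group truth.
    """
    if cfg.n_groups < 2:
        raise ValueError("simulate_codon_bias needs n_groups >= 2")
    rng = np.random.default_rng(cfg.seed)
    fams = code.synonymous_families()
    multi = sorted(aa for aa, f in fams.items() if len(f) > 1)
    records: List[SequenceRecord] = []
    truth: Dict[str, int] = {}
    for g in range(cfg.n_groups):
        prefs = _group_preferences(rng, code, cfg.bias_strength)
        for s in range(cfg.species_per_group):
            sp = f"g{g}s{s}"
            aas = [multi[int(i)] for i in rng.integers(0, len(multi), size=codons_per_species)]
            codons = []
            for aa in aas:
                family = fams[aa]
                codons.append(family[int(rng.choice(len(family), p=prefs[aa]))])
            records.append(
                SequenceRecord(id=f"{sp}_cds", species=sp, kind="cds", seq="".join(codons))
            )
            truth[sp] = g
    return records, truth


# ---------------------------------------------------------------------------
# targeting-score simulator

def simulate_targeting_scores(
    ids: Sequence[str],
    dependence: str,
    seed: int,
    functionality: Optional[Dict[str, str]] = None,
    threshold: float = 7.0,
    shift: float = 3.0,
) -> Dict[str, float]:
    """Localization-predictor scores around the calling threshold.

    ``independent``: identical Normal(threshold, 2) draws regardless of
    functionality. ``positive``: functional proteins shifted up by
    ``shift``, non-functional down by the same amount.
    """
    if dependence not in ("independent", "positive"):
        raise ValueError(f"unknown dependence {dependence!r}")
    if dependence == "positive" and functionality is None:
        raise ValueError("positive dependence requires functionality truth")
    rng = np.random.default_rng(seed)
    scores: Dict[str, float] = {}
    for pid in ids:
        base = threshold + 2.0 * rng.standard_normal()
        if dependence == "positive":
            base += shift if functionality.get(pid) == "functional" else -shift
        scores[pid] = round(float(base), 3)
    return scores


def write_scores_tsv(scores: Dict[str, float], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#protein_id\tscore\n")
        for pid in scores:
            fh.write(f"{pid}\t{scores[pid]}\n")


# ---------------------------------------------------------------------------
# alignment-on-tree simulator

def simulate_alignment_on_tree(
    tree_newick: str, n_columns: int, rate: float, seed: int
) -> List[Tuple[str, str]]:
    """i.i.d. columns evolved along a tree with branch lengths.

    Per branch each site substitutes with probability 1 - exp(-rate * L)
    to a uniformly chosen different nucleotide. rate=0 reproduces the
    root sequence at every leaf.
    """
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    root_seq = rng.integers(0, 4, size=n_columns)
    seqs = {tree.seed_node: root_seq}
    rows: List[Tuple[str, str]] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[node.parent_node]
        brlen = node.edge.length or 0.0
        p_sub = 1.0 - np.exp(-rate * brlen)
        child = parent_seq.copy()
        if p_sub > 0:
            hits = np.nonzero(rng.random(n_columns) < p_sub)[0]
            for pos in hits:
                child[pos] = (child[pos] + 1 + int(rng.integers(3))) % 4
        seqs[node] = child
    for leaf in tree.leaf_node_iter():
        seq = "".join(NUCS[i] for i in seqs[leaf])
        rows.append((leaf.taxon.label, seq))
    rows.sort()
    return rows


# ---------------------------------------------------------------------------
# reverse translation + packaged demo fixture

def reverse_translate(
    protein: str,
    rng: np.random.Generator,
    code: GeneticCode = STANDARD_CODE,
    preferences: Optional[Dict[str, np.ndarray]] = None,
) -> str:
    """Pick a codon per residue, optionally under a per-family preference.

    'X' residues become NNN.
    """
    fams = code.synonymous_families()
    out = []
    for aa in protein:
        if aa == "X" or aa not in fams:
            out.append("NNN")
            continue
        family = fams[aa]
        if preferences is not None and aa in preferences and len(family) > 1:
            out.append(family[int(rng.choice(len(family), p=preferences[aa]))])
        else:
            out.append(family[int(rng.integers(len(family)))])
    return "".join(out)


def write_demo_fixture(outdir, seed: int = 2023) -> Dict[str, Path]:
    """Generate the small end-to-end fixture (proteins, CDS, species map,
    targeting scores) the `run` subcommand demonstrates on."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species = ["speciesA", "speciesB", "speciesC"]
    cfg = SimConfig(
        seed=seed,
        n_seqs=15,
        nonfunctional_rate=0.3,
        mutation_rate=0.02,
    )
    records, _, truths = simulate_proteins(cfg, species=species)
    rng = np.random.default_rng(seed + 1)
    code = STANDARD_CODE
    prefs = {sp: _group_preferences(rng, code, 0.8) for sp in species}
    cds_records = [
        SequenceRecord(
            id=rec.id,
            species=rec.species,
            kind="cds",
            seq=reverse_translate(rec.seq, rng, code, prefs[rec.species]),
        )
        for rec in records
    ]
    truth_func = {
        t.protein_id: ("non_functional" if t.missing_his else "functional")
        for t in truths
        if t.cls != "MCO"
    }
    scores = simulate_targeting_scores(
        sorted(truth_func), "independent", seed + 2, functionality=truth_func
    )
    paths = {
        "proteins": outdir / "proteins.fasta",
        "cds": outdir / "cds.fasta",
        "species": outdir / "species.tsv",
        "targeting": outdir / "targeting.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(records, paths["proteins"])
    write_fasta(cds_records, paths["cds"])
    with paths["species"].open("w") as fh:
        fh.write("#protein_id\tspecies\n")
        for rec in records:
            fh.write(f"{rec.id}\t{rec.species}\n")
    write_scores_tsv(scores, paths["targeting"])
    with paths["truth"].open("w") as fh:
        fh.write("#protein_id\tspecies\tclass\tmissing_his\thas_kfdv\n")
        for t in truths:
            fh.write(
                f"{t.protein_id}\t{t.species}\t{t.cls}\t"
                f"{','.join(sorted(t.missing_his)) or '-'}\t{int(t.has_kfdv)}\n"
            )
    return paths
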