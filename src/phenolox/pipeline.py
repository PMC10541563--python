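"""End-to-end orchestration: classify -> residues -> kaks -> rscu ->
assoc/census -> tree, with a resolved, logged configuration and a
deterministic output directory layout.

Outputs (all TSV with '#' headers, Newick for trees):
architectures.tsv, residues.tsv, functionality.tsv, pairs_kaks.tsv,
selection_summary.tsv, rscu.tsv, rscu_dendrogram.nwk, census.tsv,
assoc.tsv, tree.nwk, run.log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Dict, List, Optional

from . import association, classify, codonbias, phylo, residues, resources, selection, seqio

log = logging.getLogger("phenolox.pipeline")


class ConfigError(ValueError):
    """Unknown or unresolvable configuration key."""


class MissingInputError(FileNotFoundError):
    """A required input file is absent (CLI exit code 2)."""


@dataclass
class RunConfig:
    """Every pipeline threshold and path, resolvable from a key=value file
    with CLI overrides. Thresholds default to the published criteria:
    duplicate pairs need >70% similarity and >80% coverage, chloroplast
    targeting needs a score >7."""

    proteins: str = ""
    cds: str = ""
    species_map: str = ""
    targeting: str = ""
    domtbl: str = ""
    profile: str = ""  # empty -> packaged synthetic CO profile
    outdir: str = "phenolox_out"
    seed: int = 0
    bootstrap: int = 100
    code_table: int = 1
    min_fraction_identity: float = classify.DEFAULT_MIN_IDENTITY
    min_domain_coverage: float = classify.DEFAULT_MIN_COVERAGE
    min_similarity: float = selection.DEFAULT_MIN_SIMILARITY
    min_coverage: float = selection.DEFAULT_MIN_COVERAGE
    neutral_band: float = 0.0
    targeting_threshold: float = association.DEFAULT_TARGETING_THRESHOLD
    skip_kaks: bool = False
    skip_rscu: bool = False
    skip_tree: bool = False
    skip_assoc: bool = False

    @classmethod
    def field_names(cls) -> set:
        return {f.name for f in fields(cls)}

    @classmethod
    def from_sources(cls, config_file: Optional[str] = None, **overrides) -> "RunConfig":
        values: Dict[str, str] = {}
        if config_file:
            for lineno, line in enumerate(Path(config_file).read_text().splitlines(), 1):
                if not line.strip() or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ConfigError(f"{config_file}:{lineno}: expected key=value")
                key, _, val = line.partition("=")
                values[key.strip()] = val.strip()
        for key, val in overrides.items():
            if val is not None:
                values[key] = val
        known = cls.field_names()
        unknown = set(values) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls()
        for key, val in values.items():
            current = getattr(cfg, key)
            if isinstance(current, bool):
                val = str(val).lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                val = int(val)
            elif isinstance(current, float):
                val = float(val)
            setattr(cfg, key, val)
        return cfg

    def resolved_lines(self) -> List[str]:
        return [f"{f.name}={getattr(self, f.name)}" for f in fields(self)]


def _require(path: str, what: str) -> Path:
    if not path:
        raise MissingInputError(f"required input not configured: {what}")
    p = Path(path)
    if not p.exists():
        raise MissingInputError(f"{what} not found: {p}")
    return p


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all enabled stages; returns the output directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("phenolox")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    try:
        log.info("resolved configuration:")
        for line in cfg.resolved_lines():
            log.info("  %s", line)
        _run_stages(cfg, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir


def _run_stages(cfg: RunConfig, outdir: Path) -> None:
    species_map = seqio.read_species_map(_require(cfg.species_map, "species map"))
    prot_path = _require(cfg.proteins, "protein FASTA")
    prot_records = []
    for rec in seqio.read_fasta(prot_path, kind="protein", species="unknown"):
        sp = species_map.get(rec.id, "unknown")
        prot_records.append(
            seqio.SequenceRecord(id=rec.id, species=sp, kind="protein", seq=rec.seq)
        )
    proteins = {r.id: r for r in prot_records}

    # --- classify -----------------------------------------------------
    if cfg.domtbl:
        rows = seqio.read_domtbl(_require(cfg.domtbl, "domain table"))
        hits_by_protein = classify.hits_from_domtbl(rows)
    else:
        templates = resources.load_templates()
        hits_by_protein = {
            rec.id: classify.detect_domains(
                rec,
                templates,
                min_fraction_identity=cfg.min_fraction_identity,
                min_coverage=cfg.min_domain_coverage,
            )
            for rec in prot_records
        }
    architectures: Dict[str, classify.Architecture] = {}
    arch_rows = []
    for rec in prot_records:
        hits = hits_by_protein.get(rec.id, [])
        arch = classify.classify_architecture(hits, protein_id=rec.id)
        kfdv_hit = next((h for h in hits if h.domain == "PPO1_KFDV"), None)
        found, pos, _anchored = classify.detect_kfdv_motif(rec, kfdv_hit)
        arch = classify.Architecture(
            protein_id=arch.protein_id,
            cls=arch.cls,
            domains_present=arch.domains_present,
            kfdv_motif=found,
        )
        architectures[rec.id] = arch
        arch_rows.append(
            {
                "protein_id": rec.id,
                "species": rec.species,
                "class": arch.cls,
                "domains": ",".join(sorted(arch.domains_present)) or "-",
                "kfdv_motif": int(found),
            }
        )
    seqio.write_tsv(
        arch_rows,
        outdir / "architectures.tsv",
        columns=["protein_id", "species", "class", "domains", "kfdv_motif"],
    )
    log.info("classify: %d proteins", len(arch_rows))

    # --- residues / functionality ------------------------------------
    if cfg.profile:
        ref_fasta = Path(cfg.profile).with_suffix(".fasta")
        refs = seqio.read_fasta(_require(str(ref_fasta), "profile reference FASTA"),
                                kind="protein", species="reference")
        profile = residues.read_profile(_require(cfg.profile, "anchor profile"), refs[0], "CO")
    else:
        profile = resources.load_co_profile()
    tyr_family_ids = [
        r.id for r in prot_records
        if architectures[r.id].cls in ("TYR_LIKE", "CO_DWL", "CO_FULL")
    ]
    residue_rows, functionality_rows = [], []
    functionality: Dict[str, str] = {}
    extracted_rows: List = []
    role_names = sorted(profile.named_positions)
    for pid in tyr_family_ids:
        aln, report = residues.profile_report(proteins[pid], profile)
        functionality[pid] = report.functionality
        residue_rows.append(
            {"protein_id": pid, **{r: report.residues[r] for r in role_names}}
        )
        functionality_rows.append(
            {
                "protein_id": pid,
                "species": proteins[pid].species,
                "functionality": report.functionality,
                "missing_his": ",".join(sorted(report.missing_his)) or "-",
            }
        )
        extracted_rows.append(
            (pid, residues.extract_domain_columns_aligned(aln, profile))
        )
    seqio.write_tsv(
        residue_rows, outdir / "residues.tsv", columns=["protein_id"] + role_names
    )
    seqio.write_tsv(
        functionality_rows,
        outdir / "functionality.tsv",
        columns=["protein_id", "species", "functionality", "missing_his"],
    )
    log.info("residues: %d tyrosinase-family proteins anchored", len(tyr_family_ids))

    code = seqio.GeneticCode.from_table(cfg.code_table)

    # --- kaks ---------------------------------------------------------
    if not cfg.skip_kaks:
        cds_path = _require(cfg.cds, "CDS FASTA")
        cds_records = []
        for rec in seqio.read_fasta(cds_path, kind="cds", species="unknown"):
            sp = species_map.get(rec.id, "unknown")
            cds_records.append(
                seqio.SequenceRecord(id=rec.id, species=sp, kind="cds", seq=rec.seq)
            )
        cds = {r.id: r for r in cds_records}
        pairs = selection.find_duplicate_pairs(
            prot_records, min_similarity=cfg.min_similarity, min_coverage=cfg.min_coverage
        )
        results = selection.kaks_for_pairs(
            pairs, proteins, cds, code=code, neutral_band=cfg.neutral_band
        )
        pair_rows = [
            {
                "species": r.pair.species,
                "id_a": r.pair.id_a,
                "id_b": r.pair.id_b,
                "identity": r.pair.fraction_identity,
                "coverage": r.pair.coverage,
                "Ka": r.Ka,
                "Ks": r.Ks,
                "ratio": r.ratio,
                "class": r.selection_class,
            }
            for r in results
        ]
        seqio.write_tsv(
            pair_rows,
            outdir / "pairs_kaks.tsv",
            columns=["species", "id_a", "id_b", "identity", "coverage", "Ka", "Ks", "ratio", "class"],
        )
        summary_rows = []
        by_species: Dict[str, List] = {}
        for r in results:
            by_species.setdefault(r.pair.species, []).append(r)
        for sp in sorted(by_species):
            func_sp = {
                pid: v for pid, v in functionality.items() if proteins[pid].species == sp
            }
            s = selection.species_summary(by_species[sp], functionality=func_sp, species=sp)
            summary_rows.append(
                {
                    "species": s.species,
                    "nonfunctionality": s.nonfunctional_of_total,
                    "n_pairs": s.n_pairs,
                    "purifying": s.n_purifying,
                    "mean_purifying": s.mean_purifying,
                    "positive": s.n_positive,
                    "mean_positive": s.mean_positive,
                    "neutral": s.n_neutral,
                    "na": s.n_na,
                }
            )
        seqio.write_tsv(
            summary_rows,
            outdir / "selection_summary.tsv",
            columns=["species", "nonfunctionality", "n_pairs", "purifying",
                     "mean_purifying", "positive", "mean_positive", "neutral", "na"],
        )
        log.info("kaks: %d pairs across %d species", len(results), len(by_species))
    else:
        cds_records = []

    # --- rscu ---------------------------------------------------------
    if not cfg.skip_rscu and cds_records:
        by_sp: Dict[str, List] = {}
        for rec in cds_records:
            by_sp.setdefault(rec.species, []).append(rec)
        profiles = [
            codonbias.rscu(codonbias.codon_counts(by_sp[sp], code), code, species=sp)
            for sp in sorted(by_sp)
        ]
        codons = codonbias.vector_codons(code)
        rscu_rows = [
            {
                "species": p.species,
                **{c: (p.rscu[c] if p.rscu[c] is not None else None) for c in codons},
            }
            for p in profiles
        ]
        seqio.write_tsv(rscu_rows, outdir / "rscu.tsv", columns=["species"] + list(codons))
        if len(profiles) >= 2:
            dend = codonbias.average_linkage(codonbias.rscu_distance(profiles))
            seqio.write_newick(dend.newick, outdir / "rscu_dendrogram.nwk")
        log.info("rscu: %d species profiles", len(profiles))

    # --- census -------------------------------------------------------
    census_rows = association.census(
        [(proteins[pid].species, arch) for pid, arch in architectures.items()],
        functionality=functionality,
    )
    seqio.write_tsv(
        [
            {
                "species": r.species,
                "tyr_like": r.n_tyr_like,
                "co": r.n_co,
                "co_dwl": r.n_co_dwl,
                "co_full": r.n_co_full,
                "mco": r.n_mco,
                "unclassified": r.n_unclassified,
                "kfdv_motif": r.n_kfdv_motif,
                "nonfunctional_co": r.nonfunctional_of_co,
            }
            for r in census_rows
        ],
        outdir / "census.tsv",
        columns=["species", "tyr_like", "co", "co_dwl", "co_full", "mco",
                 "unclassified", "kfdv_motif", "nonfunctional_co"],
    )

    # --- assoc --------------------------------------------------------
    if not cfg.skip_assoc:
        scores = association.read_scores(_require(cfg.targeting, "targeting score table"))
        calls = association.call_targeting(
            scores, threshold=cfg.targeting_threshold, ids=sorted(functionality)
        )
        table = association.functionality_targeting_table(functionality, calls)
        p = association.fisher_exact_2x2(table)
        seqio.write_tsv(
            [
                {
                    "functional_targeted": table.a,
                    "functional_not": table.b,
                    "nonfunctional_targeted": table.c,
                    "nonfunctional_not": table.d,
                    "fisher_p": p,
                    "targeted_summary": association.targeting_summary(calls),
                }
            ],
            outdir / "assoc.tsv",
        )
        log.info("assoc: Fisher p = %.4g on table %s", p, table)

    # --- tree ---------------------------------------------------------
    if not cfg.skip_tree and len(extracted_rows) >= 3:
        tree = phylo.bootstrap(extracted_rows, n_replicates=cfg.bootstrap, seed=cfg.seed)
        seqio.write_newick(tree.newick_with_supports(), outdir / "tree.nwk")
        log.info("tree: %d leaves, %d bootstrap replicates", len(extracted_rows), cfg.bootstrap)
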