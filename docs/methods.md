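# Methods

This note documents the models, conventions, and design choices behind
each stage of the package, the knobs that matter, and what the synthetic
generators do and do not emulate.

## Coordinates, formats, and alignment backend

Internally every span is 0-based half-open; every file interface
(per-domain tables, anchor profiles) is 1-based inclusive, matching the
output conventions of the scan tools whose tables we consume. Conversion
happens once, at the file boundary; the two conventions are related by an
involution that is property-tested.

All pairwise alignment (global for anchoring and duplicate pairs, local
for domain detection) uses BLOSUM62 with affine gap penalties, open 10 /
extend 1. Tracebacks are the aligner's canonical deterministic first
alignment; tests assert score optimality against brute-force enumeration
and determinism, not a particular gap placement among co-optimal
alignments.

## Domain detection and architecture classes

The detector aligns the query locally against one consensus template per
diagnostic domain (tyrosinase, PPO1_DWL, PPO1_KFDV, and the three
Cu-oxidase domains) and reports at most the best hit per domain. A hit
must reach both thresholds:

* `min_fraction_identity` (default 0.30) — identical columns divided by
  **all** columns of the aligned region, gap columns included. The
  gap-inclusive denominator matters: a gappy chance alignment between
  unrelated sequences can cherry-pick matched residues between gaps and
  exceed 30% identity over its non-gap columns alone, while a genuine
  domain match is near-gapless and unaffected. With the gap-inclusive
  definition, spurious hits on random 200-mers and on assembled
  multi-domain proteins are not observed in thousands of trials.
* `min_coverage` (default 0.60) — aligned (non-gap) columns divided by
  template length.

The architecture call is a pure function of the detected domain set:
tyrosinase alone → TYR_LIKE; + DWL → CO_DWL; + DWL + KFDV → CO_FULL; the
three Cu-oxidase domains and nothing tyrosinase-family → MCO; anything
else, including tyrosinase/Cu-oxidase chimeras, → UNCLASSIFIED with a
warning. A TYR_LIKE call cannot distinguish a true tyrosinase from a
catechol oxidase that lost its shield domains — that resolution is
phylogenetic, which is why the tree stage exists; joining the two is
deliberately left to the user.

Users who ran a real profile-HMM scan can bypass the detector with its
per-domain table; the best-scoring row per (protein, domain) is kept so
the one-hit-per-domain contract is preserved.

## Residue mapping and the six-His rule

Each query is anchored to a single annotated reference by global
alignment, rather than through a multiple alignment: pairwise anchoring
is deterministic, independent of input order, and unit-testable, and a
multi-sequence panel is recovered by anchoring all queries to the same
reference. Named positions (the six histidines, gatekeeper, HB1+1,
HB2+1, waterkeeper for the CO family; the H-A/H-B/H-C histidine regions
and the NNX anchor for LAC/AAO) are data — a plain-text profile keyed to
the reference — not code. Profile loading validates that every His role
sits on an H and the waterkeeper on an E.

A gap at a named position is reported as '-' and counts as "absent" for
the six-His rule, so substitution and deletion are both recorded (the
mapped residue distinguishes them). The functionality verdict is a
six-way conjunction: non-functional iff any of the six mapped residues
is not 'H'.

Column extraction has two variants: the reported `extracted_domain_seq`
drops query gaps (insertions between domains are invisible, deletions
shorten the string); the tree stage uses the gap-padded variant, whose
length always equals the total reference domain span, so extractions of
many queries are mutually aligned by construction.

## Selection analysis

Duplicate pairs are all within-species protein pairs whose global
alignment exceeds **strictly** 70% identity (identical columns over
aligned non-gap columns) and 80% coverage. Coverage is aligned columns
over the length of the **longer** protein, so a gene truncated to half
its paralog's length scores 0.5 no matter how well the remnant aligns.

Ka/Ks is the NG86 approximate method, implemented in-repo so that every
counting rule is explicit and oracle-checkable:

* synonymous sites per codon position = fraction of the non-stop
  single-nucleotide changes at that position that are synonymous
  (stop-creating changes drop out of numerator and denominator), so
  sites per codon sum to exactly 3;
* codon pairs differing at k positions average Sd/Nd over all k!
  minimal pathways, excluding pathways through stop codons (falling back
  to all pathways in the degenerate case where every pathway is
  blocked);
* pS = Sd/Ns and pN = Nd/Na are Jukes–Cantor corrected,
  d = −(3/4)·ln(1 − 4p/3), undefined at p ≥ 3/4.

The codon alignment is induced from the protein alignment (protein gaps
back-mapped as codon gaps); codons with a gap, N, or stop in either
sequence are skipped pairwise. ω = Ka/Ks is defined only when Ks > 0;
pairs with an undefined ratio are reported as NA and never counted as
neutral. The neutral class is ω = 1 within a configurable band,
`neutral_band`, defaulting to 0.0 — the literal reading of the
three-way rule; a continuous estimator essentially never lands exactly
on 1, so with the default the neutral bucket stays empty and users who
want a tolerant band set one explicitly.

## Codon-usage bias

RSCU_i = n_i·k/Σn_j per synonymous family; a family with zero
observations yields NA for all members. Profiles live on a 59-codon
vector: the 61 sense codons minus ATG and TGG, whose RSCU is
identically 1 whenever observed and adds only NA noise. Code tables 1
and 11 translate identically (they differ in start-codon policy), so the
vector is the same under both; the table choice is honored for forward
compatibility. Distance is Euclidean with NA imputed as 0 (the count of
imputations is logged); clustering is unweighted average linkage with a
lexicographic tie-break, so the dendrogram is deterministic even on
exactly tied distances. Merge heights are monotone non-decreasing;
Newick branch lengths are height differences (height = merge
distance / 2), giving an ultrametric rendering.

## Targeting association

Targeting scores are consumed, never computed — reimplementing an
external localization predictor is out of scope. A protein is targeted
iff its score **strictly** exceeds the threshold (default 7). The
association of structural functionality with targeting is a single 2×2
Fisher exact test; the two-sided p-value follows the probability-mass
rule (sum of hypergeometric probabilities of tables no more probable
than observed, at fixed margins), with 1e-12 relative slack on the
comparison to avoid float-tie artifacts. The implementation uses the
scipy hypergeometric pmf inside this rule; tests check it against a
direct factorial enumeration and against an independent library
implementation.

## Phylogeny

The tree stage is deliberately minimal: uncorrected p-distances with
pairwise gap deletion (a pair with zero comparable columns is an error),
classical neighbor-joining with ties on the Q criterion broken by the
lexicographically smallest label pair and negative branch lengths
clamped to zero with a warning, and column-resampling bootstrap whose
supports count, per internal bipartition of the point-estimate tree, the
replicates containing that bipartition. This is a declared fidelity
reduction relative to model-based maximum-likelihood inference: adequate
for clade assignment on strongly structured desk-scale data, not for
publication-grade phylogenetics. A distance-correction flag is reserved
but not implemented.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of their config (seed included);
repeated calls are byte-identical.

* `simulate_proteins` assembles proteins from packaged synthetic domain
  templates joined by random 8–20-residue linkers. Templates are fixed
  random 100–120-residue strings (frozen as a FASTA resource, labelled
  synthetic) with the diagnostic residues planted at known offsets; they
  share no homology with real Pfam domains. Defaults: 100 sequences, an
  architecture mix of 20% TYR_LIKE / 25% CO_DWL / 35% CO_FULL / 20% MCO
  (all four classes well represented, full-shield COs commonest, as in
  seed-plant proteomes), and a 30% planted-defect rate — the upper range
  of observed per-species non-functionality ratios, chosen so both
  verdict classes are abundant. With probability `nonfunctional_rate`
  one uniformly chosen His is substituted by a random non-H residue.
  Point mutations (rate `mutation_rate`, default 0) never fall within
  ±3 of a named position or inside the KFDV tetrapeptide, so planted
  truths survive mutation by construction — which is exactly what the
  recovery tests require and also what they are limited to showing.
* `simulate_codon_pair` evolves two lineages from a random sense-codon
  ancestor by proposal–acceptance: ~n_codons·t proposed single-
  nucleotide changes per lineage (defaults 300 codons, t = 0.3),
  stop-creating proposals redrawn, synonymous proposals accepted with
  probability 1 and nonsynonymous with ω (roles flipped and scaled by
  1/ω when ω > 1), so realized fixation odds equal ω by construction —
  a clean recovery target without matrix exponentiation, not a
  realistic codon substitution model.
* `simulate_codon_bias` gives each group a Dirichlet-perturbed codon
  preference per family (`bias_strength` interpolating uniform →
  concentrated, default 0.8 — a strong, clearly detectable contrast),
  shared by the group's species (defaults: 2 groups × 3 species,
  2000 codons per species).
* `simulate_targeting_scores` draws Normal(7, 2) scores, shifted ±3 by
  functionality class under planted positive dependence.
* `simulate_alignment_on_tree` evolves i.i.d. columns with per-branch
  substitution probability 1 − exp(−rate·L); no indels, no rate
  heterogeneity.

None of the generators emulate real amino-acid composition, domain-level
homology between families, intron structure, or alignment ambiguity
beyond linker indels. Passing the recovery tests therefore demonstrates
the correctness of the pipeline's logic under its stated assumptions,
not its accuracy on diverged natural proteomes, where domain detection
would come from a real profile-HMM scan fed in via the per-domain table
interface.

## Numerical and procedural conventions

* Strict inequalities everywhere thresholds are defined (> 0.70, > 0.80,
  > 7); boundary fixtures pin these down.
* Float formatting in TSV outputs is `%.6g`; `NA` marks undefined
  values. Output files are byte-deterministic under a fixed seed
  (`run.log` carries timestamps and is exempt).
* The acceptance driver scales its problem sizes to desk scale (200
  oracle pairs, 400–500 simulated proteins, 50–100 seeded replicates per
  stochastic check), chosen so each metric is stable across seeds.
* Exit codes of the `run` subcommand: 2 for a missing required input,
  3 for a validation failure.

## Known limitations

* The detector is a declared simplified stand-in for profile-HMM
  scanning; its thresholds were chosen for the packaged synthetic
  templates and have no calibration against Pfam gathering thresholds.
* TYR_LIKE vs single-domain CO resolution requires the tree stage and a
  user-side join; the classifier alone cannot make that call.
* NG86 is an approximate counting method; likelihood codon models (and
  significance tests on ω) are out of scope, so means over pairs are
  comparable within this package but not bit-comparable with other
  Ka/Ks software.
* The neutral selection class is empty under the default band; this is
  a documented reading of the ω = 1 rule, not a bug.
* Bootstrap supports are reported only for bipartitions of the point
  tree, not as a consensus over replicates.
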