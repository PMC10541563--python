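# phenolox

A comparative-evolution toolkit for plant phenoloxidases — the catechol
oxidases (COs), tyrosinases (TYRs), and the laccase/ascorbate-oxidase
(LAC/AAO) multicopper family — for researchers studying how these enzyme
families were gained, retained, and lost across the green-plant lineage.

Plant PPOs (TYRs and COs) share an N-terminal tyrosinase domain housing
the CuA/CuB enzymatic center; mature COs add a PPO1_DWL linker and,
in most seed plants, a C-terminal PPO1_KFDV shield domain carrying the
conserved KFDV tetrapeptide. Laccases and ascorbate oxidases instead
carry three Cu-oxidase domains. Around the CO substrate pocket sit
diagnostic residues: six copper-binding histidines (HisA1–A3, HisB1–B3),
the gatekeeper phenylalanine, the HB1+1/HB2+1 activity controllers, and
the waterkeeper glutamate. A CO missing any of the six histidines has a
structurally defective center and is called non-functional.

The package implements the full desk-scale analysis chain:

1. **Architecture classification** — Smith–Waterman detection of the five
   diagnostic domains against packaged consensus templates (or a
   precomputed hmmscan-style per-domain table), and the class call
   TYR_LIKE / CO_DWL / CO_FULL / MCO.
2. **Residue mapping** — Needleman–Wunsch anchoring of each query to an
   annotated reference, extraction of domain-aligned columns, mapping of
   the named diagnostic positions, and the six-His functionality rule.
3. **Selection analysis** — within-species duplicate pairs (aligned
   similarity > 70%, coverage > 80%), in-repo Nei–Gojobori (NG86) Ka/Ks
   with pathway averaging and Jukes–Cantor correction, and the
   positive (ω > 1) / purifying (ω < 1) / neutral (ω = 1) classification
   with a per-species summary table.
4. **Codon-usage bias** — relative synonymous codon usage (RSCU) under
   genetic code tables 1 and 11 and average-linkage clustering of species
   profiles into a dendrogram.
5. **Chloroplast-targeting association** — strict score > 7 targeting
   calls from an external predictor's table, the functionality ×
   targeting 2×2 contingency, and an exact two-sided Fisher test.
6. **Desk-scale phylogeny** — p-distances over extracted domain columns,
   neighbor-joining, and column-resampling bootstrap supports.
7. **Synthetic data** — seeded generators for every input with planted
   ground truth: domain architectures with planted His defects, codon
   pairs evolved at controlled dN/dS, species groups with controlled
   codon bias, targeting scores with planted (in)dependence, and
   alignments evolved on a planted tree.

Key formulas: NG86 counts synonymous sites per codon position as the
stop-excluded fraction of synonymous single-nucleotide changes, averages
multi-hit codon differences over all minimal mutational pathways
(excluding pathways through stops), and corrects proportions with
d = −(3/4)·ln(1 − 4p/3). RSCU for codon *i* in a family of degeneracy
*k* is n_i · k / Σ_j n_j.

## Worked example

Every stage runs from the `phenolox` console script. The packaged
synthetic fixture (15 proteins across three species, with known planted
classes and defects) exercises the whole chain:

```bash
FIX=src/phenolox/data/fixture
phenolox run --proteins $FIX/proteins.fasta --cds $FIX/cds.fasta \
    --species-map $FIX/species.tsv --targeting $FIX/targeting.tsv \
    --outdir demo_out --seed 7 --bootstrap 100
```

`demo_out/` then contains the eleven outputs (architectures, residues,
functionality, Ka/Ks pairs and summary, RSCU table and dendrogram,
census, association, tree, run log). The census:

```
#species  tyr_like  co  co_dwl  co_full  mco  unclassified  kfdv_motif  nonfunctional_co
speciesA  0         4   3       1        1    0             1           1 of 4
speciesB  1         3   2       1        1    0             1           2 of 3
speciesC  1         2   1       1        2    0             1           1 of 2
```

reads: speciesA carries four catechol oxidases (three with only the DWL
linker, one with the full KFDV shield), one multicopper oxidase, and one
of its four COs fails the six-His rule. The selection summary:

```
#species  nonfunctionality  n_pairs  purifying  mean_purifying  positive  mean_positive  neutral  na
speciesA  1 of 4            3        3          0.101808        0         NA             0        0
```

shows all three duplicate pairs of speciesA under purifying selection
(mean Ka/Ks ≈ 0.10 — the fixture's paralogs differ mostly by synonymous
codon choices). The association output reports the 2×2 functionality ×
targeting table and its Fisher p (here 0.55: no association, as planted).

Each stage is also exposed alone (`phenolox classify`, `residues`,
`kaks`, `rscu`, `tree`, `assoc`, `census`, `simulate`); see `--help`.

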