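# erv-pairscan

Strand-aware co-expression screening of human endogenous retrovirus (HERV)
loci and their neighboring genes from bulk RNA-seq count matrices.

## The problem

HERV elements — mostly solo LTRs — carry promoter/enhancer motifs and can
act as cis-regulatory elements for nearby genes, notably interferon-
stimulated genes (ISGs) in the JAK–STAT pathway. Given per-locus HERV
counts and gene counts from an experiment that perturbs interferon
signaling (IFN-β-treated wild-type vs. IFNAR1-knockout vs. IFNAR2-mutant
THP1 cells, plus an untreated control), the question is whether HERV loci
and their genomic neighbor genes change expression *together*.

The pipeline:

1. **DE screen** — each feature (gene or HERV locus) is tested between two
   conditions; a feature is differentially expressed (DEG / DEHERV) iff
   *p* < 0.05 and |log2FC| > 1 (strict inequalities). The built-in engine
   is a negative-binomial Wald test (median-of-ratios size factors, moment
   dispersion with median shrinkage, log2FC = log2((m̄_t + ½)/(m̄_c + ½)));
   external DESeq2 result tables can be imported instead.
2. **DEHERV-G pairs** — a pair is a (DEHERV, DEG) on the same strand of the
   same chromosome with interval gap ≤ 100 kb (overlap counts as 0). Each
   pair is classified into one of four patterns (both up, both down,
   HERV up/gene down, HERV down/gene up); the *consistent fraction* is the
   share of both-up + both-down pairs.
3. **Cross-contrast intersection** — pair identities (herv_id, gene_id) are
   intersected across the three contrasts (KO1, KO2, N) to find the common
   co-expressed core; all Venn region cardinalities are reported.
4. **Descriptive statistics** — DEHERV strand distribution with an exact
   two-sided binomial test against an even split, per-chromosome counts and
   their Pearson/Spearman correlation with chromosome length, and
   composition over the six ERV superfamilies (ERV1, ERVL, ERVK, Gypsy,
   ERVL-MaLR, unclassified) derived from RepeatMasker/Dfam family names.

A fully parameterized synthetic-data generator emulates the study design
(NB counts, receptor-knockout effect structure, plus-strand bias,
superfamily mix, configurable HERV–gene direction concordance ρ) so that
every stage is testable with known ground truth.

## Worked example

The numbered drivers under `analysis/` run the standard synthetic
experiment end to end:

```sh
python analysis/01_simulate_experiment.py
python analysis/02_differential_expression.py
python analysis/03_deherv_g_pairs.py
python analysis/04_strand_and_superfamily.py
```

Output of the pair-building step (seed 1, 5 replicates/condition):

```
KO1: 2137 DEHERV-G pairs over 2137 loci and 157 genes; consistent fraction 0.950; ...
KO2: 2022 DEHERV-G pairs over 2013 loci and 149 genes; consistent fraction 0.946; ...
N:   2170 DEHERV-G pairs over 2162 loci and 160 genes; consistent fraction 0.947; ...
common to all three contrasts: 2012 pairs over 2012 loci and 148 genes
```

The generator seeded ρ = 0.90 direction concordance; among HERVs that end
up differentially expressed the implied consistent fraction is
ρ/(ρ + (1−ρ)/2) ≈ 0.947, which the recovered 0.946–0.950 matches. The
strand step prints, per contrast, e.g.

```
KO1: 1359+/812- (62.6% plus), binomial p = 4.89e-32; chromosome-size Pearson r = 0.994
```

recovering the generated 63.8 % plus-strand bias and length-proportional
placement, and the same reporting applied to the emulated study's printed
per-group strand counts gives 63.8 %, 61.3 % and 63.4 % plus with exact
binomial p ≪ 0.0001 in each group.

The same stages are available as a CLI (`erv-pairscan simulate|de|pairs|
stats|run`) and as library functions (`erv_pairscan.run_pipeline` writes
`de/`, `pairs/`, `stats/` tables plus `report.json`/`report.md` whose every
aggregate re-derives from the stage TSVs).

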