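# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limitations of `erv-pairscan`.

## Coordinates and annotations

Intervals are stored 0-based half-open. GTF input (1-based inclusive) and
RepeatMasker `.out` query coordinates are converted on read; BED is taken
verbatim. Chromosome names are unified to the UCSC `chr` dialect by
default, since mixing Ensembl- and UCSC-style inputs is the most common
integration failure. Unstranded (`.`) records are accepted by the readers
and carried through DE testing, but are excluded (with a logged count) from
pairing, which is strand-aware by definition.

Superfamily classification maps a RepeatMasker/Dfam class/family string to
one of six bins — ERV1, ERVL, ERVK, Gypsy, ERVL-MaLR, unclassified — by
case-insensitive substring match after stripping a leading `LTR/` prefix,
testing `ERVL-MaLR` before `ERVL` (longest-match precedence). Anything
unmatched, including non-LTR repeat classes, is `unclassified`. The
function is total; no input raises.

## Differential expression

The built-in engine is a negative-binomial Wald test on one two-group
contrast:

- **Normalization.** Median-of-ratios size factors (the median over
  all-positive features of count/geometric-mean). If no feature is
  positive in every sample, a total-count fallback is available.
- **Dispersion.** Per-feature method-of-moments on normalized counts with
  within-condition centering: α̂ = (s² − μ̄)/μ̄², s² pooled over both
  groups with n_t + n_c − 2 degrees of freedom, floored at 1e-8. The
  estimate is shrunk toward an across-feature target with weight 0.25 on
  the per-feature value. Because s² behaves like var·χ²_dof/dof and the
  χ² median sits well below its mean at the 2–6 degrees of freedom typical
  here, the raw across-feature median underestimates the trend; the target
  therefore inverts the χ²-median factor (α_target =
  (med(α̂) + (1 − f)/μ_typ)/f with f = median(χ²_dof)/dof and μ_typ the
  median feature mean). Without this correction the test's type-I error at
  n = 3 vs 3 runs ≈ 0.075 at nominal 0.05; with it, ≈ 0.05–0.065.
- **Effect and test.** log2FC = log2((m̄_t + ½)/(m̄_c + ½)) — the ½
  pseudo-count keeps features expressed on only one side testable and
  finite. SE comes from the delta method under var = μ + αμ² (including
  the 1/s_j library term); z = log2FC/SE with a two-sided normal p-value;
  Benjamini–Hochberg adjustment over all tested features. Features with
  all-zero counts in both groups are excluded and reported `ns` with
  missing p.
- **Screen.** DE iff p < α and |log2FC| > t, strict, defaults α = 0.05,
  t = 1. `use_adjusted=True` screens on the BH-adjusted p instead; both
  modes exist because methods-level descriptions of this screen commonly
  state the raw p while figure captions use the adjusted one. Defaults
  follow the stated methods (raw p).

This engine is a deliberately simple, documented stand-in at desk scale;
for production analyses of real data, DESeq2 (or similar) output can be
imported via `import_de_table` and flows through the identical screen and
all downstream stages. n = 2 per group is permitted — the emulated
experiment used duplicates — but triggers a logged low-replication warning.

## Pairing

Distance is the gap between interval hulls (0 when overlapping); 100 kb is
inclusive (≤ window). This is the simplest reading of "within 100 kb" for
locus-level annotations; TSS-based conventions would give different
distances and are intentionally not mixed in. By default a DEHERV pairs
with *every* same-strand DEG within the window — the reported real-data
arithmetic (more common pairs than distinct loci) is only possible under
this reading — while `nearest_only=True` restricts to the minimum-distance
gene(s), keeping ties, for sensitivity analysis. Pair identity for
cross-contrast intersection is (herv_id, gene_id) regardless of pattern,
since patterns differ across contrasts by construction. The indexed
interval-tree join is property-tested against a brute-force all-pairs scan.

## Strand and composition statistics

The strand test is the exact two-sided binomial test against p₀ = 0.5,
summing the probabilities of all outcomes no more likely than the observed
one (scipy's `binomtest`; an independent enumeration oracle in the test
suite verifies it for every n ≤ 1000). A χ² goodness-of-fit alternative is
available. Percentages are reported at one decimal with half-up rounding,
re-derived from the stored integer counts at formatting time. The
chromosome-size correlation reports Pearson and Spearman over chromosomes
with a configurable exclusion list (sex chromosomes and mitochondrion by
default, matching the autosome-focused convention); at least three
chromosomes are required.

## Synthetic-data model

The generator emulates the study design, not any fitted model of the real
data. Defaults (the package's standard conditions):

| parameter | default | meaning |
|---|---|---|
| chromosomes | 5, 1–10 Mb (28 Mb total) | toy genome |
| n_genes / n_hervs | 2000 / 4000 | feature counts |
| plus_strand_prob | 0.638 | HERV plus-strand bias (the observed value) |
| superfamily_mix | ⅓ ERV1, ¼ ERVL, 1.5 % ERVK, 3 % Gypsy, ⅓ ERVL-MaLR, rest unclassified | observed composition |
| de_fraction_genes | 0.08 | genes with a true effect |
| de_up_prob | 0.7 | induction share (IFN responses are mostly up) |
| n_isg_like | 50 | genes forced to log2FC = +6 (ISG scale) |
| lfc_range | 1.2–6 | signed effect magnitudes, uniform |
| concordance_rho | 0.90 | P(HERV near a DE gene shares its direction) |
| nb_mean_log_mu/σ | 4.6 / 1.0 | log-normal baseline (~100 counts) |
| nb_dispersion | 0.05 | NB dispersion |
| mt2_attenuation | 0.3 | effect fraction retained in the IFNAR2 mutant |
| n_replicates | 2 | as in the emulated experiment |

Genes are placed on an overlap-free 10 kb slot grid, chromosomes chosen
proportionally to length, strands 50/50; 60 % of HERVs are seeded within
the window of a strand-matched gene so pairs exist, the rest uniformly.
HERV strands are i.i.d. Bernoulli(plus_strand_prob).

**Isolated DE anchors.** DE genes are drawn so that no two same-strand DE
genes lie within 2×window of each other, interleaving strands. On a dense
toy genome a 100 kb window otherwise holds several DE genes of conflicting
directions, which dilutes pair concordance for reasons unrelated to ρ;
isolation makes each HERV see at most one DE driver, so the concordance of
true pairs follows the ρ rule exactly. A HERV within the window of its
driver takes the driver's direction with probability ρ, the opposite with
(1−ρ)/2, and stays null otherwise — hence among *differentially expressed*
HERVs the expected consistent fraction is ρ/(ρ + (1−ρ)/2) (≈ 0.947 at
ρ = 0.9), which is the reference value the recovery tests use.

**Condition structure.** Four conditions: treated wild-type (full effect),
treated IFNAR1-KO (no effect), treated IFNAR2-mutant (0.3 of the effect
retained — modeling the residual exon-skipped receptor without claiming
mechanism), untreated wild-type (no effect). The three contrasts all use
treated wild-type as the treated side. Per-sample library factors are
log-normal (σ = 0.2). All randomness flows through generators derived from
the mandatory seed; identical configs give byte-identical outputs.

**What the generator does not emulate:** shared local background
(co-regulation beyond the seeded concordance), GC/length biases, outlier
samples, batch effects, overlapping genes, unstranded or missing
annotations, and the real genome's repeat density. Passing recovery tests
therefore demonstrates correctness of the pipeline's arithmetic under the
stated model, not fidelity of the model to genome-scale real data.

**Problem sizes.** Recovery experiments (acceptance and the analysis
drivers) run the default 2000-gene/4000-HERV genome at 5 replicates per
condition: with duplicate-level replication, false-positive DE genes under
the raw-p screen attach to genuinely DE HERVs and visibly dilute the
concordance estimate, so the package's standard recovery conditions use
the replication at which its own recovery examples are calibrated. Unit
and property tests use 300–500-feature instances.

## Known limitations

- The NB Wald engine is not DESeq2: no Cook's distance filtering, no
  independent filtering, no multi-factor designs, no shrunken effect
  estimates. Its p-values are mildly anticonservative below n = 3.
- Distance is hull-gap; analyses that define "within 100 kb" TSS-to-TSS
  will produce different pair sets near the boundary.
- The exact binomial p-value underflows to 0 in double precision for very
  lopsided large counts; this is reported as 0.0 rather than a log-scale
  value.
- Venn region cardinalities are exclusive regions; with more than ~6
  contrasts the 2^k regions become unwieldy.
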