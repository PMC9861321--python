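"""Synthetic experiment generator emulating the IFN-beta / IFNAR study design.

Generates a toy genome annotation (genes placed uniformly, HERV loci placed
proportionally to chromosome length with a configurable plus-strand bias and
a configurable fraction deliberately seeded near genes), negative-binomial
count matrices for the four conditions (IFN-beta-treated wild-type, treated
IFNAR1-knockout, treated IFNAR2-mutant, untreated wild-type) with replicate
structure, and the ground-truth labels needed for recovery tests.

Interferon effects are modeled as all-or-none at the receptor: a DE gene's
fold change is present in the treated wild-type condition only, fully absent
in the IFNAR1 knockout, and attenuated (``mt2_attenuation`` of it retained)
in the IFNAR2 mutant.  A HERV within the pairing window of a DE gene on the
same strand inherits the gene's effect direction with probability
``concordance_rho``, the opposite direction with probability
``(1 - rho)/2``, and no effect otherwise.

All randomness flows through numpy Generators derived from the mandatory
seed; two runs with the same config are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .annotation_io import (
    SUPERFAMILIES,
    CountMatrix,
    GeneRecord,
    GenomeAnnotation,
    GenomicInterval,
    HervLocus,
    write_bed,
    write_counts,
)
from .diffexpr import ContrastSpec
from .pairing import interval_distance

CONDITIONS = ("IFNb_N", "IFNb_KO1", "IFNb_MT2", "N")

#: representative RepeatMasker-style class/family strings per superfamily
_FAMILY_NAMES = {
    "ERV1": "LTR/ERV1",
    "ERVL": "LTR/ERVL",
    "ERVK": "LTR/ERVK",
    "Gypsy": "LTR/Gypsy",
    "ERVL-MaLR": "LTR/ERVL-MaLR",
    "unclassified": "LTR/Undefined",
}


class GenerationError(ValueError):
    pass


def _default_chroms() -> dict[str, int]:
    return {
        "chrS1": 10_000_000,
        "chrS2": 8_000_000,
        "chrS3": 6_000_000,
        "chrS4": 3_000_000,
        "chrS5": 1_000_000,
    }


def _default_mix() -> dict[str, float]:
    # mirrors the reported real-data composition: ~1/3 ERVL-MaLR, ~1/3 ERV1,
    # ~1/4 ERVL, 1.5% ERVK; remainder split over Gypsy and unclassified
    mix = {
        "ERV1": 1 / 3,
        "ERVL": 0.25,
        "ERVK": 0.015,
        "Gypsy": 0.03,
        "ERVL-MaLR": 1 / 3,
    }
    mix["unclassified"] = 1.0 - sum(mix.values())
    return mix


@dataclass
class GeneratorConfig:
    """Ground-truth parameters of one synthetic experiment.

    The defaults define the package's standard study conditions: 5 toy
    chromosomes (1-10 Mb), 2000 genes, 4000 HERV loci with the observed
    63.8% plus-strand bias and real-data superfamily mix, two replicates
    per condition as in the emulated experiment, signed fold-change
    magnitudes up to ISG scale (log2 6), and 90% direction concordance
    between a differential gene and HERVs in its 100 kb window.
    """

    seed: int
    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    n_genes: int = 2000
    n_hervs: int = 4000
    plus_strand_prob: float = 0.638
    superfamily_mix: dict[str, float] = field(default_factory=_default_mix)
    de_fraction_genes: float = 0.08
    de_up_prob: float = 0.7
    n_isg_like: int = 50          # forced strong inductions (log2fc = +6)
    lfc_range: tuple[float, float] = (1.2, 6.0)
    herv_near_gene_frac: float = 0.6
    concordance_rho: float = 0.90
    nb_mean_log_mu: float = 4.6   # ln-scale baseline mean (~100 counts)
    nb_mean_log_sigma: float = 1.0
    nb_dispersion: float = 0.05
    mt2_attenuation: float = 0.3  # effect fraction retained in the IFNAR2 mutant
    n_replicates: int = 2
    window: int = 100_000
    gene_slot: int = 10_000       # per-gene exclusive span for overlap-free placement
    gene_length_range: tuple[int, int] = (2_000, 8_000)
    herv_length_range: tuple[int, int] = (300, 3_000)

    def __post_init__(self) -> None:
        for name in ("plus_strand_prob", "de_fraction_genes", "de_up_prob",
                     "herv_near_gene_frac", "concordance_rho", "mt2_attenuation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenerationError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.superfamily_mix.values()) - 1.0) > 1e-9:
            raise GenerationError("superfamily_mix must sum to 1")
        if set(self.superfamily_mix) != set(SUPERFAMILIES):
            raise GenerationError("superfamily_mix must cover the six superfamilies")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth: signed log2 fold changes (treated wild-type vs untreated)
    and the (herv, gene, concordant) pairs implied by construction."""

    true_de_genes: dict[str, float]
    true_de_hervs: dict[str, float]
    true_pairs: list[tuple[str, str, bool]]
    parameters: GeneratorConfig

    def to_dict(self) -> dict:
        return {
            "true_de_genes": dict(self.true_de_genes),
            "true_de_hervs": dict(self.true_de_hervs),
            "true_pairs": [list(p) for p in self.true_pairs],
            "parameters": self.parameters.to_dict(),
        }


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_annotation(config: GeneratorConfig) -> GenomeAnnotation:
    """Place genes and HERV loci on the toy genome.

    Genes: chromosomes chosen proportionally to length, positions on an
    overlap-free slot grid, strands 50/50.  HERVs: a ``herv_near_gene_frac``
    share is seeded within the pairing window of a strand-matched gene (so
    pairs exist by construction); the rest land uniformly, chromosome choice
    proportional to length.  HERV strands are i.i.d. Bernoulli
    (``plus_strand_prob``); superfamilies are drawn from the configured mix.
    """
    rng = _rng(config, 0)
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    slots_per_chrom = {c: config.chrom_lengths[c] // config.gene_slot for c in chroms}
    gene_counts = rng.multinomial(config.n_genes, probs)
    for c, n in zip(chroms, gene_counts):
        if n > slots_per_chrom[c]:
            raise GenerationError(
                f"{n} genes exceed placeable capacity of {c} "
                f"({slots_per_chrom[c]} slots of {config.gene_slot} bp)")

    genes: dict[str, GeneRecord] = {}
    gid = 0
    lo_len, hi_len = config.gene_length_range
    for c, n in zip(chroms, gene_counts):
        slot_idx = rng.choice(slots_per_chrom[c], size=n, replace=False)
        slot_idx.sort()
        for s in slot_idx:
            gid += 1
            length = int(rng.integers(lo_len, hi_len + 1))
            start = int(s) * config.gene_slot
            end = min(start + length, config.chrom_lengths[c])
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"G{gid:05d}"
            genes[gene_id] = GeneRecord(
                gene_id, GenomicInterval(c, start, end, strand))

    gene_list = list(genes.values())
    by_strand = {s: [g for g in gene_list if g.interval.strand == s] for s in "+-"}

    hervs: dict[str, HervLocus] = {}
    n_linked = int(round(config.herv_near_gene_frac * config.n_hervs))
    strands = np.where(rng.random(config.n_hervs) < config.plus_strand_prob, "+", "-")
    sf_names = list(SUPERFAMILIES)
    sf_probs = np.array([config.superfamily_mix[s] for s in sf_names])
    sf_draws = rng.choice(len(sf_names), size=config.n_hervs, p=sf_probs)
    lo_h, hi_h = config.herv_length_range

    for i in range(config.n_hervs):
        strand = str(strands[i])
        length = int(rng.integers(lo_h, hi_h + 1))
        if i < n_linked and by_strand[strand]:
            anchor = by_strand[strand][int(rng.integers(len(by_strand[strand])))]
            aiv = anchor.interval
            chrom_len = config.chrom_lengths[aiv.chrom]
            gap = int(rng.integers(0, int(config.window * 0.9) + 1))
            if rng.random() < 0.5:  # upstream of the gene
                end = aiv.start - gap
                start = end - length
            else:
                start = aiv.end + gap
                end = start + length
            start = max(0, min(start, chrom_len - length))
            end = start + length
            chrom = aiv.chrom
        else:
            chrom = chroms[int(rng.choice(len(chroms), p=probs))]
            chrom_len = config.chrom_lengths[chrom]
            start = int(rng.integers(0, chrom_len - length))
            end = start + length
        sf = sf_names[int(sf_draws[i])]
        locus_id = f"H{i + 1:05d}"
        hervs[locus_id] = HervLocus(
            locus_id, GenomicInterval(chrom, start, end, strand),
            family_name=_FAMILY_NAMES[sf], superfamily=sf)

    ann = GenomeAnnotation(dict(config.chrom_lengths), genes, hervs)
    ann.validate()
    return ann


def _pick_isolated_de_genes(annotation: GenomeAnnotation, config: GeneratorConfig,
                            n_de: int, rng: np.random.Generator) -> list[str]:
    """Choose DE genes so that no two same-strand DE genes lie within
    2 x window of each other.

    The isolation guarantees each HERV locus has at most one candidate DE
    driver gene, which makes the direction-concordance of true pairs follow
    the per-HERV rho rule exactly rather than being diluted by conflicting
    multi-gene neighborhoods.
    """
    if n_de == 0:
        return []
    # separation margin covers the largest HERV sitting between two windows
    separation = 2 * config.window + config.herv_length_range[1]
    by_strand: dict[str, list[str]] = {"+": [], "-": []}
    for gid, g in annotation.genes.items():
        if g.interval.strand in by_strand:
            by_strand[g.interval.strand].append(gid)
    for pool in by_strand.values():
        rng.shuffle(pool)
    # alternate strands so DE-gene windows cover both strands evenly and the
    # HERV selection they induce stays strand-neutral seed by seed
    n_interleaved = min(len(by_strand["+"]), len(by_strand["-"]))
    order = [g for tup in zip(by_strand["+"], by_strand["-"]) for g in tup]
    order += by_strand["+"][n_interleaved:] + by_strand["-"][n_interleaved:]
    chosen: list[str] = []
    occupied: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for gid in order:
        iv = annotation.genes[gid].interval
        key = (iv.chrom, iv.strand)
        if any(max(iv.start, s) - min(iv.end, e) < separation
               for s, e in occupied.get(key, [])):
            continue
        chosen.append(gid)
        occupied.setdefault(key, []).append((iv.start, iv.end))
        if len(chosen) == n_de:
            return chosen
    raise GenerationError(
        f"only {len(chosen)} of {n_de} requested DE genes can be placed with "
        f"{separation} bp same-strand isolation; lower de_fraction_genes or "
        f"enlarge the genome")


def _herv_effects(annotation: GenomeAnnotation, config: GeneratorConfig,
                  gene_lfc: Mapping[str, float],
                  rng: np.random.Generator) -> dict[str, float]:
    """Assign HERV effects from the nearest same-strand DE gene in the window."""
    de_genes = [annotation.genes[g] for g in gene_lfc]
    herv_lfc: dict[str, float] = {}
    for locus in annotation.hervs.values():
        iv = locus.interval
        best: tuple[int, str] | None = None
        for g in de_genes:
            if g.interval.strand != iv.strand:
                continue
            d = interval_distance(iv, g.interval)
            if d is not None and d <= config.window:
                if best is None or d < best[0]:
                    best = (d, g.gene_id)
        if best is None:
            continue
        driver = gene_lfc[best[1]]
        u = rng.random()
        if u < config.concordance_rho:
            herv_lfc[locus.locus_id] = driver
        elif u < config.concordance_rho + (1 - config.concordance_rho) / 2:
            herv_lfc[locus.locus_id] = -driver
        # else: no effect
    return herv_lfc


def generate_counts(annotation: GenomeAnnotation, config: GeneratorConfig
                    ) -> tuple[CountMatrix, SyntheticTruth]:
    """NB count matrices for the four conditions plus ground truth.

    Per-feature baselines are log-normal; a ``de_fraction_genes`` share of
    genes carries a signed effect (magnitudes uniform over ``lfc_range``,
    ``n_isg_like`` of them forced to +6).  DE genes are placed as mutually
    isolated anchors (see :func:`_pick_isolated_de_genes`).  Effects are
    expressed only where the receptor
    pathway is intact: full in treated wild-type, absent in the IFNAR1
    knockout, ``mt2_attenuation`` retained in the IFNAR2 mutant.
    """
    rng = _rng(config, 1)
    gene_ids = list(annotation.genes)
    herv_ids = list(annotation.hervs)
    features = gene_ids + herv_ids

    n_de = int(round(config.de_fraction_genes * len(gene_ids)))
    n_isg = min(config.n_isg_like, n_de)
    de_gene_ids = _pick_isolated_de_genes(annotation, config, n_de, rng)
    lo, hi = config.lfc_range
    gene_lfc: dict[str, float] = {}
    for j, gid in enumerate(de_gene_ids):
        if j < n_isg:
            lfc = 6.0
        else:
            sign = 1.0 if rng.random() < config.de_up_prob else -1.0
            lfc = sign * float(rng.uniform(lo, hi))
        gene_lfc[gid] = lfc

    herv_lfc = _herv_effects(annotation, config, gene_lfc, rng)

    true_pairs: list[tuple[str, str, bool]] = []
    for hid, hl in herv_lfc.items():
        iv = annotation.hervs[hid].interval
        for gid, gl in gene_lfc.items():
            giv = annotation.genes[gid].interval
            if giv.strand != iv.strand:
                continue
            d = interval_distance(iv, giv)
            if d is not None and d <= config.window:
                true_pairs.append((hid, gid, (hl > 0) == (gl > 0)))

    baselines = rng.lognormal(config.nb_mean_log_mu, config.nb_mean_log_sigma,
                              size=len(features))
    lfc_vec = np.array([gene_lfc.get(f, herv_lfc.get(f, 0.0)) for f in features])

    effect_scale = {"IFNb_N": 1.0, "IFNb_KO1": 0.0,
                    "IFNb_MT2": config.mt2_attenuation, "N": 0.0}
    disp = config.nb_dispersion
    nb_n = 1.0 / disp

    columns, sample_condition = [], {}
    data = {}
    for cond in CONDITIONS:
        cond_mean = baselines * np.power(2.0, effect_scale[cond] * lfc_vec)
        for r in range(config.n_replicates):
            sample = f"{cond}_r{r + 1}"
            lib = float(rng.lognormal(0.0, 0.2))
            mu = cond_mean * lib
            p = nb_n / (nb_n + mu)
            data[sample] = rng.negative_binomial(nb_n, p)
            columns.append(sample)
            sample_condition[sample] = cond

    counts = pd.DataFrame(data, index=pd.Index(features, name="feature_id"),
                          columns=columns).astype("int64")
    truth = SyntheticTruth(gene_lfc, herv_lfc, true_pairs, config)
    return CountMatrix(counts, sample_condition), truth


def study_contrasts(cm: CountMatrix) -> dict[str, ContrastSpec]:
    """The three named contrasts of the emulated study: treated wild-type vs
    treated IFNAR1-KO (KO1), vs treated IFNAR2-mutant (KO2), and vs
    untreated wild-type (N)."""
    treated = tuple(cm.samples_for("IFNb_N"))
    return {
        "KO1": ContrastSpec("KO1", treated, tuple(cm.samples_for("IFNb_KO1"))),
        "KO2": ContrastSpec("KO2", treated, tuple(cm.samples_for("IFNb_MT2"))),
        "N": ContrastSpec("N", treated, tuple(cm.samples_for("N"))),
    }


def generate_experiment(config: GeneratorConfig):
    """Convenience: annotation, counts, truth and the three contrasts."""
    ann = generate_annotation(config)
    cm, truth = generate_counts(ann, config)
    return ann, cm, truth, study_contrasts(cm)


def write_synthetic_dataset(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a full dataset in the formats the pipeline reads: gene/HERV BED,
    counts TSV, design YAML, chromosome sizes TSV and truth JSON."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann, cm, truth, _ = generate_experiment(config)

    paths = {
        "genes": outdir / "genes.bed",
        "hervs": outdir / "hervs.bed",
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.yaml",
        "chrom_sizes": outdir / "chrom_sizes.tsv",
        "truth": outdir / "truth.json",
    }
    write_bed(ann.genes.values(), paths["genes"])
    write_bed(ann.hervs.values(), paths["hervs"])
    write_counts(cm, paths["counts"])
    with open(paths["design"], "w") as fh:
        yaml.safe_dump(cm.sample_condition, fh, sort_keys=True)
    with open(paths["chrom_sizes"], "w") as fh:
        for c, ln in ann.chrom_lengths.items():
            fh.write(f"{c}\t{ln}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
    return paths
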