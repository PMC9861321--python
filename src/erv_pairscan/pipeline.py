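"""End-to-end orchestration: counts + annotations -> DE screens -> DEHERV-G
pairs -> strand/superfamily statistics -> machine-readable report.

Output layout under the configured directory::

    de/<contrast>.genes.tsv, de/<contrast>.hervs.tsv
    pairs/<contrast>.pairs.tsv
    stats/<contrast>.json
    venn.json
    report.json / report.md

Every aggregate in the report is re-derivable from the stage TSVs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .annotation_io import (
    CountMatrix,
    GenomeAnnotation,
    read_counts,
    read_design,
    read_gene_annotation,
    read_herv_annotation,
)
from .diffexpr import ContrastSpec, de_ids, nb_wald_test, write_de_table
from .pairing import find_pairs, intersect_pairs, summarize_pairs, write_pairs
from .strand_stats import (
    StatisticsError,
    chrom_size_correlation,
    strand_summary,
    superfamily_tally,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        super().__init__(f"[{stage}] {message}" + (f" ({hint})" if hint else ""))


@dataclass
class PipelineConfig:
    counts_path: str
    design_path: str
    gene_annotation_path: str
    herv_annotation_path: str
    outdir: str
    gene_format: str = "bed"
    herv_format: str = "bed"
    chrom_sizes_path: str | None = None
    contrasts: dict[str, dict[str, str]] = field(default_factory=dict)
    # each contrast: {"treated": <condition>, "control": <condition>}
    alpha: float = 0.05
    lfc: float = 1.0
    use_adjusted: bool = False
    window: int = 100_000
    nearest_only: bool = False
    exclude_chroms: tuple[str, ...] = ("chrX", "chrY", "chrM")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for name in ("counts_path", "design_path", "gene_annotation_path",
                     "herv_annotation_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise PipelineError("config", f"{name} does not exist: {p}")
        if self.chrom_sizes_path and not Path(self.chrom_sizes_path).exists():
            raise PipelineError("config", f"chrom_sizes_path does not exist: "
                                          f"{self.chrom_sizes_path}")
        if len({*self.contrasts}) != len(self.contrasts):
            raise PipelineError("config", "contrast names must be unique")


@dataclass
class RunReport:
    version: str
    config: dict
    de_counts: dict[str, dict[str, int]]         # contrast -> up/down per class
    pair_summaries: dict[str, dict]
    venn: dict
    strand: dict[str, dict]
    superfamily: dict[str, dict]
    chrom_correlation: dict[str, dict | None]
    wall_clock_s: float

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "de_counts": self.de_counts,
            "pair_summaries": self.pair_summaries,
            "venn": self.venn,
            "strand": self.strand,
            "superfamily": self.superfamily,
            "chrom_correlation": self.chrom_correlation,
            "wall_clock_s": self.wall_clock_s,
        }


def _contrast_specs(config: PipelineConfig, cm: CountMatrix) -> dict[str, ContrastSpec]:
    specs = {}
    for name, sides in config.contrasts.items():
        treated = tuple(cm.samples_for(sides["treated"]))
        control = tuple(cm.samples_for(sides["control"]))
        if not treated or not control:
            raise PipelineError(
                "config", f"contrast {name}: no samples for one side",
                hint="check design condition labels")
        specs[name] = ContrastSpec(name, treated, control)
    return specs


def _read_chrom_sizes(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"], df["length"].astype(int)))


def run_pipeline(config: PipelineConfig,
                 contrast_specs: Mapping[str, ContrastSpec] | None = None,
                 ) -> RunReport:
    """Run all stages and write artifacts under ``config.outdir``.

    ``contrast_specs`` may pre-resolve contrasts to explicit sample lists,
    bypassing the condition-name lookup.  Idempotent for fixed inputs.
    """
    t0 = time.monotonic()
    config.validate()
    outdir = Path(config.outdir)
    for sub in ("de", "pairs", "stats"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    try:
        design = read_design(config.design_path)
        cm = read_counts(config.counts_path, design)
        genes = {g.gene_id: g for g in read_gene_annotation(
            config.gene_annotation_path, config.gene_format)}
        hervs = {h.locus_id: h for h in read_herv_annotation(
            config.herv_annotation_path, config.herv_format)}
    except Exception as exc:
        raise PipelineError("load", str(exc), hint="check input paths/formats") from exc

    annotated = set(genes) | set(hervs)
    n_orphans = sum(f not in annotated for f in cm.feature_ids)
    if n_orphans:
        log.info("%d count-matrix features lack coordinates: tested for DE, "
                 "excluded from pairing", n_orphans)

    if config.chrom_sizes_path:
        chrom_lengths = _read_chrom_sizes(config.chrom_sizes_path)
    else:  # infer from annotation hulls
        chrom_lengths = {}
        for rec in list(genes.values()) + list(hervs.values()):
            iv = rec.interval
            chrom_lengths[iv.chrom] = max(chrom_lengths.get(iv.chrom, 0), iv.end)

    specs = dict(contrast_specs) if contrast_specs else _contrast_specs(config, cm)
    if len(specs) == 0:
        raise PipelineError("config", "no contrasts defined")

    de_counts: dict[str, dict[str, int]] = {}
    pair_frames: dict[str, pd.DataFrame] = {}
    pair_summaries: dict[str, dict] = {}
    strand: dict[str, dict] = {}
    superfamily: dict[str, dict] = {}
    chrom_corr: dict[str, dict | None] = {}

    for name, spec in specs.items():
        try:
            de = nb_wald_test(cm, spec, alpha=config.alpha,
                              lfc_threshold=config.lfc,
                              use_adjusted=config.use_adjusted)
        except Exception as exc:
            raise PipelineError(f"de:{name}", str(exc)) from exc
        gene_de = de.loc[[f for f in de.index if f in genes]]
        herv_de = de.loc[[f for f in de.index if f in hervs]]
        write_de_table(gene_de, outdir / "de" / f"{name}.genes.tsv")
        write_de_table(herv_de, outdir / "de" / f"{name}.hervs.tsv")
        de_counts[name] = {
            "genes_up": len(de_ids(gene_de, "up")),
            "genes_down": len(de_ids(gene_de, "down")),
            "hervs_up": len(de_ids(herv_de, "up")),
            "hervs_down": len(de_ids(herv_de, "down")),
        }

        try:
            pairs = find_pairs(hervs, genes, herv_de, gene_de,
                               window=config.window, contrast=name,
                               nearest_only=config.nearest_only)
        except Exception as exc:
            raise PipelineError(f"pairs:{name}", str(exc)) from exc
        write_pairs(pairs, outdir / "pairs" / f"{name}.pairs.tsv")
        pair_frames[name] = pairs
        pair_summaries[name] = summarize_pairs(pairs).to_dict()

        dehervs = [hervs[i] for i in de_ids(herv_de)]
        ss = strand_summary(dehervs) if dehervs else None
        strand[name] = ss.to_dict() if ss else {"n_plus": 0, "n_minus": 0,
                                                "pvalue": None}
        superfamily[name] = superfamily_tally(dehervs).to_dict()
        try:
            per_chrom = {c: sum(v) for c, v in (ss.per_chrom.items() if ss else [])}
            corr = chrom_size_correlation(per_chrom, chrom_lengths,
                                          exclude=config.exclude_chroms)
            chrom_corr[name] = corr.to_dict()
        except StatisticsError as exc:
            log.warning("contrast %s: %s", name, exc)
            chrom_corr[name] = None

        with open(outdir / "stats" / f"{name}.json", "w") as fh:
            json.dump({"strand": strand[name], "superfamily": superfamily[name],
                       "chrom_correlation": chrom_corr[name]}, fh, indent=1)

    venn = (intersect_pairs(pair_frames).to_dict() if len(pair_frames) >= 2
            else {"n_common_pairs": None, "venn": {}})
    with open(outdir / "venn.json", "w") as fh:
        json.dump(venn, fh, indent=1)

    report = RunReport(
        version=__version__,
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(config).items()},
        de_counts=de_counts,
        pair_summaries=pair_summaries,
        venn=venn,
        strand=strand,
        superfamily=superfamily,
        chrom_correlation=chrom_corr,
        wall_clock_s=round(time.monotonic() - t0, 3),
    )
    write_report(report, outdir / "report.json", "json")
    write_report(report, outdir / "report.md", "markdown")
    return report


def write_report(report: RunReport, path: str | Path, format: str = "json") -> None:
    d = report.to_dict()
    if format == "json":
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=str)
    elif format == "markdown":
        lines = [f"# erv-pairscan report (v{d['version']})", ""]
        lines.append("## Differential expression counts")
        for c, v in d["de_counts"].items():
            lines.append(f"- **{c}**: genes {v['genes_up']} up / {v['genes_down']} down; "
                         f"HERVs {v['hervs_up']} up / {v['hervs_down']} down")
        lines.append("")
        lines.append("## DEHERV-G pairs")
        for c, s in d["pair_summaries"].items():
            cf = s["consistent_fraction"]
            cf_s = f"{cf:.3f}" if cf is not None else "n/a"
            lines.append(f"- **{c}**: {s['n_pairs']} pairs over "
                         f"{s['n_herv_loci']} loci / {s['n_genes']} genes; "
                         f"consistent fraction {cf_s}")
        lines.append("")
        lines.append(f"- common pairs across contrasts: "
                     f"{d['venn'].get('n_common_pairs')}")
        lines.append("")
        lines.append("## Strand distribution of DEHERVs")
        for c, s in d["strand"].items():
            lines.append(f"- **{c}**: {s['n_plus']} plus / {s['n_minus']} minus "
                         f"({s.get('percent_plus')}% plus), "
                         f"binomial p = {s.get('pvalue')}")
        lines.append("")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def load_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
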