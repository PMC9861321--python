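#!/usr/bin/env python
"""Descriptive statistics over the DEHERV sets: strand distribution with the
exact binomial test, chromosome-size correlation, and superfamily
composition — plus the same strand reporting applied to the emulated
study's printed per-group counts.

Writes results/stats/<contrast>.json and prints the headline numbers.
"""

import json
from pathlib import Path

import pandas as pd

from erv_pairscan.annotation_io import read_herv_annotation
from erv_pairscan.diffexpr import import_de_table
from erv_pairscan.strand_stats import (
    StrandSummary,
    chrom_size_correlation,
    strand_summary,
    superfamily_tally,
)

ROOT = Path(__file__).resolve().parent.parent / "results"

# printed per-group DEHERV strand counts of the emulated study
STUDY_STRAND_COUNTS = {"KO1": (4540, 2571), "KO2": (2109, 1330),
                       "N": (1184, 683)}


def main() -> None:
    hervs = {h.locus_id: h
             for h in read_herv_annotation(ROOT / "synthetic" / "hervs.bed", "bed")}
    sizes = dict(pd.read_csv(ROOT / "synthetic" / "chrom_sizes.tsv", sep="\t",
                             header=None).values)
    sizes = {c: int(l) for c, l in sizes.items()}
    outdir = ROOT / "stats"
    outdir.mkdir(parents=True, exist_ok=True)

    for name in ("KO1", "KO2", "N"):
        de = import_de_table(ROOT / "de" / f"{name}.tsv")
        dehervs = [hervs[i] for i in de.index[de["is_de"]] if i in hervs]
        ss = strand_summary(dehervs)
        tally = superfamily_tally(dehervs)
        corr = chrom_size_correlation(
            {c: sum(v) for c, v in ss.per_chrom.items()}, sizes, exclude=())
        with open(outdir / f"{name}.json", "w") as fh:
            json.dump({"strand": ss.to_dict(),
                       "superfamily": tally.to_dict(),
                       "chrom_correlation": corr.to_dict()}, fh, indent=1)
        print(f"{name}: {ss.n_plus}+/{ss.n_minus}- ({ss.percent_plus}% plus), "
              f"binomial p = {ss.pvalue:.3g}; "
              f"chromosome-size Pearson r = {corr.pearson_r:.3f}")

    print("\nstudy strand reporting from printed counts:")
    for name, (n_plus, n_minus) in STUDY_STRAND_COUNTS.items():
        s = StrandSummary.from_counts(n_plus, n_minus)
        print(f"  {name}: {n_plus}+/{n_minus}- -> {s.percent_plus}% plus, "
              f"exact binomial p = {s.pvalue:.3g}")


if __name__ == "__main__":
    main()
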