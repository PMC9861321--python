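#!/usr/bin/env python
"""Screen genes and HERV loci for differential expression in the three
contrasts (KO1: treated wild-type vs treated IFNAR1-KO; KO2: vs treated
IFNAR2-mutant; N: vs untreated wild-type).

Reads the dataset written by 01_simulate_experiment.py, runs the NB Wald
screen (p < 0.05, |log2FC| > 1) per contrast and writes per-contrast DE
tables under results/de/.  Prints the up/down counts that later drivers
summarize.
"""

from pathlib import Path

from erv_pairscan.annotation_io import read_counts, read_design
from erv_pairscan.diffexpr import ContrastSpec, de_ids, nb_wald_test, write_de_table

ROOT = Path(__file__).resolve().parent.parent / "results"

CONTRASTS = {
    "KO1": ("IFNb_N", "IFNb_KO1"),
    "KO2": ("IFNb_N", "IFNb_MT2"),
    "N": ("IFNb_N", "N"),
}


def main() -> None:
    design = read_design(ROOT / "synthetic" / "design.yaml")
    cm = read_counts(ROOT / "synthetic" / "counts.tsv", design)
    outdir = ROOT / "de"
    outdir.mkdir(parents=True, exist_ok=True)
    for name, (treated, control) in CONTRASTS.items():
        spec = ContrastSpec(name, tuple(cm.samples_for(treated)),
                            tuple(cm.samples_for(control)))
        res = nb_wald_test(cm, spec)
        write_de_table(res, outdir / f"{name}.tsv")
        up, down = len(de_ids(res, "up")), len(de_ids(res, "down"))
        print(f"{name}: {up} up, {down} down of {len(res)} features "
              f"(screen p < 0.05, |log2FC| > 1)")


if __name__ == "__main__":
    main()
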