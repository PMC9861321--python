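#!/usr/bin/env python
"""Generate the standard synthetic IFN-beta / IFNAR experiment.

Writes a full dataset (gene and HERV BED annotations, NB count matrix for
the four conditions, sample design, chromosome sizes, ground truth) under
results/synthetic/.  Downstream drivers (02-04) consume these files exactly
as they would consume real featureCounts output plus Ensembl / RepeatMasker
annotations.
"""

import json
from pathlib import Path

from erv_pairscan.synthetic import GeneratorConfig, write_synthetic_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 1


def main() -> None:
    cfg = GeneratorConfig(seed=SEED, n_replicates=5)
    paths = write_synthetic_dataset(cfg, OUT)
    truth = json.loads(paths["truth"].read_text())
    print(f"wrote synthetic dataset to {OUT}")
    print(f"  genes: {cfg.n_genes}, HERV loci: {cfg.n_hervs}, "
          f"replicates/condition: {cfg.n_replicates}")
    print(f"  true DE genes: {len(truth['true_de_genes'])}, "
          f"true DE HERVs: {len(truth['true_de_hervs'])}, "
          f"truth pairs: {len(truth['true_pairs'])}")


if __name__ == "__main__":
    main()
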