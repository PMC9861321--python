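import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from erv_pairscan.annotation_io import (
    CountMatrix,
    GeneRecord,
    GenomicInterval,
    HervLocus,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_gene(gene_id, chrom, start, end, strand):
    return GeneRecord(gene_id, GenomicInterval(chrom, start, end, strand))


def make_herv(locus_id, chrom, start, end, strand, family="LTR/ERV1"):
    from erv_pairscan.annotation_io import classify_superfamily
    return HervLocus(locus_id, GenomicInterval(chrom, start, end, strand),
                     family_name=family, superfamily=classify_superfamily(family))


def de_frame(entries):
    """Build a screened DE frame from {feature_id: (log2fc, pvalue)} or
    {feature_id: direction-string}."""
    rows = {}
    for fid, spec in entries.items():
        if isinstance(spec, str):
            lfc = {"up": 3.0, "down": -3.0, "ns": 0.0}[spec]
            p = 0.001 if spec != "ns" else 0.9
        else:
            lfc, p = spec
        rows[fid] = {"base_mean": 100.0, "log2fc": lfc, "pvalue": p, "padj": p}
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["base_mean", "log2fc", "pvalue", "padj"])
    df.index.name = "feature_id"
    from erv_pairscan.diffexpr import apply_screen
    return apply_screen(df)


@pytest.fixture
def small_counts():
    rng = np.random.default_rng(0)
    mat = rng.integers(10, 200, size=(20, 6))
    df = pd.DataFrame(mat, index=[f"F{i:02d}" for i in range(20)],
                      columns=[f"s{i}" for i in range(6)]).astype("int64")
    cond = {f"s{i}": ("treated" if i < 3 else "control") for i in range(6)}
    return CountMatrix(df, cond)
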