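"""HERV-gene pair construction, pattern classification and intersection.

A DEHERV-G pair is a (differentially expressed HERV locus, differentially
expressed gene) on the same strand of the same chromosome whose interval gap
is at most the window (default 100 kb, inclusive; overlap counts as 0).  By
default every qualifying gene within the window pairs with the locus;
``nearest_only=True`` restricts each locus to its minimum-distance gene(s),
keeping ties.  Pair identity for cross-contrast intersection is
(herv_id, gene_id) regardless of the concordance pattern.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation_io import GeneRecord, GenomicInterval, HervLocus

log = logging.getLogger(__name__)

PATTERNS = ("both_up", "both_down", "herv_up_gene_down", "herv_down_gene_up")

PAIR_COLUMNS = [
    "contrast", "herv_id", "gene_id", "chrom", "herv_start", "herv_end",
    "gene_start", "gene_end", "strand", "distance_bp",
    "herv_log2fc", "gene_log2fc", "pattern",
]

_PATTERN_OF = {
    ("up", "up"): "both_up",
    ("down", "down"): "both_down",
    ("up", "down"): "herv_up_gene_down",
    ("down", "up"): "herv_down_gene_up",
}


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Gap in bp between two intervals; 0 if they overlap, None if on
    different chromosomes."""
    if a.chrom != b.chrom:
        return None
    gap = max(a.start, b.start) - min(a.end, b.end)
    return max(gap, 0)


def classify_pattern(herv_direction: str, gene_direction: str) -> str:
    """One of the four concordance patterns from the two DE directions."""
    try:
        return _PATTERN_OF[(herv_direction, gene_direction)]
    except KeyError:
        raise ValueError(
            f"pattern undefined for directions ({herv_direction!r}, "
            f"{gene_direction!r}); both members must be DE"
        ) from None


def _as_mapping(records, id_attr):
    if isinstance(records, Mapping):
        return records
    return {getattr(r, id_attr): r for r in records}


def find_pairs(hervs: Mapping[str, HervLocus] | Iterable[HervLocus],
               genes: Mapping[str, GeneRecord] | Iterable[GeneRecord],
               herv_de: pd.DataFrame, gene_de: pd.DataFrame,
               window: int = 100_000, contrast: str = "",
               nearest_only: bool = False) -> pd.DataFrame:
    """All DEHERV-G pairs for one contrast, as a frame with PAIR_COLUMNS.

    ``herv_de``/``gene_de`` are screened DE result frames (see diffexpr);
    only features with is_de participate.  Unstranded (".") records are
    excluded with a logged count.  Interval-tree indexed; equivalent to the
    brute-force all-pairs scan.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    hervs = _as_mapping(hervs, "locus_id")
    genes = _as_mapping(genes, "gene_id")

    de_hervs = [hervs[i] for i in herv_de.index[herv_de["is_de"]] if i in hervs]
    de_genes = [genes[i] for i in gene_de.index[gene_de["is_de"]] if i in genes]
    n_unstranded = sum(r.interval.strand == "." for r in de_hervs) + \
        sum(r.interval.strand == "." for r in de_genes)
    if n_unstranded:
        log.info("contrast %s: %d unstranded DE records excluded from pairing",
                 contrast, n_unstranded)
    de_hervs = [h for h in de_hervs if h.interval.strand != "."]
    de_genes = [g for g in de_genes if g.interval.strand != "."]

    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in de_genes:
        iv = g.interval
        trees.setdefault((iv.chrom, iv.strand), IntervalTree()).addi(
            iv.start, iv.end, g)

    rows = []
    for h in de_hervs:
        iv = h.interval
        tree = trees.get((iv.chrom, iv.strand))
        if tree is None:
            continue
        # envelope query admits gap == window exactly; re-checked below
        for hit in tree.overlap(iv.start - window - 1, iv.end + window + 1):
            g = hit.data
            d = interval_distance(iv, g.interval)
            if d is None or d > window:
                continue
            hd = herv_de.at[h.locus_id, "direction"]
            gd = gene_de.at[g.gene_id, "direction"]
            rows.append({
                "contrast": contrast,
                "herv_id": h.locus_id, "gene_id": g.gene_id,
                "chrom": iv.chrom,
                "herv_start": iv.start, "herv_end": iv.end,
                "gene_start": g.interval.start, "gene_end": g.interval.end,
                "strand": iv.strand, "distance_bp": d,
                "herv_log2fc": float(herv_de.at[h.locus_id, "log2fc"]),
                "gene_log2fc": float(gene_de.at[g.gene_id, "log2fc"]),
                "pattern": classify_pattern(hd, gd),
            })
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    if nearest_only and not df.empty:
        df = df[df.groupby("herv_id")["distance_bp"].transform("min")
                == df["distance_bp"]]
    return df.sort_values(["herv_id", "gene_id"]).reset_index(drop=True)


@dataclass
class PairSetSummary:
    n_pairs: int
    n_herv_loci: int
    n_genes: int
    pattern_counts: dict[str, int]
    consistent_fraction: float | None

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_herv_loci": self.n_herv_loci,
            "n_genes": self.n_genes,
            "pattern_counts": dict(self.pattern_counts),
            "consistent_fraction": self.consistent_fraction,
        }


def summarize_pairs(pairs: pd.DataFrame) -> PairSetSummary:
    """Counts, distinct members and consistent (both-up + both-down) fraction."""
    counts = {p: 0 for p in PATTERNS}
    if not pairs.empty:
        counts.update(pairs["pattern"].value_counts().to_dict())
    n = len(pairs)
    consistent = (counts["both_up"] + counts["both_down"]) / n if n else None
    return PairSetSummary(
        n_pairs=n,
        n_herv_loci=pairs["herv_id"].nunique() if n else 0,
        n_genes=pairs["gene_id"].nunique() if n else 0,
        pattern_counts=counts,
        consistent_fraction=consistent,
    )


@dataclass
class IntersectionResult:
    """Cross-contrast overlap of pair identities (herv_id, gene_id)."""

    common: set[tuple[str, str]]
    venn: dict[str, int]            # exclusive region label -> cardinality
    n_common_hervs: int
    n_common_genes: int

    def to_dict(self) -> dict:
        return {
            "n_common_pairs": len(self.common),
            "n_common_hervs": self.n_common_hervs,
            "n_common_genes": self.n_common_genes,
            "venn": dict(self.venn),
        }


def intersect_pairs(pair_sets: Mapping[str, pd.DataFrame | set]) -> IntersectionResult:
    """Pairs common to every contrast, plus all exclusive Venn region sizes.

    A pair identity is common iff it occurs in every contrast's set,
    regardless of its pattern there.
    """
    if len(pair_sets) < 2:
        raise ValueError("intersection needs >= 2 contrasts")
    names = list(pair_sets)
    ids: dict[str, set[tuple[str, str]]] = {}
    for name, ps in pair_sets.items():
        if isinstance(ps, pd.DataFrame):
            ids[name] = set(zip(ps["herv_id"], ps["gene_id"])) if len(ps) else set()
        else:
            ids[name] = set(ps)

    venn: dict[str, int] = {}
    universe = set().union(*ids.values())
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set(universe)
            for c in combo:
                inside &= ids[c]
            for c in names:
                if c not in combo:
                    inside -= ids[c]
            venn["&".join(combo)] = len(inside)

    common = set.intersection(*ids.values())
    return IntersectionResult(
        common=common,
        venn=venn,
        n_common_hervs=len({h for h, _ in common}),
        n_common_genes=len({g for _, g in common}),
    )


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)
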