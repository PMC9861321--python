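"""Descriptive statistics over differentially expressed HERV loci:
strand distribution with an exact binomial test, per-chromosome counts and
their correlation with chromosome size, and superfamily composition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .annotation_io import SUPERFAMILIES, HervLocus


class StatisticsError(ValueError):
    pass


def exact_binom_pvalue(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value: the sum of probabilities of all
    outcomes no more likely than the observed one under Binomial(n, p0)."""
    return float(stats.binomtest(k, n, p0).pvalue)


def format_percent(fraction: float, decimals: int = 1) -> str:
    """Percentage string with half-up rounding (e.g. 0.63845 -> "63.8")."""
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class StrandSummary:
    n_plus: int
    n_minus: int
    per_chrom: dict[str, tuple[int, int]]
    pvalue: float | None     # exact two-sided binomial, p0 = 0.5

    @property
    def n(self) -> int:
        return self.n_plus + self.n_minus

    @property
    def frac_plus(self) -> float | None:
        return self.n_plus / self.n if self.n else None

    @property
    def percent_plus(self) -> str | None:
        """Plus-strand share formatted at 1 decimal (reporting style)."""
        return format_percent(self.frac_plus) if self.n else None

    @classmethod
    def from_counts(cls, n_plus: int, n_minus: int,
                    per_chrom: Mapping[str, tuple[int, int]] | None = None,
                    test: str = "binomial") -> "StrandSummary":
        n = n_plus + n_minus
        if n == 0:
            p = None
        elif test == "binomial":
            p = exact_binom_pvalue(n_plus, n)
        elif test == "chisq":
            p = float(stats.chisquare([n_plus, n_minus]).pvalue)
        else:
            raise ValueError(f"unknown strand test {test!r}")
        return cls(n_plus, n_minus, dict(per_chrom or {}), p)

    def to_dict(self) -> dict:
        return {
            "n_plus": self.n_plus,
            "n_minus": self.n_minus,
            "frac_plus": self.frac_plus,
            "percent_plus": self.percent_plus,
            "pvalue": self.pvalue,
            "per_chrom": {c: list(v) for c, v in self.per_chrom.items()},
        }


def strand_summary(loci: Iterable[HervLocus], test: str = "binomial") -> StrandSummary:
    """Strand distribution of a DEHERV set with exact binomial test of the
    plus-vs-minus split against an even (p0 = 0.5) expectation."""
    per_chrom: dict[str, list[int]] = {}
    n_plus = n_minus = 0
    for locus in loci:
        iv = locus.interval
        if iv.strand not in ("+", "-"):
            raise StatisticsError(f"unstranded locus {locus.locus_id}")
        entry = per_chrom.setdefault(iv.chrom, [0, 0])
        if iv.strand == "+":
            n_plus += 1
            entry[0] += 1
        else:
            n_minus += 1
            entry[1] += 1
    return StrandSummary.from_counts(
        n_plus, n_minus, {c: (a, b) for c, (a, b) in per_chrom.items()}, test=test)


@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n_chromosomes: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def chrom_size_correlation(per_chrom_counts: Mapping[str, int],
                           chrom_lengths: Mapping[str, int],
                           exclude: Sequence[str] = ("chrX", "chrY", "chrM"),
                           ) -> CorrelationResult:
    """Correlation between per-chromosome DEHERV counts and chromosome size.

    Chromosomes in ``exclude`` (default: sex chromosomes and mitochondrion,
    the autosome-focused convention) are dropped; chromosomes with a stated
    length but no counted loci contribute a zero count.  Requires >= 3
    chromosomes after exclusion.
    """
    excluded = set(exclude)
    chroms = [c for c in chrom_lengths if c not in excluded]
    if len(chroms) < 3:
        raise StatisticsError(
            f"need >= 3 chromosomes for a correlation, have {len(chroms)}")
    x = [chrom_lengths[c] for c in chroms]
    y = [per_chrom_counts.get(c, 0) for c in chroms]
    if len(set(y)) == 1 or len(set(x)) == 1:
        # zero variance: correlation undefined; report 0 with p = 1
        return CorrelationResult(0.0, 1.0, 0.0, 1.0, len(chroms))
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationResult(float(pr.statistic), float(pr.pvalue),
                             float(sr.statistic), float(sr.pvalue), len(chroms))


@dataclass
class SuperfamilyTally:
    counts: dict[str, int]
    fractions: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        return {"counts": dict(self.counts), "fractions": dict(self.fractions)}


def superfamily_tally(loci: Iterable[HervLocus]) -> SuperfamilyTally:
    """Counts and fractions over the six superfamily bins, zero-filled."""
    counter = Counter(l.superfamily for l in loci)
    counts = {sf: int(counter.get(sf, 0)) for sf in SUPERFAMILIES}
    total = sum(counts.values())
    fractions = {sf: (c / total if total else 0.0) for sf, c in counts.items()}
    return SuperfamilyTally(counts, fractions)
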