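"""Readers and normalizers for gene/HERV annotations and count matrices.

Coordinates are stored 0-based half-open internally.  GTF input/output is
1-based inclusive, BED is already 0-based half-open, and RepeatMasker ``.out``
query coordinates are 1-based inclusive; all are converted on read.

Chromosome names are normalized to the UCSC ``chr``-prefixed dialect by
default so that Ensembl-style ("1") and UCSC-style ("chr1") inputs can be
mixed (see :func:`normalize_chrom`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

log = logging.getLogger(__name__)

#: The six ERV superfamily bins used throughout the package.
SUPERFAMILIES = ("ERV1", "ERVL", "ERVK", "Gypsy", "ERVL-MaLR", "unclassified")

_VALID_STRANDS = ("+", "-", ".")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


class CountsError(ValueError):
    """Malformed count matrix or design/matrix mismatch."""


# ---------------------------------------------------------------------------
# coordinate conversions
# ---------------------------------------------------------------------------

def gtf_to_internal(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive (GTF) -> 0-based half-open."""
    return start - 1, end


def internal_to_gtf(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (GTF)."""
    return start + 1, end


def normalize_chrom(name: str, style: str = "chr") -> str:
    """Unify chromosome naming across Ensembl ("1", "MT") and UCSC ("chr1", "chrM").

    ``style="chr"`` (default) adds the ``chr`` prefix where missing;
    ``style="plain"`` strips it.  ``MT``/``chrMT`` map to ``chrM``/``M``.
    """
    name = name.strip()
    bare = name[3:] if name.lower().startswith("chr") else name
    if bare.upper() == "MT":
        bare = "M"
    if style == "chr":
        return "chr" + bare
    if style == "plain":
        return bare
    raise ValueError(f"unknown chromosome name style {style!r}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    ``strand`` is "+", "-" or "." (unstranded; such records are excluded
    from strand-aware pairing downstream).
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AnnotationError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _VALID_STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    interval: GenomicInterval
    gene_name: str | None = None


@dataclass(frozen=True)
class HervLocus:
    locus_id: str
    interval: GenomicInterval
    family_name: str
    superfamily: str

    def __post_init__(self) -> None:
        if self.superfamily not in SUPERFAMILIES:
            raise AnnotationError(f"unknown superfamily {self.superfamily!r}")


@dataclass
class GenomeAnnotation:
    """Chromosome lengths plus located gene and HERV records (dicts by ID)."""

    chrom_lengths: dict[str, int]
    genes: dict[str, GeneRecord] = field(default_factory=dict)
    hervs: dict[str, HervLocus] = field(default_factory=dict)

    def validate(self) -> None:
        for rec_id, iv in [(g.gene_id, g.interval) for g in self.genes.values()] + [
            (h.locus_id, h.interval) for h in self.hervs.values()
        ]:
            length = self.chrom_lengths.get(iv.chrom)
            if length is None:
                raise AnnotationError(f"{rec_id}: unknown chromosome {iv.chrom}")
            if iv.end > length:
                raise AnnotationError(
                    f"{rec_id}: interval end {iv.end} exceeds {iv.chrom} length {length}"
                )


@dataclass
class CountMatrix:
    """Non-negative integer feature x sample matrix with a condition design."""

    counts: pd.DataFrame  # features x samples, integer dtype
    sample_condition: dict[str, str]

    def __post_init__(self) -> None:
        mat = self.counts
        if not all(pd.api.types.is_integer_dtype(t) for t in mat.dtypes):
            raise CountsError("count matrix must be integral")
        if (mat.to_numpy() < 0).any():
            raise CountsError("count matrix contains negative entries")
        missing = [s for s in mat.columns if s not in self.sample_condition]
        if missing:
            raise CountsError(f"samples without condition label: {missing}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.sample_condition[s] == condition]


# ---------------------------------------------------------------------------
# superfamily classification
# ---------------------------------------------------------------------------

def classify_superfamily(family_field: str) -> str:
    """Map a RepeatMasker/Dfam class-family string to one of the six superfamilies.

    Matching is case-insensitive on the family component after stripping a
    leading ``LTR/`` class prefix; ``ERVL-MaLR`` is tested before ``ERVL``
    (longest-match precedence).  Anything else, including non-LTR repeat
    classes, maps to ``unclassified``.  Total function: never raises.
    """
    fam = (family_field or "").strip()
    fam = re.sub(r"^LTR/", "", fam, flags=re.IGNORECASE).upper()
    if "ERVL-MALR" in fam:
        return "ERVL-MaLR"
    for key, label in (("ERV1", "ERV1"), ("ERVK", "ERVK"), ("ERVL", "ERVL"),
                       ("GYPSY", "Gypsy")):
        if key in fam:
            return label
    return "unclassified"


# ---------------------------------------------------------------------------
# GTF / BED / RepeatMasker readers
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"\s*;')


def _parse_gtf_row(line: str, lineno: int) -> tuple[str, str, int, int, str, dict[str, str]]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 9:
        raise AnnotationError(f"line {lineno}: expected 9 GTF columns, got {len(parts)}")
    chrom, _source, feature, start, end, _score, strand, _frame, attrs = parts
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: non-integer coordinates") from exc
    if strand not in _VALID_STRANDS:
        raise AnnotationError(f"line {lineno}: invalid strand {strand!r}")
    attr_map = dict(_GTF_ATTR.findall(attrs))
    s0, e0 = gtf_to_internal(start_i, end_i)
    return chrom, feature, s0, e0, strand, attr_map


def _iter_data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line


def read_gene_annotation(path: str | Path, format: str = "gtf",
                         chrom_style: str = "chr") -> list[GeneRecord]:
    """Read gene records from GTF or BED6.

    For GTF, each distinct ``gene_id`` yields one record spanning its "gene"
    feature line if present, else the min-start/max-end hull over all of its
    lines.  Duplicate gene_ids with conflicting strand or chromosome raise.
    """
    if format == "bed":
        records = []
        for lineno, line in _iter_data_lines(path):
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise AnnotationError(f"line {lineno}: expected >= 6 BED columns")
            records.append(GeneRecord(
                gene_id=f[3],
                interval=GenomicInterval(normalize_chrom(f[0], chrom_style),
                                         int(f[1]), int(f[2]), f[5]),
            ))
        if not records:
            log.warning("empty gene annotation: %s", path)
        _check_unique([r.gene_id for r in records], "gene_id")
        return records

    if format != "gtf":
        raise ValueError(f"unknown gene annotation format {format!r}")

    spans: dict[str, dict] = {}
    for lineno, line in _iter_data_lines(path):
        chrom, feature, s0, e0, strand, attrs = _parse_gtf_row(line, lineno)
        gene_id = attrs.get("gene_id")
        if gene_id is None:
            continue
        chrom = normalize_chrom(chrom, chrom_style)
        rec = spans.setdefault(gene_id, {
            "chrom": chrom, "strand": strand, "start": s0, "end": e0,
            "gene_line": False, "name": attrs.get("gene_name"),
        })
        if rec["chrom"] != chrom or rec["strand"] != strand:
            raise AnnotationError(
                f"line {lineno}: gene_id {gene_id!r} has conflicting "
                f"chromosome/strand across lines"
            )
        if feature == "gene":
            if rec["gene_line"]:
                rec["start"] = min(rec["start"], s0)
                rec["end"] = max(rec["end"], e0)
            else:
                rec.update(start=s0, end=e0, gene_line=True)
        elif not rec["gene_line"]:
            rec["start"] = min(rec["start"], s0)
            rec["end"] = max(rec["end"], e0)
        if attrs.get("gene_name"):
            rec["name"] = attrs["gene_name"]
    if not spans:
        log.warning("empty gene annotation: %s", path)
    return [
        GeneRecord(gid, GenomicInterval(r["chrom"], r["start"], r["end"], r["strand"]),
                   gene_name=r["name"])
        for gid, r in spans.items()
    ]


def read_herv_annotation(path: str | Path, format: str = "bed",
                         chrom_style: str = "chr") -> list[HervLocus]:
    """Read HERV loci from GTF, BED6 (name = ``locus_id|family``) or a
    RepeatMasker ``.out``-style table.

    Rows whose family field cannot be derived are kept with an empty
    ``family_name`` and superfamily "unclassified" (with a warning); non-LTR
    repeat classes likewise land in "unclassified".
    """
    loci: list[HervLocus] = []

    def _mk(locus_id, chrom, s0, e0, strand, family, lineno):
        if not family:
            log.warning("line %d: HERV locus %s has no family annotation", lineno, locus_id)
        sf = classify_superfamily(family)
        if family and sf == "unclassified" and not family.upper().startswith("LTR"):
            log.warning("line %d: non-LTR element %r supplied as HERV locus", lineno, family)
        loci.append(HervLocus(locus_id,
                              GenomicInterval(normalize_chrom(chrom, chrom_style),
                                              s0, e0, strand),
                              family_name=family, superfamily=sf))

    if format == "bed":
        for lineno, line in _iter_data_lines(path):
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise AnnotationError(f"line {lineno}: expected >= 6 BED columns")
            locus_id, _, family = f[3].partition("|")
            _mk(locus_id, f[0], int(f[1]), int(f[2]), f[5], family, lineno)
    elif format == "gtf":
        for lineno, line in _iter_data_lines(path):
            chrom, _feat, s0, e0, strand, attrs = _parse_gtf_row(line, lineno)
            locus_id = attrs.get("locus_id") or attrs.get("gene_id")
            if locus_id is None:
                raise AnnotationError(f"line {lineno}: no locus_id/gene_id attribute")
            family = attrs.get("family") or attrs.get("repFamily") or ""
            _mk(locus_id, chrom, s0, e0, strand, family, lineno)
    elif format == "rmsk_out":
        for lineno, line in _iter_data_lines(path):
            f = line.split()
            if not f or not f[0].lstrip("-").isdigit():
                continue  # header lines ("SW score ...", "score div ...")
            if len(f) < 11:
                raise AnnotationError(f"line {lineno}: expected >= 11 RepeatMasker columns")
            chrom, qstart, qend = f[4], int(f[5]), int(f[6])
            strand = "-" if f[8] in ("C", "-") else "+"
            rep_name, rep_family = f[9], f[10]
            s0, e0 = gtf_to_internal(qstart, qend)
            locus_id = f"{rep_name}_{normalize_chrom(chrom, chrom_style)}_{s0}_{e0}"
            _mk(locus_id, chrom, s0, e0, strand, rep_family, lineno)
    else:
        raise ValueError(f"unknown HERV annotation format {format!r}")

    if not loci:
        log.warning("empty HERV annotation: %s", path)
    _check_unique([h.locus_id for h in loci], "locus_id")
    return loci


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise AnnotationError(f"duplicate {what}: {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_bed(records: Iterable[GeneRecord | HervLocus], path: str | Path) -> None:
    """Write records as BED6 (HERV name field encodes ``locus_id|family``)."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, HervLocus):
                name = f"{rec.locus_id}|{rec.family_name}"
            else:
                name = rec.gene_id
            iv = rec.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# counts and design
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> dict[str, str]:
    """Read a sample -> condition design from YAML (mapping) or 2-column TSV."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            design = yaml.safe_load(fh)
        if not isinstance(design, Mapping):
            raise CountsError("design YAML must map sample -> condition")
        return {str(k): str(v) for k, v in design.items()}
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise CountsError("design TSV needs two columns: sample, condition")
    return dict(zip(df[0].astype(str), df[1].astype(str)))


def read_counts(path: str | Path, design: Mapping[str, str]) -> CountMatrix:
    """Read a feature x sample count table (TSV/CSV, feature IDs first column),
    restricted and ordered to the samples named in ``design``."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    missing = [s for s in design if s not in df.columns]
    if missing:
        raise CountsError(f"design samples absent from counts file: {missing}")
    df = df[list(design)]
    if not all(pd.api.types.is_numeric_dtype(t) for t in df.dtypes):
        raise CountsError("non-numeric entries in count matrix")
    vals = df.to_numpy()
    if (vals % 1 != 0).any():
        raise CountsError("non-integer entries in count matrix")
    return CountMatrix(df.astype("int64"), dict(design))


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.rename_axis("feature_id").to_csv(path, sep="\t")
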