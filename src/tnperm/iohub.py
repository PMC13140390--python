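"""Readers, writers and the domain types everything else consumes.

All coordinates are held internally as 0-based half-open intervals on the
reference forward strand. The standard dialects differ only at the file
boundary: GFF3 is 1-based inclusive, BED is 0-based half-open. An insertion
``position`` is the first genome base of the transposon junction on the
forward strand regardless of read orientation.
"""

from __future__ import annotations

import io
import logging
import math
import os
from dataclasses import dataclass, field, fields, asdict
from typing import Iterable, Sequence

import gffutils
import pandas as pd

logger = logging.getLogger("tnperm")

STRANDS = ("+", "-")


class ParseError(ValueError):
    """A malformed record in an input file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class GenomeModel:
    """Contig names and lengths of a reference genome."""

    contig_ids: tuple[str, ...]
    contig_lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.contig_ids) != len(self.contig_lengths):
            raise ValueError("contig_ids and contig_lengths differ in length")
        if len(set(self.contig_ids)) != len(self.contig_ids):
            raise ValueError("duplicate contig ids")
        for name, length in zip(self.contig_ids, self.contig_lengths):
            if length <= 0:
                raise ValueError(f"contig {name!r} has non-positive length {length}")
        object.__setattr__(self, "contig_ids", tuple(self.contig_ids))
        object.__setattr__(self, "contig_lengths", tuple(int(x) for x in self.contig_lengths))

    @property
    def total_length(self) -> int:
        return sum(self.contig_lengths)

    def length_of(self, contig: str) -> int:
        try:
            return self.contig_lengths[self.contig_ids.index(contig)]
        except ValueError:
            raise KeyError(f"unknown contig {contig!r}") from None


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval (0-based half-open) with strand and identifiers."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    product: str = ""
    category: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InsertionSite:
    """One transposon junction observation: coordinate, strand, read support."""

    contig: str
    position: int
    strand: str
    read_count: int = 1
    library_id: str = ""

    def __post_init__(self):
        if self.position < 0:
            raise ValueError(f"negative position {self.position}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.read_count < 1:
            raise ValueError(f"read_count must be >= 1, got {self.read_count}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.position, self.strand)


# ---------------------------------------------------------------------------
# GFF3


def _prevalidate_gff(path: str) -> None:
    """Cheap line-level scan so parse errors can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ParseError(
                    f"expected >= 8 tab-separated columns, found {len(cols)}", lineno
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise ParseError(f"non-integer coordinates {cols[3]!r}/{cols[4]!r}", lineno)
            if end < start:
                raise ParseError(f"end {end} < start {start}", lineno)


def _attr_first(feature, *names: str) -> str | None:
    for name in names:
        values = feature.attributes.get(name)
        if values:
            return values[0]
    return None


def read_gff(path: str, feature_types: Sequence[str] = ("gene", "CDS")) -> list[GeneAnnotation]:
    """Read gene annotations from a GFF3 file.

    ``feature_types`` is a preference order: the first type with any features
    present supplies the gene set (a file annotated with both ``gene`` and
    ``CDS`` rows would otherwise yield each locus twice). GFF3 1-based
    inclusive coordinates are converted to 0-based half-open. Output is
    sorted contig-major, then by start.
    """
    _prevalidate_gff(path)
    with open(path) as fh:
        has_records = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_records:
        return []
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneAnnotation] = []
    for ftype in feature_types:
        feats = list(db.features_of_type(ftype))
        if not feats:
            continue
        for i, feat in enumerate(feats):
            gene_id = _attr_first(feat, "ID", "locus_tag", "gene_id", "Name") or f"{ftype}_{i}"
            product = _attr_first(feat, "product", "Note") or ""
            strand = feat.strand if feat.strand in STRANDS else "+"
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    contig=feat.seqid,
                    start=feat.start - 1,  # 1-based inclusive -> 0-based half-open
                    end=feat.end,
                    strand=strand,
                    product=product,
                )
            )
        break
    genes.sort(key=lambda g: (g.contig, g.start, g.end, g.gene_id))
    return genes


def write_gff(genes: Iterable[GeneAnnotation], path: str, source: str = "tnperm") -> str:
    """Write annotations back to GFF3 (internal 0-based -> printed 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.contig}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Genome lengths (FASTA or .fai)


def read_genome_lengths(path: str) -> GenomeModel:
    """Genome contig lengths from a FASTA file or a samtools .fai index."""
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        first = fh.read(1)
        fh.seek(0)
        if first == ">":
            name, n = None, 0
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        names.append(name)
                        lengths.append(n)
                    name, n = line[1:].split()[0], 0
                else:
                    n += len(line)
            if name is not None:
                names.append(name)
                lengths.append(n)
        else:  # .fai: name, length, offset, linebases, linewidth
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                cols = line.split("\t")
                if len(cols) < 2:
                    raise ParseError("expected at least 2 columns in .fai", lineno)
                names.append(cols[0])
                lengths.append(int(cols[1]))
    return GenomeModel(tuple(names), tuple(lengths))


def write_fai(genome: GenomeModel, path: str) -> str:
    with open(path, "w") as fh:
        offset = 0
        for name, length in zip(genome.contig_ids, genome.contig_lengths):
            fh.write(f"{name}\t{length}\t{offset}\t{length}\t{length + 1}\n")
            offset += length + 1
    return path


# ---------------------------------------------------------------------------
# Insertion site tables


def read_sites(path: str, dialect: str = "bed", library_id: str = "") -> list[InsertionSite]:
    """Read insertion records from a BED6 or simple TSV site table.

    ``bed``: 0-based half-open; the score column carries the read count.
    ``tsv``: columns (contig, position0, strand[, read_count[, library_id]]),
    optional header. Missing counts default to 1. Duplicate coordinates are
    kept as-is; collapsing is the sites module's job.
    """
    if dialect not in ("bed", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sites: list[InsertionSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if dialect == "bed":
                if len(cols) < 3:
                    raise ParseError("BED needs >= 3 columns", lineno)
                contig = cols[0]
                try:
                    position = int(cols[1])
                except ValueError:
                    raise ParseError(f"non-integer position {cols[1]!r}", lineno)
                count = 1
                if len(cols) >= 5 and cols[4] not in (".", ""):
                    count = int(float(cols[4]))
                strand = cols[5] if len(cols) >= 6 else "+"
                lib = library_id
            else:
                if lineno == 1 and not _looks_numeric(cols[1] if len(cols) > 1 else ""):
                    continue  # header row
                if len(cols) < 3:
                    raise ParseError("TSV needs >= 3 columns", lineno)
                contig = cols[0]
                try:
                    position = int(cols[1])
                except ValueError:
                    raise ParseError(f"non-integer position {cols[1]!r}", lineno)
                strand = cols[2]
                count = int(float(cols[3])) if len(cols) >= 4 and cols[3] != "" else 1
                lib = cols[4] if len(cols) >= 5 and cols[4] else library_id
            if strand not in STRANDS:
                raise ParseError(f"unknown strand symbol {strand!r}", lineno)
            if position < 0:
                raise ParseError(f"negative position {position}", lineno)
            try:
                sites.append(InsertionSite(contig, position, strand, count, lib))
            except ValueError as exc:
                raise ParseError(str(exc), lineno)
    return sites


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_sites_bed(sites: Iterable[InsertionSite], path: str) -> str:
    """BED6 with the read count in the score column."""
    with open(path, "w") as fh:
        for s in sites:
            name = s.library_id or "."
            fh.write(f"{s.contig}\t{s.position}\t{s.position + 1}\t{name}\t{s.read_count}\t{s.strand}\n")
    return path


def write_sites_tsv(sites: Iterable[InsertionSite], path: str) -> str:
    with open(path, "w") as fh:
        fh.write("contig\tposition\tstrand\tread_count\tlibrary_id\n")
        for s in sites:
            fh.write(f"{s.contig}\t{s.position}\t{s.strand}\t{s.read_count}\t{s.library_id}\n")
    return path


# ---------------------------------------------------------------------------
# Generic record tables


def sig3(x: float) -> str:
    """Format a number at 3 significant figures, e.g. 13962.96 -> '1.40e4'.

    Scientific notation is used for |x| >= 1e4 or 0 < |x| < 1e-3, matching
    how the summary tables print large counts.
    """
    if x == 0:
        return "0.00"
    if isinstance(x, float) and (math.isnan(x) or math.isinf(x)):
        return str(x)
    exponent = math.floor(math.log10(abs(x)))
    mantissa = x / 10 ** exponent
    # guard against rounding pushing the mantissa to 10.00
    if round(mantissa, 2) >= 10:
        mantissa /= 10
        exponent += 1
    if exponent >= 4 or exponent < -3:
        return f"{mantissa:.2f}e{exponent}"
    return f"{round(x, -exponent + 2):.{max(0, 2 - exponent)}f}"


def to_frame(records: Sequence) -> pd.DataFrame:
    """A DataFrame from a list of dataclass records (or pass one through)."""
    if isinstance(records, pd.DataFrame):
        return records.copy()
    if len(records) == 0:
        return pd.DataFrame()
    return pd.DataFrame([asdict(r) for r in records])


def write_table(records, path: str, display_sig3: Sequence[str] = ()) -> str:
    """Write records as TSV: full-precision floats, deterministic columns.

    ``display_sig3`` names float columns that additionally get a
    ``<name>_display`` column at 3 significant figures, mirroring how the
    per-library summary statistics are conventionally printed.
    """
    df = to_frame(records)
    for col in display_sig3:
        if col in df.columns:
            df[f"{col}_display"] = df[col].map(sig3)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
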