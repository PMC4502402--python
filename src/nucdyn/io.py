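"""Readers/writers for the interchange formats and the shared coordinate types.

Every coordinate inside the package is 0-based, half-open (BED-native).
GFF3 and SAM use 1-based conventions; the conversion happens here, at the
file boundary, and nowhere else.  TSS/TTS are *biological* anchors: the
strand-resolved 5' and 3' ends of a gene, so for a "-" strand gene
TSS > TTS on the genomic axis.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "FormatError",
    "ReadRecord",
    "ReadSet",
    "GenomeAnnotation",
    "OccupancyTrack",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed_reads",
    "write_bed_reads",
    "read_sam_reads",
    "read_gff3",
    "write_gff3",
    "read_bedgraph",
    "write_bedgraph",
    "sha256_file",
]

READ_COLUMNS = ["chrom", "start", "end", "strand"]


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class ReadRecord:
    """One mapped read (or collapsed paired-end fragment), half-open interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid read interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"invalid strand {self.strand!r}")


class ReadSet:
    """A set of mapped reads backed by a DataFrame (chrom, start, end, strand).

    ``paired=True`` marks records that are whole fragments (proper pairs
    collapsed to their outer coordinates); downstream read adjustment then
    uses fragment midpoints instead of strand-shifted 5' ends.
    """

    def __init__(self, df: pd.DataFrame, paired: bool = False):
        missing = [c for c in READ_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"read table missing columns: {missing}")
        self.df = df[READ_COLUMNS].reset_index(drop=True)
        self.paired = bool(paired)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ReadSet)
            and self.paired == other.paired
            and self.df.equals(other.df)
        )

    @classmethod
    def from_records(cls, records, paired: bool = False) -> "ReadSet":
        rows = [(r.chrom, r.start, r.end, r.strand) for r in records]
        return cls(pd.DataFrame(rows, columns=READ_COLUMNS), paired=paired)

    @classmethod
    def empty(cls, paired: bool = False) -> "ReadSet":
        return cls(
            pd.DataFrame(
                {
                    "chrom": pd.Series(dtype=str),
                    "start": pd.Series(dtype=np.int64),
                    "end": pd.Series(dtype=np.int64),
                    "strand": pd.Series(dtype=str),
                }
            ),
            paired=paired,
        )

    def records(self):
        for row in self.df.itertuples(index=False):
            yield ReadRecord(row.chrom, int(row.start), int(row.end), row.strand)

    def sorted(self) -> "ReadSet":
        df = self.df.sort_values(
            ["chrom", "start", "end", "strand"], kind="stable"
        ).reset_index(drop=True)
        return ReadSet(df, paired=self.paired)

    def validate_against(self, chrom_sizes: dict[str, int]) -> None:
        for chrom, sub in self.df.groupby("chrom", sort=False):
            if chrom not in chrom_sizes:
                raise FormatError(f"read on unknown chromosome {chrom!r}")
            if (sub["start"] < 0).any() or (sub["end"] > chrom_sizes[chrom]).any():
                raise FormatError(
                    f"read coordinates exceed bounds of {chrom} "
                    f"(length {chrom_sizes[chrom]})"
                )


GENE_COLUMNS = ["chrom", "start", "end", "strand", "tss", "tts"]


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus a gene table indexed by gene id.

    The gene table stores the genomic interval [start, end) and the
    strand-resolved ``tss``/``tts`` anchor positions (0-based).
    """

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame  # index: gene id; columns: GENE_COLUMNS

    def __post_init__(self):
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise FormatError(f"gene table missing columns: {missing}")
        if self.genes.index.duplicated().any():
            dup = self.genes.index[self.genes.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        for row in self.genes.itertuples():
            size = self.chrom_sizes.get(row.chrom)
            if size is None:
                raise FormatError(f"gene {row.Index} on unknown chromosome {row.chrom}")
            if not (0 <= row.start < row.end <= size):
                raise FormatError(
                    f"gene {row.Index} interval [{row.start}, {row.end}) outside "
                    f"{row.chrom} (length {size})"
                )
            if row.strand == "+":
                ok = row.tss < row.tts
            elif row.strand == "-":
                ok = row.tss > row.tts
            else:
                raise FormatError(f"gene {row.Index} has invalid strand {row.strand!r}")
            if not ok:
                raise FormatError(
                    f"gene {row.Index}: TSS/TTS not consistent with strand {row.strand}"
                )

    @classmethod
    def from_intervals(cls, chrom_sizes, rows) -> "GenomeAnnotation":
        """Build from (id, chrom, start, end, strand) rows, deriving TSS/TTS."""
        recs = []
        for gid, chrom, start, end, strand in rows:
            tss, tts = (start, end - 1) if strand == "+" else (end - 1, start)
            recs.append((gid, chrom, start, end, strand, tss, tts))
        genes = pd.DataFrame(
            recs, columns=["gene_id"] + GENE_COLUMNS
        ).set_index("gene_id")
        return cls(dict(chrom_sizes), genes)

    def anchor(self, gene_id: str, which: str) -> tuple[str, int, str]:
        """Return (chrom, position, strand) for anchor 'tss' or 'tts'."""
        try:
            row = self.genes.loc[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r}") from None
        pos = int(row["tss"] if which == "tss" else row["tts"])
        return str(row["chrom"]), pos, str(row["strand"])

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))


@dataclass
class OccupancyTrack:
    """Per-bp occupancy values for every chromosome of one sample."""

    values: dict[str, np.ndarray]
    sample: str = "sample"
    normalized: str = "raw"  # "raw" | "quantile"

    def __post_init__(self):
        for chrom, v in self.values.items():
            arr = np.asarray(v, dtype=float)
            if arr.ndim != 1:
                raise FormatError(f"track for {chrom} is not 1-D")
            if not np.all(np.isfinite(arr)) or (arr < 0).any():
                raise FormatError(f"track for {chrom} has negative/non-finite values")
            self.values[chrom] = arr

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.values.items()}

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.values])

    def genome_mean(self) -> float:
        return float(self.concatenated().mean())

    def genome_sd(self) -> float:
        # population SD (ddof=0) over every base pair of the genome
        return float(self.concatenated().std(ddof=0))


# ---------------------------------------------------------------------------
# chromosome sizes
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: malformed chrom-sizes line {lineno}")
            chrom, size = parts[0], parts[1]
            try:
                sizes[chrom] = int(size)
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer size on line {lineno}"
                ) from None
    return sizes


def write_chrom_sizes(chrom_sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# BED reads
# ---------------------------------------------------------------------------

def read_bed_reads(path, chrom_sizes=None, paired: bool = False) -> ReadSet:
    """Parse a 6-column BED file of mapped reads.

    Columns beyond the sixth are ignored; fewer than six is an error (strand
    is required).  Malformed lines are reported with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}: line {lineno}: expected >= 6 BED columns")
            chrom, start, end, _name, _score, strand = parts[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if not (0 <= start_i < end_i):
                raise FormatError(f"{path}: line {lineno}: invalid interval")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}: line {lineno}: invalid strand {strand!r}")
            rows.append((chrom, start_i, end_i, strand))
    if rows:
        df = pd.DataFrame(rows, columns=READ_COLUMNS)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        rs = ReadSet(df, paired=paired)
    else:
        rs = ReadSet.empty(paired=paired)
    if chrom_sizes is not None:
        rs.validate_against(chrom_sizes)
    return rs


def write_bed_reads(reads: ReadSet, path) -> None:
    """Write reads as 6-column BED (name '.', score 0)."""
    with open(path, "w") as fh:
        for row in reads.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t.\t0\t{row.strand}\n")


# ---------------------------------------------------------------------------
# SAM reads
# ---------------------------------------------------------------------------

def read_sam_reads(path, chrom_sizes=None) -> tuple[ReadSet, dict]:
    """Parse mapped primary records from a SAM file.

    Proper pairs are collapsed to a single fragment record spanning the mate
    outer coordinates (recorded once, from read 1, with strand "+"); all
    other mapped primary reads are kept as single-end records.  Returns the
    read set and a report with the skipped-record counts.
    """
    singles = []
    fragments = []
    skipped = {"unmapped": 0, "secondary_or_supplementary": 0, "pair_seen_twice": 0}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                skipped["unmapped"] += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                skipped["secondary_or_supplementary"] += 1
                continue
            chrom = aln.reference_name
            if aln.is_paired and aln.is_proper_pair and aln.template_length != 0:
                if aln.template_length < 0:
                    skipped["pair_seen_twice"] += 1
                    continue  # counted from the leftmost mate only
                start = aln.reference_start
                end = start + aln.template_length
                fragments.append((chrom, start, end, "+"))
            else:
                strand = "-" if aln.is_reverse else "+"
                singles.append(
                    (chrom, aln.reference_start, aln.reference_end, strand)
                )
    rows = fragments if fragments else singles
    paired = bool(fragments)
    if fragments and singles:
        # mixed input: keep fragments plus orphan singles as fragments' dialect
        rows = fragments + singles
    rs = (
        ReadSet(pd.DataFrame(rows, columns=READ_COLUMNS), paired=paired)
        if rows
        else ReadSet.empty()
    )
    if chrom_sizes is not None:
        rs.validate_against(chrom_sizes)
    return rs, skipped


# ---------------------------------------------------------------------------
# GFF3 annotation
# ---------------------------------------------------------------------------

def read_gff3(path, chrom_sizes=None, feature: str = "gene") -> GenomeAnnotation:
    """Read gene-level features from GFF3 into a GenomeAnnotation.

    Only rows whose type equals ``feature`` are used.  1-based inclusive
    GFF3 coordinates become the internal 0-based half-open convention.
    Chromosome sizes come from ``##sequence-region`` pragmas unless given.
    """
    sizes: dict[str, int] = dict(chrom_sizes) if chrom_sizes else {}
    rows = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    sizes.setdefault(parts[1], int(parts[3]))
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != feature:
                continue
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path}: line {lineno}: gene feature with missing/invalid strand"
                )
            gid = None
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    gid = item[3:]
                    break
            if gid is None:
                raise FormatError(f"{path}: line {lineno}: gene feature without ID")
            if gid in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate gene id {gid!r}")
            seen.add(gid)
            start0 = int(start) - 1  # 1-based inclusive -> 0-based half-open
            end0 = int(end)
            rows.append((gid, chrom, start0, end0, strand))
    if not sizes:
        # fall back to covering intervals so validation can proceed
        for _gid, chrom, _s, e, _strand in rows:
            sizes[chrom] = max(sizes.get(chrom, 0), e)
    return GenomeAnnotation.from_intervals(sizes, rows)


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, size in annotation.chrom_sizes.items():
            fh.write(f"##sequence-region {chrom} 1 {size}\n")
        for row in annotation.genes.itertuples():
            fh.write(
                f"{row.chrom}\tnucdyn\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.Index}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph occupancy tracks
# ---------------------------------------------------------------------------

def write_bedgraph(track: OccupancyTrack, path) -> None:
    """Write a run-length-encoded bedGraph covering every position.

    Zero-valued runs are written explicitly so that reading the file back
    reproduces the full-length vectors exactly.  Values are written with
    ``repr`` so the float round-trips bit-identically.
    """
    with open(path, "w") as fh:
        for chrom, values in track.values.items():
            if len(values) == 0:
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(values)]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{float(values[s])!r}\n")


def read_bedgraph(path, chrom_sizes: dict[str, int], sample: str = "sample",
                  normalized: str = "raw") -> OccupancyTrack:
    values = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 columns")
            chrom, start, end, value = parts
            if chrom not in values:
                raise FormatError(f"{path}: line {lineno}: unknown chromosome {chrom}")
            s, e = int(start), int(end)
            if not (0 <= s < e <= len(values[chrom])):
                raise FormatError(f"{path}: line {lineno}: interval out of bounds")
            if covered[chrom][s:e].any():
                raise FormatError(f"{path}: line {lineno}: overlapping intervals")
            covered[chrom][s:e] = True
            values[chrom][s:e] = float(value)
    return OccupancyTrack(values, sample=sample, normalized=normalized)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
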