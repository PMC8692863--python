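"""Transcript models as ordered exon-coordinate tables, plus interval arithmetic.

Coordinate conventions
----------------------
External I/O is 1-based inclusive throughout. Exon tables print coordinates
in transcript 5'->3' order, so a reverse-strand exon appears with its first
printed coordinate greater than the second; strand is inferred from that
direction. Internally every interval is normalized to ``start <= end`` and
the strand is carried explicitly. BED12 (0-based half-open) is converted on
read and write.

The packaged reference table covers the five KCNJ6/DSCR4 isoforms around the
highly restricted Down syndrome critical region (HR-DSCR) on 21q22.13, as
annotated on GRCh38, verbatim as published — including a first-exon
coordinate pair for KCNJ6-201 that overlaps the HR-DSCR; the overlap
classifier surfaces rather than hides that discrepancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_CHROM = "chr21"

TABLE_COLUMNS = ["transcript_id", "gene", "exon_label", "coord_a", "coord_b"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval, 1-based, normalized so start <= end."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(
                f"interval not normalized: start {self.start} > end {self.end}"
            )

    @classmethod
    def from_printed(cls, chrom: str, a: int, b: int, strand: str | None = None) -> "GenomicInterval":
        """Build from a printed coordinate pair; descending order implies '-'.

        An explicit ``strand`` overrides inference (needed for single-base exons).
        """
        if strand is None:
            strand = "-" if a > b else "+"
        lo, hi = (a, b) if a <= b else (b, a)
        return cls(chrom, lo, hi, strand)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end


def exon_length(iv: GenomicInterval) -> int:
    """Length of an exon (or any interval) in nucleotides: end - start + 1."""
    return iv.length


@dataclass(frozen=True)
class NamedRegion:
    name: str
    interval: GenomicInterval


#: The highly restricted Down syndrome critical region on distal 21q22.13
#: (GRCh38), ~34 kbp, triplicated in all partial-trisomy-21 cases with a DS
#: diagnosis.
HR_DSCR = NamedRegion("HR-DSCR", GenomicInterval(DEFAULT_CHROM, 37_929_229, 37_963_130))


class OverlapRelation(str, Enum):
    """Exhaustive, mutually exclusive relation of a feature to a named region."""

    DISJOINT = "disjoint"
    FEATURE_WITHIN_REGION = "feature_within_region"
    FEATURE_CONTAINS_REGION = "feature_contains_region"
    PARTIAL_OVERLAP = "partial_overlap"


def classify_overlap(feature: GenomicInterval, region: NamedRegion) -> OverlapRelation:
    """Classify how ``feature`` sits relative to ``region``.

    Equal intervals report ``FEATURE_WITHIN_REGION``. Features on a different
    chromosome are reported disjoint with a logged warning.
    """
    riv = region.interval
    if feature.chrom != riv.chrom:
        logger.warning(
            "classify_overlap: feature on %s vs region %s on %s; reporting disjoint",
            feature.chrom, region.name, riv.chrom,
        )
        return OverlapRelation.DISJOINT
    if riv.start <= feature.start and feature.end <= riv.end:
        return OverlapRelation.FEATURE_WITHIN_REGION
    if feature.start <= riv.start and riv.end <= feature.end:
        return OverlapRelation.FEATURE_CONTAINS_REGION
    if feature.end < riv.start or riv.end < feature.start:
        return OverlapRelation.DISJOINT
    return OverlapRelation.PARTIAL_OVERLAP


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: ordered exons in transcript 5'->3' order, with labels.

    For strand '-', genomic start coordinates strictly decrease along the
    exon list; for '+' they strictly increase. Exons never overlap.
    """

    transcript_id: str
    gene: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    exon_labels: tuple[str, ...]

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        if len(self.exons) != len(self.exon_labels):
            raise ValueError(f"{self.transcript_id}: exon/label count mismatch")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"{self.transcript_id}: exons on multiple chromosomes {chroms}")
        for e in self.exons:
            if e.strand != self.strand:
                raise ValueError(f"{self.transcript_id}: exon strand differs from transcript strand")
        ordered = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end >= b.start:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {a.start}-{a.end} and {b.start}-{b.end}"
                )
        starts = [e.start for e in self.exons]
        if self.strand == "+":
            if any(a >= b for a, b in zip(starts, starts[1:])):
                raise ValueError(f"{self.transcript_id}: '+' exons not in ascending transcript order")
        else:
            if any(a <= b for a, b in zip(starts, starts[1:])):
                raise ValueError(f"{self.transcript_id}: '-' exons not in descending transcript order")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        """Outermost genomic interval covered by the transcript."""
        return GenomicInterval(
            self.chrom,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)


def introns_of(t: TranscriptModel) -> list[GenomicInterval]:
    """Intervals strictly between consecutive exons, in transcript order.

    A single-exon transcript yields an empty list. Abutting exons (no gap)
    are a validation error rather than a silent merge.
    """
    introns = []
    for i, (up, down) in enumerate(zip(t.exons, t.exons[1:]), start=1):
        if t.strand == "+":
            lo, hi = up.end + 1, down.start - 1
        else:
            lo, hi = down.end + 1, up.start - 1
        if lo > hi:
            raise ValueError(
                f"{t.transcript_id}: zero-length intron between exons "
                f"{t.exon_labels[i - 1]} and {t.exon_labels[i]}"
            )
        introns.append(GenomicInterval(t.chrom, lo, hi, t.strand))
    return introns


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

def parse_transcript_table(rows, chrom: str = DEFAULT_CHROM) -> list[TranscriptModel]:
    """Parse an exon-coordinate table into transcript models.

    ``rows`` is a DataFrame with columns transcript_id, gene, exon_label,
    coord_a, coord_b, or an iterable of such 5-tuples. Printed coordinate
    order encodes direction: a transcript whose pairs descend is on '-'.
    Mixing ascending and descending pairs within one transcript is an error.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.loc[:, TABLE_COLUMNS].copy()
    else:
        df = pd.DataFrame(list(rows), columns=TABLE_COLUMNS)
    df["coord_a"] = df["coord_a"].astype(int)
    df["coord_b"] = df["coord_b"].astype(int)

    models = []
    for tid, grp in df.groupby("transcript_id", sort=False):
        genes = grp["gene"].unique()
        if len(genes) != 1:
            raise ValueError(f"{tid}: multiple gene labels {list(genes)}")
        dirs = {1 if a < b else -1 for a, b in zip(grp["coord_a"], grp["coord_b"]) if a != b}
        if len(dirs) > 1:
            raise ValueError(f"{tid}: mixed coordinate directions within one transcript")
        if dirs:
            strand = "+" if dirs == {1} else "-"
        elif len(grp) > 1:
            # all single-base exons: fall back to inter-exon order
            strand = "+" if grp["coord_a"].iloc[0] < grp["coord_a"].iloc[1] else "-"
        else:
            strand = "+"
        exons = tuple(
            GenomicInterval.from_printed(chrom, a, b, strand)
            for a, b in zip(grp["coord_a"], grp["coord_b"])
        )
        models.append(
            TranscriptModel(
                transcript_id=str(tid),
                gene=str(genes[0]),
                strand=strand,
                exons=exons,
                exon_labels=tuple(str(x) for x in grp["exon_label"]),
            )
        )
    return models


def models_to_table(models: Sequence[TranscriptModel]) -> pd.DataFrame:
    """Serialize models back to the printed-coordinate TSV dialect (inverse of
    :func:`parse_transcript_table` up to column dtypes)."""
    recs = []
    for t in models:
        for label, e in zip(t.exon_labels, t.exons):
            a, b = (e.start, e.end) if t.strand == "+" else (e.end, e.start)
            recs.append((t.transcript_id, t.gene, label, a, b))
    return pd.DataFrame(recs, columns=TABLE_COLUMNS)


def read_transcript_tsv(path: str | Path, chrom: str = DEFAULT_CHROM) -> list[TranscriptModel]:
    return parse_transcript_table(pd.read_csv(path, sep="\t"), chrom=chrom)


def write_transcript_tsv(models: Sequence[TranscriptModel], path: str | Path) -> None:
    models_to_table(models).to_csv(path, sep="\t", index=False)


def load_reference_transcripts() -> list[TranscriptModel]:
    """The packaged KCNJ6/DSCR4 exon-coordinate table (GRCh38, chr21)."""
    with resources.files("splicequery.data").joinpath("table1_exons.tsv").open() as fh:
        return parse_transcript_table(pd.read_csv(fh, sep="\t"))


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------

def write_bed12(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write models as BED12 (0-based half-open; blocks in ascending genomic
    order as the format requires). The name field carries transcript_id|gene."""
    with Path(path).open("w") as fh:
        for t in models:
            exons = sorted(t.exons, key=lambda e: e.start)
            chrom_start = exons[0].start - 1
            chrom_end = exons[-1].end
            sizes = ",".join(str(e.length) for e in exons) + ","
            starts = ",".join(str(e.start - 1 - chrom_start) for e in exons) + ","
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(chrom_start),
                        str(chrom_end),
                        f"{t.transcript_id}|{t.gene}",
                        "0",
                        t.strand,
                        str(chrom_start),
                        str(chrom_start),
                        "0",
                        str(len(exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    """Read BED12 into transcript models; exon labels are generated E1..En in
    transcript 5'->3' order (blocks are reversed for '-' strand records)."""
    models = []
    with Path(path).open() as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: BED12 requires 12 columns, got {len(f)}")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{ln}: invalid strand {strand!r}")
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if not (len(sizes) == len(offsets) == n_blocks):
                raise ValueError(f"{path}:{ln}: block count mismatch")
            exons = [
                GenomicInterval(chrom, chrom_start + off + 1, chrom_start + off + size, strand)
                for off, size in zip(offsets, sizes)
            ]
            if strand == "-":
                exons = exons[::-1]
            tid, _, gene = name.partition("|")
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene=gene or tid.split("-")[0],
                    strand=strand,
                    exons=tuple(exons),
                    exon_labels=tuple(f"E{i + 1}" for i in range(len(exons))),
                )
            )
    return models
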