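"""Sequence stores: uniform 1-based inclusive access to genomic sequence.

All coordinates in this package are 1-based inclusive on the forward
strand; strand handling (reverse complementation) is done by callers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Protocol, runtime_checkable

from Bio.Seq import reverse_complement as _bio_revcomp


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN alphabet)."""
    return str(_bio_revcomp(seq))


@runtime_checkable
class SequenceStore(Protocol):
    """Anything that can serve forward-strand sequence by genomic coordinates."""

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the forward-strand sequence of chrom[start..end], 1-based inclusive."""
        ...

    def __contains__(self, chrom: str) -> bool: ...


class InMemoryGenome:
    """A genome held in memory, optionally offset so that a short synthetic
    sequence is addressable by real assembly-style coordinates.

    ``offset`` is the 1-based genomic coordinate of the first stored base.
    """

    def __init__(self, sequences: dict[str, str], offsets: dict[str, int] | None = None):
        self._seqs = {c: s.upper() for c, s in sequences.items()}
        self._offsets = dict(offsets or {})
        for chrom in self._seqs:
            self._offsets.setdefault(chrom, 1)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def chrom_span(self, chrom: str) -> tuple[int, int]:
        """(first, last) addressable 1-based coordinate of a chromosome."""
        off = self._offsets[chrom]
        return off, off + len(self._seqs[chrom]) - 1

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start > end:
            raise ValueError(f"fetch start {start} > end {end}")
        lo, hi = self.chrom_span(chrom)
        if start < lo or end > hi:
            raise IndexError(
                f"{chrom}:{start}-{end} outside stored span {chrom}:{lo}-{hi}"
            )
        off = self._offsets[chrom]
        return self._seqs[chrom][start - off : end - off + 1]

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        """Write the store as FASTA; headers carry the coordinate offset so the
        file round-trips through :func:`read_offset_fasta`."""
        path = Path(path)
        with path.open("w") as fh:
            for chrom, seq in self._seqs.items():
                fh.write(f">{chrom} offset={self._offsets[chrom]}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def read_offset_fasta(path: str | Path) -> InMemoryGenome:
    """Read a FASTA written by :meth:`InMemoryGenome.to_fasta`, honouring the
    ``offset=`` tag in headers (defaulting to 1)."""
    seqs: dict[str, str] = {}
    offsets: dict[str, int] = {}
    name = None
    chunks: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                fields = line[1:].split()
                name = fields[0]
                offsets[name] = 1
                for tag in fields[1:]:
                    if tag.startswith("offset="):
                        offsets[name] = int(tag[len("offset=") :])
                chunks = []
            else:
                chunks.append(line.strip())
    if name is not None:
        seqs[name] = "".join(chunks)
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return InMemoryGenome(seqs, offsets)


class FastaGenome:
    """pyfaidx-backed store for on-disk reference FASTA files."""

    def __init__(self, path: str | Path):
        from pyfaidx import Fasta

        self._fa = Fasta(str(path), sequence_always_upper=True)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fa

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if start > end:
            raise ValueError(f"fetch start {start} > end {end}")
        if start < 1 or end > len(self._fa[chrom]):
            raise IndexError(f"{chrom}:{start}-{end} outside sequence bounds")
        return str(self._fa[chrom][start - 1 : end])
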