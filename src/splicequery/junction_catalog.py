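"""Exon-junction queries: construction, sequence extraction, and sharing.

A junction is identified purely by coordinates — (chrom, strand, donor,
acceptor) — where the donor is the last exonic base of the upstream exon in
transcript order and the acceptor the first exonic base of the downstream
exon. On the reverse strand the donor is therefore the *lowest* genomic
coordinate of the upstream exon's normalized interval. Coordinate identity
makes sharing decidable without any genome sequence: two isoforms share a
junction exactly when the same splice event appears in both, which is how
ambiguous (asterisked) read support arises downstream.

The query sequence for a junction is spliced and transcript-oriented: the
last ``flank`` transcript-5' bases of the upstream exon followed by the
first ``flank`` bases of the downstream exon (default 25+25 = 50 bp).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .genome import SequenceStore, revcomp
from .transcript_models import GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 25

#: (chrom, strand, donor, acceptor)
JunctionIdentity = tuple[str, str, int, int]


@dataclass(frozen=True)
class Junction:
    """A splice event. Equality and hashing use coordinate identity only;
    ``members`` records every (transcript_id, upstream_label, downstream_label)
    that produces this event, and the exon intervals of the first member are
    kept for sequence extraction."""

    chrom: str
    strand: str
    donor: int
    acceptor: int
    members: tuple[tuple[str, str, str], ...] = field(compare=False)
    upstream_exon: GenomicInterval = field(compare=False)
    downstream_exon: GenomicInterval = field(compare=False)

    @property
    def identity(self) -> JunctionIdentity:
        return (self.chrom, self.strand, self.donor, self.acceptor)

    @property
    def identity_str(self) -> str:
        return f"{self.chrom}:{self.strand}:{self.donor}:{self.acceptor}"

    @property
    def transcript_ids(self) -> set[str]:
        return {m[0] for m in self.members}

    @property
    def label(self) -> str:
        """Exon-pair label of the first member, e.g. 'E2-E3'."""
        _, up, down = self.members[0]
        return f"{up}-{down}"

    def merged_with(self, other: "Junction") -> "Junction":
        if self.identity != other.identity:
            raise ValueError("cannot merge junctions with different identities")
        extra = tuple(m for m in other.members if m not in self.members)
        return Junction(
            self.chrom, self.strand, self.donor, self.acceptor,
            members=self.members + extra,
            upstream_exon=self.upstream_exon,
            downstream_exon=self.downstream_exon,
        )


def parse_identity_str(s: str) -> JunctionIdentity:
    chrom, strand, donor, acceptor = s.rsplit(":", 3)
    return (chrom, strand, int(donor), int(acceptor))


def build_junctions(t: TranscriptModel) -> list[Junction]:
    """All exon-exon junctions of one transcript, in transcript order.

    Single-exon transcripts have none. Strand-aware: for '-' the donor is the
    normalized-start (lowest) coordinate of the upstream exon, the acceptor
    the normalized-end (highest) coordinate of the downstream exon.
    """
    junctions = []
    for i in range(t.n_exons - 1):
        up, down = t.exons[i], t.exons[i + 1]
        if t.strand == "+":
            donor, acceptor = up.end, down.start
        else:
            donor, acceptor = up.start, down.end
        junctions.append(
            Junction(
                chrom=t.chrom,
                strand=t.strand,
                donor=donor,
                acceptor=acceptor,
                members=((t.transcript_id, t.exon_labels[i], t.exon_labels[i + 1]),),
                upstream_exon=up,
                downstream_exon=down,
            )
        )
    return junctions


@dataclass(frozen=True)
class JunctionQuery:
    """The spliced query sequence around one junction.

    ``left_flank``/``right_flank`` are the realized flank lengths after any
    truncation against short exons; the junction point sits exactly after
    position ``left_flank`` of ``sequence`` (1-based).
    """

    junction: Junction
    left_flank: int
    right_flank: int
    sequence: str
    truncated: bool = False

    @property
    def query_id(self) -> str:
        return self.junction.identity_str

    def __len__(self) -> int:
        return len(self.sequence)


def junction_query_sequence(
    j: Junction,
    genome: SequenceStore,
    flank: int = DEFAULT_FLANK,
    right_flank: int | None = None,
) -> JunctionQuery:
    """Extract the transcript-oriented spliced query around a junction.

    Flanks longer than the source exon are truncated (with a logged warning)
    rather than failing — real terminal exons can be short. For '-' strand
    junctions the emitted sequence is the reverse complement of the
    forward-strand extraction, so queries always read transcript 5'->3'.
    """
    if flank < 1 or (right_flank is not None and right_flank < 1):
        raise ValueError("flank must be >= 1")
    lf_req = flank
    rf_req = flank if right_flank is None else right_flank
    lf = min(lf_req, j.upstream_exon.length)
    rf = min(rf_req, j.downstream_exon.length)
    truncated = (lf < lf_req) or (rf < rf_req)
    if truncated:
        logger.warning(
            "junction %s (%s): flank truncated to %d+%d by short exon",
            j.identity_str, j.label, lf, rf,
        )
    if j.strand == "+":
        left = genome.fetch(j.chrom, j.donor - lf + 1, j.donor)
        right = genome.fetch(j.chrom, j.acceptor, j.acceptor + rf - 1)
        seq = left + right
    else:
        # forward-strand pieces, then flip into transcript orientation
        left_fwd = genome.fetch(j.chrom, j.donor, j.donor + lf - 1)
        right_fwd = genome.fetch(j.chrom, j.acceptor - rf + 1, j.acceptor)
        seq = revcomp(right_fwd + left_fwd)
    return JunctionQuery(junction=j, left_flank=lf, right_flank=rf,
                         sequence=seq.upper(), truncated=truncated)


def transcript_sequence(t: TranscriptModel, genome: SequenceStore) -> str:
    """Fully spliced transcript sequence, 5'->3' (reverse complemented per
    exon for '-' strand models)."""
    parts = []
    for e in t.exons:
        s = genome.fetch(e.chrom, e.start, e.end)
        parts.append(s if t.strand == "+" else revcomp(s))
    return "".join(parts).upper()


# ---------------------------------------------------------------------------
# Sharing
# ---------------------------------------------------------------------------

def shared_junctions(
    catalogs: Iterable[Sequence[Junction]],
) -> dict[JunctionIdentity, set[str]]:
    """Merge per-transcript junction lists by identity; map each identity to
    the set of member transcript ids."""
    sharing: dict[JunctionIdentity, set[str]] = {}
    for catalog in catalogs:
        for j in catalog:
            sharing.setdefault(j.identity, set()).update(j.transcript_ids)
    return sharing


def count_shared_by_all(
    sharing: dict[JunctionIdentity, set[str]], transcript_ids: Iterable[str]
) -> int:
    """Number of junction identities present in *every* listed transcript."""
    wanted = set(transcript_ids)
    return sum(1 for members in sharing.values() if wanted <= members)


def count_shared_between(
    sharing: dict[JunctionIdentity, set[str]],
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> int:
    """Number of junction identities with at least one member in each group."""
    a, b = set(group_a), set(group_b)
    return sum(1 for members in sharing.values() if (members & a) and (members & b))


class JunctionCatalog:
    """Merged, deterministically ordered junction set over a transcript panel."""

    def __init__(self, models: Sequence[TranscriptModel]):
        self.models = list(models)
        merged: dict[JunctionIdentity, Junction] = {}
        order: list[JunctionIdentity] = []
        for t in self.models:
            for j in build_junctions(t):
                if j.identity in merged:
                    merged[j.identity] = merged[j.identity].merged_with(j)
                else:
                    merged[j.identity] = j
                    order.append(j.identity)
        self._by_identity = merged
        self._order = order

    @property
    def junctions(self) -> list[Junction]:
        return [self._by_identity[i] for i in self._order]

    @property
    def identities(self) -> list[JunctionIdentity]:
        return list(self._order)

    def __len__(self) -> int:
        return len(self._order)

    def __contains__(self, identity: JunctionIdentity) -> bool:
        return identity in self._by_identity

    def __getitem__(self, identity: JunctionIdentity) -> Junction:
        return self._by_identity[identity]

    @property
    def sharing(self) -> dict[JunctionIdentity, set[str]]:
        return {i: self._by_identity[i].transcript_ids for i in self._order}

    def shared_by_all(self, transcript_ids: Iterable[str]) -> int:
        return count_shared_by_all(self.sharing, transcript_ids)

    def ambiguous_identities(self) -> set[JunctionIdentity]:
        """Identities belonging to more than one transcript (the asterisk set)."""
        return {i for i, members in self.sharing.items() if len(members) > 1}

    def transcript_junctions(self, transcript_id: str) -> list[Junction]:
        """A transcript's junctions, in transcript order, as merged objects."""
        for t in self.models:
            if t.transcript_id == transcript_id:
                return [self._by_identity[j.identity] for j in build_junctions(t)]
        raise KeyError(f"unknown transcript {transcript_id!r}")

    def queries(self, genome: SequenceStore, flank: int = DEFAULT_FLANK) -> list[JunctionQuery]:
        return [junction_query_sequence(j, genome, flank=flank) for j in self.junctions]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_query_fasta(queries: Sequence[JunctionQuery], path: str | Path) -> None:
    """FASTA of junction queries. Headers: identity string, then a
    ``members=`` tag listing transcript_id|uplabel-downlabel pairs."""
    with Path(path).open("w") as fh:
        for q in queries:
            members = ",".join(f"{tid}|{up}-{down}" for tid, up, down in q.junction.members)
            fh.write(f">{q.query_id} members={members} flanks={q.left_flank}+{q.right_flank}\n")
            fh.write(q.sequence + "\n")


def read_query_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a query FASTA back as (query_id, sequence) pairs."""
    out: list[tuple[str, str]] = []
    name, chunks = None, []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out.append((name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.strip())
    if name is not None:
        out.append((name, "".join(chunks)))
    return out


def write_sharing_tsv(catalog: JunctionCatalog, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("junction\tlabel\tn_transcripts\ttranscripts\n")
        for j in catalog.junctions:
            tids = ",".join(sorted(j.transcript_ids))
            fh.write(f"{j.identity_str}\t{j.label}\t{len(j.transcript_ids)}\t{tids}\n")
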