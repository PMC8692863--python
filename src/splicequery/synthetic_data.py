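"""Synthetic surrogate genome and RNA-seq read sets with ground truth.

The real study aligned public SRA runs from a human tissue panel against
junction queries; at desk scale that is replaced by (a) an i.i.d. random
surrogate genome addressable by the real GRCh38-style chr21 coordinates of
the packaged transcript table, and (b) configurable read scenarios that
plant junction-spanning reads for a chosen expressed-isoform set, plus
exon-interior reads and intergenic background reads, with an i.i.d.
per-base substitution error rate. Everything is deterministic per seed and
every emitted read is labelled in a :class:`GroundTruth`.

Because the surrogate genome is uniform random, exon/intron sequence is
statistically independent of the junction queries, so planted
junction-spanning reads are the only reads expected to pass the
cover/identity filter.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import InMemoryGenome, revcomp
from .junction_catalog import (
    DEFAULT_FLANK,
    JunctionIdentity,
    build_junctions,
    transcript_sequence,
)
from .transcript_models import (
    DEFAULT_CHROM,
    GenomicInterval,
    TranscriptModel,
    load_reference_transcripts,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Surrogate span over distal 21q22.13 covering every exon of the packaged
#: transcript table with margin.
DEFAULT_SPAN = GenomicInterval(DEFAULT_CHROM, 37_600_000, 38_130_000)


@dataclass(frozen=True)
class SimScenario:
    """One simulated sample.

    Defaults are the package's standing study conditions: 100-nt reads,
    10 reads planted per junction of each expressed isoform, 5 exon-interior
    reads per expressed isoform, 50 intergenic background reads, and a
    0.2% per-base substitution error rate.
    """

    sample_name: str
    expressed: frozenset[str] = frozenset()
    junction_depth: int = 10
    exon_depth: int = 5
    background_reads: int = 50
    read_length: int = 100
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if min(self.junction_depth, self.exon_depth, self.background_reads) < 0:
            raise ValueError("depths must be >= 0")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        object.__setattr__(self, "expressed", frozenset(self.expressed))


#: Expressed-isoform sets per preset sample, mirroring the qualitative
#: presence/absence pattern of the published tissue panel: cerebral tissue
#: expresses KCNJ6-201, placenta the DSCR4-201 isoform (whose first junction
#: is shared with KCNJ6-202 and the other DSCR4 isoforms), testis both
#: DSCR4-201 and DSCR4-202; heart is a negative control.
PRESET_EXPRESSED: dict[str, frozenset[str]] = {
    "brain": frozenset({"KCNJ6-201"}),
    "placenta": frozenset({"DSCR4-201"}),
    "testis": frozenset({"DSCR4-201", "DSCR4-202"}),
    "heart": frozenset(),
}


def preset_scenario(name: str, seed: int = 0, **overrides) -> SimScenario:
    """A preset tissue scenario; keyword overrides adjust depths/rates."""
    if name not in PRESET_EXPRESSED:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESET_EXPRESSED)}")
    return SimScenario(
        sample_name=name, expressed=PRESET_EXPRESSED[name], seed=seed, **overrides
    )


@dataclass
class GroundTruth:
    """What the generator planted: per-junction planted read counts and a
    label for every emitted read id."""

    sample_name: str
    planted: Counter = field(default_factory=Counter)  # JunctionIdentity -> count
    read_labels: dict[str, str] = field(default_factory=dict)  # read_id -> label

    def n_reads(self, category: str | None = None) -> int:
        if category is None:
            return len(self.read_labels)
        return sum(1 for v in self.read_labels.values() if v.split(":")[0] == category)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(rid, lab) for rid, lab in self.read_labels.items()],
            columns=["read_id", "label"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def simulate_genome(
    span: GenomicInterval = DEFAULT_SPAN,
    seed: int = 0,
    models: Sequence[TranscriptModel] | None = None,
) -> InMemoryGenome:
    """Uniform random A/C/G/T sequence addressable by real coordinates.

    ``models`` (default: the packaged transcript table) must fall entirely
    within ``span``; a span that does not cover every exon is rejected.
    """
    if models is None:
        models = load_reference_transcripts()
    for t in models:
        s = t.span
        if s.chrom == span.chrom and (s.start < span.start or s.end > span.end):
            raise ValueError(
                f"span {span.chrom}:{span.start}-{span.end} does not cover "
                f"{t.transcript_id} ({s.start}-{s.end})"
            )
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=span.length).tobytes().decode("ascii")
    return InMemoryGenome({span.chrom: seq}, {span.chrom: span.start})


def _junction_positions(t: TranscriptModel) -> list[int]:
    """Spliced-transcript coordinate (bases upstream) of each junction."""
    pos, out = 0, []
    for e in t.exons[:-1]:
        pos += e.length
        out.append(pos)
    return out


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def simulate_reads(
    scn: SimScenario,
    models: Sequence[TranscriptModel],
    genome: InMemoryGenome,
    flank: int = DEFAULT_FLANK,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Emit labelled reads for one scenario.

    Junction reads are placed so their spliced footprint extends at least
    ``flank + 5`` bases into each side of the target junction — at zero
    error rate such a read is guaranteed to pass the default filter.
    Exon-interior reads are drawn from single exons at least one read long;
    background reads from uniform positions of the surrogate genome. Read
    orientation is randomized. Deterministic per (scenario, seed).
    """
    if scn.read_length < 2 * flank + 10:
        raise ValueError(
            f"read_length {scn.read_length} < 2*flank+10 = {2 * flank + 10}: "
            "cannot guarantee junction-spanning geometry"
        )
    by_id = {t.transcript_id: t for t in models}
    unknown = scn.expressed - set(by_id)
    if unknown:
        raise ValueError(f"expressed transcripts not in models: {sorted(unknown)}")

    rng = np.random.default_rng(scn.seed)
    L = scn.read_length
    margin = flank + 5
    reads: list[tuple[str, str]] = []
    truth = GroundTruth(sample_name=scn.sample_name)

    def emit(rid: str, seq: str, label: str) -> None:
        seq = _apply_errors(seq, rng, scn.error_rate)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append((rid, seq))
        truth.read_labels[rid] = label

    for tid in sorted(scn.expressed):
        t = by_id[tid]
        tseq = transcript_sequence(t, genome)
        tlen = len(tseq)
        junctions = build_junctions(t)
        for j, pos in zip(junctions, _junction_positions(t)):
            lo = max(margin, L - (tlen - pos))
            hi = min(L - margin, pos)
            if lo > hi:
                raise ValueError(
                    f"{tid} {j.label}: cannot span junction with read_length {L}"
                )
            for k in range(scn.junction_depth):
                left = int(rng.integers(lo, hi + 1))
                frag = tseq[pos - left : pos - left + L]
                rid = f"{scn.sample_name}|junc|{tid}|{j.label}|{k}"
                emit(rid, frag, f"junction:{tid}:{j.label}")
                truth.planted[j.identity] += 1
        eligible = [
            (lab, e) for lab, e in zip(t.exon_labels, t.exons) if e.length >= L
        ]
        if eligible and scn.exon_depth > 0:
            for k in range(scn.exon_depth):
                lab, e = eligible[int(rng.integers(len(eligible)))]
                off = int(rng.integers(e.length - L + 1))
                fwd = genome.fetch(e.chrom, e.start + off, e.start + off + L - 1)
                frag = fwd if t.strand == "+" else revcomp(fwd)
                rid = f"{scn.sample_name}|exon|{tid}|{lab}|{k}"
                emit(rid, frag, f"exon:{tid}:{lab}")

    chrom = DEFAULT_CHROM if DEFAULT_CHROM in genome else genome.chroms[0]
    lo_g, hi_g = genome.chrom_span(chrom)
    for k in range(scn.background_reads):
        s = int(rng.integers(lo_g, hi_g - L + 2))
        frag = genome.fetch(chrom, s, s + L - 1)
        rid = f"{scn.sample_name}|bg|{k}"
        emit(rid, frag, "background")

    return reads, truth


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path, qual_char: str = "I") -> None:
    """Constant-quality FASTQ (qualities are carried but unused downstream)."""
    with Path(path).open("w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual_char * len(seq)}\n")


def mutate_read(seq: str, positions: Sequence[int]) -> str:
    """Deterministically substitute the base at each 0-based position (A<->C,
    G<->T), for constructing boundary-case reads in tests and demos."""
    swap = {"A": "C", "C": "A", "G": "T", "T": "G", "N": "A"}
    s = list(seq)
    for p in positions:
        s[p] = swap[s[p]]
    return "".join(s)
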