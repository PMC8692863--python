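"""Local alignment of reads to junction queries with a cover/identity filter.

A read supports a splice junction when its best local alignment against the
50-bp junction query passes both filters: query cover >= 95% and identity
>= 97% (inclusive thresholds). Conventions follow BLAST: identity is
matches over alignment columns (gap columns included); query cover is the
aligned query span over the full query length. Reads are tested in both
orientations (libraries are treated as unstranded) and each read casts at
most one vote per junction query — its best-scoring alignment.

The pairwise engine is Bio.Align.PairwiseAligner in local mode with affine
gap scores and an ACGTN matrix in which N never matches anything.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .genome import revcomp

ALPHABET = "ACGTN"

#: Alignments scoring below this are not reported at all (noise floor,
#: expressed in the scoring scheme's units; 20 = ten matched bases at the
#: default match score).
DEFAULT_SCORE_FLOOR = 20.0


@dataclass(frozen=True)
class ScoringScheme:
    """BLASTN-like local alignment scores. Affine gaps: the first gap column
    costs ``gap_open``, each further column ``gap_extend``."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be > 0")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch and gap scores must be < 0")


@dataclass(frozen=True)
class FilterParams:
    """Significance thresholds, in percent, both inclusive ('at least')."""

    min_query_cover: float = 95.0
    min_identity: float = 97.0

    def __post_init__(self):
        for v in (self.min_query_cover, self.min_identity):
            if not (0 < v <= 100):
                raise ValueError("filter thresholds must be in (0, 100]")


DEFAULT_SCORING = ScoringScheme()
DEFAULT_FILTERS = FilterParams()


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment of one read against one junction query.

    Spans are 1-based inclusive; ``read_span`` always refers to coordinates
    on the read as provided (even when the reverse complement aligned).
    """

    query_id: str
    read_id: str
    query_span: tuple[int, int]
    read_span: tuple[int, int]
    read_orientation: str  # "forward" | "revcomp"
    matches: int
    alignment_columns: int
    score: float
    identity_pct: float
    query_cover_pct: float
    significant: bool


def is_significant(a: AlignmentResult, p: FilterParams = DEFAULT_FILTERS) -> bool:
    """Both thresholds met (inclusive)."""
    return a.query_cover_pct >= p.min_query_cover and a.identity_pct >= p.min_identity


_aligner_cache: dict[tuple, Align.PairwiseAligner] = {}


def _make_aligner(scoring: ScoringScheme, ungapped: bool = False) -> Align.PairwiseAligner:
    key = (scoring, ungapped)
    if key not in _aligner_cache:
        mat = np.full((len(ALPHABET), len(ALPHABET)), scoring.mismatch, dtype=float)
        for i in range(4):  # N row/column stays at mismatch
            mat[i, i] = scoring.match
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.Array(
            alphabet=ALPHABET, dims=2, data=mat
        )
        big = -1e9 if ungapped else 0.0
        aligner.open_gap_score = big if ungapped else scoring.gap_open
        aligner.extend_gap_score = big if ungapped else scoring.gap_extend
        _aligner_cache[key] = aligner
    return _aligner_cache[key]


def _clean(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    return seq


def _metrics_from_alignment(aln: Align.Alignment) -> tuple[int, int, tuple[int, int], tuple[int, int]]:
    """(matches, columns, query_span, target_span) of a local alignment.

    N columns never count as matches. Spans are 1-based inclusive on the
    aligned (local) region.
    """
    q_aln, r_aln = str(aln[0]), str(aln[1])
    columns = len(q_aln)
    matches = sum(
        1 for a, b in zip(q_aln, r_aln) if a == b and a in "ACGT"
    )
    blocks_q, blocks_r = aln.aligned
    q_span = (int(blocks_q[0][0]) + 1, int(blocks_q[-1][-1]))
    r_span = (int(blocks_r[0][0]) + 1, int(blocks_r[-1][-1]))
    return matches, columns, q_span, r_span


def local_align(
    query: str,
    read: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
    filters: FilterParams = DEFAULT_FILTERS,
    query_id: str = "query",
    read_id: str = "read",
) -> AlignmentResult:
    """Best local alignment of a read (better of forward / reverse complement)
    against a query, with metrics and the significance flag populated.

    Deterministic: orientation ties prefer forward, and the engine's first
    optimal traceback is taken. A read with no positive-scoring alignment
    yields a zero-metrics, non-significant result.
    """
    query = _clean(query)
    read = _clean(read)
    aligner = _make_aligner(scoring)
    rc = revcomp(read)
    score_f = aligner.score(query, read)
    score_r = aligner.score(query, rc)
    if score_f >= score_r:
        orientation, target, score = "forward", read, score_f
    else:
        orientation, target, score = "revcomp", rc, score_r

    if score <= 0:
        return AlignmentResult(
            query_id=query_id, read_id=read_id,
            query_span=(0, 0), read_span=(0, 0),
            read_orientation=orientation, matches=0, alignment_columns=0,
            score=0.0, identity_pct=0.0, query_cover_pct=0.0, significant=False,
        )

    aln = aligner.align(query, target)[0]
    matches, columns, q_span, t_span = _metrics_from_alignment(aln)
    if orientation == "revcomp":
        n = len(read)
        t_span = (n - t_span[1] + 1, n - t_span[0] + 1)
    identity = 100.0 * matches / columns if columns else 0.0
    cover = 100.0 * (q_span[1] - q_span[0] + 1) / len(query)
    result = AlignmentResult(
        query_id=query_id, read_id=read_id,
        query_span=q_span, read_span=t_span,
        read_orientation=orientation,
        matches=matches, alignment_columns=columns,
        score=float(score), identity_pct=identity, query_cover_pct=cover,
        significant=False,
    )
    return replace(result, significant=is_significant(result, filters))


def best_ungapped_score(query: str, read: str, scoring: ScoringScheme = DEFAULT_SCORING) -> float:
    """Best local *ungapped* alignment score over both read orientations,
    computed with gap columns forbidden. Used as a lower bound / cross-check
    for the affine-gap engine."""
    query = _clean(query)
    read = _clean(read)
    aligner = _make_aligner(scoring, ungapped=True)
    return float(max(aligner.score(query, read), aligner.score(query, revcomp(read))))


def align_reads(
    queries: Sequence[tuple[str, str]],
    reads: Iterable[tuple[str, str]],
    scoring: ScoringScheme = DEFAULT_SCORING,
    filters: FilterParams = DEFAULT_FILTERS,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> list[AlignmentResult]:
    """Align every read against every junction query.

    ``queries`` and ``reads`` are (id, sequence) pairs. One result per
    read x query with best score >= ``score_floor`` (one-read-one-vote:
    multiple local hits of a read on the same query are never double
    counted). Fast path: orientation scores are computed first and the
    traceback is only performed for reported pairs.
    """
    aligner = _make_aligner(scoring)
    out: list[AlignmentResult] = []
    qlist = [(qid, _clean(qseq)) for qid, qseq in queries]
    for read_id, read_seq in reads:
        read_seq = _clean(read_seq)
        rc = revcomp(read_seq)
        for qid, qseq in qlist:
            if max(aligner.score(qseq, read_seq), aligner.score(qseq, rc)) < score_floor:
                continue
            out.append(
                local_align(qseq, read_seq, scoring, filters, query_id=qid, read_id=read_id)
            )
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sequences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from FASTA or FASTQ, by extension (quality values
    are parsed but unused)."""
    path = Path(path)
    suffix = path.suffix.lower()
    fmt = "fastq" if suffix in (".fastq", ".fq") else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield rec.id, str(rec.seq).upper()


RESULT_COLUMNS = [
    "query_id", "read_id", "qstart", "qend", "rstart", "rend",
    "orientation", "matches", "columns", "score",
    "identity_pct", "query_cover_pct", "significant",
]


def results_to_frame(results: Sequence[AlignmentResult]) -> pd.DataFrame:
    rows = [
        (
            a.query_id, a.read_id, a.query_span[0], a.query_span[1],
            a.read_span[0], a.read_span[1], a.read_orientation,
            a.matches, a.alignment_columns, a.score,
            round(a.identity_pct, 4), round(a.query_cover_pct, 4), a.significant,
        )
        for a in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results_tsv(results: Sequence[AlignmentResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def read_results_tsv(path: str | Path) -> list[AlignmentResult]:
    df = pd.read_csv(path, sep="\t")
    return [
        AlignmentResult(
            query_id=str(r.query_id), read_id=str(r.read_id),
            query_span=(int(r.qstart), int(r.qend)),
            read_span=(int(r.rstart), int(r.rend)),
            read_orientation=str(r.orientation),
            matches=int(r.matches), alignment_columns=int(r.columns),
            score=float(r.score), identity_pct=float(r.identity_pct),
            query_cover_pct=float(r.query_cover_pct),
            significant=bool(r.significant),
        )
        for r in df.itertuples(index=False)
    ]
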