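"""Junction support matrices and isoform presence calls.

Per sample, each junction of the catalog gets the count of distinct reads
whose best alignment against its query passed the significance filter
(explicit zeros included). An isoform is then called:

* ``full``    — every one of its junctions has at least one significant read;
* ``partial`` — some but not all junctions supported;
* ``none``    — no junction supported.

Junction identities belonging to more than one isoform are flagged
ambiguous (rendered as the published tables' asterisk): their reads cannot
be attributed to a single isoform. ``uniquely_confirmed`` marks isoforms
with at least one supported junction private to them. Shared support still
counts toward completeness — only the attribution is flagged, never
apportioned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .junction_catalog import JunctionCatalog, JunctionIdentity, parse_identity_str
from .local_align import AlignmentResult
from .transcript_models import TranscriptModel


@dataclass
class SupportMatrix:
    """sample x junction -> count of significant alignments (explicit zeros)."""

    samples: list[str]
    catalog: JunctionCatalog
    counts: dict[tuple[str, JunctionIdentity], int] = field(default_factory=dict)

    def __post_init__(self):
        for s in self.samples:
            for ident in self.catalog.identities:
                self.counts.setdefault((s, ident), 0)

    def count(self, sample: str, identity: JunctionIdentity) -> int:
        return self.counts[(sample, identity)]

    def add_sample(self, sample: str, row: Mapping[JunctionIdentity, int]) -> None:
        if sample not in self.samples:
            self.samples.append(sample)
        for ident in self.catalog.identities:
            self.counts[(sample, ident)] = int(row.get(ident, 0))

    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        data = {
            j.identity_str: [self.counts[(s, j.identity)] for s in self.samples]
            for j in self.catalog.junctions
        }
        return pd.DataFrame(data, index=pd.Index(self.samples, name="sample"))


def count_junction_support(
    alignments: Iterable[AlignmentResult],
    catalog: JunctionCatalog,
    sample: str,
) -> dict[JunctionIdentity, int]:
    """One matrix row: per catalog junction, the number of *distinct* read
    ids with a significant alignment. Alignments naming a junction outside
    the catalog are an error."""
    readsets: dict[JunctionIdentity, set[str]] = {i: set() for i in catalog.identities}
    for a in alignments:
        ident = parse_identity_str(a.query_id)
        if ident not in readsets:
            raise KeyError(
                f"sample {sample!r}: alignment references junction {a.query_id} "
                "absent from the catalog"
            )
        if a.significant:
            readsets[ident].add(a.read_id)
    return {ident: len(rids) for ident, rids in readsets.items()}


def build_support_matrix(
    per_sample_alignments: Mapping[str, Iterable[AlignmentResult]],
    catalog: JunctionCatalog,
) -> SupportMatrix:
    m = SupportMatrix(samples=list(per_sample_alignments), catalog=catalog)
    for sample, alns in per_sample_alignments.items():
        m.add_sample(sample, count_junction_support(alns, catalog, sample))
    return m


@dataclass(frozen=True)
class IsoformCall:
    transcript_id: str
    sample: str
    status: str  # "full" | "partial" | "none"
    supported_junctions: tuple[str, ...]  # junction labels, transcript order
    ambiguous_junctions: tuple[str, ...]  # labels shared with other isoforms
    uniquely_confirmed: bool


def call_isoforms(
    m: SupportMatrix,
    models: Sequence[TranscriptModel],
    sharing: Mapping[JunctionIdentity, set[str]] | None = None,
) -> list[IsoformCall]:
    """Per (sample, transcript) presence calls from a support matrix.

    ``sharing`` defaults to the catalog's own sharing map. Single-exon
    transcripts (no junctions) are uncallable and reported ``none``.
    """
    if sharing is None:
        sharing = m.catalog.sharing
    calls = []
    for sample in m.samples:
        for t in models:
            junctions = m.catalog.transcript_junctions(t.transcript_id)
            labels = [
                f"{t.exon_labels[i]}-{t.exon_labels[i + 1]}"
                for i in range(t.n_exons - 1)
            ]
            supported, ambiguous = [], []
            unique_hit = False
            for lab, j in zip(labels, junctions):
                n_members = len(sharing.get(j.identity, j.transcript_ids))
                hit = m.count(sample, j.identity) >= 1
                if hit:
                    supported.append(lab)
                    if n_members == 1:
                        unique_hit = True
                if n_members > 1:
                    ambiguous.append(lab)
            if junctions and len(supported) == len(junctions):
                status = "full"
            elif supported:
                status = "partial"
            else:
                status = "none"
            calls.append(
                IsoformCall(
                    transcript_id=t.transcript_id,
                    sample=sample,
                    status=status,
                    supported_junctions=tuple(supported),
                    ambiguous_junctions=tuple(ambiguous),
                    uniquely_confirmed=unique_hit,
                )
            )
    return calls


def confirmed_expressed_set(calls: Iterable[IsoformCall], sample: str) -> set[str]:
    """Isoforms with at least one significant read on a junction private to
    them, in one sample — the conservative 'definitely present' set."""
    return {
        c.transcript_id for c in calls if c.sample == sample and c.uniquely_confirmed
    }


# ---------------------------------------------------------------------------
# Report rendering (the published tables' dialect)
# ---------------------------------------------------------------------------

def format_cell(count: int, shared: bool) -> str:
    """'No' for zero; '1 alignment' / 'n alignments'; '*' marks a junction
    shared between isoforms."""
    if count < 0:
        raise ValueError("negative count")
    if count == 0:
        return "No"
    noun = "alignment" if count == 1 else "alignments"
    return f"{count} {noun}{'*' if shared else ''}"


def render_transcript_table(
    m: SupportMatrix,
    transcript_id: str,
    sharing: Mapping[JunctionIdentity, set[str]] | None = None,
) -> pd.DataFrame:
    """One published-style table: rows = samples, columns = the transcript's
    junctions in transcript order (labelled 'E1-E2', ...), cells rendered
    with :func:`format_cell`."""
    if sharing is None:
        sharing = m.catalog.sharing
    junctions = m.catalog.transcript_junctions(transcript_id)
    labels = []
    for t in m.catalog.models:
        if t.transcript_id == transcript_id:
            labels = [
                f"{t.exon_labels[i]}-{t.exon_labels[i + 1]}"
                for i in range(t.n_exons - 1)
            ]
    data = {}
    for lab, j in zip(labels, junctions):
        shared = len(sharing.get(j.identity, j.transcript_ids)) > 1
        data[lab] = [format_cell(m.count(s, j.identity), shared) for s in m.samples]
    return pd.DataFrame(data, index=pd.Index(m.samples, name="Tissue"))


def calls_to_frame(calls: Sequence[IsoformCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.sample, c.transcript_id, c.status,
                ",".join(c.supported_junctions) or "-",
                ",".join(c.ambiguous_junctions) or "-",
                c.uniquely_confirmed,
            )
            for c in calls
        ],
        columns=[
            "sample", "transcript_id", "status",
            "supported_junctions", "ambiguous_junctions", "uniquely_confirmed",
        ],
    )


def write_report(
    calls: Sequence[IsoformCall],
    m: SupportMatrix,
    outdir: str | Path,
    json_calls: bool = True,
) -> dict[str, Path]:
    """Write per-transcript support tables plus the isoform-call table.

    Byte-deterministic for identical inputs. Returns {artifact name: path}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    sharing = m.catalog.sharing
    for t in m.catalog.models:
        if t.n_exons < 2:
            continue
        path = outdir / f"support_{t.transcript_id}.tsv"
        render_transcript_table(m, t.transcript_id, sharing).to_csv(path, sep="\t")
        written[f"support_{t.transcript_id}"] = path
    calls_path = outdir / "isoform_calls.tsv"
    calls_to_frame(calls).to_csv(calls_path, sep="\t", index=False)
    written["isoform_calls"] = calls_path
    if json_calls:
        jpath = outdir / "isoform_calls.json"
        payload = [
            {
                "sample": c.sample,
                "transcript_id": c.transcript_id,
                "status": c.status,
                "supported_junctions": list(c.supported_junctions),
                "ambiguous_junctions": list(c.ambiguous_junctions),
                "uniquely_confirmed": c.uniquely_confirmed,
            }
            for c in calls
        ]
        jpath.write_text(json.dumps(payload, indent=2) + "\n")
        written["isoform_calls_json"] = jpath
    return written
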