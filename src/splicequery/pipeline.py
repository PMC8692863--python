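"""End-to-end orchestration: models -> junction queries -> reads -> alignment
-> support matrix -> isoform calls -> reports, driven by one config object.

The config round-trips losslessly through YAML, fully determines every
output (seeds included), and is copied into the run directory next to a
manifest of artifact paths, so a run is reproducible from its own output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .genome import FastaGenome, read_offset_fasta
from .junction_catalog import DEFAULT_FLANK, JunctionCatalog, write_query_fasta, write_sharing_tsv
from .local_align import (
    DEFAULT_SCORE_FLOOR,
    FilterParams,
    ScoringScheme,
    align_reads,
    read_sequences,
    write_results_tsv,
)
from .support_caller import build_support_matrix, call_isoforms, write_report
from .synthetic_data import (
    DEFAULT_SPAN,
    SimScenario,
    preset_scenario,
    simulate_genome,
    simulate_reads,
    write_fastq,
)
from .transcript_models import load_reference_transcripts, read_bed12, read_transcript_tsv

logger = logging.getLogger(__name__)


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )


@dataclass
class PipelineConfig:
    """Everything a run needs. ``models``/``genome``/``reads`` paths may be
    omitted: models default to the packaged transcript table, and a missing
    genome/reads pair switches the run to simulation via ``scenario``."""

    outdir: str
    models: str | None = None  # TSV or BED12; None -> packaged table
    genome: str | None = None  # FASTA; None -> simulate
    reads: str | None = None  # FASTA/FASTQ; None -> simulate from scenario
    flank: int = DEFAULT_FLANK
    filters: FilterParams = field(default_factory=FilterParams)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    scenario: SimScenario | None = None
    score_floor: float = DEFAULT_SCORE_FLOOR
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        if self.scenario is not None:
            d["scenario"]["expressed"] = sorted(self.scenario.expressed)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if d.get("filters"):
            d["filters"] = FilterParams(**d["filters"])
        if d.get("scoring"):
            d["scoring"] = ScoringScheme(**d["scoring"])
        if d.get("scenario"):
            scn = dict(d["scenario"])
            scn["expressed"] = frozenset(scn.get("expressed", ()))
            d["scenario"] = SimScenario(**scn)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _load_models(cfg: PipelineConfig):
    if cfg.models is None:
        return load_reference_transcripts()
    path = Path(cfg.models)
    if not path.exists():
        raise FileNotFoundError(f"models file not found: {path}")
    if path.suffix.lower() == ".bed":
        return read_bed12(path)
    return read_transcript_tsv(path)


def run_pipeline(cfg: PipelineConfig) -> dict[str, str]:
    """Execute every stage; returns the manifest (artifact name -> path).

    Stage summaries (input/output cardinalities) go to the module logger.
    Deterministic for a fixed config.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    models = _load_models(cfg)
    logger.info("stage models: %d transcripts, %d exons",
                len(models), sum(t.n_exons for t in models))

    catalog = JunctionCatalog(models)
    logger.info("stage junctions: %d junction identities (%d shared)",
                len(catalog), len(catalog.ambiguous_identities()))

    # genome
    if cfg.genome is not None:
        gpath = Path(cfg.genome)
        if not gpath.exists():
            raise FileNotFoundError(f"genome file not found: {gpath}")
        with gpath.open() as fh:
            first = fh.readline()
        # offset-tagged FASTA (our simulated surrogate) is held in memory;
        # plain reference FASTA goes through a pyfaidx index
        if "offset=" in first:
            genome = read_offset_fasta(gpath)
        else:
            genome = FastaGenome(gpath)
    else:
        genome = simulate_genome(DEFAULT_SPAN, seed=cfg.seed, models=models)
        gpath = outdir / "genome.fasta"
        genome.to_fasta(gpath)
        manifest["genome"] = str(gpath)
        logger.info("stage genome: simulated %d nt over %s",
                    DEFAULT_SPAN.length, DEFAULT_SPAN.chrom)

    queries = catalog.queries(genome, flank=cfg.flank)
    qpath = outdir / "junction_queries.fasta"
    write_query_fasta(queries, qpath)
    manifest["junction_queries"] = str(qpath)
    spath = outdir / "junction_sharing.tsv"
    write_sharing_tsv(catalog, spath)
    manifest["junction_sharing"] = str(spath)

    # reads
    truth = None
    if cfg.reads is not None:
        rpath = Path(cfg.reads)
        if not rpath.exists():
            raise FileNotFoundError(f"reads file not found: {rpath}")
        sample = cfg.scenario.sample_name if cfg.scenario else rpath.stem
        reads = list(read_sequences(rpath))
    else:
        if cfg.scenario is None:
            raise ValueError("config needs either a reads path or a scenario")
        reads, truth = simulate_reads(cfg.scenario, models, genome, flank=cfg.flank)
        sample = cfg.scenario.sample_name
        rpath = outdir / f"reads_{sample}.fastq"
        write_fastq(reads, rpath)
        manifest["reads"] = str(rpath)
        tpath = outdir / f"ground_truth_{sample}.tsv"
        truth.to_tsv(tpath)
        manifest["ground_truth"] = str(tpath)
    logger.info("stage reads: %d reads for sample %s", len(reads), sample)

    results = align_reads(
        [(q.query_id, q.sequence) for q in queries],
        reads,
        scoring=cfg.scoring,
        filters=cfg.filters,
        score_floor=cfg.score_floor,
    )
    n_sig = sum(1 for a in results if a.significant)
    logger.info("stage align: %d reported alignments, %d significant",
                len(results), n_sig)
    apath = outdir / "alignments.tsv"
    write_results_tsv(results, apath)
    manifest["alignments"] = str(apath)

    matrix = build_support_matrix({sample: results}, catalog)
    assert matrix.total() == len(
        {(a.read_id, a.query_id) for a in results if a.significant}
    ), "support counts must conserve distinct significant (read, junction) pairs"
    calls = call_isoforms(matrix, models)
    logger.info(
        "stage call: statuses %s",
        {s: sum(1 for c in calls if c.status == s) for s in ("full", "partial", "none")},
    )
    written = write_report(calls, matrix, outdir)
    manifest.update({k: str(v) for k, v in written.items()})

    cfg.to_yaml(outdir / "config.yaml")
    manifest["config"] = str(outdir / "config.yaml")
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["manifest"] = str(mpath)
    return manifest


def run_preset(preset: str, outdir: str | Path, seed: int = 0, **scenario_overrides) -> dict[str, str]:
    """Convenience: simulate and analyse one preset tissue scenario."""
    cfg = PipelineConfig(
        outdir=str(outdir),
        scenario=preset_scenario(preset, seed=seed, **scenario_overrides),
        seed=seed,
    )
    return run_pipeline(cfg)
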