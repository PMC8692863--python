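# Methods

## Transcript models and coordinates

Transcript models are ordered exon lists in transcript 5'→3' order with
1-based inclusive genomic coordinates. The packaged table of the five
KCNJ6/DSCR4 isoforms keeps the published coordinate pairs verbatim,
including the first-exon pair of KCNJ6-201 (37,961,457–37,915,884) that
partially overlaps the HR-DSCR even though the region is described as
intergenic; we treat the fixture as source data and let the overlap
classifier surface the conflict (`partial_overlap`) rather than silently
correcting it. Strand is inferred from printed coordinate direction
(descending pairs ⇒ minus strand), which is unambiguous for every
multi-base exon; a single-exon, single-base transcript defaults to `+`.
Mixed directions within one transcript and overlapping exons are validation
errors. Abutting exons (zero-length intron) are likewise an error, not a
merge: they indicate a malformed model, and silently fusing exons would
change the junction catalog. BED12 input/output converts between 0-based
half-open and this convention; exon labels are not representable in BED12
and are regenerated as `E1..En`.

## Junction identity and queries

A junction is keyed by (chrom, strand, donor, acceptor), where donor and
acceptor are the exonic bases adjacent to the splice in transcript order.
Identity is coordinate-based, never sequence-based: sharing between
isoforms is then decidable from the models alone, and the locus's structure
follows directly — KCNJ6-201 and KCNJ6-202 share two junction identities
(their E2–E3, and E3–E4/E4b, whose downstream exons share an acceptor), and
the first DSCR4 junction is one identity across all three DSCR4 isoforms
and KCNJ6-202, even though the DSCR4 and KCNJ6-202 first exons differ at
their far (transcript-5') ends — the junction-proximal 25 nt are identical,
which is all a 25-nt flank can see.

Queries default to symmetric 25+25 flanks (50 bp), configurable and
allowed to be asymmetric. A flank longer than its source exon is truncated
to the exon with a logged warning and a `truncated` marker on the query,
because short terminal exons are real; failing would make whole transcripts
unanalysable. Queries are always emitted transcript-oriented; read
orientation is the aligner's job.

## Alignment and the significance filter

The aligner is Bio.Align.PairwiseAligner in local mode with affine gaps and
a 5-letter matrix in which N matches nothing (N can therefore never help an
alignment reach the identity threshold). Default scores are BLASTN-like
(+2 match, −3 mismatch, −5 gap open, −2 gap extend); they are configuration,
not contract — every calling decision rests on the cover/identity filter,
not on score magnitudes. Metrics follow BLAST conventions: identity =
matches / alignment columns including gap columns; query cover = aligned
query span / full query length. Both thresholds (cover ≥ 95%, identity
≥ 97%) are inclusive.

Reads are scored in both orientations (forward preferred on ties) and only
the better orientation is traced back; the engine's first optimal traceback
is taken, which is deterministic. Each read contributes at most one result
per query — one read, one vote — so a read can never be double-counted on a
junction through multiple local hits. Alignments scoring below a reporting
floor (20, i.e. ten matched bases) are not reported at all; the floor is an
output-volume control, far below anything that could pass the filter
(≥ 48 aligned columns at ≥ 97% identity scores ≥ 80).

The test suite cross-checks the engine against an exhaustive enumeration
oracle over all ungapped offsets and both orientations (Kadane's best
contiguous segment per diagonal): with gaps disabled the engine must equal
the oracle exactly on 1,000 random pairs; with affine gaps enabled its
score must never fall below the ungapped optimum.

## Synthetic data: what it emulates, what it does not

The surrogate genome is i.i.d. uniform A/C/G/T over
chr21:37,600,000–38,130,000 (530,001 nt), addressable by real GRCh38
coordinates via an internal offset, deterministic per seed. Scenarios plant:

* **junction reads** — `junction_depth` reads per junction of each
  expressed isoform, cut from the spliced transcript sequence so the
  footprint extends ≥ flank+5 (30) nt into both sides of the target
  junction; at zero error rate such reads are guaranteed significant;
* **exon-interior reads** — sampled inside single exons at least one read
  long (negative controls for the cover criterion);
* **background reads** — uniform positions of the surrogate genome
  (intergenic negatives);

with i.i.d. per-base substitution errors, random orientation, and constant
FASTQ qualities. Defaults — read length 100 nt, junction_depth 10,
exon_depth 5, background 50, error rate 0.002 — are a realistic
short-read regime: 100 nt is a standard Illumina length comfortably above
the 60-nt spanning minimum, 0.2% substitution is the right order of
magnitude for Illumina error, and depth 10 puts junction support well above
the ≥ 1-read calling threshold without inflating runtime. Tissue presets
(`brain` → KCNJ6-201; `placenta` → DSCR4-201; `testis` → DSCR4-201 +
DSCR4-202; `heart` → nothing) mirror the qualitative presence/absence
pattern reported for those tissues, so end-to-end runs reproduce the
characteristic table shapes: cerebral full-KCNJ6-201 support, the
asterisked shared first junction in placenta and testis, and all-"No" rows.

Deliberate non-realism, and hence the limits of what passing tests show:
uniform random sequence has none of the repeat structure, paralogy or GC
skew of real chr21, so the specificity results (background/exon reads never
significant) bound only chance similarity, not homology-driven
cross-mapping; there are no indel sequencing errors, no quality-dependent
errors, no fragment/paired-end model, and no expression-level realism —
the readout here is presence/absence, not abundance. Real first exons that
nearly duplicate a flank elsewhere in the genome could in principle let an
exon-interior read pass; on independent random sequence this is
vanishingly unlikely and is asserted only there.

## Calling rules

* **full** requires ≥ 1 distinct significant read on *every* junction,
  shared ones included — shared support counts toward completeness but is
  flagged, never apportioned or probabilistically split.
* **partial** is ≥ 1 supported junction but not all; **none** is zero.
  No minimum count beyond ≥ 1: any significant alignment is detection.
* Every junction identity with more than one member isoform is flagged
  ambiguous on every member's call, supported or not.
* `uniquely_confirmed` — the conservative "definitely present" predicate —
  requires a supported junction private to the isoform. Scenario-recovery
  tests use exactly this set: for every preset, across ten seeds at
  junction_depth 3 and error rate 0.005, the uniquely-confirmed set equals
  the planted expressed set. All five packaged isoforms possess at least
  one private junction, so the restriction excludes none of them.
* Counts conserve: the matrix total equals the number of distinct
  significant (read, junction) pairs; adding reads can only move a call
  along none → partial → full.

## Report dialect

Support tables render one row per sample and one column per junction in
transcript order, `No` for zero, `1 alignment` / `n alignments` otherwise,
with `*` appended on junctions shared between isoforms. Reports are
byte-deterministic given identical inputs.

## Primer QC

Annealing temperature uses the Wallace rule, 2(A+T) + 4(G+C) °C — chosen
for transparency at typical primer lengths and documented as swappable for
nearest-neighbour thermodynamics. Criteria: 55–65 °C per primer, pair
difference strictly below 2 °C, GC within an inclusive 40–60% ("around
40–60%" is applied as a hard inclusive bound). Hairpin, self-dimer and
cross-dimer screening uses a perfect-complementarity-run heuristic
(longest common substring against the reverse complement, threshold 6;
hairpins additionally require a ≥ 3-nt loop) — a deliberately simple
screen matched to the descriptive level of standard design rules, not a
thermodynamic model.

## Problem sizes

All tests run on the 530-kb surrogate genome and scenario read sets of
25–100 reads against the 12-query catalog; the full suite completes in
well under a minute and the acceptance script in seconds. These sizes were
chosen as the smallest at which every contract (exact recall, specificity
over seeds, scenario recovery, oracle equivalence at 1,000 pairs) is
exercised meaningfully.
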