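"""PCR primer-pair quality checks.

Standard design criteria for junction-validation primers: annealing
temperature (Wallace rule, 2(A+T) + 4(G+C) degC) between 55 and 65 degC per
primer with a pair difference below 2 degC; GC content within 40-60%
(inclusive); and no secondary-structure risk, screened with a simple
perfect-complementarity-run heuristic (a run of >= 6 complementary bases
flags hairpins, self-dimers and cross-dimers). The Wallace rule and the run
heuristic are deliberate simplicity choices — both are swappable for
nearest-neighbour thermodynamics without touching the report contract.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import revcomp

COMPLEMENT_RUN_THRESHOLD = 6
MIN_HAIRPIN_LOOP = 3


def _validate_primer(seq: str, name: str) -> str:
    seq = seq.upper()
    if not (10 <= len(seq) <= 40):
        raise ValueError(f"{name}: primer length must be 10-40 nt, got {len(seq)}")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"{name}: primer contains non-ACGT characters {sorted(bad)}")
    return seq


def wallace_ta(seq: str) -> float:
    """Wallace-rule annealing temperature: 2(A+T) + 4(G+C), degC."""
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return 2.0 * at + 4.0 * gc


def gc_percent(seq: str) -> float:
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def longest_complementary_run(a: str, b: str) -> int:
    """Longest perfect antiparallel duplex between two sequences = longest
    common substring of ``a`` and revcomp(``b``)."""
    rb = revcomp(b)
    best = 0
    # O(n^2) DP over <=40-nt strings
    prev = [0] * (len(rb) + 1)
    for ca in a:
        cur = [0] * (len(rb) + 1)
        for jj, cb in enumerate(rb, start=1):
            if ca == cb:
                cur[jj] = prev[jj - 1] + 1
                best = max(best, cur[jj])
        prev = cur
    return best


def has_hairpin(seq: str, stem: int = COMPLEMENT_RUN_THRESHOLD, loop: int = MIN_HAIRPIN_LOOP) -> bool:
    """A stem of >= ``stem`` self-complementary bases separated by a loop of
    >= ``loop`` bases anywhere in the primer."""
    n = len(seq)
    for i in range(n - stem + 1):
        probe = revcomp(seq[i : i + stem])
        j = seq.find(probe, i + stem + loop)
        if j != -1:
            return True
    return False


@dataclass(frozen=True)
class PrimerStats:
    sequence: str
    ta: float
    gc_pct: float
    hairpin: bool
    self_dimer: bool
    ta_ok: bool
    gc_ok: bool


@dataclass(frozen=True)
class PrimerReport:
    forward: PrimerStats
    reverse: PrimerStats
    delta_ta: float
    delta_ta_ok: bool
    cross_dimer: bool

    @property
    def passed(self) -> bool:
        per_primer = all(
            s.ta_ok and s.gc_ok and not s.hairpin and not s.self_dimer
            for s in (self.forward, self.reverse)
        )
        return per_primer and self.delta_ta_ok and not self.cross_dimer


def _primer_stats(
    seq: str,
    ta_range: tuple[float, float],
    gc_range: tuple[float, float],
    run_threshold: int,
) -> PrimerStats:
    ta = wallace_ta(seq)
    gc = gc_percent(seq)
    return PrimerStats(
        sequence=seq,
        ta=ta,
        gc_pct=gc,
        hairpin=has_hairpin(seq, stem=run_threshold),
        self_dimer=longest_complementary_run(seq, seq) >= run_threshold,
        ta_ok=ta_range[0] <= ta <= ta_range[1],
        gc_ok=gc_range[0] <= gc <= gc_range[1],
    )


def primer_pair_qc(
    forward: str,
    reverse: str,
    ta_range: tuple[float, float] = (55.0, 65.0),
    max_delta_ta: float = 2.0,
    gc_range: tuple[float, float] = (40.0, 60.0),
    run_threshold: int = COMPLEMENT_RUN_THRESHOLD,
) -> PrimerReport:
    """Evaluate a primer pair against all criteria; ``passed`` is true only
    when every criterion is met (delta Ta strictly below ``max_delta_ta``)."""
    fwd = _validate_primer(forward, "forward")
    rev = _validate_primer(reverse, "reverse")
    fs = _primer_stats(fwd, ta_range, gc_range, run_threshold)
    rs = _primer_stats(rev, ta_range, gc_range, run_threshold)
    delta = abs(fs.ta - rs.ta)
    return PrimerReport(
        forward=fs,
        reverse=rs,
        delta_ta=delta,
        delta_ta_ok=delta < max_delta_ta,
        cross_dimer=longest_complementary_run(fwd, rev) >= run_threshold,
    )
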