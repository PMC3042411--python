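"""The pseudogenization molecular clock.

A functional IGHV gene segment stays functional only while its two exons
(~355 bp together) avoid a premature stop codon.  With a genome-wide point
substitution rate μ (per base per haploid genome per generation) and the
fact that 18 of the 61 sense codons of the standard genetic code lie one
substitution away from a stop, the expected waiting time for point
inactivation is

    t_point = G / (μ · L · f)

with generation time G (years), exon length L (bp) and f = 18/61 the
per-mutation probability of creating a stop.  Observed pseudogene censuses
show about twice as many segments inactivated by structural changes
(truncations) as by point mutation, so the all-causes inactivation time is
t_point divided by (1 + structural_multiplier), with multiplier 2 by
default.  A sequence divergence d between duplicate copies dates the
duplication at

    t_div = d · G / μ

(single-lineage accumulation: the divergence is counted against the one
mutation rate, not halved per lineage — this convention is what the module's
reported times assume, and changing it scales t_div by 2).  The ratio
t_div / t_all says how many gene-inactivation half-lives the duplicate
copies have survived — a large ratio is evidence of purifying selection on
the gene segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Data import CodonTable

BASES = "ACGT"


def standard_code() -> dict[str, str]:
    """The standard genetic code as codon → amino acid, stops mapped to '*'."""
    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


def _neighbors(codon: str) -> Iterable[str]:
    for pos in range(3):
        for base in BASES:
            if base != codon[pos]:
                yield codon[:pos] + base + codon[pos + 1 :]


def single_hit_stop_codons(
    code: Mapping[str, str] | None = None,
) -> tuple[int, list[str]]:
    """Sense codons one substitution away from a stop codon.

    Exhaustively enumerates the 9 single-base neighbors of every sense codon
    and counts those with at least one stop neighbor; for the standard code
    the count is 18.  Returns (count, sorted codon list).
    """
    if code is None:
        code = standard_code()
    stops = {c for c, aa in code.items() if aa == "*"}
    hits = sorted(
        c
        for c, aa in code.items()
        if aa != "*" and any(n in stops for n in _neighbors(c))
    )
    return len(hits), hits


def stop_hit_fraction(code: Mapping[str, str] | None = None, mode: str = "codon") -> float:
    """Per-mutation probability of creating a stop.

    ``codon`` (default): fraction of sense codons reachable-to-stop in one
    hit — the convention the clock's headline times are built on.  ``path``:
    the refined per-mutation-path fraction (stop-creating single-base changes
    over all 9·n_sense changes), which is smaller.
    """
    if code is None:
        code = standard_code()
    stops = {c for c, aa in code.items() if aa == "*"}
    sense = [c for c, aa in code.items() if aa != "*"]
    if not sense:
        raise ValueError("code has no sense codons")
    if mode == "codon":
        count, _ = single_hit_stop_codons(code)
        return count / len(sense)
    if mode == "path":
        paths = sum(1 for c in sense for n in _neighbors(c) if n in stops)
        return paths / (9 * len(sense))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class ClockParams:
    """Clock parameters with the field's headline defaults.

    mu — substitutions/base/haploid genome/generation (1.1e-8);
    generation_years — 25; exon_length — 355 bp (two exons of one segment);
    f_stop — 18/61; structural_multiplier — structural-inactivation rate as a
    multiple of the point rate (2, from the observed ~2:1 pseudogene census).
    """

    mu: float = 1.1e-8
    generation_years: float = 25.0
    exon_length: float = 355.0
    f_stop: float = 18.0 / 61.0
    structural_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if min(self.mu, self.generation_years, self.exon_length) <= 0:
            raise ValueError("mu, generation_years and exon_length must be positive")
        if not (0.0 < self.f_stop < 1.0):
            raise ValueError("f_stop must be in (0, 1)")
        if self.structural_multiplier < 0:
            raise ValueError("structural_multiplier must be >= 0")


def time_to_pseudogene_point(p: ClockParams = ClockParams()) -> float:
    """Expected years for point mutation alone to break a segment's ORF:
    G / (μ·L·f) ≈ 21.7 My at the defaults."""
    return p.generation_years / (p.mu * p.exon_length * p.f_stop)


def time_to_pseudogene_all(p: ClockParams = ClockParams()) -> float:
    """Expected years for any inactivating alteration (point + structural):
    t_point / (1 + structural_multiplier) ≈ 7.2 My at the defaults."""
    return time_to_pseudogene_point(p) / (1.0 + p.structural_multiplier)


def divergence_time(d: float, p: ClockParams = ClockParams()) -> float:
    """Years needed to accumulate divergence fraction ``d``: d·G/μ
    (single-lineage convention; d = 4.36% dates the block duplication at
    ≈ 99 My)."""
    if d < 0:
        raise ValueError("divergence must be non-negative")
    return d * p.generation_years / p.mu


@dataclass(frozen=True)
class ClockReport:
    t_point_years: float
    t_all_years: float
    t_divergence_years: float
    ratio: float

    def formatted(self) -> dict[str, float]:
        """Presentation values: millions of years at one decimal."""
        return {
            "t_point_My": round(self.t_point_years / 1e6, 1),
            "t_all_My": round(self.t_all_years / 1e6, 1),
            "t_divergence_My": round(self.t_divergence_years / 1e6, 1),
            "ratio": round(self.ratio, 1),
        }

    def __str__(self) -> str:
        f = self.formatted()
        return (
            f"point inactivation: {f['t_point_My']} My; "
            f"all causes: {f['t_all_My']} My; "
            f"duplicate divergence: {f['t_divergence_My']} My "
            f"({f['ratio']}x the inactivation time)"
        )


def clock_report(d: float, p: ClockParams = ClockParams()) -> ClockReport:
    """Assemble the three clock times and the survival ratio for divergence
    fraction ``d`` between duplicate copies."""
    t_point = time_to_pseudogene_point(p)
    t_all = time_to_pseudogene_all(p)
    t_div = divergence_time(d, p)
    return ClockReport(t_point, t_all, t_div, t_div / t_all)
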