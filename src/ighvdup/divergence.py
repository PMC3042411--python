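"""Pairwise divergence accounting between gene-segment copies.

Allelic copies (same locus, homologous chromosomes) and paralogous copies
(duplicated loci on one chromosome) are compared the same way: a global
alignment, a difference count under an explicit convention, and a percent
difference at two printed decimals.  Percent differences translate into
"bases per 1,200 bp" for comparison with the genomic average of one
substitution per 1,200 bp (0.08%).  ORF status of a segment's exons decides
pseudogenization.

The difference-count and denominator conventions are configurable because
published difference tables rarely state them; defaults are substitutions
plus indel events, over the second sequence's length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from Bio import Align
from Bio.Seq import Seq

DIFFERENCE_CONVENTIONS = ("subs_only", "subs_plus_indel_events", "subs_plus_indel_columns")
DENOMINATOR_CONVENTIONS = ("len_a", "len_b", "longer", "shorter", "alignment_columns")


@dataclass(frozen=True)
class Scoring:
    """Global-alignment scoring.

    The gap-opening penalty is deliberately stiff relative to a mismatch:
    with a cheap opening cost, a pair of short gaps can out-score a cluster
    of substitutions whenever the mutations happen to create shifted local
    homology, which mis-attributes substitutions to indels in difference
    counting.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class Alignment:
    """A global pairwise alignment with difference bookkeeping."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def n_substitutions(self) -> int:
        return sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x != "-" and y != "-" and x != y
        )

    @property
    def n_indel_columns(self) -> int:
        return sum(1 for x, y in zip(self.aligned_a, self.aligned_b) if "-" in (x, y))

    @property
    def n_indel_events(self) -> int:
        events, in_gap = 0, False
        for x, y in zip(self.aligned_a, self.aligned_b):
            gap = "-" in (x, y)
            if gap and not in_gap:
                events += 1
            in_gap = gap
        return events


def global_align(a: str, b: str, scoring: Scoring = Scoring()) -> Alignment:
    """Optimal global (Needleman–Wunsch) alignment under affine gap scoring.

    Backed by Bio.Align.PairwiseAligner; among co-optimal alignments the
    aligner's first enumeration order is taken, which is deterministic for
    fixed inputs.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    aln = aligner.align(a, b)[0]
    return Alignment(str(aln[0]), str(aln[1]), float(aln.score))


def count_differences(al: Alignment, convention: str = "subs_plus_indel_events") -> int:
    if convention == "subs_only":
        return al.n_substitutions
    if convention == "subs_plus_indel_events":
        return al.n_substitutions + al.n_indel_events
    if convention == "subs_plus_indel_columns":
        return al.n_substitutions + al.n_indel_columns
    raise ValueError(f"unknown difference convention {convention!r}")


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_difference(diff: int, denominator: int) -> float:
    """Percent difference at two decimals, half-up, as printed in difference
    tables (e.g. 29/438 → 6.62, 1/454 → 0.22, 39/2245 → 1.74)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return _round_half_up(100.0 * diff / denominator, 2)


def per_1200(percent: float) -> float:
    """Translate a percent difference into bases per 1,200 bp (one decimal):
    0.22% → 2.6, 4.34% → 52.1; the genomic average 0.08% → 1.0."""
    return _round_half_up(percent / 100.0 * 1200.0, 1)


@dataclass(frozen=True)
class OrfStatus:
    in_orf: bool
    first_stop_position: int | None = None  # codon index


def orf_status(exons: list[str], frame: int = 0) -> OrfStatus:
    """Translate concatenated exons; a stop before the final codon breaks the
    open reading frame (a terminal stop does not)."""
    cds = "".join(exons)[frame:]
    cds = cds[: len(cds) - len(cds) % 3]
    if not cds:
        return OrfStatus(True, None)
    protein = str(Seq(cds).translate())
    internal = protein[:-1]
    pos = internal.find("*")
    if pos == -1:
        return OrfStatus(True, None)
    return OrfStatus(False, pos)


@dataclass(frozen=True)
class DivergenceRecord:
    name_a: str
    name_b: str
    len_a: int
    len_b: int
    diff: int
    percent: float
    relation: str  # allelic | paralogous


@dataclass(frozen=True)
class GroupSummary:
    relation: str
    total_diff: int
    total_denominator: int
    pooled_percent: float


@dataclass(frozen=True)
class DivergenceConfig:
    difference: str = "subs_plus_indel_events"
    denominator: str = "len_b"
    scoring: Scoring = field(default_factory=Scoring)

    def __post_init__(self) -> None:
        if self.difference not in DIFFERENCE_CONVENTIONS:
            raise ValueError(f"unknown difference convention {self.difference!r}")
        if self.denominator not in DENOMINATOR_CONVENTIONS:
            raise ValueError(f"unknown denominator convention {self.denominator!r}")


def _denominator(cfg: DivergenceConfig, len_a: int, len_b: int, n_columns: int) -> int:
    return {
        "len_a": len_a,
        "len_b": len_b,
        "longer": max(len_a, len_b),
        "shorter": min(len_a, len_b),
        "alignment_columns": n_columns,
    }[cfg.denominator]


def build_divergence_table(
    pairs: list[tuple[str, str, str, str, str]],
    config: DivergenceConfig = DivergenceConfig(),
) -> tuple[list[DivergenceRecord], dict[str, GroupSummary]]:
    """Align each (name_a, seq_a, name_b, seq_b, relation) pair and tabulate.

    Returns one record per pair (input order preserved; record content is
    order-independent) and, per relation group, the pooled summary: total
    difference count over total denominator.
    """
    records: list[DivergenceRecord] = []
    totals: dict[str, list[int]] = {}
    for name_a, seq_a, name_b, seq_b, relation in pairs:
        al = global_align(seq_a, seq_b, config.scoring)
        diff = count_differences(al, config.difference)
        denom = _denominator(config, len(seq_a), len(seq_b), al.n_columns)
        records.append(
            DivergenceRecord(
                name_a, name_b, len(seq_a), len(seq_b), diff,
                percent_difference(diff, denom), relation,
            )
        )
        t = totals.setdefault(relation, [0, 0])
        t[0] += diff
        t[1] += denom
    summaries = {
        rel: GroupSummary(rel, d, n, percent_difference(d, n))
        for rel, (d, n) in totals.items()
    }
    return records, summaries
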