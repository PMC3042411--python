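"""Dot-matrix sequence comparison and duplicate-block discovery.

A dot-matrix plot compares every window of one sequence against every window
of another; matches on the main diagonal mark identity, off-diagonal matches
mark repeats, and diagonal discontinuities mark rearrangement breakpoints.
The window size defaults to 9 bp, the classic dot-plot setting for this
locus.  Windows are matched exactly by hashing, or within a per-window
mismatch budget via pigeonhole seeding — both produce the same match set as
the naive all-vs-all definition.

Tandem duplicate blocks are inferred from the self-comparison: long chained
runs on a positive off-diagonal at offset *d* imply copies of unit length
*d*; the spanned interval is cut into copies, the last of which may be an
incomplete (truncated) copy.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .region import revcomp


@dataclass(frozen=True)
class DotPlotParams:
    window: int = 9
    max_mismatch: int = 0
    strand: str = "forward_only"  # or "both"

    def __post_init__(self) -> None:
        if self.window < 4:
            raise ValueError("window must be >= 4")
        if not (0 <= self.max_mismatch < self.window):
            raise ValueError("max_mismatch must be < window")
        if self.strand not in ("forward_only", "both"):
            raise ValueError("strand must be forward_only or both")


@dataclass(frozen=True)
class DotMatch:
    """Window-start offsets of one matching window pair (0-based)."""

    i: int
    j: int
    strand: str = "+"


@dataclass(frozen=True)
class DiagonalRun:
    """A chained stretch of window matches on one diagonal.

    ``length`` spans from the first window start to the last window end, so a
    single window yields ``length == window``.
    """

    a_start: int
    b_start: int
    length: int
    diagonal: int

    @property
    def a_end(self) -> int:
        return self.a_start + self.length

    @property
    def b_end(self) -> int:
        return self.b_start + self.length


@dataclass(frozen=True)
class RepeatBlock:
    """A tandem repeat family: per-copy intervals and completeness flags."""

    copies: tuple[tuple[int, int], ...]
    complete: tuple[bool, ...]
    unit_length: int

    @property
    def n_complete(self) -> int:
        return sum(self.complete)


def _hamming_leq(a: str, b: str, limit: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return True


def _forward_matches(a: str, b: str, w: int, mm: int) -> set[tuple[int, int]]:
    out: set[tuple[int, int]] = set()
    if mm == 0:
        index: dict[str, list[int]] = defaultdict(list)
        for j in range(len(b) - w + 1):
            index[b[j : j + w]].append(j)
        for i in range(len(a) - w + 1):
            for j in index.get(a[i : i + w], ()):
                out.add((i, j))
        return out
    # pigeonhole: split the window into mm+1 parts; any window pair within the
    # budget shares at least one exact part at the same in-window offset
    bounds = [round(k * w / (mm + 1)) for k in range(mm + 2)]
    parts = [(bounds[k], bounds[k + 1]) for k in range(mm + 1)]
    for ps, pe in parts:
        plen = pe - ps
        index = defaultdict(list)
        for j in range(len(b) - w + 1):
            index[b[j + ps : j + pe]].append(j)
        for i in range(len(a) - w + 1):
            for j in index.get(a[i + ps : i + pe], ()):
                if (i, j) not in out and _hamming_leq(a[i : i + w], b[j : j + w], mm):
                    out.add((i, j))
    return out


def dot_matches(a: str, b: str, p: DotPlotParams = DotPlotParams()) -> list[DotMatch]:
    """All window pairs (i, j) with at most ``p.max_mismatch`` substitutions.

    Forward strand by default; with ``strand="both"`` matches of ``a``
    windows against reverse-complemented ``b`` windows are also reported
    (``j`` in forward ``b`` coordinates, strand ``-``).  Sequences shorter
    than the window yield an empty result.
    """
    w = p.window
    if len(a) < w or len(b) < w:
        return []
    matches = [DotMatch(i, j) for i, j in sorted(_forward_matches(a, b, w, p.max_mismatch))]
    if p.strand == "both":
        rc = revcomp(b)
        n = len(b)
        matches += [
            DotMatch(i, n - w - j, "-")
            for i, j in sorted(_forward_matches(a, rc, w, p.max_mismatch))
        ]
    return matches


def diagonal_runs(
    matches: list[DotMatch],
    min_run: int,
    max_gap: int,
    window: int = 9,
) -> list[DiagonalRun]:
    """Chain matches along diagonals into runs.

    Matches on one diagonal whose consecutive window starts differ by at most
    ``max_gap`` are merged; runs shorter than ``min_run`` are discarded.
    Reverse-strand matches are ignored (direct repeats only).
    """
    per_diag: dict[int, list[int]] = defaultdict(list)
    for m in matches:
        if m.strand == "+":
            per_diag[m.j - m.i].append(m.i)
    runs: list[DiagonalRun] = []
    for d, starts in per_diag.items():
        starts.sort()
        first = prev = starts[0]
        for i in starts[1:] + [None]:
            if i is not None and i - prev <= max_gap:
                prev = i
                continue
            length = prev + window - first
            if length >= min_run:
                runs.append(DiagonalRun(first, first + d, length, d))
            if i is not None:
                first = prev = i
    runs.sort(key=lambda r: (r.a_start, r.diagonal))
    return runs


def find_repeat_units(
    region_seq: str,
    p: DotPlotParams = DotPlotParams(),
    min_unit: int = 200,
    max_gap: int = 50,
) -> list[RepeatBlock]:
    """Infer tandem duplicate blocks from a self-comparison.

    The diagonal carrying the most chained off-diagonal run length (among
    diagonals with at least one run of ``min_unit`` bp) defines the repeat
    unit length; the interval spanned by those runs is cut into unit-sized
    copies.  Copies covering at least 90% of the unit are flagged complete;
    a shorter trailing prefix is an incomplete copy.  Returns an empty list
    when no off-diagonal run reaches ``min_unit``.
    """
    matches = dot_matches(region_seq, region_seq, p)
    runs = [
        r
        for r in diagonal_runs(matches, min_run=p.window, max_gap=max_gap,
                               window=p.window)
        if r.diagonal > 0
    ]
    by_diag: dict[int, list[DiagonalRun]] = defaultdict(list)
    for r in runs:
        by_diag[r.diagonal].append(r)
    candidates = {
        d: sum(r.length for r in rs)
        for d, rs in by_diag.items()
        if any(r.length >= min_unit for r in rs)
    }
    if not candidates:
        return []
    d = max(candidates, key=lambda k: (candidates[k], -k))
    # isolated single-window matches are indistinguishable from background;
    # only chained runs (>= 2 windows) delimit the copy span
    unit_runs = [r for r in by_diag[d] if r.length > p.window]
    span_start = min(r.a_start for r in unit_runs)
    span_end = max(r.b_end for r in unit_runs)
    copies: list[tuple[int, int]] = []
    complete: list[bool] = []
    s = span_start
    while s < span_end - p.window + 1:
        e = min(s + d, span_end)
        copies.append((s, e))
        complete.append(e - s >= 0.9 * d)
        s += d
    return [RepeatBlock(tuple(copies), tuple(complete), d)]


def map_conserved_blocks(
    a: str,
    b: str,
    p: DotPlotParams = DotPlotParams(),
    min_run: int = 100,
    max_gap: int = 50,
) -> list[DiagonalRun]:
    """Conserved blocks between two haplotype sequences.

    Cross-comparison runs are reported in both coordinate systems (via
    ``a_start``/``b_start``); a change of diagonal between adjacent runs
    marks an insertion/deletion or shuffling breakpoint.
    """
    return diagonal_runs(dot_matches(a, b, p), min_run=min_run, max_gap=max_gap,
                         window=p.window)
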