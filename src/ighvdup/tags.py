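"""Sequence-tag selection and oligo design.

A sequence tag is a short (≤ 225 bp) non-coding window that occurs exactly
once in the region, assayed by multiplex PCR followed by a single-base
extension probe on a microarray.  Per tag, four oligos are designed:

* forward (F) and reverse (R) PCR primers at the tag ends,
* a nested (N) primer internal to F in the same orientation (drives
  single-strand DNA generation),
* a probe (P) internal and close to N but in the *reverse* orientation, whose
  3' end must sit next to an A or G template base so the single-base extension
  incorporates one of the two dye-labelled terminators (ddUTP for A, ddCTP
  for G).

Tags are named ``VHS`` + their start offset in kb, after the field's naming
convention for this locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .region import AnnotatedRegion, revcomp

_COMP = str.maketrans("ACGT", "TGCA")


class DesignError(ValueError):
    """No oligo placement satisfies the design rules within the tag."""


@dataclass(frozen=True)
class Tag:
    """A unique non-coding sequence tag (0-based half-open interval)."""

    name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class OligoSet:
    """The four oligos of one tag plus the extension-base bookkeeping.

    Oligo sequences are written 5'→3'.  ``extension_base`` is the template
    base immediately 3' of the probe's 3' end (A → ddUTP/Cy3 channel,
    G → ddCTP/Cy5 channel).  Footprint helpers return the interval content on
    the forward template strand, which is what detectability scanning matches
    against a haplotype sequence.
    """

    tag_name: str
    forward: str
    reverse: str
    nested: str
    probe: str
    extension_base: str

    def footprints(self) -> dict[str, str]:
        return {
            "forward": self.forward,
            "reverse": revcomp(self.reverse),
            "nested": self.nested,
            "probe": revcomp(self.probe),
        }


@dataclass(frozen=True)
class Conflict:
    """A primer pair whose 3' ends are mutually complementary."""

    oligo_a: str
    oligo_b: str
    score: int


@dataclass(frozen=True)
class SkippedInterval:
    """Warning record for a spacing interval with no usable tag window."""

    start: int
    end: int
    reason: str


@dataclass
class TagSelection:
    tags: list[Tag] = field(default_factory=list)
    skipped: list[SkippedInterval] = field(default_factory=list)


@dataclass(frozen=True)
class OligoConstraints:
    primer_len: tuple[int, int] = (18, 27)
    probe_len: tuple[int, int] = (20, 24)


def count_occurrences(
    subseq: str, region: AnnotatedRegion, max_mismatch: int = 0
) -> int:
    """Count forward-strand windows of ``region`` within ``max_mismatch``
    substitutions of ``subseq`` (overlapping; a self-occurrence counts)."""
    seq, m = region.seq, len(subseq)
    if m == 0 or m > len(seq):
        return 0
    if max_mismatch == 0:
        n = 0
        i = seq.find(subseq)
        while i != -1:
            n += 1
            i = seq.find(subseq, i + 1)
        return n
    n = 0
    for i in range(len(seq) - m + 1):
        mm = 0
        for a, b in zip(subseq, seq[i : i + m]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            n += 1
    return n


def _unique(window: str, seq: str) -> bool:
    first = seq.find(window)
    return first != -1 and seq.find(window, first + 1) == -1


def select_tags(
    region: AnnotatedRegion,
    spacing: int = 5000,
    max_len: int = 225,
    tag_len: int = 150,
    stride: int = 50,
    origin: int = 0,
) -> TagSelection:
    """Greedy left-to-right selection of unique non-coding tags.

    One tag is sought per ``spacing`` interval: the first window of
    ``tag_len`` bp past the interval boundary that overlaps no gene segment
    and occurs exactly once in the region.  Intervals with no such window
    (e.g. inside an exact tandem repeat) are skipped with a warning record.
    ``origin`` offsets the kb used in VHS names, for mimicking a larger
    assembly coordinate system.
    """
    if spacing <= max_len:
        raise ValueError("spacing must exceed max_len")
    tag_len = min(tag_len, max_len)
    genes = region.features_of("gene_segment")
    seq = region.seq
    sel = TagSelection()
    n_intervals = len(seq) // spacing
    for k in range(n_intervals):
        lo = k * spacing
        if sel.tags:  # keep consecutive tags at least half a spacing apart
            lo = max(lo, sel.tags[-1].start + spacing // 2)
        hi = min((k + 1) * spacing, len(seq) - tag_len)
        found = None
        pos = lo
        while pos <= hi:
            blocker = next(
                (g for g in genes if g.start < pos + tag_len and g.end > pos), None
            )
            if blocker is not None:
                pos = blocker.end
                continue
            if _unique(seq[pos : pos + tag_len], seq):
                found = pos
                break
            pos += stride
        if found is None:
            sel.skipped.append(
                SkippedInterval(k * spacing, (k + 1) * spacing,
                                "no unique non-coding window")
            )
        else:
            name = f"VHS{(origin + found) // 1000}"
            sel.tags.append(Tag(name, found, found + tag_len))
    return sel


def design_oligos(
    tag: Tag,
    region: AnnotatedRegion,
    constraints: OligoConstraints = OligoConstraints(),
    forward_len: int = 22,
    reverse_len: int = 22,
    nested_len: int = 21,
    probe_len: int = 21,
    gap: int = 2,
) -> OligoSet:
    """Place the four oligos inside one tag.

    F sits at the tag 5' end, R (reverse complement) at the 3' end, N starts
    ``gap`` bases past F.  The probe window is searched left-to-right from
    just past N for the first placement whose adjacent template base (one
    position 5' of the window on the template, templating the probe's 3'
    extension) is A or G.  Raises :class:`DesignError` if no placement exists.
    """
    for length, (lo, hi) in (
        (forward_len, constraints.primer_len),
        (reverse_len, constraints.primer_len),
        (nested_len, constraints.primer_len),
        (probe_len, constraints.probe_len),
    ):
        if not (lo <= length <= hi):
            raise ValueError(f"oligo length {length} outside allowed [{lo}, {hi}]")
    template = region.slice_seq(tag.start, tag.end)
    needed = forward_len + gap + nested_len + gap + probe_len + 1
    if len(template) < max(needed, reverse_len):
        raise DesignError(f"tag {tag.name}: too short for oligo layout")
    forward = template[:forward_len]
    reverse = revcomp(template[-reverse_len:])
    nested_start = forward_len + gap
    nested = template[nested_start : nested_start + nested_len]
    for p in range(nested_start + nested_len + gap, len(template) - probe_len + 1):
        ext = template[p - 1]
        if ext in "AG":
            probe = revcomp(template[p : p + probe_len])
            return OligoSet(tag.name, forward, reverse, nested, probe, ext)
    raise DesignError(f"tag {tag.name}: no probe site with an A/G extension base")


def _three_prime_comp_score(a: str, b: str) -> int:
    """Longest k such that the 3'-terminal k-mers of ``a`` and ``b`` anneal
    perfectly antiparallel, i.e. ``a[-k:] == revcomp(b[-k:])``."""
    best = 0
    for k in range(1, min(len(a), len(b)) + 1):
        if a[-k:] == revcomp(b[-k:]):
            best = k
    return best


def check_compatibility(
    oligos: list[OligoSet], threshold: int = 4
) -> list[Conflict]:
    """Screen all primers (F, R, N of every tag) for 3'-dimer potential.

    A pair is flagged when its 3'-terminal perfect complementary overlap
    reaches ``threshold``; a palindromic 3' end conflicts with itself.
    Reporting is symmetric (each unordered pair appears once).
    """
    primers: list[tuple[str, str]] = []
    for o in oligos:
        primers += [
            (f"{o.tag_name}:F", o.forward),
            (f"{o.tag_name}:R", o.reverse),
            (f"{o.tag_name}:N", o.nested),
        ]
    conflicts = []
    for i, (name_a, seq_a) in enumerate(primers):
        for name_b, seq_b in primers[i:]:
            score = _three_prime_comp_score(seq_a, seq_b)
            if score >= threshold:
                conflicts.append(Conflict(name_a, name_b, score))
    return conflicts
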