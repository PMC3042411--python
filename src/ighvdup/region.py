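"""Annotated genomic regions.

An :class:`AnnotatedRegion` is the package's central container: a nucleotide
sequence plus interval features (gene segments, exons, repeat-unit copies and
sequence tags).  Coordinates are 0-based, half-open throughout; BED export in
:mod:`ighvdup.io` shares this convention unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

VALID_BASES = frozenset("ACGT")
FEATURE_KINDS = frozenset({"gene_segment", "exon", "repeat_unit", "tag"})

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """One annotated interval.

    ``kind`` is one of ``gene_segment``, ``exon``, ``repeat_unit`` or ``tag``.
    Exon features name their parent gene segment via ``parent``.  The
    ``functional`` flag is meaningful for gene segments only (pseudogenes are
    ``functional=False``).
    """

    kind: str
    start: int
    end: int
    name: str
    strand: str = "+"
    functional: bool | None = None
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.name!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name!r}: bad strand {self.strand!r}")
        if self.kind == "exon" and self.parent is None:
            raise ValueError(f"exon {self.name!r} must reference a parent gene_segment")

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "Feature":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass
class AnnotatedRegion:
    """A named nucleotide sequence with interval features."""

    name: str
    seq: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check the container invariants; raise ``ValueError`` on violation."""
        if not self.seq:
            raise ValueError(f"region {self.name!r}: empty sequence")
        if not set(self.seq) <= VALID_BASES:
            bad = sorted(set(self.seq) - VALID_BASES)
            raise ValueError(f"region {self.name!r}: non-ACGT characters {bad}")
        genes = {f.name for f in self.features if f.kind == "gene_segment"}
        for f in self.features:
            if f.end > len(self.seq):
                raise ValueError(
                    f"region {self.name!r}: feature {f.name!r} interval "
                    f"[{f.start}, {f.end}) exceeds length {len(self.seq)}"
                )
            if f.kind == "exon" and f.parent not in genes:
                raise ValueError(
                    f"region {self.name!r}: exon {f.name!r} references missing "
                    f"gene segment {f.parent!r}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def features_of(self, kind: str) -> list[Feature]:
        """Features of one kind, sorted by start position."""
        return sorted(
            (f for f in self.features if f.kind == kind), key=lambda f: (f.start, f.end)
        )

    def slice_seq(self, start: int, end: int) -> str:
        if not (0 <= start <= end <= len(self.seq)):
            raise ValueError(f"interval [{start}, {end}) outside region {self.name!r}")
        return self.seq[start:end]
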