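"""Synthetic IGHV-like genomic material.

This module is the stand-in for the chromosome-14 region studied by sperm
typing: it builds an ancestral region with embedded gene segments, plants a
tandem segmental duplication (two complete copies plus one truncated copy),
and derives per-donor haplotype pairs that differ by deletion of repeat units
and by extra point divergence.

The generator is substitution-only by default so that every difference count
downstream is unambiguous; a single optional insertion element (mimicking a
transposon insertion private to one repeat copy) can be enabled per
duplication.  All randomness flows through explicit integer seeds; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .region import AnnotatedRegion, Feature

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

#: minimum spacer enforced between placed gene segments (and region edges)
MIN_SPACER = 100


class SizingError(ValueError):
    """Region too small for the requested gene-segment layout."""


@dataclass(frozen=True)
class GeneTemplate:
    """A gene-segment sequence with its exon layout.

    ``exons`` are intervals relative to the template start.  IGHV-style
    segments have a short leader exon and a long second exon; pseudogene
    templates carry ``functional=False``.
    """

    name: str
    seq: str
    exons: tuple[tuple[int, int], ...]
    functional: bool = True

    def __post_init__(self) -> None:
        for s, e in self.exons:
            if not (0 <= s < e <= len(self.seq)):
                raise ValueError(f"template {self.name!r}: exon [{s},{e}) out of range")


@dataclass(frozen=True)
class DuplicationSpec:
    """Parameters of a planted tandem duplication.

    ``per_copy_divergence`` is the substitution fraction applied independently
    to every emitted copy, so the expected pairwise divergence between two
    complete copies is roughly twice this value.
    """

    unit_length: int
    n_complete: int = 2
    partial_length: int = 0
    per_copy_divergence: float = 0.0
    seed: int = 0
    insertion_length: int = 0  # optional Alu-like insert in the first copy

    def __post_init__(self) -> None:
        if self.partial_length >= self.unit_length:
            raise ValueError("partial_length must be < unit_length")
        if not (0.0 <= self.per_copy_divergence < 1.0):
            raise ValueError("per_copy_divergence must be in [0, 1)")
        if self.n_complete < 1:
            raise ValueError("need at least one complete copy")


@dataclass(frozen=True)
class VariantSpec:
    """Per-haplotype edits applied by :func:`make_donor_haplotypes`."""

    delete_units: tuple[int, ...] = ()
    extra_divergence: float = 0.0


def random_seq(length: int, rng: np.random.Generator) -> str:
    """Uniform-composition random nucleotide string."""
    return rng.choice(_BASES, size=length).tobytes().decode()


def mutate(seq: str, sub_rate: float, seed: int) -> tuple[str, int]:
    """Apply point substitutions at ``sub_rate`` per position.

    Each position independently mutates with probability ``sub_rate``; a
    mutated base is drawn uniformly from the three alternatives, so the
    Hamming distance between input and output equals the returned count.
    """
    if not (0.0 <= sub_rate < 1.0):
        raise ValueError("sub_rate must be in [0, 1)")
    if sub_rate == 0.0 or not seq:
        return seq, 0
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < sub_rate
    idx = np.flatnonzero(hit)
    if idx.size:
        old = np.array([_BASE_INDEX[seq[i]] for i in idx])
        # shift by 1..3 in base space: never reproduces the original base
        new = (old + rng.integers(1, 4, size=idx.size)) % 4
        arr[idx] = _BASES[new]
    return arr.tobytes().decode(), int(idx.size)


def build_ancestral_region(
    length: int,
    gene_templates: list[GeneTemplate],
    seed: int,
    name: str = "region",
    offsets: list[int] | None = None,
) -> AnnotatedRegion:
    """Place gene segments non-overlapping in a random background.

    Segments keep their input order and are separated by pseudo-random spacers
    of at least :data:`MIN_SPACER` bp.  ``offsets`` pins segment start
    positions explicitly (still validated for spacing) — used when a
    downstream duplication needs genes at controlled locations.
    """
    total_genes = sum(len(t.seq) for t in gene_templates)
    min_len = total_genes + MIN_SPACER * (len(gene_templates) + 1)
    if length < min_len:
        raise SizingError(
            f"length {length} < minimum {min_len} for {len(gene_templates)} templates"
        )
    rng = np.random.default_rng(seed)
    if offsets is None:
        # distribute the slack over the spacer gaps
        slack = length - total_genes - MIN_SPACER * (len(gene_templates) + 1)
        cuts = np.sort(rng.integers(0, slack + 1, size=len(gene_templates)))
        extra = np.concatenate([cuts, [slack]]) - np.concatenate([[0], cuts])
        offsets = []
        pos = 0
        for i, t in enumerate(gene_templates):
            pos += MIN_SPACER + int(extra[i])
            offsets.append(pos)
            pos += len(t.seq)
    elif len(offsets) != len(gene_templates):
        raise ValueError("offsets must match gene_templates")

    seq = list(random_seq(length, rng))
    features: list[Feature] = []
    prev_end = 0
    for off, t in zip(offsets, gene_templates):
        if off < prev_end or off + len(t.seq) > length:
            raise SizingError(f"template {t.name!r} does not fit at offset {off}")
        seq[off : off + len(t.seq)] = t.seq
        features.append(
            Feature("gene_segment", off, off + len(t.seq), t.name, functional=t.functional)
        )
        for j, (es, ee) in enumerate(t.exons, start=1):
            features.append(
                Feature("exon", off + es, off + ee, f"{t.name}_ex{j}", parent=t.name)
            )
        prev_end = off + len(t.seq)
    return AnnotatedRegion(name, "".join(seq), features)


def _copy_features(
    features: list[Feature],
    unit_start: int,
    unit_end: int,
    new_start: int,
    limit: int,
    suffix: str,
) -> list[Feature]:
    """Replicate features fully inside [unit_start, unit_end) to a new copy.

    ``limit`` truncates the copy (partial copies replicate only features that
    fit).  Gene segments and their exons are renamed consistently.
    """
    out: list[Feature] = []
    renamed: dict[str, str] = {}
    for f in features:
        if f.kind == "repeat_unit":
            continue
        if f.start >= unit_start and f.end <= unit_end:
            rel_s, rel_e = f.start - unit_start, f.end - unit_start
            if rel_e > limit:
                continue
            new_name = f"{f.name}{suffix}"
            if f.kind == "gene_segment":
                renamed[f.name] = new_name
            out.append(
                replace(
                    f,
                    start=new_start + rel_s,
                    end=new_start + rel_e,
                    name=new_name,
                    parent=renamed.get(f.parent, f.parent) if f.parent else None,
                )
            )
    # exons whose parent gene was truncated away are dropped
    kept_genes = {f.name for f in out if f.kind == "gene_segment"}
    return [f for f in out if f.kind != "exon" or f.parent in kept_genes]


def plant_duplication(
    region: AnnotatedRegion, unit_span: tuple[int, int], spec: DuplicationSpec
) -> AnnotatedRegion:
    """Replace ``unit_span`` with a tandem array of diverged copies.

    The span is expanded into ``n_complete`` full copies followed by one
    truncated copy of ``partial_length`` bp (if non-zero).  Every copy is
    independently mutated at ``per_copy_divergence``; each is annotated with a
    ``repeat_unit`` feature and its internal gene segments are replicated with
    ``.1``, ``.2``, ... name suffixes.  Features straddling the span boundary
    are rejected.
    """
    start, end = unit_span
    if not (0 <= start < end <= len(region)):
        raise ValueError(f"unit_span {unit_span} outside region")
    if end - start != spec.unit_length:
        raise ValueError("unit_span length must equal spec.unit_length")
    for f in region.features:
        if (f.start < start < f.end) or (f.start < end < f.end):
            raise ValueError(f"feature {f.name!r} straddles the duplication boundary")

    unit = region.seq[start:end]
    rng = np.random.default_rng(spec.seed)
    pieces: list[str] = []
    features: list[Feature] = [
        f for f in region.features if f.end <= start and f.kind != "repeat_unit"
    ]
    pos = start
    n_copies = spec.n_complete + (1 if spec.partial_length else 0)
    for k in range(n_copies):
        is_partial = k >= spec.n_complete
        limit = spec.partial_length if is_partial else spec.unit_length
        copy_seq, _ = mutate(unit[:limit], spec.per_copy_divergence,
                             int(rng.integers(0, 2**31)))
        if k == 0 and spec.insertion_length:
            ins_at = limit // 2
            insert = random_seq(spec.insertion_length, rng)
            copy_seq = copy_seq[:ins_at] + insert + copy_seq[ins_at:]
        features.extend(
            _copy_features(region.features, start, end, pos, limit, f".{k + 1}")
        )
        features.append(
            Feature("repeat_unit", pos, pos + len(copy_seq),
                    f"{region.name}_repeat{k + 1}")
        )
        pieces.append(copy_seq)
        pos += len(copy_seq)
    shift = pos - end
    features.extend(
        f.shifted(shift)
        for f in region.features
        if f.start >= end and f.kind != "repeat_unit"
    )
    new_seq = region.seq[:start] + "".join(pieces) + region.seq[end:]
    return AnnotatedRegion(region.name, new_seq, features)


def _mutate_spans(
    region: AnnotatedRegion, spans: list[tuple[int, int]], rate: float, seed: int
) -> AnnotatedRegion:
    """Substitute within the given spans only; coordinates are unchanged."""
    seq = list(region.seq)
    rng = np.random.default_rng(seed)
    for s, e in spans:
        mutated, _ = mutate("".join(seq[s:e]), rate, int(rng.integers(0, 2**31)))
        seq[s:e] = mutated
    return AnnotatedRegion(region.name, "".join(seq), list(region.features))


def _delete_span(region: AnnotatedRegion, start: int, end: int) -> AnnotatedRegion:
    """Remove [start, end); drop contained features and shift downstream ones."""
    gap = end - start
    kept: list[Feature] = []
    for f in region.features:
        if f.end <= start:
            kept.append(f)
        elif f.start >= end:
            kept.append(f.shifted(-gap))
        # features overlapping the deleted span are dropped entirely
    genes = {f.name for f in kept if f.kind == "gene_segment"}
    kept = [f for f in kept if f.kind != "exon" or f.parent in genes]
    return AnnotatedRegion(region.name, region.seq[:start] + region.seq[end:], kept)


def make_donor_haplotypes(
    region: AnnotatedRegion,
    variant_specs: tuple[VariantSpec, VariantSpec],
    seed: int,
) -> tuple[AnnotatedRegion, AnnotatedRegion]:
    """Derive a donor's two haplotypes from the reference region.

    Each :class:`VariantSpec` deletes whole repeat-unit copies (by 0-based
    index in genomic order) and/or applies extra point divergence within the
    remaining repeat-unit spans — the two mechanisms by which sequence tags
    become undetectable (deletion vs divergence of primer/probe sites).
    """
    rng = np.random.default_rng(seed)
    haps = []
    for h, vs in enumerate(variant_specs, start=1):
        hap = AnnotatedRegion(f"{region.name}_H{h}", region.seq, list(region.features))
        units = hap.features_of("repeat_unit")
        for idx in vs.delete_units:
            if idx < 0 or idx >= len(units):
                raise ValueError(
                    f"delete_units index {idx} not present ({len(units)} copies)"
                )
        # delete right-to-left so earlier spans stay valid
        for idx in sorted(set(vs.delete_units), reverse=True):
            u = units[idx]
            hap = _delete_span(hap, u.start, u.end)
            hap.name = f"{region.name}_H{h}"
            units = hap.features_of("repeat_unit")
        if vs.extra_divergence:
            spans = [(u.start, u.end) for u in hap.features_of("repeat_unit")]
            hap = _mutate_spans(hap, spans, vs.extra_divergence,
                                int(rng.integers(0, 2**31)))
        else:
            _ = rng.integers(0, 2**31)  # keep the seed stream aligned
        haps.append(hap)
    return haps[0], haps[1]


def default_gene_templates(seed: int = 7) -> list[GeneTemplate]:
    """IGHV-like gene-segment templates for the default study region.

    Six segments destined for the duplicated unit — one functional IGHV4-like
    and one functional IGHV3-like segment plus two pseudogenes per family,
    mirroring the observed six-segments-per-complete-copy layout — and two
    flanking segments that stay single-copy.  Exon layout: ~46 bp leader exon,
    ~85 bp intron, long second exon; exon total ≈ 355 bp for full segments.
    """
    rng = np.random.default_rng(seed)

    def tmpl(name: str, length: int, functional: bool, truncated: bool = False):
        seq = random_seq(length, rng)
        if truncated:  # truncated pseudogene: leader exon only survives
            exons = ((0, 46),)
        else:
            exons = ((0, 46), (131, min(length, 131 + 309)))
        return GeneTemplate(name, seq, exons, functional=functional)

    return [
        tmpl("V4-27", 438, True),          # flanking, single copy
        tmpl("V4-28", 438, True),          # inside unit (→ .1/.2/.3 copies)
        tmpl("V4-28.1P", 253, False, truncated=True),
        tmpl("V3-29P", 458, False),
        tmpl("V3-30", 454, True),
        tmpl("V4-30.1P", 274, False, truncated=True),
        tmpl("V3-30.2P", 449, False),
        tmpl("V4-35", 438, True),          # flanking, single copy
    ]
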