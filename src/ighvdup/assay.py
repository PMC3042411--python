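"""Single-sperm tag assay: simulation, genotype calling and phasing.

Sperm are haploid, so the two parental haplotypes of a donor segregate into
different cells and can be read directly: clustering the per-sperm
presence/absence vectors of the sequence tags into two groups recovers the
two haplotypes without any pedigree.  This module provides

* :func:`tag_detectability` — whether a tag's oligo set would yield signal on
  a given haplotype sequence (deletion or primer/probe divergence both break
  detection),
* :func:`simulate_sperm_panel` — a noisy panel of single-sperm observations,
* :func:`phase_sperm` — two-cluster phasing with per-tag consensus calls
  using the field's three-symbol alphabet ``+`` (detected), ``ud``
  (undetectable) and ``-`` (unresolved),
* downstream summaries: per-tag polymorphism classes, runs of consecutive
  undetectable tags, and delimitation of the polymorphic region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .region import AnnotatedRegion
from .tags import OligoSet

#: statuses counted as "not detected" in run/region logic; '-' (unresolved)
#: is kept distinct in output but treated as undetectable here.
UNDETECTED_STATUSES = frozenset({"ud", "-"})


class InsufficientDataError(ValueError):
    """Too few sperm to support a two-cluster phasing."""


@dataclass(frozen=True)
class NoiseModel:
    """Binary observation noise of the single-sperm assay.

    ``dropout`` is the probability that a truly detectable tag reads
    undetected in one sperm (allele dropout of single-cell multiplex PCR);
    ``false_positive`` the probability that a truly absent tag reads detected
    (contamination / cross-hybridisation).
    """

    dropout: float = 0.05
    false_positive: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.dropout, self.false_positive):
            if not (0.0 <= v < 1.0):
                raise ValueError("noise probabilities must be in [0, 1)")


@dataclass(frozen=True)
class DetectionRules:
    """Mismatch tolerances of :func:`tag_detectability`.

    ``max_mismatch`` — maximum edit distance tolerated per oligo footprint;
    ``three_prime_window`` / ``three_prime_max`` — window at each primer's 3'
    terminus and the mismatches tolerated inside it (extension from a
    mismatched 3' end fails even when the overall primer still anneals).
    """

    max_mismatch: int = 1
    three_prime_window: int = 4
    three_prime_max: int = 0


@dataclass
class GenotypeMatrix:
    """Sperm × tags presence/absence observations for one donor."""

    donor: str
    sperm_ids: list[str]
    tags: list[str]
    detected: np.ndarray  # bool, shape (n_sperm, n_tags)

    def __post_init__(self) -> None:
        self.detected = np.asarray(self.detected, dtype=bool)
        if self.detected.shape != (len(self.sperm_ids), len(self.tags)):
            raise ValueError("matrix shape does not match sperm/tag labels")
        if len(self.sperm_ids) < 1:
            raise ValueError("need at least one sperm")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.detected.astype(int), index=self.sperm_ids, columns=self.tags
        )


@dataclass(frozen=True)
class TagSupport:
    n_detected: int
    n_assigned: int


@dataclass
class HaplotypeCall:
    """Per-tag consensus statuses for one inferred parental haplotype."""

    donor: str
    label: str  # H1 or H2
    statuses: dict[str, str]  # tag name -> '+', 'ud' or '-'
    support: dict[str, TagSupport] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s for s in self.statuses.values()} - {"+", "ud", "-"}
        if bad:
            raise ValueError(f"invalid statuses {sorted(bad)}")

    def pattern(self, ordered_tags: list[str]) -> tuple[str, ...]:
        return tuple(self.statuses[t] for t in ordered_tags)


@dataclass(frozen=True)
class Run:
    """A maximal run of consecutive undetectable tags."""

    start_tag: str
    end_tag: str
    length: int


@dataclass(frozen=True)
class SimTruth:
    """Ground truth kept aside by the simulator, for evaluation only."""

    assignments: tuple[str, ...]  # per-sperm H1/H2
    patterns: dict[str, tuple[bool, ...]]  # haplotype -> per-tag detectability


def _best_hit(footprint: str, seq: str) -> tuple[int, tuple[int, int] | None]:
    res = edlib.align(footprint, seq, mode="HW", task="locations")
    locs = res["locations"]
    return res["editDistance"], (locs[0] if locs else None)


def tag_detectability(
    tag_oligos: OligoSet,
    haplotype_seq: str | AnnotatedRegion,
    rules: DetectionRules = DetectionRules(),
) -> bool:
    """Decide whether a tag yields signal on one haplotype sequence.

    The tag is *undetectable* when (a) any oligo footprint has no match in
    the haplotype within ``rules.max_mismatch`` edits, (b) the template base
    adjacent to the probe's 3' end is no longer the designed A/G extension
    base, or (c) a primer's 3'-terminal window carries more than
    ``rules.three_prime_max`` mismatches.  Returns True when detectable.
    """
    seq = haplotype_seq.seq if isinstance(haplotype_seq, AnnotatedRegion) else haplotype_seq
    fp = tag_oligos.footprints()
    hits: dict[str, tuple[int, int] | None] = {}
    for name, foot in fp.items():
        dist, loc = _best_hit(foot, seq)
        if dist < 0 or dist > rules.max_mismatch or loc is None:
            return False
        hits[name] = loc

    w = rules.three_prime_window
    for primer, three_prime_left in (("forward", False), ("reverse", True),
                                     ("nested", False)):
        foot = fp[primer]
        start, end = hits[primer]
        segment = seq[start : end + 1]
        if len(segment) != len(foot):  # indel alignment: treat as failed 3' end
            return False
        window = slice(0, w) if three_prime_left else slice(len(foot) - w, len(foot))
        mism = sum(a != b for a, b in zip(foot[window], segment[window]))
        if mism > rules.three_prime_max:
            return False

    # extension-base rule: the base 5' of the probe footprint on the template
    p_start, _ = hits["probe"]
    if p_start == 0 or seq[p_start - 1] != tag_oligos.extension_base:
        return False
    return True


def simulate_sperm_panel(
    hap_pair: tuple[AnnotatedRegion, AnnotatedRegion],
    tags: list[OligoSet],
    n_sperm: int,
    noise: NoiseModel,
    donor: str = "donor",
    rules: DetectionRules = DetectionRules(),
) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a noisy single-sperm panel for one donor.

    Each sperm carries H1 or H2 with probability 1/2; its true call per tag
    comes from :func:`tag_detectability` on that haplotype, then dropout and
    false-positive noise flip entries independently.  The hidden truth is
    returned separately and must only be used for evaluation.
    """
    rng = np.random.default_rng(noise.seed)
    patterns = {
        f"H{i + 1}": tuple(tag_detectability(o, hap.seq, rules) for o in tags)
        for i, hap in enumerate(hap_pair)
    }
    labels = list(patterns)
    assign = rng.integers(0, 2, size=n_sperm)
    truth_rows = np.array([patterns[labels[a]] for a in assign], dtype=bool)
    flip_up = rng.random(truth_rows.shape) < noise.false_positive
    flip_down = rng.random(truth_rows.shape) < noise.dropout
    observed = np.where(truth_rows, ~flip_down, flip_up)
    matrix = GenotypeMatrix(
        donor=donor,
        sperm_ids=[f"{donor}_s{i + 1}" for i in range(n_sperm)],
        tags=[o.tag_name for o in tags],
        detected=observed,
    )
    return matrix, SimTruth(tuple(labels[a] for a in assign), patterns)


def _consensus(
    rows: np.ndarray, tags: list[str], consensus_frac: float, min_support: int
) -> tuple[dict[str, str], dict[str, TagSupport]]:
    n = rows.shape[0]
    statuses, support = {}, {}
    for j, t in enumerate(tags):
        det = int(rows[:, j].sum())
        support[t] = TagSupport(det, n)
        if n < min_support:
            statuses[t] = "-"
        elif det / n >= consensus_frac:
            statuses[t] = "+"
        elif (n - det) / n >= consensus_frac:
            statuses[t] = "ud"
        else:
            statuses[t] = "-"
    return statuses, support


def phase_sperm(
    m: GenotypeMatrix,
    min_support: int = 5,
    consensus_frac: float = 0.7,
    max_iter: int = 100,
) -> tuple[tuple[HaplotypeCall, HaplotypeCall], list[str]]:
    """Partition sperm into two haplotype clusters and call consensuses.

    Clusters are seeded with the most dissimilar pair of call vectors and
    refined by nearest-centroid reassignment until convergence.  Per tag and
    cluster the consensus is ``+`` when at least ``consensus_frac`` of the
    assigned sperm detected the tag, ``ud`` when at least that fraction did
    not, and ``-`` (unresolved) otherwise or when the cluster is smaller than
    ``min_support``.  If the panel contains no dissimilarity at all, both
    haplotypes report the common pattern.
    """
    X = m.detected.astype(float)
    n = X.shape[0]
    if n < 2 * min_support:
        raise InsufficientDataError(
            f"{n} sperm < 2×min_support ({2 * min_support}) for donor {m.donor}"
        )
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    if d2.max() == 0:  # all rows identical: one pattern, reported twice
        statuses, support = _consensus(m.detected, m.tags, consensus_frac, min_support)
        calls = tuple(
            HaplotypeCall(m.donor, lab, dict(statuses), dict(support))
            for lab in ("H1", "H2")
        )
        return calls, ["H1"] * n

    def refine(seed_pair: tuple[int, int]) -> tuple[np.ndarray, float]:
        centroids = np.stack([X[seed_pair[0]], X[seed_pair[1]]])
        assign = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            dist = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            new_assign = dist.argmin(axis=1)
            for c in (0, 1):  # never let a cluster die
                if not (new_assign == c).any():
                    new_assign[dist[:, 1 - c].argmax()] = c
            if (new_assign == assign).all():
                break
            assign = new_assign
            centroids = np.stack([X[assign == c].mean(axis=0) for c in (0, 1)])
        dispersion = float(
            sum(
                ((X[assign == c] - X[assign == c].mean(axis=0)) ** 2).sum()
                for c in (0, 1)
            )
        )
        return assign, dispersion

    # a single most-dissimilar pair can seed a noise-driven local optimum;
    # restart from the few most separated pairs and keep the tightest result
    flat_order = np.argsort(d2, axis=None)[::-1]
    seen, seeds = set(), []
    for idx in flat_order:
        i, j = np.unravel_index(int(idx), d2.shape)
        if i >= j or d2[i, j] == 0:
            continue
        key = (int(i), int(j))
        if key not in seen:
            seen.add(key)
            seeds.append(key)
        if len(seeds) == 5:
            break
    assign, _ = min((refine(s) for s in seeds), key=lambda t: t[1])

    # Balanced-segregation check: the two haplotypes of a heterozygous donor
    # segregate 1:1 into gametes, so a genuine cluster holds about half the
    # panel.  A cluster below 20% of sperm (or below min_support) marks a
    # bipartition driven by correlated noise, no better than a single
    # cluster: both haplotypes then report the common pattern.
    smallest = min(int((assign == c).sum()) for c in (0, 1))
    if smallest < max(min_support, int(np.ceil(0.2 * n))):
        statuses, support = _consensus(m.detected, m.tags, consensus_frac, min_support)
        calls = tuple(
            HaplotypeCall(m.donor, lab, dict(statuses), dict(support))
            for lab in ("H1", "H2")
        )
        return calls, ["H1"] * n

    # deterministic labelling: the cluster containing the first sperm is H1
    order = (0, 1) if assign[0] == 0 else (1, 0)
    calls = []
    for lab, c in zip(("H1", "H2"), order):
        statuses, support = _consensus(
            m.detected[assign == c], m.tags, consensus_frac, min_support
        )
        calls.append(HaplotypeCall(m.donor, lab, statuses, support))
    label_of = {order[0]: "H1", order[1]: "H2"}
    return (calls[0], calls[1]), [label_of[int(a)] for a in assign]


def classify_tags(calls: list[HaplotypeCall]) -> dict[str, str]:
    """Classify every tag across haplotypes.

    ``undetectable_in_all`` — literally ``ud`` in every haplotype;
    ``polymorphic`` — detection status differs between haplotypes (``-``
    counts as undetected); otherwise ``non_polymorphic_detected``.
    """
    if len(calls) < 2:
        raise ValueError("classification needs at least two haplotypes")
    tags = list(calls[0].statuses)
    out = {}
    for t in tags:
        statuses = [c.statuses[t] for c in calls]
        if all(s == "ud" for s in statuses):
            out[t] = "undetectable_in_all"
        elif len({s in UNDETECTED_STATUSES for s in statuses}) > 1:
            out[t] = "polymorphic"
        else:
            out[t] = "non_polymorphic_detected"
    return out


def find_undetectable_runs(
    call: HaplotypeCall, ordered_tags: list[str]
) -> list[Run]:
    """Maximal runs of consecutive undetectable (``ud`` or ``-``) tags."""
    runs: list[Run] = []
    run_start = None
    for i, t in enumerate(ordered_tags + [None]):  # sentinel flushes last run
        undet = t is not None and call.statuses[t] in UNDETECTED_STATUSES
        if undet and run_start is None:
            run_start = i
        elif not undet and run_start is not None:
            runs.append(
                Run(ordered_tags[run_start], ordered_tags[i - 1], i - run_start)
            )
            run_start = None
    return runs


@dataclass(frozen=True)
class PolymorphicRegion:
    """Minimal tag interval covering all polymorphic tags, with the nearest
    flanking detected non-polymorphic tags on either side (None if absent)."""

    first_tag: str | None
    last_tag: str | None
    flank_left: str | None
    flank_right: str | None


def delimit_polymorphic_region(
    classes: dict[str, str], ordered_tags: list[str]
) -> PolymorphicRegion:
    poly_idx = [i for i, t in enumerate(ordered_tags) if classes[t] == "polymorphic"]
    if not poly_idx:
        return PolymorphicRegion(None, None, None, None)
    lo, hi = poly_idx[0], poly_idx[-1]
    flank_left = next(
        (ordered_tags[i] for i in range(lo - 1, -1, -1)
         if classes[ordered_tags[i]] == "non_polymorphic_detected"),
        None,
    )
    flank_right = next(
        (ordered_tags[i] for i in range(hi + 1, len(ordered_tags))
         if classes[ordered_tags[i]] == "non_polymorphic_detected"),
        None,
    )
    return PolymorphicRegion(ordered_tags[lo], ordered_tags[hi], flank_left, flank_right)
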