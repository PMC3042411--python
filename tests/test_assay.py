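"""Detectability rules, panel simulation statistics, phasing behaviour and
the Table-2-style summaries (classification, runs, region delimitation)."""

import numpy as np
import pytest

from ighvdup.assay import (GenotypeMatrix, HaplotypeCall, InsufficientDataError,
                           NoiseModel, classify_tags,
                           delimit_polymorphic_region, find_undetectable_runs,
                           phase_sperm, simulate_sperm_panel, tag_detectability)
from ighvdup.datasets import TAG_ORDER, sperm_panel_calls
from ighvdup.region import AnnotatedRegion, revcomp
from ighvdup.synthetic import random_seq
from ighvdup.tags import Tag, design_oligos


@pytest.fixture(scope="module")
def designed():
    rng = np.random.default_rng(42)
    seq = random_seq(600, rng)
    region = AnnotatedRegion("r", seq)
    tag = Tag("VHS0", 100, 250)
    oligos = design_oligos(tag, region)
    return region, tag, oligos


def mutate_at(seq: str, pos: int, rng=None) -> str:
    new = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
    return seq[:pos] + new + seq[pos + 1 :]


class TestTagDetectability:
    def test_design_template_is_detectable(self, designed):
        region, _, oligos = designed
        assert tag_detectability(oligos, region.seq)

    def test_two_base_probe_substitution_breaks_detection(self, designed):
        # a two-base change in the middle of the probe footprint exceeds the
        # one-mismatch tolerance
        region, tag, oligos = designed
        template = region.seq[tag.start : tag.end]
        p = tag.start + template.index(revcomp(oligos.probe))
        mid = p + len(oligos.probe) // 2
        seq = mutate_at(mutate_at(region.seq, mid), mid + 1)
        assert not tag_detectability(oligos, seq)

    def test_single_probe_mismatch_tolerated(self, designed):
        region, tag, oligos = designed
        template = region.seq[tag.start : tag.end]
        p = tag.start + template.index(revcomp(oligos.probe))
        seq = mutate_at(region.seq, p + len(oligos.probe) // 2)
        assert tag_detectability(oligos, seq)

    def test_mutated_extension_base_breaks_detection(self, designed):
        # the extension-template base alone decides the labelling reaction
        region, tag, oligos = designed
        template = region.seq[tag.start : tag.end]
        p = tag.start + template.index(revcomp(oligos.probe))
        seq = mutate_at(region.seq, p - 1)
        assert seq[p - 1] != oligos.extension_base
        assert not tag_detectability(oligos, seq)

    def test_three_prime_primer_mismatch_breaks_detection(self, designed):
        region, tag, oligos = designed
        # last base of the forward primer footprint
        seq = mutate_at(region.seq, tag.start + len(oligos.forward) - 1)
        assert not tag_detectability(oligos, seq)

    def test_deleted_tag_region_undetectable(self, designed):
        region, tag, oligos = designed
        seq = region.seq[: tag.start] + region.seq[tag.end :]
        assert not tag_detectability(oligos, seq)


def _two_hap_panel(rng_seed=0, n_sperm=60, dropout=0.0, fp=0.0):
    rng = np.random.default_rng(7)
    seq = random_seq(2500, rng)
    region = AnnotatedRegion("r", seq)
    tags = [Tag(f"T{s}", s, s + 150) for s in (100, 700, 1300, 1900)]
    oligos = [design_oligos(t, region) for t in tags]
    h1 = AnnotatedRegion("r_H1", seq)
    # haplotype 2 loses the middle two tags (deletion of a 1 kb block)
    h2 = AnnotatedRegion("r_H2", seq[:600] + seq[1600:])
    noise = NoiseModel(dropout=dropout, false_positive=fp, seed=rng_seed)
    return simulate_sperm_panel((h1, h2), oligos, n_sperm, noise, donor="d")


class TestSimulateSpermPanel:
    def test_noise_free_panel_has_two_row_patterns(self):
        matrix, truth = _two_hap_panel()
        patterns = {tuple(row) for row in matrix.detected}
        assert patterns == {(True,) * 4, (True, False, False, True)}

    def test_truth_patterns_match_rows(self):
        matrix, truth = _two_hap_panel()
        for row, lab in zip(matrix.detected, truth.assignments):
            assert tuple(row) == truth.patterns[lab]

    def test_dropout_rate_binomial(self):
        # flipped detectable entries across seeds ~ Binomial(n, 0.05)
        flipped = total = 0
        for seed in range(100):
            matrix, truth = _two_hap_panel(rng_seed=seed, dropout=0.05)
            truth_rows = np.array([truth.patterns[a] for a in truth.assignments])
            flipped += int((truth_rows & ~matrix.detected).sum())
            total += int(truth_rows.sum())
        p_hat = flipped / total
        sd = np.sqrt(0.05 * 0.95 / total)
        assert abs(p_hat - 0.05) < 3 * sd


class TestPhaseSperm:
    def test_trivial_four_sperm_panel(self):
        rows = np.array(
            [[1, 1, 1, 1], [1, 0, 0, 1], [1, 1, 1, 1], [1, 0, 0, 1]], dtype=bool
        )
        m = GenotypeMatrix("d", [f"s{i}" for i in range(4)],
                           ["t1", "t2", "t3", "t4"], rows)
        (h1, h2), assign = phase_sperm(m, min_support=1, consensus_frac=0.7)
        patterns = {h1.pattern(m.tags), h2.pattern(m.tags)}
        assert patterns == {("+", "+", "+", "+"), ("+", "ud", "ud", "+")}
        assert assign[0] != assign[1] and assign[0] == assign[2]

    def test_label_symmetry_and_exact_recovery_no_noise(self):
        matrix, truth = _two_hap_panel()
        (h1, h2), assign = phase_sperm(matrix)
        want = {
            tuple("+" if d else "ud" for d in truth.patterns[lab])
            for lab in ("H1", "H2")
        }
        assert {h1.pattern(matrix.tags), h2.pattern(matrix.tags)} == want

    def test_noisy_recovery(self):
        ok = 0
        for seed in range(30):
            matrix, truth = _two_hap_panel(rng_seed=seed, n_sperm=60,
                                           dropout=0.05, fp=0.01)
            (h1, h2), _ = phase_sperm(matrix)
            want = {
                tuple("+" if d else "ud" for d in truth.patterns[lab])
                for lab in ("H1", "H2")
            }
            ok += {h1.pattern(matrix.tags), h2.pattern(matrix.tags)} == want
        assert ok >= 28

    def test_homozygous_panel_reports_common_pattern_twice(self):
        rng = np.random.default_rng(3)
        seq = random_seq(1200, rng)
        region = AnnotatedRegion("r", seq)
        tags = [Tag("VHS0", 100, 250), Tag("VHS0b", 700, 850)]
        oligos = [design_oligos(t, region) for t in tags]
        noise = NoiseModel(dropout=0.05, false_positive=0.01, seed=11)
        matrix, _ = simulate_sperm_panel((region, region), oligos, 50, noise)
        (h1, h2), _ = phase_sperm(matrix)
        assert h1.statuses == h2.statuses == {"VHS0": "+", "VHS0b": "+"}

    def test_too_few_sperm_rejected(self):
        rows = np.ones((6, 3), dtype=bool)
        m = GenotypeMatrix("d", [f"s{i}" for i in range(6)], ["a", "b", "c"], rows)
        with pytest.raises(InsufficientDataError):
            phase_sperm(m, min_support=5)


class TestReferencePanelLogic:
    """The published 17-tag × 12-haplotype genotype panel drives the
    classification, run-finding and delimitation logic."""

    def test_classification(self):
        classes = classify_tags(sperm_panel_calls())
        assert {t for t, c in classes.items() if c == "polymorphic"} == {
            "VHS468", "VHS475", "VHS485", "VHS493", "VHS499", "VHS510"
        }
        assert {t for t, c in classes.items() if c == "undetectable_in_all"} == {
            "VHS458", "VHS479", "VHS504"
        }

    def test_four_of_twelve_haplotypes_have_runs_of_two_or_more(self):
        calls = sperm_panel_calls()
        qualifying = [
            f"{c.donor}/{c.label}"
            for c in calls
            if any(r.length >= 2 for r in find_undetectable_runs(c, TAG_ORDER))
        ]
        assert len(calls) == 12 and len(qualifying) == 4
        assert set(qualifying) == {"#12/H1", "#12/H2", "AB027/H2", "D18/H1"}

    def test_run_structure_of_fully_deleted_haplotype(self):
        # haplotype 1 of the second donor: runs of length 1 (VHS458) and 8
        # (VHS468 through VHS510), the whole polymorphic region
        call = next(c for c in sperm_panel_calls()
                    if c.donor == "#12" and c.label == "H1")
        runs = {(r.start_tag, r.end_tag, r.length)
                for r in find_undetectable_runs(call, TAG_ORDER)}
        assert ("VHS458", "VHS458", 1) in runs
        assert ("VHS468", "VHS510", 8) in runs

    def test_smallest_variable_haplotype_has_run_of_two(self):
        call = next(c for c in sperm_panel_calls()
                    if c.donor == "D18" and c.label == "H1")
        assert max(r.length for r in find_undetectable_runs(call, TAG_ORDER)) == 2

    def test_all_detected_column_has_no_runs(self):
        call = next(c for c in sperm_panel_calls()
                    if c.donor == "#002" and c.label == "H1")
        runs = find_undetectable_runs(call, TAG_ORDER)
        assert all(r.length == 1 for r in runs)  # only the three ud-in-all tags

    def test_delimitation_and_flanks(self):
        classes = classify_tags(sperm_panel_calls())
        span = delimit_polymorphic_region(classes, TAG_ORDER)
        assert (span.first_tag, span.last_tag) == ("VHS468", "VHS510")
        assert (span.flank_left, span.flank_right) == ("VHS462", "VHS514")

    def test_no_polymorphic_tags_yields_empty_interval(self):
        calls = [
            HaplotypeCall("d", lab, {"a": "+", "b": "+"}) for lab in ("H1", "H2")
        ]
        classes = classify_tags(calls)
        span = delimit_polymorphic_region(classes, ["a", "b"])
        assert span.first_tag is None and span.last_tag is None

    def test_single_polymorphic_tag_interval_of_one(self):
        calls = [
            HaplotypeCall("d", "H1", {"a": "+", "b": "+"}),
            HaplotypeCall("d", "H2", {"a": "+", "b": "ud"}),
        ]
        span = delimit_polymorphic_region(classify_tags(calls), ["a", "b"])
        assert span.first_tag == span.last_tag == "b"

    def test_classification_needs_two_haplotypes(self):
        with pytest.raises(ValueError):
            classify_tags([HaplotypeCall("d", "H1", {"a": "+"})])
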