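"""Alignment counting conventions, printed-table arithmetic, per-1,200-bp
translation, ORF scanning and divergence-table assembly."""

from functools import lru_cache

import numpy as np
import pytest

from ighvdup.datasets import ALLELIC_POOLED, DIVERGENCE_ROWS
from ighvdup.divergence import (Alignment, DivergenceConfig, Scoring,
                                build_divergence_table, count_differences,
                                global_align, orf_status, per_1200,
                                percent_difference)
from ighvdup.synthetic import mutate, random_seq


def oracle_score(a: str, b: str, s: Scoring) -> float:
    """Exhaustive global alignment score by plain recursion (tiny inputs).

    Gap cost is affine: open + (length-1)*extend, tracked via a state flag.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            sub = s.match if a[i] == b[j] else s.mismatch
            options.append(sub + best(i + 1, j + 1, "m"))
        if i < len(a):
            cost = s.gap_extend if state == "ga" else s.gap_open
            options.append(cost + best(i + 1, j, "ga"))
        if j < len(b):
            cost = s.gap_extend if state == "gb" else s.gap_open
            options.append(cost + best(i, j + 1, "gb"))
        return max(options)

    return best(0, 0, "m")


class TestGlobalAlign:
    def test_identical_sequences(self):
        al = global_align("ACGTACGT", "ACGTACGT")
        assert al.n_substitutions == 0 and al.n_indel_events == 0

    def test_single_substitution(self):
        al = global_align("ACGT", "ACTT")
        assert al.n_substitutions == 1 and al.n_indel_events == 0

    def test_score_matches_recursive_oracle_on_short_pairs(self, rng):
        scoring = Scoring()
        for seed in range(10):
            a = random_seq(12, np.random.default_rng(seed))
            b = mutate(a, 0.15, seed)[0]
            if seed % 2:
                b = b[:5] + b[7:]  # throw in a deletion
            al = global_align(a, b, scoring)
            assert al.score == pytest.approx(oracle_score(a, b, scoring))

    def test_gap_removal_recovers_inputs(self, rng):
        a, b = random_seq(60, rng), random_seq(55, rng)
        al = global_align(a, b)
        assert al.aligned_a.replace("-", "") == a
        assert al.aligned_b.replace("-", "") == b


class TestCountDifferences:
    aln = Alignment("ACGTACG---T", "ATGTACGCCCT", score=0.0)

    def test_conventions(self):
        # 1 substitution (C->T at column 2) and one 3-column gap
        assert count_differences(self.aln, "subs_only") == 1
        assert count_differences(self.aln, "subs_plus_indel_events") == 2
        assert count_differences(self.aln, "subs_plus_indel_columns") == 4

    def test_identical_zero_under_all_conventions(self):
        al = global_align("ACGTAC", "ACGTAC")
        for conv in ("subs_only", "subs_plus_indel_events",
                     "subs_plus_indel_columns"):
            assert count_differences(al, conv) == 0

    def test_gap_free_equals_hamming(self, rng):
        a = random_seq(80, rng)
        b, n = mutate(a, 0.05, 3)
        al = global_align(a, b)
        assert count_differences(al, "subs_only") == n


class TestPrintedTableArithmetic:
    """The published difference table reproduces exactly from its printed
    (difference, length) cells under two-decimal half-up rounding."""

    @pytest.mark.parametrize(
        "diff,denom,expected",
        [(29, 438, 6.62), (1, 454, 0.22), (19, 438, 4.34), (39, 2245, 1.74)],
    )
    def test_headline_cells(self, diff, denom, expected):
        assert percent_difference(diff, denom) == expected

    @pytest.mark.parametrize("row", DIVERGENCE_ROWS,
                             ids=lambda r: f"{r.name_a}-{r.name_b}-{r.percent}")
    def test_every_row_reproduces(self, row):
        assert percent_difference(row.diff, row.denominator) == row.percent

    def test_pooled_allelic_percent(self):
        diff, denom, expected = ALLELIC_POOLED
        allelic = [r for r in DIVERGENCE_ROWS if r.group == "allelic"]
        assert sum(r.diff for r in allelic) == diff
        assert sum(r.denominator for r in allelic) == denom
        assert percent_difference(diff, denom) == expected

    def test_zero_difference(self):
        assert percent_difference(0, 438) == 0.0


class TestPer1200:
    @pytest.mark.parametrize("percent,expected",
                             [(4.34, 52.1), (0.22, 2.6), (0.08, 1.0)])
    def test_printed_translations(self, percent, expected):
        assert per_1200(percent) == expected


class TestOrfStatus:
    def test_open_frame(self):
        assert orf_status(["ATGAAACCC"]).in_orf

    def test_internal_stop(self):
        st = orf_status(["ATGTAAAAA"])
        assert not st.in_orf and st.first_stop_position == 1

    def test_terminal_stop_keeps_orf_open(self):
        assert orf_status(["ATGAAATAA"]).in_orf

    def test_agrees_with_exhaustive_codon_scan(self, rng):
        stops = {"TAA", "TAG", "TGA"}
        for seed in range(30):
            seq = random_seq(120, np.random.default_rng(seed))
            codons = [seq[i : i + 3] for i in range(0, len(seq) - 2, 3)]
            first = next((k for k, c in enumerate(codons[:-1]) if c in stops), None)
            st = orf_status([seq])
            assert st.in_orf == (first is None)
            if first is not None:
                assert st.first_stop_position == first

    def test_single_hit_stop_mutation_breaks_orf(self):
        # construct the pseudogenizing point mutation from the stop-reachable
        # codon enumeration
        from ighvdup.clock import single_hit_stop_codons, standard_code

        _, reachable = single_hit_stop_codons()
        codon = reachable[0]
        stops = {"TAA", "TAG", "TGA"}
        mutant = next(
            codon[:p] + b + codon[p + 1 :]
            for p in range(3)
            for b in "ACGT"
            if b != codon[p] and codon[:p] + b + codon[p + 1 :] in stops
        )
        gene = "ATG" + codon + "GGGCCC"
        broken = "ATG" + mutant + "GGGCCC"
        assert orf_status([gene]).in_orf
        assert not orf_status([broken]).in_orf


class TestBuildDivergenceTable:
    def test_substitution_only_pairs_recover_generator_counts(self):
        # the core self-consistency: aligned difference counts equal the
        # generator's realized substitution counts
        pairs, want = [], []
        for seed in range(30):
            a = random_seq(300, np.random.default_rng(seed))
            b, n = mutate(a, (seed % 10) / 100, seed + 1)
            pairs.append((f"a{seed}", a, f"b{seed}", b, "allelic"))
            want.append(n)
        records, _ = build_divergence_table(
            pairs, DivergenceConfig(difference="subs_only")
        )
        assert [r.diff for r in records] == want

    def test_identical_pair_zero_percent(self):
        records, summaries = build_divergence_table(
            [("x", "ACGTACGT" * 20, "y", "ACGTACGT" * 20, "allelic")]
        )
        assert records[0].percent == 0.0
        assert summaries["allelic"].pooled_percent == 0.0

    def test_records_invariant_to_input_order(self, rng):
        pairs = []
        for seed in range(5):
            a = random_seq(200, np.random.default_rng(seed))
            b = mutate(a, 0.05, seed)[0]
            pairs.append((f"a{seed}", a, f"b{seed}", b, "paralogous"))
        fwd, s1 = build_divergence_table(pairs)
        rev, s2 = build_divergence_table(pairs[::-1])
        assert sorted(map(repr, fwd)) == sorted(map(repr, rev))
        assert s1 == s2

    def test_pooled_summary_is_total_over_total(self):
        pairs = []
        for seed in range(4):
            a = random_seq(250, np.random.default_rng(seed + 50))
            b = mutate(a, 0.03, seed)[0]
            pairs.append((f"a{seed}", a, f"b{seed}", b, "allelic"))
        records, summaries = build_divergence_table(pairs)
        s = summaries["allelic"]
        assert s.total_diff == sum(r.diff for r in records)
        assert s.total_denominator == sum(r.len_b for r in records)
        assert s.pooled_percent == percent_difference(s.total_diff,
                                                      s.total_denominator)
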