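"""Diversity estimators, star alignment, logo information content."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from satlib import (DataError, HapRow, HaplotypeTable, ParameterError,
                    SpeciesProfile, align_monomers, amplify_species,
                    haplotype_diversity, logo_matrix, nucleotide_diversity,
                    simulate_library, summarize)

from oracles import brute_force_pi, random_dna


class TestAlignMonomers:
    def test_identical_sequences_align_without_gaps(self):
        rows = align_monomers(["ACGTACGT"] * 3)
        assert rows == ["ACGTACGT"] * 3

    def test_single_deletion_gives_one_gap(self):
        rows = align_monomers(["ACGTACGT", "ACGACGT"])
        assert len(rows[0]) == len(rows[1]) == 8
        assert rows[0] == "ACGTACGT"
        assert rows[1].count("-") == 1
        assert rows[1].replace("-", "") == "ACGACGT"

    def test_single_sequence_returned_unchanged(self):
        assert align_monomers(["ACGT"]) == ["ACGT"]

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            align_monomers([])

    def test_ungapping_recovers_inputs(self, consensus, rng):
        c = consensus.sequence
        seqs = []
        for _ in range(8):
            s = "".join(x if rng.random() > 0.05 else "ACGT"[rng.integers(0, 4)]
                        for x in c)
            pos = int(rng.integers(0, len(s)))
            if rng.random() < 0.5:
                s = s[:pos] + s[pos + int(rng.integers(1, 5)):]  # deletion
            else:
                s = s[:pos] + random_dna(rng, int(rng.integers(1, 5))) + s[pos:]
            seqs.append(s)
        rows = align_monomers(seqs, reference=c)
        assert len({len(r) for r in rows}) == 1
        assert [r.replace("-", "") for r in rows] == seqs


class TestHaplotypeDiversity:
    @pytest.mark.parametrize("counts,expected", [
        ((2, 1), 2 / 3),
        ((5,), 0.0),
        ((2, 1, 1, 1), 0.9),
        ((1,) * 8, 1.0),
        ((1, 1), 1.0),
        ((2, 1) + (1,) * 16, (19 / 18) * (1 - (4 + 17) / 361)),
    ])
    def test_unbiased_estimator_values(self, counts, expected):
        assert haplotype_diversity(counts) == pytest.approx(expected)

    def test_undefined_below_two_sequences(self):
        with pytest.raises(ParameterError):
            haplotype_diversity([1])

    @given(st.lists(st.integers(1, 10), min_size=2, max_size=6))
    def test_label_permutation_invariance(self, counts):
        assert haplotype_diversity(counts) == \
            pytest.approx(haplotype_diversity(sorted(counts, reverse=True)))

    def test_moving_copy_to_new_haplotype_increases_hd(self):
        # exhaustive over all count configurations with n <= 8
        for n in range(2, 9):
            for k in range(1, n + 1):
                for combo in itertools.combinations(range(1, n), k - 1):
                    parts = [b - a for a, b in zip((0,) + combo, combo + (n,))]
                    if max(parts) < 2:
                        continue
                    i = parts.index(max(parts))
                    moved = parts.copy()
                    moved[i] -= 1
                    moved.append(1)
                    assert haplotype_diversity(moved) > haplotype_diversity(parts)


class TestNucleotideDiversity:
    def test_identical_rows_give_zero(self):
        assert nucleotide_diversity(["AAAA", "AAAA"], [1, 1]) == 0.0

    def test_single_difference_over_four_sites(self):
        assert nucleotide_diversity(["AAAA", "AAAT"], [1, 1]) == pytest.approx(0.25)

    def test_three_rows_brute_force(self):
        pi = nucleotide_diversity(["AAAA", "AAAT", "AATT"], [1, 1, 1])
        assert pi == pytest.approx((1 / 4 + 2 / 4 + 1 / 4) / 3)

    def test_indel_counted_as_single_event(self):
        # one 2-nt indel event: d=1 over L=4+1 sites
        pi = nucleotide_diversity(["AC--GT", "ACTTGT"], [1, 1],
                                  indel_policy="gap_as_event")
        assert pi == pytest.approx(1 / 5)

    def test_complete_deletion_drops_gapped_columns(self):
        pi = nucleotide_diversity(["AC--GT", "ACTTGT"], [1, 1],
                                  indel_policy="complete_deletion")
        assert pi == 0.0

    def test_all_gapped_columns_rejected(self):
        with pytest.raises(DataError):
            nucleotide_diversity(["--", "AA"], [1, 1],
                                 indel_policy="complete_deletion")

    @pytest.mark.parametrize("policy", ["gap_as_event", "complete_deletion"])
    @pytest.mark.parametrize("seed", range(10))
    def test_weighted_formula_equals_brute_force(self, seed, policy):
        rng = np.random.default_rng(seed)
        n_rows = int(rng.integers(2, 6))
        L = int(rng.integers(6, 15))
        rows = ["".join(rng.choice(list("ACGT-"), L, p=[.23, .23, .23, .23, .08]))
                for _ in range(n_rows)]
        if policy == "complete_deletion" and all("-" in "".join(c) for c in zip(*rows)):
            return
        counts = [int(c) for c in rng.integers(1, 4, n_rows)]
        try:
            pi = nucleotide_diversity(rows, counts, indel_policy=policy)
        except DataError:
            return
        assert pi == pytest.approx(brute_force_pi(rows, counts, policy))

    def test_pi_increases_with_mutation_rate(self):
        # parameter recovery: higher per-site mutation -> higher estimated pi
        lib = simulate_library(1, 120, 0.0, seed=5)
        orderings = 0
        for seed in range(20):
            pis = []
            for mu in (0.001, 0.01, 0.05):
                pool = amplify_species(
                    lib, SpeciesProfile("sp", [1.0], 40, mutation_rate=mu),
                    seed=seed)
                seqs = [m.sequence for m in pool]
                pis.append(nucleotide_diversity(seqs, [1] * len(seqs)))
            orderings += pis[0] < pis[1] < pis[2]
        assert orderings >= 19


class TestLogoMatrix:
    def test_conserved_column_has_two_bits(self):
        df = logo_matrix(["A", "A", "A"])
        assert df.R_bits[0] == pytest.approx(2.0)

    def test_uniform_column_has_zero_bits(self):
        df = logo_matrix(["A", "C", "G", "T"])
        assert df.R_bits[0] == pytest.approx(0.0)

    def test_weighted_half_quarter_quarter(self):
        df = logo_matrix(["A", "A", "C", "G"])
        assert df.H_bits[0] == pytest.approx(1.5)
        assert df.R_bits[0] == pytest.approx(0.5)

    def test_counts_weight_frequencies(self):
        df = logo_matrix(["A", "C"], counts=[3, 1])
        assert df.fA[0] == pytest.approx(0.75)

    def test_all_gap_column_is_missing(self):
        df = logo_matrix(["-A", "-C"])
        assert math.isnan(df.R_bits[0])
        assert df.fgap[0] == pytest.approx(1.0)

    def test_frequencies_sum_to_one(self, rng):
        rows = ["".join(rng.choice(list("ACGT-"), 30)) for _ in range(6)]
        df = logo_matrix(rows, counts=[2, 1, 1, 3, 1, 1])
        sums = df[["fA", "fC", "fG", "fT", "fgap"]].sum(axis=1)
        assert np.allclose(sums, 1.0)


class TestSummarize:
    def test_all_distinct_haplotypes(self, consensus, rng):
        c = consensus.sequence
        rows = []
        for i in range(8):
            s = "".join(x if rng.random() > 0.1 else "ACGT"[rng.integers(0, 4)]
                        for x in c)
            rows.append(HapRow(f"h{i}", s, 1, "A. fasciatus", "illumina"))
        stats = summarize(HaplotypeTable(rows))
        assert stats.n == 8 and stats.hap == 8
        assert stats.hd == pytest.approx(1.0)

    def test_two_identical_clones(self):
        table = HaplotypeTable([HapRow("h1", "ACGT" * 42, 2, "A. fasciatus", "pcr")])
        stats = summarize(table)
        assert (stats.hap, stats.hd, stats.pi) == (1, 0.0, 0.0)

    def test_empty_table_rejected(self):
        with pytest.raises(DataError):
            summarize(HaplotypeTable([]))

    def test_size_range_reports_ungapped_lengths(self):
        table = HaplotypeTable([HapRow("h1", "ACGTACGT", 2, "sp", "illumina"),
                                HapRow("h2", "ACGACGT", 3, "sp", "illumina")])
        stats = summarize(table)
        assert (stats.size_min, stats.size_max) == (7, 8)
        assert stats.n == 5
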