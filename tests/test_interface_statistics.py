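"""Frequencies, co-occurrence, segments, Wu-Kabat, germline, bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abinterface.datatypes import STANDARD_AA3, ComputationError, ContactRecord
from abinterface.interface_statistics import (
    aa_frequencies,
    class_frequencies,
    cooccurrence_matrix,
    epitope_segments,
    germline_mutation_fraction,
    group_mean_ci,
    position_aa_frequencies,
    wu_kabat,
)

aa_codes = st.sampled_from(STANDARD_AA3)


def _contact(ab_aa="TYR", ag_aa="ALA", ab_seq=100, ag_seq=5,
             ab_atom="CB", ag_atom="CB"):
    return ContactRecord(ab_chain="H", ab_seq=ab_seq, ab_icode="", ab_aa=ab_aa,
                         ab_atom=ab_atom, ab_domain="VH", ag_chain="A",
                         ag_seq=ag_seq, ag_icode="", ag_aa=ag_aa,
                         ag_atom=ag_atom, distance=4.0)


class TestAaFrequencies:
    def test_hand_tally(self):
        freq = aa_frequencies(["TYR", "TYR", "SER", "GLY"])
        assert freq["TYR"] == 50.0
        assert freq["SER"] == freq["GLY"] == 25.0
        assert freq["ALA"] == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(aa_codes, min_size=1, max_size=60))
    def test_sums_to_100(self, residues):
        assert aa_frequencies(residues).sum() == pytest.approx(100.0)

    def test_unique_residue_basis_is_multiplicity_invariant(self):
        """Doubling every contact leaves uPR-based frequencies unchanged."""
        contacts = [_contact("TYR", "ALA", ab_seq=1),
                    _contact("SER", "GLY", ab_seq=2)]
        def upr_freq(cs):
            unique = {(c.ab_chain, c.ab_seq, c.ab_icode): c.ab_aa for c in cs}
            return aa_frequencies(list(unique.values()))
        pd.testing.assert_series_equal(upr_freq(contacts),
                                       upr_freq(contacts * 2))

    def test_empty_raises(self):
        with pytest.raises(ComputationError):
            aa_frequencies([])


class TestClassFrequencies:
    def test_pure_serine_is_polar(self):
        assert class_frequencies(aa_frequencies(["SER"]))["polar"] == 100.0

    def test_pure_glycine_is_special(self):
        assert class_frequencies(aa_frequencies(["GLY"]))["special"] == 100.0

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(aa_codes, min_size=1, max_size=60))
    def test_classes_partition_the_alphabet(self, residues):
        classes = class_frequencies(aa_frequencies(residues))
        assert classes.sum() == pytest.approx(100.0)
        assert (classes >= 0).all()


class TestCooccurrenceMatrix:
    def test_single_contact_row(self):
        matrix, zero_rows = cooccurrence_matrix([_contact("TYR", "ALA")])
        assert matrix.loc["TYR", "ALA"] == 100.0
        assert matrix.loc["TYR"].sum() == 100.0
        assert "TYR" not in zero_rows and "SER" in zero_rows
        assert matrix.loc["SER"].sum() == 0.0

    def test_counts_total_contacts_not_unique_residues(self):
        # one TYR residue contacts ALA twice and GLY once: row 2/3 vs 1/3
        contacts = [_contact("TYR", "ALA", ag_seq=1),
                    _contact("TYR", "ALA", ag_seq=2),
                    _contact("TYR", "GLY", ag_seq=3)]
        matrix, _ = cooccurrence_matrix(contacts)
        assert matrix.loc["TYR", "ALA"] == pytest.approx(200 / 3)
        assert matrix.loc["TYR", "GLY"] == pytest.approx(100 / 3)

    def test_random_table_rows_sum_to_100(self, rng):
        contacts = [_contact(STANDARD_AA3[rng.integers(20)],
                             STANDARD_AA3[rng.integers(20)],
                             ab_seq=int(rng.integers(1, 50)),
                             ag_seq=int(rng.integers(1, 50)))
                    for _ in range(300)]
        matrix, zero_rows = cooccurrence_matrix(contacts)
        assert matrix.shape == (20, 20)
        populated = matrix.drop(index=zero_rows)
        assert np.allclose(populated.sum(axis=1), 100.0, atol=1e-6)
        # independent count-then-normalize oracle on one cell
        tyr = [c for c in contacts if c.ab_aa == "TYR"]
        if tyr:
            expected = 100 * sum(c.ag_aa == "ALA" for c in tyr) / len(tyr)
            assert matrix.loc["TYR", "ALA"] == pytest.approx(expected)


class TestEpitopeSegments:
    @pytest.mark.parametrize("numbers, expected", [
        ([10, 11, 12], 1),
        ([10, 12], 2),
        ([5, 6, 9, 10, 30], 3),
        ([7], 1),
    ])
    def test_run_rule(self, numbers, expected):
        assert epitope_segments([("A", n, "") for n in numbers]) == expected

    def test_chains_are_independent(self):
        keys = [("A", 10, ""), ("A", 11, ""), ("B", 11, "")]
        assert epitope_segments(keys) == 2

    def test_insertion_codes_are_adjacent_to_their_base(self):
        keys = [("A", 100, ""), ("A", 100, "A"), ("A", 101, "")]
        assert epitope_segments(keys) == 1

    @settings(derandomize=True, max_examples=50)
    @given(st.sets(st.integers(min_value=1, max_value=60), min_size=1,
                   max_size=30))
    def test_count_bounds(self, numbers):
        keys = [("A", n, "") for n in numbers]
        count = epitope_segments(keys)
        assert 1 <= count <= len(numbers)
        adjacent = any(b - a == 1 for a, b in
                       zip(sorted(numbers), sorted(numbers)[1:]))
        assert (count == len(numbers)) == (not adjacent)


class TestPositionAaFrequencies:
    def test_single_complex_single_position(self):
        freqs = position_aa_frequencies([{("VH", 107, ""): "TYR"}])
        assert freqs[("VH", 107, "")]["TYR"] == 100.0

    def test_planted_group_matches_hand_tally(self):
        group = [{("VH", 107, ""): "TYR"}] * 3 + [{("VH", 107, ""): "SER"}]
        vec = position_aa_frequencies(group)[("VH", 107, "")]
        assert vec["TYR"] == 75.0 and vec["SER"] == 25.0
        assert vec.sum() == pytest.approx(100.0)

    def test_positions_never_upr_absent(self):
        freqs = position_aa_frequencies([{("VH", 107, ""): "TYR"}])
        assert ("VH", 50, "") not in freqs


class TestWuKabat:
    @pytest.mark.parametrize("column, expected", [
        (["ALA"] * 10, 1.0),                      # fully conserved
        (["ALA", "ARG", "ASN", "ASP", "CYS"], 25.0),  # all distinct: 5*5/1
        (["ALA", "ALA", "ALA", "ARG", "ARG"], 5 * 2 / 3),
    ])
    def test_formula(self, column, expected):
        assert wu_kabat(column).variability == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(aa_codes, min_size=1, max_size=40))
    def test_lower_bound_attained_exactly_on_conserved_columns(self, column):
        value = wu_kabat(column).variability
        assert value >= 1.0
        assert (value == 1.0) == (len(set(column)) == 1)

    def test_empty_raises(self):
        with pytest.raises(ComputationError):
            wu_kabat([])


class TestGroupMeanCI:
    def test_zero_variance_degenerate_interval(self):
        ci = group_mean_ci([7.0, 7.0, 7.0], n_boot=200, seed=1)
        assert ci.point == ci.lo == ci.hi == 7.0

    def test_default_n_boot_is_5000(self):
        ci = group_mean_ci([1.0, 2.0], seed=1)
        assert ci.n_boot == 5000

    def test_bit_reproducible_under_fixed_seed(self):
        values = list(np.random.default_rng(3).normal(size=30))
        a = group_mean_ci(values, n_boot=500, seed=99)
        b = group_mean_ci(values, n_boot=500, seed=99)
        assert (a.lo, a.hi) == (b.lo, b.hi)
        c = group_mean_ci(values, n_boot=500, seed=100)
        assert (a.lo, a.hi) != (c.lo, c.hi)

    def test_interval_within_observed_range(self, rng):
        values = rng.normal(size=40)
        ci = group_mean_ci(list(values), n_boot=300, seed=5)
        assert values.min() <= ci.lo <= ci.hi <= values.max()
        assert ci.lo <= ci.point <= ci.hi


class TestGermlineMutationFraction:
    def test_identical_to_germline_everywhere(self):
        group = [{("VH", 52, ""): "TYR"}] * 4
        germ = [{("VH", 52, ""): "TYR"}] * 4
        table, pooled = germline_mutation_fraction(group, germ)
        assert (table["mutated_pct"] == 0.0).all()
        assert pooled == 0.0

    def test_always_mutated_position(self):
        group = [{("VH", 52, ""): "ARG"}] * 3
        germ = [{("VH", 52, ""): "TYR"}] * 3
        table, pooled = germline_mutation_fraction(group, germ)
        assert table["mutated_pct"].iloc[0] == 100.0 and pooled == 100.0

    def test_planted_6_of_10(self):
        group = [{("VH", 55, ""): "ARG"}] * 6 + [{("VH", 55, ""): "TYR"}] * 4
        germ = [{("VH", 55, ""): "TYR"}] * 10
        table, pooled = germline_mutation_fraction(group, germ)
        assert table["mutated_pct"].iloc[0] == 60.0

    def test_positions_without_germline_excluded(self):
        group = [{("VH", 52, ""): "ARG", ("VH", 99, ""): "SER"}]
        germ = [{("VH", 52, ""): "TYR"}]
        table, _ = germline_mutation_fraction(group, germ)
        assert list(table["position"]) == ["52"]

    def test_no_overlap_gives_empty_table(self):
        table, pooled = germline_mutation_fraction(
            [{("VH", 52, ""): "ARG"}], [{}])
        assert table.empty and pooled is None
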