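"""IMGT region mapping, hotspot tables, capture fractions, DSSP collapse."""

import pandas as pd
import pytest

from abinterface.datatypes import ComputationError, RegionScheme, REGION_ORDER
from abinterface.interface_contacts import find_contacts
from abinterface.region_annotation import (
    assign_region,
    cdr3_length,
    cdr_capture_fraction,
    collapse_ss,
    epitope_ss_distribution,
    hotspot_map,
    paratope_proportions,
    read_ss_table,
    region_distribution,
)

from conftest import make_atom, make_complex, make_residue

DEFAULT = RegionScheme()
EXPANDED_CDR2 = RegionScheme(cdr2=(55, 66))


class TestAssignRegion:
    @pytest.mark.parametrize("seq_id, region", [
        (1, "FR1"), (26, "FR1"),
        (27, "CDR1"), (38, "CDR1"),
        (39, "FR2"), (55, "FR2"),
        (56, "CDR2"), (65, "CDR2"),
        (66, "FR3"), (104, "FR3"),
        (105, "CDR3"), (117, "CDR3"),
        (118, "FR4"), (128, "FR4"),
    ])
    def test_default_boundaries(self, seq_id, region):
        assert assign_region(seq_id, DEFAULT) == region

    def test_position_55_moves_into_expanded_cdr2(self):
        assert assign_region(55, DEFAULT) == "FR2"
        assert assign_region(55, EXPANDED_CDR2) == "CDR2"
        assert assign_region(66, EXPANDED_CDR2) == "CDR2"

    def test_insertion_code_ignored_for_membership(self):
        assert assign_region(111, DEFAULT, icode="A") == "CDR3"

    def test_constant_domain_raises(self):
        with pytest.raises(ComputationError):
            assign_region(129, DEFAULT)

    def test_regions_partition_the_variable_domain(self):
        sizes = {r: 0 for r in REGION_ORDER}
        for seq_id in range(1, DEFAULT.vr_max + 1):
            sizes[assign_region(seq_id, DEFAULT)] += 1
        assert sum(sizes.values()) == DEFAULT.vr_max
        assert all(v > 0 for v in sizes.values())


class TestRegionDistribution:
    def test_all_uprs_in_one_region(self):
        means, _ = region_distribution([{"CDRH3": 5}, {"CDRH3": 2}])
        assert means["CDRH3"] == 100.0

    def test_proportions_sum_to_100_per_complex(self):
        counts = [{"CDRH1": 2, "CDRH3": 6}, {"FRH2": 1, "CDRH3": 3}]
        means, df = region_distribution(counts)
        assert sum(means.values()) == pytest.approx(100.0)
        assert (df.sum(axis=1) > 0).all()

    def test_matches_hand_computed_average(self):
        # complex 1: 25% CDRH1, 75% CDRH3; complex 2: 50/50
        counts = [{"CDRH1": 1, "CDRH3": 3}, {"CDRH1": 2, "CDRH3": 2}]
        means, _ = region_distribution(counts)
        assert means["CDRH1"] == pytest.approx(37.5)
        assert means["CDRH3"] == pytest.approx(62.5)


def _complex_with_upr(positions, n_residues=128):
    """VH-only complex whose uPRs are exactly the given IMGT positions."""
    residues = []
    planted = []
    for i in range(1, n_residues + 1):
        x = 20.0 * i
        atoms = [make_atom("CA", (x, 0.0, 0.0), "C")]
        residues.append(make_residue("H", i, "TYR", atoms))
    antigen = []
    for j, pos in enumerate(sorted(positions), start=1):
        antigen.append(make_residue("A", j, "ALA",
                                    [make_atom("CB", (20.0 * pos, 4.0, 0.0),
                                               "C")]))
    if not antigen:
        antigen = [make_residue("A", 1, "ALA",
                                [make_atom("CB", (-100.0, 0.0, 0.0), "C")])]
    return make_complex({"VH": residues}, {"A": antigen})


class TestParatopeProportions:
    def test_paratope_equals_all_cdr_residues(self):
        cdr_positions = [p for p in range(1, 129)
                         if assign_region(p, DEFAULT).startswith("CDR")]
        cx = _complex_with_upr(cdr_positions)
        fractions = paratope_proportions(cx, find_contacts(cx), DEFAULT)
        assert fractions["CDR"] == pytest.approx(1.0)
        assert fractions["FR"] == pytest.approx(0.0)
        assert fractions["VR"] == pytest.approx(len(cdr_positions) / 128)

    def test_empty_paratope_all_zero(self):
        cx = _complex_with_upr([])
        fractions = paratope_proportions(cx, [], DEFAULT)
        assert fractions == {"VR": 0.0, "CDR": 0.0, "FR": 0.0}


class TestHotspotMap:
    def _group(self, upr_lists, n_residues=128):
        return [( _complex_with_upr(positions, n_residues),
                  find_contacts(_complex_with_upr(positions, n_residues)))
                for positions in upr_lists]

    def test_conditional_and_background_percentages(self):
        group = self._group([[107]] * 5 + [[20]] * 5)
        table = hotspot_map(group, DEFAULT)
        row = table[(table["domain"] == "VH") & (table["position"] == "107")]
        assert row["background_pct"].iloc[0] == 100.0
        assert row["conditional_pct"].iloc[0] == 50.0
        assert row["n_present"].iloc[0] == 10

    def test_planted_7_of_10(self):
        group = self._group([[107]] * 7 + [[20]] * 3)
        table = hotspot_map(group, DEFAULT)
        row = table[table["position"] == "107"]
        assert row["conditional_pct"].iloc[0] == 70.0

    def test_rare_positions_filtered(self):
        # position 128 exists in only 1 of 20 complexes (5% < 10%)
        group = self._group([[20]] * 19, n_residues=120) + \
            self._group([[20]], n_residues=128)
        table = hotspot_map(group, DEFAULT, min_occurrence=0.10)
        assert "128" not in set(table["position"])
        assert "120" in set(table["position"])

    def test_raising_min_occurrence_never_adds_rows(self):
        group = self._group([[107]] * 6, n_residues=120) + \
            self._group([[50]] * 4, n_residues=128)
        low = hotspot_map(group, DEFAULT, min_occurrence=0.10)
        high = hotspot_map(group, DEFAULT, min_occurrence=0.60)
        assert len(high) <= len(low)
        assert set(zip(high["domain"], high["position"])) <= \
            set(zip(low["domain"], low["position"]))

    def test_conditional_pct_bounded(self):
        group = self._group([[10, 50, 107], [107], [20, 107]])
        table = hotspot_map(group, DEFAULT)
        assert table["conditional_pct"].between(0, 100).all()
        assert (table["n_contact"] <= table["n_present"]).all()


class TestCdrCaptureFraction:
    def test_all_inside(self):
        assert cdr_capture_fraction([[("VH", 107, "")]], DEFAULT) == 100.0

    def test_position_55_under_both_schemes(self):
        positions = [[("VH", 55, "")]]
        assert cdr_capture_fraction(positions, DEFAULT) == 0.0
        assert cdr_capture_fraction(positions, EXPANDED_CDR2) == 100.0

    def test_planted_9_of_10(self):
        positions = [[("VH", 107, "")]] * 9 + [[("VH", 45, "")]]
        assert cdr_capture_fraction(positions, DEFAULT) == 90.0

    def test_widening_cdr2_is_monotone(self):
        positions = [[("VH", p, "") for p in (30, 55, 60, 66, 107, 4)]]
        default = cdr_capture_fraction(positions, DEFAULT)
        expanded = cdr_capture_fraction(positions, EXPANDED_CDR2)
        assert expanded >= default
        assert expanded == pytest.approx(100 * 5 / 6)


class TestCollapseSS:
    @pytest.mark.parametrize("code, cls", [
        ("H", "helix"), ("G", "helix"), ("I", "helix"),
        ("E", "strand"), ("B", "strand"),
        ("T", "loop"), ("S", "loop"), (" ", "loop"), ("-", "loop"),
        ("P", "loop"),  # polyproline II from newer DSSP versions
        ("?", "loop"),  # unknown codes degrade to loop with a warning
    ])
    def test_collapse(self, code, cls):
        assert collapse_ss(code) == cls

    def test_class_masses_sum_to_100(self):
        keys = [("A", i, "") for i in range(1, 9)]
        codes = dict(zip(keys, "HGIEBTS "))
        dist = epitope_ss_distribution(keys, codes)
        assert sum(dist.values()) == pytest.approx(100.0)
        assert dist["helix"] == pytest.approx(100 * 3 / 8)


class TestCdr3Length:
    def _chain(self, ids_icodes):
        return [make_residue("H", seq, "ALA", icode=icode)
                for seq, icode in ids_icodes]

    def test_canonical_range_is_13(self):
        chain = self._chain([(i, "") for i in range(100, 125)])
        assert cdr3_length(chain, DEFAULT) == 13

    def test_insertions_extend_the_count(self):
        chain = self._chain([(i, "") for i in range(105, 118)]
                            + [(111, "A"), (111, "B")])
        assert cdr3_length(chain, DEFAULT) == 15

    def test_no_cdr3_residues(self):
        assert cdr3_length(self._chain([(i, "") for i in range(1, 50)]),
                           DEFAULT) == 0


class TestSSTableReader:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text("A:10\tH\nA:111A\tE\nB:5\tT\n")
        codes = read_ss_table(path)
        assert codes[("A", 10, "")] == "H"
        assert codes[("A", 111, "A")] == "E"
        assert collapse_ss(codes[("B", 5, "")]) == "loop"
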