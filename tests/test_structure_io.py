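"""Annotation loading, PDB parsing, dataset filters, and group labels."""

import numpy as np
import pytest

from abinterface.datatypes import ChainAnnotation, FormatError, StructuralError
from abinterface.structure_io import (
    classify_group,
    filter_dataset,
    load_annotation_summary,
    map_residue_name,
    parse_complex,
    write_pdb,
)

from conftest import make_annotation, make_atom, make_complex, make_residue

HEADER = "pdb\tHchain\tLchain\tantigen_chain\tantigen_type\tresolution\n"


def _write_summary(tmp_path, rows):
    path = tmp_path / "summary.tsv"
    path.write_text(HEADER + "".join(r + "\n" for r in rows))
    return path


class TestLoadAnnotationSummary:
    def test_direct_field_mapping(self, tmp_path):
        path = _write_summary(tmp_path, ["1ABC\tH\tL\tA\tprotein\t2.2"])
        (ann,) = load_annotation_summary(path)
        assert ann.structure_id == "1ABC"
        assert ann.heavy_chain_id == "H" and ann.light_chain_id == "L"
        assert ann.antigen_chain_ids == ["A"]
        assert ann.antigen_type == "protein" and ann.resolution == 2.2

    def test_single_chain_constructs_are_skipped(self, tmp_path):
        """Heavy and light chain on the same PDB chain ID cannot be analyzed."""
        path = _write_summary(tmp_path, ["1ABC\tA\tA\tB\tprotein\t2.0",
                                         "2DEF\tH\tL\tA\tprotein\t2.0"])
        anns = load_annotation_summary(path)
        assert [a.structure_id for a in anns] == ["2DEF"]

    def test_malformed_resolution_row_is_skipped(self, tmp_path):
        path = _write_summary(tmp_path, [
            "1AAA\tH\tL\tA\tprotein\t2.0",
            "2BBB\tH\tL\tA\tprotein\tnot-a-number",
            "3CCC\tH\tNA\tA\tpeptide\t1.8",
        ])
        anns = load_annotation_summary(path)
        assert len(anns) == 2
        assert anns[1].light_chain_id is None

    def test_multiple_antigen_chains_pipe_separated(self, tmp_path):
        path = _write_summary(tmp_path, ["1ABC\tH\tL\tA | B\tprotein\t2.0"])
        (ann,) = load_annotation_summary(path)
        assert ann.antigen_chain_ids == ["A", "B"]

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("pdb\tHchain\tLchain\tresolution\n1ABC\tH\tL\t2.0\n")
        with pytest.raises(FormatError):
            load_annotation_summary(path)


class TestParseComplex:
    def test_minimal_two_chain_file(self, minimal_pdb):
        ann = make_annotation(structure_id="MINI", heavy="H", light=None)
        cx = parse_complex(minimal_pdb, ann)
        assert [r.label for r in cx.antibody_residues["VH"]] == ["50"]
        assert [r.label for r in cx.antigen_residues["A"]] == ["1"]
        assert cx.antibody_residues["VH"][0].aa == "TYR"

    def test_hydrogens_parsed_but_contact_ineligible(self):
        pdb = (
            "ATOM      1  CA  TYR H  50      10.000  10.000  10.000  1.00 15.00           C\n"
            "ATOM      2  HA  TYR H  50      10.500  10.000  10.000  1.00 15.00           H\n"
            "ATOM      3  CA  ALA A   1      12.000  10.000  10.000  1.00 25.00           C\n"
            "END\n")
        cx = parse_complex(pdb, make_annotation(heavy="H", light=None))
        residue = cx.antibody_residues["VH"][0]
        assert len(residue.atoms) == 2
        assert [a.name for a in residue.eligible_atoms()] == ["CA"]

    def test_altloc_keeps_highest_occupancy(self):
        pdb = (
            "ATOM      1  CA ATYR H  50      10.000  10.000  10.000  0.60 15.00           C\n"
            "ATOM      2  CA BTYR H  50      11.000  10.000  10.000  0.40 15.00           C\n"
            "ATOM      3  CA  ALA A   1      12.000  10.000  10.000  1.00 25.00           C\n"
            "END\n")
        cx = parse_complex(pdb, make_annotation(heavy="H", light=None))
        (atom,) = cx.antibody_residues["VH"][0].atoms
        assert atom.altloc == "A" and atom.occupancy == 0.6
        assert atom.position[0] == pytest.approx(10.0)

    def test_waters_and_ions_go_to_solvent_store(self):
        pdb = (
            "ATOM      1  CA  TYR H  50      10.000  10.000  10.000  1.00 15.00           C\n"
            "ATOM      2  CA  ALA A   1      12.000  10.000  10.000  1.00 25.00           C\n"
            "HETATM    3  O   HOH A 101      11.000  10.000  10.000  1.00 30.00           O\n"
            "HETATM    4 ZN    ZN A 102      14.000  10.000  10.000  1.00 30.00          ZN\n"
            "END\n")
        cx = parse_complex(pdb, make_annotation(heavy="H", light=None))
        assert len(cx.antigen_residues["A"]) == 1
        assert sorted(r.aa for r in cx.solvent) == ["HOH", "ZN"]

    def test_mse_maps_to_met(self):
        pdb = (
            "ATOM      1  CA  TYR H  50      10.000  10.000  10.000  1.00 15.00           C\n"
            "HETATM    2  CA  MSE A   1      12.000  10.000  10.000  1.00 25.00           C\n"
            "END\n")
        cx = parse_complex(pdb, make_annotation(heavy="H", light=None))
        assert cx.antigen_residues["A"][0].aa == "MET"

    def test_missing_chain_raises(self, minimal_pdb):
        ann = make_annotation(heavy="X", light=None)
        with pytest.raises(StructuralError):
            parse_complex(minimal_pdb, ann)

    def test_chain_with_no_amino_acids_raises(self):
        pdb = (
            "ATOM      1  CA  TYR H  50      10.000  10.000  10.000  1.00 15.00           C\n"
            "HETATM    2  O   HOH A   1      12.000  10.000  10.000  1.00 25.00           O\n"
            "END\n")
        with pytest.raises(StructuralError):
            parse_complex(pdb, make_annotation(heavy="H", light=None))

    def test_round_trip_preserves_inventory(self, rng):
        from conftest import random_complex
        cx = random_complex(rng)
        text = write_pdb([cx])
        reparsed = parse_complex(text, cx.annotation)
        orig = [(r.key, a.name, tuple(np.round(a.position, 3)))
                for r in cx.all_antibody_residues() + cx.all_antigen_residues()
                for a in r.atoms]
        back = [(r.key, a.name, tuple(np.round(a.position, 3)))
                for r in (reparsed.all_antibody_residues()
                          + reparsed.all_antigen_residues())
                for a in r.atoms]
        assert sorted(orig) == sorted(back)


class TestMapResidueName:
    @pytest.mark.parametrize("raw, expected", [
        ("ALA", "ALA"), ("MSE", "MET"), ("PTR", "TYR"), ("SEP", "SER"),
        ("HOH", None), (" ZN", None), ("UNK", None),
    ])
    def test_mapping(self, raw, expected):
        assert map_residue_name(raw) == expected


class TestFilterDataset:
    def _complex(self, sid, resolution):
        ann = make_annotation(structure_id=sid, heavy="H", light=None,
                              resolution=resolution)
        return make_complex({"VH": [make_residue("H", 1)]},
                            {"A": [make_residue("A", 1)]}, ann)

    def test_resolution_boundary_inclusive(self):
        cxs = [self._complex("GOOD", 2.5), self._complex("EDGE", 3.0),
               self._complex("BADD", 3.01)]
        retained, removals = filter_dataset(cxs)
        assert [c.structure_id for c in retained] == ["GOOD", "EDGE"]
        assert removals[0][0] == "BADD" and "resolution" in removals[0][1]

    def test_exclusion_list(self):
        cxs = [self._complex("KEEP", 2.0), self._complex("DROP", 2.0)]
        retained, removals = filter_dataset(cxs, exclusion_list=["drop"])
        assert [c.structure_id for c in retained] == ["KEEP"]
        assert removals == [("DROP", "in exclusion list")]

    def test_filtering_is_idempotent(self):
        cxs = [self._complex(f"S{i:03d}", r)
               for i, r in enumerate([1.5, 2.9, 3.0, 3.5, 4.0])]
        once, _ = filter_dataset(cxs)
        twice, _ = filter_dataset(once)
        assert [c.structure_id for c in once] == [c.structure_id for c in twice]


class TestClassifyGroup:
    def _complex(self, domains, ag_len, ag_type):
        antibody = {}
        heavy = light = None
        if "VH" in domains:
            antibody["VH"] = [make_residue("H", 1)]
            heavy = "H"
        if "VL" in domains:
            antibody["VL"] = [make_residue("L", 1)]
            light = "L"
        ann = make_annotation(heavy=heavy, light=light, antigen_type=ag_type)
        antigen = {"A": [make_residue("A", i) for i in range(1, ag_len + 1)]}
        return make_complex(antibody, antigen, ann)

    @pytest.mark.parametrize("domains, ag_type, expected", [
        (("VH", "VL"), "protein", "protein_Fv"),
        (("VH", "VL"), "peptide", "peptide_Fv"),
        (("VH",), "protein", "protein_VH_sdAb"),
        (("VL",), "peptide", "peptide_VL_sdAb"),
    ])
    def test_annotated_type(self, domains, ag_type, expected):
        assert classify_group(self._complex(domains, 10, ag_type)) == expected

    @pytest.mark.parametrize("ag_len, expected", [
        (49, "peptide_Fv"),   # < 50 residues: peptide
        (50, "protein_Fv"),   # exactly 50: protein (strict < 50 rule)
        (80, "protein_Fv"),
    ])
    def test_type_derived_from_chain_length(self, ag_len, expected):
        cx = self._complex(("VH", "VL"), ag_len, None)
        assert classify_group(cx) == expected

    def test_fv_label_requires_both_domains(self):
        for domains in (("VH",), ("VL",)):
            label = classify_group(self._complex(domains, 60, "protein"))
            assert "Fv" not in label
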