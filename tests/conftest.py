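"""Shared fixtures: hand-built complexes, random complexes, brute-force oracle."""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pytest

from abinterface.datatypes import (
    AbAgComplex,
    Atom,
    ChainAnnotation,
    ContactRecord,
    Residue,
)


def make_atom(name: str, xyz, element: str = "", b: float = 20.0,
              occupancy: float = 1.0, altloc: str = "") -> Atom:
    if not element:
        element = name.strip().lstrip("0123456789")[:1]
    return Atom(name=name, element=element, position=np.asarray(xyz, float),
                b_factor=b, occupancy=occupancy, altloc=altloc)


def make_residue(chain: str, seq: int, aa: str = "ALA",
                 atoms: Optional[Sequence[Atom]] = None,
                 icode: str = "") -> Residue:
    if atoms is None:
        atoms = [make_atom("CA", (0.0, 0.0, 0.0), "C")]
    return Residue(chain_id=chain, seq_id=seq, icode=icode, aa=aa,
                   atoms=list(atoms))


def make_annotation(structure_id: str = "TEST", heavy: Optional[str] = "H",
                    light: Optional[str] = "L",
                    antigen: Sequence[str] = ("A",),
                    antigen_type: Optional[str] = "protein",
                    resolution: float = 2.0) -> ChainAnnotation:
    return ChainAnnotation(structure_id=structure_id, heavy_chain_id=heavy,
                           light_chain_id=light,
                           antigen_chain_ids=list(antigen),
                           antigen_type=antigen_type, resolution=resolution)


def make_complex(antibody: Dict[str, List[Residue]],
                 antigen: Dict[str, List[Residue]],
                 annotation: Optional[ChainAnnotation] = None,
                 unit_index: int = 0,
                 solvent: Optional[List[Residue]] = None) -> AbAgComplex:
    if annotation is None:
        heavy = antibody["VH"][0].chain_id if "VH" in antibody else None
        light = antibody["VL"][0].chain_id if "VL" in antibody else None
        annotation = make_annotation(heavy=heavy, light=light,
                                     antigen=sorted(antigen))
    return AbAgComplex(annotation=annotation, antibody_residues=antibody,
                       antigen_residues=antigen, unit_index=unit_index,
                       solvent=solvent or [])


def brute_force_contacts(cx: AbAgComplex, cutoff: float) -> List[ContactRecord]:
    """All-pairs double-loop contact oracle (the correctness reference)."""
    records = []
    ab_side = [(dom, res, atom) for dom in sorted(cx.antibody_residues)
               for res in cx.antibody_residues[dom]
               for atom in res.atoms if not atom.is_hydrogen]
    ag_side = [(cid, res, atom) for cid in sorted(cx.antigen_residues)
               for res in cx.antigen_residues[cid]
               for atom in res.atoms if not atom.is_hydrogen]
    for (dom, ab_res, ab_atom), (cid, ag_res, ag_atom) in \
            itertools.product(ab_side, ag_side):
        dist = float(np.linalg.norm(ab_atom.position - ag_atom.position))
        if dist <= cutoff:
            records.append(ContactRecord(
                ab_chain=ab_res.chain_id, ab_seq=ab_res.seq_id,
                ab_icode=ab_res.icode, ab_aa=ab_res.aa, ab_atom=ab_atom.name,
                ab_domain=dom, ag_chain=ag_res.chain_id,
                ag_seq=ag_res.seq_id, ag_icode=ag_res.icode, ag_aa=ag_res.aa,
                ag_atom=ag_atom.name, distance=dist))
    records.sort(key=lambda r: r.sort_key)
    return records


AA_POOL = ("ALA", "ARG", "GLY", "SER", "TYR", "TRP", "ASP", "LYS")


def random_complex(rng: np.random.Generator, n_ab: int = 12, n_ag: int = 12,
                   atoms_per_res: int = 4, box: float = 18.0) -> AbAgComplex:
    """Random atom cloud on both sides of a shared box (dense in contacts)."""
    def residues(chain: str, n: int) -> List[Residue]:
        out = []
        for i in range(1, n + 1):
            atoms = [make_atom(name, rng.uniform(0.0, box, size=3), "C")
                     for name in ("CA", "CB", "CG", "CD")[:atoms_per_res]]
            out.append(make_residue(chain, i, AA_POOL[rng.integers(len(AA_POOL))],
                                    atoms))
        return out
    antibody = {"VH": residues("H", n_ab)}
    antigen = {"A": residues("A", n_ag)}
    return make_complex(antibody, antigen)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230131)


# minimal PDB text used by the parsing tests
MINIMAL_PDB = """\
ATOM      1  CA  TYR H  50      10.000  10.000  10.000  1.00 15.00           C
TER       2      TYR H  50
ATOM      3  CA  ALA A   1      12.000  10.000  10.000  1.00 25.00           C
TER       4      ALA A   1
END
"""


@pytest.fixture
def minimal_pdb() -> str:
    return MINIMAL_PDB
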