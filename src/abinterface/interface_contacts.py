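"""Interface contact extraction and unique residue/atom accounting.

A contact is an antibody-atom/antigen-atom pair of non-hydrogen amino-acid
atoms within a Euclidean distance cutoff (default 5 A, boundary inclusive).
Waters, ions, modified residues without a standard parent, and small
molecules never appear in contacts.  The neighbour search uses a k-d tree;
the brute-force all-pairs computation lives in the test suite as the
correctness oracle.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import (
    MAIN_CHAIN_ATOMS,
    STANDARD_AA3,
    WATER_RESNAMES,
    AbAgComplex,
    ComputationError,
    ContactRecord,
    InterfaceSummary,
    Residue,
)

logger = logging.getLogger(__name__)

_KNOWN_SIDE_CHAIN = frozenset({
    "CB", "CG", "CG1", "CG2", "CD", "CD1", "CD2", "CE", "CE1", "CE2", "CE3",
    "CZ", "CZ2", "CZ3", "CH2", "ND1", "ND2", "NE", "NE1", "NE2", "NZ", "NH1",
    "NH2", "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH", "SD", "SG",
})


def classify_atom_class(atom_name: str) -> str:
    """``main_chain`` for backbone atoms {N, CA, C, O, OXT}, else ``side_chain``."""
    name = atom_name.strip().upper()
    if name in MAIN_CHAIN_ATOMS:
        return "main_chain"
    if name not in _KNOWN_SIDE_CHAIN:
        logger.warning("unrecognized atom name %r classified as side_chain",
                       atom_name)
    return "side_chain"


def _eligible_atom_table(residues: Sequence[Tuple[str, Residue]]):
    """Flatten (domain_or_chain, residue) pairs into parallel atom arrays."""
    meta = []
    coords = []
    for tag, res in residues:
        for atom in res.eligible_atoms():
            meta.append((tag, res, atom))
            coords.append(atom.position)
    return meta, (np.asarray(coords, dtype=float) if coords
                  else np.empty((0, 3)))


def find_contacts(cx: AbAgComplex, cutoff: float = 5.0) -> List[ContactRecord]:
    """All antibody/antigen atom pairs within ``cutoff`` (inclusive).

    One record per unordered pair, sorted by
    (ab_chain, ab_res, ab_atom, ag_chain, ag_res, ag_atom).  Raises
    :class:`ComputationError` when either side has no eligible atom.
    """
    ab_meta, ab_xyz = _eligible_atom_table(
        [(dom, r) for dom in sorted(cx.antibody_residues)
         for r in cx.antibody_residues[dom]])
    ag_meta, ag_xyz = _eligible_atom_table(
        [(cid, r) for cid in sorted(cx.antigen_residues)
         for r in cx.antigen_residues[cid]])
    if len(ab_meta) == 0 or len(ag_meta) == 0:
        raise ComputationError(
            f"{cx.structure_id}: no contact-eligible atoms on one side")

    tree = cKDTree(ag_xyz)
    records: List[ContactRecord] = []
    for (dom, ab_res, ab_atom), xyz in zip(ab_meta, ab_xyz):
        for j in tree.query_ball_point(xyz, cutoff):
            cid, ag_res, ag_atom = ag_meta[j]
            dist = float(np.linalg.norm(xyz - ag_xyz[j]))
            records.append(ContactRecord(
                ab_chain=ab_res.chain_id, ab_seq=ab_res.seq_id,
                ab_icode=ab_res.icode, ab_aa=ab_res.aa,
                ab_atom=ab_atom.name, ab_domain=dom,
                ag_chain=ag_res.chain_id, ag_seq=ag_res.seq_id,
                ag_icode=ag_res.icode, ag_aa=ag_res.aa,
                ag_atom=ag_atom.name, distance=dist))
    records.sort(key=lambda r: r.sort_key)
    return records


def summarize_interface(contacts: Sequence[ContactRecord]) -> InterfaceSummary:
    """Total contacts plus unique paratope/epitope residue and atom counts.

    uPR/uER are distinct (chain, residue) keys per side; uPA/uEA distinct
    (chain, residue, atom name) keys.  The unique paratope atoms are split
    into main-chain and side-chain classes.  Per-domain counts (VH/VL) are
    included for grouped statistics.
    """
    upr = {c.ab_res_key for c in contacts}
    uer = {c.ag_res_key for c in contacts}
    upa = {c.ab_res_key + (c.ab_atom,) for c in contacts}
    uea = {c.ag_res_key + (c.ag_atom,) for c in contacts}
    upa_main = sum(1 for key in upa if classify_atom_class(key[3]) == "main_chain")

    per_domain: Dict[str, Dict[str, int]] = {}
    for dom in sorted({c.ab_domain for c in contacts}):
        sub = [c for c in contacts if c.ab_domain == dom]
        per_domain[dom] = {
            "total_contacts": len(sub),
            "upr": len({c.ab_res_key for c in sub}),
            "upa": len({c.ab_res_key + (c.ab_atom,) for c in sub}),
        }

    return InterfaceSummary(
        total_contacts=len(contacts),
        upr=len(upr), uer=len(uer), upa=len(upa), uea=len(uea),
        upa_main=upa_main, upa_side=len(upa) - upa_main,
        per_domain=per_domain)


def count_interfacial_waters(cx: AbAgComplex, cutoff: float = 5.0
                             ) -> Tuple[int, int]:
    """Count interfacial waters and their water-mediated contacts.

    A water is interfacial iff its oxygen lies within ``cutoff`` of at least
    one eligible antibody atom AND one eligible antigen atom.  For those
    waters, every (water oxygen, protein atom) pair within the cutoff counts
    as one water-mediated contact.  Reported separately; never mixed into the
    direct contact records.
    """
    waters = [r for r in cx.solvent if r.aa in WATER_RESNAMES]
    if not waters:
        return (0, 0)
    _, ab_xyz = _eligible_atom_table(
        [(dom, r) for dom in sorted(cx.antibody_residues)
         for r in cx.antibody_residues[dom]])
    _, ag_xyz = _eligible_atom_table(
        [(cid, r) for cid in sorted(cx.antigen_residues)
         for r in cx.antigen_residues[cid]])
    ab_tree = cKDTree(ab_xyz) if len(ab_xyz) else None
    ag_tree = cKDTree(ag_xyz) if len(ag_xyz) else None
    n_waters = 0
    n_mediated = 0
    for water in waters:
        oxygens = [a for a in water.eligible_atoms()
                   if a.element.upper() == "O" or a.name.startswith("O")]
        if not oxygens or ab_tree is None or ag_tree is None:
            continue
        pos = oxygens[0].position
        ab_hits = ab_tree.query_ball_point(pos, cutoff)
        ag_hits = ag_tree.query_ball_point(pos, cutoff)
        if ab_hits and ag_hits:
            n_waters += 1
            n_mediated += len(ab_hits) + len(ag_hits)
    return (n_waters, n_mediated)
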