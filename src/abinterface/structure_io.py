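"""Reading structures and chain annotations; dataset-level filters.

PDB files are parsed with Biopython's :class:`Bio.PDB.PDBParser`.  The parsed
model is reduced to the package's lightweight residue/atom types: alternate
locations are resolved to one atom per name (highest occupancy, ties broken by
altloc character), nonstandard residues are mapped to their standard parent
(MSE -> MET etc.), and waters/ions/unmappable heteroresidues are moved to a
separate solvent store so they can never appear in a contact.
"""

from __future__ import annotations

import io
import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data.PDBData import protein_letters_3to1_extended
from Bio.PDB import PDBParser

from .datatypes import (
    AA_1TO3,
    AA_3TO1,
    STANDARD_AA3,
    WATER_RESNAMES,
    AbAgComplex,
    Atom,
    ChainAnnotation,
    ClassificationError,
    FormatError,
    Residue,
    StructuralError,
)

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("pdb", "Hchain", "Lchain", "antigen_chain",
                    "antigen_type", "resolution")

_MISSING = {"", "na", "nan", "none", "-"}


def _clean(value: str) -> Optional[str]:
    value = value.strip()
    return None if value.lower() in _MISSING else value


def load_annotation_summary(path) -> List[ChainAnnotation]:
    """Read a tab-separated chain-annotation summary.

    One :class:`ChainAnnotation` per (structure, antibody) row.  Rows with the
    heavy and light chain annotated to the same chain ID (e.g. single-chain
    constructs) and rows with an unparseable resolution are skipped with a
    warning; a missing required column raises :class:`FormatError`.
    """
    annotations: List[ChainAnnotation] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty annotation file")
        header = [h.strip() for h in header_line.rstrip("\n").split("\t")]
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s): {missing}")
        idx = {c: header.index(c) for c in REQUIRED_COLUMNS}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(header):
                fields += [""] * (len(header) - len(fields))
            pdb_id = (fields[idx["pdb"]] or "").strip()
            hchain = _clean(fields[idx["Hchain"]])
            lchain = _clean(fields[idx["Lchain"]])
            ag_raw = _clean(fields[idx["antigen_chain"]]) or ""
            ag_chains = [c.strip() for part in ag_raw.split("|")
                         for c in part.split(",") if c.strip()]
            ag_type = _clean(fields[idx["antigen_type"]])
            if ag_type is not None:
                ag_type = ag_type.lower()
            try:
                resolution = float(fields[idx["resolution"]])
            except ValueError:
                logger.warning("%s line %d: unparseable resolution %r; row skipped",
                               path, lineno, fields[idx["resolution"]])
                continue
            try:
                ann = ChainAnnotation(
                    structure_id=pdb_id,
                    heavy_chain_id=hchain,
                    light_chain_id=lchain,
                    antigen_chain_ids=ag_chains,
                    antigen_type=ag_type,
                    resolution=resolution,
                )
            except ValueError as exc:
                logger.warning("%s line %d: row skipped (%s)", path, lineno, exc)
                continue
            annotations.append(ann)
    return annotations


# --- residue mapping ---------------------------------------------------------

def map_residue_name(resname: str) -> Optional[str]:
    """Map a residue name to its standard 3-letter parent, or None.

    Standard residues map to themselves; modified residues with a standard
    parent (MSE, PTR, SEP, ...) map to the parent via Biopython's extended
    3-to-1 table.  Returns ``None`` for anything unmappable (waters, ions,
    ligands, X residues).
    """
    resname = resname.strip().upper()
    if resname in AA_3TO1:
        return resname
    one = protein_letters_3to1_extended.get(resname)
    if one is None or one not in AA_1TO3:
        return None
    return AA_1TO3[one]


def _convert_atom(bio_atom) -> Atom:
    occ = bio_atom.get_occupancy()
    occ = 1.0 if occ is None else min(max(float(occ), 0.0), 1.0)
    return Atom(
        name=bio_atom.get_name(),
        element=(bio_atom.element or "").strip(),
        position=np.array(bio_atom.get_coord(), dtype=float),
        b_factor=float(bio_atom.get_bfactor() or 0.0),
        occupancy=occ,
        altloc=(bio_atom.get_altloc() or "").strip(),
    )


def _convert_chain(bio_chain) -> Tuple[List[Residue], List[Residue]]:
    """Split one Biopython chain into (amino-acid residues, solvent residues)."""
    residues: List[Residue] = []
    solvent: List[Residue] = []
    for bio_res in bio_chain:
        if bio_res.is_disordered() == 2:  # disordered residue: take selected child
            bio_res = bio_res.selected_child
        hetflag, seq_id, icode = bio_res.get_id()
        resname = bio_res.get_resname().strip()
        atoms = [_convert_atom(a) for a in bio_res.get_unpacked_list()]
        # unpacked list expands alternate locations; keep one copy per atom
        # name: highest occupancy, tie broken by altloc character order
        by_name: Dict[str, Atom] = {}
        for a in atoms:
            prev = by_name.get(a.name)
            if prev is None or (a.occupancy, -ord(a.altloc or "~")) > (
                    prev.occupancy, -ord(prev.altloc or "~")):
                by_name[a.name] = a
        atom_list = list(by_name.values())
        mapped = None if hetflag == "W" or resname in WATER_RESNAMES \
            else map_residue_name(resname)
        res = Residue(chain_id=bio_chain.id, seq_id=int(seq_id),
                      icode=(icode or "").strip(), aa=mapped or resname,
                      atoms=atom_list)
        if mapped is None:
            if resname not in WATER_RESNAMES and hetflag != "W":
                logger.info("chain %s residue %s%s: unmappable residue %r kept "
                            "in solvent store", bio_chain.id, seq_id, icode, resname)
            solvent.append(res)
        else:
            residues.append(res)
    return residues, solvent


def parse_complex(pdb_text: str, annotation: ChainAnnotation,
                  unit_index: int = 0) -> AbAgComplex:
    """Build one :class:`AbAgComplex` from PDB text and one annotation row.

    Hydrogens/deuteriums are parsed but flagged contact-ineligible via their
    element; waters, ions and non-amino-acid heteroatoms go to the solvent
    store.  A named chain missing from the file, or containing zero
    amino-acid residues, raises :class:`StructuralError`.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(annotation.structure_id, io.StringIO(pdb_text))
    model = next(structure.get_models())
    chains = {c.id: c for c in model}

    converted: Dict[str, Tuple[List[Residue], List[Residue]]] = {}
    for cid in annotation.antibody_chain_ids + annotation.antigen_chain_ids:
        if cid not in chains:
            raise StructuralError(
                f"{annotation.structure_id}: chain {cid!r} not found in file")
        converted[cid] = _convert_chain(chains[cid])
        if not converted[cid][0]:
            raise StructuralError(
                f"{annotation.structure_id}: chain {cid!r} has no amino-acid residues")

    antibody: Dict[str, List[Residue]] = {}
    if annotation.heavy_chain_id:
        antibody["VH"] = converted[annotation.heavy_chain_id][0]
    if annotation.light_chain_id:
        antibody["VL"] = converted[annotation.light_chain_id][0]
    antigen = {cid: converted[cid][0] for cid in annotation.antigen_chain_ids}
    solvent = [r for cid in converted for r in converted[cid][1]]
    # waters may sit on their own chains too
    for cid, chain in chains.items():
        if cid in converted:
            continue
        _, extra_solvent = _convert_chain(chain)
        solvent.extend(extra_solvent)

    return AbAgComplex(annotation=annotation, antibody_residues=antibody,
                       antigen_residues=antigen, unit_index=unit_index,
                       solvent=solvent)


def parse_units(pdb_text: str, annotations: Sequence[ChainAnnotation]
                ) -> List[AbAgComplex]:
    """Parse every biological unit of one file: one complex per annotation row."""
    return [parse_complex(pdb_text, ann, unit_index=i)
            for i, ann in enumerate(annotations)]


# --- writing ----------------------------------------------------------------

def _atom_line(serial: int, atom: Atom, res: Residue, record: str = "ATOM") -> str:
    name = atom.name
    # wwPDB convention: atom names of <4 chars start in column 14 unless the
    # element symbol is two characters
    if len(name) < 4 and len(atom.element.strip()) < 2:
        name = f" {name}"
    x, y, z = atom.position
    return (f"{record:<6}{serial:>5} {name:<4}{'':1}{res.aa:>3} {res.chain_id:1}"
            f"{res.seq_id:>4}{res.icode or ' ':1}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
            f"          {atom.element:>2}")


def write_pdb(complexes: Sequence[AbAgComplex]) -> str:
    """Serialize complexes back to PDB text (ATOM records + TER/END).

    The inverse of :func:`parse_complex` up to format precision: re-parsing
    yields the same residue and atom inventory.
    """
    lines: List[str] = []
    serial = 1
    for cx in complexes:
        chain_groups: List[List[Residue]] = []
        for dom in sorted(cx.antibody_residues):
            chain_groups.append(cx.antibody_residues[dom])
        for cid in sorted(cx.antigen_residues):
            chain_groups.append(cx.antigen_residues[cid])
        for residues in chain_groups:
            for res in residues:
                for atom in res.atoms:
                    lines.append(_atom_line(serial, atom, res))
                    serial += 1
            if residues:
                lines.append(f"TER   {serial:>5}      {residues[-1].aa:>3} "
                             f"{residues[-1].chain_id:1}{residues[-1].seq_id:>4}"
                             f"{residues[-1].icode or ' ':1}")
                serial += 1
        for res in cx.solvent:
            for atom in res.atoms:
                lines.append(_atom_line(serial, atom, res, record="HETATM"))
                serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# --- dataset filters ----------------------------------------------------------

def filter_dataset(complexes: Sequence[AbAgComplex],
                   max_resolution: float = 3.0,
                   exclusion_list: Iterable[str] = ()
                   ) -> Tuple[List[AbAgComplex], List[Tuple[str, str]]]:
    """Apply the resolution cutoff (inclusive) and the manual exclusion list.

    Returns ``(retained, removals)`` where each removal is
    ``(structure_id, reason)``.
    """
    excluded = {s.upper() for s in exclusion_list}
    retained: List[AbAgComplex] = []
    removals: List[Tuple[str, str]] = []
    for cx in complexes:
        sid = cx.structure_id
        if sid.upper() in excluded:
            removals.append((sid, "in exclusion list"))
        elif cx.annotation.resolution > max_resolution:
            removals.append(
                (sid, f"resolution {cx.annotation.resolution:g} A > "
                      f"{max_resolution:g} A"))
        else:
            retained.append(cx)
    return retained, removals


def classify_group(cx: AbAgComplex, peptide_max_len: int = 50) -> str:
    """Assign the group label: {protein,peptide} x {Fv, VH_sdAb, VL_sdAb}.

    The antigen type comes from the annotation when present; otherwise an
    antigen is a peptide iff every antigen chain is shorter than
    ``peptide_max_len`` residues (a chain of exactly 50 residues is protein).
    """
    domains = cx.domains
    if not domains:
        raise ClassificationError(f"{cx.structure_id}: no variable domain")
    ag_type = cx.annotation.antigen_type
    if ag_type is None:
        lengths = [len(res) for res in cx.antigen_residues.values()]
        ag_type = "peptide" if all(n < peptide_max_len for n in lengths) else "protein"
    if domains == ["VH", "VL"]:
        part = "Fv"
    elif domains == ["VH"]:
        part = "VH_sdAb"
    elif domains == ["VL"]:
        part = "VL_sdAb"
    else:  # pragma: no cover - dict keys restricted to VH/VL upstream
        raise ClassificationError(f"{cx.structure_id}: domains {domains}")
    return f"{ag_type}_{part}"
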