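"""Core domain types shared across the pipeline.

The objects here are deliberately lightweight: plain dataclasses holding the
subset of structural information the interface analysis needs (identity keys,
coordinates, B-factors, contact eligibility), rather than full crystallographic
models.  Parsing from PDB files is done in :mod:`abinterface.structure_io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

# --- amino-acid vocabulary -------------------------------------------------

#: The 20 standard amino acids, 3-letter codes, alphabetical.
STANDARD_AA3: Tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

AA_3TO1: Dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3: Dict[str, str] = {v: k for k, v in AA_3TO1.items()}

#: Physicochemical classes used for grouped paratope/epitope frequencies.
AA_CLASSES: Dict[str, Tuple[str, ...]] = {
    "nonpolar": ("ALA", "VAL", "PRO", "LEU", "ILE", "TRP", "PHE"),
    "polar": ("SER", "THR", "TYR", "ASN", "GLN"),
    "positive": ("LYS", "HIS", "ARG"),
    "negative": ("GLU", "ASP"),
    "special": ("GLY", "CYS", "MET"),
}

#: Backbone atom names; everything else on a standard residue is side chain.
MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Residue names treated as water in the solvent store.
WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

VALID_GROUP_LABELS = (
    "protein_Fv", "peptide_Fv",
    "protein_VH_sdAb", "peptide_VH_sdAb",
    "protein_VL_sdAb", "peptide_VL_sdAb",
)


class AbInterfaceError(Exception):
    """Base class for all package errors."""


class FormatError(AbInterfaceError):
    """Malformed input file (missing columns, unparseable fields)."""


class StructuralError(AbInterfaceError):
    """A structure does not satisfy the annotation (missing/empty chains)."""


class ClassificationError(AbInterfaceError):
    """A complex cannot be assigned a group label."""


class ComputationError(AbInterfaceError):
    """A statistic is undefined for the given input (e.g. zero atoms)."""


# --- structural primitives -------------------------------------------------

@dataclass
class Atom:
    """One atom with the fields the interface analysis consumes."""

    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    b_factor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        """True for hydrogen and deuterium; these never count as contacts."""
        elem = self.element.strip().upper()
        if elem:
            return elem in ("H", "D")
        # fall back to the atom-name heuristic: strip leading digits, look at
        # the first letter (e.g. "1HB2", "HD21", "D2")
        stripped = self.name.strip().lstrip("0123456789")
        return stripped[:1].upper() in ("H", "D")


@dataclass
class Residue:
    """An amino-acid residue; ``(chain_id, seq_id, icode)`` is its identity key."""

    chain_id: str
    seq_id: int
    icode: str
    aa: str  # 3-letter code, one of the 20 standard codes after mapping
    atoms: List[Atom] = field(default_factory=list)

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.icode)

    @property
    def label(self) -> str:
        """Residue number with insertion code, e.g. ``111A``."""
        return f"{self.seq_id}{self.icode.strip()}"

    def eligible_atoms(self) -> List[Atom]:
        """Non-hydrogen atoms, i.e. those that may form interface contacts."""
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class ChainAnnotation:
    """One row of the chain-annotation summary: chain roles for one antibody."""

    structure_id: str
    heavy_chain_id: Optional[str]
    light_chain_id: Optional[str]
    antigen_chain_ids: List[str]
    antigen_type: Optional[str]  # "protein" | "peptide" | None (derive from length)
    resolution: float

    def __post_init__(self) -> None:
        if self.heavy_chain_id is None and self.light_chain_id is None:
            raise ValueError(f"{self.structure_id}: no antibody chain annotated")
        if (self.heavy_chain_id is not None
                and self.heavy_chain_id == self.light_chain_id):
            raise ValueError(
                f"{self.structure_id}: heavy and light chain share ID "
                f"{self.heavy_chain_id!r}")
        if not self.antigen_chain_ids:
            raise ValueError(f"{self.structure_id}: no antigen chain annotated")
        ab = {c for c in (self.heavy_chain_id, self.light_chain_id) if c}
        if ab & set(self.antigen_chain_ids):
            raise ValueError(
                f"{self.structure_id}: antibody and antigen chain labels overlap")
        if not (self.resolution > 0 and math.isfinite(self.resolution)):
            raise ValueError(f"{self.structure_id}: resolution must be positive")
        if self.antigen_type is not None and self.antigen_type not in ("protein", "peptide"):
            raise ValueError(
                f"{self.structure_id}: unknown antigen type {self.antigen_type!r}")

    @property
    def antibody_chain_ids(self) -> List[str]:
        return [c for c in (self.heavy_chain_id, self.light_chain_id) if c]

    @property
    def domains(self) -> List[str]:
        out = []
        if self.heavy_chain_id:
            out.append("VH")
        if self.light_chain_id:
            out.append("VL")
        return out


@dataclass
class AbAgComplex:
    """One biological unit: antibody variable domains plus antigen chains.

    ``antibody_residues`` maps domain ("VH"/"VL") to the residue list of the
    corresponding chain; ``antigen_residues`` maps antigen chain ID to its
    residues.  Waters, ions, and unmappable heteroresidues live in
    ``solvent``, never in the residue lists.
    """

    annotation: ChainAnnotation
    antibody_residues: Dict[str, List[Residue]]
    antigen_residues: Dict[str, List[Residue]]
    unit_index: int = 0
    solvent: List[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        chain_of = {"VH": self.annotation.heavy_chain_id,
                    "VL": self.annotation.light_chain_id}
        for dom, residues in self.antibody_residues.items():
            want = chain_of.get(dom)
            for r in residues:
                if r.chain_id != want:
                    raise ValueError(
                        f"{self.structure_id}: {dom} residue {r.label} on chain "
                        f"{r.chain_id!r}, annotation says {want!r}")
        ag = set(self.annotation.antigen_chain_ids)
        for cid, residues in self.antigen_residues.items():
            if cid not in ag:
                raise ValueError(
                    f"{self.structure_id}: antigen chain {cid!r} not in annotation")
            for r in residues:
                if r.chain_id != cid:
                    raise ValueError(
                        f"{self.structure_id}: residue {r.label} keyed under "
                        f"chain {cid!r} but labelled {r.chain_id!r}")

    @property
    def structure_id(self) -> str:
        return self.annotation.structure_id

    @property
    def domains(self) -> List[str]:
        return sorted(self.antibody_residues)

    def all_antibody_residues(self) -> List[Residue]:
        return [r for dom in sorted(self.antibody_residues)
                for r in self.antibody_residues[dom]]

    def all_antigen_residues(self) -> List[Residue]:
        return [r for cid in sorted(self.antigen_residues)
                for r in self.antigen_residues[cid]]


# --- interface records -----------------------------------------------------

@dataclass(frozen=True)
class ContactRecord:
    """One non-hydrogen atom-atom contact across the antibody-antigen interface."""

    ab_chain: str
    ab_seq: int
    ab_icode: str
    ab_aa: str
    ab_atom: str
    ab_domain: str  # "VH" | "VL"
    ag_chain: str
    ag_seq: int
    ag_icode: str
    ag_aa: str
    ag_atom: str
    distance: float

    @property
    def ab_res(self) -> str:
        return f"{self.ab_seq}{self.ab_icode.strip()}"

    @property
    def ag_res(self) -> str:
        return f"{self.ag_seq}{self.ag_icode.strip()}"

    @property
    def ab_res_key(self) -> Tuple[str, int, str]:
        return (self.ab_chain, self.ab_seq, self.ab_icode)

    @property
    def ag_res_key(self) -> Tuple[str, int, str]:
        return (self.ag_chain, self.ag_seq, self.ag_icode)

    @property
    def sort_key(self):
        return (self.ab_chain, self.ab_seq, self.ab_icode, self.ab_atom,
                self.ag_chain, self.ag_seq, self.ag_icode, self.ag_atom)


@dataclass
class InterfaceSummary:
    """Per-complex accounting of total contacts and unique residues/atoms.

    uPR/uER count distinct residues, uPA/uEA distinct atoms; a residue (atom)
    mediating many contacts is counted once.  ``upa_main``/``upa_side`` split
    the unique paratope atoms into backbone and side-chain atoms.
    """

    total_contacts: int
    upr: int
    uer: int
    upa: int
    uea: int
    upa_main: int
    upa_side: int
    per_domain: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.total_contacts
        checks = [
            self.upr <= t or t == 0, self.uer <= t or t == 0,
            self.upa <= t or t == 0, self.uea <= t or t == 0,
            self.upr <= self.upa, self.uer <= self.uea,
            self.upa == self.upa_main + self.upa_side,
        ]
        if not all(checks):
            raise ValueError(f"inconsistent interface summary: {self}")


@dataclass(frozen=True)
class RegionScheme:
    """IMGT region boundaries for one variable domain.

    Defaults follow the IMGT definition: CDR1 27-38, CDR2 56-65, CDR3 105-117,
    variable domain ending at position 128.  FR1-FR4 are the complement.
    """

    cdr1: Tuple[int, int] = (27, 38)
    cdr2: Tuple[int, int] = (56, 65)
    cdr3: Tuple[int, int] = (105, 117)
    vr_max: int = 128

    def __post_init__(self) -> None:
        ranges = [self.cdr1, self.cdr2, self.cdr3]
        prev_end = 0
        for lo, hi in ranges:
            if not (1 <= lo <= hi <= self.vr_max):
                raise ValueError(f"CDR range {lo}-{hi} outside [1, {self.vr_max}]")
            if lo <= prev_end:
                raise ValueError("CDR ranges must be ascending and non-overlapping")
            prev_end = hi
        # each CDR must leave room for at least position 1 before CDR1 and the
        # framework after CDR3 may be empty only if cdr3 ends at vr_max
        if self.cdr1[0] < 2:
            raise ValueError("FR1 would be empty; CDR1 must start at >= 2")

    @property
    def framework_ranges(self) -> Dict[str, Tuple[int, int]]:
        return {
            "FR1": (1, self.cdr1[0] - 1),
            "FR2": (self.cdr1[1] + 1, self.cdr2[0] - 1),
            "FR3": (self.cdr2[1] + 1, self.cdr3[0] - 1),
            "FR4": (self.cdr3[1] + 1, self.vr_max),
        }

    @property
    def region_ranges(self) -> Dict[str, Tuple[int, int]]:
        fr = self.framework_ranges
        return {"FR1": fr["FR1"], "CDR1": self.cdr1, "FR2": fr["FR2"],
                "CDR2": self.cdr2, "FR3": fr["FR3"], "CDR3": self.cdr3,
                "FR4": fr["FR4"]}


REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")
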