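"""Antibody redundancy removal by variable-domain sequence clustering.

Popular antigens get crystallized with the same (or nearly the same) antibody
many times; left in place, those copies would dominate every interface
statistic.  VH and VL sequences over IMGT positions <= 128 are clustered
separately at 95% identity with a greedy longest-first scheme (the CD-HIT
strategy); complexes whose domains all land in the same clusters form one
redundancy family, of which a single representative is kept.

Identity between two sequences is defined as the number of identical aligned
positions of a global alignment (match +1, mismatch 0, linear gap penalty)
divided by the length of the shorter sequence — CD-HIT's convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import Align

from .datatypes import (
    AA_3TO1,
    AbAgComplex,
    AbInterfaceError,
    ComputationError,
    Residue,
)
from .complex_selection import mean_bfactor

logger = logging.getLogger(__name__)

Source = Tuple[str, str]  # (structure_id, domain)


@dataclass(frozen=True)
class VariableSequence:
    """1-letter sequence of one variable domain (IMGT numeric ID <= 128)."""

    source: Source
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.source}: empty variable-domain sequence")


@dataclass
class ClusterAssignment:
    mapping: Dict[Source, int]
    threshold: float = 0.95
    representatives: Dict[int, str] = field(default_factory=dict)


def extract_variable_sequence(chain: Sequence[Residue], domain: str,
                              structure_id: str = "?") -> VariableSequence:
    """Sequence over residues with numeric IMGT ID <= 128, ordered by (ID, icode).

    Constant-domain residues (ID > 128) are excluded; residues whose
    amino-acid code cannot be mapped to a standard letter are dropped with a
    warning.  Raises :class:`ComputationError` if nothing remains.
    """
    if not chain:
        raise ComputationError(f"{structure_id}/{domain}: empty chain")
    variable = sorted((r for r in chain if r.seq_id <= 128),
                      key=lambda r: (r.seq_id, r.icode))
    letters = []
    for res in variable:
        letter = AA_3TO1.get(res.aa)
        if letter is None:
            logger.warning("%s/%s residue %s: unmappable code %r dropped from "
                           "variable sequence", structure_id, domain,
                           res.label, res.aa)
            continue
        letters.append(letter)
    if not letters:
        raise ComputationError(
            f"{structure_id}/{domain}: no variable-domain residues (IMGT ID <= 128)")
    return VariableSequence(source=(structure_id, domain), sequence="".join(letters))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def sequence_identity(a: str, b: str,
                      aligner: Optional[Align.PairwiseAligner] = None) -> float:
    """Global-alignment identity: matched positions / shorter sequence length."""
    if aligner is None:
        aligner = _make_aligner()
    if a == b:
        return 1.0
    alignment = aligner.align(a, b)[0]
    identities = alignment.counts().identities
    return identities / min(len(a), len(b))


def cluster_sequences(seqs: Sequence[VariableSequence],
                      threshold: float = 0.95) -> ClusterAssignment:
    """Greedy longest-first clustering at the given identity threshold.

    Sequences are visited by descending length (ties by source for
    determinism); each joins the first existing cluster whose representative
    is at least ``threshold`` identical (inclusive), else founds a new
    cluster.  VH and VL populations must be clustered in separate calls.
    """
    if not seqs:
        raise ComputationError("cluster_sequences: empty input")
    aligner = _make_aligner()
    order = sorted(seqs, key=lambda s: (-len(s.sequence), s.source))
    reps: List[str] = []
    mapping: Dict[Source, int] = {}
    for seq in order:
        assigned = None
        for ci, rep in enumerate(reps):
            if sequence_identity(seq.sequence, rep, aligner) >= threshold:
                assigned = ci
                break
        if assigned is None:
            assigned = len(reps)
            reps.append(seq.sequence)
        mapping[seq.source] = assigned
    return ClusterAssignment(mapping=mapping, threshold=threshold,
                             representatives=dict(enumerate(reps)))


def _family_key(cx: AbAgComplex, vh: ClusterAssignment, vl: ClusterAssignment):
    domains = cx.domains
    sid = cx.structure_id
    if domains == ["VH", "VL"]:
        try:
            return ("Fv", vh.mapping[(sid, "VH")], vl.mapping[(sid, "VL")])
        except KeyError as exc:
            raise AbInterfaceError(f"{sid}: domain missing from cluster "
                                   f"assignment: {exc}") from exc
    if domains == ["VH"]:
        if (sid, "VH") not in vh.mapping:
            raise AbInterfaceError(f"{sid}: VH missing from cluster assignment")
        return ("VH", vh.mapping[(sid, "VH")])
    if domains == ["VL"]:
        if (sid, "VL") not in vl.mapping:
            raise AbInterfaceError(f"{sid}: VL missing from cluster assignment")
        return ("VL", vl.mapping[(sid, "VL")])
    raise AbInterfaceError(f"{sid}: unexpected domain set {domains}")


def remove_redundant(complexes: Sequence[AbAgComplex],
                     vh_clusters: ClusterAssignment,
                     vl_clusters: ClusterAssignment
                     ) -> Tuple[List[AbAgComplex], Dict[tuple, List[str]]]:
    """Keep one representative per redundancy family.

    A family is a set of complexes whose antibody chains all fall in the same
    clusters: same VH cluster and, for Fv antibodies, the same VL cluster.
    Fv antibodies sharing only one chain's cluster (e.g. common-light-chain
    antibodies) are not duplicates; Fv and sdAb complexes never share a
    family.  The representative is the complex with the best (numerically
    lowest) resolution, then the lowest mean B-factor, then the
    lexicographically smallest structure ID.

    Returns ``(survivors, families)`` with families keyed by cluster tuple.
    """
    families: Dict[tuple, List[AbAgComplex]] = {}
    for cx in complexes:
        families.setdefault(_family_key(cx, vh_clusters, vl_clusters), []).append(cx)

    def keep_rank(cx: AbAgComplex):
        return (cx.annotation.resolution, mean_bfactor(cx).mean_b, cx.structure_id)

    survivors: List[AbAgComplex] = []
    family_ids: Dict[tuple, List[str]] = {}
    for key, members in families.items():
        family_ids[key] = sorted(m.structure_id for m in members)
        winner = min(members, key=keep_rank)
        survivors.append(winner)
        if len(members) > 1:
            logger.info("redundancy family %s: kept %s of %s", key,
                        winner.structure_id, family_ids[key])
    # preserve the input order of the survivors
    kept_ids = {id(cx) for cx in survivors}
    ordered = [cx for cx in complexes if id(cx) in kept_ids]
    return ordered, family_ids


# --- interoperability with an external clusterer -----------------------------

def write_fasta(seqs: Sequence[VariableSequence], path) -> None:
    """Export variable-domain sequences, one record per structure/domain."""
    with open(path, "wt", encoding="utf-8") as fh:
        for seq in seqs:
            fh.write(f">{seq.source[0]}_{seq.source[1]}\n{seq.sequence}\n")


def read_cdhit_clusters(path) -> Dict[Source, int]:
    """Parse a CD-HIT ``.clstr`` file into a source -> cluster-index mapping."""
    mapping: Dict[Source, int] = {}
    cluster = -1
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">Cluster"):
                cluster = int(line.split()[-1])
            elif line:
                name = line.split(">", 1)[1].split("...", 1)[0]
                sid, dom = name.rsplit("_", 1)
                mapping[(sid, dom)] = cluster
    return mapping
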